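import numpy as np
import pytest

from caninefc.prep import compute_fd
from caninefc.synthgen import (
    CohortConfig,
    CoreEdge,
    PeripheryEdge,
    build_target_fc,
    default_config,
    generate_behavior,
    generate_cohort,
    generate_motion,
    generate_timeseries,
    nearest_correlation,
    null_config,
)


class TestConfig:
    def test_defaults_validate(self):
        default_config().validate()
        null_config().validate()

    def test_overlapping_edge_lists_rejected(self):
        cfg = CohortConfig(
            periphery_edges=(PeripheryEdge(0, 1),), core_edges=(CoreEdge(0, 1),)
        )
        with pytest.raises(ValueError, match="disjoint"):
            cfg.validate()

    def test_bad_edge_indices_rejected(self):
        with pytest.raises(ValueError, match="n_regions"):
            CohortConfig(n_regions=5, core_edges=(CoreEdge(3, 7),)).validate()

    def test_tiny_cohort_rejected(self):
        with pytest.raises(ValueError, match="4 dogs"):
            CohortConfig(n_success=1, n_fail=2).validate()


class TestBehavior:
    def test_subscores_in_range_and_ibs_is_sum(self):
        b = generate_behavior(default_config(), np.random.default_rng(0))
        for col in ("retrieve", "hunt", "environment"):
            assert b[col].between(1, 5).all()
        assert (b["ibs"] == b["retrieve"] + b["hunt"] + b["environment"]).all()
        assert b["ibs"].between(3, 15).all()

    def test_zero_gain_zero_noise_constant(self):
        cfg = CohortConfig(
            behavior_gain_mean=0.0,
            behavior_gain_sd=0.0,
            behavior_subscore_sd=0.0,
            behavior_maintain_sd=0.0,
            group_behavior_d=0.0,
        )
        b = generate_behavior(cfg, np.random.default_rng(1))
        wide = b.pivot(index="dog_id", columns="timepoint", values="ibs")
        assert (wide.nunique(axis=1) == 1).all()

    def test_gain_mean_recovered_large_cohort(self):
        cfg = CohortConfig(n_success=500, n_fail=500, behavior_gain_mean=3.0,
                           behavior_gain_sd=1.0)
        b = generate_behavior(cfg, np.random.default_rng(2))
        wide = b.pivot(index="dog_id", columns="timepoint", values="ibs")
        gain = (wide["TP2"] - wide["TP1"]).mean()
        assert gain == pytest.approx(3.0, abs=0.1)

    def test_successful_dogs_higher_mean(self):
        cfg = CohortConfig(n_success=300, n_fail=300, group_behavior_d=0.8)
        b = generate_behavior(cfg, np.random.default_rng(3))
        tp1 = b[b["timepoint"] == "TP1"].set_index("dog_id")["ibs"]
        succ = tp1.iloc[:300].mean()
        fail = tp1.iloc[300:].mean()
        assert succ > fail

    def test_impossible_gain_rejected(self):
        cfg = CohortConfig(behavior_gain_mean=30.0)
        with pytest.raises(ValueError, match="outside"):
            generate_behavior(cfg, np.random.default_rng(4))

    def test_plateau_tp2_tp3(self):
        cfg = CohortConfig(n_success=500, n_fail=500)
        b = generate_behavior(cfg, np.random.default_rng(5))
        wide = b.pivot(index="dog_id", columns="timepoint", values="ibs")
        assert abs((wide["TP3"] - wide["TP2"]).mean()) < 0.15


class TestTargetFc:
    def test_no_edges_zero_noise_identity(self):
        cfg = CohortConfig(noise_sd=0.0, periphery_edges=(), core_edges=())
        target = build_target_fc(cfg, rng=np.random.default_rng(0))
        np.testing.assert_array_equal(target, np.eye(cfg.n_regions))

    def test_psd_input_is_fixed_point(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(10, 10))
        c = np.corrcoef(a)  # already a PSD correlation matrix
        repaired = nearest_correlation(c)
        np.testing.assert_allclose(repaired, c, atol=1e-12)

    def test_core_offset_monte_carlo_target_scale(self):
        # literal offset semantics: d * noise_sd on the target matrix
        cfg = CohortConfig(
            n_success=13, n_fail=17, noise_sd=0.1,
            core_edges=(CoreEdge(10, 11, group_effect_d=1.5),),
            periphery_edges=(), effect_scale="target",
        )
        rng = np.random.default_rng(2)
        diffs = []
        for _ in range(500):
            base = np.eye(cfg.n_regions)
            with_offset = build_target_fc(cfg, baseline=base, offsets_z={(10, 11): 0.15})
            without = build_target_fc(cfg, baseline=base)
            diffs.append(with_offset[10, 11] - without[10, 11])
        assert np.mean(diffs) == pytest.approx(np.tanh(0.15), abs=0.01)

    def test_output_is_correlation_matrix(self):
        cfg = default_config()
        rng = np.random.default_rng(3)
        target = build_target_fc(cfg, rng=rng, offsets_z={(0, 1): 0.5, (2, 3): -0.4})
        np.testing.assert_allclose(np.diag(target), 1.0)
        np.testing.assert_allclose(target, target.T)
        assert np.linalg.eigvalsh(target).min() > -1e-7

    def test_requested_offsets_survive_psd_repair(self):
        cfg = default_config()
        rng = np.random.default_rng(4)
        from caninefc.synthgen import _factor_baseline

        base = _factor_baseline(cfg, rng)
        offsets = {(0, 1): 0.45, (2, 3): 0.45, (4, 5): 0.45}
        target = build_target_fc(cfg, baseline=base, offsets_z=offsets)
        for (i, j), dz in offsets.items():
            achieved = np.arctanh(target[i, j]) - np.arctanh(np.clip(base[i, j], -0.995, 0.995))
            assert achieved == pytest.approx(dz, abs=2e-3)


class TestTimeseries:
    def test_output_dimensions(self):
        ts = generate_timeseries(np.eye(6), 50, np.random.default_rng(0))
        assert ts.samples.shape == (50, 6)

    def test_identity_target_uncorrelated(self):
        ts = generate_timeseries(np.eye(8), 200, np.random.default_rng(1))
        r = np.corrcoef(ts.samples, rowvar=False)
        off = np.abs(r[~np.eye(8, dtype=bool)])
        assert off.mean() < 3 / np.sqrt(199)

    def test_strong_edge_converges(self):
        target = np.eye(2)
        target[0, 1] = target[1, 0] = 0.8
        ts = generate_timeseries(target, 100_000, np.random.default_rng(2))
        r = np.corrcoef(ts.samples, rowvar=False)[0, 1]
        assert r == pytest.approx(0.8, abs=0.01)

    def test_non_psd_rejected(self):
        bad = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99], [-0.99, 0.99, 1.0]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            generate_timeseries(bad, 50, np.random.default_rng(3))

    def test_ar1_preserves_cross_correlation(self):
        target = np.eye(2)
        target[0, 1] = target[1, 0] = 0.6
        ts = generate_timeseries(target, 50_000, np.random.default_rng(4), ar_coeff=0.5)
        r = np.corrcoef(ts.samples, rowvar=False)[0, 1]
        assert r == pytest.approx(0.6, abs=0.02)
        lag1 = np.corrcoef(ts.samples[:-1, 0], ts.samples[1:, 0])[0, 1]
        assert lag1 == pytest.approx(0.5, abs=0.02)


class TestMotion:
    def test_no_spikes_fd_below_drift_bound(self):
        m = generate_motion(500, 0.0, 0.5, np.random.default_rng(0))
        fd = compute_fd(m)
        assert fd.fd.max() < 0.01

    def test_all_spikes_all_flagged(self):
        m = generate_motion(100, 1.0, 0.5, np.random.default_rng(1))
        fd = compute_fd(m)
        assert fd.flagged()[1:].all()

    def test_flag_fraction_binomial(self):
        m = generate_motion(10_000, 0.1, 0.5, np.random.default_rng(2))
        fd = compute_fd(m)
        assert fd.flagged().mean() == pytest.approx(0.1, abs=0.01)


class TestCohort:
    def test_bit_identical_reproducibility(self):
        a = generate_cohort(default_config(seed=11))
        b = generate_cohort(default_config(seed=11))
        assert a.manifest.equals(b.manifest)
        assert a.behavior.equals(b.behavior)
        assert a.truth == b.truth
        for key in a.runs:
            np.testing.assert_array_equal(a.runs[key].samples, b.runs[key].samples)
            np.testing.assert_array_equal(
                a.motion[key].as_matrix(), b.motion[key].as_matrix()
            )

    def test_every_dog_has_all_runs(self):
        cohort = generate_cohort(null_config(seed=1))
        cfg = cohort.config
        assert len(cohort.runs) == cfg.n_dogs * cfg.n_timepoints * cfg.runs_per_tp

    def test_truth_records_configured_edges(self):
        cohort = generate_cohort(default_config(seed=2))
        planted = {(e["i"], e["j"]) for e in cohort.truth["core_edges"]}
        assert planted == {(e.i, e.j) for e in default_config().core_edges}

    def test_planted_coupling_recovered(self, default_table_cohort):
        # empirical corr(dFC, dIBS) on planted periphery edges falls in the
        # n=30 Fisher 95% band around the configured coupling
        table, cohort = default_table_cohort
        ibs = (
            cohort.behavior.pivot(index="dog_id", columns="timepoint", values="ibs")
            .loc[table.dog_ids]
        )
        dibs = (ibs["TP2"] - ibs["TP1"]).to_numpy(float)
        dfc = table.values[:, 1, :] - table.values[:, 0, :]
        n = len(table.dog_ids)
        half_width = 1.96 / np.sqrt(n - 3)
        lo, hi = np.tanh(np.arctanh(0.8) - half_width), np.tanh(np.arctanh(0.8) + half_width)
        for e in cohort.config.periphery_edges:
            k = int(np.flatnonzero((table.edges[:, 0] == e.i) & (table.edges[:, 1] == e.j))[0])
            r = np.corrcoef(dfc[:, k], dibs)[0, 1]
            assert lo <= r <= hi
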