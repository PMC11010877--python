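import numpy as np
import pandas as pd
import pytest

from caninefc.connectivity import EdgeTable, edge_index
from caninefc.periphery import (
    PeripheryCriteria,
    _bh_qvalues,
    correlate_delta,
    delta_across_timepoints,
    paired_change_test,
    periphery_mask,
    select_periphery,
)


def _table(values, n_regions=4):
    values = np.asarray(values, dtype=float)
    dogs = [f"dog{d:02d}" for d in range(values.shape[0])]
    tps = ["TP1", "TP2", "TP3"][: values.shape[1]]
    return EdgeTable(
        dog_ids=dogs,
        timepoints=tps,
        edges=edge_index(n_regions),
        values=values,
        region_labels=[f"R{i}" for i in range(n_regions)],
    )


def _behavior(ibs_by_tp):
    """ibs_by_tp: dict timepoint -> array of per-dog IBS."""
    rows = []
    for tp, vals in ibs_by_tp.items():
        for d, v in enumerate(vals):
            rows.append({"dog_id": f"dog{d:02d}", "timepoint": tp, "ibs": v})
    return pd.DataFrame(rows)


class TestDelta:
    def test_identical_fc_zero_delta(self):
        v = np.tile(np.arange(6.0), (5, 3, 1))
        table = _table(v)
        behavior = _behavior({"TP1": [5] * 5, "TP2": [9] * 5})
        dfc, dibs, dogs = delta_across_timepoints(table, behavior, "TP1", "TP2")
        np.testing.assert_array_equal(dfc, 0.0)
        np.testing.assert_array_equal(dibs, 4.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        table = _table(rng.normal(size=(6, 3, 6)))
        behavior = _behavior({"TP1": [9, 8, 7, 10, 11, 9], "TP2": [13, 12, 10, 14, 13, 12]})
        a_fc, a_ibs, _ = delta_across_timepoints(table, behavior, "TP1", "TP2")
        b_fc, b_ibs, _ = delta_across_timepoints(table, behavior, "TP2", "TP1")
        np.testing.assert_allclose(a_fc, -b_fc)
        np.testing.assert_allclose(a_ibs, -b_ibs)

    def test_all_nan_dog_dropped(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(5, 3, 6))
        v[2, :, :] = np.nan
        behavior = _behavior({"TP1": [9] * 5, "TP2": [12, 13, 11, 14, 10]})
        dfc, dibs, dogs = delta_across_timepoints(_table(v), behavior, "TP1", "TP2")
        assert "dog02" not in dogs and len(dogs) == 4


class TestCorrelateDelta:
    def test_proportional_gives_r_one(self):
        dibs = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        dfc = np.column_stack([2.0 * dibs, -0.5 * dibs])
        r, p = correlate_delta(dfc, dibs)
        np.testing.assert_allclose(r, [1.0, -1.0])
        np.testing.assert_allclose(p, 0.0, atol=1e-12)

    def test_matches_scipy_pearson(self):
        from scipy import stats

        rng = np.random.default_rng(2)
        dfc = rng.normal(size=(12, 5))
        dibs = rng.normal(size=12)
        r, p = correlate_delta(dfc, dibs)
        for k in range(5):
            rr, pp = stats.pearsonr(dfc[:, k], dibs)
            assert r[k] == pytest.approx(rr)
            assert p[k] == pytest.approx(pp)

    def test_zero_behavior_spread_sets_p_one(self):
        dfc = np.random.default_rng(3).normal(size=(8, 4))
        with pytest.warns(RuntimeWarning, match="spread"):
            r, p = correlate_delta(dfc, np.zeros(8))
        np.testing.assert_array_equal(p, 1.0)

    def test_too_few_dogs_rejected(self):
        with pytest.raises(ValueError, match="4 dogs"):
            correlate_delta(np.zeros((3, 2)), np.arange(3.0))

    def test_spearman_option(self):
        from scipy import stats

        rng = np.random.default_rng(4)
        dfc = rng.normal(size=(10, 3))
        dibs = rng.normal(size=10)
        r, p = correlate_delta(dfc, dibs, method="spearman")
        for k in range(3):
            rr, _ = stats.spearmanr(dfc[:, k], dibs)
            assert r[k] == pytest.approx(rr)


class TestPairedChange:
    def test_no_change_p_one(self):
        v = np.tile(np.random.default_rng(5).normal(size=6), (5, 3, 1))
        p, mean = paired_change_test(_table(v), "TP1", "TP2")
        np.testing.assert_array_equal(p, 1.0)
        np.testing.assert_array_equal(mean, 0.0)

    def test_constant_shift_degenerate_rule(self):
        v = np.tile(np.random.default_rng(6).normal(size=6), (5, 3, 1))
        v[:, 1, :] += 1.0
        with pytest.warns(RuntimeWarning, match="zero within-pair"):
            p, mean = paired_change_test(_table(v), "TP1", "TP2")
        np.testing.assert_array_equal(p, 0.0)
        np.testing.assert_allclose(mean, 1.0)

    def test_matches_scipy_ttest_rel(self):
        from scipy import stats

        rng = np.random.default_rng(7)
        v = rng.normal(size=(10, 3, 6))
        p, mean = paired_change_test(_table(v), "TP1", "TP2")
        ref = stats.ttest_rel(v[:, 1, :], v[:, 0, :], axis=0)
        np.testing.assert_allclose(p, ref.pvalue, atol=1e-12)

    def test_null_calibration_small(self):
        rng = np.random.default_rng(8)
        v = rng.normal(size=(24, 3, 780))
        p, _ = paired_change_test(_table(v, n_regions=40), "TP1", "TP2")
        assert (p < 0.05).mean() == pytest.approx(0.05, abs=0.02)


class TestSelection:
    def _planted_table(self, rho=0.95, n=24, seed=9):
        """One strongly coupled rising edge (index 0) among 6 edges."""
        rng = np.random.default_rng(seed)
        dibs = rng.normal(4.0, 1.5, size=n)
        v = rng.normal(0.0, 0.3, size=(n, 3, 6))
        inc = 0.6 + 0.25 * (dibs - dibs.mean()) / dibs.std()
        v[:, 1, 0] = v[:, 0, 0] + inc + rng.normal(0, 0.05, size=n)
        v[:, 2, 0] = v[:, 1, 0] + rng.normal(0, 0.05, size=n)
        behavior = _behavior({
            "TP1": np.full(n, 8.0), "TP2": 8.0 + dibs, "TP3": 8.0 + dibs,
        })
        return _table(v), behavior

    def test_planted_edge_selected(self):
        table, behavior = self._planted_table()
        stats_table = select_periphery(table, behavior, PeripheryCriteria())
        assert bool(stats_table.loc[0, "selected"])

    def test_maintenance_criterion_blocks_growth(self):
        table, behavior = self._planted_table()
        # make edge 0 keep growing strongly TP2 -> TP3
        table.values[:, 2, 0] = table.values[:, 1, 0] + 1.0 + \
            np.random.default_rng(1).normal(0, 0.05, size=table.values.shape[0])
        stats_table = select_periphery(table, behavior, PeripheryCriteria())
        assert not bool(stats_table.loc[0, "selected"])
        assert stats_table.loc[0, "p_change_tp2_tp3"] < 0.05

    def test_decreasing_edge_not_selected(self):
        table, behavior = self._planted_table()
        table.values[:, 1, 0] = table.values[:, 0, 0] - (
            table.values[:, 1, 0] - table.values[:, 0, 0]
        )
        stats_table = select_periphery(table, behavior, PeripheryCriteria())
        assert not bool(stats_table.loc[0, "selected"])

    def test_strict_mode_is_subset(self):
        table, behavior = self._planted_table()
        lax = select_periphery(table, behavior, PeripheryCriteria(strict=False))
        strict = select_periphery(table, behavior, PeripheryCriteria(strict=True))
        assert set(strict.index[strict["selected"]]) <= set(lax.index[lax["selected"]])

    def test_mask_agrees_with_full_table(self):
        rng = np.random.default_rng(10)
        table, behavior = self._planted_table()
        ibs = (
            behavior.pivot(index="dog_id", columns="timepoint", values="ibs")
            .loc[table.dog_ids, ["TP1", "TP2", "TP3"]]
            .to_numpy(float)
        )
        mask = periphery_mask(table.values, ibs)
        stats_table = select_periphery(table, behavior, PeripheryCriteria())
        np.testing.assert_array_equal(mask, stats_table["selected"].to_numpy())

    def test_one_sided_flag_is_laxer(self):
        rng = np.random.default_rng(11)
        v = rng.normal(size=(24, 3, 780))
        v[:, 1, :] += 0.05  # weak broad increase
        table = _table(v, n_regions=40)
        dibs = rng.normal(size=24)
        behavior = _behavior({"TP1": np.full(24, 9.0), "TP2": 9.0 + dibs,
                              "TP3": 9.0 + dibs})
        two = select_periphery(table, behavior, PeripheryCriteria())["selected"].sum()
        one = select_periphery(
            table, behavior, PeripheryCriteria(one_sided_increase=True)
        )["selected"].sum()
        assert one >= two


class TestBhQvalues:
    def test_monotone_and_bounded(self):
        p = np.array([0.001, 0.01, 0.2, 0.8, 0.04])
        q = _bh_qvalues(p)
        assert np.all((q >= p - 1e-15) & (q <= 1.0))
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_all_null_uniform_qs_large(self):
        q = _bh_qvalues(np.linspace(0.05, 1.0, 20))
        assert q.min() > 0.5
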