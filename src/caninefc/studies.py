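"""Simulation studies: calibration, recovery, and robustness checks.

These are the package's own quality-control experiments, shared by the test
suite and the acceptance script.  Each study generates synthetic cohorts,
pushes them through the real preprocessing + analysis chain, and reports
summary rates:

* ``null_calibration`` -- false-positive rates of the periphery and core
  selectors on fully null cohorts (p-value calibration);
* ``null_auc_study`` -- pooled classifier AUCs on null cohorts under nested
  (unbiased) feature selection, which should sit at chance;
* ``recovery_study`` -- sensitivity / false-edge rate for planted periphery
  and core networks;
* ``auc_study`` -- the qualitative AUC ordering core > periphery > chance on
  cohorts with planted effects;
* ``fingerprint_permutation_study`` -- label-permutation recovery and noise
  robustness of region matching;
* ``label_permutation_destroys_core`` / ``timepoint_permutation_destroys_periphery``
  -- planted signals vanish under the appropriate exchangeability permutation.

Replicate counts are sized so that binomial/standard errors are small against
the tolerance being checked (see docs/methods.md); they are configuration, not
tuning knobs.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np

from .connectivity import EdgeTable, FcMatrix
from .core_classify import _core_mask, compare_feature_sets, encode_labels, select_core
from .homology import build_fingerprint, match_regions
from .periphery import PeripheryCriteria, periphery_mask, select_periphery
from .pipeline import process_cohort
from .prep import PrepSettings
from .synthgen import (
    CohortConfig,
    default_config,
    generate_cohort,
    null_config,
    periphery_study_config,
)

__all__ = [
    "auc_bruteforce",
    "cohort_edge_table",
    "null_calibration",
    "null_auc_study",
    "recovery_study",
    "auc_study",
    "fingerprint_permutation_study",
    "label_permutation_destroys_core",
    "permuted_label_auc_study",
    "timepoint_permutation_destroys_periphery",
]


def auc_bruteforce(scores: np.ndarray, y: np.ndarray) -> float:
    """Concordant-pair AUC with half credit for ties (Mann-Whitney oracle)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=bool)
    pos = scores[y]
    neg = scores[~y]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need both classes")
    diff = pos[:, None] - neg[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / (pos.size * neg.size))


def cohort_edge_table(config: CohortConfig, settings: PrepSettings = PrepSettings()):
    """Generate one cohort and run it through prep + FC; returns (table, cohort)."""
    cohort = generate_cohort(config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        table = process_cohort(cohort, settings)
    return table, cohort


def _ibs_matrix(cohort, table: EdgeTable) -> np.ndarray:
    return (
        cohort.behavior.pivot(index="dog_id", columns="timepoint", values="ibs")
        .loc[table.dog_ids, list(table.timepoints)]
        .to_numpy(dtype=float)
    )


# ---------------------------------------------------------------------------
# null calibration
# ---------------------------------------------------------------------------

def null_calibration(
    seed: int = 0,
    n_cohorts: int = 13,
    alpha_periphery: float = 0.05,
    alpha_core: float = 0.01,
) -> dict:
    """False-positive rates of all selectors on fully null cohorts.

    Pools edges across ``n_cohorts`` independent 24-dog null cohorts (780
    edges each; 13 cohorts give 10,140 edge tests).  Reports the rejection
    rate of the delta-delta correlation alone, the full periphery conjunction
    rate, and the directional core-selection rate.
    """
    n_dd = n_peri = n_core = n_edges = 0
    for k in range(n_cohorts):
        table, cohort = cohort_edge_table(null_config(seed=seed + k))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            stats_table = select_periphery(
                table, cohort.behavior, PeripheryCriteria(alpha=alpha_periphery)
            )
            core = select_core(table, cohort.labels(), "TP1", alpha=alpha_core)
        n_edges += table.n_edges
        n_dd += int((stats_table["p_delta"] < alpha_periphery).sum())
        n_peri += int(stats_table["selected"].sum())
        n_core += int(core.sum())
    return {
        "n_edges": n_edges,
        "delta_delta_rejection_rate": n_dd / n_edges,
        "periphery_selection_rate": n_peri / n_edges,
        "core_selection_rate": n_core / n_edges,
    }


def null_auc_study(
    seed: int = 0,
    n_cohorts: int = 48,
    n_iterations: int = 200,
) -> dict:
    """Mean pooled classifier AUC per feature set on null cohorts.

    Feature selection runs in nested mode (re-selected inside every training
    fold), which is the unbiased estimator; under the null every AUC has
    expectation 0.5.  A single cohort's pooled AUC retains cohort-level chance
    association (measured sd ~ 0.12 at 24 dogs), so the study averages across
    cohorts; 48 cohorts put the standard error of the mean near 0.018, small
    against a +/- 0.05 check band.
    """
    sums = {"behavior_ibs": 0.0, "periphery_fc_tp1": 0.0, "core_fc_tp1": 0.0}
    total_iterations = 0
    for k in range(n_cohorts):
        table, cohort = cohort_edge_table(null_config(seed=seed + 10_000 + k))
        rng = np.random.default_rng(seed + 20_000 + k)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            results = compare_feature_sets(
                table, cohort.behavior, cohort.labels(),
                mode="nested", n_iterations=n_iterations, rng=rng,
            )
        for name, res in results.items():
            sums[name] += res.auc
        total_iterations += n_iterations
    return {
        "n_cohorts": n_cohorts,
        "n_iterations_total": total_iterations,
        "auc": {name: s / n_cohorts for name, s in sums.items()},
    }


# ---------------------------------------------------------------------------
# planted-network recovery
# ---------------------------------------------------------------------------

def _recovery_rates(selected: np.ndarray, planted: set[tuple[int, int]],
                    edges: np.ndarray) -> tuple[float, float]:
    """(sensitivity, false-positive rate among non-planted edges)."""
    is_planted = np.array([(i, j) in planted for i, j in edges])
    sens = float(selected[is_planted].mean()) if is_planted.any() else float("nan")
    fpr = float(selected[~is_planted].mean()) if (~is_planted).any() else float("nan")
    return sens, fpr


def recovery_study(seed: int = 0, n_replicates: int = 100) -> dict:
    """Sensitivity and false-edge rates for planted periphery and core edges.

    Per replicate, one periphery cohort (24 dogs, 5 coupled edges) and one
    core cohort (13 successful / 17 non-successful dogs, 7 offset edges) are
    generated and analysed end to end.  The false rate is the per-replicate
    selection rate among non-planted edges, averaged across replicates.
    """
    peri_sens, peri_fpr, core_sens, core_fpr = [], [], [], []
    for r in range(n_replicates):
        table, cohort = cohort_edge_table(periphery_study_config(seed=seed + r))
        planted = {(e.i, e.j) for e in cohort.config.periphery_edges}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            stats_table = select_periphery(table, cohort.behavior, PeripheryCriteria())
        s, f = _recovery_rates(stats_table["selected"].to_numpy(), planted, table.edges)
        peri_sens.append(s)
        peri_fpr.append(f)

        table, cohort = cohort_edge_table(default_config(seed=seed + 100_000 + r))
        planted = {(e.i, e.j) for e in cohort.config.core_edges}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            core = select_core(table, cohort.labels(), "TP1", alpha=0.01)
        s, f = _recovery_rates(core, planted, table.edges)
        core_sens.append(s)
        core_fpr.append(f)
    return {
        "n_replicates": n_replicates,
        "periphery_sensitivity": float(np.mean(peri_sens)),
        "periphery_false_edge_rate": float(np.mean(peri_fpr)),
        "core_sensitivity": float(np.mean(core_sens)),
        "core_false_edge_rate": float(np.mean(core_fpr)),
    }


def auc_study(seed: int = 0, n_cohorts: int = 8, n_iterations: int = 500) -> dict:
    """Mean pooled AUC per feature set on cohorts with planted effects.

    Uses the historically faithful mode (features selected once on the whole
    cohort); the quantity of interest is the ordering
    core > periphery features > chance, plus the absolute core AUC.
    """
    sums = {"behavior_ibs": [], "periphery_fc_tp1": [], "core_fc_tp1": []}
    for k in range(n_cohorts):
        table, cohort = cohort_edge_table(default_config(seed=seed + 200_000 + k))
        rng = np.random.default_rng(seed + 300_000 + k)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            results = compare_feature_sets(
                table, cohort.behavior, cohort.labels(),
                mode="historical", n_iterations=n_iterations, rng=rng,
            )
        for name, res in results.items():
            if res.applicable:
                sums[name].append(res.auc)
    return {
        "n_cohorts": n_cohorts,
        "auc": {name: float(np.mean(v)) if v else float("nan") for name, v in sums.items()},
    }


# ---------------------------------------------------------------------------
# fingerprint matching
# ---------------------------------------------------------------------------

def _random_connectome(n: int, rng: np.random.Generator) -> np.ndarray:
    a = rng.normal(size=(n, n))
    c = np.corrcoef(a)
    np.fill_diagonal(c, 1.0)
    return c


def fingerprint_permutation_study(
    seed: int = 0,
    n_regions: int = 10,
    n_targets: int = 19,
    noise_levels: tuple[float, ...] = (0.0, 0.1, 0.3, 0.6, 1.0, 2.0),
    n_replicates: int = 20,
) -> dict:
    """Region matching against a label-permuted copy, over a noise grid.

    Cohort A is a random connectome extended with ``n_targets`` target
    regions; cohort B is the same connectome with its source regions permuted
    and Gaussian noise of the given sd added to every profile entry.  Reports
    the fraction of sources whose top match is their true counterpart at each
    noise level (averaged over replicates); at zero noise recovery is exact.
    """
    accuracies = []
    for noise in noise_levels:
        hits = trials = 0
        for rep in range(n_replicates):
            rng = np.random.default_rng(seed + 1000 * rep + int(noise * 997))
            total = n_regions + n_targets
            base = _random_connectome(total, rng)
            labels = [f"S{i:02d}" for i in range(n_regions)] + [
                f"T{k:02d}" for k in range(n_targets)
            ]
            fc_a = FcMatrix(values=base, scale="pearson_r", dog_id="A", timepoint="TP1",
                            region_labels=labels)
            targets = labels[n_regions:]
            perm = rng.permutation(n_regions)
            fps_a = [build_fingerprint(fc_a, labels[i], targets) for i in range(n_regions)]
            fps_b = []
            for i in perm:
                fp = build_fingerprint(fc_a, labels[i], targets)
                fp.profile = fp.profile + rng.normal(0.0, noise, size=fp.profile.shape)
                fps_b.append(fp)
            matches = match_regions(fps_a, fps_b, n_permutations=0, rng=rng)
            for m in matches:
                hits += m.best == m.source_region
                trials += 1
        accuracies.append(hits / trials)
    return {
        "noise_levels": list(noise_levels),
        "accuracy": accuracies,
        "exact_at_zero_noise": accuracies[0] == 1.0,
    }


# ---------------------------------------------------------------------------
# permutation destruction of planted signals
# ---------------------------------------------------------------------------

def label_permutation_destroys_core(seed: int = 0, n_permutations: int = 20) -> dict:
    """Core-selection rate after shuffling success labels on a planted cohort.

    With labels permuted the group offset is no longer aligned with the
    grouping, so the directional selection rate should revert to its null
    band.  One cohort, many label permutations (the expensive part -- prep --
    runs once).
    """
    table, cohort = cohort_edge_table(default_config(seed=seed))
    y = encode_labels(cohort.labels(), table.dog_ids)
    rng = np.random.default_rng(seed + 1)
    v_tp1 = table.values[:, table.tp_index("TP1"), :]
    rates = []
    for _ in range(n_permutations):
        yp = rng.permutation(y)
        mask = _core_mask(v_tp1, yp, alpha=0.01)
        mask &= np.nanmean(v_tp1[yp], axis=0) > np.nanmean(v_tp1[~yp], axis=0)
        rates.append(mask.mean())
    true_mask = _core_mask(v_tp1, y, alpha=0.01)
    true_mask &= np.nanmean(v_tp1[y], axis=0) > np.nanmean(v_tp1[~y], axis=0)
    return {
        "selection_rate_true_labels": float(true_mask.mean()),
        "selection_rate_permuted_mean": float(np.mean(rates)),
    }


def permuted_label_auc_study(
    seed: int = 0,
    n_cohorts: int = 16,
    n_iterations: int = 200,
) -> dict:
    """Mean nested-mode AUC on planted cohorts whose labels are shuffled.

    With success labels randomly reassigned, planted group structure no longer
    aligns with the classification target, so every feature set's AUC should
    revert toward 0.5.  A single cohort's pooled AUC has sd ~ 0.12, so the
    study averages across cohorts (se of the mean ~ 0.03 at 16 cohorts).
    """
    perm_rng = np.random.default_rng(seed + 400_000)
    sums = {"behavior_ibs": 0.0, "periphery_fc_tp1": 0.0, "core_fc_tp1": 0.0}
    for k in range(n_cohorts):
        table, cohort = cohort_edge_table(default_config(seed=seed + 500_000 + k))
        dogs = table.dog_ids
        labels = cohort.labels()
        values = [labels[d] for d in dogs]
        order = perm_rng.permutation(len(dogs))
        shuffled = {dogs[i]: values[order[i]] for i in range(len(dogs))}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            results = compare_feature_sets(
                table, cohort.behavior, shuffled,
                mode="nested", n_iterations=n_iterations,
                rng=np.random.default_rng(seed + 600_000 + k),
            )
        for name, res in results.items():
            sums[name] += res.auc
    return {
        "n_cohorts": n_cohorts,
        "auc": {name: s / n_cohorts for name, s in sums.items()},
    }


def timepoint_permutation_destroys_periphery(seed: int = 0, n_permutations: int = 20) -> dict:
    """Periphery-selection rate after permuting each dog's timepoints.

    Randomly reordering TP1/TP2/TP3 within each dog breaks the
    increase-then-maintain trajectory and its coupling to behavior change;
    the full conjunction rate should revert to its null band.
    """
    table, cohort = cohort_edge_table(periphery_study_config(seed=seed))
    ibs = _ibs_matrix(cohort, table)
    rng = np.random.default_rng(seed + 1)
    rates = []
    for _ in range(n_permutations):
        values = table.values.copy()
        for d in range(values.shape[0]):
            order = rng.permutation(values.shape[1])
            values[d] = values[d, order]
            # behavior trajectories stay as observed; only FC time order breaks
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            mask = periphery_mask(values, ibs)
        rates.append(mask.mean())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        true_mask = periphery_mask(table.values, ibs)
    return {
        "selection_rate_true_order": float(true_mask.mean()),
        "selection_rate_permuted_mean": float(np.mean(rates)),
    }
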