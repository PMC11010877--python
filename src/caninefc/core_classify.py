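"""Stable-core selection and trainability classification.

The core is the set of edges whose pre-training (TP1) connectivity is
significantly stronger in dogs that eventually succeed at detection training
than in dogs that do not (Welch two-sample t, two-sided p < 0.01, with the
successful-group mean required to be the larger).  Core stability is verified
post hoc: within each group, paired tests between every pair of timepoints
should all be non-significant.

Classification of eventual success from TP1 data uses L2-regularized logistic
regression evaluated by repeated class-stratified 75/25 train/test shuffles
(1000 iterations by default; a literal stratified 4-fold mode is available).
Test-set class-probability scores are pooled across iterations into a single
ROC curve and AUC; the per-iteration AUC mean is reported alongside.

Feature selection can run in two modes:

* ``"historical"``: edges are selected once on the full cohort before
  cross-validation.  This is the historical design being reproduced and is
  optimistic -- the test dogs inform the feature set.
* ``"nested"``: selection is recomputed inside every training fold, giving an
  unbiased estimate.  The gap between the two modes is itself a quantity of
  interest and is reported, never hidden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.preprocessing import StandardScaler

from .connectivity import EdgeTable
from .periphery import PeripheryCriteria, periphery_mask

__all__ = [
    "ClassifierResult",
    "group_difference_test",
    "select_core",
    "verify_core_stability",
    "logistic_train_predict",
    "roc_auc",
    "stratified_shuffle_eval",
    "compare_feature_sets",
]

POSITIVE_LABEL = "successful"


def encode_labels(labels: dict[str, str] | pd.DataFrame, dog_ids: list[str]) -> np.ndarray:
    """Boolean vector (successful = True) aligned to ``dog_ids``."""
    if isinstance(labels, pd.DataFrame):
        labels = dict(zip(labels["dog_id"], labels["label"]))
    y = np.array([labels[d] == POSITIVE_LABEL for d in dog_ids])
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    return y


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Welch t-test over columns -> (two-sided p, mean_a - mean_b)."""
    na, nb = a.shape[0], b.shape[0]
    ma, mb = np.nanmean(a, axis=0), np.nanmean(b, axis=0)
    va, vb = np.nanvar(a, axis=0, ddof=1), np.nanvar(b, axis=0, ddof=1)
    se2 = va / na + vb / nb
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df=np.where(np.isfinite(df) & (df > 0), df, 1.0))
    p = np.where(se2 == 0.0, np.nan, p)
    return p, ma - mb


def group_difference_test(
    edge_table: EdgeTable,
    labels: dict[str, str] | pd.DataFrame,
    timepoint: str = "TP1",
) -> pd.DataFrame:
    """Edge-wise Welch t-test between success groups at one timepoint.

    Returns per-edge two-sided p, the mean difference (successful minus
    non-successful), and whether the successful group is the stronger one.
    Degenerate zero-variance edges get NaN p and are excluded downstream with
    a warning.
    """
    y = encode_labels(labels, edge_table.dog_ids)
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need at least 2 dogs per group")
    v = edge_table.values[:, edge_table.tp_index(timepoint), :]
    p, diff = _welch(v[y], v[~y])
    if np.isnan(p).any():
        warnings.warn(
            f"{int(np.isnan(p).sum())} degenerate zero-variance edge(s) excluded",
            RuntimeWarning,
        )
    labels_ = edge_table.region_labels
    return pd.DataFrame(
        {
            "i": edge_table.edges[:, 0],
            "j": edge_table.edges[:, 1],
            "region_i": [labels_[i] for i in edge_table.edges[:, 0]],
            "region_j": [labels_[j] for j in edge_table.edges[:, 1]],
            "p": p,
            "mean_diff": diff,
            "stronger_in_successful": diff > 0,
        }
    )


def _core_mask(v_tp: np.ndarray, y: np.ndarray, alpha: float) -> np.ndarray:
    """Boolean core-selection mask on a dogs x E value matrix."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        p, diff = _welch(v_tp[y], v_tp[~y])
    return np.nan_to_num(p, nan=1.0) < alpha

def select_core(
    edge_table: EdgeTable,
    labels: dict[str, str] | pd.DataFrame,
    timepoint: str = "TP1",
    alpha: float = 0.01,
) -> np.ndarray:
    """Edges significantly *stronger* in the successful group (directional)."""
    table = group_difference_test(edge_table, labels, timepoint)
    p = table["p"].to_numpy()
    return (np.nan_to_num(p, nan=1.0) < alpha) & table["stronger_in_successful"].to_numpy()


def verify_core_stability(
    edge_table: EdgeTable,
    labels: dict[str, str] | pd.DataFrame,
    core_mask: np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Within-group paired tests across all timepoint pairs for core edges.

    An edge is flagged stable when none of the six tests (two groups x three
    timepoint pairs) is significant at ``alpha``.  Identical values across
    timepoints give p = 1 by the degenerate rule and therefore count as
    stable.
    """
    from .periphery import _paired_t

    y = encode_labels(labels, edge_table.dog_ids)
    core_idx = np.flatnonzero(np.asarray(core_mask, dtype=bool))
    tps = edge_table.timepoints
    pairs = [(a, b) for ai, a in enumerate(tps) for b in tps[ai + 1:]]
    rows: dict[str, np.ndarray] = {
        "i": edge_table.edges[core_idx, 0],
        "j": edge_table.edges[core_idx, 1],
    }
    stable = np.ones(core_idx.size, dtype=bool)
    for group, mask in (("successful", y), ("non_successful", ~y)):
        for a, b in pairs:
            d = (
                edge_table.values[mask][:, edge_table.tp_index(b), :][:, core_idx]
                - edge_table.values[mask][:, edge_table.tp_index(a), :][:, core_idx]
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=RuntimeWarning)
                p, _ = _paired_t(d, warn=False)
            rows[f"p_{group}_{a}_{b}"] = p
            stable &= p > alpha
    rows["stable"] = stable
    return pd.DataFrame(rows)


def logistic_train_predict(
    features: np.ndarray,
    y: np.ndarray,
    train_index: np.ndarray,
    test_index: np.ndarray,
    c_value: float = 1.0,
) -> np.ndarray:
    """Fit an L2 logistic model on the training dogs, score the test dogs.

    Features are standardized using training-set statistics only.  With an
    empty feature set the model degenerates to the training-class prior.
    Returns class-probability scores for the positive (successful) class.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim == 1:
        features = features[:, None]
    y = np.asarray(y, dtype=bool)
    train_index = np.asarray(train_index)
    test_index = np.asarray(test_index)
    if np.intersect1d(train_index, test_index).size:
        raise ValueError("train and test sets must be disjoint")
    y_train = y[train_index]
    if y_train.all() or not y_train.any():
        raise ValueError("training set must contain both classes")
    if features.shape[1] == 0:
        prior = y_train.mean()
        return np.full(test_index.size, prior)
    scaler = StandardScaler().fit(features[train_index])
    x_train = scaler.transform(features[train_index])
    x_test = scaler.transform(features[test_index])
    model = LogisticRegression(C=c_value, solver="lbfgs", max_iter=1000)
    model.fit(x_train, y_train)
    return model.predict_proba(x_test)[:, 1]


def roc_auc(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC by threshold sweep and trapezoidal AUC.

    Ties receive half credit, so the AUC equals the Mann-Whitney statistic
    U / (n_pos * n_neg).  Returns (fpr, tpr, auc).
    """
    y = np.asarray(y, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("ROC requires both classes")
    fpr, tpr, _ = roc_curve(y, scores, drop_intermediate=False)
    return fpr, tpr, float(sk_auc(fpr, tpr))


@dataclass
class ClassifierResult:
    """Pooled evaluation of one feature set."""

    feature_set_name: str
    applicable: bool
    auc: float
    mean_iteration_auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    n_iterations: int
    test_fraction: float
    mean_n_features: float
    pooled_scores: np.ndarray = field(repr=False, default=None)
    pooled_labels: np.ndarray = field(repr=False, default=None)

    def summary(self) -> dict:
        return {
            "feature_set": self.feature_set_name,
            "applicable": self.applicable,
            "auc_pooled": None if not self.applicable else round(self.auc, 6),
            "auc_mean_per_iteration": None if not self.applicable
            else round(self.mean_iteration_auc, 6),
            "n_iterations": self.n_iterations,
            "test_fraction": self.test_fraction,
            "mean_n_features": round(self.mean_n_features, 3),
        }


def _not_applicable(name: str, n_iterations: int, test_fraction: float) -> ClassifierResult:
    return ClassifierResult(
        feature_set_name=name,
        applicable=False,
        auc=float("nan"),
        mean_iteration_auc=float("nan"),
        fpr=np.array([0.0, 1.0]),
        tpr=np.array([0.0, 1.0]),
        n_iterations=n_iterations,
        test_fraction=test_fraction,
        mean_n_features=0.0,
    )


def stratified_shuffle_eval(
    features: np.ndarray | None,
    y: np.ndarray,
    n_iterations: int = 1000,
    test_fraction: float = 0.25,
    rng: np.random.Generator | None = None,
    feature_selector=None,
    feature_pool: np.ndarray | None = None,
    name: str = "features",
    split_mode: str = "shuffle",
    c_value: float = 1.0,
) -> ClassifierResult:
    """Repeated stratified 75/25 evaluation with pooled ROC/AUC.

    ``features`` is the fixed dogs x E feature matrix; alternatively pass a
    ``feature_pool`` (dogs x E candidates) together with a
    ``feature_selector(train_index) -> boolean column mask`` for nested
    per-fold selection.  ``split_mode="kfold"`` swaps the shuffles for
    repeated stratified 4-fold cross-validation (25% test folds).
    """
    y = np.asarray(y, dtype=bool)
    rng = rng or np.random.default_rng()
    seed = int(rng.integers(0, 2**31 - 1))
    n = y.size
    if feature_selector is None:
        if features is None:
            raise ValueError("need features or a feature_selector")
        features = np.asarray(features, dtype=float)
        if features.ndim == 1:
            features = features[:, None]
        if features.shape[1] == 0:
            return _not_applicable(name, n_iterations, test_fraction)
    if split_mode == "shuffle":
        splitter = StratifiedShuffleSplit(
            n_splits=n_iterations, test_size=test_fraction, random_state=seed
        )
        splits = splitter.split(np.zeros(n), y)
    elif split_mode == "kfold":
        k = max(int(round(1.0 / test_fraction)), 2)
        n_repeats = max(n_iterations // k, 1)
        def _kfold_splits():
            for rep in range(n_repeats):
                kf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + rep)
                yield from kf.split(np.zeros(n), y)
        splits = _kfold_splits()
    else:
        raise ValueError(f"unknown split mode {split_mode!r}")

    pooled_scores, pooled_labels, iter_aucs, n_feats = [], [], [], []
    n_done = 0
    for train_idx, test_idx in splits:
        if feature_selector is not None:
            cols = np.asarray(feature_selector(train_idx))
            if cols.dtype == bool:
                cols = np.flatnonzero(cols)
            x = feature_pool[:, cols] if cols.size else np.empty((n, 0))
        else:
            x = features
        n_feats.append(x.shape[1])
        scores = logistic_train_predict(x, y, train_idx, test_idx, c_value=c_value)
        pooled_scores.append(scores)
        pooled_labels.append(y[test_idx])
        yt = y[test_idx]
        if yt.any() and not yt.all():
            if np.ptp(scores) > 0:
                _, _, a = roc_auc(scores, yt)
            else:
                a = 0.5
            iter_aucs.append(a)
        n_done += 1
    pooled_scores = np.concatenate(pooled_scores)
    pooled_labels = np.concatenate(pooled_labels)
    fpr, tpr, pooled_auc = roc_auc(pooled_scores, pooled_labels)
    return ClassifierResult(
        feature_set_name=name,
        applicable=True,
        auc=pooled_auc,
        mean_iteration_auc=float(np.mean(iter_aucs)) if iter_aucs else float("nan"),
        fpr=fpr,
        tpr=tpr,
        n_iterations=n_done,
        test_fraction=test_fraction,
        mean_n_features=float(np.mean(n_feats)),
        pooled_scores=pooled_scores,
        pooled_labels=pooled_labels,
    )


def compare_feature_sets(
    edge_table: EdgeTable,
    behavior: pd.DataFrame,
    labels: dict[str, str] | pd.DataFrame,
    mode: str = "historical",
    n_iterations: int = 1000,
    test_fraction: float = 0.25,
    rng: np.random.Generator | None = None,
    alpha_core: float = 0.01,
    periphery_criteria: PeripheryCriteria = PeripheryCriteria(),
    split_mode: str = "shuffle",
) -> dict[str, ClassifierResult]:
    """Evaluate the three feature sets: behavior, periphery FC, core FC at TP1.

    ``mode="historical"`` selects periphery/core edges once on the whole
    cohort before cross-validation; ``mode="nested"`` re-selects them inside
    every training fold.  Returns results keyed by feature-set name.
    """
    if mode not in ("historical", "nested"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = rng or np.random.default_rng()
    y = encode_labels(labels, edge_table.dog_ids)
    t1 = edge_table.tp_index("TP1")
    v_tp1 = np.nan_to_num(edge_table.values[:, t1, :], nan=0.0)
    ibs = (
        behavior.pivot(index="dog_id", columns="timepoint", values="ibs")
        .loc[edge_table.dog_ids, list(edge_table.timepoints)]
        .to_numpy(dtype=float)
    )
    values = np.nan_to_num(edge_table.values, nan=0.0)

    results: dict[str, ClassifierResult] = {}
    results["behavior_ibs"] = stratified_shuffle_eval(
        ibs[:, 0:1], y, n_iterations, test_fraction, rng, name="behavior_ibs",
        split_mode=split_mode,
    )

    if mode == "historical":
        from .periphery import periphery_mask as _pm

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            peri = _pm(values, ibs, alpha=periphery_criteria.alpha,
                       one_sided_increase=periphery_criteria.one_sided_increase)
            core = _core_mask(v_tp1, y, alpha_core)
            core &= np.nanmean(v_tp1[y], axis=0) > np.nanmean(v_tp1[~y], axis=0)
        for name, mask in (("periphery_fc_tp1", peri), ("core_fc_tp1", core)):
            if not mask.any():
                results[name] = _not_applicable(name, n_iterations, test_fraction)
            else:
                results[name] = stratified_shuffle_eval(
                    v_tp1[:, mask], y, n_iterations, test_fraction, rng, name=name,
                    split_mode=split_mode,
                )
    else:
        def peri_selector(train_idx: np.ndarray) -> np.ndarray:
            return periphery_mask(
                values[train_idx], ibs[train_idx],
                alpha=periphery_criteria.alpha,
                one_sided_increase=periphery_criteria.one_sided_increase,
            )

        def core_selector(train_idx: np.ndarray) -> np.ndarray:
            vt = v_tp1[train_idx]
            yt = y[train_idx]
            mask = _core_mask(vt, yt, alpha_core)
            return mask & (np.nanmean(vt[yt], axis=0) > np.nanmean(vt[~yt], axis=0))

        results["periphery_fc_tp1"] = stratified_shuffle_eval(
            None, y, n_iterations, test_fraction, rng,
            feature_selector=peri_selector, feature_pool=v_tp1,
            name="periphery_fc_tp1", split_mode=split_mode,
        )
        results["core_fc_tp1"] = stratified_shuffle_eval(
            None, y, n_iterations, test_fraction, rng,
            feature_selector=core_selector, feature_pool=v_tp1,
            name="core_fc_tp1", split_mode=split_mode,
        )
    return results
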