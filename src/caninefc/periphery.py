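"""Flexible-periphery network selection.

The periphery is the set of edges whose functional connectivity changes with
training in lock-step with behavior.  Selection is a two-step conjunction of
uncorrected edge-wise tests:

(a) the per-dog FC change TP2-TP1 correlates with the per-dog change in the
    integrated behavioral score (Pearson, p < 0.05 two-sided);
(b) FC significantly increases from TP1 to TP2 (paired test, p < 0.05, with a
    positive mean change);
(c) FC does not change significantly from TP2 to TP3 (paired test p > 0.05) --
    an absence-of-evidence maintenance rule whose leniency grows as the cohort
    shrinks, which is why the per-edge p-values are always reported alongside
    the boolean flag.

A strict mode adds two confirmatory checks: (d) the TP2-TP1 change is
significantly larger than the TP2-TP3 change, and (e) the TP3-TP1 FC change
also correlates with the TP3-TP1 behavior change.  These are reported as
columns in every run and only gate selection when ``strict=True``.

No multiple-comparison correction is applied in the default (uncorrected)
mode; Benjamini-Hochberg FDR q-values are emitted alongside for transparency
but never gate selection unless requested.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import EdgeTable

__all__ = [
    "PeripheryCriteria",
    "delta_across_timepoints",
    "correlate_delta",
    "paired_change_test",
    "periphery_mask",
    "select_periphery",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PeripheryCriteria:
    """Thresholds and variants for periphery selection."""

    alpha: float = 0.05
    one_sided_increase: bool = False  # True reproduces the laxer one-sided-at-alpha reading
    strict: bool = False
    method: str = "pearson"  # or "spearman" for the delta-delta correlation


def _behavior_ibs(behavior: pd.DataFrame, dog_ids: list[str], timepoint: str) -> np.ndarray:
    sub = behavior[behavior["timepoint"] == timepoint].set_index("dog_id")["ibs"]
    missing = [d for d in dog_ids if d not in sub.index]
    if missing:
        raise ValueError(f"behavior records missing for {missing} at {timepoint}")
    return sub.loc[dog_ids].to_numpy(dtype=float)


def delta_across_timepoints(
    edge_table: EdgeTable,
    behavior: pd.DataFrame,
    tp_a: str,
    tp_b: str,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-dog FC change and IBS change between two timepoints.

    Returns ``(delta_fc, delta_ibs, dog_ids)`` with
    ``delta = value(tp_b) - value(tp_a)``.  Dogs missing an FC value at either
    timepoint on any edge of interest are excluded edgewise via NaN; dogs
    missing behavior raise, dogs with all-NaN FC are dropped with a log entry.
    """
    ta, tb = edge_table.tp_index(tp_a), edge_table.tp_index(tp_b)
    delta_fc = edge_table.values[:, tb, :] - edge_table.values[:, ta, :]
    keep = ~np.all(np.isnan(delta_fc), axis=1)
    if not keep.all():
        dropped = [d for d, k in zip(edge_table.dog_ids, keep) if not k]
        logger.info("excluding dogs without both timepoints: %s", dropped)
    dog_ids = [d for d, k in zip(edge_table.dog_ids, keep) if k]
    delta_fc = delta_fc[keep]
    ibs_a = _behavior_ibs(behavior, dog_ids, tp_a)
    ibs_b = _behavior_ibs(behavior, dog_ids, tp_b)
    return delta_fc, ibs_b - ibs_a, dog_ids


def correlate_delta(
    delta_fc: np.ndarray,
    delta_ibs: np.ndarray,
    method: str = "pearson",
) -> tuple[np.ndarray, np.ndarray]:
    """Edge-wise correlation of FC change with behavior change across dogs.

    Vectorised Pearson correlation per edge with a two-sided p-value from the
    exact t reference distribution (Spearman optional).  Zero behavioral
    spread makes the correlation undefined: all p are set to 1 with a warning.
    """
    delta_fc = np.asarray(delta_fc, dtype=float)
    delta_ibs = np.asarray(delta_ibs, dtype=float)
    n = delta_fc.shape[0]
    if n < 4:
        raise ValueError("need at least 4 dogs for the delta-delta correlation")
    if delta_ibs.std() == 0.0:
        warnings.warn("no behavioral spread; delta-delta p-values set to 1", RuntimeWarning)
        return np.zeros(delta_fc.shape[1]), np.ones(delta_fc.shape[1])
    if method == "spearman":
        delta_fc = stats.rankdata(delta_fc, axis=0)
        delta_ibs = stats.rankdata(delta_ibs)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    y = delta_ibs - delta_ibs.mean()
    x = delta_fc - np.nanmean(delta_fc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = np.nansum(x * y[:, None], axis=0)
        den = np.sqrt(np.nansum(x**2, axis=0) * (y @ y))
        r = num / den
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(r), np.nan, np.where(np.abs(r) >= 1.0, 0.0, p))
    return r, p


def _paired_t(d: np.ndarray, warn: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Columnwise paired t on a dogs x E difference matrix -> (p, mean)."""
    d = np.atleast_2d(np.asarray(d, dtype=float))
    n = np.sum(~np.isnan(d), axis=0)
    mean = np.nanmean(d, axis=0)
    sd = np.nanstd(d, axis=0, ddof=1)
    degenerate = sd == 0.0
    if warn and degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} edge(s) with zero within-pair variance", RuntimeWarning
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=np.maximum(n - 1, 1))
    p = np.where(degenerate, np.where(mean == 0.0, 1.0, 0.0), p)
    return p, mean


def paired_change_test(
    edge_table: EdgeTable,
    tp_a: str,
    tp_b: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Edge-wise paired t-test of FC between two timepoints.

    Returns two-sided p-values and the signed mean change (tp_b - tp_a).
    Degenerate edges with zero within-pair variance get p = 1 when the mean
    difference is 0 and p = 0 otherwise, with a warning.
    """
    ta, tb = edge_table.tp_index(tp_a), edge_table.tp_index(tp_b)
    d = edge_table.values[:, tb, :] - edge_table.values[:, ta, :]
    if np.max(np.sum(~np.isnan(d), axis=0)) < 3:
        raise ValueError("need at least 3 dogs with both timepoints")
    return _paired_t(d)


def periphery_mask(
    values: np.ndarray,
    ibs: np.ndarray,
    alpha: float = 0.05,
    one_sided_increase: bool = False,
) -> np.ndarray:
    """Lean array form of the selection conjunction (used inside CV folds).

    ``values`` is dogs x 3 timepoints x E (z scale), ``ibs`` is dogs x 3.
    Returns the boolean selected mask without building the statistics table.
    """
    dfc = values[:, 1, :] - values[:, 0, :]
    dibs = ibs[:, 1] - ibs[:, 0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        _, p_delta = correlate_delta(dfc, dibs)
        p_inc, mean_inc = _paired_t(dfc, warn=False)
        p_maint, _ = _paired_t(values[:, 2, :] - values[:, 1, :], warn=False)
    if one_sided_increase:
        inc_ok = (p_inc / 2.0 < alpha) & (mean_inc > 0)
    else:
        inc_ok = (p_inc < alpha) & (mean_inc > 0)
    return (p_delta < alpha) & inc_ok & (p_maint > alpha)


def select_periphery(
    edge_table: EdgeTable,
    behavior: pd.DataFrame,
    criteria: PeripheryCriteria = PeripheryCriteria(),
) -> pd.DataFrame:
    """Full two-step periphery selection; returns the per-edge statistics table.

    Columns: edge indices and labels, r_delta/p_delta (TP2-TP1 FC change vs
    IBS change), p_increase_tp1_tp2 and its mean change, p_change_tp2_tp3,
    the confirmatory strict-mode statistics, BH q-values, and the ``selected``
    flag.  An empty selection is a valid outcome.
    """
    alpha = criteria.alpha
    dfc, dibs, _ = delta_across_timepoints(edge_table, behavior, "TP1", "TP2")
    r_delta, p_delta = correlate_delta(dfc, dibs, method=criteria.method)
    p_inc, mean_inc = paired_change_test(edge_table, "TP1", "TP2")
    p_maint, mean_maint = paired_change_test(edge_table, "TP2", "TP3")

    # confirmatory: (d) TP2-TP1 change larger than TP2-TP3 change
    t1 = edge_table.tp_index("TP1")
    t2 = edge_table.tp_index("TP2")
    t3 = edge_table.tp_index("TP3")
    d21 = edge_table.values[:, t2, :] - edge_table.values[:, t1, :]
    d23 = edge_table.values[:, t2, :] - edge_table.values[:, t3, :]
    diff = d21 - d23
    n = np.sum(~np.isnan(diff), axis=0)
    mean_d = np.nanmean(diff, axis=0)
    sd_d = np.nanstd(diff, axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_stat = mean_d / (sd_d / np.sqrt(n))
    p_growth_vs_maint = 2.0 * stats.t.sf(np.abs(t_stat), df=np.maximum(n - 1, 1))
    p_growth_vs_maint = np.where(sd_d == 0.0, np.where(mean_d == 0.0, 1.0, 0.0),
                                 p_growth_vs_maint)

    # confirmatory: (e) TP3-TP1 delta-delta correlation
    dfc31, dibs31, _ = delta_across_timepoints(edge_table, behavior, "TP1", "TP3")
    r_delta31, p_delta31 = correlate_delta(dfc31, dibs31, method=criteria.method)

    if criteria.one_sided_increase:
        inc_ok = (p_inc / 2.0 < alpha) & (mean_inc > 0)
    else:
        inc_ok = (p_inc < alpha) & (mean_inc > 0)
    selected = (p_delta < alpha) & inc_ok & (p_maint > alpha)
    if criteria.strict:
        selected &= (p_growth_vs_maint < alpha) & (mean_d > 0) & (p_delta31 < alpha)

    q_delta = _bh_qvalues(p_delta)
    labels = edge_table.region_labels
    out = pd.DataFrame(
        {
            "i": edge_table.edges[:, 0],
            "j": edge_table.edges[:, 1],
            "region_i": [labels[i] for i in edge_table.edges[:, 0]],
            "region_j": [labels[j] for j in edge_table.edges[:, 1]],
            "r_delta": r_delta,
            "p_delta": p_delta,
            "p_increase_tp1_tp2": p_inc,
            "mean_increase_tp1_tp2": mean_inc,
            "p_change_tp2_tp3": p_maint,
            "mean_change_tp2_tp3": mean_maint,
            "p_growth_vs_maintenance": p_growth_vs_maint,
            "r_delta_tp3_tp1": r_delta31,
            "p_delta_tp3_tp1": p_delta31,
            "q_delta_fdr": q_delta,
            "selected": selected,
        }
    )
    return out


def _bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values (reported for transparency only)."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv)
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0.0, 1.0)
    q[ok] = out
    return q
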