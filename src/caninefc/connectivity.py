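"""Edge-wise resting-state functional connectivity.

FC for one dog at one timepoint is the N x N matrix of Pearson correlations
between region time series, computed over retained (non-censored) frames.
Matrices are Fisher z-transformed before run averaging and before all cohort
statistics (variance stabilisation); a raw-r mode is available by simply not
transforming.  Undefined edges (zero-variance regions) are stored as NaN and
excluded from cohort statistics downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .prep import RoiTimeSeries

__all__ = [
    "FcMatrix",
    "EdgeTable",
    "fc_pearson",
    "to_fisher_z",
    "from_fisher_z",
    "average_runs",
    "build_edge_table",
]

TIMEPOINTS = ("TP1", "TP2", "TP3")


@dataclass
class FcMatrix:
    """Symmetric N x N edge-strength matrix for one dog x timepoint."""

    values: np.ndarray
    scale: str  # "pearson_r" or "fisher_z"
    dog_id: str
    timepoint: str
    region_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("FC matrix must be square")
        if len(self.region_labels) != n:
            raise ValueError("label count must match matrix size")
        if self.scale not in ("pearson_r", "fisher_z"):
            raise ValueError(f"unknown scale {self.scale!r}")
        finite = np.isfinite(self.values)
        if not np.allclose(
            np.where(finite, self.values, 0.0),
            np.where(finite & finite.T, self.values.T, 0.0),
            atol=1e-12,
        ):
            raise ValueError("FC matrix must be symmetric")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


def fc_pearson(ts: RoiTimeSeries) -> FcMatrix:
    """Pearson correlation between all region pairs over retained frames.

    Zero-variance regions yield undefined correlations: the affected edges are
    recorded as NaN (with a warning) and excluded from cohort statistics.
    """
    mask = ts.censor_mask
    if mask.sum() < 3:
        raise ValueError("need at least 3 retained frames for correlation")
    x = ts.samples[mask]
    sd = x.std(axis=0)
    degenerate = sd == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance region(s); edges recorded as missing",
            RuntimeWarning,
        )
        r[degenerate, :] = np.nan
        r[:, degenerate] = np.nan
    np.fill_diagonal(r, 1.0)
    off = ~np.eye(r.shape[0], dtype=bool)
    r[off] = np.clip(r[off], -1.0, 1.0)
    return FcMatrix(
        values=r,
        scale="pearson_r",
        dog_id="",
        timepoint="",
        region_labels=list(ts.region_labels),
    )


def to_fisher_z(fc: FcMatrix) -> FcMatrix:
    """Fisher z = atanh(r), elementwise off-diagonal; diagonal stored as 0.

    |r| = 1 (e.g. duplicated regions) is mapped to atanh(1 - 1e-7) with a
    warning instead of infinity.
    """
    if fc.scale != "pearson_r":
        raise ValueError("input must be on the pearson_r scale")
    r = fc.values.copy()
    off = ~np.eye(r.shape[0], dtype=bool)
    saturated = off & (np.abs(r) >= 1.0) & np.isfinite(r)
    if saturated.any():
        warnings.warn("|r| = 1 clipped to 1 - 1e-7 before atanh", RuntimeWarning)
        r[saturated] = np.sign(r[saturated]) * (1.0 - 1e-7)
    z = np.arctanh(np.where(off, r, 0.0))
    z[~off] = 0.0
    z[off & ~np.isfinite(fc.values)] = np.nan
    return FcMatrix(
        values=z,
        scale="fisher_z",
        dog_id=fc.dog_id,
        timepoint=fc.timepoint,
        region_labels=list(fc.region_labels),
    )


def from_fisher_z(fc: FcMatrix) -> FcMatrix:
    """Inverse transform, for reporting edges back on the r scale."""
    if fc.scale != "fisher_z":
        raise ValueError("input must be on the fisher_z scale")
    r = np.tanh(fc.values)
    np.fill_diagonal(r, 1.0)
    return FcMatrix(
        values=r,
        scale="pearson_r",
        dog_id=fc.dog_id,
        timepoint=fc.timepoint,
        region_labels=list(fc.region_labels),
    )


def average_runs(fcs: list[FcMatrix]) -> FcMatrix:
    """Elementwise mean of same-dog, same-timepoint runs on the z scale.

    Runs are averaged rather than concatenated because censoring makes run
    lengths unequal.  Missing edges are ignored in the mean; an edge is
    missing in the output only if missing in every run.
    """
    if not fcs:
        raise ValueError("cannot average an empty list of runs")
    first = fcs[0]
    for fc in fcs:
        if fc.scale != "fisher_z":
            raise ValueError("run averaging operates on the fisher_z scale")
        if fc.dog_id != first.dog_id or fc.timepoint != first.timepoint:
            raise ValueError("all runs must belong to the same dog and timepoint")
        if fc.region_labels != first.region_labels:
            raise ValueError("region labels must match across runs")
    stack = np.stack([fc.values for fc in fcs])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
    return FcMatrix(
        values=mean,
        scale="fisher_z",
        dog_id=first.dog_id,
        timepoint=first.timepoint,
        region_labels=list(first.region_labels),
    )


def edge_index(n_regions: int) -> np.ndarray:
    """Stable lexicographic (i, j), i < j edge ordering; E = N(N-1)/2 rows."""
    iu, ju = np.triu_indices(n_regions, k=1)
    return np.column_stack([iu, ju])


@dataclass
class EdgeTable:
    """Vectorised cohort FC: values[dog, timepoint, edge] on a fixed scale."""

    dog_ids: list[str]
    timepoints: list[str]
    edges: np.ndarray  # E x 2, lexicographic, i < j
    values: np.ndarray  # dogs x timepoints x E
    region_labels: list[str]
    scale: str = "fisher_z"

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.region_labels)
        if self.edges.shape != (n * (n - 1) // 2, 2):
            raise ValueError("edge index must enumerate all N(N-1)/2 pairs")
        if self.values.shape != (len(self.dog_ids), len(self.timepoints), self.edges.shape[0]):
            raise ValueError("values must be dogs x timepoints x edges")

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def tp_index(self, timepoint: str) -> int:
        return self.timepoints.index(timepoint)

    def matrix(self, dog_id: str, timepoint: str) -> FcMatrix:
        """Round-trip one dog x timepoint back to a symmetric matrix."""
        d = self.dog_ids.index(dog_id)
        t = self.tp_index(timepoint)
        n = len(self.region_labels)
        m = np.zeros((n, n))
        m[self.edges[:, 0], self.edges[:, 1]] = self.values[d, t]
        m = m + m.T
        if self.scale == "pearson_r":
            np.fill_diagonal(m, 1.0)
        return FcMatrix(
            values=m,
            scale=self.scale,
            dog_id=dog_id,
            timepoint=timepoint,
            region_labels=list(self.region_labels),
        )

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format (dog_id, timepoint, i, j, value) view for export."""
        rows = []
        for d, dog in enumerate(self.dog_ids):
            for t, tp in enumerate(self.timepoints):
                rows.append(
                    pd.DataFrame(
                        {
                            "dog_id": dog,
                            "timepoint": tp,
                            "i": self.edges[:, 0],
                            "j": self.edges[:, 1],
                            "value": self.values[d, t],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


def build_edge_table(matrices: dict[tuple[str, str], FcMatrix]) -> EdgeTable:
    """Vectorise a cohort of per-dog, per-timepoint FC matrices.

    Keys are (dog_id, timepoint).  Every dog must be present at every
    timepoint appearing in the input, with identical region labels.
    """
    if not matrices:
        raise ValueError("no matrices supplied")
    dogs = sorted({k[0] for k in matrices})
    tps = sorted({k[1] for k in matrices})
    ref = next(iter(matrices.values()))
    labels = ref.region_labels
    scale = ref.scale
    for (dog, tp), fc in matrices.items():
        if fc.region_labels != labels:
            raise ValueError(f"inconsistent region labels for dog {dog} at {tp}")
        if fc.scale != scale:
            raise ValueError("all matrices must share one scale")
    edges = edge_index(len(labels))
    values = np.full((len(dogs), len(tps), edges.shape[0]), np.nan)
    for d, dog in enumerate(dogs):
        for t, tp in enumerate(tps):
            if (dog, tp) not in matrices:
                raise ValueError(f"dog {dog} is missing timepoint {tp}")
            m = matrices[(dog, tp)].values
            values[d, t] = m[edges[:, 0], edges[:, 1]]
    return EdgeTable(
        dog_ids=dogs,
        timepoints=tps,
        edges=edges,
        values=values,
        region_labels=list(labels),
        scale=scale,
    )
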