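"""Plain-text layouts for cohorts and analysis outputs.

A cohort directory contains::

    manifest.csv            dog_id,sex,label,timepoint,run,file,motion_file
    behavior.csv            dog_id,timepoint,retrieve,hunt,environment,ibs
    truth.json              planted ground truth (synthetic cohorts only)
    runs/<dog>_<tp>_run<k>.tsv         T x N samples, header = region labels
    runs/<dog>_<tp>_run<k>_motion.tsv  tx,ty,tz (mm), rx,ry,rz (rad)

All floats round-trip at full precision (%.17g).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import FcMatrix
from .prep import MotionTrace, RoiTimeSeries
from .synthgen import SyntheticCohort

__all__ = [
    "LoadedCohort",
    "write_cohort",
    "read_cohort",
    "write_fc_matrix",
    "read_fc_matrix",
    "write_node_edge",
]

FLOAT_FMT = "%.17g"
MOTION_COLUMNS = ["tx_mm", "ty_mm", "tz_mm", "rx_rad", "ry_rad", "rz_rad"]


@dataclass
class LoadedCohort:
    """A cohort read back from disk (truth present only for synthetic data)."""

    manifest: pd.DataFrame
    behavior: pd.DataFrame
    runs: dict[tuple[str, str, int], RoiTimeSeries]
    motion: dict[tuple[str, str, int], MotionTrace]
    truth: dict | None = None

    @property
    def dog_ids(self) -> list[str]:
        return sorted(self.manifest["dog_id"].unique())

    @property
    def timepoints(self) -> list[str]:
        return sorted(self.manifest["timepoint"].unique())

    def labels(self) -> dict[str, str]:
        return dict(zip(self.manifest["dog_id"], self.manifest["label"]))


def _write_tsv(path: Path, header: list[str], data: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        np.savetxt(fh, data, fmt=FLOAT_FMT, delimiter="\t")


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """Write a generated cohort to the plain-text directory layout."""
    out = Path(out_dir)
    (out / "runs").mkdir(parents=True, exist_ok=True)
    rows = []
    labels = cohort.labels()
    sexes = dict(zip(cohort.manifest["dog_id"], cohort.manifest["sex"]))
    for (dog, tp, run), ts in sorted(cohort.runs.items()):
        stem = f"{dog}_{tp}_run{run}"
        _write_tsv(out / "runs" / f"{stem}.tsv", ts.region_labels, ts.samples)
        _write_tsv(
            out / "runs" / f"{stem}_motion.tsv",
            MOTION_COLUMNS,
            cohort.motion[(dog, tp, run)].as_matrix(),
        )
        rows.append(
            {
                "dog_id": dog,
                "sex": sexes[dog],
                "label": labels[dog],
                "timepoint": tp,
                "run": run,
                "file": f"runs/{stem}.tsv",
                "motion_file": f"runs/{stem}_motion.tsv",
            }
        )
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    cohort.behavior.to_csv(out / "behavior.csv", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=2, sort_keys=True)
    return out


def read_cohort(cohort_dir: str | Path, tr_seconds: float = 1.0) -> LoadedCohort:
    """Read a cohort directory back into memory."""
    root = Path(cohort_dir)
    manifest = pd.read_csv(root / "manifest.csv")
    behavior = pd.read_csv(root / "behavior.csv")
    runs: dict[tuple[str, str, int], RoiTimeSeries] = {}
    motion: dict[tuple[str, str, int], MotionTrace] = {}
    for _, row in manifest.iterrows():
        key = (row["dog_id"], row["timepoint"], int(row["run"]))
        frame = pd.read_csv(root / row["file"], sep="\t")
        runs[key] = RoiTimeSeries(
            samples=frame.to_numpy(dtype=float),
            region_labels=list(frame.columns),
            tr_seconds=tr_seconds,
        )
        m = pd.read_csv(root / row["motion_file"], sep="\t").to_numpy(dtype=float)
        motion[key] = MotionTrace(
            translations_mm=m[:, :3], rotations_rad=m[:, 3:], tr_seconds=tr_seconds
        )
    truth = None
    truth_path = root / "truth.json"
    if truth_path.exists():
        truth = json.loads(truth_path.read_text())
    return LoadedCohort(manifest=manifest, behavior=behavior, runs=runs, motion=motion,
                        truth=truth)


def write_fc_matrix(fc: FcMatrix, path: str | Path) -> None:
    """Square CSV with region labels as header and index."""
    pd.DataFrame(fc.values, index=fc.region_labels, columns=fc.region_labels).to_csv(
        path, float_format=FLOAT_FMT
    )


def read_fc_matrix(path: str | Path, scale: str, dog_id: str = "",
                   timepoint: str = "") -> FcMatrix:
    frame = pd.read_csv(path, index_col=0)
    return FcMatrix(
        values=frame.to_numpy(dtype=float),
        scale=scale,
        dog_id=dog_id,
        timepoint=timepoint,
        region_labels=[str(c) for c in frame.columns],
    )


def write_node_edge(
    region_labels: list[str],
    edges: np.ndarray,
    weights: np.ndarray,
    stem: str | Path,
) -> tuple[Path, Path]:
    """Export a subnetwork as BrainNet-style .node/.edge text files.

    No anatomical coordinates exist for the synthetic parcellation, so nodes
    are placed on a circle of radius 100; node size encodes degree within the
    exported subnetwork.  ``edges`` is an E x 2 index array into
    ``region_labels`` and ``weights`` the matching edge strengths.
    """
    stem = Path(stem)
    n = len(region_labels)
    angles = 2.0 * np.pi * np.arange(n) / max(n, 1)
    coords = np.column_stack([100.0 * np.cos(angles), 100.0 * np.sin(angles), np.zeros(n)])
    adjacency = np.zeros((n, n))
    degree = np.zeros(n)
    for (i, j), w in zip(np.asarray(edges, dtype=int), np.asarray(weights, dtype=float)):
        adjacency[i, j] = adjacency[j, i] = w
        degree[i] += 1
        degree[j] += 1
    node_path = stem.with_suffix(".node")
    with open(node_path, "w") as fh:
        for k, label in enumerate(region_labels):
            fh.write(
                f"{coords[k, 0]:.3f}\t{coords[k, 1]:.3f}\t{coords[k, 2]:.3f}\t"
                f"1\t{max(degree[k], 1.0):.0f}\t{label}\n"
            )
    edge_path = stem.with_suffix(".edge")
    with open(edge_path, "w") as fh:
        np.savetxt(fh, adjacency, fmt="%.6f", delimiter="\t")
    return node_path, edge_path
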