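"""End-to-end orchestration: synth -> prep -> FC -> periphery + core -> homology.

Stages communicate through plain-text files in the output directory, so any
stage can be re-run from cached upstream outputs and reproduce the full-run
result.  Every analysis output embeds the configuration hash and seed; a
summary JSON collects the headline results (selected periphery edges, core
edges, the three feature-set AUCs, homology matches) and is byte-identical
for identical config + seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cfio
from .connectivity import EdgeTable, average_runs, build_edge_table, edge_index, fc_pearson, to_fisher_z
from .core_classify import (
    compare_feature_sets,
    group_difference_test,
    select_core,
    verify_core_stability,
)
from .homology import build_fingerprint, match_regions, matches_to_frame
from .periphery import PeripheryCriteria, select_periphery
from .prep import PrepSettings, preprocess_run
from .synthgen import CohortConfig, SyntheticCohort, generate_cohort

__all__ = ["RunConfig", "run_pipeline", "process_cohort", "config_hash", "load_run_config"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full pipeline run."""

    out_dir: str = "caninefc_out"
    cohort_dir: str | None = None  # existing data; None => synthesise
    cohort: CohortConfig = field(default_factory=CohortConfig)
    prep: PrepSettings = field(default_factory=PrepSettings)
    alpha_periphery: float = 0.05
    alpha_core: float = 0.01
    one_sided_increase: bool = False
    strict_periphery: bool = False
    n_iterations: int = 1000
    test_fraction: float = 0.25
    mode: str = "historical"  # or "nested"
    split_mode: str = "shuffle"  # or "kfold"
    n_homology_targets: int = 19
    homology_metric: str = "cosine"
    n_permutations: int = 1000
    make_plots: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.alpha_periphery < 1.0 or not 0.0 <= self.alpha_core < 1.0:
            raise ValueError("alpha thresholds must lie in [0, 1)")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")


def config_hash(config: RunConfig) -> str:
    """Short stable digest of the analysis configuration.

    Filesystem locations (``out_dir``, ``cohort_dir``) are excluded: two runs
    of the same analysis into different directories are the same analysis and
    must produce identical outputs.
    """
    d = asdict(config)
    d.pop("out_dir", None)
    d.pop("cohort_dir", None)
    blob = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_run_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML mapping (keys mirror the dataclasses)."""
    import yaml

    from .synthgen import CoreEdge, PeripheryEdge

    raw = yaml.safe_load(Path(path).read_text()) or {}
    cohort_kwargs = raw.pop("cohort", {})
    if "periphery_edges" in cohort_kwargs:
        cohort_kwargs["periphery_edges"] = tuple(
            PeripheryEdge(**e) for e in cohort_kwargs["periphery_edges"]
        )
    if "core_edges" in cohort_kwargs:
        cohort_kwargs["core_edges"] = tuple(
            CoreEdge(**e) for e in cohort_kwargs["core_edges"]
        )
    cohort = CohortConfig(**cohort_kwargs)
    prep_kwargs = raw.pop("prep", {})
    if "band_hz" in prep_kwargs:
        prep_kwargs["band_hz"] = tuple(prep_kwargs["band_hz"])
    prep = PrepSettings(**prep_kwargs)
    return RunConfig(cohort=cohort, prep=prep, **raw)


def _stamp(path: Path, digest: str, seed: int) -> None:
    """Prefix a CSV with a comment line carrying the config hash and seed."""
    text = path.read_text()
    path.write_text(f"# config_hash={digest} seed={seed}\n{text}")


def _read_stamped_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# cohort -> edge table
# ---------------------------------------------------------------------------

def process_cohort(
    cohort: SyntheticCohort | cfio.LoadedCohort,
    settings: PrepSettings = PrepSettings(),
) -> EdgeTable:
    """Preprocess every run, compute FC, Fisher-z, average runs, vectorise.

    Accepts either an in-memory synthetic cohort or a cohort loaded from disk;
    both expose ``runs`` and ``motion`` dictionaries keyed by
    (dog_id, timepoint, run).
    """
    by_dog_tp: dict[tuple[str, str], list] = {}
    for (dog, tp, run), ts in cohort.runs.items():
        clean = preprocess_run(ts, cohort.motion[(dog, tp, run)], settings)
        fc = fc_pearson(clean)
        fc.dog_id, fc.timepoint = dog, tp
        by_dog_tp.setdefault((dog, tp), []).append(to_fisher_z(fc))
    matrices = {key: average_runs(fcs) for key, fcs in by_dog_tp.items()}
    return build_edge_table(matrices)


def _edge_table_to_csv(table: EdgeTable, path: Path) -> None:
    table.to_long_frame().to_csv(path, index=False, float_format="%.17g")


def _edge_table_from_csv(path: Path, region_labels: list[str]) -> EdgeTable:
    frame = _read_stamped_csv(path)
    dogs = sorted(frame["dog_id"].unique())
    tps = sorted(frame["timepoint"].unique())
    edges = edge_index(len(region_labels))
    values = np.full((len(dogs), len(tps), edges.shape[0]), np.nan)
    eidx = {(i, j): k for k, (i, j) in enumerate(map(tuple, edges))}
    for (dog, tp), sub in frame.groupby(["dog_id", "timepoint"]):
        d, t = dogs.index(dog), tps.index(tp)
        rows = [eidx[(i, j)] for i, j in zip(sub["i"], sub["j"])]
        values[d, t, rows] = sub["value"].to_numpy()
    return EdgeTable(
        dog_ids=dogs, timepoints=tps, edges=edges, values=values,
        region_labels=region_labels,
    )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_synth(config: RunConfig, out: Path) -> Path:
    cohort_cfg = replace(config.cohort, seed=config.seed)
    cohort = generate_cohort(cohort_cfg)
    return cfio.write_cohort(cohort, out / "cohort")


def stage_fc(config: RunConfig, out: Path, cohort_dir: Path) -> None:
    cohort = cfio.read_cohort(cohort_dir, tr_seconds=config.cohort.tr_seconds)
    table = process_cohort(cohort, config.prep)
    fc_dir = out / "fc"
    fc_dir.mkdir(parents=True, exist_ok=True)
    for dog in table.dog_ids:
        for tp in table.timepoints:
            cfio.write_fc_matrix(table.matrix(dog, tp), fc_dir / f"fc_{dog}_{tp}.csv")
    path = out / "edge_table.csv"
    _edge_table_to_csv(table, path)
    _stamp(path, config_hash(config), config.seed)


def _load_table(config: RunConfig, out: Path, cohort_dir: Path) -> tuple[EdgeTable, cfio.LoadedCohort]:
    cohort = cfio.read_cohort(cohort_dir, tr_seconds=config.cohort.tr_seconds)
    first = next(iter(cohort.runs.values()))
    table = _edge_table_from_csv(out / "edge_table.csv", first.region_labels)
    return table, cohort


def stage_periphery(config: RunConfig, out: Path, cohort_dir: Path) -> pd.DataFrame:
    table, cohort = _load_table(config, out, cohort_dir)
    criteria = PeripheryCriteria(
        alpha=config.alpha_periphery,
        one_sided_increase=config.one_sided_increase,
        strict=config.strict_periphery,
    )
    stats_table = select_periphery(table, cohort.behavior, criteria)
    path = out / "periphery.csv"
    stats_table.to_csv(path, index=False)
    _stamp(path, config_hash(config), config.seed)
    sel = stats_table[stats_table["selected"]]
    cfio.write_node_edge(
        table.region_labels,
        sel[["i", "j"]].to_numpy(),
        sel["r_delta"].to_numpy(),
        out / "periphery",
    )
    return stats_table


def stage_core(config: RunConfig, out: Path, cohort_dir: Path) -> pd.DataFrame:
    table, cohort = _load_table(config, out, cohort_dir)
    labels = cohort.labels()
    diff = group_difference_test(table, labels, "TP1")
    mask = select_core(table, labels, "TP1", alpha=config.alpha_core)
    diff["selected"] = mask
    stability = verify_core_stability(table, labels, mask)
    path = out / "core.csv"
    diff.to_csv(path, index=False)
    _stamp(path, config_hash(config), config.seed)
    spath = out / "core_stability.csv"
    stability.to_csv(spath, index=False)
    _stamp(spath, config_hash(config), config.seed)
    sel = diff[diff["selected"]]
    cfio.write_node_edge(
        table.region_labels,
        sel[["i", "j"]].to_numpy(),
        sel["mean_diff"].to_numpy(),
        out / "core",
    )
    return diff


def stage_classify(config: RunConfig, out: Path, cohort_dir: Path) -> dict:
    table, cohort = _load_table(config, out, cohort_dir)
    rng = np.random.default_rng(config.seed + 1)
    results = compare_feature_sets(
        table,
        cohort.behavior,
        cohort.labels(),
        mode=config.mode,
        n_iterations=config.n_iterations,
        test_fraction=config.test_fraction,
        rng=rng,
        alpha_core=config.alpha_core,
        periphery_criteria=PeripheryCriteria(
            alpha=config.alpha_periphery, one_sided_increase=config.one_sided_increase
        ),
        split_mode=config.split_mode,
    )
    payload = {
        "config_hash": config_hash(config),
        "seed": config.seed,
        "mode": config.mode,
        "results": {name: res.summary() for name, res in results.items()},
        "roc": {
            name: {"fpr": res.fpr.tolist(), "tpr": res.tpr.tolist()}
            for name, res in results.items()
            if res.applicable
        },
    }
    with open(out / "classifier.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    if config.make_plots:
        _plot_roc(results, out / "roc.png")
    return payload


def _plot_roc(results: dict, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, res in results.items():
        if res.applicable:
            ax.plot(res.fpr, res.tpr, label=f"{name} (AUC = {res.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("False-positive rate")
    ax.set_ylabel("True-positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def stage_homology(config: RunConfig, out: Path, cohort_dir: Path) -> pd.DataFrame:
    """Cross-timepoint fingerprint matching as a within-study consistency check.

    The cohort-mean connectome at the first timepoint provides source
    fingerprints over a shared target list (the last ``n_homology_targets``
    regions by default); candidate regions come from the cohort-mean
    connectome at the last timepoint.  Baseline connectivity is trait-like
    (stable within dog across timepoints), so the expected best match of every
    region is itself; the self-match fraction reported in the summary is a
    region-identifiability score.
    """
    table, cohort = _load_table(config, out, cohort_dir)
    labels = table.region_labels
    k = min(config.n_homology_targets, len(labels) - 1)
    targets = labels[-k:]
    sources = labels[: len(labels) - k]
    rng = np.random.default_rng(config.seed + 2)
    fingerprints = []
    for tp in (table.timepoints[0], table.timepoints[-1]):
        mats = [table.matrix(d, tp).values for d in table.dog_ids]
        mean_fc = table.matrix(table.dog_ids[0], tp)
        mean_fc.values = np.mean(mats, axis=0)
        fingerprints.append(
            [build_fingerprint(mean_fc, s, targets) for s in sources]
        )
    matches = match_regions(
        fingerprints[0], fingerprints[1],
        metric=config.homology_metric, n_permutations=config.n_permutations, rng=rng,
    )
    frame = matches_to_frame(matches)
    path = out / "homology.csv"
    frame.to_csv(path, index=False)
    _stamp(path, config_hash(config), config.seed)
    return frame


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

STAGES = ("synth", "fc", "periphery", "core", "classify", "homology")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the summary report; returns the summary dict.

    A failure inside a stage raises with the stage name; outputs of completed
    stages are preserved on disk.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = config_hash(config)
    timings: dict[str, float] = {}

    def timed(stage: str, fn, *args):
        t0 = time.perf_counter()
        try:
            result = fn(*args)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
        timings[stage] = time.perf_counter() - t0
        logger.info("stage %s finished in %.2f s", stage, timings[stage])
        return result

    if config.cohort_dir is not None:
        cohort_dir = Path(config.cohort_dir)
    else:
        cohort_dir = timed("synth", stage_synth, config, out)
    timed("fc", stage_fc, config, out, cohort_dir)
    peri = timed("periphery", stage_periphery, config, out, cohort_dir)
    core = timed("core", stage_core, config, out, cohort_dir)
    classifier = timed("classify", stage_classify, config, out, cohort_dir)
    matches = timed("homology", stage_homology, config, out, cohort_dir)

    top = matches[matches["rank"] == 1]
    summary = {
        "config_hash": digest,
        "seed": config.seed,
        "mode": config.mode,
        "n_periphery_selected": int(peri["selected"].sum()),
        "periphery_edges": [
            [int(i), int(j)] for i, j in peri.loc[peri["selected"], ["i", "j"]].to_numpy()
        ],
        "n_core_selected": int(core["selected"].sum()),
        "core_edges": [
            [int(i), int(j)] for i, j in core.loc[core["selected"], ["i", "j"]].to_numpy()
        ],
        "auc": {
            name: res["auc_pooled"] for name, res in classifier["results"].items()
        },
        "homology_self_match_fraction": float(
            (top["source"] == top["candidate"]).mean()
        ),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("stage timings: %s", {k: round(v, 2) for k, v in timings.items()})
    return summary
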