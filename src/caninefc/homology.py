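"""Connectivity fingerprints and cross-cohort region matching.

A region's connectivity fingerprint is the vector of its FC to a fixed,
ordered list of target regions (19 cortical/subcortical targets in the
original design; the target identities are configuration, not constants).
Candidate functional homologs between two cohorts -- e.g. dog and human
connectomes sharing a common target list -- are ranked by the similarity of
their cohort-mean fingerprints.  The default similarity is the cosine between
mean profiles; Pearson-across-targets and (negative) Manhattan distance are
exposed as options.  A permutation p-value for each top match is obtained by
shuffling the target entries of the source profile.

Output is a similarity ranking only; no claim of anatomical homology is made.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import FcMatrix

__all__ = ["Fingerprint", "MatchResult", "build_fingerprint", "mean_fingerprint",
           "match_regions"]

DEFAULT_N_PERMUTATIONS = 1000


@dataclass
class Fingerprint:
    """FC of one source region to K ordered targets, for one subject."""

    source_region: str
    target_labels: list[str]
    profile: np.ndarray
    subject_id: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        self.profile = np.asarray(self.profile, dtype=float)
        if self.profile.shape != (len(self.target_labels),):
            raise ValueError("profile length must equal the target count")
        if self.source_region in self.target_labels:
            raise ValueError("source region must not appear among the targets")


@dataclass
class MatchResult:
    """Ranked candidate homologs for one source region."""

    source_region: str
    candidates: list[str]  # sorted by similarity, non-increasing
    similarities: np.ndarray
    p_permutation: float

    def __post_init__(self) -> None:
        self.similarities = np.asarray(self.similarities, dtype=float)
        if np.any(np.diff(self.similarities) > 1e-12):
            raise ValueError("similarities must be sorted non-increasing")

    @property
    def best(self) -> str:
        return self.candidates[0]


def build_fingerprint(
    fc: FcMatrix,
    source: str,
    targets: list[str],
    subject_id: str = "",
    species: str = "",
) -> Fingerprint:
    """Extract ``fc[source, target_k]`` for each target, in target order."""
    labels = fc.region_labels
    missing = [r for r in [source] + list(targets) if r not in labels]
    if missing:
        raise ValueError(f"regions not present in the FC matrix: {missing}")
    si = labels.index(source)
    profile = np.array([fc.values[si, labels.index(t)] for t in targets], dtype=float)
    return Fingerprint(
        source_region=source,
        target_labels=list(targets),
        profile=profile,
        subject_id=subject_id,
        species=species,
    )


def mean_fingerprint(fingerprints: list[Fingerprint]) -> Fingerprint:
    """Average per-subject fingerprints of one region across a cohort."""
    if not fingerprints:
        raise ValueError("no fingerprints to average")
    first = fingerprints[0]
    for f in fingerprints:
        if f.source_region != first.source_region or f.target_labels != first.target_labels:
            raise ValueError("fingerprints must share source region and target list")
    return Fingerprint(
        source_region=first.source_region,
        target_labels=list(first.target_labels),
        profile=np.mean([f.profile for f in fingerprints], axis=0),
        species=first.species,
    )


def _similarity(a: np.ndarray, b: np.ndarray, metric: str) -> float:
    if metric == "cosine":
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0.0 or nb == 0.0:
            return 0.0
        return float(a @ b / (na * nb))
    if metric == "pearson":
        if a.std() == 0.0 or b.std() == 0.0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])
    if metric == "manhattan":
        return float(-np.abs(a - b).sum())
    raise ValueError(f"unknown similarity metric {metric!r}")


def match_regions(
    fingerprints_a: list[Fingerprint],
    fingerprints_b: list[Fingerprint],
    metric: str = "cosine",
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    rng: np.random.Generator | None = None,
) -> list[MatchResult]:
    """Rank every cohort-B region against each cohort-A source region.

    Inputs are cohort-level (already averaged) fingerprints sharing one target
    list in the same order.  For each A region all B regions are ranked by
    profile similarity; the top match gets a permutation p-value from
    shuffling the source profile's target entries (add-one corrected).
    """
    if not fingerprints_a or not fingerprints_b:
        raise ValueError("both cohorts must supply fingerprints")
    targets = fingerprints_a[0].target_labels
    for f in fingerprints_a + fingerprints_b:
        if f.target_labels != targets:
            raise ValueError("cohorts must share the same target list in the same order")
    rng = rng or np.random.default_rng()
    results = []
    for fa in fingerprints_a:
        sims = np.array([_similarity(fa.profile, fb.profile, metric) for fb in fingerprints_b])
        order = np.argsort(-sims, kind="stable")
        top_sim = sims[order[0]]
        top_profile = fingerprints_b[order[0]].profile
        exceed = 0
        for _ in range(n_permutations):
            perm = rng.permutation(fa.profile)
            if _similarity(perm, top_profile, metric) >= top_sim:
                exceed += 1
        p = (exceed + 1) / (n_permutations + 1)
        results.append(
            MatchResult(
                source_region=fa.source_region,
                candidates=[fingerprints_b[k].source_region for k in order],
                similarities=sims[order],
                p_permutation=float(p),
            )
        )
    return results


def matches_to_frame(results: list[MatchResult]) -> pd.DataFrame:
    """Long-format (source, rank, candidate, similarity, p_perm) table."""
    rows = []
    for res in results:
        for rank, (cand, sim) in enumerate(zip(res.candidates, res.similarities), start=1):
            rows.append(
                {
                    "source": res.source_region,
                    "rank": rank,
                    "candidate": cand,
                    "similarity": sim,
                    "p_perm": res.p_permutation if rank == 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)
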