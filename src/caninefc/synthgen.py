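"""Synthetic longitudinal cohorts with planted periphery/core structure.

No dog resting-state data are publicly available for this design, so every
downstream stage is exercised on synthetic cohorts that emulate the study
conditions: three timepoints (pre-training TP1, post-training TP2,
post-maintenance TP3), two 200-volume runs per dog per timepoint at TR = 1 s,
a 13 successful / 17 non-successful label split, integrated behavioral scores
(IBS) that rise with training and then plateau, and two planted edge systems:

* **periphery edges** whose FC strengthens from TP1 to TP2 (then maintains)
  by a per-dog increment correlated, across dogs, with that dog's IBS change;
* **core edges** carrying a stable group-mean FC offset (successful >
  non-successful) at every timepoint.

The time-series generator draws stationary Gaussian samples whose population
correlation equals a per-dog target matrix, so the population FC of the
generated data is exactly the planted structure.  Baseline connectivity is a
per-dog low-rank factor correlation matrix (positive semi-definite by
construction, off-diagonal spread set by ``noise_sd``) that is held fixed
across timepoints: FC is trait-like, and longitudinal differences then
isolate planted change plus sampling noise.

Planted effect sizes can be expressed on two scales (``effect_scale``):

* ``"observed"`` (default): ``group_effect_d``, ``fc_gain`` and
  ``coupling_rho`` are realized on the *measured* run-averaged Fisher-z FC.
  The generator compensates the planted target offsets for the analytic
  sampling variance of the band-limited correlation estimate
  (:func:`measured_z_variance`), so a configured d of 1.5 is (in expectation)
  the standardized group difference an analyst would actually estimate.
* ``"target"``: literal offsets on the target correlation matrix
  (``offset = d * noise_sd``), with no compensation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .prep import MotionTrace, RoiTimeSeries

__all__ = [
    "PeripheryEdge",
    "CoreEdge",
    "CohortConfig",
    "SyntheticCohort",
    "measured_z_variance",
    "generate_behavior",
    "build_target_fc",
    "nearest_correlation",
    "generate_timeseries",
    "generate_motion",
    "generate_cohort",
    "default_config",
    "null_config",
    "periphery_study_config",
]

TIMEPOINTS = ("TP1", "TP2", "TP3")

#: Default placements keep the two planted systems disjoint.
DEFAULT_PERIPHERY_PAIRS = ((0, 1), (2, 3), (4, 5), (6, 7), (8, 9))
DEFAULT_CORE_PAIRS = ((10, 11), (12, 13), (14, 15), (16, 17), (18, 19), (20, 21), (22, 23))

#: Motion confound count regressed out downstream (6 rigid-body parameters).
N_MOTION_CONFOUNDS = 6


@dataclass(frozen=True)
class PeripheryEdge:
    """A flexible edge: training increment coupled to behavior change."""

    i: int
    j: int
    coupling_rho: float = 0.8
    fc_gain: float = 1.2


@dataclass(frozen=True)
class CoreEdge:
    """A stable edge: constant group-mean offset at every timepoint."""

    i: int
    j: int
    group_effect_d: float = 1.5


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to generate one reproducible synthetic cohort."""

    n_success: int = 13
    n_fail: int = 17
    n_regions: int = 40
    n_timepoints: int = 3
    runs_per_tp: int = 2
    volumes_per_run: int = 200
    tr_seconds: float = 1.0
    periphery_edges: tuple[PeripheryEdge, ...] = tuple(
        PeripheryEdge(i, j) for i, j in DEFAULT_PERIPHERY_PAIRS
    )
    core_edges: tuple[CoreEdge, ...] = tuple(CoreEdge(i, j) for i, j in DEFAULT_CORE_PAIRS)
    # behavior model (subscore latent scale; subscores are 1-5 integers)
    behavior_base_mean: float = 2.5
    behavior_subscore_sd: float = 0.6
    behavior_gain_mean: float = 3.0
    behavior_gain_sd: float = 1.0
    behavior_maintain_sd: float = 0.2
    group_behavior_d: float = 0.45
    # connectivity model
    noise_sd: float = 0.2
    n_factors: int = 5
    periphery_increment_sd: float = 0.3
    periphery_group_d: float = 0.3
    effect_scale: str = "observed"  # or "target"
    ar_coeff: float = 0.0
    # motion model
    spike_prob: float = 0.05
    spike_mm: float = 0.5
    # analysis band the cohort is calibrated for (used by "observed" scale)
    analysis_low_hz: float = 0.01
    analysis_high_hz: float = 0.1
    seed: int = 0

    @property
    def n_dogs(self) -> int:
        return self.n_success + self.n_fail

    def validate(self) -> None:
        if self.n_success + self.n_fail < 4:
            raise ValueError("need at least 4 dogs")
        if self.volumes_per_run < 10:
            raise ValueError("need at least 10 volumes per run")
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        if not 0.0 <= self.spike_prob <= 1.0:
            raise ValueError("spike_prob must be a probability")
        if self.effect_scale not in ("observed", "target"):
            raise ValueError("effect_scale must be 'observed' or 'target'")
        if not 0.0 <= abs(self.ar_coeff) < 1.0:
            raise ValueError("ar_coeff must lie in (-1, 1)")
        seen: set[tuple[int, int]] = set()
        for e in list(self.periphery_edges) + list(self.core_edges):
            if not (0 <= e.i < e.j < self.n_regions):
                raise ValueError(f"edge ({e.i}, {e.j}) must satisfy 0 <= i < j < n_regions")
            if (e.i, e.j) in seen:
                raise ValueError("periphery and core edge lists must be disjoint")
            seen.add((e.i, e.j))
        for e in self.periphery_edges:
            if not -1.0 < e.coupling_rho < 1.0:
                raise ValueError("coupling_rho must lie in (-1, 1)")
        if self.noise_sd < 0 or self.noise_sd > 0.4:
            raise ValueError("noise_sd must lie in [0, 0.4] (correlation scale)")

    def to_json(self) -> str:
        d = asdict(self)
        d["periphery_edges"] = [asdict(e) for e in self.periphery_edges]
        d["core_edges"] = [asdict(e) for e in self.core_edges]
        return json.dumps(d, sort_keys=True)


def default_config(**overrides) -> CohortConfig:
    """The canonical demo cohort: 13/17 dogs with planted periphery and core."""
    return CohortConfig(**overrides)


def null_config(n_success: int = 12, n_fail: int = 12, **overrides) -> CohortConfig:
    """A fully null cohort: behavior still improves, but no FC effect is planted."""
    return CohortConfig(
        n_success=n_success,
        n_fail=n_fail,
        periphery_edges=(),
        core_edges=(),
        group_behavior_d=0.0,
        **overrides,
    )


def periphery_study_config(**overrides) -> CohortConfig:
    """Periphery-recovery conditions: 24 dogs, planted periphery edges only."""
    return CohortConfig(
        n_success=12,
        n_fail=12,
        core_edges=(),
        **overrides,
    )


# ---------------------------------------------------------------------------
# measurement-variance model (the "observed" effect scale)
# ---------------------------------------------------------------------------

def _n_inband_bins(config: CohortConfig) -> int:
    t, tr = config.volumes_per_run, config.tr_seconds
    freqs = np.fft.rfftfreq(t, d=tr)
    return int(np.sum((freqs >= config.analysis_low_hz) & (freqs <= config.analysis_high_hz)))


def measured_z_variance(config: CohortConfig, per_timepoint: bool = True) -> float:
    """Approximate sampling variance of a measured Fisher-z edge value.

    After ideal band-pass filtering, one run's correlation estimate draws on
    two real degrees of freedom per in-band frequency bin, minus a small fixed
    cost: ``var(z) ~ 1 / (n_eff - 3)`` with ``n_eff = 2 m - 2`` (m in-band
    bins).  Censoring and the motion confounds turn out to cost almost no
    in-band degrees of freedom (censored frames are re-filled by interpolation
    and the confounds are broadband), which direct simulation of the full
    preprocessing chain confirms across volume counts, spike rates, and run
    counts (observed n_eff within ~1 dof of 2m - 2; see docs/methods.md).
    Run averaging divides the variance by ``runs_per_tp``.
    """
    m = _n_inband_bins(config)
    n_eff = 2.0 * m - 2.0
    var_run = 1.0 / max(n_eff - 3.0, 4.0)
    return var_run / config.runs_per_tp if per_timepoint else var_run


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def _success_labels(config: CohortConfig) -> np.ndarray:
    return np.array([True] * config.n_success + [False] * config.n_fail)


def _behavior_group_offset(config: CohortConfig) -> float:
    # analytic sd of integer IBS: 3 latent subscores + rounding noise
    sd_ibs = np.sqrt(3.0 * config.behavior_subscore_sd**2 + 3.0 / 12.0)
    return config.group_behavior_d * sd_ibs / 3.0  # per subscore


def generate_behavior(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Integer 1-5 subscores per dog x timepoint; IBS is their sum.

    Latent Gaussian subscores receive a shared per-dog training gain between
    TP1 and TP2 (mean ``behavior_gain_mean`` on the IBS scale) and only
    maintenance jitter between TP2 and TP3, then are rounded and clipped to
    the ordinal 1-5 rubric.  Successful dogs are drawn with higher means.
    """
    config.validate()
    # misconfiguration guard: a gain that pushes latent subscores outside the
    # rubric more than half the time signals an impossible configuration
    mean_tp2 = config.behavior_base_mean + config.behavior_gain_mean / 3.0
    sd_tp2 = np.sqrt(config.behavior_subscore_sd**2 + (config.behavior_gain_sd / 3.0) ** 2)
    if sd_tp2 == 0:
        p_out = 0.0 if 1.0 <= mean_tp2 <= 5.0 else 1.0
    else:
        p_out = stats.norm.cdf(1.0, mean_tp2, sd_tp2) + stats.norm.sf(5.0, mean_tp2, sd_tp2)
    if p_out > 0.5:
        raise ValueError(
            f"behavior_gain_mean={config.behavior_gain_mean} forces subscores outside "
            f"[1, 5] {p_out:.0%} of the time"
        )
    n = config.n_dogs
    succ = _success_labels(config)
    base = (
        config.behavior_base_mean
        + _behavior_group_offset(config) * succ[:, None]
        + rng.normal(0.0, config.behavior_subscore_sd, size=(n, 3))
    )
    gain = rng.normal(config.behavior_gain_mean, config.behavior_gain_sd, size=n)
    latents = {
        "TP1": base,
        "TP2": base + gain[:, None] / 3.0,
    }
    latents["TP3"] = latents["TP2"] + rng.normal(0.0, config.behavior_maintain_sd, size=(n, 3))
    rows = []
    for t, tp in enumerate(TIMEPOINTS[: config.n_timepoints]):
        scores = np.clip(np.rint(latents[tp]), 1, 5).astype(int)
        for d in range(n):
            r, h, e = scores[d]
            rows.append(
                {
                    "dog_id": f"dog{d:02d}",
                    "timepoint": tp,
                    "retrieve": int(r),
                    "hunt": int(h),
                    "environment": int(e),
                    "ibs": int(r + h + e),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# target correlation matrices
# ---------------------------------------------------------------------------

def nearest_correlation(a: np.ndarray, tol: float = 1e-8, max_iter: int = 200) -> np.ndarray:
    """Nearest correlation matrix by alternating projections (Higham 2002).

    Alternates projection onto the PSD cone and the unit-diagonal affine set,
    with Dykstra's correction.  A matrix that is already a PSD correlation
    matrix is a fixed point and is returned unchanged (to within solver
    round-off).  Raises if the iteration has not converged within ``tol``.
    """
    a = np.asarray(a, dtype=float)
    y = a.copy()
    ds = np.zeros_like(a)
    for _ in range(max_iter):
        r = y - ds
        w, v = np.linalg.eigh((r + r.T) / 2.0)
        x = (v * np.clip(w, 0.0, None)) @ v.T
        x = (x + x.T) / 2.0
        ds = x - r
        y_new = x.copy()
        np.fill_diagonal(y_new, 1.0)
        change = np.linalg.norm(y_new - y, ord="fro") / max(np.linalg.norm(y, ord="fro"), 1.0)
        y = y_new
        if change < tol:
            min_eig = np.linalg.eigvalsh((y + y.T) / 2.0).min()
            if min_eig < -tol:
                continue
            return y
    raise RuntimeError(f"nearest-correlation projection did not converge within tol={tol}")


def _factor_baseline(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-dog baseline correlation matrix with off-diagonal sd ~ noise_sd."""
    n, k = config.n_regions, config.n_factors
    if config.noise_sd == 0.0:
        return np.eye(n)
    # var(C_ij) ~ k / (k + v)^2  =>  v = sqrt(k)/noise_sd - k
    v = np.sqrt(k) / config.noise_sd - k
    if v <= 0:
        raise ValueError("noise_sd too large for the factor baseline; reduce noise_sd")
    w = rng.normal(size=(n, k))
    m = w @ w.T + v * np.eye(n)
    d = 1.0 / np.sqrt(np.diag(m))
    return m * np.outer(d, d)


def build_target_fc(
    config: CohortConfig,
    rng: np.random.Generator | None = None,
    baseline: np.ndarray | None = None,
    offsets_z: dict[tuple[int, int], float] | None = None,
    psd_tol: float = 1e-8,
) -> np.ndarray:
    """Target correlation matrix for one dog x timepoint.

    Starts from a baseline correlation matrix (drawn from the factor model if
    not supplied), applies planted Fisher-z offsets to specific edges, and
    repairs the result to the nearest positive semi-definite correlation
    matrix.  Because the PSD repair shrinks the very edges it was asked to
    move, the offsets are re-applied iteratively against the repair until the
    achieved z-offsets match the requested ones (within ``offset_tol``), so
    the planted structure survives the projection un-attenuated; iteration
    stops early if the requested offsets are infeasible inside the PSD cone.
    """
    config.validate()
    if baseline is None:
        if rng is None:
            raise ValueError("need an rng to draw a baseline")
        baseline = _factor_baseline(config, rng)
    baseline = np.array(baseline, dtype=float)
    n = config.n_regions
    if baseline.shape != (n, n):
        raise ValueError("baseline has wrong shape")

    def _apply(offsets: dict[tuple[int, int], float]) -> np.ndarray:
        out = baseline.copy()
        for (i, j), dz in offsets.items():
            base = np.clip(out[i, j], -0.995, 0.995)
            val = np.tanh(np.arctanh(base) + dz)
            out[i, j] = out[j, i] = val
        np.fill_diagonal(out, 1.0)
        min_eig = np.linalg.eigvalsh((out + out.T) / 2.0).min()
        if min_eig < -psd_tol:
            out = nearest_correlation(out, tol=psd_tol)
        return out

    if not offsets_z:
        return _apply({})
    offset_tol = 1e-3
    requested = dict(offsets_z)
    applied = dict(requested)
    base_z = {k: np.arctanh(np.clip(baseline[k], -0.995, 0.995)) for k in requested}
    target = _apply(applied)
    for _ in range(10):
        achieved = {
            k: np.arctanh(np.clip(target[k], -0.999999, 0.999999)) - base_z[k]
            for k in requested
        }
        err = {k: requested[k] - achieved[k] for k in requested}
        if max(abs(e) for e in err.values()) < offset_tol:
            break
        applied = {k: applied[k] + err[k] for k in requested}
        target = _apply(applied)
    return target


# ---------------------------------------------------------------------------
# time series and motion
# ---------------------------------------------------------------------------

def _psd_factor(target_fc: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    w, v = np.linalg.eigh((target_fc + target_fc.T) / 2.0)
    if w.min() < -tol:
        raise ValueError("target correlation matrix is not positive semi-definite")
    return v * np.sqrt(np.clip(w, 0.0, None))


def generate_timeseries(
    target_fc: np.ndarray,
    volumes: int,
    rng: np.random.Generator,
    tr_seconds: float = 1.0,
    region_labels: list[str] | None = None,
    ar_coeff: float = 0.0,
) -> RoiTimeSeries:
    """Zero-mean stationary Gaussian samples with the given correlation.

    Default draws are temporally white (the FC analysis is correlation-only,
    so the simplest process whose population FC equals the target suffices);
    ``ar_coeff`` adds optional AR(1) temporal smoothness while preserving the
    stationary cross-correlation exactly.
    """
    target_fc = np.asarray(target_fc, dtype=float)
    n = target_fc.shape[0]
    chol = _psd_factor(target_fc)
    innov = rng.standard_normal((volumes, n)) @ chol.T
    if ar_coeff:
        phi = float(ar_coeff)
        scale = np.sqrt(1.0 - phi**2)
        x = np.empty_like(innov)
        x[0] = innov[0]
        for t in range(1, volumes):
            x[t] = phi * x[t - 1] + scale * innov[t]
    else:
        x = innov
    if region_labels is None:
        region_labels = [f"R{i:02d}" for i in range(n)]
    return RoiTimeSeries(samples=x, region_labels=region_labels, tr_seconds=tr_seconds)


def generate_motion(
    volumes: int,
    spike_prob: float,
    spike_mm: float,
    rng: np.random.Generator,
    tr_seconds: float = 1.0,
) -> MotionTrace:
    """Motion trace: smooth sub-0.01 mm drift plus step displacements.

    Each spike is a sustained level shift of one translation axis by
    ``spike_mm`` (random sign), so exactly the spiked frame exceeds an FD
    threshold below ``spike_mm``; the expected flagged fraction is
    ``spike_prob``.
    """
    if not 0.0 <= spike_prob <= 1.0:
        raise ValueError("spike_prob must be a probability")
    # drift: bounded uniform steps; total per-frame FD from drift < 0.01 mm
    trans_steps = rng.uniform(-0.0012, 0.0012, size=(volumes, 3))
    rot_steps = rng.uniform(-0.0012 / 50.0, 0.0012 / 50.0, size=(volumes, 3))
    trans_steps[0] = 0.0
    rot_steps[0] = 0.0
    spikes = rng.random(volumes) < spike_prob
    spikes[0] = False
    axis = rng.integers(0, 3, size=volumes)
    sign = rng.choice([-1.0, 1.0], size=volumes)
    spike_steps = np.zeros((volumes, 3))
    spike_steps[np.arange(volumes)[spikes], axis[spikes]] = sign[spikes] * spike_mm
    translations = np.cumsum(trans_steps + spike_steps, axis=0)
    rotations = np.cumsum(rot_steps, axis=0)
    return MotionTrace(
        translations_mm=translations, rotations_rad=rotations, tr_seconds=tr_seconds
    )


# ---------------------------------------------------------------------------
# whole-cohort generation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """One generated cohort: manifest, behavior, ground truth, runs, motion."""

    config: CohortConfig
    manifest: pd.DataFrame  # dog_id, sex, label
    behavior: pd.DataFrame  # dog_id, timepoint, retrieve, hunt, environment, ibs
    truth: dict
    runs: dict[tuple[str, str, int], RoiTimeSeries]
    motion: dict[tuple[str, str, int], MotionTrace]

    @property
    def dog_ids(self) -> list[str]:
        return list(self.manifest["dog_id"])

    @property
    def timepoints(self) -> list[str]:
        return list(TIMEPOINTS[: self.config.n_timepoints])

    def labels(self) -> dict[str, str]:
        return dict(zip(self.manifest["dog_id"], self.manifest["label"]))


def _resolve_offsets(
    config: CohortConfig,
    delta_ibs: np.ndarray,
    rng: np.random.Generator,
) -> dict:
    """Translate configured effect sizes into per-dog Fisher-z offsets."""
    n = config.n_dogs
    var_tp = measured_z_variance(config) if config.effect_scale == "observed" else 0.0
    sd_between = np.sqrt(config.noise_sd**2 + var_tp)
    core_dz = {
        (e.i, e.j): e.group_effect_d * (sd_between if config.effect_scale == "observed"
                                        else config.noise_sd)
        for e in config.core_edges
    }
    gamma = config.periphery_group_d * (sd_between if config.effect_scale == "observed"
                                        else config.noise_sd)
    # standardized realized behavior change drives the periphery coupling
    s = delta_ibs.std()
    z_ibs = (delta_ibs - delta_ibs.mean()) / s if s > 0 else np.zeros(n)
    g = config.periphery_increment_sd
    increments: dict[tuple[int, int], np.ndarray] = {}
    periphery_meta = {}
    for e in config.periphery_edges:
        if config.effect_scale == "observed":
            sd_delta = np.sqrt(g**2 + 2.0 * var_tp)
            mean_inc = e.fc_gain * sd_delta
            c = e.coupling_rho * sd_delta / g if g > 0 else 0.0
        else:
            sd_delta = g
            mean_inc = e.fc_gain * config.noise_sd
            c = e.coupling_rho
        if abs(c) > 1.0:
            warnings.warn(
                "periphery_increment_sd too small to realize coupling_rho after "
                "measurement noise; coupling clamped",
                RuntimeWarning,
            )
            c = np.sign(c)
        eps = rng.standard_normal(n)
        increments[(e.i, e.j)] = mean_inc + g * (c * z_ibs + np.sqrt(1.0 - c**2) * eps)
        periphery_meta[(e.i, e.j)] = {"mean_increment_z": float(mean_inc), "mixing": float(c)}
    return {
        "core_dz": core_dz,
        "periphery_group_dz": gamma,
        "periphery_increments": increments,
        "periphery_meta": periphery_meta,
        "measured_z_variance_per_tp": float(var_tp),
    }


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full reproducible cohort (identical config + seed => identical data)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_dogs
    dog_ids = [f"dog{d:02d}" for d in range(n)]
    succ = _success_labels(config)
    sexes = rng.choice(["M", "F"], size=n)
    manifest = pd.DataFrame(
        {
            "dog_id": dog_ids,
            "sex": sexes,
            "label": np.where(succ, "successful", "non_successful"),
        }
    )
    behavior = generate_behavior(config, rng)
    ibs = behavior.pivot(index="dog_id", columns="timepoint", values="ibs").loc[dog_ids]
    delta_ibs = (ibs["TP2"] - ibs["TP1"]).to_numpy(dtype=float) if config.n_timepoints >= 2 \
        else np.zeros(n)
    resolved = _resolve_offsets(config, delta_ibs, rng)

    region_labels = [f"R{i:02d}" for i in range(config.n_regions)]
    tps = list(TIMEPOINTS[: config.n_timepoints])
    runs: dict[tuple[str, str, int], RoiTimeSeries] = {}
    motion: dict[tuple[str, str, int], MotionTrace] = {}
    for d, dog in enumerate(dog_ids):
        baseline = _factor_baseline(config, rng)
        for t, tp in enumerate(tps):
            offsets: dict[tuple[int, int], float] = {}
            if succ[d]:
                for edge, dz in resolved["core_dz"].items():
                    offsets[edge] = offsets.get(edge, 0.0) + dz
                for edge in resolved["periphery_increments"]:
                    offsets[edge] = offsets.get(edge, 0.0) + resolved["periphery_group_dz"]
            if t >= 1:
                for edge, inc in resolved["periphery_increments"].items():
                    offsets[edge] = offsets.get(edge, 0.0) + float(inc[d])
            target = build_target_fc(config, baseline=baseline, offsets_z=offsets)
            for r in range(config.runs_per_tp):
                runs[(dog, tp, r)] = generate_timeseries(
                    target,
                    config.volumes_per_run,
                    rng,
                    tr_seconds=config.tr_seconds,
                    region_labels=region_labels,
                    ar_coeff=config.ar_coeff,
                )
                motion[(dog, tp, r)] = generate_motion(
                    config.volumes_per_run,
                    config.spike_prob,
                    config.spike_mm,
                    rng,
                    tr_seconds=config.tr_seconds,
                )
    truth = {
        "periphery_edges": [asdict(e) for e in config.periphery_edges],
        "core_edges": [asdict(e) for e in config.core_edges],
        "effect_scale": config.effect_scale,
        "periphery_group_dz": resolved["periphery_group_dz"],
        "core_dz": {f"{i},{j}": v for (i, j), v in resolved["core_dz"].items()},
        "periphery_mean_increment_z": {
            f"{i},{j}": m["mean_increment_z"]
            for (i, j), m in resolved["periphery_meta"].items()
        },
        "measured_z_variance_per_tp": resolved["measured_z_variance_per_tp"],
        "seed": config.seed,
    }
    return SyntheticCohort(
        config=config,
        manifest=manifest,
        behavior=behavior,
        truth=truth,
        runs=runs,
        motion=motion,
    )
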