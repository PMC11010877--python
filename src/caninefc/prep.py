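"""Temporal preprocessing of ROI-level BOLD time series.

The pipeline starts from region-averaged time series (one column per brain
region, one row per acquired volume) together with the six rigid-body motion
parameters estimated during realignment.  The stages implemented here are the
temporal half of a standard resting-state pipeline:

1. framewise displacement (FD) from the motion parameters,
2. motion censoring at an FD threshold with linear interpolation of the
   discarded volumes (so that filtering sees a gap-free series),
3. linear detrending,
4. nuisance regression (motion parameters, plus any extra confounds),
5. band-pass filtering, by default an ideal rectangular filter in the
   0.01-0.1 Hz band.

Image-space steps (slice timing, realignment, spatial normalisation,
smoothing) are out of scope; they happen before the ROI series exist.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sp_signal

__all__ = [
    "MotionTrace",
    "RoiTimeSeries",
    "FdSeries",
    "PrepSettings",
    "compute_fd",
    "censor_and_interpolate",
    "regress_nuisance",
    "detrend_bandpass",
    "preprocess_run",
]

DEFAULT_FD_THRESHOLD_MM = 0.2
#: Conventional sphere radius for converting rotations to arc length.  The
#: human default is 50 mm; ``CANINE_HEAD_RADIUS_MM`` is a documented smaller
#: option for dog heads.
DEFAULT_HEAD_RADIUS_MM = 50.0
CANINE_HEAD_RADIUS_MM = 30.0
DEFAULT_BAND_HZ = (0.01, 0.1)


@dataclass
class MotionTrace:
    """Six rigid-body motion parameters for one run.

    Parameters are stored as a T x 3 translation block (mm) and a T x 3
    rotation block (radians), matching the realignment output convention.
    """

    translations_mm: np.ndarray
    rotations_rad: np.ndarray
    tr_seconds: float = 1.0

    def __post_init__(self) -> None:
        self.translations_mm = np.asarray(self.translations_mm, dtype=float)
        self.rotations_rad = np.asarray(self.rotations_rad, dtype=float)
        if self.translations_mm.shape != self.rotations_rad.shape:
            raise ValueError("translation and rotation blocks must have equal shape")
        if self.translations_mm.ndim != 2 or self.translations_mm.shape[1] != 3:
            raise ValueError("motion blocks must be T x 3")

    @property
    def n_frames(self) -> int:
        return self.translations_mm.shape[0]

    def as_matrix(self) -> np.ndarray:
        """T x 6 matrix (tx, ty, tz, rx, ry, rz)."""
        return np.hstack([self.translations_mm, self.rotations_rad])


@dataclass
class RoiTimeSeries:
    """One run's T x N matrix of BOLD samples with region labels.

    ``censor_mask`` marks retained frames (True).  Interpolated frames stay in
    ``samples`` so filtering operates on a complete series, but downstream
    correlations honour the mask.
    """

    samples: np.ndarray
    region_labels: list[str]
    tr_seconds: float = 1.0
    censor_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a T x N matrix")
        t, n = self.samples.shape
        if n < 2:
            raise ValueError("need at least two regions")
        if t < 10:
            raise ValueError("need at least 10 volumes")
        self.region_labels = [str(l) for l in self.region_labels]
        if len(self.region_labels) != n:
            raise ValueError("label count must match column count")
        if len(set(self.region_labels)) != n:
            raise ValueError("region labels must be unique")
        if self.censor_mask is None:
            self.censor_mask = np.ones(t, dtype=bool)
        else:
            self.censor_mask = np.asarray(self.censor_mask, dtype=bool)
            if self.censor_mask.shape != (t,):
                raise ValueError("censor mask length must match volume count")

    @property
    def n_frames(self) -> int:
        return self.samples.shape[0]

    @property
    def n_regions(self) -> int:
        return self.samples.shape[1]


@dataclass
class FdSeries:
    """Per-frame framewise displacement (mm); fd[0] = 0 by convention."""

    fd: np.ndarray
    threshold_mm: float = DEFAULT_FD_THRESHOLD_MM

    def __post_init__(self) -> None:
        self.fd = np.asarray(self.fd, dtype=float)
        if self.fd.ndim != 1:
            raise ValueError("fd must be one-dimensional")
        if self.fd[0] != 0.0:
            raise ValueError("fd[0] must be 0")
        if np.any(self.fd < 0):
            raise ValueError("fd entries must be non-negative")

    def flagged(self) -> np.ndarray:
        """Boolean mask of frames exceeding the censoring threshold."""
        return self.fd > self.threshold_mm


@dataclass(frozen=True)
class PrepSettings:
    """Configuration of the temporal preprocessing chain."""

    fd_threshold_mm: float = DEFAULT_FD_THRESHOLD_MM
    head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ
    filter_kind: str = "ideal"  # "ideal" or "butterworth"
    max_censor_fraction: float = 0.5


def compute_fd(motion: MotionTrace, head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM) -> FdSeries:
    """Framewise displacement: sum of absolute backward differences.

    ``fd[t] = sum|d translations| + head_radius * sum|d rotations|`` with the
    rotation terms converted to arc length on a sphere of the given radius.
    """
    params = motion.as_matrix()
    if params.shape[0] < 2:
        raise ValueError("need at least two frames to compute FD")
    if not np.all(np.isfinite(params)):
        raise ValueError("motion parameters contain non-finite values")
    diffs = np.abs(np.diff(params, axis=0))
    fd_tail = diffs[:, :3].sum(axis=1) + head_radius_mm * diffs[:, 3:].sum(axis=1)
    fd = np.concatenate([[0.0], fd_tail])
    return FdSeries(fd=fd)


def censor_and_interpolate(ts: RoiTimeSeries, fd: FdSeries) -> RoiTimeSeries:
    """Censor frames with FD above threshold and fill them by interpolation.

    Censored samples are replaced by linear interpolation between the nearest
    retained neighbours (edge frames are held at the nearest retained value),
    and ``censor_mask`` records which frames were discarded so correlations
    can exclude them again.  A run with more than half its frames flagged is
    rejected as unusable.
    """
    if fd.fd.shape[0] != ts.n_frames:
        raise ValueError("FD series length must match the time series")
    bad = fd.flagged()
    frac = bad.mean()
    if frac > 0.5:
        raise ValueError(
            f"{frac:.0%} of frames exceed FD {fd.threshold_mm} mm; run rejected as unusable"
        )
    mask = ~bad
    samples = ts.samples.copy()
    if bad.any():
        t_idx = np.arange(ts.n_frames)
        good = t_idx[mask]
        for col in range(ts.n_regions):
            samples[bad, col] = np.interp(t_idx[bad], good, samples[mask, col])
    return RoiTimeSeries(
        samples=samples,
        region_labels=list(ts.region_labels),
        tr_seconds=ts.tr_seconds,
        censor_mask=ts.censor_mask & mask,
    )


def regress_nuisance(ts: RoiTimeSeries, confounds: np.ndarray) -> RoiTimeSeries:
    """Regress confound columns (plus an intercept) out of every region.

    Returns least-squares residuals, orthogonal to every confound column.
    Rank-deficient confound matrices are handled by the pseudo-inverse with a
    warning rather than an error.
    """
    confounds = np.asarray(confounds, dtype=float)
    if confounds.ndim == 1:
        confounds = confounds[:, None]
    if confounds.shape[0] != ts.n_frames:
        raise ValueError("confound row count must match the time series")
    design = np.column_stack([np.ones(ts.n_frames), confounds])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn("confound matrix is rank deficient; using pseudo-inverse", RuntimeWarning)
    beta = np.linalg.pinv(design) @ ts.samples
    resid = ts.samples - design @ beta
    return replace(ts, samples=resid)


def _linear_detrend(x: np.ndarray) -> np.ndarray:
    """Remove the least-squares line (intercept + slope) from each column."""
    t = np.arange(x.shape[0], dtype=float)
    t = t - t.mean()
    denom = t @ t
    slope = (t @ x) / denom
    return x - x.mean(axis=0) - np.outer(t, slope)


def _band_mask(n_frames: int, tr_seconds: float, low_hz: float, high_hz: float) -> np.ndarray:
    freqs = np.fft.rfftfreq(n_frames, d=tr_seconds)
    return (freqs >= low_hz) & (freqs <= high_hz)


def _ideal_bandpass(x: np.ndarray, tr_seconds: float, low_hz: float, high_hz: float) -> np.ndarray:
    """Orthogonal projection onto the Fourier band subspace.

    No time-domain detrend precedes this projection: a least-squares ramp fit
    couples to any finite sinusoid sample, and the subtracted ramp has
    broadband spectrum, so it would leak back into the pass band and break the
    exact-attenuation property.  Drift removal is spectral instead — the
    rectangular high-pass edge discards the DC and near-DC bins that carry a
    slow drift's energy — and the projection is exactly idempotent.
    """
    spec = np.fft.rfft(x, axis=0)
    keep = _band_mask(x.shape[0], tr_seconds, low_hz, high_hz)
    spec[~keep] = 0.0
    return np.fft.irfft(spec, n=x.shape[0], axis=0)


def _butter_bandpass(x: np.ndarray, tr_seconds: float, low_hz: float, high_hz: float,
                     order: int = 4) -> np.ndarray:
    nyq = 0.5 / tr_seconds
    b, a = sp_signal.butter(order, [low_hz / nyq, high_hz / nyq], btype="band")
    y = sp_signal.filtfilt(b, a, x, axis=0)
    return y - y.mean(axis=0)


def detrend_bandpass(
    ts: RoiTimeSeries,
    low_hz: float = DEFAULT_BAND_HZ[0],
    high_hz: float = DEFAULT_BAND_HZ[1],
    filter_kind: str = "ideal",
) -> RoiTimeSeries:
    """Detrend and band-pass filter every region.

    The default filter zeroes Fourier components outside [low_hz, high_hz]
    (ideal rectangular response, exact attenuation for bin-aligned
    frequencies); detrending is then spectral — DC and sub-band drift bins are
    zeroed by the same projection, and no time-domain ramp fit is applied
    because its broadband leakage would re-enter the pass band.
    ``filter_kind="butterworth"`` selects a 4th-order zero-phase Butterworth
    alternative with an explicit least-squares linear detrend first.
    """
    nyquist = 0.5 / ts.tr_seconds
    if not (0.0 < low_hz < high_hz < nyquist):
        raise ValueError(f"band must satisfy 0 < low < high < Nyquist ({nyquist:g} Hz)")
    if filter_kind == "ideal":
        filtered = _ideal_bandpass(ts.samples, ts.tr_seconds, low_hz, high_hz)
    elif filter_kind == "butterworth":
        filtered = _butter_bandpass(_linear_detrend(ts.samples), ts.tr_seconds, low_hz, high_hz)
    else:
        raise ValueError(f"unknown filter kind: {filter_kind!r}")
    return replace(ts, samples=filtered)


def preprocess_run(
    ts: RoiTimeSeries,
    motion: MotionTrace,
    settings: PrepSettings = PrepSettings(),
    extra_confounds: np.ndarray | None = None,
) -> RoiTimeSeries:
    """Full temporal chain: censor -> interpolate -> detrend -> nuisance -> band-pass.

    The six motion parameters (and any extra confounds, e.g. tissue signals)
    are regressed out between detrending and filtering.  The censor mask from
    the FD step is carried through so connectivity can exclude interpolated
    frames.
    """
    if motion.n_frames != ts.n_frames:
        raise ValueError("motion trace length must match the time series")
    fd = compute_fd(motion, head_radius_mm=settings.head_radius_mm)
    fd.threshold_mm = settings.fd_threshold_mm
    if fd.flagged().mean() > settings.max_censor_fraction:
        raise ValueError("run rejected: censored fraction exceeds limit")
    clean = censor_and_interpolate(ts, fd)
    if settings.filter_kind != "ideal":
        # the ideal projection detrends spectrally; a time-domain ramp fit
        # before it would leak broadband ramp energy into the pass band
        clean = replace(clean, samples=_linear_detrend(clean.samples))
    confounds = motion.as_matrix()
    if extra_confounds is not None:
        confounds = np.column_stack([confounds, extra_confounds])
    clean = regress_nuisance(clean, confounds)
    if settings.filter_kind == "ideal":
        filtered = _ideal_bandpass(clean.samples, ts.tr_seconds, *settings.band_hz)
    else:
        filtered = _butter_bandpass(clean.samples, ts.tr_seconds, *settings.band_hz)
    return replace(clean, samples=filtered)
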