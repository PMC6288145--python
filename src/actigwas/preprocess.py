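"""Raw triaxial acceleration -> calibrated, resampled, 30-s epoch summaries.

The processing chain mirrors the standard UK Biobank accelerometer pipeline:

1. **Autocalibration** — per-axis gain and offset are estimated by iterated
   least squares that maps the mean acceleration vector of stationary windows
   onto the unit-gravity sphere.  During a truly stationary period the only
   acceleration is gravity, so the measured vector should have Euclidean norm
   exactly 1 g; deviations are attributed to gain/offset miscalibration.
2. **Resampling** — linear interpolation onto a uniform grid (nominally
   100 Hz).  Recording gaps longer than one second are left as missing (NaN)
   rather than interpolated across.
3. **Epoch summaries** — non-overlapping 30-s epochs, each reduced to its
   ENMO (Euclidean norm minus one, truncated at zero, in milli-gravity),
   per-axis standard deviations, and the fraction of samples at the clip
   limit of the device's dynamic range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "RawRecording",
    "CalibrationResult",
    "EpochSeries",
    "calibrate",
    "resample",
    "epoch_summaries",
]

GRAVITY_G = 1.0  # working unit is g throughout


@dataclass
class RawRecording:
    """Timestamped triaxial acceleration in g.

    ``times`` is strictly increasing, in seconds from an arbitrary origin
    (``t0_clock_s`` gives the clock time of the origin, seconds past local
    midnight, used for time-of-day logic downstream).  ``accel`` is an
    (n, 3) array; NaN rows mark recording gaps introduced by :func:`resample`.
    """

    times: np.ndarray
    accel: np.ndarray
    clip_limit: float = 8.0
    t0_clock_s: float = 0.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        if self.accel.ndim != 2 or self.accel.shape[1] != 3:
            raise ValueError("accel must be an (n, 3) array")
        if self.times.shape[0] != self.accel.shape[0]:
            raise ValueError("times and accel lengths differ")
        if self.times.size == 0:
            raise ValueError("empty recording")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.clip_limit <= 0:
            raise ValueError("clip_limit must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.times.size)

    @property
    def duration_s(self) -> float:
        return float(self.times[-1] - self.times[0])

    def sample_rate(self) -> float:
        """Median sampling rate in Hz."""
        return float(1.0 / np.median(np.diff(self.times)))


@dataclass
class CalibrationResult:
    gain: np.ndarray          # per-axis multiplicative correction (unitless)
    offset_mg: np.ndarray     # per-axis additive correction, in mg
    residual_mg: float        # mean | ||v_corrected|| - 1 g | over stationary points, mg
    n_stationary: int
    ok: bool

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        self.offset_mg = np.asarray(self.offset_mg, dtype=float)
        if self.residual_mg < 0:
            raise ValueError("residual must be non-negative")


@dataclass
class EpochSeries:
    """Aligned per-epoch summaries; the unit of classification downstream.

    Epochs are half-open ``[start, start + epoch_s)`` intervals anchored at
    the recording start; a trailing partial epoch is dropped.  ``enmo`` and
    ``axis_sd`` are in mg.  ``wear``/``state``/``features`` are filled in by
    later stages.
    """

    epoch_start: np.ndarray            # s, absolute (recording time base)
    enmo: np.ndarray                   # mg
    axis_sd: np.ndarray                # (n, 3) mg
    clipped_fraction: np.ndarray
    epoch_s: float = 30.0
    t0_clock_s: float = 0.0            # clock time of the first epoch start
    wear: np.ndarray | None = None
    state: np.ndarray | None = None    # int labels, -1 = unknown
    features: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.epoch_start = np.asarray(self.epoch_start, dtype=float)
        self.enmo = np.asarray(self.enmo, dtype=float)
        self.axis_sd = np.asarray(self.axis_sd, dtype=float)
        self.clipped_fraction = np.asarray(self.clipped_fraction, dtype=float)
        n = self.epoch_start.size
        if not (self.enmo.size == n and self.axis_sd.shape == (n, 3) and self.clipped_fraction.size == n):
            raise ValueError("epoch arrays misaligned")
        with np.errstate(invalid="ignore"):
            if np.any(self.enmo[np.isfinite(self.enmo)] < 0):
                raise ValueError("ENMO must be non-negative")
            cf = self.clipped_fraction[np.isfinite(self.clipped_fraction)]
            if np.any((cf < 0) | (cf > 1)):
                raise ValueError("clipped_fraction outside [0, 1]")
        if self.wear is None:
            self.wear = np.ones(n, dtype=bool)

    @property
    def n_epochs(self) -> int:
        return int(self.epoch_start.size)

    def clock_slot(self, slots_per_day: int | None = None) -> np.ndarray:
        """Clock slot index of each epoch (default: one slot per epoch length)."""
        day = 86400.0
        if slots_per_day is None:
            slots_per_day = int(round(day / self.epoch_s))
        slot_s = day / slots_per_day
        clock = (self.t0_clock_s + (self.epoch_start - self.epoch_start[0])) % day
        return (clock / slot_s).astype(int) % slots_per_day

    def day_index(self) -> np.ndarray:
        day = 86400.0
        abs_clock = self.t0_clock_s + (self.epoch_start - self.epoch_start[0])
        return (abs_clock // day).astype(int)


# ---------------------------------------------------------------------------
# calibration


def _stationary_window_means(
    raw: RawRecording,
    window_s: float,
    sd_thresh_mg: float,
) -> np.ndarray:
    """Mean acceleration vectors of stationary windows (all axis SDs < threshold)."""
    rate = raw.sample_rate()
    n_win = max(1, int(round(window_s * rate)))
    n = (raw.n_samples // n_win) * n_win
    if n == 0:
        return np.empty((0, 3))
    a = raw.accel[:n].reshape(-1, n_win, 3)
    ok = np.all(np.isfinite(a), axis=(1, 2))
    sd = np.nanstd(a, axis=1)  # (n_windows, 3) in g
    stat = ok & np.all(sd * 1000.0 < sd_thresh_mg, axis=1)
    return a[stat].mean(axis=1)


def calibrate(
    raw: RawRecording,
    sd_thresh_mg: float = 13.0,
    window_s: float = 10.0,
    min_stationary: int = 10,
    residual_max_mg: float = 10.0,
    sphere_crit_g: float = 0.3,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> tuple[RawRecording, CalibrationResult]:
    """Estimate and apply per-axis gain/offset so stationary vectors lie on the unit sphere.

    Iterated least squares: each stationary-window mean vector is projected to
    its closest point on the unit sphere and each axis is regressed onto that
    target; the per-axis linear maps compose across iterations.  Gain and
    offset are only identifiable when the stationary orientations cover the
    sphere, so calibration additionally requires values beyond
    +/-``sphere_crit_g`` on every axis.  When too few stationary windows
    exist, coverage is inadequate, or the final residual exceeds
    ``residual_max_mg``, ``ok`` is False and the input is returned unchanged.
    """
    if raw.duration_s < 3600.0:
        raise ValueError("calibration requires a recording spanning at least 1 h")
    pts = _stationary_window_means(raw, window_s, sd_thresh_mg)
    identity = CalibrationResult(np.ones(3), np.zeros(3), np.nan, len(pts), False)
    covered = len(pts) > 0 and bool(
        np.all(pts.min(axis=0) < -sphere_crit_g) and np.all(pts.max(axis=0) > sphere_crit_g)
    )
    if len(pts) < min_stationary or not covered:
        identity.residual_mg = float("inf")
        return raw, identity

    gain = np.ones(3)
    offset = np.zeros(3)  # in g
    cur = pts.copy()
    prev_res = np.inf
    for _ in range(max_iter):
        norms = np.linalg.norm(cur, axis=1)
        keep = norms > 1e-6
        target = cur[keep] / norms[keep, None]
        res = float(np.mean(np.abs(norms[keep] - 1.0)))
        if abs(prev_res - res) < tol:
            break
        prev_res = res
        for ax in range(3):
            x = cur[keep, ax]
            A = np.column_stack([x, np.ones_like(x)])
            (g, o), *_ = np.linalg.lstsq(A, target[:, ax], rcond=None)
            gain[ax] *= g
            offset[ax] = offset[ax] * g + o
            cur[:, ax] = cur[:, ax] * g + o
    residual_mg = float(np.mean(np.abs(np.linalg.norm(cur, axis=1) - 1.0)) * 1000.0)
    ok = residual_mg <= residual_max_mg
    result = CalibrationResult(gain, offset * 1000.0, residual_mg, len(pts), ok)
    if not ok:
        return raw, result
    corrected = raw.accel * gain + offset
    out = RawRecording(raw.times, corrected, raw.clip_limit, raw.t0_clock_s, dict(raw.meta))
    return out, result


# ---------------------------------------------------------------------------
# resampling


def resample(raw: RawRecording, target_rate: float = 100.0, max_gap_s: float = 1.0) -> RawRecording:
    """Linear interpolation onto a uniform grid; gaps > ``max_gap_s`` become NaN."""
    if raw.n_samples < 2:
        raise ValueError("resampling requires at least 2 samples")
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    dt = 1.0 / target_rate
    grid = np.arange(raw.times[0], raw.times[-1] + 0.5 * dt, dt)
    out = np.empty((grid.size, 3))
    for ax in range(3):
        out[:, ax] = np.interp(grid, raw.times, raw.accel[:, ax])
    # mark samples that fall inside a recording gap as missing
    gaps = np.diff(raw.times)
    gap_idx = np.nonzero(gaps > max_gap_s)[0]
    for i in gap_idx:
        lo, hi = raw.times[i], raw.times[i + 1]
        out[(grid > lo) & (grid < hi)] = np.nan
    return RawRecording(grid, out, raw.clip_limit, raw.t0_clock_s, dict(raw.meta))


# ---------------------------------------------------------------------------
# epoch summaries


def epoch_summaries(raw: RawRecording, epoch_s: float = 30.0) -> EpochSeries:
    """Reduce a calibrated, uniformly sampled recording to 30-s epoch summaries.

    Per epoch: ENMO = mean of max(0, ||v|| - 1 g) in mg; per-axis SD in mg;
    clipped_fraction = fraction of samples with any axis at or beyond the
    clip limit.  NaN samples (gaps) are excluded from the means; an epoch
    that is entirely missing gets NaN summaries.
    """
    rate = raw.sample_rate()
    n_per = int(round(epoch_s * rate))
    if n_per < 1:
        raise ValueError("epoch shorter than one sample")
    n_full = raw.n_samples // n_per
    if n_full == 0:
        raise ValueError("recording shorter than one epoch")
    a = raw.accel[: n_full * n_per].reshape(n_full, n_per, 3)
    t = raw.times[: n_full * n_per : n_per]

    with np.errstate(invalid="ignore"):
        vm = np.linalg.norm(a, axis=2)
        enmo_g = np.clip(vm - GRAVITY_G, 0.0, None)
        valid = np.isfinite(vm)
        any_valid = valid.any(axis=1)
        enmo = np.full(n_full, np.nan)
        enmo[any_valid] = np.nanmean(np.where(valid, enmo_g, np.nan), axis=1)[any_valid] * 1000.0
        sd = np.full((n_full, 3), np.nan)
        sd[any_valid] = np.nanstd(a[any_valid], axis=1) * 1000.0
        clipped = np.abs(a) >= raw.clip_limit - 1e-9
        clipped_fraction = np.where(
            any_valid,
            np.nansum(np.any(clipped, axis=2) & valid, axis=1) / np.maximum(valid.sum(axis=1), 1),
            np.nan,
        )
    return EpochSeries(
        epoch_start=t,
        enmo=enmo,
        axis_sd=sd,
        clipped_fraction=clipped_fraction,
        epoch_s=epoch_s,
        t0_clock_s=raw.t0_clock_s,
    )
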