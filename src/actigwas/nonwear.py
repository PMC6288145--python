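"""Non-wear detection, time-of-day imputation, and participant-level QC.

Non-wear is identified as consecutive stationary episodes lasting at least
60 minutes: an epoch is stationary when all three axis standard deviations
are below 13 mg, and any maximal run of at least 120 such 30-s epochs is
flagged as non-wear.  Flagged epochs are imputed with the average of worn
epochs at the same clock slot (one of 2880 30-s slots per day) on other
days of the measurement, separately for ENMO and for each behaviour
probability.

Participants are excluded when the device could not be calibrated, too many
samples sat at the clip limit, mean ENMO is implausibly high (> 100 mg), or
wear time is insufficient (< 72 h worn, or some 1-h clock period never
covered by worn data).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import DEFAULT_CONFIG, PipelineConfig
from .preprocess import CalibrationResult, EpochSeries

__all__ = ["WearMask", "QcReport", "detect_nonwear", "impute_nonwear", "participant_qc"]

REASON_CODES = ("calibration_failed", "too_many_clipped", "value_too_high", "insufficient_wear")


@dataclass
class WearMask:
    wear: np.ndarray                               # per-epoch boolean
    episodes: list[tuple[int, int, str]] = field(default_factory=list)
    # episodes are half-open [start, end) epoch-index runs, type 'wear'/'nonwear'

    def __post_init__(self) -> None:
        self.wear = np.asarray(self.wear, dtype=bool)

    @property
    def n_epochs(self) -> int:
        return int(self.wear.size)


@dataclass
class QcReport:
    included: bool
    reasons: list[str]
    wear_hours: float
    hour_coverage: np.ndarray          # 24 booleans
    mean_enmo: float

    def __post_init__(self) -> None:
        self.hour_coverage = np.asarray(self.hour_coverage, dtype=bool)
        if self.included != (len(self.reasons) == 0):
            raise ValueError("included must hold exactly when reasons is empty")


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open (start, end) index pairs."""
    out = []
    n = mask.size
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def detect_nonwear(
    epochs: EpochSeries,
    sd_thresh_mg: float = DEFAULT_CONFIG.stationary_sd_mg,
    min_minutes: float = DEFAULT_CONFIG.nonwear_min,
) -> WearMask:
    """Flag maximal stationary runs of >= ``min_minutes`` as non-wear.

    Stationary: all three axis SDs < ``sd_thresh_mg``.  Epochs with missing
    axis SDs (recording gaps) count as stationary for run-building purposes
    so that a gap inside a stationary stretch does not split the episode.
    """
    sd = epochs.axis_sd
    with np.errstate(invalid="ignore"):
        stationary = np.all(sd < sd_thresh_mg, axis=1) | ~np.all(np.isfinite(sd), axis=1)
    min_epochs = int(round(min_minutes * 60.0 / epochs.epoch_s))
    wear = np.ones(epochs.n_epochs, dtype=bool)
    episodes: list[tuple[int, int, str]] = []
    for start, end in _runs(stationary):
        if end - start >= min_epochs:
            wear[start:end] = False
    for start, end in _runs(~wear):
        episodes.append((start, end, "nonwear"))
    for start, end in _runs(wear):
        episodes.append((start, end, "wear"))
    episodes.sort()
    return WearMask(wear, episodes)


def impute_nonwear(
    epochs: EpochSeries,
    probs: np.ndarray | None,
    mask: WearMask,
) -> tuple[EpochSeries, np.ndarray | None, np.ndarray]:
    """Impute non-wear epochs from same-clock-slot worn epochs on other days.

    For each non-wear epoch at clock slot t, ENMO and each behaviour
    probability are replaced by the mean over worn epochs at slot t on
    *different* days; the label becomes the argmax of the imputed
    probabilities.  Slots with no worn donor stay missing (NaN).

    Returns (imputed epochs, imputed probs, imputed_flag) where
    ``imputed_flag`` marks epochs that received donor values.
    """
    if mask.n_epochs != epochs.n_epochs:
        raise ValueError("mask not aligned to epochs")
    slots = epochs.clock_slot()
    days = epochs.day_index()
    wear = mask.wear
    enmo = epochs.enmo.copy()
    new_probs = probs.copy() if probs is not None else None
    imputed = np.zeros(epochs.n_epochs, dtype=bool)

    targets = np.flatnonzero(~wear)
    if targets.size:
        # donors grouped by slot once
        worn_idx = np.flatnonzero(wear & np.isfinite(epochs.enmo))
        donor_by_slot: dict[int, np.ndarray] = {
            s: worn_idx[slots[worn_idx] == s]
            for s in set(int(slots[i]) for i in worn_idx)
        }
        for i in targets:
            donors = donor_by_slot.get(int(slots[i]))
            if donors is None:
                enmo[i] = np.nan
                continue
            donors = donors[days[donors] != days[i]]
            if donors.size == 0:
                enmo[i] = np.nan
                continue
            enmo[i] = float(np.mean(epochs.enmo[donors]))
            if new_probs is not None:
                new_probs[i] = probs[donors].mean(axis=0)
            imputed[i] = True

    out = EpochSeries(
        epoch_start=epochs.epoch_start,
        enmo=enmo,
        axis_sd=epochs.axis_sd,
        clipped_fraction=epochs.clipped_fraction,
        epoch_s=epochs.epoch_s,
        t0_clock_s=epochs.t0_clock_s,
        wear=mask.wear.copy(),
        state=epochs.state,
        features=epochs.features,
    )
    return out, new_probs, imputed


def participant_qc(
    epochs: EpochSeries,
    calib: CalibrationResult,
    mask: WearMask,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> QcReport:
    """Apply the participant-level inclusion rules.

    Exclusion reasons: ``calibration_failed`` (autocalibration did not
    converge), ``too_many_clipped`` (recording-wide clipped fraction above
    threshold), ``value_too_high`` (mean ENMO > 100 mg), and
    ``insufficient_wear`` (< 72 h worn, or a 1-h clock period with no worn
    epoch).  Only worn epochs count toward wear time and hour coverage.
    """
    reasons: list[str] = []
    if not calib.ok:
        reasons.append("calibration_failed")
    with np.errstate(invalid="ignore"):
        cf = epochs.clipped_fraction
        overall_clipped = float(np.nanmean(cf)) if np.isfinite(cf).any() else 0.0
    if overall_clipped > config.clipped_fraction_max:
        reasons.append("too_many_clipped")
    valid = np.isfinite(epochs.enmo)
    mean_enmo = float(np.mean(epochs.enmo[valid])) if valid.any() else float("nan")
    if np.isfinite(mean_enmo) and mean_enmo > config.enmo_max_mg:
        reasons.append("value_too_high")

    wear = mask.wear
    wear_hours = float(wear.sum() * epochs.epoch_s / 3600.0)
    clock_hour = (epochs.clock_slot(slots_per_day=24)).astype(int)
    hour_coverage = np.zeros(24, dtype=bool)
    for h in range(24):
        hour_coverage[h] = bool(np.any(wear & (clock_hour == h)))
    if wear_hours < config.min_wear_h or not hour_coverage.all():
        reasons.append("insufficient_wear")

    return QcReport(
        included=not reasons,
        reasons=reasons,
        wear_hours=wear_hours,
        hour_coverage=hour_coverage,
        mean_enmo=mean_enmo,
    )
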