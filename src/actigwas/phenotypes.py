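"""Per-participant phenotype derivation.

After classification and non-wear imputation, each participant is reduced
to the traits carried into genetic analysis: overall activity (mean ENMO in
mg over worn and imputed epochs), the fraction of time in each behaviour
(epoch predictions for a class divided by all classified epochs), sleep
duration in hours/day (sleep fraction x 24), and short/long-sleep flags
(bottom/top quintile of the cohort sleep-duration distribution).

Clinical derivations used by the Mendelian-randomisation stage are also
here: hypertension (SBP > 140 mmHg, or DBP > 90 mmHg, or blood-pressure
medication use, evaluated on raw pressures) and medication-adjusted
continuous pressures (+15 mmHg systolic, +10 mmHg diastolic for medicated
participants).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classifier import STATES
from .nonwear import WearMask
from .preprocess import EpochSeries

__all__ = [
    "BloodPressureRecord",
    "summarize_behaviours",
    "overall_activity",
    "sleep_extreme_flags",
    "derive_hypertension",
]


def summarize_behaviours(
    labels: np.ndarray,
    mask: WearMask | None = None,
    states: tuple[str, ...] = STATES,
) -> dict[str, dict[str, float]]:
    """Per-state time fractions and hours/day from an epoch label sequence.

    ``labels`` is the post-imputation sequence (worn + imputed epochs);
    epochs whose label is missing (None/'' / negative index) are excluded
    from the denominator.  fraction_s = #epochs labelled s / #labelled
    epochs; hours/day = 24 x fraction.
    """
    labels = np.asarray(labels)
    if labels.dtype.kind in "iu":
        known = labels >= 0
        names = np.array(states)[labels[known]]
    else:
        known = np.array([l is not None and str(l) in states for l in labels])
        names = labels[known].astype(str)
    n = int(known.sum())
    if n == 0:
        raise ValueError("no labelled epochs")
    fractions = {s: float(np.sum(names == s)) / n for s in states}
    hours = {s: 24.0 * f for s, f in fractions.items()}
    return {"fraction": fractions, "hours_per_day": hours}


def overall_activity(epochs: EpochSeries, mask: WearMask | None = None) -> float:
    """Mean ENMO (mg) over worn + imputed epochs — the overall-activity trait.

    Imputed non-wear epochs carry finite ENMO and are included;
    un-imputable epochs are NaN and drop out.
    """
    enmo = epochs.enmo
    valid = np.isfinite(enmo)
    if not valid.any():
        raise ValueError("no usable epochs")
    return float(np.mean(enmo[valid]))


def sleep_extreme_flags(cohort_sleep_hours: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Bottom/top-quintile sleep-duration flags across a cohort.

    short iff value <= 20th percentile, long iff value >= 80th percentile
    (linear-interpolation percentiles, inclusive comparisons).  With fewer
    than 5 participants quintiles are meaningless and the call is rejected.
    Note the degenerate case: if all values are equal, every participant is
    flagged both short and long under this convention.
    """
    x = np.asarray(cohort_sleep_hours, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 participants for quintile flags")
    lo = np.percentile(x, 20)
    hi = np.percentile(x, 80)
    return x <= lo, x >= hi


@dataclass
class BloodPressureRecord:
    sbp: float
    dbp: float
    on_medication: bool
    sbp_adj: float = float("nan")
    dbp_adj: float = float("nan")
    hypertensive: bool | None = None


def derive_hypertension(sbp: float, dbp: float, on_medication: bool) -> BloodPressureRecord:
    """Hypertension case definition and medication-adjusted pressures.

    hypertensive = (SBP > 140) or (DBP > 90) or medication use — strict
    inequalities, evaluated on raw pressures.  For continuous-trait analyses
    the adjusted pressures add 15/10 mmHg (systolic/diastolic) when the
    participant is on blood-pressure medication.  Missing pressures without
    medication use give a missing outcome.
    """
    missing = not (np.isfinite(sbp) and np.isfinite(dbp))
    if missing and not on_medication:
        return BloodPressureRecord(sbp, dbp, on_medication, hypertensive=None)
    if not missing and (sbp < 0 or dbp < 0):
        raise ValueError("pressures must be non-negative")
    hyper = bool(on_medication or (not missing and (sbp > 140.0 or dbp > 90.0)))
    sbp_adj = sbp + 15.0 if on_medication else sbp
    dbp_adj = dbp + 10.0 if on_medication else dbp
    return BloodPressureRecord(sbp, dbp, on_medication, sbp_adj, dbp_adj, hyper)
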