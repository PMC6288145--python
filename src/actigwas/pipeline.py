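"""End-to-end phenotyping: raw recording -> QC report + phenotype row.

Chains preprocessing (calibration, resampling, epoching), feature
extraction, classification with HMM smoothing, non-wear detection and
imputation, participant QC, and phenotype summarisation.  Per-stage counts
are collected for logging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

from .classifier import STATES, BalancedRandomForest, HmmParams, viterbi_smooth
from .config import DEFAULT_CONFIG, PipelineConfig
from .features import extract_feature_matrix
from .nonwear import detect_nonwear, impute_nonwear, participant_qc
from .phenotypes import overall_activity, summarize_behaviours
from .preprocess import RawRecording, calibrate, epoch_summaries, resample


@dataclass
class PhenotypingResult:
    qc: Any
    phenotypes: dict | None
    labels: np.ndarray | None
    stage_counts: dict[str, Any]


def run_phenotyping(
    raw: RawRecording,
    model: BalancedRandomForest | None = None,
    hmm: HmmParams | None = None,
    config: PipelineConfig = DEFAULT_CONFIG,
    truth_labels: np.ndarray | None = None,
) -> PhenotypingResult:
    """Run the full behaviour-phenotyping chain on one recording.

    When no classifier model is supplied, ``truth_labels`` (e.g. from a
    simulation) may stand in for the predicted sequence; one of the two must
    be present.  Phenotypes are returned only for participants passing QC.
    """
    counts: dict[str, Any] = {"n_samples_in": raw.n_samples}
    raw = resample(raw, config.sample_rate)
    cal_raw, calib = calibrate(
        raw,
        sd_thresh_mg=config.stationary_sd_mg,
        window_s=config.stationary_window_s,
        min_stationary=config.calib_min_stationary,
        residual_max_mg=config.calib_residual_max_mg,
    )
    counts["calibration_ok"] = calib.ok
    epochs = epoch_summaries(cal_raw, config.epoch_s)
    counts["n_epochs"] = epochs.n_epochs

    if model is not None:
        feats = extract_feature_matrix(cal_raw, config.epoch_s)
        proba = model.predict_proba(feats)
        labels = model.classes_[proba.argmax(axis=1)]
        if hmm is not None:
            labels = viterbi_smooth(labels, hmm)
    elif truth_labels is not None:
        labels = np.asarray(truth_labels)
        idx = labels if labels.dtype.kind in "iu" else np.array(
            [STATES.index(l) for l in labels])
        proba = np.eye(len(STATES))[idx]
    else:
        raise ValueError("either a classifier model or truth labels are required")

    mask = detect_nonwear(epochs, config.stationary_sd_mg, config.nonwear_min)
    counts["n_nonwear_epochs"] = int((~mask.wear).sum())
    epochs_imp, proba_imp, imputed = impute_nonwear(epochs, proba, mask)
    counts["n_imputed_epochs"] = int(imputed.sum())
    if proba_imp is not None:
        lab_idx = proba_imp.argmax(axis=1)
        labels = (lab_idx if np.asarray(labels).dtype.kind in "iu"
                  else np.asarray([STATES[i] for i in lab_idx]))

    qc = participant_qc(epochs_imp, calib, mask, config)
    counts["qc_reasons"] = list(qc.reasons)
    if not qc.included:
        return PhenotypingResult(qc, None, labels, counts)

    lab_for_summary = np.asarray(labels)[mask.wear | imputed]
    behav = summarize_behaviours(lab_for_summary)
    phen = {
        "overall_activity_mg": overall_activity(epochs_imp, mask),
        **{f"fraction_{s}": behav["fraction"][s] for s in STATES},
        **{f"hours_{s}": behav["hours_per_day"][s] for s in STATES},
        "sleep_duration_h": behav["hours_per_day"]["sleep"],
    }
    return PhenotypingResult(qc, phen, labels, counts)
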