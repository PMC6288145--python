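"""Per-epoch feature extraction for activity classification.

Each 30-s window of triaxial acceleration is reduced to a fixed,
126-dimensional vector mixing time-domain statistics (per-axis and
ENMO moments, quartiles, median absolute deviation, inter-axis
correlations, roll/pitch orientation statistics, signal energy,
zero-crossing rates) and frequency-domain statistics (dominant
frequencies and their power, spectral entropy, power in fixed bands,
short-lag autocorrelation of the ENMO trace).

The vector is deterministic, its name list is stable across runs, and
every entry is finite for every valid window: statistics that are
undefined on degenerate input (correlation of a constant axis, skewness
at zero variance) are 0 by convention.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sstats

__all__ = ["FEATURE_NAMES", "N_FEATURES", "extract_features", "extract_feature_matrix"]

_AXES = ("x", "y", "z")
# fixed analysis bands in Hz; bands above the Nyquist of a given recording
# simply carry zero power
_BANDS = ((0.1, 0.5), (0.5, 1.0), (1.0, 2.0), (2.0, 3.0),
          (3.0, 4.0), (4.0, 5.0), (5.0, 7.5), (7.5, 10.0))
_ACF_LAGS_S = tuple(round(0.1 * k, 1) for k in range(1, 21))  # 0.1 .. 2.0 s

_TIME_STATS = ("mean", "sd", "range", "min", "max", "q25", "median", "q75",
               "skew", "kurtosis", "mad")


def _build_names() -> list[str]:
    names: list[str] = []
    for ax in _AXES:
        names += [f"{ax}_{s}" for s in _TIME_STATS]
    names += [f"enmo_{s}" for s in _TIME_STATS]
    names += ["corr_xy", "corr_xz", "corr_yz"]
    names += ["roll_mean", "roll_sd", "pitch_mean", "pitch_sd"]
    for ax in _AXES:
        names += [f"{ax}_dom_freq", f"{ax}_dom_power", f"{ax}_spec_entropy"]
    for ax in _AXES:
        names += [f"{ax}_band_{lo}_{hi}" for lo, hi in _BANDS]
    names += ["enmo_dom_freq", "enmo_dom_power", "enmo_dom2_freq",
              "enmo_dom2_power", "enmo_spec_entropy", "enmo_total_power"]
    names += [f"enmo_band_{lo}_{hi}" for lo, hi in _BANDS]
    names += [f"enmo_acf_{lag}s" for lag in _ACF_LAGS_S]
    names += [f"{ax}_energy" for ax in _AXES]
    names += ["enmo_energy", "enmo_zero_cross"]
    names += [f"{ax}_zero_cross" for ax in _AXES]
    return names


FEATURE_NAMES: tuple[str, ...] = tuple(_build_names())
N_FEATURES: int = len(FEATURE_NAMES)
assert N_FEATURES == 126, f"feature vector must have 126 entries, got {N_FEATURES}"


def _safe(v: float) -> float:
    return float(v) if np.isfinite(v) else 0.0


def _time_stats(x: np.ndarray) -> list[float]:
    sd = float(np.std(x))
    if sd < 1e-12:  # constant signal up to float rounding
        sd = 0.0
    q25, med, q75 = np.percentile(x, [25, 50, 75])
    if sd > 0:
        skew = _safe(sstats.skew(x))
        kurt = _safe(sstats.kurtosis(x))
    else:
        skew = kurt = 0.0
    mad = float(np.median(np.abs(x - med)))
    return [float(np.mean(x)), sd, float(np.ptp(x)), float(np.min(x)),
            float(np.max(x)), float(q25), float(med), float(q75), skew, kurt, mad]


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) < 1e-12 or np.std(b) < 1e-12:
        return 0.0  # convention: correlation with a constant axis is 0
    return _safe(np.corrcoef(a, b)[0, 1])


def _spectrum(x: np.ndarray, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided power spectrum of the mean-removed, Hann-tapered signal (DC excluded)."""
    n = x.size
    win = np.hanning(n)
    X = np.fft.rfft((x - x.mean()) * win)
    power = np.abs(X) ** 2 / n
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    return freqs[1:], power[1:]


def _spectral_feats(x: np.ndarray, rate: float, second_peak: bool) -> list[float]:
    freqs, power = _spectrum(x, rate)
    total = float(power.sum())
    if total <= 0 or freqs.size == 0:
        base = [0.0, 0.0, 0.0, 0.0, 0.0, 0.0] if second_peak else [0.0, 0.0, 0.0]
        return base
    i1 = int(np.argmax(power))
    p = power / total
    entropy = float(-(p[p > 0] * np.log2(p[p > 0])).sum())
    if not second_peak:
        return [float(freqs[i1]), float(power[i1]), entropy]
    # second dominant peak: exclude the +/-1 bin neighbourhood of the first
    mask = np.ones_like(power, dtype=bool)
    mask[max(0, i1 - 1): i1 + 2] = False
    if mask.any():
        i2 = int(np.flatnonzero(mask)[np.argmax(power[mask])])
        f2, p2 = float(freqs[i2]), float(power[i2])
    else:
        f2 = p2 = 0.0
    return [float(freqs[i1]), float(power[i1]), f2, p2, entropy, total]


def _band_powers(x: np.ndarray, rate: float) -> list[float]:
    freqs, power = _spectrum(x, rate)
    out = []
    for lo, hi in _BANDS:
        sel = (freqs >= lo) & (freqs < hi)
        out.append(float(power[sel].sum()) if sel.any() else 0.0)
    return out


def _autocorr(x: np.ndarray, rate: float) -> list[float]:
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    out = []
    for lag_s in _ACF_LAGS_S:
        k = int(round(lag_s * rate))
        if denom <= 0 or k <= 0 or k >= x.size:
            out.append(0.0)
        else:
            out.append(_safe(np.dot(xc[:-k], xc[k:]) / denom))
    return out


def _zero_cross(x: np.ndarray) -> float:
    xc = x - x.mean()
    s = np.sign(xc)
    s[s == 0] = 1
    return float(np.mean(s[1:] != s[:-1]))


def extract_features(window: np.ndarray, rate: float) -> np.ndarray:
    """126-dimensional feature vector for one epoch of (n, 3) samples in g.

    ``rate`` is the uniform sampling rate in Hz.  Raises on an empty window;
    NaN samples (recording gaps) are dropped first.  The output is finite
    everywhere by construction.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[1] != 3:
        raise ValueError("window must be an (n, 3) array")
    window = window[np.all(np.isfinite(window), axis=1)]
    if window.shape[0] < max(2, int(rate)):
        raise ValueError("window must contain at least 1 s of valid samples")
    x, y, z = window.T
    vm = np.linalg.norm(window, axis=1)
    enmo = np.clip(vm - 1.0, 0.0, None)

    vals: list[float] = []
    for axis in (x, y, z):
        vals += _time_stats(axis)
    vals += _time_stats(enmo)
    vals += [_corr(x, y), _corr(x, z), _corr(y, z)]
    # roll/pitch from the low-passed (here: window-mean removed dynamic vs static) signal
    with np.errstate(invalid="ignore", divide="ignore"):
        roll = np.arctan2(y, z)
        pitch = np.arctan2(-x, np.sqrt(y * y + z * z))
    vals += [_safe(np.mean(roll)), _safe(np.std(roll)),
             _safe(np.mean(pitch)), _safe(np.std(pitch))]
    for axis in (x, y, z):
        vals += _spectral_feats(axis, rate, second_peak=False)
    for axis in (x, y, z):
        vals += _band_powers(axis, rate)
    vals += _spectral_feats(enmo, rate, second_peak=True)
    vals += _band_powers(enmo, rate)
    vals += _autocorr(enmo, rate)
    vals += [float(np.mean(a * a)) for a in (x, y, z)]
    vals += [float(np.mean(enmo * enmo)), _zero_cross(enmo)]
    vals += [_zero_cross(a) for a in (x, y, z)]

    out = np.asarray(vals, dtype=float)
    if out.size != N_FEATURES:  # pragma: no cover - structural guard
        raise AssertionError(f"feature vector length {out.size} != {N_FEATURES}")
    out[~np.isfinite(out)] = 0.0
    return out


def extract_feature_matrix(raw, epoch_s: float = 30.0) -> np.ndarray:
    """Feature matrix (n_epochs, 126) for a uniformly sampled RawRecording.

    Epochs with less than 1 s of valid samples get an all-zero row (they are
    excluded from classification via the wear mask downstream).
    """
    rate = raw.sample_rate()
    n_per = int(round(epoch_s * rate))
    n_full = raw.n_samples // n_per
    out = np.zeros((n_full, N_FEATURES))
    for i in range(n_full):
        w = raw.accel[i * n_per: (i + 1) * n_per]
        try:
            out[i] = extract_features(w, rate)
        except ValueError:
            pass  # all-gap epoch: leave zeros
    return out
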