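"""Synthetic data with known ground truth for every pipeline stage.

Three generator families:

* **Accelerometer traces** — free-living wrist-accelerometer recordings in
  the measurement regime of the study device (triaxial, nominally 100 Hz,
  +/-8 g dynamic range).  Behaviour follows a semi-Markov chain over
  {sleep, sedentary, walking, moderate} with geometric dwell times; sleep
  and sedentary have near-zero dynamic acceleration (with occasional
  movement bursts, so genuine wear never mimics the 60-min non-wear rule),
  walking is a sinusoid at its dominant gait frequency, moderate activity
  is higher-amplitude broadband noise.  Gravity is a unit-norm vector whose
  orientation is redrawn each behaviour episode; per-axis gain/offset error
  and clipping are injected last.  Non-wear blocks have zero dynamic
  movement and a frozen orientation.

* **Epoch-level behaviour series** — the same state process emitted
  directly as 30-s epoch summaries (ENMO, axis SDs), cheap enough for
  multi-day QC and smoothing experiments.

* **GWAS / MR summary statistics** — per-variant effect estimates with a
  known causal set, block-constant LD, and Wald p-values; and two-sample MR
  instrument tables with a known causal slope and optional (directional)
  pleiotropy.

Everything is seed-deterministic: the same profile and seed give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .classifier import STATES
from .preprocess import EpochSeries, RawRecording

__all__ = [
    "StateSignal",
    "SimProfile",
    "SimTruth",
    "DEFAULT_SIGNALS",
    "simulate_state_sequence",
    "simulate_accelerometer",
    "simulate_epoch_series",
    "simulate_predictions",
    "simulate_gwas_summary",
    "ld_lookup_from_blocks",
    "simulate_mr_study",
]


# ---------------------------------------------------------------------------
# profiles


@dataclass
class StateSignal:
    """Per-state signal description.

    ``amp_mg``: dynamic acceleration amplitude; ``freq_hz``: dominant
    frequency (0 = broadband/none); ``orient_sd``: orientation jitter SD in
    g; ``burst_prob``/``burst_amp_mg``: probability per epoch of a movement
    burst and its amplitude (models posture shifts and fidgeting during
    otherwise still behaviours).
    """

    amp_mg: float
    freq_hz: float = 0.0
    orient_sd: float = 0.01
    burst_prob: float = 0.0
    burst_amp_mg: float = 0.0


# With uniform switching between episodes, long-run time share per state is
# dwell / sum(dwell): these means give ~8.8 h/day sleep, ~12.3 h sedentary,
# ~1.8 h walking, ~1.2 h moderate, and a mean ENMO near 27 mg — plausible
# free-living wrist numbers.  Amplitudes bracket the ENMO ranges seen on wrists.
DEFAULT_DWELL_MIN = {"sleep": 150.0, "sedentary": 210.0, "walking": 30.0, "moderate": 20.0}
DEFAULT_SIGNALS = {
    "sleep": StateSignal(amp_mg=3.0, orient_sd=0.005, burst_prob=0.55, burst_amp_mg=30.0),
    "sedentary": StateSignal(amp_mg=8.0, orient_sd=0.01, burst_prob=0.75, burst_amp_mg=25.0),
    "walking": StateSignal(amp_mg=120.0, freq_hz=2.0, orient_sd=0.02),
    "moderate": StateSignal(amp_mg=250.0, freq_hz=0.0, orient_sd=0.03),
}


@dataclass
class SimProfile:
    """Complete description of one synthetic recording."""

    seed: int = 0
    duration_h: float = 24.0
    sample_rate: float = 100.0
    state_dwell_min: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DWELL_MIN))
    state_signal: dict[str, StateSignal] = field(default_factory=lambda: dict(DEFAULT_SIGNALS))
    nonwear_blocks: list[tuple[float, float]] = field(default_factory=list)  # (start_min, length_min)
    calib_gain: tuple[float, float, float] = (1.0, 1.0, 1.0)
    calib_offset_mg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    clip_limit: float = 8.0
    epoch_s: float = 30.0
    t0_clock_s: float = 0.0

    def __post_init__(self) -> None:
        if self.duration_h <= 0:
            raise ValueError("duration must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample rate must be positive")
        if self.clip_limit <= 0:
            raise ValueError("clip limit must be positive")
        for s in STATES:
            if self.state_dwell_min.get(s, 1.0) <= 0:
                raise ValueError(f"dwell mean for {s!r} must be positive")

    @property
    def n_epochs(self) -> int:
        return int(self.duration_h * 3600.0 // self.epoch_s)


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated object."""

    state_sequence: np.ndarray | None = None   # per-epoch true state index
    nonwear_mask: np.ndarray | None = None     # per-epoch boolean (True = non-wear)
    causal_effect: float | None = None
    causal_variants: set | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# behaviour state process


def simulate_state_sequence(n_epochs: int, dwell_min: dict[str, float],
                            epoch_s: float, rng: np.random.Generator) -> np.ndarray:
    """Semi-Markov state sequence with geometric dwell times.

    Dwell length in epochs is geometric with the stated mean; on leaving a
    state the next state is drawn uniformly from the others.
    """
    means = np.array([max(dwell_min[s] * 60.0 / epoch_s, 1.0) for s in STATES])
    seq = np.empty(n_epochs, dtype=int)
    pos = 0
    state = int(rng.integers(len(STATES)))
    while pos < n_epochs:
        dwell = int(rng.geometric(1.0 / means[state]))
        seq[pos: pos + dwell] = state
        pos += dwell
        others = [s for s in range(len(STATES)) if s != state]
        state = int(rng.choice(others))
    return seq


def _epoch_nonwear_mask(profile: SimProfile) -> np.ndarray:
    mask = np.zeros(profile.n_epochs, dtype=bool)
    for start_min, length_min in profile.nonwear_blocks:
        lo = int(start_min * 60.0 // profile.epoch_s)
        hi = int(np.ceil((start_min + length_min) * 60.0 / profile.epoch_s))
        mask[max(lo, 0): min(hi, profile.n_epochs)] = True
    return mask


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# raw accelerometer simulation


def simulate_accelerometer(profile: SimProfile) -> tuple[RawRecording, SimTruth]:
    """Generate a raw triaxial recording plus its epoch-level ground truth.

    The gravity component has unit norm before gain/offset injection; the
    measured signal is ``gain * true + offset`` per axis, clipped to the
    device dynamic range.  The number of clipped samples is reported in
    ``truth.extras['n_clipped']``.
    """
    rng = np.random.default_rng(profile.seed)
    n_epochs = profile.n_epochs
    if n_epochs < 1:
        raise ValueError("duration shorter than one epoch")
    n_per = int(round(profile.epoch_s * profile.sample_rate))
    states = simulate_state_sequence(n_epochs, profile.state_dwell_min, profile.epoch_s, rng)
    nonwear = _epoch_nonwear_mask(profile)

    accel = np.empty((n_epochs * n_per, 3))
    t_in_epoch = np.arange(n_per) / profile.sample_rate
    orient = _random_unit(rng)
    nonwear_orient = _random_unit(rng)
    prev_state = -1
    for i in range(n_epochs):
        s = states[i]
        sig = profile.state_signal[STATES[s]]
        if s != prev_state:
            orient = _random_unit(rng)       # new posture each behaviour episode
            prev_state = s
        if nonwear[i]:
            # device off the wrist: frozen orientation, sensor noise only
            g = nonwear_orient
            dyn = rng.normal(0.0, 0.5e-3, size=(n_per, 3))
        else:
            g = orient + rng.normal(0.0, sig.orient_sd, size=3)
            g = g / np.linalg.norm(g)
            amp = sig.amp_mg * 1e-3
            if sig.freq_hz > 0:
                # periodic gait: sinusoid along a movement axis + broadband noise
                axis = _random_unit(rng)
                phase = rng.uniform(0, 2 * np.pi)
                wave = np.sin(2 * np.pi * sig.freq_hz * t_in_epoch + phase)
                dyn = amp * wave[:, None] * axis + rng.normal(0.0, 0.3 * amp, size=(n_per, 3))
            else:
                dyn = rng.normal(0.0, amp, size=(n_per, 3))
            if sig.burst_prob > 0 and rng.random() < sig.burst_prob:
                # brief movement burst (posture shift / fidget)
                b0 = int(rng.integers(0, max(n_per - n_per // 6, 1)))
                b1 = b0 + n_per // 6
                dyn[b0:b1] += rng.normal(0.0, sig.burst_amp_mg * 1e-3, size=(b1 - b0, 3))
        accel[i * n_per: (i + 1) * n_per] = g + dyn

    gain = np.asarray(profile.calib_gain, dtype=float)
    offset = np.asarray(profile.calib_offset_mg, dtype=float) * 1e-3
    measured = accel * gain + offset
    n_clipped = int(np.sum(np.abs(measured) > profile.clip_limit))
    measured = np.clip(measured, -profile.clip_limit, profile.clip_limit)

    times = np.arange(n_epochs * n_per) / profile.sample_rate
    raw = RawRecording(times, measured, profile.clip_limit, profile.t0_clock_s,
                       meta={"nominal_rate": profile.sample_rate, "synthetic": True})
    truth = SimTruth(state_sequence=states, nonwear_mask=nonwear,
                     extras={"n_clipped": n_clipped})
    return raw, truth


# ---------------------------------------------------------------------------
# epoch-level simulation (cheap multi-day series)

# per-state (mean, sd) of epoch ENMO in mg, consistent with the raw-signal
# amplitudes above
_EPOCH_ENMO = {"sleep": (3.0, 1.0), "sedentary": (10.0, 3.0),
               "walking": (120.0, 20.0), "moderate": (250.0, 40.0)}
# probability an epoch of a still behaviour contains enough movement to
# break stationarity (posture shifts); walking/moderate always move
_EPOCH_MOVE_PROB = {"sleep": 0.55, "sedentary": 0.75, "walking": 1.0, "moderate": 1.0}


def simulate_epoch_series(
    n_days: float = 7.0,
    seed: int = 0,
    dwell_min: dict[str, float] | None = None,
    nonwear_blocks: list[tuple[float, float]] | None = None,
    epoch_s: float = 30.0,
    t0_clock_s: float = 0.0,
) -> tuple[EpochSeries, SimTruth]:
    """Multi-day epoch summaries generated directly at the 30-s level.

    Statistically matches what :func:`simulate_accelerometer` +
    :func:`actigwas.preprocess.epoch_summaries` produce, at a fraction of
    the cost; used for wear-time QC and smoothing experiments that need
    many days of data.
    """
    rng = np.random.default_rng(seed)
    n_epochs = int(n_days * 86400.0 // epoch_s)
    dwell = dict(DEFAULT_DWELL_MIN if dwell_min is None else dwell_min)
    states = simulate_state_sequence(n_epochs, dwell, epoch_s, rng)
    nonwear = np.zeros(n_epochs, dtype=bool)
    for start_min, length_min in (nonwear_blocks or []):
        lo = int(start_min * 60.0 // epoch_s)
        hi = int(np.ceil((start_min + length_min) * 60.0 / epoch_s))
        nonwear[max(lo, 0): min(hi, n_epochs)] = True

    enmo = np.empty(n_epochs)
    axis_sd = np.empty((n_epochs, 3))
    for si, name in enumerate(STATES):
        sel = states == si
        m, sd = _EPOCH_ENMO[name]
        enmo[sel] = np.clip(rng.normal(m, sd, size=sel.sum()), 0.0, None)
        moving = rng.random(sel.sum()) < _EPOCH_MOVE_PROB[name]
        base = rng.uniform(3.0, 9.0, size=(sel.sum(), 3))           # still: below 13 mg
        burst = rng.uniform(18.0, 60.0, size=(sel.sum(), 3))        # moving: above
        axis_sd[sel] = np.where(moving[:, None], burst, base)
    enmo[nonwear] = np.clip(rng.normal(0.5, 0.2, size=nonwear.sum()), 0.0, None)
    axis_sd[nonwear] = rng.uniform(0.5, 3.0, size=(int(nonwear.sum()), 3))

    epochs = EpochSeries(
        epoch_start=np.arange(n_epochs) * epoch_s,
        enmo=enmo,
        axis_sd=axis_sd,
        clipped_fraction=np.zeros(n_epochs),
        epoch_s=epoch_s,
        t0_clock_s=t0_clock_s,
        state=states,
    )
    return epochs, SimTruth(state_sequence=states, nonwear_mask=nonwear)


def simulate_predictions(true_states: np.ndarray, emission: np.ndarray,
                         seed: int = 0) -> np.ndarray:
    """Corrupt a true state sequence through a confusion channel.

    ``emission[i, k]`` = P(predicted k | true i); stands in for an epoch
    classifier of known noise level.
    """
    emission = np.asarray(emission, dtype=float)
    if np.any(np.abs(emission.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("emission rows must sum to 1")
    rng = np.random.default_rng(seed)
    true_states = np.asarray(true_states, dtype=int)
    k = emission.shape[0]
    u = rng.random(true_states.size)
    cdf = np.cumsum(emission, axis=1)
    return np.minimum((u[:, None] > cdf[true_states]).sum(axis=1), k - 1)


# ---------------------------------------------------------------------------
# GWAS summary statistics


def simulate_gwas_summary(
    n_variants: int,
    n_causal: int,
    effect_sd: float = 0.03,
    n_samples: int = 100_000,
    ld_block_size: int = 10,
    seed: int = 0,
    pos_step: int = 50_000,
    block_r: float = 0.8,
) -> tuple[pd.DataFrame, SimTruth]:
    """Per-variant association summary statistics with known causal truth.

    Variants sit on one chromosome every ``pos_step`` bp, in LD blocks of
    ``ld_block_size`` consecutive variants with block-constant correlation
    ``block_r``.  Causal variants get effects ~ N(0, effect_sd); a
    non-causal variant's expected marginal beta is ``block_r`` times any
    causal effect in its block.  Estimation noise has SD
    1/sqrt(2 * EAF * (1-EAF) * n_samples) and is ``block_r``-correlated
    within blocks; p-values come from the two-sided Wald statistic.
    """
    if n_variants < 1:
        raise ValueError("need at least one variant")
    if n_causal > n_variants:
        raise ValueError("n_causal exceeds n_variants")
    rng = np.random.default_rng(seed)
    idx = np.arange(n_variants)
    block = idx // ld_block_size
    eaf = rng.uniform(0.05, 0.95, size=n_variants)
    se = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n_samples)

    beta_true = np.zeros(n_variants)
    causal = rng.choice(n_variants, size=n_causal, replace=False) if n_causal else np.array([], int)
    causal_effects = rng.normal(0.0, effect_sd, size=n_causal)
    for ci, b in zip(causal, causal_effects):
        same = block == block[ci]
        beta_true[same] += block_r * b
        beta_true[ci] += (1.0 - block_r) * b  # own effect at full strength

    z_block = rng.normal(size=block.max() + 1 if n_variants else 1)
    z_own = rng.normal(size=n_variants)
    z = np.sqrt(block_r) * z_block[block] + np.sqrt(1.0 - block_r) * z_own
    beta_hat = beta_true + se * z
    p = 2.0 * sstats.norm.sf(np.abs(beta_hat / se))

    alleles = np.array(["A", "C", "G", "T"])
    ea = rng.integers(0, 4, size=n_variants)
    oa = (ea + rng.integers(1, 4, size=n_variants)) % 4
    df = pd.DataFrame({
        "snp": [f"rs{i}" for i in idx],
        "chr": 1,
        "pos": idx * pos_step + 1,
        "effect_allele": alleles[ea],
        "other_allele": alleles[oa],
        "eaf": eaf,
        "beta": beta_hat,
        "se": se,
        "p": p,
        "info": rng.uniform(0.85, 1.0, size=n_variants),
        "maf": np.minimum(eaf, 1.0 - eaf),
    })
    truth = SimTruth(
        causal_variants={f"rs{int(i)}" for i in causal},
        extras={"beta_true": beta_true, "block": block, "block_r": block_r,
                "causal_effects": dict(zip((f"rs{int(i)}" for i in causal), causal_effects))},
    )
    return df, truth


def ld_lookup_from_blocks(df: pd.DataFrame, truth: SimTruth):
    """Pairwise r^2 lookup implied by the block-constant LD of a simulated panel."""
    block = dict(zip(df["snp"], truth.extras["block"]))
    r2 = truth.extras["block_r"] ** 2

    def lookup(a: str, b: str) -> float:
        if a == b:
            return 1.0
        return r2 if block.get(a) == block.get(b) else 0.0

    return lookup


# ---------------------------------------------------------------------------
# two-sample MR


def simulate_mr_study(
    n_instruments: int,
    causal_effect: float = 0.0,
    pleiotropy_mean: float = 0.0,
    pleiotropy_sd: float = 0.0,
    nx: int = 100_000,
    ny: int = 100_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Harmonised two-sample MR instrument table with known causal slope.

    Exposure effects are drawn away from zero (all instruments are genuine)
    and coded to the exposure-increasing allele, the usual two-sample-MR
    convention — so a non-zero ``pleiotropy_mean`` is genuinely directional.
    Estimation SE is proportional to 1/sqrt(nx); outcome effects are
    ``causal_effect * beta_x + alpha_j`` with per-SNP pleiotropy
    alpha_j ~ N(pleiotropy_mean, pleiotropy_sd) and SE proportional to
    1/sqrt(ny).
    """
    if n_instruments < 1:
        raise ValueError("need at least one instrument")
    if pleiotropy_sd < 0:
        raise ValueError("pleiotropy SD must be non-negative")
    rng = np.random.default_rng(seed)
    eaf = rng.uniform(0.1, 0.9, size=n_instruments)
    se_x = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * nx)
    se_y = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * ny)
    bx_true = 0.02 + np.abs(rng.normal(0.0, 0.02, size=n_instruments))
    alpha = rng.normal(pleiotropy_mean, pleiotropy_sd, size=n_instruments) \
        if (pleiotropy_mean or pleiotropy_sd) else np.zeros(n_instruments)
    bx_hat = bx_true + rng.normal(0.0, se_x)
    by_hat = causal_effect * bx_true + alpha + rng.normal(0.0, se_y)
    df = pd.DataFrame({
        "snp": [f"iv{i}" for i in range(n_instruments)],
        "beta_exposure": bx_hat,
        "se_exposure": se_x,
        "beta_outcome": by_hat,
        "se_outcome": se_y,
        "eaf": eaf,
        "n_exposure": nx,
        "n_outcome": ny,
    })
    truth = SimTruth(causal_effect=causal_effect,
                     extras={"beta_x_true": bx_true, "pleiotropy": alpha})
    return df, truth
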