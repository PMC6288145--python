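"""Two-sample Mendelian randomisation estimators and sensitivity analyses.

Works on a harmonised instrument table (per-SNP exposure and outcome betas
with standard errors, effect-allele frequencies, sample sizes).  Estimators:

- ``wald``            single-SNP ratio beta_out / beta_exp
- ``ivw``             fixed-effect inverse-variance-weighted regression
                      through the origin
- ``ml``              maximum likelihood: a joint-normal model with per-SNP
                      true exposure effects as nuisance parameters and a
                      single causal slope, profiled out; the primary
                      estimator here
- ``egger``           weighted regression with a free intercept; the
                      intercept is the directional-pleiotropy diagnostic
- ``weighted_median`` inverse-variance-weighted median of Wald ratios,
                      consistent when >= 50% of weight is valid
- ``weighted_mode``   mode of the kernel-smoothed ratio density (modified
                      Silverman bandwidth), consistent when the largest
                      group of instruments is valid

Sensitivity analyses: Steiger directionality (variance explained in
exposure vs outcome), leave-one-out influence, and bi-directional testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "MR_METHODS",
    "MrResult",
    "harmonise",
    "mr_estimate",
    "steiger_direction",
    "leave_one_out",
    "bidirectional",
]

MR_METHODS = ("wald", "ivw", "ml", "egger", "weighted_median", "weighted_mode")
MR_COLUMNS = ("beta_exposure", "se_exposure", "beta_outcome", "se_outcome")


@dataclass
class MrResult:
    method: str
    estimate: float
    se: float
    p: float
    n_snp: int
    wald_ratios: np.ndarray = field(repr=False, default=None)
    diagnostics: dict[str, Any] = field(default_factory=dict)


def _check(data: pd.DataFrame, min_snp: int, method: str) -> pd.DataFrame:
    missing = [c for c in MR_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"MR dataset missing columns: {missing}")
    if np.any(data["se_exposure"] <= 0) or np.any(data["se_outcome"] <= 0):
        raise ValueError("standard errors must be positive")
    if len(data) < min_snp:
        raise ValueError(f"method {method!r} needs >= {min_snp} instruments, got {len(data)}")
    return data


def harmonise(data: pd.DataFrame, palindromic_eaf=(0.42, 0.58)) -> pd.DataFrame:
    """Align exposure and outcome effects to the same effect allele.

    Rows whose outcome alleles are flipped relative to the exposure get
    their outcome beta sign-flipped; palindromic SNPs (A/T or C/G) with EAF
    inside ``palindromic_eaf`` are dropped as strand-ambiguous.  Without
    allele columns the table is assumed pre-harmonised and passed through.
    """
    if "effect_allele_outcome" not in data.columns:
        return data.copy()
    df = data.copy()
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    keep = np.ones(len(df), dtype=bool)
    for i, row in enumerate(df.itertuples(index=False)):
        ea, oa = row.effect_allele, row.other_allele
        eao, oao = row.effect_allele_outcome, row.other_allele_outcome
        palindromic = comp.get(ea) == oa
        if palindromic:
            eaf = getattr(row, "eaf", 0.5)
            if palindromic_eaf[0] < eaf < palindromic_eaf[1]:
                keep[i] = False
                continue
        if (eao, oao) == (ea, oa):
            continue
        if (eao, oao) in ((oa, ea), (comp.get(oa), comp.get(ea))):
            df.iloc[i, df.columns.get_loc("beta_outcome")] *= -1.0
        elif (eao, oao) == (comp.get(ea), comp.get(oa)):
            continue
        else:
            keep[i] = False
    out = df[keep].reset_index(drop=True)
    out.attrs["n_dropped_harmonisation"] = int((~keep).sum())
    return out


# ---------------------------------------------------------------------------
# estimators


def _wald(bx, sx, by, sy) -> tuple[float, float]:
    est = by / bx
    se = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    return float(est), float(se)


def _ivw(bx, sx, by, sy) -> tuple[float, float]:
    w = 1.0 / sy**2
    est = float(np.sum(w * bx * by) / np.sum(w * bx**2))
    se = float(np.sqrt(1.0 / np.sum(w * bx**2)))
    return est, se


def _ml_profile_nll(theta: float, bx, sx, by, sy) -> float:
    # profile out the per-SNP true exposure effects in closed form
    denom = 1.0 / sx**2 + theta**2 / sy**2
    g = (bx / sx**2 + theta * by / sy**2) / denom
    return float(np.sum((bx - g) ** 2 / (2 * sx**2) + (by - theta * g) ** 2 / (2 * sy**2)))


def _ml(bx, sx, by, sy) -> tuple[float, float]:
    theta0, _ = _ivw(bx, sx, by, sy)
    span = 10.0 * (abs(theta0) + 1.0)
    res = optimize.minimize_scalar(
        _ml_profile_nll, args=(bx, sx, by, sy),
        bounds=(theta0 - span, theta0 + span), method="bounded",
        options={"xatol": 1e-10},
    )
    theta = float(res.x)
    h = 1e-5 * (abs(theta) + 1.0)
    d2 = (_ml_profile_nll(theta + h, bx, sx, by, sy)
          - 2 * _ml_profile_nll(theta, bx, sx, by, sy)
          + _ml_profile_nll(theta - h, bx, sx, by, sy)) / h**2
    se = float(1.0 / np.sqrt(max(d2, 1e-30)))
    return theta, se


def _egger(bx, sx, by, sy) -> tuple[float, float, dict[str, float]]:
    # orient so all exposure effects are positive (intercept is direction-sensitive)
    sign = np.sign(bx)
    sign[sign == 0] = 1.0
    bxp, byp = bx * sign, by * sign
    w = 1.0 / sy**2
    X = np.column_stack([np.ones_like(bxp), bxp])
    WX = X * w[:, None]
    xtx_inv = np.linalg.inv(X.T @ WX)
    coef = xtx_inv @ (WX.T @ byp)
    resid = byp - X @ coef
    n = len(bxp)
    sigma2 = float(np.sum(w * resid**2) / (n - 2))
    scale = max(1.0, sigma2)  # multiplicative over-dispersion, never < 1
    cov = xtx_inv * scale
    slope, slope_se = float(coef[1]), float(np.sqrt(cov[1, 1]))
    inter, inter_se = float(coef[0]), float(np.sqrt(cov[0, 0]))
    tdist = stats.t(df=n - 2)
    diag = {
        "egger_intercept": inter,
        "egger_intercept_se": inter_se,
        "egger_intercept_p": float(2 * tdist.sf(abs(inter / inter_se))),
    }
    return slope, slope_se, diag


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, cum, r))


def _silverman_bw(x: np.ndarray, w: np.ndarray, phi: float = 1.0) -> float:
    mu = np.average(x, weights=w)
    sd = np.sqrt(np.average((x - mu) ** 2, weights=w))
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    s = min(sd, iqr / 1.349) if iqr > 0 else sd
    s = s if s > 0 else (abs(mu) + 1e-8)
    return float(phi * 0.9 * s * len(x) ** (-1 / 5))


def _weighted_mode_point(ratios: np.ndarray, weights: np.ndarray, phi: float = 1.0) -> float:
    bw = _silverman_bw(ratios, weights, phi)
    lo, hi = ratios.min() - 3 * bw, ratios.max() + 3 * bw
    grid = np.linspace(lo, hi, 2048)
    dens = np.sum(weights[:, None] * np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / bw) ** 2),
                  axis=0)
    return float(grid[int(np.argmax(dens))])


def _bootstrap_se(point_fn, ratios, ratio_se, weights, n_boot: int, seed: int) -> float:
    rng = np.random.default_rng(seed)
    draws = np.empty(n_boot)
    for b in range(n_boot):
        r = rng.normal(ratios, ratio_se)
        draws[b] = point_fn(r, weights)
    return float(np.std(draws, ddof=1))


def mr_estimate(data: pd.DataFrame, method: str = "ml",
                n_boot: int = 500, seed: int = 0,
                mode_bandwidth_phi: float = 1.0) -> MrResult:
    """Causal-effect estimate from harmonised summary statistics.

    ``method`` is one of ``wald, ivw, ml, egger, weighted_median,
    weighted_mode``; ``ml`` (the primary estimator) profiles a joint-normal
    likelihood over per-SNP true exposure effects.  Median/mode standard
    errors come from a seeded parametric bootstrap of the Wald ratios.
    With a single instrument every defined method reduces to the Wald
    ratio; egger/median/mode require at least 3 instruments.
    """
    if method not in MR_METHODS:
        raise ValueError(f"unknown MR method {method!r}")
    min_snp = 3 if method in ("egger", "weighted_median", "weighted_mode") else 1
    df = _check(data, min_snp, method)
    bx = df["beta_exposure"].to_numpy(float)
    sx = df["se_exposure"].to_numpy(float)
    by = df["beta_outcome"].to_numpy(float)
    sy = df["se_outcome"].to_numpy(float)
    if np.any(bx == 0):
        raise ValueError("zero exposure effect produces an undefined Wald ratio")
    ratios = by / bx
    ratio_se = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    diag: dict[str, Any] = {}

    if method == "wald" or len(df) == 1:
        if method == "wald" and len(df) != 1:
            raise ValueError("wald method applies to a single instrument")
        est, se = _wald(bx[0], sx[0], by[0], sy[0])
        used = "wald" if method in ("wald",) else method
        p = float(2 * stats.norm.sf(abs(est / se)))
        return MrResult(used, est, se, p, 1, ratios, diag)

    if method == "ivw":
        est, se = _ivw(bx, sx, by, sy)
        p = float(2 * stats.norm.sf(abs(est / se)))
    elif method == "ml":
        est, se = _ml(bx, sx, by, sy)
        p = float(2 * stats.norm.sf(abs(est / se)))
    elif method == "egger":
        est, se, diag = _egger(bx, sx, by, sy)
        p = float(2 * stats.t(df=len(df) - 2).sf(abs(est / se)))
    elif method == "weighted_median":
        w = 1.0 / ratio_se**2
        est = _weighted_median_point(ratios, w)
        se = _bootstrap_se(_weighted_median_point, ratios, ratio_se, w, n_boot, seed)
        p = float(2 * stats.norm.sf(abs(est / se)))
    else:  # weighted_mode
        w = 1.0 / ratio_se**2
        point = lambda r, wt: _weighted_mode_point(r, wt, mode_bandwidth_phi)
        est = point(ratios, w)
        se = _bootstrap_se(point, ratios, ratio_se, w, n_boot, seed)
        p = float(2 * stats.norm.sf(abs(est / se)))
    return MrResult(method, est, se, p, len(df), ratios, diag)


# ---------------------------------------------------------------------------
# sensitivity analyses


def steiger_direction(data: pd.DataFrame) -> tuple[str, float]:
    """Directionality test: do the instruments explain more variance in the
    exposure than in the outcome?

    Per-SNP r^2 with a standardised trait is 2 * EAF * (1 - EAF) * beta^2.
    The summed correlations are compared with a Fisher-z test using the
    study sample sizes.  Returns ('exposure_to_outcome' |
    'outcome_to_exposure' | 'indeterminate', p).
    """
    for col in ("eaf", "n_exposure", "n_outcome"):
        if col not in data.columns or data[col].isna().any():
            raise ValueError(f"Steiger test requires complete column {col!r}")
    eaf = data["eaf"].to_numpy(float)
    var_snp = 2.0 * eaf * (1.0 - eaf)
    r2_exp = float(np.sum(var_snp * data["beta_exposure"].to_numpy(float) ** 2))
    r2_out = float(np.sum(var_snp * data["beta_outcome"].to_numpy(float) ** 2))
    r_exp = np.sqrt(min(r2_exp, 1.0 - 1e-12))
    r_out = np.sqrt(min(r2_out, 1.0 - 1e-12))
    nx = float(data["n_exposure"].mean())
    ny = float(data["n_outcome"].mean())
    if nx <= 3 or ny <= 3:
        raise ValueError("sample sizes too small for the Fisher-z comparison")
    z = (np.arctanh(r_exp) - np.arctanh(r_out)) / np.sqrt(1.0 / (nx - 3) + 1.0 / (ny - 3))
    p = float(2 * stats.norm.sf(abs(z)))
    if r2_exp > r2_out:
        direction = "exposure_to_outcome"
    elif r2_out > r2_exp:
        direction = "outcome_to_exposure"
    else:
        direction = "indeterminate"
    return direction, p


def leave_one_out(data: pd.DataFrame, method: str = "ml", **kwargs) -> pd.DataFrame:
    """Re-estimate with each instrument omitted in turn.

    Flags instruments whose omission moves the estimate by more than one
    full-sample SE.  Returns one row per omitted SNP.
    """
    df = _check(data, 3, "leave_one_out")
    full = mr_estimate(df, method=method, **kwargs)
    rows = []
    for i in range(len(df)):
        sub = df.drop(df.index[i])
        res = mr_estimate(sub, method=method, **kwargs)
        rows.append({
            "omitted": df.index[i],
            "estimate": res.estimate,
            "se": res.se,
            "p": res.p,
            "shift": res.estimate - full.estimate,
            "influential": bool(abs(res.estimate - full.estimate) > full.se),
        })
    out = pd.DataFrame(rows)
    out.attrs["full_estimate"] = full.estimate
    out.attrs["full_se"] = full.se
    return out


def bidirectional(data_fwd: pd.DataFrame, data_rev: pd.DataFrame | None,
                  method: str = "ml", alpha: float = 0.05,
                  **kwargs) -> dict[str, Any]:
    """Estimate both causal directions and summarise their joint significance.

    Verdicts: 'bidirectional' (both significant at ``alpha``),
    'forward_only', 'reverse_only', 'neither', or
    'forward only, reverse untestable' when no reverse instruments exist.
    """
    fwd = mr_estimate(data_fwd, method=method, **kwargs)
    if data_rev is None or len(data_rev) == 0:
        verdict = ("forward only, reverse untestable" if fwd.p < alpha
                   else "neither significant, reverse untestable")
        return {"forward": fwd, "reverse": None, "verdict": verdict}
    rev = mr_estimate(data_rev, method=method, **kwargs)
    f_sig, r_sig = fwd.p < alpha, rev.p < alpha
    verdict = {(True, True): "bidirectional", (True, False): "forward_only",
               (False, True): "reverse_only", (False, False): "neither"}[(f_sig, r_sig)]
    return {"forward": fwd, "reverse": rev, "verdict": verdict}
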