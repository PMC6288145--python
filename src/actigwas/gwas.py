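"""GWAS summary-statistic post-processing.

Operations downstream of association testing: variant QC (MAF and
imputation-quality filters), the Hardy-Weinberg exact test, distance-based
locus definition around genome-wide-significant peaks (+/-400 kb windows at
p < 5e-9), novelty assessment against previously reported variants,
LD/distance-pruned instrument selection for Mendelian randomisation,
replication sample-size calculation from variance explained, Bonferroni
thresholds, and the z-test for sex-dimorphic heritability.

Summary statistics travel as a pandas DataFrame with columns
``chr, pos, effect_allele, other_allele, eaf, beta, se, p`` and optional
``info, maf, snp`` (positions 1-based, beta in SD units).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "REQUIRED_COLUMNS",
    "Locus",
    "validate_summary",
    "variant_qc",
    "hwe_exact_test",
    "define_loci",
    "novelty_check",
    "select_instruments",
    "replication_sample_size",
    "replication_power",
    "bonferroni_threshold",
    "sex_dimorphism_z",
]

REQUIRED_COLUMNS = ("chr", "pos", "effect_allele", "other_allele", "eaf", "beta", "se", "p")


def validate_summary(stats_df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in stats_df.columns]
    if missing:
        raise ValueError(f"summary statistics missing columns: {missing}")
    df = stats_df.copy()
    if np.any((df["eaf"] <= 0) | (df["eaf"] >= 1)):
        raise ValueError("EAF must lie strictly in (0, 1)")
    if np.any(df["se"] <= 0):
        raise ValueError("SE must be positive")
    if np.any((df["p"] < 0) | (df["p"] > 1)):
        raise ValueError("p must lie in [0, 1]")
    return df


# ---------------------------------------------------------------------------
# variant QC


def variant_qc(stats_df: pd.DataFrame, maf_min: float = 0.001, info_min: float = 0.3) -> pd.DataFrame:
    """Drop variants with MAF < ``maf_min`` or imputation info < ``info_min``.

    Boundary values are retained (the rules remove strictly-below variants).
    A ``maf`` column is used when present, otherwise derived from EAF.
    Filter counts are attached as ``df.attrs['qc_counts']``.
    """
    df = validate_summary(stats_df)
    maf = df["maf"] if "maf" in df.columns else np.minimum(df["eaf"], 1.0 - df["eaf"])
    keep = maf >= maf_min
    n_maf = int((~keep).sum())
    if "info" in df.columns:
        keep_info = df["info"] >= info_min
    else:
        keep_info = pd.Series(True, index=df.index)
    n_info = int((keep & ~keep_info).sum())
    out = df[keep & keep_info].copy()
    out.attrs["qc_counts"] = {"input": len(df), "removed_maf": n_maf,
                              "removed_info": n_info, "output": len(out)}
    return out


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_test(n_aa_hom: int, n_het: int, n_bb_hom: int, method: str = "exact") -> float:
    """Hardy-Weinberg equilibrium p-value from genotype counts.

    ``method='exact'``: the exact conditional test — conditioning on the
    observed allele counts, sum the probabilities of all heterozygote counts
    (same parity as observed) that are no more probable than the observed
    one.  ``method='chi2'``: the 1-df goodness-of-fit chi-square.
    """
    n_aa_hom, n_het, n_bb_hom = int(n_aa_hom), int(n_het), int(n_bb_hom)
    if min(n_aa_hom, n_het, n_bb_hom) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa_hom + n_het + n_bb_hom
    if n == 0:
        raise ValueError("total genotype count must be positive")
    n_a = 2 * n_aa_hom + n_het
    n_b = 2 * n_bb_hom + n_het
    if method == "chi2":
        p_a = n_a / (2.0 * n)
        exp = np.array([n * p_a**2, 2 * n * p_a * (1 - p_a), n * (1 - p_a) ** 2])
        obs = np.array([n_aa_hom, n_het, n_bb_hom], dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = np.nansum(np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0))
        return float(stats.chi2.sf(chi2, df=1))
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    rare = min(n_a, n_b)
    # possible heterozygote counts share the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(n_het = h | allele counts) up to a common constant:
    # log n! - log a1! - log h! - log a2! + h log 2, with a1=(n_a-h)/2, a2=(n_b-h)/2
    a1 = (n_a - hets) // 2
    a2 = (n_b - hets) // 2
    logp = (hets * np.log(2.0)
            - special.gammaln(a1 + 1) - special.gammaln(hets + 1) - special.gammaln(a2 + 1))
    logp -= special.logsumexp(logp)
    prob = np.exp(logp)
    obs_prob = prob[np.flatnonzero(hets == n_het)[0]]
    return float(min(1.0, prob[prob <= obs_prob * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# locus definition / novelty


@dataclass
class Locus:
    chr: object
    pos: int
    index: pd.Series            # full summary-stat row of the index variant
    window: tuple[int, int]     # [pos - half, pos + half]
    members: pd.DataFrame = field(repr=False, default=None)
    novel: bool | None = None


def define_loci(stats_df: pd.DataFrame, p_threshold: float = 5e-9,
                half_window: int = 400_000) -> list[Locus]:
    """Greedy distance-based clumping of genome-wide-significant peaks.

    Per chromosome: take the smallest-p variant below ``p_threshold``, open
    a locus spanning +/- ``half_window`` around it, remove every variant in
    the window (boundary inclusive), repeat.  Retained index variants on one
    chromosome are therefore separated by strictly more than the window.
    Ties in p break by position.
    """
    df = validate_summary(stats_df)
    loci: list[Locus] = []
    for _, sub in df.groupby("chr", sort=True):
        cand = sub[sub["p"] < p_threshold].sort_values(["p", "pos"], kind="mergesort")
        remaining = cand.copy()
        while len(remaining):
            top = remaining.iloc[0]
            pos = int(top["pos"])
            in_window = (sub["pos"] >= pos - half_window) & (sub["pos"] <= pos + half_window)
            loci.append(Locus(
                chr=top["chr"], pos=pos, index=top,
                window=(pos - half_window, pos + half_window),
                members=sub[in_window].copy(),
            ))
            keep = (remaining["pos"] < pos - half_window) | (remaining["pos"] > pos + half_window)
            remaining = remaining[keep]
    loci.sort(key=lambda l: (str(l.chr), l.pos))
    return loci


def novelty_check(index_variants: Iterable[tuple[object, int]],
                  known_variants: Iterable[tuple[object, int]],
                  half_window: int = 400_000) -> list[bool]:
    """An index variant is novel iff no known variant on the same chromosome
    lies within +/- ``half_window`` (boundary inclusive -> not novel)."""
    known: dict[object, list[int]] = {}
    for c, p in known_variants:
        known.setdefault(c, []).append(int(p))
    flags = []
    for c, p in index_variants:
        near = any(abs(int(p) - q) <= half_window for q in known.get(c, ()))
        flags.append(not near)
    return flags


# ---------------------------------------------------------------------------
# instrument selection


def select_instruments(stats_df: pd.DataFrame,
                       ld_r2: Callable[[object, object], float] | dict,
                       p_max: float = 5e-6,
                       r2_max: float = 0.001,
                       min_dist: int = 10_000_000,
                       id_col: str = "snp") -> pd.DataFrame:
    """Greedy LD/distance pruning of candidate instruments, ascending p.

    Candidates with p < ``p_max`` are visited in order of ascending p (ties
    by position); each is accepted iff its LD r^2 with every accepted
    instrument is below ``r2_max`` and it is strictly more than ``min_dist``
    bp from every accepted instrument on the same chromosome.  ``ld_r2`` is
    a pair lookup ((id_a, id_b) -> r^2, unordered); absent pairs and
    cross-chromosome pairs count as r^2 = 0.
    """
    df = validate_summary(stats_df)
    if id_col not in df.columns:
        df = df.copy()
        df[id_col] = [f"{c}:{p}" for c, p in zip(df["chr"], df["pos"])]

    if isinstance(ld_r2, dict):
        table = ld_r2
        def lookup(a, b):
            return table.get((a, b), table.get((b, a), 0.0))
    else:
        lookup = ld_r2

    cand = df[df["p"] < p_max].sort_values(["p", "pos"], kind="mergesort")
    accepted: list[pd.Series] = []
    for _, row in cand.iterrows():
        ok = True
        for acc in accepted:
            if lookup(row[id_col], acc[id_col]) >= r2_max:
                ok = False
                break
            if row["chr"] == acc["chr"] and abs(int(row["pos"]) - int(acc["pos"])) <= min_dist:
                ok = False
                break
        if ok:
            accepted.append(row)
    return pd.DataFrame(accepted).reset_index(drop=True) if accepted else df.iloc[0:0]


# ---------------------------------------------------------------------------
# power / multiplicity


def _required_ncp(alpha: float, power: float) -> float:
    crit = stats.chi2.ppf(1.0 - alpha, df=1)
    f = lambda ncp: stats.ncx2.sf(crit, df=1, nc=ncp) - power
    return float(optimize.brentq(f, 1e-9, 1e4))


def replication_sample_size(alpha: float, power: float, r2_explained: float) -> float:
    """Participants needed so a SNP explaining ``r2_explained`` of trait
    variance replicates at level ``alpha`` with the requested power.

    The 1-df association chi-square has non-centrality n * r^2 / (1 - r^2);
    n is the value making the non-central tail beyond the alpha critical
    value equal the requested power.
    """
    for name, v in (("alpha", alpha), ("power", power), ("r2_explained", r2_explained)):
        if not (0.0 < v < 1.0):
            raise ValueError(f"{name} must lie in (0, 1), got {v}")
    ncp = _required_ncp(alpha, power)
    return ncp * (1.0 - r2_explained) / r2_explained


def replication_power(alpha: float, n: float, r2_explained: float) -> float:
    """Power of a replication test at sample size ``n`` (inverse of the above)."""
    crit = stats.chi2.ppf(1.0 - alpha, df=1)
    ncp = n * r2_explained / (1.0 - r2_explained)
    return float(stats.ncx2.sf(crit, df=1, nc=ncp))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise alpha divided by the number of tests."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / m


# ---------------------------------------------------------------------------
# sex-dimorphism z-test


def sex_dimorphism_z(h2_f: float, var_f: float, h2_m: float, var_m: float,
                     mode: str = "as_printed") -> tuple[float, float]:
    """z-test for a female-male difference in heritability.

    ``mode='as_printed'`` uses the radicand var_f - var_m, exactly as the
    defining equation is printed; this is only evaluable when var_f > var_m
    and an explicit error is raised otherwise, naming the ambiguity.
    ``mode='sum'`` uses the conventional variance of a difference of
    independent estimates, var_f + var_m.  Returns (z, two-tailed p).
    """
    if var_f < 0 or var_m < 0:
        raise ValueError("variances must be non-negative")
    if mode == "as_printed":
        radicand = var_f - var_m
        if radicand <= 0:
            raise ValueError(
                "as-printed radicand var_f - var_m is non-positive; the printed "
                "difference form of the z denominator is undefined here — use "
                "mode='sum' for the conventional variance of a difference"
            )
    elif mode == "sum":
        radicand = var_f + var_m
        if radicand <= 0:
            raise ValueError("total variance must be positive")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    z = (h2_f - h2_m) / np.sqrt(radicand)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return float(z), p
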