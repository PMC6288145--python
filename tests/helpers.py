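"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: exhaustive path
enumeration for Viterbi, exhaustive subset search for the greedy
locus/instrument selections, and factorial-based enumeration for the
Hardy-Weinberg exact test.
"""

from __future__ import annotations

from math import factorial

import numpy as np


def brute_force_viterbi(obs: np.ndarray, prior: np.ndarray, transition: np.ndarray,
                        emission: np.ndarray, tie_tol: float = 1e-9):
    """Exhaustive path enumeration (vectorised over all k^T paths).

    Returns ``(best_path, best_logprob, n_ties)`` where ``n_ties`` counts
    paths within ``tie_tol`` of the maximum: distinct paths can share the
    same probability, so a decoder is only pinned to a unique answer when
    ``n_ties == 1``.
    """
    obs = np.asarray(obs, dtype=int)
    k = prior.size
    T = obs.size
    paths = np.stack(np.meshgrid(*([np.arange(k)] * T), indexing="ij"), axis=-1).reshape(-1, T)
    with np.errstate(divide="ignore"):
        lp = np.log(prior)[paths[:, 0]] + np.log(emission)[paths[:, 0], obs[0]]
        for t in range(1, T):
            lp = lp + np.log(transition)[paths[:, t - 1], paths[:, t]]
            lp = lp + np.log(emission)[paths[:, t], obs[t]]
    best = int(np.argmax(lp))
    n_ties = int(np.sum(lp >= lp[best] - tie_tol))
    return paths[best], float(lp[best]), n_ties


def path_log_prob(path: np.ndarray, obs: np.ndarray, prior: np.ndarray,
                  transition: np.ndarray, emission: np.ndarray) -> float:
    """Log joint probability of one hidden path and the observed sequence."""
    path = np.asarray(path, dtype=int)
    obs = np.asarray(obs, dtype=int)
    with np.errstate(divide="ignore"):
        lp = np.log(prior[path[0]]) + np.log(emission[path[0], obs[0]])
        for t in range(1, obs.size):
            lp = lp + np.log(transition[path[t - 1], path[t]])
            lp = lp + np.log(emission[path[t], obs[t]])
    return float(lp)


def brute_force_greedy_selection(p_values: np.ndarray, conflict: np.ndarray) -> list[int]:
    """Reference result for greedy-by-p selection under pairwise exclusion.

    Enumerates every subset of candidates, keeps the admissible ones (no
    conflicting pair), restricts to maximal admissible subsets, and returns
    the one whose ascending-sorted p-vector is lexicographically smallest.
    This is provably what greedy-by-ascending-p produces, via an independent
    search.
    """
    n = len(p_values)
    assert n <= 16, "exhaustive search limited to small panels"
    masks = np.arange(1 << n, dtype=np.int64)
    pair_bits = np.array(
        [(1 << i) | (1 << j) for i in range(n) for j in range(i + 1, n) if conflict[i, j]],
        dtype=np.int64,
    )
    admissible = np.ones(1 << n, dtype=bool)
    for pb in pair_bits:
        admissible &= (masks & pb) != pb
    bits = 1 << np.arange(n, dtype=np.int64)
    # maximal admissible subsets: no single candidate can be added
    extendable = np.zeros(1 << n, dtype=bool)
    for j in range(n):
        absent = (masks & bits[j]) == 0
        extendable |= absent & admissible[masks | bits[j]]
    best: tuple | None = None
    best_mask = 0
    for m in np.flatnonzero(admissible & ~extendable):
        members = [j for j in range(n) if m & bits[j]]
        key = tuple(sorted(p_values[j] for j in members))
        if best is None or key < best:
            best = key
            best_mask = int(m)
    return [j for j in range(n) if best_mask & bits[j]]


def hwe_enumeration(n_aa: int, n_het: int, n_bb: int) -> float:
    """Exact conditional HWE p-value by direct factorial enumeration."""
    n = n_aa + n_het + n_bb
    na = 2 * n_aa + n_het
    nb = 2 * n_bb + n_het

    def prob(h: int) -> float:
        a = (na - h) // 2
        b = (nb - h) // 2
        return (factorial(n) * factorial(na) * factorial(nb) * 2**h) / (
            factorial(a) * factorial(h) * factorial(b) * factorial(2 * n)
        )

    hets = range(na % 2 if na <= nb else nb % 2, min(na, nb) + 1, 2)
    probs = {h: prob(h) for h in hets}
    obs = probs[n_het]
    return min(1.0, sum(v for v in probs.values() if v <= obs * (1 + 1e-12)))


def random_hmm(rng: np.random.Generator, k: int = 4):
    """Random strictly-positive HMM parameters (prior, transition, emission)."""
    prior = rng.dirichlet(np.ones(k))
    transition = rng.dirichlet(np.ones(k), size=k)
    emission = rng.dirichlet(np.ones(k), size=k)
    return prior, transition, emission
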