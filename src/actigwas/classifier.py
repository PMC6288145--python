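"""Activity-state classification: balanced random forest + HMM smoothing.

The classifier assigns each 30-s epoch one of four states
{sleep, sedentary, walking, moderate}.  Because free-living training data
are heavily imbalanced (sleep and sedentary dominate), each tree of the
forest is grown on a class-balanced bootstrap: an equal number of draws,
with replacement, from every class.

A random forest treats epochs as exchangeable, so isolated misclassified
epochs ("blips") appear inside otherwise homogeneous bouts.  A hidden
Markov model fixes this: hidden states are the *true* behaviours, the
transition matrix is estimated from the training label dynamics, and the
emission matrix is the classifier's confusion matrix P(predicted | true).
Viterbi decoding of the predicted sequence then recovers the most probable
true-state path; posterior (forward-backward) decoding is available as an
alternative.

Agreement is scored with Cohen's kappa, the chance-corrected multi-class
agreement statistic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "STATES",
    "HmmParams",
    "BalancedRandomForest",
    "train_balanced_rf",
    "predict_states",
    "fit_hmm",
    "viterbi_smooth",
    "posterior_smooth",
    "cohens_kappa",
]

STATES: tuple[str, ...] = ("sleep", "sedentary", "walking", "moderate")


# ---------------------------------------------------------------------------
# HMM parameters


@dataclass
class HmmParams:
    """Prior, transition and emission (confusion) matrices over the activity states.

    ``transition[i, j]`` = P(true state j at t+1 | true state i at t);
    ``emission[i, k]`` = P(classifier predicts k | true state i).
    Rows are stochastic within 1e-12.
    """

    states: tuple[str, ...]
    prior: np.ndarray
    transition: np.ndarray
    emission: np.ndarray

    def __post_init__(self) -> None:
        self.states = tuple(self.states)
        k = len(self.states)
        self.prior = np.asarray(self.prior, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.emission = np.asarray(self.emission, dtype=float)
        if self.prior.shape != (k,) or self.transition.shape != (k, k) or self.emission.shape != (k, k):
            raise ValueError("HmmParams shapes inconsistent with state count")
        for name, m in (("prior", self.prior[None, :]), ("transition", self.transition),
                        ("emission", self.emission)):
            if np.any(m < 0):
                raise ValueError(f"{name} has negative entries")
            if np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-12):
                raise ValueError(f"{name} rows must sum to 1")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "states": list(self.states),
            "prior": self.prior.tolist(),
            "transition": self.transition.tolist(),
            "emission": self.emission.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "HmmParams":
        d = json.loads(Path(path).read_text())
        return cls(tuple(d["states"]), np.array(d["prior"]),
                   np.array(d["transition"]), np.array(d["emission"]))


# ---------------------------------------------------------------------------
# balanced random forest


class BalancedRandomForest:
    """Random forest with a class-balanced bootstrap per tree.

    Each tree draws ``min_class_count`` samples with replacement from every
    class, countering class imbalance without reweighting.  Out-of-bag votes
    give an unbiased confusion matrix used later as the HMM emission matrix.
    """

    def __init__(self, n_trees: int = 100, seed: int = 0, **tree_kwargs):
        self.n_trees = int(n_trees)
        self.seed = int(seed)
        self.tree_kwargs = tree_kwargs
        self.trees_: list[DecisionTreeClassifier] = []
        self.classes_: np.ndarray | None = None
        self.oob_confusion_: np.ndarray | None = None
        self.oob_accuracy_: float = float("nan")

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BalancedRandomForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if not np.all(np.isfinite(X)):
            raise ValueError("features must be finite")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        k = len(self.classes_)
        if k < 2:
            raise ValueError("training data must contain at least 2 classes")
        per_class = [np.flatnonzero(y_idx == c) for c in range(k)]
        n_draw = min(len(ix) for ix in per_class)
        rng = np.random.default_rng(self.seed)
        n = X.shape[0]
        oob_votes = np.zeros((n, k))
        self.trees_ = []
        for _ in range(self.n_trees):
            boot = np.concatenate([rng.choice(ix, size=n_draw, replace=True) for ix in per_class])
            tree = DecisionTreeClassifier(
                max_features="sqrt",
                random_state=int(rng.integers(2**31 - 1)),
                **self.tree_kwargs,
            )
            tree.fit(X[boot], y_idx[boot])
            self.trees_.append(tree)
            oob = np.ones(n, dtype=bool)
            oob[boot] = False
            if oob.any():
                pred = tree.predict(X[oob])
                oob_votes[np.flatnonzero(oob), pred] += 1.0
        voted = oob_votes.sum(axis=1) > 0
        oob_pred = oob_votes.argmax(axis=1)
        conf = np.zeros((k, k))
        for t, p in zip(y_idx[voted], oob_pred[voted]):
            conf[t, p] += 1
        self.oob_confusion_ = conf
        self.oob_accuracy_ = float(np.trace(conf) / conf.sum()) if conf.sum() else float("nan")
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if not self.trees_:
            raise ValueError("model not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.trees_[0].n_features_in_:
            raise ValueError("feature dimension mismatch with training data")
        k = len(self.classes_)
        votes = np.zeros((X.shape[0], k))
        for tree in self.trees_:
            votes[np.arange(X.shape[0]), tree.predict(X)] += 1.0
        return votes / self.n_trees

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


def train_balanced_rf(features: np.ndarray, labels: np.ndarray,
                      n_trees: int = 100, seed: int = 0) -> BalancedRandomForest:
    return BalancedRandomForest(n_trees=n_trees, seed=seed).fit(features, labels)


def predict_states(model: BalancedRandomForest, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-epoch argmax label and tree-vote class probabilities."""
    proba = model.predict_proba(features)
    return model.classes_[proba.argmax(axis=1)], proba


# ---------------------------------------------------------------------------
# HMM estimation and decoding


def _as_indices(labels: np.ndarray, states: tuple[str, ...]) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "iu":
        idx = labels.astype(int)
        if idx.size and (idx.min() < 0 or idx.max() >= len(states)):
            raise ValueError("label index outside state range")
        return idx
    lookup = {s: i for i, s in enumerate(states)}
    try:
        return np.array([lookup[l] for l in labels], dtype=int)
    except KeyError as e:  # pragma: no cover - message only
        raise ValueError(f"unknown label {e.args[0]!r}") from None


def fit_hmm(true_labels: np.ndarray, predicted_labels: np.ndarray,
            states: tuple[str, ...] = STATES, eps: float = 1e-4) -> HmmParams:
    """Estimate HMM parameters from aligned (true, predicted) training sequences.

    prior = empirical true-state frequencies; transition = row-normalised
    adjacent true-state pair counts; emission = row-normalised confusion
    counts P(predicted | true).  ``eps`` is added to every count before
    normalisation so no row is degenerate.
    """
    t = _as_indices(true_labels, states)
    p = _as_indices(predicted_labels, states)
    if t.size != p.size:
        raise ValueError("true and predicted sequences must have equal length")
    if t.size == 0:
        raise ValueError("empty training sequences")
    k = len(states)
    prior = np.bincount(t, minlength=k).astype(float) + eps
    trans = np.full((k, k), eps)
    np.add.at(trans, (t[:-1], t[1:]), 1.0)
    emis = np.full((k, k), eps)
    np.add.at(emis, (t, p), 1.0)
    return HmmParams(states, prior / prior.sum(),
                     trans / trans.sum(axis=1, keepdims=True),
                     emis / emis.sum(axis=1, keepdims=True))


def viterbi_smooth(predicted: np.ndarray, hmm: HmmParams) -> np.ndarray:
    """Most probable hidden true-state path given the predicted sequence.

    Log-space Viterbi; ties break toward the earlier-indexed state.  Returns
    labels of the same dtype family as the input (strings in -> strings out).
    """
    obs = _as_indices(np.asarray(predicted), hmm.states)
    if obs.size == 0:
        return np.asarray(predicted)
    with np.errstate(divide="ignore"):
        log_prior = np.log(hmm.prior)
        log_trans = np.log(hmm.transition)
        log_emis = np.log(hmm.emission)
    n, k = obs.size, len(hmm.states)
    delta = log_prior + log_emis[:, obs[0]]
    back = np.zeros((n, k), dtype=int)
    for i in range(1, n):
        cand = delta[:, None] + log_trans  # (from, to)
        back[i] = cand.argmax(axis=0)      # argmax takes the earliest on ties
        delta = cand[back[i], np.arange(k)] + log_emis[:, obs[i]]
    path = np.zeros(n, dtype=int)
    path[-1] = int(delta.argmax())
    for i in range(n - 1, 0, -1):
        path[i - 1] = back[i, path[i]]
    if np.asarray(predicted).dtype.kind in "iu":
        return path
    return np.array([hmm.states[i] for i in path])


def posterior_smooth(predicted: np.ndarray, hmm: HmmParams) -> np.ndarray:
    """Per-epoch posterior-mode decoding (forward-backward), the alternative to Viterbi."""
    obs = _as_indices(np.asarray(predicted), hmm.states)
    n, k = obs.size, len(hmm.states)
    if n == 0:
        return np.asarray(predicted)
    alpha = np.zeros((n, k))
    c = np.zeros(n)
    alpha[0] = hmm.prior * hmm.emission[:, obs[0]]
    c[0] = alpha[0].sum() or 1.0
    alpha[0] /= c[0]
    for i in range(1, n):
        alpha[i] = (alpha[i - 1] @ hmm.transition) * hmm.emission[:, obs[i]]
        c[i] = alpha[i].sum() or 1.0
        alpha[i] /= c[i]
    beta = np.ones((n, k))
    for i in range(n - 2, -1, -1):
        beta[i] = (hmm.transition @ (hmm.emission[:, obs[i + 1]] * beta[i + 1])) / c[i + 1]
    post = alpha * beta
    path = post.argmax(axis=1)
    if np.asarray(predicted).dtype.kind in "iu":
        return path
    return np.array([hmm.states[i] for i in path])


# ---------------------------------------------------------------------------
# agreement


def cohens_kappa(a: np.ndarray, b: np.ndarray) -> float:
    """Chance-corrected agreement between two label sequences.

    kappa = (p_o - p_e) / (1 - p_e) with p_e from the product of marginals.
    When both sequences are constant and identical (p_e = 1) agreement is
    perfect and kappa is defined as 1.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.size != b.size:
        raise ValueError("sequences must have equal length")
    if a.size == 0:
        raise ValueError("empty sequences")
    labels = np.union1d(a, b)
    ai = np.searchsorted(labels, a)
    bi = np.searchsorted(labels, b)
    k = len(labels)
    conf = np.zeros((k, k))
    np.add.at(conf, (ai, bi), 1.0)
    n = conf.sum()
    p_o = np.trace(conf) / n
    p_e = float((conf.sum(axis=1) / n) @ (conf.sum(axis=0) / n))
    if p_e >= 1.0 - 1e-15:
        return 1.0 if p_o >= 1.0 - 1e-15 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))
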