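"""Balanced random forest, confusion-matrix HMM, Viterbi, Cohen's kappa."""

import numpy as np
import pytest

from actigwas.classifier import (
    STATES,
    HmmParams,
    cohens_kappa,
    fit_hmm,
    posterior_smooth,
    predict_states,
    train_balanced_rf,
    viterbi_smooth,
)
from helpers import brute_force_viterbi, path_log_prob, random_hmm


# ---------------------------------------------------------------------------
# balanced random forest


def _two_blobs(rng, n=400, sep=6.0):
    X = rng.normal(size=(n, 5))
    y = (np.arange(n) % 2).astype(int)
    X[y == 1, 0] += sep
    return X, y


class TestBalancedRF:
    def test_separable_classes_high_oob(self, rng):
        X, y = _two_blobs(rng)
        m = train_balanced_rf(X, y, n_trees=50, seed=0)
        assert m.oob_accuracy_ >= 0.99

    def test_shuffled_labels_at_chance(self, rng):
        X = rng.normal(size=(600, 5))
        y = rng.integers(0, 4, size=600)
        m = train_balanced_rf(X, y, n_trees=80, seed=1)
        assert abs(m.oob_accuracy_ - 0.25) < 0.05

    def test_minority_recall_close_to_majority_when_balanced(self, rng):
        # symmetric separable problem, 90/10 imbalance
        n_major, n_minor = 900, 100
        X = np.vstack([rng.normal(0, 1, size=(n_major, 4)),
                       rng.normal(4, 1, size=(n_minor, 4))])
        y = np.r_[np.zeros(n_major, int), np.ones(n_minor, int)]
        m = train_balanced_rf(X, y, n_trees=100, seed=2)
        conf = m.oob_confusion_
        recalls = np.diag(conf) / conf.sum(axis=1)
        assert abs(recalls[0] - recalls[1]) < 0.1

    def test_resubstitution_at_least_oob(self, rng):
        X, y = _two_blobs(rng, sep=2.0)
        m = train_balanced_rf(X, y, n_trees=50, seed=3)
        pred, proba = predict_states(m, X)
        assert np.mean(pred == y) >= m.oob_accuracy_ - 1e-9
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            train_balanced_rf(rng.normal(size=(50, 3)), np.zeros(50, int))

    def test_dimension_mismatch_rejected(self, rng):
        X, y = _two_blobs(rng, n=100)
        m = train_balanced_rf(X, y, n_trees=10, seed=0)
        with pytest.raises(ValueError):
            m.predict_proba(rng.normal(size=(10, 7)))

    def test_seed_reproducible(self, rng):
        X, y = _two_blobs(rng, sep=1.0)
        m1 = train_balanced_rf(X, y, n_trees=20, seed=7)
        m2 = train_balanced_rf(X, y, n_trees=20, seed=7)
        assert np.array_equal(m1.predict(X), m2.predict(X))
        assert m1.oob_accuracy_ == m2.oob_accuracy_


# ---------------------------------------------------------------------------
# HMM estimation


class TestFitHmm:
    def test_perfect_classifier_gives_identity_emission(self):
        seq = np.array([0, 1, 2, 3, 0, 1, 2, 3] * 10)
        hmm = fit_hmm(seq, seq)
        assert np.allclose(hmm.emission, np.eye(4), atol=1e-3)

    def test_alternating_sequence_gives_off_diagonal_transition(self):
        true = np.array([0, 1] * 50)
        hmm = fit_hmm(true, true)
        assert hmm.transition[0, 0] < 1e-3
        assert hmm.transition[1, 1] < 1e-3
        assert hmm.transition[0, 1] > 0.99

    def test_hand_counted_six_epoch_sequence(self):
        true = np.array([0, 0, 1, 1, 0, 2])
        pred = np.array([0, 1, 1, 1, 0, 2])
        hmm = fit_hmm(true, pred, eps=1e-12)
        # transitions from state 0: 0->0 once, 0->1 once, 0->2 once
        assert np.allclose(hmm.transition[0], [1 / 3, 1 / 3, 1 / 3, 0], atol=1e-9)
        # emissions from true 0 (3 epochs): predicted 0 twice, 1 once
        assert np.allclose(hmm.emission[0], [2 / 3, 1 / 3, 0, 0], atol=1e-9)
        # prior = empirical frequencies 3/6, 2/6, 1/6, 0
        assert np.allclose(hmm.prior, [0.5, 1 / 3, 1 / 6, 0], atol=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fit_hmm(np.zeros(5, int), np.zeros(4, int))

    def test_row_stochastic_after_json_round_trip(self, tmp_path, rng):
        t = rng.integers(0, 4, 200)
        p = rng.integers(0, 4, 200)
        hmm = fit_hmm(t, p)
        f = tmp_path / "hmm.json"
        hmm.to_json(f)
        back = HmmParams.from_json(f)
        assert np.array_equal(back.transition, hmm.transition)
        assert np.array_equal(back.emission, hmm.emission)
        assert np.all(np.abs(back.transition.sum(axis=1) - 1) <= 1e-12)


# ---------------------------------------------------------------------------
# decoding


class TestViterbi:
    def test_identity_emission_returns_input(self, rng):
        prior, trans, _ = random_hmm(rng)
        hmm = HmmParams(STATES, prior, trans, np.eye(4))
        obs = rng.integers(0, 4, size=50)
        assert np.array_equal(viterbi_smooth(obs, hmm), obs)

    def test_two_state_blip_corrected(self):
        # persistent dynamics + decent classifier: A,A,B,A,A decodes to all A
        hmm = HmmParams(("A", "B"), [0.5, 0.5],
                        [[0.99, 0.01], [0.01, 0.99]],
                        [[0.9, 0.1], [0.2, 0.8]])
        obs = np.array(["A", "A", "B", "A", "A"])
        decoded = viterbi_smooth(obs, hmm)
        assert list(decoded) == ["A"] * 5
        # cross-check against exhaustive enumeration over all 2^5 paths
        brute, _, _ = brute_force_viterbi(np.array([0, 0, 1, 0, 0]), hmm.prior,
                                          hmm.transition, hmm.emission)
        assert np.array_equal(brute, np.zeros(5, int))

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(60):
            prior, trans, emis = random_hmm(rng)
            hmm = HmmParams(STATES, prior, trans, emis)
            T = int(rng.integers(1, 9))
            obs = rng.integers(0, 4, size=T)
            v = viterbi_smooth(obs, hmm)
            b, best_lp, n_ties = brute_force_viterbi(obs, prior, trans, emis)
            # the decoded path must attain the enumerated maximum; the label
            # sequence itself is only pinned down when the argmax is unique
            assert path_log_prob(v, obs, prior, trans, emis) >= best_lp - 1e-9
            if n_ties == 1:
                assert np.array_equal(v, b)

    def test_string_labels_round_trip(self, rng):
        prior, trans, emis = random_hmm(rng)
        hmm = HmmParams(STATES, prior, trans, emis)
        obs = np.array([STATES[i] for i in rng.integers(0, 4, size=20)])
        out = viterbi_smooth(obs, hmm)
        assert set(out) <= set(STATES)

    def test_unknown_label_rejected(self):
        hmm = HmmParams(("A", "B"), [0.5, 0.5], np.eye(2), np.eye(2))
        with pytest.raises(ValueError):
            viterbi_smooth(np.array(["A", "C"]), hmm)

    def test_posterior_smoothing_agrees_on_easy_instances(self, rng):
        hmm = HmmParams(("A", "B"), [0.5, 0.5],
                        [[0.99, 0.01], [0.01, 0.99]],
                        [[0.9, 0.1], [0.2, 0.8]])
        obs = np.array([0, 0, 1, 0, 0])
        assert np.array_equal(posterior_smooth(obs, hmm), viterbi_smooth(obs, hmm))


# ---------------------------------------------------------------------------
# kappa


class TestCohensKappa:
    def test_identical_sequences_kappa_one(self, rng):
        a = rng.integers(0, 4, size=100)
        assert cohens_kappa(a, a) == 1.0

    def test_hand_confusion_table_gives_0p4(self):
        # confusion [[20, 5], [10, 15]]: p_o = 0.7, p_e = 0.5
        a = np.array([0] * 25 + [1] * 25)
        b = np.array([0] * 20 + [1] * 5 + [0] * 10 + [1] * 15)
        assert cohens_kappa(a, b) == pytest.approx(0.4)

    def test_independent_labels_near_zero(self, rng):
        a = rng.integers(0, 4, size=10_000)
        b = rng.integers(0, 4, size=10_000)
        assert abs(cohens_kappa(a, b)) < 0.05

    def test_both_constant_same_label_is_one(self):
        assert cohens_kappa(np.zeros(10, int), np.zeros(10, int)) == 1.0

    def test_length_mismatch_and_empty_rejected(self):
        with pytest.raises(ValueError):
            cohens_kappa(np.zeros(3, int), np.zeros(4, int))
        with pytest.raises(ValueError):
            cohens_kappa(np.array([]), np.array([]))
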