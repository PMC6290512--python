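"""Ensemble re-representation and the categorical naive-Bayes meta-classifier.

The naive Bayes is bespoke, so it is checked against independent oracles:
hand-computed smoothed frequencies, a brute-force tally on a random meta
table, and exhaustive posterior enumeration over every possible label
vector at small M.
"""

import itertools
import math
from collections import Counter

import numpy as np
import pytest

from hiermc import (
    COMBINED_45,
    MetaRepresentation,
    build_balanced_sets,
    build_meta_representation,
    coarse_predict,
    fit_coarse,
    fit_naive_bayes_meta,
    fit_simple_meta_classifier,
    train_base_classifiers,
)
from conftest import make_recordset, separable_recordset


def _nb_oracle(vectors, labels, alphabet, alpha):
    """Independent tally-based naive Bayes: returns functions computing
    priors, conditionals and posterior-argmax predictions."""
    n = len(labels)
    classes = sorted(set(labels))
    n_c = Counter(labels)
    prior = {c: n_c[c] / n for c in classes}
    cond = {}
    m = len(vectors[0])
    for j in range(m):
        for c in classes:
            for v in alphabet:
                num = sum(
                    1 for vec, lab in zip(vectors, labels) if lab == c and vec[j] == v
                )
                cond[(j, c, v)] = (num + alpha) / (n_c[c] + alpha * len(alphabet))

    def predict_one(vec, tie_priority):
        scores = {
            c: math.log(prior[c])
            + sum(math.log(cond[(j, c, vec[j])]) for j in range(m))
            for c in classes
        }
        best = max(scores.values())
        for c in tie_priority:
            if scores[c] == best:
                return c
        raise AssertionError

    return prior, cond, predict_one


class TestFitNaiveBayes:
    def test_hand_computed_smoothing(self):
        # two records, M=1, labels agree with class, alpha=1:
        # P(C_1=3 | 3) = (1+1)/(1+2) = 2/3
        meta = MetaRepresentation(
            vectors=np.array([[3], [COMBINED_45]]), label_alphabet=(3, COMBINED_45)
        )
        nb = fit_naive_bayes_meta(meta, np.array([3, COMBINED_45]), alpha=1.0)
        c3 = int(np.flatnonzero(nb.classes == 3)[0])
        v3 = int(np.flatnonzero(nb.alphabet == 3)[0])
        assert math.exp(nb.log_cond[0, c3, v3]) == pytest.approx(2 / 3)
        assert math.exp(nb.log_priors[c3]) == pytest.approx(0.5)

    def test_conditional_rows_normalise(self):
        rng = np.random.default_rng(0)
        vectors = rng.choice([3, COMBINED_45], size=(50, 4))
        labels = rng.choice([3, COMBINED_45], size=50)
        meta = MetaRepresentation(vectors, (3, COMBINED_45))
        nb = fit_naive_bayes_meta(meta, labels, alpha=0.7)
        rows = np.exp(nb.log_cond).sum(axis=2)
        np.testing.assert_allclose(rows, 1.0, rtol=1e-12)

    def test_frequencies_match_brute_force_tally(self):
        rng = np.random.default_rng(42)
        vectors = rng.choice([3, COMBINED_45], size=(200, 3))
        labels = rng.choice([3, COMBINED_45], size=200, p=[0.7, 0.3])
        alphabet = (3, COMBINED_45)
        meta = MetaRepresentation(vectors, alphabet)
        nb = fit_naive_bayes_meta(meta, labels, alpha=1.0)
        prior, cond, _ = _nb_oracle(
            [tuple(v) for v in vectors], list(labels), list(alphabet), 1.0
        )
        for c_i, c in enumerate(nb.classes):
            assert math.exp(nb.log_priors[c_i]) == pytest.approx(prior[c])
            for j in range(3):
                for v_i, v in enumerate(nb.alphabet):
                    assert math.exp(nb.log_cond[j, c_i, v_i]) == pytest.approx(
                        cond[(j, int(c), int(v))]
                    )

    def test_single_class_rejected(self):
        meta = MetaRepresentation(np.array([[3], [3]]), (3, COMBINED_45))
        with pytest.raises(ValueError, match="single class"):
            fit_naive_bayes_meta(meta, np.array([3, 3]))

    def test_nonpositive_alpha_rejected(self):
        meta = MetaRepresentation(
            np.array([[3], [COMBINED_45]]), (3, COMBINED_45)
        )
        with pytest.raises(ValueError):
            fit_naive_bayes_meta(meta, np.array([3, COMBINED_45]), alpha=0.0)


class TestNaiveBayesPredict:
    @pytest.mark.parametrize("m", [1, 2, 3, 4])
    def test_exhaustive_enumeration_oracle(self, m):
        rng = np.random.default_rng(m)
        vectors = rng.choice([3, COMBINED_45], size=(120, m))
        labels = rng.choice([3, COMBINED_45], size=120, p=[0.6, 0.4])
        meta = MetaRepresentation(vectors, (3, COMBINED_45))
        nb = fit_naive_bayes_meta(meta, labels, alpha=1.0)
        _, _, predict_one = _nb_oracle(
            [tuple(v) for v in vectors], list(labels), [3, COMBINED_45], 1.0
        )
        grid = np.array(list(itertools.product([3, COMBINED_45], repeat=m)))
        got = nb.predict(grid)
        want = [predict_one(tuple(v), (COMBINED_45, 3)) for v in grid]
        np.testing.assert_array_equal(got, want)

    def test_symmetric_tie_returns_combined_class(self):
        # perfectly symmetric training data: posterior for the all-3 and
        # all-45 vectors is identical between classes, so ties must go 45
        vectors = np.array([[3, COMBINED_45], [COMBINED_45, 3]])
        labels = np.array([3, COMBINED_45])
        nb = fit_naive_bayes_meta(
            MetaRepresentation(vectors, (3, COMBINED_45)), labels, alpha=1.0
        )
        pred = nb.predict(np.array([[3, 3], [COMBINED_45, COMBINED_45]]))
        assert (pred == COMBINED_45).all()

    def test_dominant_conditionals(self):
        # both base labels say 45 and P(45|45) > P(45|3): must predict 45
        rng = np.random.default_rng(1)
        n = 40
        labels = np.repeat([3, COMBINED_45], n // 2)
        flipped = 48 - labels[:, None]  # 3 <-> 45
        vectors = np.where(rng.random((n, 2)) < 0.9, labels[:, None], flipped)
        nb = fit_naive_bayes_meta(
            MetaRepresentation(vectors, (3, COMBINED_45)), labels
        )
        assert nb.predict(np.array([[COMBINED_45, COMBINED_45]]))[0] == COMBINED_45

    def test_posteriors_match_sklearn_categorical_nb(self):
        # independent library cross-check: identical smoothing (alpha=1,
        # unsmoothed frequency priors) must give identical posteriors
        from scipy.special import logsumexp
        from sklearn.naive_bayes import CategoricalNB

        rng = np.random.default_rng(7)
        vectors = rng.choice([3, COMBINED_45], size=(150, 5))
        labels = rng.choice([3, COMBINED_45], size=150, p=[0.7, 0.3])
        nb = fit_naive_bayes_meta(
            MetaRepresentation(vectors, (3, COMBINED_45)), labels, alpha=1.0
        )
        enc = (vectors == COMBINED_45).astype(int)
        sk = CategoricalNB(alpha=1.0).fit(enc, labels)
        test = rng.choice([3, COMBINED_45], size=(40, 5))
        scores = nb.posterior_scores(test)
        log_post = scores - logsumexp(scores, axis=1, keepdims=True)
        np.testing.assert_allclose(
            log_post,
            sk.predict_log_proba((test == COMBINED_45).astype(int)),
            rtol=1e-10,
            atol=1e-10,
        )

    def test_reordering_base_classifiers_invariant(self):
        rng = np.random.default_rng(3)
        vectors = rng.choice([3, COMBINED_45], size=(80, 4))
        labels = rng.choice([3, COMBINED_45], size=80)
        nb = fit_naive_bayes_meta(MetaRepresentation(vectors, (3, COMBINED_45)), labels)
        perm = [2, 0, 3, 1]
        nb_perm = fit_naive_bayes_meta(
            MetaRepresentation(vectors[:, perm], (3, COMBINED_45)), labels
        )
        test = rng.choice([3, COMBINED_45], size=(30, 4))
        np.testing.assert_array_equal(
            nb.predict(test), nb_perm.predict(test[:, perm])
        )


class TestEnsemble:
    def test_one_model_per_subset(self, fast_spec):
        train = separable_recordset(n3=70, n4=6, n5=4)
        bs = build_balanced_sets(train, 3, M=7, seed=0)
        models = train_base_classifiers(bs, fast_spec)
        assert len(models) == 7
        for m in models:
            assert set(m.classes_) == {3, COMBINED_45}

    def test_separable_subset_trains_to_perfect_coarse_accuracy(self, fast_spec):
        train = separable_recordset(n3=30, n4=10, n5=5, noise=0.01)
        bs = build_balanced_sets(train, 3, M=2, seed=0)
        models = train_base_classifiers(bs, fast_spec)
        sub = bs.subsets[0]
        want = np.where(sub.stages == 3, 3, COMBINED_45)
        np.testing.assert_array_equal(models[0].predict(sub.features), want)

    def test_meta_representation_order_and_determinism(self, fast_spec):
        train = separable_recordset(n3=40, n4=10, n5=5)
        bs = build_balanced_sets(train, 3, M=2, seed=0)
        models = train_base_classifiers(bs, fast_spec)
        rep1 = build_meta_representation(models, train)
        rep2 = build_meta_representation(models, train)
        np.testing.assert_array_equal(rep1.vectors, rep2.vectors)
        assert rep1.vectors.shape == (len(train), 2)
        np.testing.assert_array_equal(
            rep1.vectors[:, 1], models[1].predict(train.features)
        )

    def test_dimension_mismatch_rejected(self, fast_spec):
        train = separable_recordset(n3=40, n4=10, n5=5)
        bs = build_balanced_sets(train, 3, M=2, seed=0)
        models = train_base_classifiers(bs, fast_spec)
        other = make_recordset([3, 4], n_features=7)
        with pytest.raises(ValueError, match="dimension"):
            build_meta_representation(models, other)

    def test_m1_meta_reproduces_base_coarse_labels(self, fast_spec):
        # with a single, confident base model the meta step can only echo it
        train = separable_recordset(n3=20, n4=10, n5=10, noise=0.01)
        bs = build_balanced_sets(train, 3, M=1, seed=0)
        coarse = fit_coarse(train, bs, fast_spec)
        base_labels = coarse.base_models[0].predict(train.features)
        np.testing.assert_array_equal(coarse_predict(coarse, train), base_labels)


class TestSimpleMC:
    def test_prediction_alphabet_and_determinism(self, fast_spec):
        train = separable_recordset(n3=60, n4=20, n5=10)
        test = separable_recordset(n3=30, n4=10, n5=5, seed=9)
        m1 = fit_simple_meta_classifier(train, fast_spec, seed=5)
        m2 = fit_simple_meta_classifier(train, fast_spec, seed=5)
        p1 = coarse_predict(m1, test)
        p2 = coarse_predict(m2, test)
        assert set(np.unique(p1)) <= {3, 4, 5}
        np.testing.assert_array_equal(p1, p2)

    def test_base_models_keep_three_classes(self, fast_spec):
        train = separable_recordset(n3=60, n4=20, n5=10)
        m = fit_simple_meta_classifier(train, fast_spec, M=2)
        assert all(set(bm.classes_) == {3, 4, 5} for bm in m.base_models)
        assert tuple(m.nb.alphabet) == (3, 4, 5)
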