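import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from meascreen.classifier import (ClassifierOutput, CostParams, CvConfig,
                                  GreedySparseLDA, classifier_input,
                                  cost_binary, cost_multiclass,
                                  evaluate_weights, lda_classify,
                                  regularization_penalty, stop_check)


def _out(predicted, confidence, classes=(-1, 1)):
    return ClassifierOutput(np.asarray(predicted),
                            np.asarray(confidence, dtype=float),
                            np.asarray(classes))


class TestBinaryCost:
    @pytest.mark.parametrize("labels,alpha", [
        ((1, 1, -1, -1), 1.0), ((1, 1, -1, -1), 2.0),
        ((1, -1, -1), 3.5), ((1, 1, 1, 1, -1), 2.0),
    ])
    def test_all_correct_full_confidence_is_minus_two(self, labels, alpha):
        out = _out(labels, np.ones(len(labels)))
        assert cost_binary(labels, out, alpha) == pytest.approx(-2.0)

    @pytest.mark.parametrize("labels", [(1, 1, -1, -1), (1, -1, -1)])
    def test_all_wrong_reaches_upper_bound(self, labels):
        flipped = [-l for l in labels]
        out = _out(flipped, np.ones(len(labels)))
        assert cost_binary(labels, out, 1.0) == pytest.approx(2.0)
        assert cost_binary(labels, out, 3.0) == pytest.approx(4.0)

    def test_term_by_term_example(self):
        l = (1, 1, -1, -1)
        out = _out((1, -1, -1, -1), np.ones(4))
        assert cost_binary(l, out, 2.0) == pytest.approx(-0.5)

    @settings(derandomize=True, max_examples=300)
    @given(st.data())
    def test_bounds_fuzz(self, data):
        n = data.draw(st.integers(2, 30))
        labels = data.draw(
            st.lists(st.sampled_from([-1, 1]), min_size=n, max_size=n)
            .filter(lambda ls: len(set(ls)) == 2))
        preds = data.draw(st.lists(st.sampled_from([-1, 1]),
                                   min_size=n, max_size=n))
        conf = data.draw(st.lists(st.floats(0.5, 1.0),
                                  min_size=n, max_size=n))
        alpha = data.draw(st.floats(1.0, 5.0))
        s = cost_binary(labels, _out(preds, conf), alpha)
        assert -2.0 - 1e-9 <= s <= 1.0 + alpha + 1e-9

    def test_balanced_accuracy_identity(self):
        """alpha=1, confidence 1: -s/2 equals 2*BA - 1 (direct algebra)."""
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = 40
            labels = np.concatenate([np.ones(n // 2), -np.ones(n // 2)])
            preds = rng.choice([-1, 1], size=n)
            s = cost_binary(labels, _out(preds, np.ones(n)), 1.0)
            tpr = np.mean(preds[labels == 1] == 1)
            tnr = np.mean(preds[labels == -1] == -1)
            ba = 0.5 * (tpr + tnr)
            assert -s / 2 == pytest.approx(2 * ba - 1)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cost_binary((1, 1), _out((1, 1), (1, 1)), 2.0)


class TestMulticlassCost:
    def test_all_correct_is_minus_k(self):
        labels = (1, 2, 3, 1, 2, 3)
        out = _out(labels, np.ones(6), classes=(1, 2, 3))
        assert cost_multiclass(labels, out) == pytest.approx(-3.0)

    def test_all_wrong_is_sum_of_alphas(self):
        labels = (1, 2, 3)
        out = _out((2, 3, 1), np.ones(3), classes=(1, 2, 3))
        assert cost_multiclass(labels, out) == pytest.approx(3.0)
        assert cost_multiclass(labels, out,
                               alphas=(2.0, 1.0, 0.5)) == pytest.approx(3.5)

    def test_term_by_term_example(self):
        labels = (1, 2, 3)
        out = _out((1, 3, 3), np.ones(3), classes=(1, 2, 3))
        assert cost_multiclass(labels, out) == pytest.approx(-1.0)

    @settings(derandomize=True, max_examples=200)
    @given(st.data())
    def test_bounds_fuzz(self, data):
        k = data.draw(st.integers(2, 4))
        reps = data.draw(st.integers(1, 6))
        labels = np.tile(np.arange(1, k + 1), reps)
        n = labels.size
        preds = data.draw(st.lists(st.integers(1, k), min_size=n,
                                   max_size=n))
        conf = data.draw(st.lists(st.floats(1.0 / k, 1.0), min_size=n,
                                  max_size=n))
        alphas = data.draw(st.lists(st.floats(0.1, 4.0), min_size=k,
                                    max_size=k))
        out = _out(preds, conf, classes=tuple(range(1, k + 1)))
        s = cost_multiclass(labels, out, alphas)
        assert -k - 1e-9 <= s <= sum(alphas) + 1e-9

    def test_missing_class_rejected(self):
        out = _out((1, 1), np.ones(2), classes=(1, 2))
        with pytest.raises(ValueError):
            cost_multiclass((1, 1), out)


class TestRegularization:
    def test_unit_norm_row_contributes_nothing(self):
        row = np.zeros(10)
        row[3] = 1.0
        assert regularization_penalty(row, 0.1, "as_printed") == 0.0
        assert regularization_penalty(row, 0.1, "squared") == 0.0

    def test_printed_and_squared_modes(self):
        row = np.array([1.0, 1.0])
        assert regularization_penalty(row, 0.1,
                                      "as_printed") == pytest.approx(-0.1)
        assert regularization_penalty(row, 0.1,
                                      "squared") == pytest.approx(0.1)

    def test_penalty_breaks_scale_invariance(self):
        """LDA cost ignores row scaling; the squared penalty does not."""
        rng = np.random.default_rng(3)
        F = rng.normal(size=(40, 4))
        y = np.where(F[:, 1] > 0, 1, -1)
        row = np.zeros(4)
        row[1] = 1.0
        cp = CostParams(alpha=1.0, beta=0.1, penalty_mode="squared")
        cv = CvConfig(n_kfold=5, seed=1)
        s1, r1, _ = evaluate_weights(F, y, row, cp, cv)
        s2, r2, _ = evaluate_weights(F, y, 10 * row, cp, cv)
        assert s2 == pytest.approx(s1, abs=1e-9)     # cost scale-invariant
        assert r2 - s2 == pytest.approx(0.1 * 99.0 ** 2)
        assert r2 > r1


class TestLdaClassify:
    def test_separable_clouds(self):
        rng = np.random.default_rng(0)
        M = np.concatenate([rng.normal(-5, 0.1, 50),
                            rng.normal(5, 0.1, 50)])[:, None]
        y = np.array([-1] * 50 + [1] * 50)
        out = lda_classify(M, y, M)
        assert np.array_equal(out.predicted, y)
        assert np.all(out.confidence > 0.99)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(1)
        M = np.concatenate([rng.normal(-1, 1, 30),
                            rng.normal(1, 1, 30)])[:, None]
        y = np.array([-1] * 30 + [1] * 30)
        a = lda_classify(M, y, M)
        b = lda_classify(M, -y, M)
        np.testing.assert_array_equal(a.predicted, -b.predicted)

    def test_degenerate_constant_feature_never_crashes(self, caplog):
        M = np.column_stack([np.ones(20), np.r_[np.zeros(10), np.ones(10)]])
        y = np.array([-1] * 10 + [1] * 10)
        out = lda_classify(M, y, M)
        assert out.predicted.shape == (20,)


class TestClassifierInput:
    def test_single_selection_row(self):
        F = np.arange(12.0).reshape(4, 3)
        omega = np.zeros((1, 3))
        omega[0, 2] = 1.0
        np.testing.assert_array_equal(classifier_input(F, omega).ravel(),
                                      F[:, 2])

    def test_zero_weights_zero_input(self):
        F = np.random.default_rng(0).normal(size=(5, 4))
        assert np.all(classifier_input(F, np.zeros((2, 4))) == 0.0)

    def test_matches_double_loop_summation(self):
        rng = np.random.default_rng(4)
        F = rng.normal(size=(6, 5))
        omega = rng.normal(size=(2, 5))
        M = classifier_input(F, omega)
        brute = np.zeros((6, 2))
        for i in range(6):
            for k in range(2):
                for j in range(5):
                    brute[i, k] += omega[k, j] * F[i, j]
        np.testing.assert_allclose(M, brute, rtol=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classifier_input(np.zeros((3, 4)), np.zeros((1, 5)))


class TestEvaluateWeights:
    def test_perfect_feature_approaches_lower_bound(self):
        rng = np.random.default_rng(5)
        y = np.array([1, -1] * 30)
        F = np.column_stack([y + rng.normal(0, 0.01, 60),
                             rng.normal(size=60)])
        row = np.array([1.0, 0.0])
        s, _, _ = evaluate_weights(F, y, row, CostParams(alpha=2.0),
                                   CvConfig(n_kfold=10, seed=0))
        assert s < -1.9

    def test_noise_features_score_near_chance(self):
        rng = np.random.default_rng(6)
        y = np.array([1, -1] * 40)
        F = rng.normal(size=(80, 3))
        s, _, _ = evaluate_weights(F, y, np.array([1.0, 0.5, -0.5]),
                                   CostParams(alpha=1.0),
                                   CvConfig(n_kfold=10, seed=0))
        assert s > -0.5

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(7)
        y = np.array([1, -1] * 20)
        F = rng.normal(size=(40, 3))
        cp = CostParams()
        a = evaluate_weights(F, y, np.array([1.0, 0, 0]), cp,
                             CvConfig(n_kfold=5, seed=3))[0]
        b = evaluate_weights(F, y, np.array([1.0, 0, 0]), cp,
                             CvConfig(n_kfold=5, seed=3))[0]
        assert a == b

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            evaluate_weights(np.zeros((4, 2)), [1, 1, -1, -1],
                             np.zeros(2), CostParams())


class TestStopCheck:
    @pytest.mark.parametrize("hist,tol,expected", [
        ((-1.0, -1.2), 0.05, True),     # 20% change: continue
        ((-1.00, -1.01), 0.05, False),  # 1% change: stop
        ((-1.0,), 0.05, True),          # first component always accepted
        ((0.0, -0.1), 0.05, True),      # zero guard: absolute change
        ((0.0, 0.0), 0.05, False),
    ])
    def test_examples(self, hist, tol, expected):
        assert stop_check(hist, tol) is expected


def _spiked_dataset(seed, n=60, nb=12):
    """One perfectly separating entry hidden among noise entries."""
    rng = np.random.default_rng(seed)
    y = np.array([1, -1] * (n // 2))
    F = rng.normal(size=(n, nb))
    good = rng.integers(0, nb)
    F[:, good] = y * 2.0 + rng.normal(0, 0.05, n)
    return F, y, int(good)


class TestGreedySparseLDA:
    def test_first_pick_matches_exhaustive_search(self):
        """Oracle equivalence over 5 seeded datasets."""
        for seed in range(5):
            F, y, good = _spiked_dataset(seed)
            est = GreedySparseLDA(d_max=1, n_comp_max=1,
                                  optimizer="coordinate", max_evals=10,
                                  cv_n_kfold=5, random_state=seed)
            est.fit(F, y)
            # brute-force single-entry search with the same cost
            costs = []
            for j in range(F.shape[1]):
                row = np.zeros(F.shape[1])
                row[j] = 1.0
                _, s_reg, _ = evaluate_weights(
                    F, y, row, CostParams(),
                    CvConfig(n_kfold=5, seed=seed))
                costs.append(s_reg)
            assert est.selected_[0][0] == int(np.argmin(costs)) == good

    def test_infinite_tolerance_stops_immediately(self):
        F, y, _ = _spiked_dataset(1)
        est = GreedySparseLDA(d_max=3, n_comp_max=3, tol=np.inf,
                              optimizer="coordinate", max_evals=10,
                              cv_n_kfold=3, random_state=0)
        est.fit(F, y)
        assert est.omega_.shape[0] == 1
        assert len(est.selected_[0]) == 1

    def test_accepted_costs_non_increasing_within_dimension(self):
        F, y, _ = _spiked_dataset(2, n=40, nb=8)
        est = GreedySparseLDA(d_max=1, n_comp_max=4, tol=1e-6,
                              optimizer="coordinate", max_evals=20,
                              cv_n_kfold=3, random_state=0)
        est.fit(F, y)
        costs = est.trace_.costs(dimension=0)
        assert all(b <= a + 1e-12 for a, b in zip(costs, costs[1:]))

    def test_deterministic_under_random_state(self):
        F, y, _ = _spiked_dataset(3, n=30, nb=6)
        kw = dict(d_max=1, n_comp_max=2, max_evals=30, cv_n_kfold=3,
                  random_state=11)
        a = GreedySparseLDA(**kw).fit(F, y)
        b = GreedySparseLDA(**kw).fit(F, y)
        np.testing.assert_array_equal(a.omega_, b.omega_)

    def test_sklearn_estimator_contract(self):
        est = GreedySparseLDA(alpha=3.0, d_max=1)
        params = est.get_params()
        assert params["alpha"] == 3.0
        cloned = clone(est)
        assert cloned.get_params() == params
        F, y, _ = _spiked_dataset(4, n=30, nb=6)
        cloned.set_params(optimizer="coordinate", max_evals=10,
                          cv_n_kfold=3, n_comp_max=1)
        cloned.fit(F, y)
        assert cloned.predict(F).shape == y.shape
        proba = cloned.predict_proba(F)
        assert proba.shape == (30, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)

    def test_cmaes_improves_weights_on_two_entry_problem(self):
        """CMA-ES finds a mixing weight a fixed unit weight cannot."""
        rng = np.random.default_rng(8)
        n = 80
        y = np.array([1, -1] * (n // 2))
        h = rng.normal(size=n)
        F = np.column_stack([y + 3 * h, 3 * h + rng.normal(0, 0.05, n)])
        est = GreedySparseLDA(d_max=1, n_comp_max=2, tol=1e-9,
                              optimizer="cmaes", max_evals=120,
                              cv_n_kfold=5, random_state=2)
        est.fit(F, y)
        # the difference F0 - F1 ~ y is separable; both entries needed
        assert len(est.selected_[0]) == 2
        acc = (est.predict(F) == y).mean()
        assert acc > 0.95

    def test_report_names_selected_entries(self):
        import pandas as pd
        F, y, good = _spiked_dataset(5, n=30, nb=6)
        df = pd.DataFrame(F, columns=[f"entry_{j}" for j in range(6)])
        est = GreedySparseLDA(d_max=1, n_comp_max=1, optimizer="coordinate",
                              max_evals=5, cv_n_kfold=3, random_state=0)
        est.fit(df, y)
        assert f"entry_{good}" in est.report()
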