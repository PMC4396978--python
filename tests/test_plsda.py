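"""NIPALS PLS-DA: algebraic identities, oracle equivalences, VIP behavior."""

import numpy as np
import pytest

from shockmetab import (autoscale, decision_scores, fit_plsda, predict,
                        select_vip, vip_scores)
from shockmetab.plsda import ModelError, PLSDAModel, VIPTable, decision_path

from conftest import separable_xy


def _random_xy(n=30, p=10, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    y = np.array(["CPF", "FS"])[rng.integers(0, 2, n)]
    while len(set(y)) < 2:
        y = np.array(["CPF", "FS"])[rng.integers(0, 2, n)]
    return X, y


class TestFit:
    def test_response_as_column_gives_perfect_fit(self):
        rng = np.random.default_rng(1)
        y = np.array(["CPF"] * 10 + ["FS"] * 10)
        coded = np.where(y == "CPF", 1.0, -1.0)
        noise = rng.standard_normal((20, 3))
        noise -= noise.mean(axis=0)
        noise -= np.outer(coded, coded @ noise) / (coded @ coded)  # y-orthogonal
        X = np.column_stack([coded, noise])
        model = fit_plsda(X, y, 1)
        assert model.r2y == pytest.approx(1.0, abs=1e-10)
        assert (predict(model, X) == y).all()

    def test_orthogonal_predictors_give_null_fit(self):
        # columns alternate within each class, so X'y_centered = 0 exactly
        y = np.array(["CPF"] * 4 + ["FS"] * 4)
        base = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        X = np.column_stack([base, base * np.array([1, 1, -1, -1] * 2)])
        model = fit_plsda(X, y, 1)
        assert abs(model.q).max() < 1e-10
        assert model.r2y < 1e-10
        assert np.abs(decision_scores(model, X) - model.y_mean).max() < 1e-10

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).standard_normal((10, 3))
        with pytest.raises(ModelError):
            fit_plsda(X, ["CPF"] * 10, 1)

    def test_too_many_components_rejected(self):
        X, y = _random_xy(10, 4, seed=2)
        with pytest.raises(ModelError):
            fit_plsda(X, y, 5)

    def test_full_rank_equals_least_squares(self):
        """At A = rank(X), PLS prediction equals the least-squares oracle."""
        X, y = _random_xy(30, 10, seed=3)
        model = fit_plsda(X, y, 10)
        coded = np.where(y == model.classes[0], 1.0, -1.0)
        Xs = autoscale(X).values
        beta, *_ = np.linalg.lstsq(Xs, coded - coded.mean(), rcond=None)
        ols_fit = Xs @ beta + coded.mean()
        np.testing.assert_allclose(decision_scores(model, X), ols_fit,
                                   rtol=1e-8, atol=1e-8)

    def test_matches_sklearn_pls_regression(self):
        """Fitted values agree with scikit-learn's NIPALS PLS on scaled data."""
        PLSRegression = pytest.importorskip(
            "sklearn.cross_decomposition").PLSRegression
        X, y = _random_xy(24, 8, seed=4)
        for a in (1, 2, 3):
            model = fit_plsda(X, y, a)
            coded = np.where(y == model.classes[0], 1.0, -1.0)
            Xs = autoscale(X).values
            ref = PLSRegression(n_components=a, scale=False).fit(Xs, coded)
            np.testing.assert_allclose(decision_scores(model, X),
                                       ref.predict(Xs).ravel(), atol=1e-8)


class TestModelInvariants:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_score_orthogonality_and_unit_weights(self, seed):
        X, y = _random_xy(25, 7, seed=seed)
        model = fit_plsda(X, y, 4)
        T = model.T
        for a in range(T.shape[1]):
            assert np.linalg.norm(model.W[:, a]) == pytest.approx(1.0)
            for b in range(a):
                dot = abs(T[:, a] @ T[:, b])
                assert dot < 1e-8 * np.linalg.norm(T[:, a]) * np.linalg.norm(T[:, b])

    def test_r2y_nondecreasing_in_components(self):
        X, y = _random_xy(20, 8, seed=7)
        r2 = [fit_plsda(X, y, a).r2y for a in range(1, 7)]
        assert all(b >= a - 1e-12 for a, b in zip(r2, r2[1:]))
        assert 0.0 <= r2[0] and r2[-1] <= 1.0

    def test_decision_path_consistent_with_individual_fits(self):
        X, y = _random_xy(22, 6, seed=8)
        model = fit_plsda(X, y, 5)
        path = decision_path(model, X)
        for a in (1, 3, 5):
            sub = fit_plsda(X, y, a)
            np.testing.assert_allclose(path[:, a - 1], decision_scores(sub, X),
                                       atol=1e-10)


class TestPredict:
    def test_training_separation_zero_misclassification(self):
        X, y = separable_xy(gap=8.0, seed=1)
        model = fit_plsda(X, y, 2)
        assert (predict(model, X) == y).all()

    def test_in_sample_consistency(self):
        X, y = _random_xy(18, 5, seed=9)
        model = fit_plsda(X, y, 3)
        single = decision_scores(model, X[4:5])
        assert single[0] == pytest.approx(decision_scores(model, X)[4])

    def test_labels_invariant_to_class_name_swap(self):
        """Renaming classes (which flips the +-1 coding) flips no prediction."""
        X, y = _random_xy(20, 6, seed=10)
        swap = {"CPF": "ZFS", "FS": "ACPF"}  # reverses the sort order
        y_swapped = np.array([swap[v] for v in y])
        m1 = fit_plsda(X, y, 2)
        m2 = fit_plsda(X, y_swapped, 2)
        inverse = {v: k for k, v in swap.items()}
        back = np.array([inverse[v] for v in predict(m2, X)])
        assert (predict(m1, X) == back).all()

    def test_column_mismatch_rejected(self):
        X, y = _random_xy(15, 6, seed=11)
        model = fit_plsda(X, y, 2)
        with pytest.raises(ModelError):
            predict(model, X[:, :3])

    def test_json_round_trip_predicts_identically(self, tmp_path):
        X, y = _random_xy(16, 5, seed=12)
        model = fit_plsda(X, y, 2)
        path = model.to_json(tmp_path / "model.json")
        back = PLSDAModel.from_json(path)
        np.testing.assert_allclose(decision_scores(back, X),
                                   decision_scores(model, X), rtol=1e-12)


class TestVIP:
    def test_sum_of_squares_equals_p(self):
        for seed in range(5):
            X, y = _random_xy(25, 9, seed=seed)
            model = fit_plsda(X, y, 3)
            table = vip_scores(model)
            assert (table.vip ** 2).sum() == pytest.approx(9, abs=1e-6)

    def test_equal_weights_give_unit_vip(self):
        # one component, all |w_j| equal -> every VIP is exactly 1
        y = np.array(["CPF"] * 6 + ["FS"] * 6)
        coded = np.where(y == "CPF", 1.0, -1.0)
        rng = np.random.default_rng(3)
        noise = rng.standard_normal(12) * 0.1
        X = np.column_stack([coded + noise] * 4)  # identical columns
        model = fit_plsda(X, y, 1)
        table = vip_scores(model)
        np.testing.assert_allclose(table.vip, 1.0, atol=1e-10)

    def test_planted_metabolite_has_top_vip(self):
        """A single informative variable wins the VIP ranking almost always."""
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n = 30
            y = np.array(["CPF"] * 15 + ["FS"] * 15)
            X = rng.standard_normal((n, 8))
            X[:15, 5] += 3.0
            model = fit_plsda(X, y, 2)
            table = vip_scores(model)
            hits += int(np.argmax(table.vip)) == 5
        assert hits >= 95

    def test_selection_cap(self):
        table = VIPTable(names=[f"m{i:02d}" for i in range(15)],
                         vip=np.linspace(2.0, 1.1, 15))
        sel = select_vip(table)
        assert len(sel) == 10
        assert sel[0] == "m00"

    def test_none_above_threshold_empty(self):
        table = VIPTable(names=["a", "b"], vip=np.array([0.5, 0.9]))
        assert select_vip(table) == []

    def test_three_above_threshold_descending(self):
        table = VIPTable(names=["a", "b", "c", "d"],
                         vip=np.array([1.2, 0.4, 2.0, 1.5]))
        assert select_vip(table) == ["c", "d", "a"]

    def test_boundary_ties_broken_by_name(self):
        names = [f"m{i}" for i in range(12)]
        vip = np.array([1.5] * 12)
        table = VIPTable(names=names, vip=vip)
        assert select_vip(table) == sorted(names)[:10]
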