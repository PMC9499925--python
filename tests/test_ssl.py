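import numpy as np
import pytest
from sklearn.base import clone

from gravinet import (
    GraphConfig,
    GraphSSLClassifier,
    build_graph,
    fit_predict,
    propagate,
    tune_hyperparameters,
    youden_threshold,
)
from gravinet.cohort import fit_standardizer
from gravinet.graph import PatientGraph


def random_graph(n: int, seed: int) -> PatientGraph:
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 3))
    return build_graph(X, GraphConfig(sigma=1.0))


def jacobi(W: np.ndarray, y: np.ndarray, mu: float, tol: float = 1e-13) -> np.ndarray:
    """Fixed-point iteration for (I + mu L) f = y, used as an oracle."""
    d = W.sum(axis=1)
    f = np.zeros_like(y, dtype=float)
    for _ in range(500_000):
        f_new = (y + mu * (W @ f)) / (1.0 + mu * d)
        if np.abs(f_new - f).max() < tol:
            return f_new
        f = f_new
    raise RuntimeError("Jacobi iteration did not converge")


class TestPropagate:
    def test_identity_limit_at_tiny_mu(self):
        g = random_graph(25, 0)
        y = np.random.default_rng(1).choice([-1.0, 0.0, 1.0], size=25)
        f = propagate(g, y, mu=1e-12)
        assert np.abs(f - y).max() < 1e-8

    def test_two_node_hand_solution(self):
        # W = [[0,1],[1,0]], mu=1: (I+L)^-1 = [[2,1],[1,2]]/3, y=(1,0) -> (2/3, 1/3)
        g = PatientGraph(weights=np.array([[0.0, 1.0], [1.0, 0.0]]))
        f = propagate(g, np.array([1.0, 0.0]), mu=1.0)
        assert np.allclose(f, [2 / 3, 1 / 3], atol=1e-12)

    def test_matches_jacobi_iteration(self):
        g = random_graph(30, 2)
        y = np.random.default_rng(3).choice([-1.0, 0.0, 1.0], size=30)
        f = propagate(g, y, mu=0.7)
        assert np.abs(f - jacobi(g.weights, y, 0.7)).max() < 1e-8

    def test_flat_limit_at_huge_mu(self):
        g = random_graph(20, 4)
        y = np.random.default_rng(5).choice([-1.0, 1.0], size=20)
        f = propagate(g, y, mu=1e6)
        assert np.abs(f - y.mean()).max() < 1e-3

    def test_scores_bounded_by_label_range(self):
        for seed in range(10):
            g = random_graph(15, seed)
            y = np.random.default_rng(seed).choice([-1.0, 0.0, 1.0], size=15)
            f = propagate(g, y, mu=10 ** np.random.default_rng(seed).uniform(-2, 2))
            assert f.min() >= y.min() - 1e-10
            assert f.max() <= y.max() + 1e-10

    def test_permuting_patients_permutes_scores(self):
        g = random_graph(18, 6)
        y = np.random.default_rng(7).choice([-1.0, 0.0, 1.0], size=18)
        f = propagate(g, y, mu=2.0)
        perm = np.random.default_rng(8).permutation(18)
        g_p = PatientGraph(weights=g.weights[np.ix_(perm, perm)])
        f_p = propagate(g_p, y[perm], mu=2.0)
        assert np.allclose(f_p, f[perm], atol=1e-12)

    def test_smoothness_penalty_decreases_with_mu(self):
        g = random_graph(22, 9)
        y = np.random.default_rng(10).choice([-1.0, 0.0, 1.0], size=22)
        L = g.laplacian
        penalties = [
            float(f @ L @ f)
            for f in (propagate(g, y, mu) for mu in (0.01, 0.1, 1.0, 10.0, 100.0))
        ]
        assert all(a >= b - 1e-12 for a, b in zip(penalties, penalties[1:]))

    def test_nonpositive_mu_rejected(self):
        g = random_graph(5, 11)
        with pytest.raises(ValueError):
            propagate(g, np.zeros(5), mu=0.0)


class TestYoudenThreshold:
    def test_perfect_separation_returns_midpoint(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, -1, -1])
        assert youden_threshold(scores, labels) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            youden_threshold(np.array([0.1, 0.2]), np.array([1, 1]))

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            n = int(rng.integers(4, 40))
            scores = np.round(rng.normal(size=n), 1)  # ties on purpose
            labels = rng.choice([-1, 1], size=n)
            if len(set(labels)) < 2:
                continue
            thr = youden_threshold(scores, labels)
            uniq = np.unique(scores)
            best_j, best_t = -np.inf, None
            for t in (uniq[:-1] + uniq[1:]) / 2:
                sens = np.mean(scores[labels == 1] > t)
                spec = np.mean(scores[labels == -1] <= t)
                if sens + spec - 1 > best_j + 1e-12:  # first maximum on ties
                    best_j, best_t = sens + spec - 1, t
            if best_t is not None:
                assert thr == pytest.approx(best_t)


class TestGraphSSLClassifier:
    def _toy(self, seed=0, n=80):
        rng = np.random.default_rng(seed)
        y = rng.choice([-1, 1], size=n, p=[0.7, 0.3])
        X = rng.normal(size=(n, 3)) + 1.5 * y[:, None]
        return X, y

    def test_sklearn_protocol(self):
        clf = GraphSSLClassifier(sigma=2.0, mu=0.5)
        assert clone(clf).get_params()["mu"] == 0.5
        X, y = self._toy()
        clf.fit(X, y)
        assert hasattr(clf, "scores_") and hasattr(clf, "threshold_")
        assert set(clf.predict(X[:5])) <= {-1, 1}

    def test_unlabeled_rows_get_scores_but_no_votes(self):
        X, y = self._toy(seed=1)
        y_masked = y.copy()
        y_masked[:20] = 0
        clf = GraphSSLClassifier(sigma=2.0, mu=1.0).fit(X, y_masked)
        assert np.all(np.abs(clf.scores_[:20]) <= 1 + 1e-10)
        # masked rows are mostly recovered through their neighbours
        assert (np.sign(clf.scores_[:20]) == y[:20]).mean() > 0.7

    def test_labeled_only_fit_equals_full_fit_without_unlabeled(self, small_cohort):
        cohort, _, _ = small_cohort
        lab = cohort.subset(cohort.y != 0)
        a = fit_predict(lab, lab.variable_names, sigma=2.0, mu=1.0,
                        include_unlabeled=True)
        b = fit_predict(lab, lab.variable_names, sigma=2.0, mu=1.0,
                        include_unlabeled=False)
        assert np.allclose(a.scores.to_numpy(), b.scores.to_numpy(), atol=1e-14)
        assert a.threshold == b.threshold

    def test_far_away_patient_scores_zero_and_classifies_negative(self):
        X, y = self._toy(seed=2)
        clf = GraphSSLClassifier(sigma=1.0, mu=1.0).fit(X, y)
        clf.threshold_ = 0.0  # the documented sign convention: 0 is negative
        far = np.full((1, 3), 1e6)
        f = clf.decision_function(far)
        assert abs(f[0]) < 1e-12
        assert clf.predict(far)[0] == -1

    def test_test_labels_never_enter_propagation(self, small_cohort):
        cohort, _, _ = small_cohort
        flipped = cohort.subset(np.arange(cohort.n))
        test_mask = flipped.split == "test"
        flipped.y[test_mask] = -flipped.y[test_mask]  # corrupt test outcomes
        a = fit_predict(cohort, cohort.variable_names, sigma=2.0, mu=1.0)
        b = fit_predict(flipped, flipped.variable_names, sigma=2.0, mu=1.0)
        assert np.allclose(a.scores.to_numpy(), b.scores.to_numpy())


class TestTuneHyperparameters:
    def _train(self, small_cohort):
        cohort, _, _ = small_cohort
        train = cohort.subset(cohort.split == "train")
        std = fit_standardizer(train)
        return std.transform(train.X.to_numpy(float)), train.y

    def test_single_grid_point_is_returned(self, small_cohort):
        X, y = self._train(small_cohort)
        res = tune_hyperparameters(
            X, y, sigma_grid=[1.3], mu_grid=[0.7], cv_repeats=2, seed=0
        )
        assert (res.sigma, res.mu) == (1.3, 0.7)
        assert len(res.table) == 1

    def test_same_seed_gives_identical_tables(self, small_cohort):
        X, y = self._train(small_cohort)
        kw = dict(sigma_grid=[1.0, 2.0], mu_grid=[0.1, 1.0], cv_repeats=3, seed=5)
        a = tune_hyperparameters(X, y, **kw)
        b = tune_hyperparameters(X, y, **kw)
        assert a.table.equals(b.table)
        assert (a.sigma, a.mu) == (b.sigma, b.mu)

    def test_informative_tuning_beats_permuted_labels(self, small_cohort):
        X, y = self._train(small_cohort)
        res = tune_hyperparameters(X, y, cv_repeats=3, seed=1)
        best = res.table["mean_auroc"].max()
        rng = np.random.default_rng(2)
        nulls = []
        for _ in range(5):
            y_perm = y.copy()
            lab = np.flatnonzero(y != 0)
            y_perm[lab] = y[rng.permutation(lab)]
            null = tune_hyperparameters(
                X, y_perm, sigma_grid=[res.sigma], mu_grid=[res.mu],
                cv_repeats=3, seed=3,
            )
            nulls.append(null.table["mean_auroc"].iloc[0])
        assert best > 0.5 + 3 * max(np.std(nulls), 1e-3)
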