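import numpy as np
import pytest
from scipy.special import logsumexp
from sklearn.mixture import GaussianMixture

from sonoliver import (
    AAOClassifier,
    AAOGMMClassifier,
    AlgaeConfig,
    GMMClassifier,
    HarmonyConfig,
    HSClassifier,
    SDCModel,
    SVMModel,
    TargetScheme,
    aao_optimize,
    check_target_separation,
    encode_targets,
    harmony_search,
    make_classifier,
)
from sonoliver.classifiers import _friction


class TestTargetCoding:
    def test_default_targets(self):
        np.testing.assert_allclose(
            encode_targets(["normal", "abnormal"]), [0.1, 0.85]
        )
        np.testing.assert_allclose(encode_targets([0, 1, 0]), [0.1, 0.85, 0.1])

    def test_insufficient_separation_rejected(self):
        with pytest.raises(ValueError):
            TargetScheme(0.1, 0.5)

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValueError):
            encode_targets(["normal", "weird"])

    def test_separation_check_logs_not_raises(self, caplog):
        # normal-class mean far above its 0.1 bound: warned, not an error
        ok = check_target_separation({"normal": np.full((5, 3), 0.9)})
        assert not ok
        assert check_target_separation({"normal": np.full((5, 3), 0.05)})

    def test_all_normal_degenerate_set(self):
        out = encode_targets(["normal", "normal"])
        np.testing.assert_allclose(out, [0.1, 0.1])


class TestGMM:
    def test_bayes_separable_accuracy(self):
        rng = np.random.default_rng(0)
        Xtr = np.r_[rng.normal(0, 0.1, (100, 1)), rng.normal(1, 0.1, (100, 1))]
        ytr = np.r_[np.zeros(100, int), np.ones(100, int)]
        Xte = np.r_[rng.normal(0, 0.1, (50, 1)), rng.normal(1, 0.1, (50, 1))]
        yte = np.r_[np.zeros(50, int), np.ones(50, int)]
        model = GMMClassifier(n_components=1, seed=1).fit(Xtr, ytr)
        assert (model.predict(Xte) == yte).mean() > 0.99

    def test_point_at_class_mean_wins(self):
        rng = np.random.default_rng(1)
        X = np.r_[rng.normal(0, 0.05, (30, 2)), rng.normal(5, 0.05, (30, 2))]
        y = np.r_[np.zeros(30, int), np.ones(30, int)]
        model = GMMClassifier(seed=0).fit(X, y)
        mu0 = model.mixtures_[0].means[0]
        assert model.predict(mu0[None, :])[0] == 0

    def test_em_loglik_trace_non_decreasing(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = np.r_[rng.normal(0, 1, (40, 2)), rng.normal(2, 0.5, (40, 2))]
            y = np.r_[np.zeros(40, int), np.ones(40, int)]
            model = GMMClassifier(n_components=2, seed=seed).fit(X, y)
            for mix in model.mixtures_.values():
                trace = np.asarray(mix.loglik_trace)
                assert np.all(np.diff(trace) >= -1e-8)

    def test_agrees_with_sklearn_mixture(self):
        """Independent cross-check: our EM and sklearn's converge to the same
        single-component density on the same data."""
        rng = np.random.default_rng(3)
        X = rng.normal([1.0, -2.0], [0.5, 1.5], size=(500, 2))
        y = np.zeros(500, int)
        ours = GMMClassifier(n_components=1, seed=0).fit(X, y).mixtures_[0]
        ref = GaussianMixture(1, covariance_type="full", random_state=0).fit(X)
        np.testing.assert_allclose(ours.means[0], ref.means_[0], atol=1e-6)
        np.testing.assert_allclose(ours.covs[0], ref.covariances_[0], atol=1e-3)

    def test_deterministic(self, separable_features):
        X, y = separable_features
        a = GMMClassifier(n_components=2, seed=5).fit(X, y).predict(X)
        b = GMMClassifier(n_components=2, seed=5).fit(X, y).predict(X)
        np.testing.assert_array_equal(a, b)


class TestSDC:
    def test_stored_vector_wins(self):
        X = np.array([[0.0, 0.0], [5.0, 5.0]])
        y = np.array([0, 1])
        model = SDCModel().fit(X, y)
        assert model.predict(np.array([[0.0, 0.0]]))[0] == 0
        assert model.predict(np.array([[5.0, 5.0]]))[0] == 1

    def test_lambda_to_zero_gives_class_size_prior(self):
        """As lambda -> 0 the score tends to log(class size)."""
        rng = np.random.default_rng(0)
        X = np.vstack([rng.uniform(size=(10, 2)), rng.uniform(size=(30, 2))])
        y = np.r_[np.zeros(10, int), np.ones(30, int)]
        model = SDCModel(lam=1e-9).fit(X, y)
        s = model.scores(np.array([[0.5, 0.5]]))
        assert s[0, 0] == pytest.approx(np.log(10), abs=1e-5)
        assert s[0, 1] == pytest.approx(np.log(30), abs=1e-5)

    def test_scores_match_direct_formula_on_grid(self, separable_features):
        X, y = separable_features
        model = SDCModel(lam=0.5).fit(X, y)
        grid = np.array(
            [[a, b] for a in np.linspace(0, 1, 9) for b in np.linspace(0, 1, 9)]
        )
        s = model.scores(grid)
        for gi, g in enumerate(grid):  # independent direct evaluation
            for ci, label in enumerate(sorted(model.class_vectors_)):
                vals = [
                    -0.5 * float(np.sum((g - k) ** 2))
                    for k in model.class_vectors_[label]
                ]
                assert s[gi, ci] == pytest.approx(logsumexp(vals), abs=1e-10)

    def test_single_class_and_invalid_lambda(self):
        # fit with a single class present stores one class only
        m = SDCModel().fit(np.zeros((3, 2)), np.zeros(3, int))
        assert list(m.class_vectors_) == [0]
        with pytest.raises(ValueError):
            SDCModel(lam=0.0)


XOR_X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
XOR_Y = np.array([0, 0, 1, 1])


class TestSVM:
    def test_separable_linear_zero_training_error(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [3.0, 3.0], [3.0, 4.0]])
        y = np.array([0, 0, 1, 1])
        model = SVMModel("linear", C=100.0, class_weight=1.0).fit(X, y)
        np.testing.assert_array_equal(model.predict(X), y)

    def test_xor_kernel_ordering(self):
        lin = SVMModel("linear", C=100.0, class_weight=1.0).fit(XOR_X, XOR_Y)
        assert (lin.predict(XOR_X) == XOR_Y).mean() <= 0.75
        for kernel in ("poly", "rbf"):
            m = SVMModel(kernel, C=100.0, class_weight=1.0).fit(XOR_X, XOR_Y)
            assert (m.predict(XOR_X) == XOR_Y).mean() == 1.0

    @pytest.mark.parametrize("kernel", ["linear", "poly", "rbf"])
    def test_decision_matches_dual_recomputation(self, kernel, separable_features):
        X, y = separable_features
        model = SVMModel(kernel).fit(X, y)
        svc = model._svc
        grid = np.random.default_rng(0).uniform(0, 1, size=(20, 2))
        K = model.kernel_matrix(svc.support_vectors_, grid)
        recomputed = svc.dual_coef_ @ K + svc.intercept_
        np.testing.assert_allclose(
            model.decision_function(grid), recomputed.ravel(), atol=1e-8
        )

    def test_table_defaults(self):
        assert SVMModel("linear").C == 0.85 and SVMModel("linear").class_weight == 0.4
        m = SVMModel("poly")
        assert (m.C, m.gamma, m.class_weight, m.degree) == (0.8, 10.0, 0.5, 2)
        m = SVMModel("rbf")
        assert (m.C, m.gamma, m.class_weight) == (0.8, 100.0, 0.87)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            SVMModel("linear").fit(np.zeros((4, 2)), np.zeros(4, int))


class TestHarmonySearch:
    def test_sphere_convergence(self):
        sphere = lambda x: float(np.sum(x**2))
        ok = sum(
            harmony_search(sphere, 2, HarmonyConfig(), seed=s, bounds=(-5, 5),
                           max_evals=500)[1] < 1e-3
            for s in range(10)
        )
        assert ok >= 9

    def test_1d_quadratic_with_default_bounds(self):
        """Minimising (x-0.5)^2 over the default [0.1, 1] interval reaches the
        configured stop level (fitness <= 1e-5, i.e. |x-0.5| <= ~3.2e-3)."""
        hits = 0
        for s in range(10):
            best, f, _ = harmony_search(
                lambda v: float((v[0] - 0.5) ** 2), 1, HarmonyConfig(), seed=s
            )
            hits += abs(best[0] - 0.5) <= np.sqrt(HarmonyConfig().mse_stop)
        assert hits >= 9

    def test_trace_non_increasing_and_stop(self):
        _, f, trace = harmony_search(
            lambda v: float(np.sum(v**2)), 3, HarmonyConfig(), seed=0,
            bounds=(-1, 1),
        )
        assert np.all(np.diff(trace) <= 0)
        assert f <= HarmonyConfig().mse_stop or len(trace) >= 1000

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            HarmonyConfig(hmcr=1.5)
        with pytest.raises(ValueError):
            HarmonyConfig(bounds=(1.0, 0.1))


class TestHSClassifier:
    def test_target_coincident_vectors(self):
        clf = HSClassifier(seed=0)
        X = np.vstack([np.full(6, 0.1), np.full(6, 0.85)])
        np.testing.assert_array_equal(clf.predict(X), [0, 1])

    def test_outputs_near_feature_mean(self):
        clf = HSClassifier(seed=1)
        f = np.array([0.2, 0.3, 0.4, 0.5])
        out = clf.predict_outputs(f[None, :])[0]
        assert abs(out - f.mean()) < 0.05


class TestAAO:
    def test_sphere_convergence(self):
        sphere = lambda x: float(np.sum(x**2))
        cfg = AlgaeConfig(n_colonies=40, max_evals=500)
        ok = sum(
            aao_optimize(sphere, 2, (-5, 5), cfg, seed=s)[1] < 1e-3
            for s in range(10)
        )
        assert ok >= 9

    def test_trace_non_increasing(self):
        _, _, trace = aao_optimize(
            lambda x: float(np.sum(x**2)), 3, (-2, 2),
            AlgaeConfig(n_colonies=10, max_evals=200), seed=1,
        )
        assert np.all(np.diff(trace) <= 0)

    def test_friction_monotone_in_size(self):
        sizes = np.linspace(0.01, 1.0, 50)
        tau = _friction(sizes, shear=3.0)
        assert np.all(np.diff(tau) > 0)  # strictly increasing below the cap

    def test_non_finite_objective_rejected(self):
        def nasty(x):
            return float("nan") if x[0] > 0 else float(np.sum(x**2))

        _, f, _ = aao_optimize(
            nasty, 2, (-1, 1), AlgaeConfig(n_colonies=8, max_evals=150), seed=0
        )
        assert np.isfinite(f)

    def test_constant_objective_terminates(self):
        _, f, trace = aao_optimize(
            lambda x: 1.0, 2, (-1, 1), AlgaeConfig(n_colonies=5, max_evals=60),
            seed=0,
        )
        assert f == 1.0 and np.all(np.array(trace) == 1.0)

    def test_classify_targets(self):
        clf = AAOClassifier(seed=0)
        X = np.vstack([np.full(6, 0.1), np.full(6, 0.85)])
        np.testing.assert_array_equal(clf.predict(X), [0, 1])


class TestAAOGMM:
    def test_no_worse_than_plain_gmm(self):
        """Hybrid accuracy on the Bayes-separable toy is within 0.01 of plain
        GMM over seeds (held out)."""
        accs_g, accs_h = [], []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            Xtr = np.r_[rng.normal(0.2, 0.05, (40, 1)), rng.normal(0.8, 0.05, (40, 1))]
            ytr = np.r_[np.zeros(40, int), np.ones(40, int)]
            Xte = np.r_[rng.normal(0.2, 0.05, (20, 1)), rng.normal(0.8, 0.05, (20, 1))]
            yte = np.r_[np.zeros(20, int), np.ones(20, int)]
            g = GMMClassifier(seed=seed).fit(Xtr, ytr)
            h = AAOGMMClassifier(seed=seed).fit(Xtr, ytr)
            accs_g.append((g.predict(Xte) == yte).mean())
            accs_h.append((h.predict(Xte) == yte).mean())
        assert np.mean(accs_h) >= np.mean(accs_g) - 0.01

    def test_search_trace_non_increasing(self, separable_features):
        X, y = separable_features
        model = AAOGMMClassifier(seed=0).fit(X, y)
        trace = np.asarray(model.search_trace_)
        assert np.all(np.diff(trace) <= 0)
        assert model.best_k_ in (1, 2, 3)

    def test_deterministic(self, separable_features):
        X, y = separable_features
        a = AAOGMMClassifier(seed=3).fit(X, y).predict(X)
        b = AAOGMMClassifier(seed=3).fit(X, y).predict(X)
        np.testing.assert_array_equal(a, b)


class TestCommonContract:
    @pytest.mark.parametrize("name", ["gmm", "sdc", "svm-linear", "svm-poly",
                                      "svm-rbf", "hs", "aao"])
    def test_fit_predict_shapes_and_determinism(self, name, separable_features):
        X, y = separable_features
        m1 = make_classifier(name, seed=2).fit(X, y)
        m2 = make_classifier(name, seed=2).fit(X, y)
        p1, p2 = m1.predict(X[:10]), m2.predict(X[:10])
        assert p1.shape == (10,)
        assert set(np.unique(p1)) <= {0, 1}
        np.testing.assert_array_equal(p1, p2)

    @pytest.mark.parametrize("name", ["gmm", "sdc", "svm-linear"])
    def test_label_permutation_flips_predictions(self, name, separable_features):
        X, y = separable_features
        m = make_classifier(name, seed=0).fit(X, y)
        m_flipped = make_classifier(name, seed=0).fit(X, 1 - y)
        np.testing.assert_array_equal(m.predict(X), 1 - m_flipped.predict(X))

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            make_classifier("mystery")
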