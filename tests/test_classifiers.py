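"""The seven classifiers: equation-level identities, oracles and sanity runs."""

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import trapezoid
from sklearn.svm import SVC

from lungspectra import FitError, InvalidConfigError, make_classifier, select_targets
from lungspectra.classifiers import (
    KernelSpec,
    Standardizer,
    cuboid_score,
    gaussian_pdf,
    gmm_class_log_likelihood,
    gmm_fit,
    gmm_posterior,
    gmm_predict,
    nbc_fit,
    nbc_joint_log_likelihood,
    nbc_posterior,
    nbc_predict,
    nlr_fit,
    nlr_predict,
    sdc_fit,
    sdc_predict,
    sdc_proba,
    svm_fit,
    svm_predict,
)
from lungspectra.classifiers.gmm import Mixture


class TestTargets:
    def test_defaults_returned_for_normalized_input(self):
        rng = np.random.default_rng(0)
        tm = select_targets(rng.uniform(0, 0.5, (10, 4)), rng.uniform(0, 0.5, (10, 3)))
        assert tm.t_adeno == 0.85
        assert tm.t_meso == 0.65

    def test_all_zero_features_satisfy_mapping_constraints(self):
        tm = select_targets(np.zeros((5, 3)), np.zeros((5, 2)))
        assert tm.adeno_constraint_ok and tm.meso_constraint_ok

    def test_default_separation_constraint_reports_violation(self):
        # |0.85 - 0.65| = 0.2 < 0.5
        tm = select_targets(np.zeros((5, 3)), np.zeros((5, 2)))
        assert not tm.separation_ok
        assert any("0.5" in w for w in tm.warnings)

    def test_mean_above_target_attaches_warning_but_returns_defaults(self):
        tm = select_targets(np.full((5, 3), 0.99), np.zeros((5, 2)))
        assert not tm.adeno_constraint_ok
        assert tm.t_adeno == 0.85


class TestNLR:
    def test_zero_distance_gives_zero_score(self):
        assert cuboid_score(0.0, k1=0.5) == pytest.approx(0.0)

    def test_cuboid_polynomial_hand_value(self):
        # k1=0.5 -> k2=0.05, k3=0.005; y=2:
        # 0.5*2 + 0.0025*4 + 1.25e-7*8 = 1.010001
        assert cuboid_score(2.0, k1=0.5) == pytest.approx(1.010001, abs=1e-12)

    def test_threshold_identity_and_separable_accuracy(self):
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            Xa = np.clip(rng.normal(0.85, 0.05, (30, 4)), 0, 1)
            Xm = np.clip(rng.normal(0.40, 0.05, (15, 4)), 0, 1)
            X = np.vstack([Xa, Xm])
            y = np.array(["Adeno"] * 30 + ["Meso"] * 15, dtype=object)
            model = nlr_fit(X, y)
            assert model.g == pytest.approx(model.f + model.d0)
            assert model.k1 > model.k2 > model.k3 > 0
            accs.append(np.mean(nlr_predict(model, X) == y))
        assert np.mean(accs) >= 0.9

    def test_single_sample_class_rejected(self):
        X = np.array([[0.8], [0.8], [0.2]])
        y = np.array(["Adeno", "Adeno", "Meso"], dtype=object)
        with pytest.raises(FitError):
            nlr_fit(X, y)


class TestGaussianPDF:
    def test_standard_normal_mode(self):
        assert gaussian_pdf([0.0], [0.0], [[1.0]]) == pytest.approx(
            1.0 / np.sqrt(2 * np.pi)
        )

    def test_integrates_to_one_on_grid(self):
        x = np.linspace(-8, 8, 4001)
        dens = [gaussian_pdf([v], [0.3], [[1.7]]) for v in x]
        assert trapezoid(dens, x) == pytest.approx(1.0, abs=1e-3)

    def test_symmetric_about_mean(self):
        mu = np.array([1.0, -2.0])
        cov = np.array([[2.0, 0.3], [0.3, 1.0]])
        delta = np.array([0.7, 0.4])
        assert gaussian_pdf(mu + delta, mu, cov) == pytest.approx(
            gaussian_pdf(mu - delta, mu, cov)
        )

    def test_non_positive_definite_rejected(self):
        with pytest.raises(FitError):
            gaussian_pdf([0.0, 0.0], [0.0, 0.0], [[1.0, 2.0], [2.0, 1.0]])


class TestGMM:
    def test_single_component_mean_is_sample_mean(self, separable_blobs):
        X, y = separable_blobs
        model = gmm_fit(X, y, n_components=1)
        np.testing.assert_allclose(
            model.mixtures["Adeno"].means[0], X[y == "Adeno"].mean(axis=0)
        )

    def test_responsibilities_sum_to_one(self, separable_blobs):
        X, y = separable_blobs
        model = gmm_fit(X, y, n_components=2, seed=1)
        resp = model.mixtures["Adeno"].responsibilities(X[y == "Adeno"])
        np.testing.assert_allclose(resp.sum(axis=1), 1.0)

    def test_em_recovers_two_blob_means(self):
        """EM on two well-separated blobs recovers the generating means
        within 3 standard errors, across seeds."""
        centers = np.array([[4.0, 0.0], [-4.0, 0.0]])
        n_per = 60
        sd = 0.5
        se = sd / np.sqrt(n_per)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            Xc = np.vstack(
                [rng.normal(c, sd, (n_per, 2)) for c in centers]
            )
            # single-class fit: wrap with a dummy Meso blob far away
            Xm = rng.normal([0.0, 50.0], sd, (10, 2))
            X = np.vstack([Xc, Xm])
            y = np.array(["Adeno"] * (2 * n_per) + ["Meso"] * 10, dtype=object)
            model = gmm_fit(X, y, n_components=2, seed=seed)
            fitted = model.mixtures["Adeno"].means
            order = np.argsort(fitted[:, 0])[::-1]
            for mu_hat, mu in zip(fitted[order], centers):
                assert np.all(np.abs(mu_hat - mu) < 3 * se + 1e-9)

    def test_equidistant_point_has_half_posterior(self):
        rng = np.random.default_rng(2)
        Xa = rng.normal([3.0, 0.0], 0.5, (25, 2))
        Xm = -Xa  # mirror image: balanced, symmetric about the origin
        X = np.vstack([Xa, Xm])
        y = np.array(["Adeno"] * 25 + ["Meso"] * 25, dtype=object)
        model = gmm_fit(X, y, n_components=1)
        post = gmm_posterior(model, np.zeros((1, 2)))
        assert post[0, 0] == pytest.approx(0.5, abs=1e-9)

    def test_blob_centers_classified_to_own_class(self, separable_blobs):
        X, y = separable_blobs
        model = gmm_fit(X, y, n_components=1)
        pred = gmm_predict(model, np.array([[2.0, 2.0], [-2.0, -2.0]]))
        assert list(pred) == ["Adeno", "Meso"]

    def test_log_likelihood_matches_brute_force_density_sum(self, separable_blobs):
        X, y = separable_blobs
        model = gmm_fit(X, y, n_components=2, seed=0)
        mix: Mixture = model.mixtures["Adeno"]
        pts = X[:5]
        oracle = np.log(
            [
                sum(
                    mix.weights[k] * gaussian_pdf(p, mix.means[k], mix.covariances[k])
                    for k in range(2)
                )
                for p in pts
            ]
        )
        np.testing.assert_allclose(mix.score_samples(pts), oracle, rtol=1e-9)

    def test_more_components_than_samples_rejected(self):
        X = np.array([[0.0], [1.0], [5.0]])
        y = np.array(["Adeno", "Adeno", "Meso"], dtype=object)
        with pytest.raises(InvalidConfigError):
            gmm_fit(X, y, n_components=2)


class TestSDC:
    def test_equal_scores_give_uniform_probabilities(self):
        X = np.array([[1.0, -1.0]] * 4)
        y = np.array(["Adeno", "Adeno", "Meso", "Meso"], dtype=object)
        model = sdc_fit(X, y, epochs=0)  # zero-initialized weights
        p = sdc_proba(model, X)
        np.testing.assert_allclose(p, 0.5)
        # argmax tie resolves to the lowest class index (Adeno)
        assert list(sdc_predict(model, X)) == ["Adeno"] * 4

    def test_probabilities_form_a_simplex(self, separable_blobs):
        X, y = separable_blobs
        model = sdc_fit(Standardizer().fit_transform(X), y)
        p = sdc_proba(model, Standardizer().fit_transform(X))
        np.testing.assert_allclose(p.sum(axis=1), 1.0)
        assert np.all(p >= 0)

    def test_one_sample_problem_drives_loss_to_zero(self):
        X = np.array([[1.0, 2.0]])
        y = np.array(["Meso"], dtype=object)
        model = sdc_fit(X, y, learning_rate=1.0, epochs=2000)
        assert model.loss_trace[-1] < 1e-2
        assert sdc_proba(model, X)[0, 1] > 0.99

    def test_loss_trace_non_increasing(self, separable_blobs):
        X, y = separable_blobs
        model = sdc_fit(Standardizer().fit_transform(X), y, learning_rate=0.1)
        trace = np.array(model.loss_trace)
        assert np.all(np.diff(trace) <= 1e-12)

    def test_separable_toy_reaches_full_training_accuracy(self, separable_blobs):
        X, y = separable_blobs
        Xs = Standardizer().fit_transform(X)
        model = sdc_fit(Xs, y, epochs=1000)
        assert np.mean(sdc_predict(model, Xs) == y) == 1.0


class TestNBC:
    def test_balanced_classes_have_equal_priors(self):
        X = np.vstack([np.zeros((5, 2)), np.ones((5, 2))])
        y = np.array(["Adeno"] * 5 + ["Meso"] * 5, dtype=object)
        model = nbc_fit(X, y)
        np.testing.assert_allclose(np.exp(model.log_priors), 0.5)

    def test_posteriors_sum_to_one(self, separable_blobs):
        X, y = separable_blobs
        model = nbc_fit(X, y)
        post = nbc_posterior(model, X)
        np.testing.assert_allclose(post.sum(axis=1), 1.0)

    def test_factorization_matches_log_domain_oracle(self, separable_blobs):
        """The joint likelihood equals the product of per-feature Gaussian
        likelihoods — checked in the log domain against scipy."""
        X, y = separable_blobs
        model = nbc_fit(X, y)
        jll = nbc_joint_log_likelihood(model, X[:7])
        for cls in (0, 1):
            oracle = model.log_priors[cls] + np.sum(
                stats.norm.logpdf(
                    X[:7], model.means[cls], np.sqrt(model.variances[cls])
                ),
                axis=1,
            )
            np.testing.assert_allclose(jll[:, cls], oracle, rtol=1e-9, atol=1e-9)

    def test_symmetric_point_goes_to_majority_prior_class(self):
        rng = np.random.default_rng(3)
        Xa = rng.normal(2.0, 1.0, (20, 2))
        Xm = -Xa[:10]  # fewer Meso: Adeno prior dominates at the midpoint
        X = np.vstack([Xa, Xm])
        y = np.array(["Adeno"] * 20 + ["Meso"] * 10, dtype=object)
        model = nbc_fit(X, y)
        # construct a point with equal class likelihoods by symmetry of means
        assert nbc_predict(model, np.zeros((1, 2)))[0] == "Adeno"

    def test_strong_signal_sample_classified_to_signal_class(self, separable_blobs):
        X, y = separable_blobs
        model = nbc_fit(X, y)
        assert nbc_predict(model, np.array([[-2.0, -2.0]]))[0] == "Meso"

    def test_zero_variance_feature_handled_by_floor(self):
        X = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 5.0], [1.0, 6.0]])
        y = np.array(["Adeno", "Adeno", "Meso", "Meso"], dtype=object)
        model = nbc_fit(X, y)  # first feature constant: floored, no exception
        assert np.all(model.variances > 0)


class TestSVM:
    def test_rbf_kernel_is_one_at_zero_distance(self):
        k = KernelSpec(kind="rbf", sigma=100.0)
        x = np.array([[1.0, 2.0, 3.0]])
        assert k.matrix(x, x)[0, 0] == pytest.approx(1.0)

    def test_degree_one_polynomial_equals_linear_kernel(self):
        rng = np.random.default_rng(4)
        A = rng.normal(size=(6, 3))
        B = rng.normal(size=(5, 3))
        poly = KernelSpec(kind="poly", gamma=1.0, coef0=0.0, degree=1)
        lin = KernelSpec(kind="linear")
        np.testing.assert_allclose(poly.matrix(A, B), lin.matrix(A, B), rtol=1e-12)

    def test_two_point_problem_has_boundary_at_zero_and_margin_two(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array(["Adeno", "Meso"], dtype=object)
        model = svm_fit(X, y, kernel="linear", C=1000.0)
        assert model.decision_function([[0.0]])[0] == pytest.approx(0.0, abs=1e-9)
        w = model.weight_vector()
        assert 2.0 / np.abs(w[0]) == pytest.approx(2.0, rel=1e-6)  # margin
        assert list(svm_predict(model, X)) == ["Adeno", "Meso"]
        assert model.n_support == 2

    def test_support_vector_scores_consistent_between_fit_and_predict(
        self, separable_blobs
    ):
        X, y = separable_blobs
        model = svm_fit(X, y, kernel="rbf", sigma=2.0, C=1.0, seed=0)
        d = model.decision_function(X)
        assert np.array_equal(svm_predict(model, X), np.where(d >= 0, "Adeno", "Meso"))

    def test_duplicating_a_non_support_point_keeps_the_boundary(self, separable_blobs):
        X, y = separable_blobs
        model = svm_fit(X, y, kernel="linear", C=1.0, seed=0)
        d = model.decision_function(X)
        # pick the most interior correctly-classified Adeno point
        interior = int(np.argmax(d))
        X2 = np.vstack([X, X[interior]])
        y2 = np.append(y, y[interior])
        model2 = svm_fit(X2, y2, kernel="linear", C=1.0, seed=0)
        grid = np.array([[a, b] for a in (-2.0, 0.0, 2.0) for b in (-2.0, 0.0, 2.0)])
        np.testing.assert_allclose(
            model.decision_function(grid), model2.decision_function(grid), atol=5e-2
        )

    def test_support_count_bounded_by_training_size(self, separable_blobs):
        X, y = separable_blobs
        model = svm_fit(X, y, kernel="rbf", sigma=2.0, C=1.0)
        assert model.n_support <= X.shape[0]

    def test_non_psd_kernel_names_the_kernel(self, separable_blobs):
        X, y = separable_blobs
        with pytest.raises(FitError, match="poly"):
            svm_fit(X, y, kernel=KernelSpec(kind="poly", gamma=-1.0, degree=1))

    def test_agrees_with_reference_solver_on_blobs(self, separable_blobs):
        """Independent cross-check: predictions match sklearn's SVC."""
        X, y = separable_blobs
        sigma = 2.0
        ours = svm_fit(X, y, kernel="rbf", sigma=sigma, C=1.0)
        ref = SVC(kernel="rbf", gamma=1.0 / (2 * sigma**2), C=1.0)
        ref.fit(X, (y == "Adeno").astype(int))
        ref_pred = np.where(ref.predict(X) == 1, "Adeno", "Meso")
        assert np.mean(svm_predict(ours, X) == ref_pred) >= 0.95


class TestFacade:
    @pytest.mark.parametrize(
        "name", ["nlr", "gmm", "sdc", "nbc", "svm-linear", "svm-poly", "svm-rbf"]
    )
    def test_all_models_fit_and_predict_separable_blobs(self, name, separable_blobs):
        X, y = separable_blobs
        params = {}
        if name == "nlr":
            # NLR expects [0,1]-normalized features
            X = (X - X.min(0)) / (X.max(0) - X.min(0))
        elif name == "svm-rbf":
            # the shipped sigma=100 suits 2049-feature vectors; scale to 2-D
            params = {"sigma": 1.0}
        Xs = Standardizer().fit_transform(X)
        clf = make_classifier(name, **params)
        clf.fit(Xs, y)
        pred = clf.predict(Xs)
        assert np.mean(pred == y) >= 0.9
        post = clf.posterior(Xs)
        if post is not None:
            np.testing.assert_allclose(post.sum(axis=1), 1.0)

    def test_unknown_name_rejected(self):
        with pytest.raises(InvalidConfigError):
            make_classifier("mlp")
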