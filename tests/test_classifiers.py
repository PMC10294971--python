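import numpy as np
import pytest

import ppgcvd as p
from ppgcvd import classifiers as C


class TestTargetCoding:
    def test_defaults_and_midpoint(self):
        coding = C.TargetCoding()
        assert (coding.t_cvd, coding.t_normal) == (0.85, 0.1)
        assert coding.midpoint == pytest.approx(0.475)

    def test_gap_below_half_rejected(self):
        with pytest.raises(ValueError, match="gap"):
            C.TargetCoding(t_cvd=0.9, t_normal=0.5)

    def test_code_targets_examples(self):
        coded = C.code_targets([p.CVD, p.NORMAL])
        np.testing.assert_allclose(coded, [0.85, 0.1])
        all_cvd = C.code_targets([p.CVD] * 5)
        np.testing.assert_allclose(all_cvd, 0.85)

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValueError, match="non-binary"):
            C.code_targets(["CVD", "MAYBE"])


class TestTrainingMse:
    def test_exact_and_offset(self):
        t = C.code_targets([p.CVD, p.NORMAL, p.CVD])
        assert C.training_mse(t, t) == 0.0
        assert C.training_mse(t + 0.1, t) == pytest.approx(0.01)

    def test_matches_hand_summed_oracle(self):
        rng = np.random.default_rng(0)
        s, t = rng.normal(size=5), rng.normal(size=5)
        expected = sum((a - b) ** 2 for a, b in zip(s, t)) / 5
        assert C.training_mse(s, t) == pytest.approx(expected, rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            C.training_mse([], [])


class TestStopRule:
    def test_defaults(self):
        rule = C.StopRule()
        assert rule.mse_tol == 1e-5 and rule.max_iter == 1000

    def test_validation(self):
        with pytest.raises(ValueError):
            C.StopRule(mse_tol=0.0)


class TestDfaExponent:
    def test_white_noise_near_half(self):
        rng = np.random.default_rng(1)
        ws = [8, 16, 32, 64, 128]
        alphas = [C.dfa_exponent(rng.normal(size=2000), ws) for _ in range(30)]
        assert np.mean(alphas) == pytest.approx(0.5, abs=0.1)

    def test_brownian_path_near_three_halves(self):
        rng = np.random.default_rng(2)
        ws = [8, 16, 32, 64, 128]
        alphas = [
            C.dfa_exponent(np.cumsum(rng.normal(size=2000)), ws) for _ in range(30)
        ]
        assert np.mean(alphas) == pytest.approx(1.5, abs=0.15)

    def test_linear_profile_flagged_undefined(self):
        # a constant series has a perfectly linear (zero) profile: F(n) = 0
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(C.dfa_exponent(np.full(200, 3.0)))

    def test_validation(self):
        with pytest.raises(ValueError, match="window"):
            C.dfa_exponent(np.zeros(100), window_sizes=[4, 8])
        with pytest.raises(ValueError, match="twice"):
            C.dfa_exponent(np.zeros(30), window_sizes=[4, 8, 16])


class TestFitPredictContract:
    def test_unknown_kind_rejected(self, blobs100):
        Xtr, ytr, Xte, yte = blobs100
        with pytest.raises(ValueError, match="unknown"):
            C.fit_predict("SVM", Xtr, ytr, Xte)

    def test_single_class_training_rejected(self, blobs100):
        Xtr, ytr, Xte, _ = blobs100
        sel = ytr == p.CVD
        with pytest.raises(ValueError, match="both classes"):
            C.fit_predict("SDC", Xtr[sel], ytr[sel], Xte)

    def test_dimension_mismatch_rejected(self, blobs100):
        Xtr, ytr, Xte, _ = blobs100
        with pytest.raises(ValueError, match="dimensions"):
            C.fit_predict("SDC", Xtr, ytr, Xte[:, :10])

    def test_empty_test_rejected(self, blobs100):
        Xtr, ytr, _, _ = blobs100
        with pytest.raises(ValueError, match="empty"):
            C.fit_predict("SDC", Xtr, ytr, np.empty((0, Xtr.shape[1])))

    @pytest.mark.parametrize("kind", C.KINDS)
    def test_labels_are_thresholded_scores(self, kind, blobs100):
        Xtr, ytr, Xte, _ = blobs100
        res = C.fit_predict(kind, Xtr[:200], ytr[:200], Xte[:100], seed=3)
        expected = np.where(res.scores >= res.threshold, p.CVD, p.NORMAL)
        np.testing.assert_array_equal(res.labels, expected)
        assert np.all(np.isfinite(res.mse_trace))

    @pytest.mark.parametrize("kind", ["FIREFLY", "HARMONY", "EM", "KNN_PAC", "GMM"])
    def test_deterministic_given_seed(self, kind, blobs100):
        Xtr, ytr, Xte, _ = blobs100
        a = C.fit_predict(kind, Xtr[:200], ytr[:200], Xte[:80], seed=11)
        b = C.fit_predict(kind, Xtr[:200], ytr[:200], Xte[:80], seed=11)
        np.testing.assert_array_equal(a.scores, b.scores)
        np.testing.assert_array_equal(a.labels, b.labels)


class TestKindSpecificBehavior:
    def test_sdc_zero_distance_sample_wins(self):
        Xtr = np.array([[0.0, 0.0], [3.0, 3.0]])
        ytr = np.array([p.CVD, p.NORMAL])
        res = C.fit_predict("SDC", Xtr, ytr, Xtr[:1])
        # test point equals the CVD training sample: class score log exp(0)=0
        assert res.labels[0] == p.CVD
        assert res.scores[0] > res.threshold

    def test_firefly_attractiveness_at_zero_distance(self):
        # alpha_s(r) = alpha_s0 * exp(-beta r^2) equals alpha_s0 at r = 0
        alpha_s0, beta = 0.65, 0.1
        assert alpha_s0 * np.exp(-beta * 0.0**2) == pytest.approx(0.65)

    def test_bldc_boundary_is_perpendicular_bisector(self):
        # symmetric Gaussians, equal priors: the discriminant difference is
        # antisymmetric about the midpoint of the class means, which is
        # therefore on the decision boundary
        rng = np.random.default_rng(4)
        mu = np.array([2.0, 0.0, 0.0])
        Xtr = np.vstack([rng.normal(size=(300, 3)) + mu, rng.normal(size=(300, 3)) - mu])
        ytr = np.array([p.CVD] * 300 + [p.NORMAL] * 300)
        center = 0.5 * (Xtr[:300].mean(0) + Xtr[300:].mean(0))
        v = rng.normal(size=(10, 3))
        pts = np.vstack([center + v, center - v, center[None, :]])
        res = C.fit_predict("BLDC", Xtr, ytr, pts)
        # mirror-image points have complementary scores; the center scores 0.5
        np.testing.assert_allclose(res.scores[:10] + res.scores[10:20], 1.0, atol=1e-9)
        assert res.scores[20] == pytest.approx(0.5, abs=1e-9)
        # points displaced toward the CVD mean are labeled CVD
        toward = C.fit_predict("BLDC", Xtr, ytr, center + np.array([[1.5, 0, 0]]))
        assert toward.labels[0] == p.CVD

    def test_em_objective_monotone(self, blobs100):
        Xtr, ytr, Xte, _ = blobs100
        res = C.fit_predict("EM", Xtr, ytr, Xte, seed=0)
        trace = res.objective_trace
        assert len(trace) >= 2
        assert np.all(np.diff(trace) >= -1e-7 * (1 + np.abs(trace[:-1])))

    def test_gmm_objective_monotone(self, blobs100):
        Xtr, ytr, Xte, _ = blobs100
        res = C.fit_predict("GMM", Xtr, ytr, Xte, seed=0)
        for trace in (res.extras["trace_cvd"], res.extras["trace_normal"]):
            assert np.all(np.diff(trace) >= -1e-7 * (1 + np.abs(trace[:-1])))

    @pytest.mark.parametrize("kind", ["FIREFLY", "HARMONY"])
    def test_metaheuristic_best_mse_non_increasing(self, kind):
        # moderate separation so the search actually has to iterate
        X, y = p.generate_feature_blobs(150, 20, 1.5, seed=6)
        res = C.fit_predict(
            kind, X[:200], y[:200], X[200:], seed=2,
            stop=C.StopRule(max_iter=60),
        )
        trace = res.mse_trace
        assert len(trace) > 1
        assert np.all(np.diff(trace) <= 1e-12)

    def test_pca_threshold_is_stated_default(self, blobs100):
        Xtr, ytr, Xte, _ = blobs100
        res = C.fit_predict("PCA", Xtr, ytr, Xte)
        assert res.threshold == 0.72
        assert np.all((res.scores >= 0) & (res.scores <= 1))

    def test_logreg_threshold_is_stated_default(self, blobs100):
        Xtr, ytr, Xte, _ = blobs100
        res = C.fit_predict("LOGREG", Xtr, ytr, Xte)
        assert res.threshold == 0.5

    def test_knn_pac_selects_k_from_grid(self, blobs100):
        Xtr, ytr, Xte, _ = blobs100
        res = C.fit_predict("KNN_PAC", Xtr[:200], ytr[:200], Xte[:50], seed=0)
        assert res.extras["k"] in (3, 5, 7)

    def test_dfa_classifier_reports_class_exponents(self, blobs100):
        Xtr, ytr, Xte, _ = blobs100
        res = C.fit_predict("DFA", Xtr, ytr, Xte, seed=0)
        exps = res.extras["class_mean_exponents"]
        assert set(exps) == {p.CVD, p.NORMAL}
        assert all(np.isfinite(v) for v in exps.values())
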