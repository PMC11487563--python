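"""Prewhitened GLM, ReML noise estimation, ROI summaries, group age model."""

import numpy as np
import pytest
from scipy import stats

from boldhrf import glm


class TestDCTHighpass:
    def test_first_column_constant(self):
        D = glm.dct_highpass_set(100, 2.0)
        assert np.allclose(D[:, 0], D[0, 0])

    def test_cosine_count_convention(self):
        # floor(2 * 261 * 1.97 / 128) = 8 non-constant cosines
        D = glm.dct_highpass_set(261, 1.97)
        assert D.shape[1] == 9
        # every retained cosine has period >= 128 s: the k-th cosine
        # completes k half-cycles over the run, period = 2*T/k
        T = 261 * 1.97
        for k in range(1, D.shape[1]):
            assert 2 * T / k >= 128.0

    def test_columns_orthonormal(self):
        D = glm.dct_highpass_set(173, 1.97)
        assert np.max(np.abs(D.T @ D - np.eye(D.shape[1]))) < 1e-10


class TestReML:
    def test_white_noise_gives_null_ar_weight(self, rng):
        n = 300
        Y = rng.standard_normal((n, 40))
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        nm = glm.reml_ar1(Y, X)
        assert abs(nm.weights[1]) < 0.1
        assert nm.weights[0] == pytest.approx(1.0, abs=0.1)

    def test_ar1_residuals_are_whitened(self, rng):
        n, rho = 400, 0.5
        Y = np.empty((n, 30))
        for v in range(30):
            x = np.empty(n)
            x[0] = rng.standard_normal()
            for i in range(1, n):
                x[i] = rho * x[i - 1] + np.sqrt(1 - rho**2) * rng.standard_normal()
            Y[:, v] = x
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 3))])
        nm = glm.reml_ar1(Y, X)
        W = nm.whitener
        WY = W @ Y
        lag1 = np.mean([np.corrcoef(WY[:-1, v], WY[1:, v])[0, 1]
                        for v in range(30)])
        assert abs(lag1) < 0.1

    def test_whitening_efficacy_across_replicates(self, rng):
        """Mean |lag-1 autocorrelation| of whitened residuals stays under
        0.05 across independent AR(1) datasets."""
        n = 200
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        vals = []
        for _ in range(40):
            rho = rng.uniform(0.1, 0.5)
            E = np.empty((n, 5))
            for v in range(5):
                x = np.empty(n)
                x[0] = rng.standard_normal()
                for i in range(1, n):
                    x[i] = rho * x[i - 1] + np.sqrt(1 - rho**2) * rng.standard_normal()
                E[:, v] = x
            nm = glm.reml_ar1(E, X)
            WE = nm.whitener @ E
            r = np.mean([np.corrcoef(WE[:-1, v], WE[1:, v])[0, 1] for v in range(5)])
            vals.append(abs(r))
        assert np.mean(vals) < 0.05

    def test_identity_component_only_recovers_scaled_identity(self, rng):
        n = 150
        Y = 3.0 * rng.standard_normal((n, 50))
        X = np.ones((n, 1))
        nm = glm.reml_ar1(Y, X)
        # whitener of (approximately) sigma^2*I is a scaled identity
        off = nm.covariance - np.diag(np.diag(nm.covariance))
        assert np.max(np.abs(off)) < 0.1 * np.max(np.diag(nm.covariance))


class TestFitGLM:
    def test_matches_normal_equation_oracle(self, rng):
        n, p = 60, 5
        X = rng.standard_normal((n, p))
        Y = rng.standard_normal((n, 3)) + 50.0
        fit = glm.fit_glm(Y, X, grand_mean=None)
        beta_ref = np.linalg.solve(X.T @ X, X.T @ Y)
        assert np.max(np.abs(fit.coefficients - beta_ref)) < 1e-10

    def test_noise_free_recovery(self, rng):
        n, p = 80, 4
        X = rng.standard_normal((n, p))
        beta = rng.standard_normal(p)
        y = X @ beta
        fit = glm.fit_glm(y, X, grand_mean=None)
        assert np.max(np.abs(fit.coefficients - beta)) < 1e-10
        assert fit.residual_variance == pytest.approx(0.0, abs=1e-18)

    def test_f_statistic_matches_hand_computed_ess(self, rng):
        n = 40
        X = rng.standard_normal((n, 2))
        conf = np.ones((n, 1))
        y = X @ np.array([1.0, -0.5]) + conf[:, 0] * 2 + rng.standard_normal(n)
        fit = glm.fit_glm(y, X, confounds=conf, grand_mean=None)
        Xf = np.column_stack([X, conf])
        bf = np.linalg.lstsq(Xf, y, rcond=None)[0]
        rss = np.sum((y - Xf @ bf) ** 2)
        b0 = np.linalg.lstsq(conf, y, rcond=None)[0]
        rss0 = np.sum((y - conf @ b0) ** 2)
        dof = n - 3
        f_ref = ((rss0 - rss) / 2) / (rss / dof)
        assert fit.f_stat == pytest.approx(f_ref, rel=1e-10)
        assert fit.f_dof == (2.0, float(dof))

    def test_grand_mean_scaling(self, rng):
        n = 50
        X = rng.standard_normal((n, 2))
        Y = 500.0 + rng.standard_normal((n, 4))
        fit = glm.fit_glm(Y, X, dct=glm.dct_highpass_set(n, 2.0), grand_mean=100.0)
        # the constant column's coefficient reflects the rescaled baseline
        assert fit.fitted.shape == (n, 4)

    def test_rank_deficiency_rejected(self, rng):
        n = 30
        x = rng.standard_normal(n)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError, match="rank deficient"):
            glm.fit_glm(rng.standard_normal(n), X, grand_mean=None)


class TestVoxelSelection:
    def test_null_voxels_selected_at_alpha_rate(self, rng):
        n, nv = 100, 10000
        X = rng.standard_normal((n, 3))
        Y = rng.standard_normal((n, nv))
        fit = glm.fit_glm(Y, X, confounds=np.ones((n, 1)), grand_mean=None)
        sel = glm.participant_voxel_selection(fit, alpha=0.05)
        rate = len(sel) / nv
        ci = 3 * np.sqrt(0.05 * 0.95 / nv)
        assert abs(rate - 0.05) < ci

    def test_strong_signal_voxel_selected(self, rng):
        n = 100
        X = rng.standard_normal((n, 2))
        y = X @ np.array([10.0, -10.0]) + rng.standard_normal(n)
        fit = glm.fit_glm(y[:, None], X, confounds=np.ones((n, 1)),
                          grand_mean=None)
        assert 0 in glm.participant_voxel_selection(fit)

    def test_empty_selection_flags_exclusion(self, rng):
        n = 60
        X = rng.standard_normal((n, 2))
        Y = rng.standard_normal((n, 3))
        fit = glm.fit_glm(Y, X, confounds=np.ones((n, 1)), grand_mean=None)
        sel = glm.participant_voxel_selection(fit, alpha=1e-9)
        assert sel.size == 0  # caller excludes the participant


class TestEigenvariate:
    def test_identical_voxels_recover_common_timecourse(self, rng):
        y = rng.standard_normal(80)
        Y = np.column_stack([y] * 6)
        s = glm.roi_eigenvariate(Y)
        assert abs(np.corrcoef(s.eigenvariate, y)[0, 1]) > 1 - 1e-12
        assert s.variance_explained == pytest.approx(1.0)

    def test_rank1_plus_noise_dominates(self, rng):
        y = rng.standard_normal(120)
        Y = np.outer(y, rng.uniform(0.5, 1.5, 8))
        Y += 0.01 * rng.standard_normal(Y.shape)
        s = glm.roi_eigenvariate(Y)
        assert s.variance_explained > 0.99

    def test_sign_convention_mean_weight_positive(self, rng):
        y = rng.standard_normal(80)
        Y = np.column_stack([y] * 5)
        s_pos = glm.roi_eigenvariate(Y)
        s_neg = glm.roi_eigenvariate(-Y)
        assert s_pos.voxel_weights.mean() > 0
        assert s_neg.voxel_weights.mean() > 0
        assert np.allclose(s_pos.eigenvariate, -s_neg.eigenvariate)

    def test_empty_selection_rejected(self, rng):
        with pytest.raises(ValueError, match="no selected voxels"):
            glm.roi_eigenvariate(rng.standard_normal((10, 3)), np.array([], dtype=int))


class TestSecondLevelAgeGLM:
    def test_identical_participants_have_null_age_effects(self):
        fir = np.tile(np.sin(np.arange(32) / 3), (12, 1))
        ages = np.linspace(20, 80, 12)
        res = glm.second_level_age_glm(fir, ages)
        assert np.max(np.abs(res.bin_effects[:, 1:])) < 1e-10

    def test_injected_linear_trend_recovered_in_target_bin(self, rng):
        n = 60
        ages = rng.uniform(18, 88, n)
        z = (ages - ages.mean()) / ages.std()
        fir = rng.standard_normal((n, 16)) * 0.1
        fir[:, 5] += 1.5 * z
        res = glm.second_level_age_glm(fir, ages)
        assert res.bin_effects[5, 1] == pytest.approx(1.5, abs=0.15)
        assert res.f_pvalues["linear"] < 1e-6
        other = np.delete(res.bin_effects[:, 1], 5)
        assert np.max(np.abs(other)) < 0.15

    def test_quadratic_f_calibrated_under_null(self, rng):
        """Without quadratic structure, the quadratic F-test rejects at
        roughly its nominal rate."""
        hits = 0
        reps = 120
        for _ in range(reps):
            n = 24
            ages = rng.uniform(18, 88, n)
            fir = rng.standard_normal((n, 6))
            res = glm.second_level_age_glm(fir, ages)
            hits += res.f_pvalues["quadratic"] < 0.05
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(hits / reps - 0.05) < 4 * se

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError):
            glm.second_level_age_glm(np.zeros((3, 8)), np.array([20, 30, 40]))
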