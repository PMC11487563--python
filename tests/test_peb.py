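"""Group-level empirical Bayes and Bayesian model reduction."""

import numpy as np
import pytest

from boldhrf import peb
from boldhrf.vl import Posterior

MASK = ("beta", "kappa", "transit_rate")


def make_posterior(mean, var=0.02, prior_var=(1.0, 1 / 16, 1 / 16)):
    mean = np.asarray(mean, dtype=float)
    p = len(mean)
    return Posterior(
        mask=MASK[:p], mean=mean, covariance=np.eye(p) * var,
        free_energy=0.0, noise_log_precision=(0.0, 1.0),
        fitted=np.zeros(2), converged=True, free_energy_trace=np.zeros(1),
        prior_means=np.zeros(p), prior_variances=np.asarray(prior_var[:p]),
    )


def simulate_posteriors(rng, n=120, B=None, within_var=0.02, between_sd=0.1):
    """Participant posteriors from a known group model mu_i = B x_i + noise."""
    if B is None:
        B = np.array([[0.6, 0.0], [0.0, 0.25], [-0.1, -0.25]])
    ages = rng.uniform(18, 88, n)
    z = (ages - ages.mean()) / ages.std(ddof=0)
    posts = []
    for i in range(n):
        mu = B @ np.array([1.0, z[i]])
        mu = mu + rng.normal(0, between_sd, 3)
        mu_obs = mu + rng.multivariate_normal(np.zeros(3), np.eye(3) * within_var)
        posts.append(make_posterior(mu_obs, var=within_var))
    return posts, ages, B


def refit_oracle(posteriors, design, between, prior_mean, prior_cov):
    """Explicit evidence/posterior computation for arbitrary priors —
    the from-scratch counterpart of analytic reduction."""
    H, h, const = peb._group_suffstats(posteriors, design, between)
    return peb._posterior_and_evidence(H, h, const, prior_mean, prior_cov)


class TestGroupDesign:
    def test_mean_and_age_zscored(self):
        d = peb.GroupDesign.mean_and_age(np.array([20.0, 40.0, 60.0, 80.0]))
        assert np.allclose(d.matrix[:, 0], 1.0)
        assert d.matrix[:, 1].mean() == pytest.approx(0.0, abs=1e-12)
        assert d.matrix[:, 1].std(ddof=0) == pytest.approx(1.0)

    def test_rank_deficient_rejected(self):
        with pytest.raises(ValueError, match="rank deficient"):
            peb.GroupDesign(matrix=np.ones((5, 2)), names=("a", "b"))


class TestPEBFit:
    def test_identical_posteriors_mean_only(self):
        """With identical participants, an (effectively) flat effect prior
        and evidence-optimised between-subject variance, the group mean is
        the shared posterior mean (closed-form linear-Gaussian check)."""
        shared = np.array([0.5, 0.2, -0.3])
        posts = [make_posterior(shared) for _ in range(10)]
        design = peb.GroupDesign(matrix=np.ones((10, 1)), names=("mean",))
        res = peb.peb_fit(posts, design, effect_prior_variance=100.0)
        assert np.allclose(res.mean, shared, atol=1e-3)

    def test_age_effect_recovered_within_ci(self, rng):
        posts, ages, B = simulate_posteriors(rng)
        res = peb.peb_fit(posts, peb.GroupDesign.mean_and_age(ages))
        sd = np.sqrt(np.diag(res.covariance))
        for pi, pname in enumerate(MASK):
            idx = res.effect_index(pname, "age")
            assert abs(res.mean[idx] - B[pi, 1]) < 3 * sd[idx] + 0.02

    def test_zero_between_variance_is_precision_weighted_average(self, rng):
        """With no between-subject variance and a flat effect prior, the
        group mean is the precision-weighted average of participant means
        (closed-form oracle)."""
        means = [rng.normal(0.5, 0.1, 3) for _ in range(8)]
        variances = rng.uniform(0.01, 0.05, 8)
        posts = [make_posterior(m, var=v) for m, v in zip(means, variances)]
        design = peb.GroupDesign(matrix=np.ones((8, 1)), names=("mean",))
        tiny = np.full(3, 1e-10)
        H, h, const = peb._group_suffstats(posts, design, tiny)
        m, C, F = peb._posterior_and_evidence(H, h, const, np.zeros(3),
                                              np.eye(3) * 1e6)
        w = 1.0 / variances
        expect = (np.stack(means) * w[:, None]).sum(axis=0) / w.sum()
        assert np.allclose(m, expect, atol=1e-4)

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            peb.peb_fit([make_posterior([0, 0, 0])],
                        peb.GroupDesign(matrix=np.ones((1, 1)), names=("mean",)))


class TestBMREvidence:
    def test_identity_reduction_is_exact_zero(self, rng):
        posts, ages, _ = simulate_posteriors(rng, n=40)
        res = peb.peb_fit(posts, peb.GroupDesign.mean_and_age(ages),
                          optimize_between=False)
        dF, mr, Cr = peb.bmr_evidence(res, res.prior_mean, res.prior_covariance)
        assert dF == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(mr, res.mean, atol=1e-9)
        assert np.allclose(Cr, res.covariance, atol=1e-9)

    def test_matches_explicit_refit_on_random_instances(self, rng):
        """Analytic reduction equals refitting with the reduced priors, on
        50 random linear-Gaussian instances."""
        for _ in range(50):
            n = rng.integers(10, 30)
            posts, ages, _ = simulate_posteriors(rng, n=int(n))
            design = peb.GroupDesign.mean_and_age(ages)
            res = peb.peb_fit(posts, design, optimize_between=False)
            scale = rng.uniform(1e-6, 1.0, 6)
            red_cov = np.diag(scale * np.diag(res.prior_covariance))
            red_mean = np.zeros(6)
            dF, mr, Cr = peb.bmr_evidence(res, red_mean, red_cov)
            _, _, F_full = refit_oracle(posts, design, res.between_variance,
                                        res.prior_mean, res.prior_covariance)
            m2, C2, F_red = refit_oracle(posts, design, res.between_variance,
                                         red_mean, red_cov)
            assert abs(dF - (F_red - F_full)) < 1e-3
            assert np.allclose(mr, m2, atol=1e-6)

    def test_pruning_uninformed_effect_is_free(self, rng):
        """Removing a parameter whose posterior still equals its prior
        changes the evidence by (almost) nothing."""
        posts = [make_posterior([0.5, 0.0, 0.0], var=0.02) for _ in range(20)]
        # make the age covariate carry no information: identical participants
        design = peb.GroupDesign(
            matrix=np.column_stack([np.ones(20), np.linspace(-1, 1, 20)]),
            names=("mean", "age"))
        res = peb.peb_fit(posts, design, optimize_between=False)
        idx = res.effect_index("kappa", "age")
        cov = res.prior_covariance.copy()
        cov[idx, idx] = peb.PRUNED_VARIANCE
        dF, _, _ = peb.bmr_evidence(res, res.prior_mean, cov)
        assert abs(dF) < 0.1 or dF > 0  # never penalised for pruning noise


class TestBMRSearch:
    def test_figure_pattern_pruned_and_retained(self, rng):
        """No true age->efficacy effect, positive age->decay, negative
        age->transit: the efficacy age effect is pruned and the other two
        retained with the correct signs."""
        posts, ages, _ = simulate_posteriors(rng, n=150)
        res = peb.peb_fit(posts, peb.GroupDesign.mean_and_age(ages))
        search = peb.bmr_search(res)
        assert "beta:age" in search.pruned
        assert search.retained["kappa:age"]["expectation"] > 0
        assert search.retained["kappa:age"]["ci_low"] > 0
        assert search.retained["transit_rate:age"]["expectation"] < 0
        assert search.retained["transit_rate:age"]["ci_high"] < 0

    def test_all_strong_effects_retained(self, rng):
        B = np.array([[0.6, 0.3], [0.2, 0.25], [-0.1, -0.25]])
        posts, ages, _ = simulate_posteriors(rng, n=150, B=B)
        res = peb.peb_fit(posts, peb.GroupDesign.mean_and_age(ages))
        search = peb.bmr_search(res)
        assert search.pruned == ()

    def test_all_null_age_effects_pruned(self, rng):
        B = np.array([[0.6, 0.0], [0.0, 0.0], [-0.1, 0.0]])
        posts, ages, _ = simulate_posteriors(rng, n=150, B=B)
        res = peb.peb_fit(posts, peb.GroupDesign.mean_and_age(ages))
        search = peb.bmr_search(res)
        assert set(search.pruned) == {"beta:age", "kappa:age",
                                      "transit_rate:age"}

    def test_pruning_invariant_to_parameter_order(self, rng):
        posts, ages, _ = simulate_posteriors(rng, n=100)
        res = peb.peb_fit(posts, peb.GroupDesign.mean_and_age(ages),
                          optimize_between=False)
        search = peb.bmr_search(res)
        # same data with the parameter axes permuted
        perm = [2, 0, 1]
        posts_p = []
        for post in posts:
            posts_p.append(Posterior(
                mask=tuple(MASK[j] for j in perm),
                mean=post.mean[perm],
                covariance=post.covariance[np.ix_(perm, perm)],
                free_energy=0.0, noise_log_precision=(0.0, 1.0),
                fitted=np.zeros(2), converged=True,
                free_energy_trace=np.zeros(1),
                prior_means=post.prior_means[perm],
                prior_variances=post.prior_variances[perm],
            ))
        res_p = peb.peb_fit(posts_p, peb.GroupDesign.mean_and_age(ages),
                            optimize_between=False)
        search_p = peb.bmr_search(res_p)
        assert set(search.pruned) == set(search_p.pruned)

    def test_collinear_effects_not_both_retained(self, rng):
        """When first-level estimation identifies only the sum of efficacy
        and decay (their difference is a soft likelihood direction), a true
        decay-only age effect leaks into the efficacy posterior means —
        producing a strong spurious marginal correlation — yet reduction,
        which sees the posterior covariance, retains at most one of the
        collinear pair."""
        from scipy.stats import spearmanr

        n = 150
        ages = rng.uniform(18, 88, n)
        z = (ages - ages.mean()) / ages.std(ddof=0)
        R = np.array([[1, 1, 0], [1, -1, 0], [0, 0, np.sqrt(2)]]) / np.sqrt(2)
        # sum direction tightly measured, difference essentially free
        lam = R @ np.diag([1 / 0.004, 1 / 400.0, 1 / 0.01]) @ R.T
        pi0 = np.diag([1.0, 16.0, 16.0])
        sig = np.linalg.inv(lam + pi0)
        posts = []
        for i in range(n):
            mu_true = np.array([
                0.0,
                0.25 * z[i] + rng.normal(0, 0.05),
                -0.1 + rng.normal(0, 0.05),
            ])
            ml = mu_true + rng.multivariate_normal(np.zeros(3),
                                                   np.linalg.inv(lam))
            posts.append(Posterior(
                mask=MASK, mean=sig @ (lam @ ml), covariance=sig,
                free_energy=0.0, noise_log_precision=(0.0, 1.0),
                fitted=np.zeros(2), converged=True,
                free_energy_trace=np.zeros(1), prior_means=np.zeros(3),
                prior_variances=np.array([1.0, 1 / 16, 1 / 16]),
            ))
        means = np.array([p.mean for p in posts])
        # the marginal analysis is fooled ...
        assert spearmanr(means[:, 0], ages).pvalue < 1e-6
        # ... but joint reduction keeps at most one of the pair
        res = peb.peb_fit(posts, peb.GroupDesign.mean_and_age(ages))
        search = peb.bmr_search(res)
        retained_of_pair = {"beta:age", "kappa:age"} - set(search.pruned)
        assert len(retained_of_pair) <= 1
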