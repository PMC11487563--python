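"""Parametric Empirical Bayes over participant posteriors, with Bayesian
Model Reduction of group effects.

Each participant's Variational Laplace fit supplies a Gaussian posterior
(mu_i, Sigma_i) over the free hemodynamic parameters.  The group model is a
Bayesian hierarchical linear regression,

    mu_i ~ N(X_i @ B, Sigma_i + Sigma_between)

where the design row ``X_i`` holds the group covariates (a constant and
z-scored age by default), ``B`` is the matrix of group effects (parameters
by covariates) with a Gaussian prior, and ``Sigma_between`` is a diagonal
between-participant covariance whose per-parameter log-scalings are
optimised by evidence ascent.  Because the model is linear-Gaussian, the
group posterior and the log evidence (free energy) are available in closed
form, and Bayesian Model Reduction evaluates the evidence for any reduced
prior (e.g. an effect switched off) analytically, without refitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import optimize

from .vl import Posterior

__all__ = [
    "GroupDesign",
    "PEBResult",
    "BMRSearchResult",
    "peb_fit",
    "bmr_evidence",
    "bmr_search",
]

#: Prior variance assigned to a pruned (switched-off) effect during BMR.
PRUNED_VARIANCE = 1e-8


@dataclass(frozen=True)
class GroupDesign:
    """Per-participant covariate rows; column 0 is conventionally the mean."""

    matrix: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self):
        M = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        object.__setattr__(self, "matrix", M)
        if M.shape[1] != len(self.names):
            raise ValueError("design columns and names differ in number")
        if np.linalg.matrix_rank(M) < M.shape[1]:
            raise ValueError("group design is rank deficient")

    @classmethod
    def mean_and_age(cls, ages: np.ndarray) -> "GroupDesign":
        ages = np.asarray(ages, dtype=float)
        z = (ages - ages.mean()) / ages.std(ddof=0)
        return cls(matrix=np.column_stack([np.ones_like(z), z]),
                   names=("mean", "age"))


@dataclass(frozen=True)
class PEBResult:
    """Posterior over group effects B (flattened parameter-major:
    effect (p, c) at index p * n_covariates + c)."""

    param_names: tuple[str, ...]
    covariate_names: tuple[str, ...]
    mean: np.ndarray
    covariance: np.ndarray
    prior_mean: np.ndarray
    prior_covariance: np.ndarray
    between_variance: np.ndarray  # per hemodynamic parameter
    free_energy: float
    # cached sufficient statistics for analytic reduction
    _data_precision: np.ndarray = None  # type: ignore[assignment]
    _data_precision_mean: np.ndarray = None  # type: ignore[assignment]
    _loglike_const: float = 0.0

    def __post_init__(self):
        C = np.asarray(self.covariance)
        if np.any(np.linalg.eigvalsh(0.5 * (C + C.T)) < -1e-8):
            raise ValueError("group posterior covariance is not PSD")

    def effect_index(self, param: str, covariate: str) -> int:
        return (self.param_names.index(param) * len(self.covariate_names)
                + self.covariate_names.index(covariate))


def _group_suffstats(posteriors, design, between_var):
    """Gaussian likelihood of the group effects: precision, precision*mean
    and constant, marginalising each participant's first-level posterior."""
    X = design.matrix
    n, c = X.shape
    p = len(posteriors[0].mask)
    d = p * c
    H = np.zeros((d, d))
    h = np.zeros(d)
    const = 0.0
    Sb = np.diag(between_var)
    for i, post in enumerate(posteriors):
        A = np.kron(np.eye(p), X[i:i + 1])  # maps vec(B) -> expected mu_i
        V = post.covariance + Sb
        # guard: fixed (zero-variance) parameters still need an invertible V
        V = V + 1e-12 * np.eye(p)
        iV = np.linalg.inv(V)
        H += A.T @ iV @ A
        h += A.T @ iV @ post.mean
        sign, logdet = np.linalg.slogdet(V)
        const += -0.5 * (post.mean @ iV @ post.mean + logdet
                         + p * np.log(2 * np.pi))
    return H, h, const


def _posterior_and_evidence(H, h, const, prior_mean, prior_cov):
    """Closed-form posterior over effects and log evidence for a
    linear-Gaussian model with likelihood N(h|H) and Gaussian prior."""
    iC0 = np.linalg.inv(prior_cov)
    P = H + iC0
    C = np.linalg.inv(P)
    m = C @ (h + iC0 @ prior_mean)
    sign, logdet_C = np.linalg.slogdet(C)
    sign0, logdet_C0 = np.linalg.slogdet(prior_cov)
    # evidence: complete the square in the effect vector
    quad = m @ P @ m - prior_mean @ iC0 @ prior_mean
    F = const + 0.5 * (logdet_C - logdet_C0) + 0.5 * quad
    return m, 0.5 * (C + C.T), float(F)


def peb_fit(
    posteriors: list[Posterior],
    design: GroupDesign,
    effect_prior_variance: float = 1.0,
    optimize_between: bool = True,
) -> PEBResult:
    """Fit the group-level Bayesian regression.

    Between-participant variances start at 1/16 of each parameter's
    first-level prior variance and are optimised on the log scale by
    Nelder-Mead ascent of the closed-form evidence (skipped when
    ``optimize_between`` is false).
    """
    if len(posteriors) < 2:
        raise ValueError("PEB needs at least 2 participants")
    if design.matrix.shape[0] != len(posteriors):
        raise ValueError("design rows must match the number of participants")
    mask = posteriors[0].mask
    if any(post.mask != mask for post in posteriors):
        raise ValueError("all posteriors must share the free-parameter mask")
    p = len(mask)
    c = design.matrix.shape[1]
    d = p * c
    prior_mean = np.zeros(d)
    prior_cov = np.eye(d) * effect_prior_variance

    base_var = posteriors[0].prior_variances / 16.0
    base_var = np.where(base_var > 0, base_var, 1e-6)

    def neg_evidence(log_scale):
        bv = base_var * np.exp(log_scale)
        H, h, const = _group_suffstats(posteriors, design, bv)
        _, _, F = _posterior_and_evidence(H, h, const, prior_mean, prior_cov)
        return -F

    log_scale = np.zeros(p)
    if optimize_between:
        res = optimize.minimize(neg_evidence, log_scale, method="Nelder-Mead",
                                options={"xatol": 1e-3, "fatol": 1e-4,
                                         "maxiter": 200 * p})
        log_scale = res.x
    between = base_var * np.exp(log_scale)
    H, h, const = _group_suffstats(posteriors, design, between)
    m, C, F = _posterior_and_evidence(H, h, const, prior_mean, prior_cov)
    return PEBResult(
        param_names=mask,
        covariate_names=design.names,
        mean=m,
        covariance=C,
        prior_mean=prior_mean,
        prior_covariance=prior_cov,
        between_variance=between,
        free_energy=F,
        _data_precision=H,
        _data_precision_mean=h,
        _loglike_const=const,
    )


def bmr_evidence(
    full: PEBResult,
    reduced_prior_mean: np.ndarray,
    reduced_prior_cov: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Analytic change in log evidence under altered priors, without refit.

    Returns ``(delta_F, reduced_posterior_mean, reduced_posterior_cov)``
    where ``delta_F = F_reduced - F_full``.  With the full prior passed
    back in, ``delta_F`` is exactly 0 and the posterior is unchanged.
    """
    iC0 = np.linalg.inv(full.prior_covariance)
    iC0r = np.linalg.inv(reduced_prior_cov)
    P = np.linalg.inv(full.covariance)
    Pr = P - iC0 + iC0r
    evals = np.linalg.eigvalsh(0.5 * (Pr + Pr.T))
    if np.any(evals <= 0):
        raise ValueError("reduced-prior precision combination is singular")
    Cr = np.linalg.inv(Pr)
    mr = Cr @ (P @ full.mean - iC0 @ full.prior_mean + iC0r @ reduced_prior_mean)
    sign, ld_P = np.linalg.slogdet(P)
    _, ld_Pr = np.linalg.slogdet(Pr)
    _, ld_iC0 = np.linalg.slogdet(iC0)
    _, ld_iC0r = np.linalg.slogdet(iC0r)
    quad = (mr @ Pr @ mr - full.mean @ P @ full.mean
            + full.prior_mean @ iC0 @ full.prior_mean
            - reduced_prior_mean @ iC0r @ reduced_prior_mean)
    dF = 0.5 * (ld_iC0r - ld_iC0 + ld_P - ld_Pr + quad)
    return float(dF), mr, 0.5 * (Cr + Cr.T)


@dataclass(frozen=True)
class BMRSearchResult:
    """Outcome of the model search over switchable group effects."""

    retained: dict
    pruned: tuple[str, ...]
    posterior_mean: np.ndarray
    posterior_covariance: np.ndarray
    delta_f: float
    n_models: int


def bmr_search(
    peb: PEBResult,
    switchable_covariates: tuple[str, ...] = ("age",),
    credible_mass: float = 0.90,
) -> BMRSearchResult:
    """Search over on/off mixtures of switchable group effects.

    Every effect of a switchable covariate may be pruned (prior variance
    collapsed to near zero).  With at most 8 switchable effects the search
    is exhaustive over all 2^k mixtures; beyond that a greedy backward
    pruning is used.  The mixture with the greatest analytic evidence wins;
    retained effects are reported with posterior expectations and central
    credible intervals.
    """
    switch_idx = [
        peb.effect_index(pname, cname)
        for pname in peb.param_names
        for cname in peb.covariate_names
        if cname in switchable_covariates
    ]
    k = len(switch_idx)

    def reduced_for(off_flags):
        cov = peb.prior_covariance.copy()
        for idx, off in zip(switch_idx, off_flags):
            if off:
                cov[idx, :] = 0.0
                cov[:, idx] = 0.0
                cov[idx, idx] = PRUNED_VARIANCE
        return peb.prior_mean, cov

    n_models = 0
    if k <= 8:
        best = (None, -np.inf, None, None)
        for flags in product([False, True], repeat=k):
            mean_r, cov_r = reduced_for(flags)
            dF, mr, Cr = bmr_evidence(peb, mean_r, cov_r)
            n_models += 1
            if dF > best[1]:
                best = (flags, dF, mr, Cr)
        flags, dF, mr, Cr = best
    else:
        flags = [False] * k
        dF, mr, Cr = 0.0, peb.mean, peb.covariance
        improved = True
        while improved:
            improved = False
            for j in range(k):
                if flags[j]:
                    continue
                trial = list(flags)
                trial[j] = True
                mean_r, cov_r = reduced_for(trial)
                dFt, mrt, Crt = bmr_evidence(peb, mean_r, cov_r)
                n_models += 1
                if dFt > dF:
                    flags, dF, mr, Cr = trial, dFt, mrt, Crt
                    improved = True

    from scipy.stats import norm

    zq = norm.ppf(0.5 + credible_mass / 2.0)
    retained, pruned = {}, []
    for pname in peb.param_names:
        for cname in peb.covariate_names:
            idx = peb.effect_index(pname, cname)
            label = f"{pname}:{cname}"
            if idx in switch_idx and flags[switch_idx.index(idx)]:
                pruned.append(label)
                continue
            sd = np.sqrt(max(Cr[idx, idx], 0.0))
            retained[label] = {
                "expectation": float(mr[idx]),
                "ci_low": float(mr[idx] - zq * sd),
                "ci_high": float(mr[idx] + zq * sd),
            }
    return BMRSearchResult(
        retained=retained,
        pruned=tuple(pruned),
        posterior_mean=mr,
        posterior_covariance=Cr,
        delta_f=float(dF),
        n_models=n_models,
    )
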