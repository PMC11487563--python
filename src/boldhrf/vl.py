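"""Bayesian inversion of the hemodynamic model by Variational Laplace.

A participant's ROI timeseries ``y`` is modelled as

    y = g(theta) + X0 * b0 + e,     e ~ N(0, exp(-lambda) * I)

where ``g`` integrates the balloon model (:mod:`boldhrf.hdm`) for the
participant's event train and samples it at scan times, ``X0`` holds
flat-prior nuisance regressors (constant and drift cosines), and ``lambda``
is a log-precision hyperparameter with a Gaussian hyperprior.  Free
hemodynamic parameters carry Gaussian priors on an estimation scale: rate
parameters (decay ``kappa``, ``transit_rate``, feedback ``gamma``) as log
deviations from their prior expectations (0.64, 1.02 and 0.41 Hz), the
neural efficacy ``beta`` on its natural linear scale.

Fitting is Gauss-Newton ascent on the Laplace free energy with
Levenberg-Marquardt damping and explicit accept/reject, so the free energy
is non-decreasing across accepted steps.  Prediction gradients use central
finite differences; all replicate/participant fits in
:func:`vl_fit_batch` share one vectorised integration per iteration, which
is what makes cohort-scale inversion tractable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import hdm

__all__ = [
    "PriorSpec",
    "Posterior",
    "HDMModel",
    "vl_fit",
    "vl_fit_batch",
    "posterior_rates_in_hz",
    "HDM3_MASK",
]

#: The three-parameter mask used throughout: neural efficacy plus the two
#: "vascular" rates.
HDM3_MASK = ("beta", "kappa", "transit_rate")

_ALLOWED_FREE = ("beta", "kappa", "transit_rate", "gamma", "alpha", "eps_h")

#: Parameters estimated as multiplicative (log) deviations from the prior
#: expectation; ``beta`` is estimated on its linear scale.
_LOG_SCALE = ("kappa", "transit_rate", "gamma", "alpha", "eps_h")


@dataclass(frozen=True)
class PriorSpec:
    """Gaussian priors on the estimation scale.

    ``means``/``variances`` map free-parameter names to prior moments:
    log-deviation scale for rate-like parameters (mean 0 means "at the
    prior expectation"), linear scale for ``beta``.  ``noise_log_precision``
    is the hyperprior (mean, variance) on the observation log precision;
    a mean of ``None`` defers to the data variance at fit time.
    """

    means: dict = field(default_factory=dict)
    variances: dict = field(default_factory=dict)
    noise_log_precision_mean: float | None = None
    noise_log_precision_variance: float = 16.0

    def moments(self, name: str) -> tuple[float, float]:
        mean = self.means.get(name, 0.0)
        default_var = 1.0 if name == "beta" else 1.0 / 16.0
        var = self.variances.get(name, default_var)
        if var < 0:
            raise ValueError(f"negative prior variance for {name}")
        return float(mean), float(var)


@dataclass(frozen=True)
class Posterior:
    """Gaussian posterior over free parameters from one VL fit."""

    mask: tuple[str, ...]
    mean: np.ndarray
    covariance: np.ndarray
    free_energy: float
    noise_log_precision: tuple[float, float]  # posterior mean, variance
    fitted: np.ndarray
    converged: bool
    free_energy_trace: np.ndarray
    prior_means: np.ndarray
    prior_variances: np.ndarray

    def __post_init__(self):
        C = np.asarray(self.covariance)
        if not np.allclose(C, C.T, atol=1e-8):
            raise ValueError("posterior covariance must be symmetric")
        if not np.isfinite(self.free_energy):
            raise ValueError("free energy must be finite")


@dataclass(frozen=True)
class HDMModel:
    """Forward model for one scanning run: events, scan grid and mask."""

    onsets: np.ndarray
    tr_s: float
    n_scans: int
    mask: tuple[str, ...] = HDM3_MASK
    base_params: hdm.HDMParams = field(default_factory=hdm.HDMParams)
    dt: float = hdm.DEFAULT_DT
    offset_s: float = 0.0
    event_duration_s: float | None = None  # None -> one integration bin

    def __post_init__(self):
        bad = set(self.mask) - set(_ALLOWED_FREE)
        if bad:
            raise ValueError(f"parameters not eligible to be free: {sorted(bad)}")
        if len(self.mask) == 0:
            raise ValueError("free-parameter mask must be non-empty")
        object.__setattr__(self, "onsets", np.asarray(self.onsets, dtype=float))

    @property
    def duration_s(self) -> float:
        return self.n_scans * self.tr_s

    def neural_input(self) -> hdm.NeuralInput:
        dur = self.event_duration_s if self.event_duration_s is not None else self.dt
        return hdm.NeuralInput.from_events(self.onsets, dur, self.dt, self.duration_s)

    def params_from_theta(self, theta: np.ndarray) -> hdm.HDMParams:
        """Map an estimation-scale vector to biophysical parameters:
        ``rate = prior_mean * exp(theta)`` for rates, ``beta = theta``."""
        updates = {}
        for name, value in zip(self.mask, theta):
            if name in _LOG_SCALE:
                updates[name] = getattr(self.base_params, name) * float(np.exp(value))
            else:
                updates[name] = float(value)
        return replace(self.base_params, **updates)

    def predict(self, theta: np.ndarray) -> np.ndarray:
        """Scan-grid prediction at one estimation-scale parameter vector."""
        return self.predict_many(np.atleast_2d(theta))[0]

    def predict_many(self, thetas: np.ndarray) -> np.ndarray:
        """Batched scan-grid predictions, one row per parameter vector."""
        thetas = np.atleast_2d(thetas)
        params = [self.params_from_theta(t) for t in thetas]
        z = self.neural_input().z
        Z = np.broadcast_to(z, (len(params), len(z)))
        Y = hdm.integrate_batch(params, Z, self.dt)
        return np.stack([
            hdm.downsample_to_scans(y, self.dt, self.tr_s, self.n_scans, self.offset_s)
            for y in Y
        ])


def _fd_jacobian_thetas(theta: np.ndarray, step: float) -> np.ndarray:
    """Stack of parameter vectors for central finite differences."""
    p = len(theta)
    out = [theta]
    for j in range(p):
        up, dn = theta.copy(), theta.copy()
        up[j] += step
        dn[j] -= step
        out.extend([up, dn])
    return np.stack(out)


def vl_fit(
    y: np.ndarray,
    model: HDMModel,
    priors: PriorSpec | None = None,
    nuisance: np.ndarray | None = None,
    max_iter: int = 64,
    fd_step: float = 1e-4,
    f_tol: float = 0.01,
) -> Posterior:
    """Invert the hemodynamic model for one timeseries (see module docstring)."""
    return vl_fit_batch(
        np.atleast_2d(y), [model], priors=priors, nuisance=nuisance,
        max_iter=max_iter, fd_step=fd_step, f_tol=f_tol,
    )[0]


def vl_fit_batch(
    Y: np.ndarray,
    models: list[HDMModel],
    priors: PriorSpec | None = None,
    nuisance: np.ndarray | None = None,
    max_iter: int = 64,
    fd_step: float = 1e-4,
    f_tol: float = 0.01,
) -> list[Posterior]:
    """Invert many runs at once (one model per row of ``Y``).

    All runs must share the scan grid and integration step so each
    Gauss-Newton iteration integrates every run and finite-difference
    perturbation in a single vectorised pass.
    """
    if priors is None:
        priors = PriorSpec()
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n_sub, n_scans = Y.shape
    if len(models) != n_sub:
        raise ValueError("need one forward model per timeseries")
    mask = models[0].mask
    if any(m.mask != mask for m in models) or any(
        (m.n_scans, m.tr_s, m.dt) != (models[0].n_scans, models[0].tr_s, models[0].dt)
        for m in models
    ):
        raise ValueError("batched fits must share mask, scan grid and dt")
    if not np.all(np.isfinite(Y)):
        raise ValueError("timeseries contain non-finite values")
    if models[0].n_scans != n_scans:
        raise ValueError("timeseries length does not match the model scan count")

    p = len(mask)
    prior_mean = np.array([priors.moments(name)[0] for name in mask])
    prior_var = np.array([priors.moments(name)[1] for name in mask])
    free = prior_var > 0
    if nuisance is None:
        nuisance = np.ones((n_scans, 1))
    X0 = np.atleast_2d(nuisance.T).T
    k = X0.shape[1]
    # combined parameter vector phi = (theta, b0); nuisance priors are flat
    m0 = np.concatenate([prior_mean, np.zeros(k)])
    v0 = np.concatenate([np.where(free, prior_var, 1.0), np.full(k, 1e6)])
    pi0 = 1.0 / v0
    n_phi = p + k

    lam0 = np.array([
        priors.noise_log_precision_mean
        if priors.noise_log_precision_mean is not None
        else -np.log(max(np.var(Y[i]), 1e-12))
        for i in range(n_sub)
    ])
    v_lam = priors.noise_log_precision_variance

    z_dt = models[0].dt
    z_stack = np.stack([m.neural_input().z for m in models])
    n_free = int(np.sum(free))
    free_idx = np.flatnonzero(free)
    rows_per_sub = 1 + 2 * n_free

    def predict_with_jacobian(phi_all: np.ndarray, active: np.ndarray):
        """Central-difference Jacobians for the active runs, one integration."""
        thetas, owners = [], []
        for i in active:
            theta = phi_all[i, :p].copy()
            stack = [theta]
            for j in free_idx:
                up, dn = theta.copy(), theta.copy()
                up[j] += fd_step
                dn[j] -= fd_step
                stack.extend([up, dn])
            thetas.extend(stack)
            owners.extend([i] * rows_per_sub)
        params = [models[owners[r]].params_from_theta(t) for r, t in enumerate(thetas)]
        Z = z_stack[np.asarray(owners)]
        # proposals probing unstable regimes yield NaN rows, which the
        # accept/reject step below treats as free energy -inf
        Yfine = hdm.integrate_batch(params, Z, z_dt, on_divergence="nan")
        md = models[0]
        grid = np.arange(Yfine.shape[1]) * z_dt
        times = np.arange(n_scans) * md.tr_s + md.offset_s
        Yscan = np.empty((Yfine.shape[0], n_scans))
        for r in range(Yfine.shape[0]):
            Yscan[r] = np.interp(times, grid, Yfine[r])
        G = np.empty((len(active), n_scans))
        J = np.zeros((len(active), n_scans, n_phi))
        for a, i in enumerate(active):
            base = a * rows_per_sub
            G[a] = Yscan[base] + X0 @ phi_all[i, p:]
            for jj, j in enumerate(free_idx):
                J[a, :, j] = (Yscan[base + 1 + 2 * jj]
                              - Yscan[base + 2 + 2 * jj]) / (2 * fd_step)
            J[a, :, p:] = X0
        return G, J

    # state per run
    phi = np.tile(m0, (n_sub, 1))
    lam = lam0.copy()
    nu = np.full(n_sub, 1.0 / 128.0)  # LM damping
    F = np.full(n_sub, -np.inf)
    Sig = np.zeros((n_sub, n_phi, n_phi))
    lam_var_post = np.full(n_sub, v_lam)
    fitted = np.zeros((n_sub, n_scans))
    streak = np.zeros(n_sub, dtype=int)
    traces: list[list[float]] = [[] for _ in range(n_sub)]
    done = np.zeros(n_sub, dtype=bool)

    def evaluate(phi_all, lam_all, active):
        """Free energy, posterior covariance and fit at given (phi, lambda),
        for the active subset.  ``lam_all`` entries are Newton-updated."""
        G, J = predict_with_jacobian(phi_all, active)
        out_F = np.empty(len(active))
        out_Sig = np.empty((len(active), n_phi, n_phi))
        out_lamvar = np.empty(len(active))
        e = Y[active] - G
        JtJ_all = np.einsum("ita,itb->iab", J, J)
        for a, i in enumerate(active):
            if not (np.all(np.isfinite(e[a])) and np.all(np.isfinite(JtJ_all[a]))):
                out_F[a] = -np.inf
                out_Sig[a] = np.eye(n_phi)
                out_lamvar[a] = v_lam
                continue
            # update lambda by Newton ascent given current residuals
            li = lam_all[i]
            JtJ = JtJ_all[a]
            for _ in range(8):
                P = np.exp(li) * JtJ + np.diag(pi0)
                Sigma = np.linalg.inv(P)
                E = e[a] @ e[a] + np.trace(Sigma @ JtJ)
                dF = 0.5 * n_scans - 0.5 * np.exp(li) * E - (li - lam0[i]) / v_lam
                ddF = -0.5 * np.exp(li) * E - 1.0 / v_lam
                step = dF / -ddF
                li += np.clip(step, -2.0, 2.0)
                if abs(step) < 1e-4:
                    break
            lam_all[i] = li
            P = np.exp(li) * JtJ + np.diag(pi0)
            Sigma = np.linalg.inv(P)
            E = e[a] @ e[a] + np.trace(Sigma @ JtJ)
            dphi = phi_all[i] - m0
            sign, logdet_Sig = np.linalg.slogdet(Sigma)
            lam_var = 1.0 / (0.5 * np.exp(li) * E + 1.0 / v_lam)
            Fi = (
                -0.5 * np.exp(li) * E
                + 0.5 * n_scans * li
                - 0.5 * n_scans * np.log(2 * np.pi)
                - 0.5 * dphi @ (pi0 * dphi)
                + 0.5 * (logdet_Sig + np.sum(np.log(pi0)))
                - 0.5 * (li - lam0[i]) ** 2 / v_lam
                + 0.5 * np.log(lam_var / v_lam)
            )
            out_F[a] = Fi
            out_Sig[a] = Sigma
            out_lamvar[a] = lam_var
        return out_F, out_Sig, out_lamvar, G, e, J, JtJ_all

    # initial evaluation at the prior means
    all_idx = np.arange(n_sub)
    F, Sig, lam_var_post, Gcur, ecur, Jcur, JtJ_cur = evaluate(phi, lam, all_idx)
    for i in range(n_sub):
        traces[i].append(F[i])
    fitted = Gcur.copy()

    for _ in range(max_iter):
        active = np.flatnonzero(~done)
        if active.size == 0:
            break
        # proposed Gauss-Newton / LM step from the current state
        phi_new = phi.copy()
        idx_fixed = np.concatenate([~free, np.zeros(k, dtype=bool)])
        for i in active:
            JtJ = JtJ_cur[i]
            g = np.exp(lam[i]) * (Jcur[i].T @ ecur[i]) - pi0 * (phi[i] - m0)
            P = np.exp(lam[i]) * JtJ + np.diag(pi0)
            Pd = P + nu[i] * np.diag(np.diag(P))
            step = np.linalg.solve(Pd, g)
            step[idx_fixed] = 0.0
            phi_new[i] = phi[i] + step
        lam_new = lam.copy()
        F_new, Sig_new, lamvar_new, G_new, e_new, J_new, JtJ_new = evaluate(
            phi_new, lam_new, active
        )
        for a, i in enumerate(active):
            if F_new[a] >= F[i] - 1e-9:
                dF = abs(F_new[a] - F[i])
                phi[i], lam[i] = phi_new[i], lam_new[i]
                F[i], Sig[i] = F_new[a], Sig_new[a]
                lam_var_post[i] = lamvar_new[a]
                fitted[i] = G_new[a]
                ecur[i], Jcur[i], JtJ_cur[i] = e_new[a], J_new[a], JtJ_new[a]
                traces[i].append(F[i])
                nu[i] = max(nu[i] / 2.0, 1e-8)
                streak[i] = streak[i] + 1 if dF < f_tol else 0
            else:
                # the proposal failed: damp harder; an unimproved free
                # energy still counts toward the stationarity streak
                nu[i] = min(nu[i] * 8.0, 1e6)
                streak[i] = streak[i] + 1 if nu[i] >= 1.0 else 0
            if streak[i] >= 4 or nu[i] >= 1e6:
                done[i] = True

    posteriors = []
    for i in range(n_sub):
        cov = Sig[i][:p, :p].copy()
        cov[~free, :] = 0.0
        cov[:, ~free] = 0.0
        cov = 0.5 * (cov + cov.T)
        posteriors.append(Posterior(
            mask=mask,
            mean=phi[i, :p].copy(),
            covariance=cov,
            free_energy=float(F[i]),
            noise_log_precision=(float(lam[i]), float(lam_var_post[i])),
            fitted=fitted[i].copy(),
            converged=bool(done[i] and streak[i] >= 4),
            free_energy_trace=np.array(traces[i]),
            prior_means=prior_mean.copy(),
            prior_variances=prior_var.copy(),
        ))
    return posteriors


def posterior_rates_in_hz(post: Posterior) -> dict[str, float]:
    """Transform posterior means of log-deviation rate parameters back to Hz
    (``prior_expectation * exp(mu)``); linear-scale parameters pass through."""
    base = hdm.HDMParams()
    out = {}
    for name, mu in zip(post.mask, post.mean):
        if name in _LOG_SCALE:
            out[name] = float(getattr(base, name) * np.exp(mu))
        else:
            out[name] = float(mu)
    return out
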