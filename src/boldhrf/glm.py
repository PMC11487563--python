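"""First-level prewhitened GLM fitting and ROI summarisation.

The first-level model follows the standard event-related fMRI pipeline:
the data are scaled to a grand mean of 100, a discrete-cosine set high-pass
filters both model and data at 1/128 Hz, the error autocorrelation is
modelled as a first-order-autoregressive-plus-white-noise mixture whose
weights are estimated by restricted maximum likelihood (ReML), and ordinary
least squares is applied to the prewhitened model and data.  Voxels
responding to the task are selected by an uncorrected F-test across the
basis-function regressors, and the region's timeseries is summarised by the
first temporal component of a singular-value decomposition across the
selected voxels (the eigenvariate).  A second-level model estimates the
mean response per post-stimulus time bin together with linear and quadratic
modulations by (z-scored) age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.linalg import toeplitz

__all__ = [
    "NoiseModel",
    "GLMFit",
    "ROISummary",
    "AgeGLMResult",
    "dct_highpass_set",
    "reml_ar1",
    "fit_glm",
    "participant_voxel_selection",
    "roi_eigenvariate",
    "second_level_age_glm",
]

#: Fixed first-order coefficient of the AR covariance component mixed with
#: white noise during ReML (software convention; configurable per call).
DEFAULT_AR_COEF = 0.2


@dataclass(frozen=True)
class NoiseModel:
    """ReML-estimated error covariance V = sum_i weight_i * Q_i and its
    whitening operator W = V^{-1/2} (so cov(W e) is proportional to I)."""

    weights: np.ndarray
    covariance: np.ndarray
    whitener: np.ndarray
    n_iterations: int
    converged: bool


@dataclass(frozen=True)
class GLMFit:
    """Prewhitened least-squares fit for one or more voxels."""

    coefficients: np.ndarray      # (n_regressors, n_voxels)
    residual_variance: np.ndarray  # (n_voxels,)
    dof: float                     # residual degrees of freedom
    f_stat: np.ndarray             # F over the interest columns, per voxel
    f_p: np.ndarray
    f_dof: tuple[float, float]
    interest: np.ndarray           # indices of interest columns in the design
    fitted: np.ndarray             # (n_scans, n_voxels), whitened-space fit

    def __post_init__(self):
        if np.any(self.residual_variance < -1e-12):
            raise ValueError("negative residual variance")
        if self.dof <= 0:
            raise ValueError("non-positive residual degrees of freedom")


@dataclass(frozen=True)
class ROISummary:
    """First-eigenvariate summary of a multi-voxel region."""

    eigenvariate: np.ndarray
    voxel_weights: np.ndarray
    selected: np.ndarray
    variance_explained: float

    def __post_init__(self):
        if not (0 < self.variance_explained <= 1 + 1e-12):
            raise ValueError("variance explained must lie in (0, 1]")


@dataclass(frozen=True)
class AgeGLMResult:
    """Second-level FIR-by-age model: per-bin mean, linear and quadratic
    age effects, with F-tests spanning bins for each effect."""

    bin_effects: np.ndarray   # (n_bins, 3): mean, linear, quadratic
    f_stats: dict[str, float]
    f_pvalues: dict[str, float]
    f_dofs: dict[str, tuple[float, float]]


def dct_highpass_set(n_scans: int, tr_s: float, cutoff_s: float = 128.0) -> np.ndarray:
    """Discrete-cosine high-pass regressors: a constant plus every cosine
    with period >= ``cutoff_s``; the count of non-constant cosines is
    ``floor(2 * run_length / cutoff_s)``.  Columns are orthonormal."""
    if n_scans < 2:
        raise ValueError("need at least 2 scans")
    total = n_scans * tr_s
    n_cos = int(np.floor(2.0 * total / cutoff_s))
    n = np.arange(n_scans)
    cols = [np.full(n_scans, 1.0 / np.sqrt(n_scans))]
    for k in range(1, n_cos + 1):
        c = np.sqrt(2.0 / n_scans) * np.cos(np.pi * k * (2 * n + 1) / (2 * n_scans))
        cols.append(c)
    return np.column_stack(cols)


def ar1_component(n_scans: int, coefficient: float = DEFAULT_AR_COEF) -> np.ndarray:
    """Off-diagonal part of an AR(1) correlation matrix (the white-noise
    component supplies the diagonal)."""
    if not (-1 < coefficient < 1):
        raise ValueError("|AR coefficient| must be < 1")
    col = coefficient ** np.arange(n_scans)
    return toeplitz(col) - np.eye(n_scans)


def reml_ar1(
    Y: np.ndarray,
    X: np.ndarray,
    ar_coefficient: float = DEFAULT_AR_COEF,
    max_iter: int = 32,
    tol: float = 1e-6,
) -> NoiseModel:
    """Estimate AR(1)+white-noise covariance weights by ReML Fisher scoring.

    The error covariance is modelled as ``V = w0 * I + w1 * Q_AR`` where
    ``Q_AR`` holds the off-diagonal AR(1) correlations at a fixed
    coefficient.  Weights maximise the restricted likelihood given the
    design ``X`` (whose span is projected out); the returned whitener is
    ``V^{-1/2}``, normalised so that ``trace(V) = n``.
    """
    Y = np.atleast_2d(Y.T).T  # (n, m)
    n, m = Y.shape
    if X.shape[0] != n:
        raise ValueError("Y and X must have the same number of scans")
    if n <= X.shape[1]:
        raise ValueError("need more scans than regressors for ReML")
    comps = [np.eye(n), ar1_component(n, ar_coefficient)]
    YY = (Y @ Y.T) / m
    lam = np.array([np.trace(YY) / n, 0.0])
    trace_log = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        V = lam[0] * comps[0] + lam[1] * comps[1]
        try:
            iV = np.linalg.inv(V)
        except np.linalg.LinAlgError:
            raise RuntimeError(
                f"ReML covariance became singular; trace: {trace_log}"
            ) from None
        iVX = iV @ X
        P = iV - iVX @ np.linalg.solve(X.T @ iVX, iVX.T)
        PQ = [P @ Q for Q in comps]
        PYYP = P @ YY @ P
        g = np.array([
            -0.5 * m * np.trace(PQi) + 0.5 * m * np.trace(Qi @ PYYP)
            for PQi, Qi in zip(PQ, comps)
        ])
        # expected curvature (Fisher information)
        H = np.array([[0.5 * m * np.trace(PQ[i] @ PQ[j]) for j in range(2)]
                      for i in range(2)])
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            raise RuntimeError(f"singular ReML information matrix; trace: {trace_log}")
        # damp steps that would destroy positive definiteness
        scale = 1.0
        for _ in range(16):
            trial = lam + scale * step
            Vt = trial[0] * comps[0] + trial[1] * comps[1]
            if np.all(np.linalg.eigvalsh(Vt) > 1e-10 * max(1.0, trial[0])):
                break
            scale *= 0.5
        lam = lam + scale * step
        trace_log.append(dict(iteration=it, weights=lam.copy(),
                              gradient_norm=float(np.linalg.norm(g))))
        if np.max(np.abs(scale * step)) < tol * max(1.0, abs(lam[0])):
            converged = True
            break
    V = lam[0] * comps[0] + lam[1] * comps[1]
    V = V * (n / np.trace(V))  # unit average variance; scale goes to sigma^2
    evals, evecs = np.linalg.eigh(V)
    W = evecs @ np.diag(1.0 / np.sqrt(evals)) @ evecs.T
    return NoiseModel(weights=lam, covariance=V, whitener=W,
                      n_iterations=it, converged=converged)


def fit_glm(
    Y: np.ndarray,
    X: np.ndarray,
    confounds: np.ndarray | None = None,
    noise: NoiseModel | None = None,
    dct: np.ndarray | None = None,
    grand_mean: float | None = 100.0,
) -> GLMFit:
    """Prewhitened least-squares GLM.

    ``X`` holds the regressors of interest (basis-function convolutions);
    ``confounds`` and ``dct`` are appended as nuisance columns.  Data are
    scaled to ``grand_mean`` over all voxels and scans (pass ``None`` to
    skip), both model and data are multiplied by the whitening operator,
    coefficients are estimated by OLS, and an F-statistic over the interest
    columns is formed from extra sums of squares.
    """
    Y = np.asarray(Y, dtype=float)
    one_d = Y.ndim == 1
    if one_d:
        Y = Y[:, None]
    n = Y.shape[0]
    blocks = [np.atleast_2d(X.T).T]
    if confounds is not None:
        blocks.append(np.atleast_2d(confounds.T).T)
    if dct is not None:
        blocks.append(dct)
    Xf = np.column_stack(blocks)
    if Xf.shape[0] != n:
        raise ValueError("design and data must have the same number of scans")
    rank = np.linalg.matrix_rank(Xf)
    if rank < Xf.shape[1]:
        raise ValueError(f"design is rank deficient ({rank} < {Xf.shape[1]})")
    if grand_mean is not None:
        gm = Y.mean()
        if gm <= 0:
            raise ValueError("grand-mean scaling requires positive-mean data")
        Y = Y * (grand_mean / gm)
    W = noise.whitener if noise is not None else np.eye(n)
    WY, WX = W @ Y, W @ Xf
    beta, _, _, _ = np.linalg.lstsq(WX, WY, rcond=None)
    fitted = WX @ beta
    resid = WY - fitted
    dof = n - rank
    rss = np.sum(resid**2, axis=0)
    res_var = rss / dof
    # extra-sum-of-squares F over the interest columns
    p_int = np.atleast_2d(X.T).T.shape[1]
    interest = np.arange(p_int)
    X0 = WX[:, p_int:]
    if X0.shape[1]:
        beta0, _, _, _ = np.linalg.lstsq(X0, WY, rcond=None)
        rss0 = np.sum((WY - X0 @ beta0) ** 2, axis=0)
    else:
        rss0 = np.sum(WY**2, axis=0)
    df1 = p_int
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss0 - rss) / df1) / np.where(res_var > 0, res_var, np.nan)
    f_p = stats.f.sf(f, df1, dof)
    return GLMFit(
        coefficients=beta[:, 0] if one_d else beta,
        residual_variance=res_var[0] if one_d else res_var,
        dof=float(dof),
        f_stat=f[0] if one_d else f,
        f_p=f_p[0] if one_d else f_p,
        f_dof=(float(df1), float(dof)),
        interest=interest,
        fitted=fitted[:, 0] if one_d else fitted,
    )


def participant_voxel_selection(fit: GLMFit, alpha: float = 0.05) -> np.ndarray:
    """Voxels whose basis-set F-test survives ``p < alpha`` (uncorrected).

    An empty return flags the participant for exclusion: with no responsive
    voxel the ROI summary would be pure noise.
    """
    p = np.atleast_1d(fit.f_p)
    return np.flatnonzero(p < alpha)


def roi_eigenvariate(voxel_data: np.ndarray, selected: np.ndarray | None = None) -> ROISummary:
    """First temporal SVD component across (selected) voxels.

    The eigenvariate is the first left singular vector scaled to the
    region's typical voxel amplitude (``sigma_1 / sqrt(n_voxels)``); its
    sign is chosen so the mean voxel weight is positive.
    """
    Y = np.atleast_2d(voxel_data.T).T
    if selected is None:
        selected = np.arange(Y.shape[1])
    if len(selected) == 0:
        raise ValueError("cannot summarise a region with no selected voxels")
    Ys = Y[:, selected]
    u, s, vt = np.linalg.svd(Ys, full_matrices=False)
    if vt[0].mean() < 0:
        u, vt = -u, -vt
    nv = Ys.shape[1]
    eig = u[:, 0] * s[0] / np.sqrt(nv)
    var_exp = float(s[0] ** 2 / np.sum(s**2))
    return ROISummary(
        eigenvariate=eig,
        voxel_weights=vt[0],
        selected=np.asarray(selected),
        variance_explained=var_exp,
    )


def second_level_age_glm(fir: np.ndarray, ages: np.ndarray) -> AgeGLMResult:
    """Group model on per-participant FIR estimates: per-bin mean, linear
    and quadratic effects of z-scored age, with an F-test spanning bins for
    each effect (extra sum of squares in a long-format GLM)."""
    fir = np.asarray(fir, dtype=float)
    ages = np.asarray(ages, dtype=float)
    n, b = fir.shape
    if n < 4:
        raise ValueError("need at least 4 participants")
    z = (ages - ages.mean()) / ages.std(ddof=0)
    per_bin = np.empty((b, 3))
    Xb = np.column_stack([np.ones(n), z, z**2])
    coef, _, _, _ = np.linalg.lstsq(Xb, fir, rcond=None)
    per_bin[:] = coef.T
    # long format: y_(i,bin) with bin-specific mean/linear/quadratic columns
    y = fir.ravel()  # participant-major
    eye_b = np.eye(b)
    bins = np.tile(eye_b, (n, 1))
    X_full = np.column_stack([bins, bins * np.repeat(z, b)[:, None],
                              bins * np.repeat(z**2, b)[:, None]])
    blocks = {"mean": slice(0, b), "linear": slice(b, 2 * b),
              "quadratic": slice(2 * b, 3 * b)}
    rank = 3 * b
    dof = n * b - rank
    beta, _, _, _ = np.linalg.lstsq(X_full, y, rcond=None)
    rss = np.sum((y - X_full @ beta) ** 2)
    f_stats, f_ps, f_dofs = {}, {}, {}
    for name, sl in blocks.items():
        keep = np.ones(rank, dtype=bool)
        keep[sl] = False
        X0 = X_full[:, keep]
        b0, _, _, _ = np.linalg.lstsq(X0, y, rcond=None)
        rss0 = np.sum((y - X0 @ b0) ** 2)
        f = ((rss0 - rss) / b) / (rss / dof)
        f_stats[name] = float(f)
        f_ps[name] = float(stats.f.sf(f, b, dof))
        f_dofs[name] = (float(b), float(dof))
    return AgeGLMResult(bin_effects=per_bin, f_stats=f_stats,
                        f_pvalues=f_ps, f_dofs=f_dofs)
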