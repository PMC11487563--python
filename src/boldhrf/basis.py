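"""HRF basis sets and convolution design matrices.

Two families of temporal basis are provided for linear (GLM) modelling of the
BOLD impulse response:

* a finite impulse response (FIR) set — contiguous 1 s top-hat functions
  covering the first 32 s of post-stimulus time, giving an unconstrained
  per-bin estimate of the response;
* the "informed" set — a canonical two-gamma HRF plus its temporal
  derivative (finite difference under a 1 s onset shift) and dispersion
  derivative (finite difference under a 1 % widening of the peak gamma).

Design matrices are built in a microtime space of ``bins_per_tr`` time
points per TR (a delta train at event onsets convolved with each basis
column) and down-sampled at the middle microtime bin of each scan.  The
canonical two-gamma form can also be refit to an empirical FIR curve to give
a revised canonical HRF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize
from scipy.stats import gamma as gamma_dist

from .design import EventSequence

__all__ = [
    "BasisSet",
    "TwoGammaParams",
    "DesignMatrix",
    "fir_basis",
    "two_gamma_hrf",
    "informed_basis",
    "fit_two_gamma",
    "build_design_matrix",
]


@dataclass(frozen=True)
class BasisSet:
    """Basis curves sampled on a regular microtime grid."""

    step_s: float
    window_s: float
    columns: np.ndarray  # (n_timepoints, n_basis)
    names: tuple[str, ...]

    def __post_init__(self):
        if self.window_s < 16:
            raise ValueError("basis window must cover at least 16 s")
        if self.columns.ndim != 2 or self.columns.shape[1] != len(self.names):
            raise ValueError("columns/names mismatch")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.columns.shape[0]) * self.step_s

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.columns, index=self.times, columns=list(self.names))


@dataclass(frozen=True)
class TwoGammaParams:
    """Parameters of the canonical double-gamma HRF.

    The response is the difference of two gamma densities: one for the
    positive peak (around 5 s) and one, down-weighted by ``ratio``, for the
    later undershoot (around 15 s).  Delays are in seconds; each gamma has
    shape ``delay/dispersion`` and scale ``dispersion``.
    """

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    ratio: float = 6.0
    onset_s: float = 0.0
    length_s: float = 32.0

    def __post_init__(self):
        if self.peak_delay_s <= 0 or self.undershoot_delay_s <= 0:
            raise ValueError("delays must be positive")
        if self.peak_dispersion <= 0 or self.undershoot_dispersion <= 0:
            raise ValueError("dispersions must be positive")
        if self.ratio <= 0:
            raise ValueError("peak:undershoot ratio must be positive")


@dataclass(frozen=True)
class DesignMatrix:
    """Scan-sampled convolution regressors, one column per basis function."""

    matrix: np.ndarray  # (n_scans, n_basis)
    names: tuple[str, ...]
    tr_s: float
    basis: BasisSet


def fir_basis(
    n_bins: int = 32,
    bin_width_s: float = 1.0,
    microtime_step_s: float = 1.97 / 32,
) -> BasisSet:
    """Top-hat FIR basis: column ``k`` is the indicator of post-stimulus
    time ``[k*width, (k+1)*width)``.  Columns are mutually orthogonal and
    partition the window (pointwise sum 1)."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    window = n_bins * bin_width_s
    t = np.arange(0.0, window - microtime_step_s / 2, microtime_step_s)
    idx = np.floor(t / bin_width_s).astype(int)
    cols = np.zeros((len(t), n_bins))
    cols[np.arange(len(t)), np.clip(idx, 0, n_bins - 1)] = 1.0
    names = tuple(f"fir_{k:02d}" for k in range(n_bins))
    return BasisSet(step_s=microtime_step_s, window_s=window, columns=cols, names=names)


def _double_gamma(t: np.ndarray, p: TwoGammaParams) -> np.ndarray:
    tt = t - p.onset_s
    peak = gamma_dist.pdf(tt, p.peak_delay_s / p.peak_dispersion,
                          scale=p.peak_dispersion)
    under = gamma_dist.pdf(tt, p.undershoot_delay_s / p.undershoot_dispersion,
                           scale=p.undershoot_dispersion)
    return np.where(tt >= 0, peak - under / p.ratio, 0.0)


def two_gamma_hrf(p: TwoGammaParams, step_s: float = 1.97 / 32) -> np.ndarray:
    """Canonical two-gamma HRF on a ``step_s`` grid, peak-normalised to 1."""
    t = np.arange(0.0, p.length_s - step_s / 2, step_s)
    h = _double_gamma(t, p)
    m = np.max(h)
    if m <= 0:
        raise ValueError("degenerate two-gamma parameters: no positive peak")
    return h / m


def informed_basis(
    p: TwoGammaParams | None = None,
    step_s: float = 1.97 / 32,
    orthogonalize: bool = True,
) -> BasisSet:
    """Canonical HRF plus temporal and dispersion derivative columns.

    The temporal derivative is the finite difference after delaying the
    onset by 1 s; the dispersion derivative the finite difference after
    widening the peak dispersion by 1 %.  With ``orthogonalize`` the
    derivative columns are Gram-Schmidt orthogonalised against the
    preceding ones (serial orthogonalisation), so the canonical column
    carries all variance it can explain.
    """
    if p is None:
        p = TwoGammaParams()
    canon = two_gamma_hrf(p, step_s)
    shift = 1.0
    shifted = two_gamma_hrf(replace(p, onset_s=p.onset_s + shift), step_s)
    temporal = (canon - shifted) / shift
    dfrac = 0.01
    widened = two_gamma_hrf(
        replace(p, peak_dispersion=p.peak_dispersion * (1 + dfrac)), step_s
    )
    dispersion = (canon - widened) / dfrac
    cols = np.column_stack([canon, temporal, dispersion])
    if orthogonalize:
        for j in range(1, 3):
            for i in range(j):
                proj = cols[:, i] @ cols[:, j] / (cols[:, i] @ cols[:, i])
                cols[:, j] = cols[:, j] - proj * cols[:, i]
    return BasisSet(
        step_s=step_s,
        window_s=p.length_s,
        columns=cols,
        names=("canonical", "temporal_derivative", "dispersion_derivative"),
    )


def fit_two_gamma(
    curve: np.ndarray,
    step_s: float = 1.0,
    p0: TwoGammaParams | None = None,
) -> tuple[TwoGammaParams, float]:
    """Refit the two-gamma form to an empirical HRF (e.g. a mean FIR curve).

    Least-squares over (peak delay, undershoot delay, dispersions, ratio)
    with a free amplitude; returns the fitted parameters and the R^2 of the
    reconstruction.  Useful for deriving a revised canonical HRF from group
    FIR estimates.
    """
    curve = np.asarray(curve, dtype=float)
    if len(curve) * step_s < 24:
        raise ValueError("curve must cover at least 24 s of post-stimulus time")
    t = np.arange(len(curve)) * step_s
    if p0 is None:
        p0 = TwoGammaParams(length_s=max(32.0, t[-1] + step_s))

    def model(x):
        pd_, ud, pdisp, udisp, ratio, amp = x
        pp = TwoGammaParams(
            peak_delay_s=pd_, undershoot_delay_s=ud, peak_dispersion=pdisp,
            undershoot_dispersion=udisp, ratio=ratio, onset_s=p0.onset_s,
            length_s=p0.length_s,
        )
        h = _double_gamma(t, pp)
        m = np.max(h)
        return amp * (h / m if m > 0 else h)

    amp0 = curve[np.argmax(np.abs(curve))]
    x0 = np.array([p0.peak_delay_s, p0.undershoot_delay_s, p0.peak_dispersion,
                   p0.undershoot_dispersion, p0.ratio, amp0 if amp0 != 0 else 1.0])
    lower = [1.0, 4.0, 0.05, 0.05, 0.5, -np.inf]
    upper = [12.0, 30.0, 4.0, 4.0, 50.0, np.inf]
    res = optimize.least_squares(
        lambda x: model(x) - curve, x0, bounds=(lower, upper), xtol=1e-12, ftol=1e-12
    )
    fit = model(res.x)
    ss_res = np.sum((curve - fit) ** 2)
    ss_tot = np.sum((curve - curve.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    params = TwoGammaParams(
        peak_delay_s=res.x[0], undershoot_delay_s=res.x[1],
        peak_dispersion=res.x[2], undershoot_dispersion=res.x[3],
        ratio=res.x[4], onset_s=p0.onset_s, length_s=p0.length_s,
    )
    if not res.success:
        raise RuntimeError(
            f"two-gamma fit did not converge (status {res.status}); "
            f"best parameters so far: {params}"
        )
    return params, float(r2)


def build_design_matrix(
    events: EventSequence,
    basis: BasisSet,
    tr_s: float,
    n_scans: int,
    bins_per_tr: int = 32,
) -> DesignMatrix:
    """Convolve a delta train at event onsets with each basis column in
    microtime, then sample at the middle microtime bin of each scan."""
    step = tr_s / bins_per_tr
    if abs(step - basis.step_s) > 1e-9:
        raise ValueError(
            f"basis microtime step {basis.step_s:.6f} s does not match "
            f"tr_s/bins_per_tr = {step:.6f} s"
        )
    run_length = n_scans * tr_s
    onsets = np.asarray(events.onsets, dtype=float)
    keep = onsets < run_length
    if not np.all(keep):
        warnings.warn(
            f"dropping {np.sum(~keep)} event(s) after the last scan", stacklevel=2
        )
        onsets = onsets[keep]
    n_fine = n_scans * bins_per_tr
    delta = np.zeros(n_fine)
    idx = np.round(onsets / step).astype(int)
    np.add.at(delta, idx[idx < n_fine], 1.0)
    sample_idx = np.arange(n_scans) * bins_per_tr + bins_per_tr // 2
    cols = np.empty((n_scans, basis.columns.shape[1]))
    for j in range(basis.columns.shape[1]):
        conv = np.convolve(delta, basis.columns[:, j])[:n_fine]
        cols[:, j] = conv[sample_idx]
    return DesignMatrix(matrix=cols, names=basis.names, tr_s=tr_s, basis=basis)
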