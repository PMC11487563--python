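"""HRF shape features, fit-quality metrics, age correlations and
cross-validated age prediction.

Peak features follow the convention used for empirical impulse-response
estimates: the amplitude is the signed value at the time bin with maximal
absolute response within the first 16 s of post-stimulus time, and the
latency is the time of that bin.  Model comparison uses per-participant
leave-one-out multiple linear regression of age on parameter estimates,
summarised by the Pearson correlation between actual and predicted age and
by paired two-sided sign tests on absolute prediction errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "HRFFeatures",
    "ModelComparison",
    "peak_features",
    "rmse_timeseries",
    "rmse_pst",
    "spearman_age",
    "loo_age_prediction",
    "sign_test",
    "compare_models",
]


@dataclass(frozen=True)
class HRFFeatures:
    """Signed peak amplitude and its latency within the search window."""

    peak_amplitude: float
    peak_latency_s: float
    window_s: float = 16.0

    def __post_init__(self):
        if not (0 <= self.peak_latency_s <= self.window_s):
            raise ValueError("latency must fall inside the search window")


@dataclass(frozen=True)
class ModelComparison:
    """Cross-validated age-prediction comparison across models."""

    absolute_errors: dict
    median_errors: dict
    pearson_r: dict
    sign_test_p: dict

    def __post_init__(self):
        for name, err in self.absolute_errors.items():
            if np.any(np.asarray(err) < 0):
                raise ValueError(f"negative absolute errors for {name}")


def peak_features(curve: np.ndarray, step_s: float, window_s: float = 16.0) -> HRFFeatures:
    """Peak amplitude (signed value at the maximal absolute response) and
    peak latency within the first ``window_s`` seconds; ties take the
    earliest bin."""
    curve = np.asarray(curve, dtype=float)
    n = min(len(curve), int(np.floor(window_s / step_s)) + 1)
    seg = curve[:n]
    if np.allclose(seg, 0):
        raise ValueError("all-zero curve has no defined peak")
    idx = int(np.argmax(np.abs(seg)))  # argmax returns the earliest maximum
    return HRFFeatures(
        peak_amplitude=float(seg[idx]),
        peak_latency_s=float(idx * step_s),
        window_s=window_s,
    )


def rmse_timeseries(y: np.ndarray, fit: np.ndarray) -> float:
    """Root-mean-squared residual across an original BOLD timeseries."""
    y = np.asarray(y, dtype=float)
    fit = np.asarray(fit, dtype=float)
    if y.shape != fit.shape:
        raise ValueError("timeseries and fit must have equal length")
    return float(np.sqrt(np.mean((y - fit) ** 2)))


def rmse_pst(fir_curve: np.ndarray, model_curve: np.ndarray) -> float:
    """Root-mean-squared error across trial-averaged post-stimulus time."""
    return rmse_timeseries(fir_curve, model_curve)


def spearman_age(values: np.ndarray, ages: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation of a feature with age (two-sided p)."""
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if len(values) != len(ages) or len(values) < 4:
        raise ValueError("need paired samples, n >= 4")
    if np.all(values == values[0]) or np.all(ages == ages[0]):
        raise ValueError("rank correlation undefined for constant input")
    rho, p = stats.spearmanr(values, ages)
    return float(rho), float(p)


def loo_age_prediction(
    features: np.ndarray,
    ages: np.ndarray,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Leave-one-out multiple linear regression of age on features.

    For each participant, an intercept-plus-features OLS model is trained
    on all other participants and predicts the held-out age.  Returns
    ``(predictions, pearson_r, absolute_errors)``.  The hat-matrix identity
    for OLS makes the n leave-one-out fits a single decomposition.
    """
    F = np.atleast_2d(np.asarray(features, dtype=float))
    ages = np.asarray(ages, dtype=float)
    n, k = F.shape
    if n != len(ages):
        raise ValueError("feature rows must match number of ages")
    if n <= k + 1:
        raise ValueError("need more participants than features + 1")
    X = np.column_stack([np.ones(n), F])
    # guard conditioning before trusting the closed form
    s = np.linalg.svd(X, compute_uv=False)
    if s[0] / s[-1] > 1e10:
        raise ValueError("ill-conditioned feature matrix")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ ages
    resid = ages - X @ beta
    h = np.einsum("ij,jk,ik->i", X, XtX_inv, X)
    loo_resid = resid / (1.0 - h)  # standard leave-one-out residual identity
    pred = ages - loo_resid
    r = float(np.corrcoef(ages, pred)[0, 1])
    return pred, r, np.abs(loo_resid)


def sign_test(errors_a: np.ndarray, errors_b: np.ndarray) -> float:
    """Two-sided paired sign test on (a - b); exact ties are discarded."""
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diff = a - b
    nz = diff[diff != 0]
    if len(nz) == 0:
        raise ValueError("all pairs tie; sign test degenerate")
    k = int(np.sum(nz > 0))
    return float(stats.binomtest(k, len(nz), 0.5, alternative="two-sided").pvalue)


def compare_models(
    model_features: dict,
    ages: np.ndarray,
    reference: str | None = None,
) -> ModelComparison:
    """LOO age prediction for several models plus pairwise sign tests
    against a reference model (default: the first)."""
    names = list(model_features)
    if reference is None:
        reference = names[0]
    abs_err, med, rs = {}, {}, {}
    for name in names:
        _, r, err = loo_age_prediction(model_features[name], ages)
        abs_err[name] = err
        med[name] = float(np.median(err))
        rs[name] = r
    sign_p = {}
    for name in names:
        if name == reference:
            continue
        try:
            sign_p[name] = sign_test(abs_err[name], abs_err[reference])
        except ValueError:
            sign_p[name] = np.nan
    return ModelComparison(
        absolute_errors=abs_err, median_errors=med, pearson_r=rs, sign_test_p=sign_p
    )
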