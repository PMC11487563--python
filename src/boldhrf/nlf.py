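"""Nonlinear four-parameter template fitting of individual HRF estimates.

A group template HRF (first singular vector of the participants-by-bins FIR
matrix) is warped in time and scaled in amplitude to match each individual's
FIR curve:

    y_hat(t) = a1 * Y(t1 * t - t0) + a0

where ``t0`` is a latency offset (constant delay), ``t1`` a latency scaling
(cumulative delay: features at post-stimulus time ``t`` move to ``t / t1``),
``a0`` an amplitude offset and ``a1`` an amplitude scaling.  Because the
Pearson correlation is invariant to affine amplitude transforms, the warp
``(t0, t1)`` is fit by maximising the correlation between warped template
and individual curve, after which ``(a0, a1)`` follow in closed form by
least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NLFParams", "HRFTemplate", "make_template", "warp_template", "fit_nlf"]

#: Default search bounds for the warp parameters.
T0_BOUNDS = (-4.0, 4.0)
T1_BOUNDS = (0.5, 2.0)


@dataclass(frozen=True)
class NLFParams:
    """Fitted shape parameters: amplitude offset/scaling, latency offset (s)
    and latency scaling (dimensionless, 1 = no stretch)."""

    a0: float
    a1: float
    t0: float
    t1: float

    def __post_init__(self):
        if not (T1_BOUNDS[0] - 1e-9 <= self.t1 <= T1_BOUNDS[1] + 1e-9):
            raise ValueError(f"t1 = {self.t1} outside bounds {T1_BOUNDS}")
        if not (T0_BOUNDS[0] - 1e-9 <= self.t0 <= T0_BOUNDS[1] + 1e-9):
            raise ValueError(f"t0 = {self.t0} outside bounds {T0_BOUNDS}")


@dataclass(frozen=True)
class HRFTemplate:
    """Group HRF template on a regular post-stimulus-time grid."""

    curve: np.ndarray
    step_s: float
    provenance: str = ""

    def __post_init__(self):
        c = np.asarray(self.curve, dtype=float)
        object.__setattr__(self, "curve", c)
        if np.allclose(c, c[0]):
            raise ValueError("template curve is constant (degenerate)")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.curve)) * self.step_s


def make_template(fir_matrix: np.ndarray, step_s: float = 1.0,
                  provenance: str = "") -> HRFTemplate:
    """Template = first right singular vector of the participants-by-bins
    FIR matrix, sign-fixed so its dominant extremum within 8 s is positive."""
    M = np.atleast_2d(np.asarray(fir_matrix, dtype=float))
    if M.shape[0] < 2:
        raise ValueError("need at least 2 participants to form a template")
    if not np.any(M):
        raise ValueError("rank-0 FIR matrix")
    _, s, vt = np.linalg.svd(M, full_matrices=False)
    curve = vt[0]
    early = curve[: max(1, int(np.ceil(8.0 / step_s)))]
    if early[np.argmax(np.abs(early))] < 0:
        curve = -curve
    return HRFTemplate(curve=curve, step_s=step_s, provenance=provenance)


def warp_template(
    template: HRFTemplate,
    t0: float,
    t1: float,
    convention: str = "scale_then_shift",
) -> np.ndarray:
    """Evaluate the warped template on its own time grid.

    ``scale_then_shift`` (default) implements ``Y(t1 * t - t0)``; the
    alternative ``shift_then_scale`` implements ``Y((t - t0) / t1)``.
    Arguments falling outside the template support evaluate to 0.
    """
    t = template.times
    if convention == "scale_then_shift":
        arg = t1 * t - t0
    elif convention == "shift_then_scale":
        arg = (t - t0) / t1
    else:
        raise ValueError(f"unknown warp convention {convention!r}")
    return np.interp(arg, t, template.curve, left=0.0, right=0.0)


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def fit_nlf(
    template: HRFTemplate,
    individual: np.ndarray,
    convention: str = "scale_then_shift",
    t0_bounds: tuple[float, float] = T0_BOUNDS,
    t1_bounds: tuple[float, float] = T1_BOUNDS,
) -> tuple[NLFParams, float]:
    """Fit the four shape parameters to one individual FIR curve.

    The warp is found by multi-start local ascent on the Pearson correlation
    between warped template and individual curve (a 3 x 3 grid of starts
    over the bounds, plus the identity warp, each refined by coordinate-wise
    step-halving ascent); ties break toward the identity warp.  Amplitude
    parameters are then solved in closed form.  Returns the parameters and
    the achieved correlation, which is never below the correlation at the
    identity warp.
    """
    y = np.asarray(individual, dtype=float)
    if len(y) != len(template.curve):
        raise ValueError("individual curve must share the template grid")
    if np.allclose(y, y[0]):
        raise ValueError("individual curve is flat; fit undefined")

    def objective(t0, t1):
        return _corr(warp_template(template, t0, t1, convention), y)

    starts = [(0.0, 1.0)]
    for t0 in np.linspace(*t0_bounds, 3):
        for t1 in np.linspace(*t1_bounds, 3):
            starts.append((float(t0), float(t1)))

    def ascend(t0, t1):
        steps = (0.5, 0.1)
        best = objective(t0, t1)
        for _ in range(60):
            improved = False
            for dim in (0, 1):
                step = steps[dim]
                while step > (0.001 if dim == 0 else 0.0005):
                    for sgn in (+1, -1):
                        c0, c1 = (t0 + sgn * step, t1) if dim == 0 else (t0, t1 + sgn * step)
                        c0 = float(np.clip(c0, *t0_bounds))
                        c1 = float(np.clip(c1, *t1_bounds))
                        val = objective(c0, c1)
                        if val > best + 1e-12:
                            t0, t1, best = c0, c1, val
                            improved = True
                            break
                    else:
                        step *= 0.5
                        continue
                    break
            if not improved:
                break
        return t0, t1, best

    candidates = [ascend(t0, t1) for t0, t1 in starts]
    # tie-break toward identity warp among near-equal optima
    best_val = max(c[2] for c in candidates)
    near = [c for c in candidates if c[2] >= best_val - 1e-9]
    t0, t1, achieved = min(near, key=lambda c: (c[0] ** 2 + (c[1] - 1.0) ** 2))
    # closed-form amplitude: regress individual on warped template
    w = warp_template(template, t0, t1, convention)
    A = np.column_stack([w, np.ones_like(w)])
    (a1, a0), _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    return NLFParams(a0=float(a0), a1=float(a1), t0=float(t0), t1=float(t1)), achieved
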