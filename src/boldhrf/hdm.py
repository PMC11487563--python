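"""Biophysical hemodynamic forward model (balloon model with neurovascular input).

The model maps a neural input train ``z(t)`` to a BOLD percent-signal
timeseries through four hidden states: vasoactive signal ``s``, normalised
inflow ``f_in``, venous volume ``v`` and deoxyhemoglobin content ``q``::

    df_in/dt = s
    ds/dt    = beta * z - kappa * s - gamma * (f_in - 1)
    dv/dt    = transit_rate * (f_in - f_out(v)),         f_out(v) = v**(1/alpha)
    dq/dt    = transit_rate * (f_in * E(f_in)/E0 - f_out(v) * q / v)

with oxygen extraction ``E(f) = 1 - (1 - E0)**(1/f)`` and the observation

    y = 100 * V0 * (k1*(1 - q) + k2*(1 - q/v) + k3*(1 - v))
    k1 = 4.3 * theta0 * E0 * TE,   k2 = eps_h * r0 * E0 * TE,   k3 = 1 - eps_h

``beta`` is the neural efficacy, ``kappa`` (Hz) the vasoactive-signal decay
rate, ``gamma`` (Hz) the autoregulatory feedback rate and ``transit_rate``
(Hz) the inverse mean transit time of blood through the venous compartment.

Integration uses classical RK4 with ``f_in, v, q`` propagated in log space so
their positivity is structural rather than enforced by clipping.  All heavy
routines are batched over a leading axis so that many parameter vectors
and/or input trains integrate in one vectorised pass; the model-inversion
module relies on this.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "HDMParams",
    "HDMState",
    "NeuralInput",
    "dstate_dt",
    "bold_from_state",
    "integrate",
    "integrate_batch",
    "downsample_to_scans",
    "volterra_kernel1",
    "volterra_kernel2",
    "second_order_variance_fraction",
    "DEFAULT_DT",
]

#: Default integration step (s).  A finer step does not change results
#: beyond the convergence tolerance checked in the test suite.
DEFAULT_DT = 0.375

# Fields estimated on a log-deviation scale during inversion are the rates.
RATE_FIELDS = ("kappa", "gamma", "transit_rate")


@dataclass(frozen=True)
class HDMParams:
    """Hemodynamic model parameters.

    Defaults: the decay rate ``kappa`` = 0.64 Hz and ``transit_rate`` =
    1.02 Hz are the prior expectations used for inversion; the fixed
    biophysical constants (``gamma``, ``alpha``, ``e0``, ``v0``, ``theta0``,
    ``r0``, ``eps_h``, ``te``) take conventional 3T gradient-echo values.
    """

    beta: float = 1.0        # neural efficacy (dimensionless, may be negative)
    kappa: float = 0.64      # vasoactive signal decay rate (Hz)
    gamma: float = 0.41      # autoregulatory feedback rate (Hz)
    transit_rate: float = 1.02  # 1/tau_h, venous transit rate (Hz)
    alpha: float = 0.32      # Grubb's exponent (flow-volume coupling)
    e0: float = 0.4          # resting oxygen extraction fraction
    v0: float = 0.04         # resting venous blood volume fraction
    theta0: float = 40.3     # frequency offset at outer vessel surface (Hz)
    r0: float = 25.0         # intravascular relaxation slope (Hz)
    eps_h: float = 1.0       # intra/extra-vascular signal ratio
    te: float = 0.03         # echo time (s)

    def __post_init__(self):
        if self.transit_rate <= 0:
            raise ValueError("transit_rate must be positive")
        if not (0 < self.e0 < 1):
            raise ValueError("e0 must lie in (0, 1)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.v0 <= 0 or self.te <= 0:
            raise ValueError("v0 and te must be positive")

    def bold_coefficients(self) -> tuple[float, float, float]:
        """Observation coefficients (k1, k2, k3)."""
        k1 = 4.3 * self.theta0 * self.e0 * self.te
        k2 = self.eps_h * self.r0 * self.e0 * self.te
        k3 = 1.0 - self.eps_h
        return k1, k2, k3


@dataclass(frozen=True)
class HDMState:
    """Hidden states; (0, 1, 1, 1) is the resting fixed point."""

    s: float = 0.0
    f_in: float = 1.0
    v: float = 1.0
    q: float = 1.0

    def __post_init__(self):
        if self.f_in <= 0 or self.v <= 0 or self.q <= 0:
            raise ValueError("f_in, v and q must remain positive")


@dataclass(frozen=True)
class NeuralInput:
    """Neural drive z(t) in {0, 1} on a regular dt grid (one value per step)."""

    z: np.ndarray
    dt: float

    @classmethod
    def from_events(
        cls,
        onsets: np.ndarray,
        durations: np.ndarray | float,
        dt: float,
        duration_s: float,
    ) -> "NeuralInput":
        """Boxcar input: z = 1 within each event window, else 0.

        An event shorter than one integration bin still occupies one full bin
        (trials are treated as brief bursts at the integrator's resolution).
        """
        n_steps = int(round(duration_s / dt))
        z = np.zeros(n_steps)
        onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
        durations = np.broadcast_to(np.atleast_1d(np.asarray(durations, dtype=float)),
                                    onsets.shape)
        for t0, d in zip(onsets, durations):
            start = int(np.floor(t0 / dt + 1e-9))
            stop = max(start + 1, int(np.ceil((t0 + d) / dt - 1e-9)))
            if start < n_steps:
                z[start:min(stop, n_steps)] = 1.0
        return cls(z=z, dt=dt)


def dstate_dt(state: HDMState, z: float, p: HDMParams) -> tuple[float, float, float, float]:
    """Time derivatives (ds, df_in, dv, dq) of the hidden states."""
    s, f, v, q = state.s, state.f_in, state.v, state.q
    if not all(np.isfinite([s, f, v, q])):
        raise ValueError("non-finite hidden state")
    f_out = v ** (1.0 / p.alpha)
    ds = p.beta * z - p.kappa * s - p.gamma * (f - 1.0)
    df = s
    dv = p.transit_rate * (f - f_out)
    extraction = (1.0 - (1.0 - p.e0) ** (1.0 / f)) / p.e0
    dq = p.transit_rate * (f * extraction - f_out * q / v)
    return ds, df, dv, dq


def bold_from_state(state: HDMState, p: HDMParams) -> float:
    """BOLD observation (percent signal change) at one state."""
    k1, k2, k3 = p.bold_coefficients()
    v, q = state.v, state.q
    return 100.0 * p.v0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))


# ---------------------------------------------------------------------------
# batched integration core


def _param_arrays(params, batch: int) -> dict[str, np.ndarray]:
    """Broadcast HDMParams (one instance or a sequence) to per-batch arrays."""
    if isinstance(params, HDMParams):
        params = [params] * batch
    if len(params) != batch:
        raise ValueError("number of parameter sets must match batch size")
    names = ("beta", "kappa", "gamma", "transit_rate", "alpha",
             "e0", "v0", "theta0", "r0", "eps_h", "te")
    return {n: np.array([getattr(p, n) for p in params], dtype=float) for n in names}


def _deriv_log(x: np.ndarray, z: np.ndarray, par: dict[str, np.ndarray]) -> np.ndarray:
    """Derivatives of (s, log f, log v, log q), vectorised over the batch."""
    s = x[:, 0]
    lf, lv, lq = x[:, 1], x[:, 2], x[:, 3]
    f = np.exp(lf)
    inv_alpha = 1.0 / par["alpha"]
    ds = par["beta"] * z - par["kappa"] * s - par["gamma"] * (f - 1.0)
    dlf = s * np.exp(-lf)
    # (f - v^{1/a}) / v  and  (f E(f)/E0 / q - v^{1/a}/v), in log coordinates
    fout_over_v = np.exp(lv * (inv_alpha - 1.0))
    dlv = par["transit_rate"] * (f * np.exp(-lv) - fout_over_v)
    extraction = (1.0 - (1.0 - par["e0"]) ** np.exp(-lf)) / par["e0"]
    dlq = par["transit_rate"] * (f * extraction * np.exp(-lq) - fout_over_v)
    return np.stack([ds, dlf, dlv, dlq], axis=1)


_LOG_BOUND = 30.0  # |log state| beyond this is treated as divergence


def integrate_batch(
    params,
    z: np.ndarray,
    dt: float,
    on_divergence: str = "raise",
) -> np.ndarray:
    """Integrate a batch of hemodynamic systems with RK4.

    Parameters
    ----------
    params
        One :class:`HDMParams` (shared) or a sequence of length ``B``.
    z
        Neural input, shape ``(B, n_steps)``; ``z[:, i]`` drives the step from
        ``t = i*dt`` to ``(i+1)*dt`` (piecewise-constant input).
    dt
        Integration step (s).
    on_divergence
        ``"raise"`` (default) raises :class:`FloatingPointError` naming the
        offending parameter regime; ``"nan"`` instead fills the diverging
        rows with NaN from the point of divergence and continues the rest
        of the batch (used by optimisers probing unstable regimes).

    Returns
    -------
    ndarray, shape ``(B, n_steps + 1)``
        BOLD percent signal on the grid ``t = 0, dt, ..., n_steps*dt``,
        starting from rest.
    """
    if on_divergence not in ("raise", "nan"):
        raise ValueError("on_divergence must be 'raise' or 'nan'")
    z = np.atleast_2d(np.asarray(z, dtype=float))
    B, n_steps = z.shape
    par = _param_arrays(params, B)
    x = np.zeros((B, 4))  # rest: s=0, log f = log v = log q = 0
    k1c, k2c, k3c = (4.3 * par["theta0"] * par["e0"] * par["te"],
                     par["eps_h"] * par["r0"] * par["e0"] * par["te"],
                     1.0 - par["eps_h"])

    # Explicit RK4 is only stable while dt times the fastest local rate
    # (the volume equation's transit_rate/alpha dominates) stays below its
    # stability bound; stiff parameter draws are integrated with an integer
    # number of substeps per output bin.  Default parameters use one.
    max_rate = float(np.max(np.maximum(par["transit_rate"] / par["alpha"],
                                       par["kappa"] + par["gamma"])))
    n_sub = max(1, int(np.ceil(dt * max_rate / 1.2)))

    def bold(xx):
        v = np.exp(xx[:, 2])
        q = np.exp(xx[:, 3])
        return 100.0 * par["v0"] * (k1c * (1.0 - q) + k2c * (1.0 - q / v)
                                    + k3c * (1.0 - v))

    y = np.empty((B, n_steps + 1))
    y[:, 0] = bold(x)
    z_prev = np.zeros(B)
    diverged = np.zeros(B, dtype=bool)
    with np.errstate(over="ignore", invalid="ignore"):
        for i in range(n_steps):
            zi = z[:, i]
            # bins where the drive switches restart the dynamics from a
            # kink; refining them keeps the local error fourth-order
            ns = n_sub * (4 if np.any(zi != z_prev) else 1)
            z_prev = zi
            h = dt / ns
            half = 0.5 * h
            for _ in range(ns):
                a = _deriv_log(x, zi, par)
                b = _deriv_log(x + half * a, zi, par)
                c = _deriv_log(x + half * b, zi, par)
                d = _deriv_log(x + h * c, zi, par)
                x = x + (h / 6.0) * (a + 2.0 * b + 2.0 * c + d)
            bad = (~np.all(np.isfinite(x), axis=1)
                   | (np.max(np.abs(x[:, 1:]), axis=1) > _LOG_BOUND))
            if np.any(bad & ~diverged):
                if on_divergence == "raise":
                    j = int(np.flatnonzero(bad)[0])
                    regime = {k: float(v[j]) for k, v in par.items()
                              if k in ("beta", "kappa", "gamma",
                                       "transit_rate", "alpha")}
                    raise FloatingPointError(
                        f"hemodynamic integration diverged at "
                        f"t={(i + 1) * dt:.3f} s for parameter regime {regime}"
                    )
                diverged |= bad
                x[diverged] = 0.0  # park at rest; outputs stay NaN below
            y[:, i + 1] = bold(x)
            if np.any(diverged):
                y[diverged, i + 1] = np.nan
    return y


def integrate(
    p: HDMParams,
    neural: NeuralInput,
    dt: float | None = None,
    duration_s: float | None = None,
) -> np.ndarray:
    """Integrate one system; returns BOLD on the ``dt`` grid (length n+1).

    ``dt`` defaults to the input's grid step; if ``duration_s`` extends past
    the input, the drive is zero-padded (post-stimulus evolution).
    """
    dt = neural.dt if dt is None else dt
    if dt <= 0:
        raise ValueError("dt must be positive")
    if abs(dt - neural.dt) > 1e-12:
        raise ValueError("integration dt must match the neural input grid")
    z = neural.z
    if duration_s is not None:
        n_steps = int(round(duration_s / dt))
        if n_steps < 1:
            raise ValueError("duration must cover at least one step")
        if n_steps > len(z):
            z = np.concatenate([z, np.zeros(n_steps - len(z))])
        else:
            z = z[:n_steps]
    return integrate_batch(p, z[None, :], dt)[0]


def downsample_to_scans(
    y: np.ndarray,
    dt: float,
    tr_s: float,
    n_scans: int,
    offset_s: float = 0.0,
) -> np.ndarray:
    """Sample a dt-grid series at scan acquisition times by linear interpolation.

    ``offset_s`` shifts all scan times (e.g. to a middle-slice reference).
    """
    if tr_s <= 0 or n_scans <= 0:
        raise ValueError("tr_s and n_scans must be positive")
    grid = np.arange(len(y)) * dt
    times = np.arange(n_scans) * tr_s + offset_s
    if times[0] < grid[0] - 1e-9 or times[-1] > grid[-1] + 1e-9:
        raise ValueError(
            f"scan times [{times[0]:.3f}, {times[-1]:.3f}] s fall outside the "
            f"integrated grid [0, {grid[-1]:.3f}] s"
        )
    return np.interp(times, grid, y)


# ---------------------------------------------------------------------------
# Volterra kernels


def _impulse_train(times: np.ndarray, n_steps: int, dt: float) -> np.ndarray:
    z = np.zeros(n_steps)
    for t in np.atleast_1d(times):
        k = int(round(t / dt))
        if 0 <= k < n_steps:
            z[k] += 1.0
    return z


def volterra_kernel1(
    p: HDMParams,
    lag_grid: np.ndarray,
    dt: float = DEFAULT_DT,
) -> np.ndarray:
    """First-order Volterra kernel: BOLD response at each lag after one
    unit impulse (one integration bin of unit neural drive)."""
    lag_grid = np.asarray(lag_grid, dtype=float)
    if np.any(lag_grid < 0):
        raise ValueError("lags must be non-negative")
    n_steps = int(np.ceil(lag_grid.max() / dt)) + 1
    z = _impulse_train(np.array([0.0]), n_steps, dt)
    y = integrate_batch(p, z[None, :], dt)[0]
    return np.interp(lag_grid, np.arange(n_steps + 1) * dt, y)


def volterra_kernel2(
    p: HDMParams,
    lag_grid: np.ndarray,
    dt: float = DEFAULT_DT,
) -> np.ndarray:
    """Second-order Volterra kernel on a lag-pair grid.

    ``K2[i, j]`` is the response at lags ``(sigma_i, sigma_j)`` after an
    impulse pair, minus the sum of the two isolated first-order responses —
    the nonlinear interaction (saturation/refractoriness) of responses to
    stimuli separated by ``|sigma_i - sigma_j|``.  Symmetric by construction;
    computed by integrating the full nonlinear system for every distinct
    pair separation in one batched pass.
    """
    lags = np.asarray(lag_grid, dtype=float)
    if np.any(lags < 0):
        raise ValueError("lags must be non-negative")
    m = len(lags)
    k1 = volterra_kernel1(p, lags, dt=dt)
    # distinct separations; impulses at t=0 and t=delta, response read at the
    # larger lag (time since first impulse)
    deltas = sorted({round(abs(lags[j] - lags[i]), 6) for i in range(m) for j in range(m)})
    n_steps = int(np.ceil(lags.max() / dt)) + 1
    zs = np.stack([_impulse_train(np.array([0.0, d]), n_steps, dt) for d in deltas])
    ys = integrate_batch(p, zs, dt)
    grid = np.arange(n_steps + 1) * dt
    pair_resp = {d: np.interp(lags, grid, ys[k]) for k, d in enumerate(deltas)}
    K2 = np.empty((m, m))
    for i in range(m):
        for j in range(i, m):
            d = round(abs(lags[j] - lags[i]), 6)
            big = max(lags[i], lags[j])
            y_pair = np.interp(big, lags, pair_resp[d]) if m > 1 else pair_resp[d][0]
            K2[i, j] = K2[j, i] = y_pair - k1[i] - k1[j]
    return K2


def second_order_variance_fraction(
    onsets: np.ndarray,
    p: HDMParams,
    dt: float = DEFAULT_DT,
    memory_s: float = 32.0,
    duration_s: float | None = None,
) -> float:
    """Fraction of kernel-explained timeseries variance carried by the
    second-order (pairwise-interaction) kernel over a given event design.

    The first-order contribution is the superposition of isolated impulse
    responses; the second-order contribution sums the pairwise interaction
    kernel over all event pairs closer than ``memory_s``.  Returns
    ``var(y2) / var(y1 + y2)``.
    """
    onsets = np.sort(np.asarray(onsets, dtype=float))
    if duration_s is None:
        duration_s = onsets.max() + memory_s
    t = np.arange(0.0, duration_s + dt / 2, dt)
    lag_grid = np.arange(0.0, memory_s + dt / 2, dt)
    k1 = volterra_kernel1(p, lag_grid, dt=dt)
    y1 = np.zeros_like(t)
    for t0 in onsets:
        lags = t - t0
        mask = (lags >= 0) & (lags <= memory_s)
        y1[mask] += np.interp(lags[mask], lag_grid, k1)
    # pairwise interactions
    pairs = [(a, b) for i, a in enumerate(onsets) for b in onsets[i + 1:]
             if (b - a) <= memory_s]
    y2 = np.zeros_like(t)
    if pairs:
        K2 = volterra_kernel2(p, lag_grid, dt=dt)
        grid_step = lag_grid[1] - lag_grid[0]
        for a, b in pairs:
            lags_b = t - b
            mask = (lags_b >= 0) & (t - a <= memory_s)
            la = (t[mask] - a) / grid_step
            lb = lags_b[mask] / grid_step
            ia = np.clip(la.astype(int), 0, len(lag_grid) - 2)
            ib = np.clip(lb.astype(int), 0, len(lag_grid) - 2)
            wa, wb = la - ia, lb - ib
            vals = ((1 - wa) * (1 - wb) * K2[ia, ib]
                    + wa * (1 - wb) * K2[ia + 1, ib]
                    + (1 - wa) * wb * K2[ia, ib + 1]
                    + wa * wb * K2[ia + 1, ib + 1])
            y2[mask] += vals
    total = np.var(y1 + y2)
    if total <= 0:
        raise ValueError("design explains zero variance; fraction undefined")
    return float(np.var(y2) / total)


def with_params(p: HDMParams, **kwargs) -> HDMParams:
    """Return a copy of ``p`` with the given fields replaced."""
    return replace(p, **kwargs)
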