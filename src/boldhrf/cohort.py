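"""Synthetic cohorts with known age-dependent hemodynamic parameters.

The generator emulates the structure of a lifespan event-related fMRI
study: ages drawn uniformly on 18-88 years, an m-sequence event design
(base SOA 2 s, jitter U(0.1, 0.3) s), and per-participant biophysical
parameters whose decay rate rises and transit rate falls with age.  Each
region of interest contains several voxels sharing one balloon-model BOLD
signal, corrupted by AR(1) scanner noise, slow drift and small leakage
from eight confound regressors (six motion-like, two compartment-like),
with the grand mean scaled to 100.  Because every participant's true
parameters are recorded, downstream estimators can be validated against a
known ground truth.

Age enters rate parameters on the log scale (multiplicative deviations
from the prior expectation) and the neural efficacy on the linear scale,
matching the estimation scale used at inversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import hdm
from .design import EventSequence, assign_trial_types, build_event_timing, generate_msequence

__all__ = [
    "ParamAgeModel",
    "ROIProfile",
    "NoiseSpec",
    "DesignSpec",
    "CohortSpec",
    "SyntheticParticipant",
    "CohortDataset",
    "sample_ages",
    "sample_parameters",
    "simulate_roi_timeseries",
    "generate_cohort",
]

#: Parameters of the hemodynamic model that the generator varies.
FREE_PARAMS = ("beta", "kappa", "transit_rate")
_LOG_SCALE = ("kappa", "transit_rate")


@dataclass(frozen=True)
class ParamAgeModel:
    """Linear age model for one free parameter.

    Rate parameters: ``value = prior_mean * exp(intercept + slope * z(age)
    + N(0, sd^2))``; neural efficacy: ``value = intercept + slope * z(age)
    + N(0, sd^2)`` (linear scale).  ``z(age)`` is the population z-score
    under the cohort's uniform age distribution.
    """

    intercept: float = 0.0
    slope: float = 0.0
    sd: float = 0.0

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("between-subject SD must be non-negative")


@dataclass(frozen=True)
class ROIProfile:
    """Voxel count and signal/noise composition of one region."""

    n_voxels: int = 12
    shared_signal_fraction: float = 0.9
    voxel_noise_sd: float = 0.3

    def __post_init__(self):
        if self.n_voxels < 1:
            raise ValueError("each ROI needs at least one voxel")
        if not (0 <= self.shared_signal_fraction <= 1):
            raise ValueError("shared_signal_fraction must lie in [0, 1]")
        if self.voxel_noise_sd < 0:
            raise ValueError("voxel_noise_sd must be non-negative")


@dataclass(frozen=True)
class NoiseSpec:
    """Scanner noise: AR(1) innovations, slow drift, confound leakage.

    ``confound_leakage`` bounds the uniform leakage coefficients of the
    eight confound series into each voxel, as a fraction of the shared
    signal's standard deviation.
    """

    ar1_coefficient: float = 0.2
    innovation_sd: float = 0.6
    drift_amplitude: float = 0.5
    confound_leakage: float = 0.1

    def __post_init__(self):
        if not (-1 < self.ar1_coefficient < 1):
            raise ValueError("|ar1_coefficient| must be < 1")
        if self.innovation_sd < 0 or self.drift_amplitude < 0:
            raise ValueError("noise amplitudes must be non-negative")
        if self.confound_leakage < 0:
            raise ValueError("confound_leakage must be non-negative")


@dataclass(frozen=True)
class DesignSpec:
    """Scanning and event-schedule geometry."""

    tr_s: float = 1.97
    n_scans: int = 261
    base_soa_s: float = 2.0
    jitter_low_s: float = 0.1
    jitter_high_s: float = 0.3
    msequence_degree: int = 8

    def __post_init__(self):
        if self.tr_s <= 0 or self.n_scans <= 0:
            raise ValueError("tr_s and n_scans must be positive")

    @property
    def run_length_s(self) -> float:
        return self.n_scans * self.tr_s


def _default_age_models() -> dict:
    return {
        "beta": ParamAgeModel(intercept=0.6, slope=0.0, sd=0.15),
        "kappa": ParamAgeModel(intercept=0.0, slope=0.2, sd=0.15),
        "transit_rate": ParamAgeModel(intercept=0.0, slope=-0.2, sd=0.15),
    }


def _default_rois() -> dict:
    return {
        "auditory": ROIProfile(n_voxels=12),
        "visual": ROIProfile(n_voxels=10),
        "motor_contra": ROIProfile(n_voxels=8),
        "motor_ipsi": ROIProfile(n_voxels=6),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for one synthetic cohort."""

    n_participants: int = 20
    age_low: float = 18.0
    age_high: float = 88.0
    param_age_models: dict = field(default_factory=_default_age_models)
    roi_profiles: dict = field(default_factory=_default_rois)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    design: DesignSpec = field(default_factory=DesignSpec)
    base_params: hdm.HDMParams = field(default_factory=hdm.HDMParams)
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 0:
            raise ValueError("n_participants must be non-negative")
        if self.age_low > self.age_high:
            raise ValueError("age_low must not exceed age_high")
        unknown = set(self.param_age_models) - set(FREE_PARAMS)
        if unknown:
            raise ValueError(f"age models for unknown parameters: {sorted(unknown)}")

    def age_zscore(self, age: float | np.ndarray) -> np.ndarray:
        """Population z-score of age under U(age_low, age_high)."""
        mean = 0.5 * (self.age_low + self.age_high)
        sd = (self.age_high - self.age_low) / np.sqrt(12.0)
        if sd == 0:
            return np.zeros_like(np.asarray(age, dtype=float))
        return (np.asarray(age, dtype=float) - mean) / sd


@dataclass(frozen=True)
class SyntheticParticipant:
    """One simulated participant with its generating truth."""

    age: float
    true_params: dict          # ROI name -> HDMParams
    events: EventSequence
    voxel_data: dict           # ROI name -> (n_scans, n_voxels)
    confounds: np.ndarray      # (n_scans, 8)
    seed: int

    def __post_init__(self):
        if self.confounds.shape[1] != 8:
            raise ValueError("expected 8 confound regressors")
        for name, mat in self.voxel_data.items():
            if mat.shape[0] != self.confounds.shape[0]:
                raise ValueError(f"ROI {name}: scan count mismatch")


@dataclass(frozen=True)
class CohortDataset:
    """A generated cohort plus its recipe (the truth record)."""

    spec: CohortSpec
    participants: list

    @property
    def ages(self) -> np.ndarray:
        return np.array([s.age for s in self.participants])

    def true_parameter(self, name: str, roi: str) -> np.ndarray:
        return np.array([getattr(s.true_params[roi], name)
                         for s in self.participants])


def sample_ages(spec: CohortSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Ages uniform on [age_low, age_high]; reproducible given the spec seed."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    return rng.uniform(spec.age_low, spec.age_high, size=spec.n_participants)


def sample_parameters(
    age: float,
    spec: CohortSpec,
    rng: np.random.Generator,
) -> hdm.HDMParams:
    """Draw one participant's biophysical parameters given age."""
    if not (spec.age_low <= age <= spec.age_high):
        raise ValueError(f"age {age} outside cohort range")
    z = float(spec.age_zscore(age))
    updates = {}
    for name in FREE_PARAMS:
        model = spec.param_age_models.get(name, ParamAgeModel())
        lin = model.intercept + model.slope * z + (
            rng.normal(0.0, model.sd) if model.sd > 0 else 0.0
        )
        if name in _LOG_SCALE:
            updates[name] = getattr(spec.base_params, name) * float(np.exp(lin))
        else:
            updates[name] = float(lin)
    return replace(spec.base_params, **updates)


def _ar1_series(n: int, rho: float, innovation_sd: float,
                rng: np.random.Generator) -> np.ndarray:
    e = rng.standard_normal(n) * innovation_sd
    x = np.empty(n)
    x[0] = e[0] / np.sqrt(max(1.0 - rho**2, 1e-12))  # stationary start
    for i in range(1, n):
        x[i] = rho * x[i - 1] + e[i]
    return x


def make_confounds(n_scans: int, rng: np.random.Generator) -> np.ndarray:
    """Eight nuisance series: six motion-like random walks and two
    compartment-like (slowly varying AR) series, each standardised."""
    cols = []
    for _ in range(6):
        walk = np.cumsum(rng.standard_normal(n_scans))
        cols.append(walk)
    for _ in range(2):
        cols.append(_ar1_series(n_scans, 0.9, 1.0, rng))
    C = np.column_stack(cols)
    C = C - C.mean(axis=0)
    sd = C.std(axis=0)
    sd[sd == 0] = 1.0
    return C / sd


def simulate_roi_timeseries(
    params: hdm.HDMParams,
    events: EventSequence,
    roi: ROIProfile,
    noise: NoiseSpec,
    design: DesignSpec,
    rng: np.random.Generator,
    confounds: np.ndarray | None = None,
    shared_signal: np.ndarray | None = None,
    dt: float = hdm.DEFAULT_DT,
) -> np.ndarray:
    """Simulate one ROI's (n_scans, n_voxels) data matrix.

    Every voxel carries the same balloon-model BOLD signal (scaled by the
    shared-signal fraction) on a baseline of 100, plus voxel-specific AR(1)
    noise, white voxel noise, a slow cosine drift and small random leakage
    of the confound series; the matrix is then rescaled to grand mean 100.
    Pass ``shared_signal`` to reuse a precomputed scan-grid prediction.
    """
    if design.tr_s <= 0 or design.n_scans <= 0:
        raise ValueError("non-positive TR or scan count")
    n_scans = design.n_scans
    if shared_signal is None:
        if len(events.onsets) and events.onsets.max() >= design.run_length_s:
            raise ValueError("events extend beyond the scan window")
        neural = hdm.NeuralInput.from_events(
            events.onsets, dt, dt, design.run_length_s + dt
        )
        y_fine = hdm.integrate(params, neural)
        shared_signal = hdm.downsample_to_scans(y_fine, dt, design.tr_s, n_scans)
    sig = roi.shared_signal_fraction * shared_signal
    sig_sd = max(sig.std(), 1e-12)
    t = np.arange(n_scans) * design.tr_s
    Y = np.empty((n_scans, roi.n_voxels))
    for j in range(roi.n_voxels):
        voxel = 100.0 + sig
        if noise.innovation_sd > 0:
            voxel = voxel + _ar1_series(n_scans, noise.ar1_coefficient,
                                        noise.innovation_sd, rng)
        if roi.voxel_noise_sd > 0:
            voxel = voxel + rng.standard_normal(n_scans) * roi.voxel_noise_sd
        if noise.drift_amplitude > 0:
            period = rng.uniform(128.0, 4.0 * 128.0)
            phase = rng.uniform(0.0, 2 * np.pi)
            voxel = voxel + noise.drift_amplitude * np.cos(
                2 * np.pi * t / period + phase
            )
        if confounds is not None and noise.confound_leakage > 0:
            leak = rng.uniform(-noise.confound_leakage, noise.confound_leakage,
                               size=confounds.shape[1]) * sig_sd
            voxel = voxel + confounds @ leak
        Y[:, j] = voxel
    return Y * (100.0 / Y.mean())


def generate_cohort(spec: CohortSpec) -> CohortDataset:
    """Generate a full cohort, deterministic given ``spec.seed``.

    Shared balloon-model signals for all participants and ROIs are
    integrated in a single batched pass.
    """
    root = np.random.SeedSequence(spec.seed)
    age_seed, *participant_seeds = root.spawn(spec.n_participants + 1)
    ages = sample_ages(spec, np.random.default_rng(age_seed))
    roi_names = list(spec.roi_profiles)
    d = spec.design

    # first pass: events and true parameters per participant
    events_list, params_list = [], []
    rngs = []
    for i in range(spec.n_participants):
        rng = np.random.default_rng(participant_seeds[i])
        rngs.append(rng)
        seq = generate_msequence(d.msequence_degree)
        ev = build_event_timing(seq, d.base_soa_s, d.jitter_low_s,
                                d.jitter_high_s, rng)
        n_ev = len(ev)
        if n_ev == 128:
            ev = assign_trial_types(ev, rng=rng)
        keep = ev.onsets < d.run_length_s
        if not np.all(keep):
            ev = EventSequence(onsets=ev.onsets[keep], durations=ev.durations[keep],
                               trial_types=ev.trial_types[keep],
                               jitters=ev.jitters[keep])
        events_list.append(ev)
        params_list.append({
            roi: sample_parameters(ages[i], spec, rng) for roi in roi_names
        })

    # one batched integration for every (participant, ROI) signal
    dt = hdm.DEFAULT_DT
    duration = d.run_length_s + dt
    flat_params, flat_z = [], []
    for i in range(spec.n_participants):
        z = hdm.NeuralInput.from_events(events_list[i].onsets, dt, dt, duration).z
        for roi in roi_names:
            flat_params.append(params_list[i][roi])
            flat_z.append(z)
    shared = {}
    if flat_params:
        Yfine = hdm.integrate_batch(flat_params, np.stack(flat_z), dt)
        r = 0
        for i in range(spec.n_participants):
            for roi in roi_names:
                shared[(i, roi)] = hdm.downsample_to_scans(
                    Yfine[r], dt, d.tr_s, d.n_scans
                )
                r += 1

    participants = []
    for i in range(spec.n_participants):
        rng = rngs[i]
        confounds = make_confounds(d.n_scans, rng)
        voxel_data = {
            roi: simulate_roi_timeseries(
                params_list[i][roi], events_list[i], spec.roi_profiles[roi],
                spec.noise, d, rng, confounds=confounds,
                shared_signal=shared[(i, roi)],
            )
            for roi in roi_names
        }
        participants.append(SyntheticParticipant(
            age=float(ages[i]),
            true_params=params_list[i],
            events=events_list[i],
            voxel_data=voxel_data,
            confounds=confounds,
            seed=i,  # spawn index under the cohort's root seed sequence
        ))
    return CohortDataset(spec=spec, participants=participants)
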