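# Methods

This note documents the models, the numerical choices behind them, what the
synthetic data do and do not emulate, and the package's known limitations.

## Hemodynamic forward model

The generative model couples a neurovascular input stage to the balloon
model. Neural drive `z(t) ∈ {0,1}` (a boxcar of one integration bin per
trial by default) produces a vasoactive signal `s` with efficacy `β`, decay
rate `κ` and autoregulatory feedback `γ`; the signal drives inflow `f_in`,
which inflates venous volume `v` against outflow `f_out(v) = v^{1/α}` and
dilutes deoxyhemoglobin `q` at transit rate `λ = 1/τ_h`, with oxygen
extraction `E(f) = 1 − (1−E₀)^{1/f}`. The BOLD observation is
`y = 100·V₀·[k₁(1−q) + k₂(1−q/v) + k₃(1−v)]` with
`k₁ = 4.3·ϑ₀·E₀·TE`, `k₂ = ε_h·r₀·E₀·TE`, `k₃ = 1 − ε_h`.

Fixed constants (defaults, all exposed): `γ = 0.41 Hz`, `α = 0.32`,
`E₀ = 0.4`, `V₀ = 0.04`, `ϑ₀ = 40.3 Hz`, `r₀ = 25 Hz`, `ε_h = 1`,
`TE = 30 ms`. Prior expectations of the free rates: decay `κ = 0.64 Hz`,
transit `λ = 1.02 Hz`. These are conventional 3 T gradient-echo values;
they are assumptions of this package, not fitted quantities.

### Integration

Classical RK4 on the transformed state `(s, log f_in, log v, log q)` at a
default step of 0.375 s; the log coordinates make positivity of flow,
volume and deoxyhemoglobin structural. Two refinements keep the default
step honest:

- *Stability.* The volume equation's local rate `λ/α` bounds the explicit
  step; parameter draws with fast transit are integrated with
  `ceil(dt·rate/1.2)` substeps per bin. Default parameters use one.
- *Accuracy at input transitions.* Bins where `z` switches start from a
  kink in the vector field; they are refined ×4, which restores
  fourth-order convergence of the whole trajectory (relative L2 change
  under halving the step from 0.375 s to 0.1875 s is < 10⁻³; against a
  tight adaptive-solver reference the error ratio under halving is ≈ 2⁴).

The model has **no valid fixed point for sustained drive `βz < −γ`**
(inflow would have to be negative), and trajectories genuinely diverge for
efficacies below roughly −0.7 under dense stimulation with slow signal
decay. `integrate_batch` either raises a diagnostic error naming the
parameter regime or, for optimisers probing such regimes
(`on_divergence="nan"`), returns NaN for the offending batch rows so the
proposal can be rejected.

### Volterra kernels

The first-order kernel is the response to one unit impulse; the
second-order kernel `K₂(σ₁, σ₂)` is the response to an impulse pair minus
the two isolated responses, computed by direct integration of the full
nonlinear system for every distinct pair separation (batched), symmetric by
construction. The second-order variance fraction of a design is
`var(y₂)/var(y₁+y₂)` where `y₁` superposes first-order responses over the
event train and `y₂` sums pairwise interactions within a 32 s memory.

## First-level GLM

Regressors are built in microtime (32 bins per TR; at TR = 1.97 s the
resolution is 0.0616 s, reported as 0.062 s), convolving a delta train at
event onsets with each basis column and sampling at the middle microtime
bin of each scan (reference-slice offset 0 for synthetic data). Data are
scaled to a grand mean of 100. A discrete-cosine set high-passes model and
data at 1/128 Hz; the number of non-constant cosines is
`floor(2·T/128)` (a stated convention of this package). Error covariance is
`w₀I + w₁Q_AR` with a fixed AR coefficient of 0.2 in `Q_AR` (off-diagonal
only); weights are estimated by ReML Fisher scoring (converges when the
step falls below 10⁻⁶ relative, cap 32 iterations), and `V^{-1/2}` whitens
both model and data before OLS. F-statistics use extra sums of squares with
residual degrees of freedom `n − rank(X)`.

Voxels pass selection at F-test p < 0.05 uncorrected; a participant with no
surviving voxel is excluded (mirroring real-study practice). The ROI
summary is the first left singular vector of the confound-adjusted,
whitened voxel matrix, scaled by `σ₁/√n_voxels` and signed so the mean
voxel weight is positive.

The second-level FIR model regresses each post-stimulus bin on a constant,
z-scored age and its square, with spanning F-tests computed by extra sums
of squares in a long-format GLM.

## NLF template fit

The template is the first right singular vector of the participants × bins
FIR matrix, signed so its dominant extremum within 8 s is positive. The
warp is applied as `Y(t₁·t − t₀)` (an option provides `Y((t−t₀)/t₁)`, since
both compositions are defensible); linear interpolation, zero outside
support; bounds `t₀ ∈ [−4, 4] s`, `t₁ ∈ [0.5, 2]`. Because Pearson
correlation is affine-invariant, the warp is fit first — multi-start
(3 × 3 grid plus identity) coordinate ascent with step halving, tie-broken
toward the identity warp — and the amplitude pair `(a₁, a₀)` follows by
closed-form least squares. Recovery is validated against an exhaustive
0.01-resolution grid search.

## Variational Laplace inversion

Observation model `y = g(θ) + X₀b₀ + e`, `e ~ N(0, e^{−λ}I)`; nuisance
columns (constant, drift cosines) carry flat priors (variance 10⁶) and are
estimated jointly. Estimation scale: rates as log deviations from their
prior expectations (prior variance 1/16), efficacy linear (prior mean 0,
variance 1 — priors are configurable per fit). The noise log-precision has
a Gaussian hyperprior with mean set from the data variance and variance 16.

Each iteration: central-difference Jacobian (step 10⁻⁴), Newton update of
λ, Gauss–Newton step with Levenberg–Marquardt damping, explicit
accept/reject on the free energy (so the accepted trace is non-decreasing);
convergence when |ΔF| < 0.01 four times in a row, cap 64 iterations. All
participants or replicates sharing a scan grid are fitted in one batched
pass — every finite-difference perturbation of every run goes through a
single vectorised integration per iteration, which is what makes
200-participant inversions take seconds rather than hours.

Calibration: with truth drawn from the fitting prior (positive-efficacy
regime β ~ N(0.6, 0.2²), rates N(0, 0.25²)) and iid noise at the default
cohort level, pooled 90 % credible-interval coverage over 200 replicates is
within 5 percentage points of nominal, with a slight undercoverage typical
of Laplace approximations.

## PEB and Bayesian model reduction

The group model treats each participant's posterior `(μᵢ, Σᵢ)` as data:
`μᵢ ~ N(Xᵢ·B, Σᵢ + Σ_b)` with covariates (constant, z-scored age), a
Gaussian prior on the effects `B` (variance 1 per effect), and diagonal
between-participant covariance `Σ_b` initialised at 1/16 of each
parameter's first-level prior variance and optimised on the log scale by
Nelder–Mead ascent of the closed-form evidence. Because the model is
linear-Gaussian, posterior and evidence are exact, and reduction to any
altered prior (an effect switched off = prior variance 10⁻⁸) is analytic.
The search over on/off mixtures of age effects is exhaustive up to 2⁸
models, greedy backward beyond; retained effects are reported with 90 %
credible intervals. Reduction agrees with explicit refits to < 10⁻³ and is
invariant to parameter ordering.

## Synthetic cohorts

The generator emulates: ages uniform on 18–88; per-participant degree-8
m-sequence designs (255 slots, SOA 2 s, jitter U(0.1, 0.3) s, 120/4/4
trial-type split) over 261 scans at TR 1.97 s; age trends applied on the
estimation scale (default slopes per SD of age: decay +0.2, transit −0.2,
efficacy 0; between-participant SD 0.15; efficacy intercept 0.6); ROIs of
6–12 voxels sharing one balloon-model signal (shared fraction 0.9); AR(1)
scanner noise (coefficient 0.2, innovation SD 0.6), white voxel noise (SD
0.3), slow cosine drift (amplitude 0.5, period 128–512 s), and ≤ 10 %
leakage of eight confound series (six motion-like random walks, two
compartment-like AR series); grand mean 100. Noise levels were set so
single-voxel task R² falls in roughly 0.2–0.35, a plausible event-related
fMRI regime. Everything is deterministic given the cohort seed
(per-participant seed-sequence spawning).

Not emulated: volumetric imaging and spatial preprocessing, physiological
(cardiac/respiratory) noise, age-dependent residual variance (configurable
but off by default), MEG, and task behaviour. Passing tests therefore
demonstrate estimator correctness and attribution power under the stated
generative assumptions — not robustness to artefacts the generator does
not produce.

## Problem sizes used by the test suite

End-to-end validation fits 200 participants (single ROI, full first-level
path) for the age-trend and age-prediction checks; group-reduction pattern
checks use a 120-participant cohort with single-voxel ROIs read out
directly; coverage uses 200 replicates of a compact degree-6 design
(64 scans at TR 2 s). These sizes were chosen to make the full suite run in
a few minutes while leaving all statistical margins comfortable.

## Known limitations

- Through the full multi-voxel path (selection, whitening, SVD summary),
  the fitted efficacy acquires a small systematic age trend (≈ −0.03 per SD
  of age at default settings) even when none is injected — an artefact of
  age-dependent summary scaling. It is far smaller than the vascular
  effects but, with ~100+ participants, strong enough that model reduction
  correctly declines to prune it. Analyses that hinge on small efficacy
  effects should calibrate this bias on matched synthetic cohorts first.
- Strongly negative efficacy (pronounced negative responses) sits near the
  model's inflow singularity; such regimes may be flagged divergent rather
  than fitted.
- The Laplace posterior slightly undercovers (≈ 87 % at nominal 90 % in the
  default regime); group-level conclusions inherit this.
- The NLF warp's two compositions (`Y(t₁t − t₀)` vs `Y((t−t₀)/t₁)`) fit
  equally well near the identity but parameter values are not comparable
  across conventions; the default is stated above and in the API.
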