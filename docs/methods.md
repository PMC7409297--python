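# Methods

## Model

`cachexsim` implements a stem-cell-lineage description of skeletal muscle
with two compartments, satellite cells S(t) and differentiated muscle cells
M(t), measured as tissue volume (mm³). An activated satellite cell divides
symmetrically: into two satellite cells with probability p, or two muscle
cells with probability 1−p, at rate ν. Both p and ν are decreasing
Hill-type functions of the muscle volume (shared half-saturation m), which
is the negative feedback that holds the tissue at homeostasis:

    dS/dt = (2p−1) ν S
    dM/dt = 2(1−p) ν S − d0 M,   p = p0 + p1/(1+M/m),  ν = ν0 + ν1/(1+M/m)

Because dS/dt changes sign at p = 1/2, a positive steady state requires
p0 < 1/2 < p0+p1; the closed forms are

    Mss = m (2(p0+p1)−1)/(1−2p0)
    Sss = 2 m d0 p1 (2(p0+p1)−1) / [(1−2p0)(2p1ν0 + (1−2p0)ν1)]
    ψss = Sss/Mss = 2 d0 p1 / (2p1ν0 + (1−2p0)ν1) ≤ d0/ν0.

Transients with p > 1/2 occur during normal growth and are permitted;
only the steady-state operations enforce the inequality (eagerly, with the
violated inequality named in the error).

A tumor grows by the exponential-linear law

    dT/dt = μT (1 + (T/Tth)^η)^(−1/η),  Tth = μ1/μ,  η = 20,

which is exponential (rate μ) below Tth and linear (rate μ1) above;
η = 20 makes the blend track the sharp piecewise law within 2 %. Tth is
always recomputed from (μ, μ1), never stored. The tumor perturbs the
healthy system through three saturating mechanisms sharing a
half-saturation m2: proliferation suppression 1 − εT/(m2+T) on ν, and
added death rates dS·T/(m2+T) and dM·T/(m2+T). The self-renewal
probability p is assumed unaffected by the tumor (stated model
assumption; implemented as stated). Treatment scales ε, dS, dM by
efficacies A1, A2, A3 and the natural death rate d0 by A4, all in [0,1],
from a start day t_start; the tumor itself is untreated. Setting
A1..A4 = 1 reproduces the cachexia system bit for bit, and ε = dS = dM = 0
reproduces the healthy system plus independent tumor growth — these
reduction identities are tested exactly.

## Units, conversions, and time origins

The model state is volume (mm³) internally; grams appear only at I/O
boundaries. Body weight deconstructs as 40 % skeletal lean mass, split
95 % muscle / 5 % satellite, converted by ξ = 0.002 g/mm³ (a 1000 mm³
tumor weighs 2 g). For tumor-bearing cohorts the lean mass is 40 % of
(weight − predicted tumor mass ξT).

Two IC recipes exist, both exposed:

* the 95/5 deconstruction of a measured weight (used for the 3-week-old,
  11.26 g reference mouse: S0 = 112.6, M0 = 2139.4 mm³), and
* the reference-ratio split of the 40 % lean volume at the day-49 stem
  ratio ψ49: M0 = 0.4W/((1+ψ49)ξ), S0 = ψ49·M0 (used for tumor-implant
  cohorts, keeping the feedback state age-appropriate).

Integrating the healthy model from the 3-week deconstruction ICs gives
ψ49 = S(49)/M(49) = 0.05266544 and the day-49 state (268.01, 5088.92) mm³
— exactly the printed 10-week reference volumes, whose ratio equals ψ49.
The package therefore treats those printed volumes as the day-49 state of
the growth solve, and all cohort ICs derive from ψ49 computed this way
(the printed Group A/B volumes are reproduced to the printed 0.01 mm³).

Time origins: healthy-model day 0 is age 3 weeks; cachexia/treatment day 0
is tumor implantation = healthy day 49 (a 10-week-old animal). Both are
recorded in trajectory metadata.

## Numerics

Integration uses LSODA (stiff-capable, adaptive) at rtol 1e−10 /
atol 1e−12 by default — the day-49 stem ratio is quoted to 7 significant
figures and reproduces under tolerance refinement to < 1e−6 relative. The
solution is sampled on the reporting grid, so refining the grid never
changes shared values. The tumor growth factor is evaluated in log space
(softplus form), since (T/Tth)^20 overflows for large tumors. Treatment
runs solve the cachexia system on [0, t_start), then the treatment system
from the switch state (state-continuous by construction); a
`treatment_from_zero` flag instead applies the treatment equations over
the whole window, since the original fitting convention is ambiguous —
the package asserts neither convention as "the" one.

Wound healing integrates the healthy model from (χSss, χMss) and defines
healing time as the first t with Mss − M(t) < 0.1 (model volume units,
mm³; the published threshold carries no units, so the gram reading
0.1 g = 50 mm³ is available as a knob). The crossing is resolved by root
finding (Brent) on the dense solution, not grid lookup. Healing times are
long (hundreds of days) because M approaches Mss asymptotically at rate
~d0; they grow monotonically and sub-linearly with injury size
(t(30 %)/t(10 %) < 3).

## Calibration

* **Logistic extension.** dW/dt = αW(1−W/K) fitted in closed form by
  nonlinear least squares (scipy `curve_fit`); W0 is fixed to the day-0
  observation when present. A constant series leaves α unidentifiable and
  is reported as such, not guessed. The observed record is extended by
  sampling the fitted curve every 10 days from day 90 to day 300 so the
  adult plateau constrains the feedback fit.
* **Simulated annealing** (healthy fit, p0, p1, ν0, ν1). The published
  procedure names the algorithm but no schedule; defaults are geometric
  cooling (factor 0.95), 200 temperatures × 50 proposals, per-parameter
  Gaussian proposals with reflective bounds, and the proposal scale
  annealed with √(T/T0) so the walk refines late in the schedule.
  Feasibility (0 < p0+p1 ≤ 1 and p0 < 1/2 < p0+p1) is enforced by
  rejection. The objective pools muscle and stem residuals unweighted in
  grams (a weight option exists because the stem series is ~19× smaller).
  An outer one-at-a-time loop re-runs the annealer over a small (d0, m)
  grid and keeps the global best. Every run records its seed, acceptance
  counts and objective trace, and is bit-reproducible from the seed. On
  noiseless self-generated data the fitted trajectory reproduces the data
  to < 0.01 g pooled RMSE; individual parameters can trade off along the
  p0/p1 ridge, so recovery is asserted on the trajectory, not per
  parameter.
* **Grid searches** (tumor, cachexia, treatment). Exhaustive evaluation of
  a supplied grid, returning the argmin and the full RMSE surface
  (retained so the ε ≈ 0 flat direction can be inspected; boundary argmins
  are flagged). All grid points are integrated simultaneously as one
  stacked vectorized ODE system (RK45, rtol 1e−8), which makes 10³–10⁴
  point grids interactive. The documented default ranges are generous
  (μ ∈ [0.05, 1] step 0.002, μ1 ∈ [10, 300] step 0.5, ε ∈ [0, 0.5],
  dS ∈ [0, 0.2], dM ∈ [0, 0.3] step 0.002, m2 ∈ [50, 1000] step 2,
  Ai ∈ [0, 1] step 0.01); the full 4-D products are astronomically large,
  so callers pass focused grids in practice. T(0) = 0.5 mm³ (the implant)
  and η = 20 are held fixed during tumor fitting.

## Sensitivity

φ = 100·(y(ρ(1±f)) − y(ρ))/y(ρ) with f = 5 % by default. At the healthy
steady state the observables are the closed forms; which parameters an
observable structurally contains is derived symbolically (sympy free
symbols), and the non-dependent cells are reported NA rather than 0 —
Mss contains only (m, p0, p1). The +5 % perturbation of p0 crosses the
p0 = 1/2 boundary; the closed form is evaluated anyway, reproducing the
documented extreme values (+22 541.6 % satellite, −964.1 % muscle), and
the row is flagged `unphysical_regime` instead of erroring. For cachexia
and treatment parameters the observables are S and M on day 20
post-implant (during active wasting; the cachectic animal never reaches a
steady state), re-solved per perturbation with the simulation defaults;
the evaluation day is configurable. Treatment sensitivities default to A3
and A4 only, since A1 = A2 = 0 in both group fits and a multiplicative
perturbation of zero is identically zero.

## Synthetic data

The generators state the world the calibration tests assume:

* healthy cohorts: closed-form logistic weights (α = 0.0756/day,
  K = 28.3 g, W0 = 11.26 g) on the published cadence (weekly to day 84,
  every 10 days to 300);
* cachectic/treated cohorts: the disease ODE solves from the day-0 weight
  ICs (Group A 25.26 g, Group B 25.10 g, T0 = 0.5 mm³), sampled daily to
  day 30, emitting lean mass ξ(S+M), gross weight lean/0.4 + ξT, and
  tumor volume.

Measurement noise is multiplicative Gaussian (CV 0.02 by default) on the
reported weights and tumor volumes, truncated at ±4σ to preserve
positivity; the published data carry no noise model, and proportional
error is what a scale produces. Reported lean mass is derived from the
noisy weight by the same deconstruction used in fitting, so at CV = 0 the
generator/deconstruction pair is a lossless round trip — this is what
makes exact parameter-recovery tests possible. The generators do not
simulate per-animal parameter heterogeneity or dropout; a green recovery
test therefore establishes estimator correctness under the assumed noise,
not robustness to biological random effects.

## Design notes and limitations

* The noisy-recovery test asserts (dS, dM) within one grid step in ≥ 90 %
  of 50 replicates using a 0.008/day step: the 1σ uncertainty of dS from
  31 daily lean observations at 2 % CV is ≈ 0.003/day, so a finer grid
  would turn the argmin location into a coin flip rather than a statement
  about the estimator.
* Earlier treatment keeps lean mass at or above later treatment at every
  shared day of the 30-day observation window; beyond ~day 33 the curves
  can cross, because both runs share the same treated equilibrium and the
  early run's transient overshoots then dips. The ordering claim is
  therefore asserted on the observation window only.
* Whole-window vs from-t_start treatment conventions differ measurably
  over the first weeks; both are supported and neither is asserted as the
  original fitting convention.
* Out of scope by design: asymmetric stem division, intermediate
  progenitor compartments, fiber-diameter atrophy, ActRIIA co-blockade,
  spatial/PDE structure, and inflammation/metabolism coupling. The
  molecular signaling cascade is represented only through the effective
  parameters (ε, dS, dM, m2, A1..A4).
* The published RMSE values of the original fits are context, not
  targets: the underlying digitized datasets are not available
  machine-readably, so the fitted parameter values are shipped as
  fixtures and all recomputable claims are derived quantities.
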