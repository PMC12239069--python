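# Methods

## The transport model

A microcapsule of diameter d_p (180–200 μm in the reference experiments)
whose polymer shell carries ppm-level loadings of superparamagnetic iron-oxide
nanoparticles is pulled toward a permanent magnet through a viscous fluid. In
the creeping-flow regime the magnetic body force and Stokes drag balance at
the terminal velocity

    v_t(x) = V_p · χ_eff / (3π η d_p μ0 (1 + χ_eff)²) · B_a(x) · dB_a/dx,

with V_p = π d_p³/6 the capsule volume, η the fluid's dynamic viscosity, μ0
the vacuum permeability and χ_eff the capsule's effective volume
susceptibility. Because V_p/(3π d_p) = d_p²/18, the speed scales with d_p²
at fixed χ_eff, with B_a² at fixed geometry, and linearly with χ_eff in the
dilute regime (χ_eff ≪ 1). The (1 + χ_eff)² denominator is implemented
exactly as stated and isolated in one helper (`dynamics._mobility`) so an
alternative normalization can be reconciled later without touching callers;
at the χ_eff ~ 1e-5 scale of these experiments it is a 2·1e-5 relative
correction.

The field of the magnet along the transport axis is modelled as a pure
exponential decay B_a(x) = B0 · exp(−x/x0) with x the distance from the
magnet face. The driving factor is then

    B_a · dB_a/dx = −(B0²/x0) · exp(−2x/x0),

negative everywhere: the force points toward the magnet. The model is 1-D by
construction; transverse field components are not represented. No additive
field offset is modelled (zero asymptote far from the magnet).

Assumptions inherited from this force balance: Newtonian fluid, particle
Reynolds number below 1 (checked at run time, with a warning when violated),
no capsule–capsule dipolar interactions, no Brownian motion (the Péclet
number at 190 μm is enormous), no wall drag.

## Effective susceptibility

χ_eff folds the nanoparticle content into one dimensionless number via the
dilute Maxwell-Garnett / demagnetization mixing rule

    χ_eff = φ (χ_i − χ_f) / (1 + N_d (χ_i − χ_f)),

where φ is the nanoparticle volume fraction (converted from the mass-ppm
loading with the magnetite and PDMS densities), χ_i the intrinsic volume
susceptibility of the nanoparticle material at its size, χ_f the fluid
susceptibility, and N_d the demagnetization factor (1/3 for a uniformly
magnetized sphere). The rule is linear in φ, vanishes at zero loading or
zero contrast, and saturates at φ/N_d for large contrast. It is a plain
function, deliberately pluggable, because the exact mixing law appropriate
to these shells (particle-level vs capsule-level demagnetization) is an open
question; everything downstream depends on composition only through χ_eff.

The size dependence of χ_i is *not* modelled: the velocity optimum at
intermediate nanoparticle size is an empirical fact that the packaged
configurations encode as per-size calibrated χ_i values (see Calibration).
An optional Langevin single-domain model
(`capsule.langevin_intrinsic_susceptibility`) is provided as a clearly
labelled exploration tool, not as a claim.

Default material constants (all overridable): magnetite density 5180 kg/m³,
PDMS density 965 kg/m³, water viscosity 8.9e-4 Pa·s at 25 °C, water
susceptibility 0 (its true −9e-6 is negligible at the model's precision),
water density 997 kg/m³.

## Hindered motion

At elevated local capsule volume fraction the transport slows. The package
uses the Richardson–Zaki correction v·(1−φ_local)^n with the low-Reynolds
exponent n = 4.65 by default (configurable, and disabled at n = 0). This is
a semiempirical stand-in with the right limits — exact in the dilute limit,
strictly decreasing in φ_local — not a fitted law; no attempt is made to
estimate the exponent from data.

## Integrators

* Overdamped mode (default): dx/dt = v_t(x), fixed-step RK4. Step sizes are
  validated against the field's length scale (a step may not move a capsule
  more than x0/10; the batch sampler subdivides to x0/20). Fixed-step RK4 is
  deliberate: the ODE is mild, and a fixed, auditable step keeps the
  generated data exactly reproducible.
* Inertial mode: m dv/dt = F_m(x) − 3π η d_p v, with m from capsule geometry
  and densities. The drag term is stiff and linear (relaxation time
  τ = ρ_p d_p²/(18η) ≈ 2 ms for a 190 μm capsule in water), so the update is
  an integrating-factor (exponential) step with the magnetic forcing frozen
  at a midpoint position: the relaxation toward the local terminal velocity
  is treated exactly within each step, and the only error is the slow drift
  of v_t over a step (a tiny fraction of x0). A velocity-Verlet-style
  explicit update was rejected because at the default dt = τ/5 its
  O((dt/τ)²) relaxation error (~0.3%) exceeds the 0.1% agreement demanded of
  the closed-form cross-check.
* Quasi-static validity: the true inertial solution lags the closed form by
  a relative ≈ 2τ|v|/x0. In the experimental regime this is ~1e-6–1e-3; the
  closed-form-equivalence test draws random configurations with that
  parameter below 2e-4 because outside the negligible-acceleration regime
  the closed form itself is not claimed.
* Trajectories end (flagged "arrived") when the capsule reaches the stop
  distance, by default its own radius — contact with the magnet-side wall.

Coordinate and sign conventions: x = 0 at the magnet face, increasing away;
internal velocities are signed (negative = toward the magnet); every
user-facing table reports positive approach speed and says so in its header.

## Synthetic experiments

The generator emulates the reference acquisition: n capsules (12/15/14 per
condition) in a chamber next to the magnet, imaged at 24 fps. Model
trajectories are sampled at the frame rate and perturbed with isotropic
Gaussian localization noise (default sd 0.5 μm, the typical centroid error
of tracking large bright objects) and optional independent detection
dropout (0 in the packaged configurations — a 190 μm capsule is not
plausibly missed). y positions are constant per capsule in truth (the
physics is 1-D) and scatter only through localization noise.

Start positions default to a stratified-uniform sampler over the observation
window (one capsule per equal-width stratum, uniform within it): capsules
introduced as a suspension are spread through the chamber, and
stratification keeps small-n experiments representative of that spread. A
plain `uniform` sampler is available; only with it does the documented
stream-splitting rule (one master seed, per-track child streams) guarantee
that adding a track leaves existing tracks bit-identical, since strata
depend on n.

Recording duration defaults to 60 s. At the three conditions' speeds this
lets most, not all, capsules traverse the window — slower conditions retain
more far-field samples, exactly as a fixed-length video would.

What the generator does not emulate: optics (diffraction, depth of field),
capsule size dispersity, overlap/occlusion, capsule–capsule interactions,
flow disturbances. Passing tests therefore demonstrate the internal
consistency of model + pipeline under the stated noise model, not robustness
to every artefact of real video.

An optional renderer turns detections into 16-bit image stacks (Gaussian
spots of configurable width on a uniform background, optional Poisson photon
noise, 1 μm default pixel size — the experimental magnification is not
known) so the detection stage can be exercised end to end.

## Measurement pipeline

* Detection: median background, robust (MAD-based) threshold at 5 noise SDs
  (floor of 5% of peak excess on noise-free images), connected components,
  intensity-weighted sub-pixel centroids.
* Linking: per frame pair, a padded linear assignment (scipy's
  Hungarian solver) minimizing total squared displacement with a hard gate —
  links beyond `max_displacement` per frame of gap are forbidden and
  skipping costs gate², so a link is made exactly when it beats starting a
  new track. Gaps up to `max_gap` (default 2) frames are bridged by linear
  interpolation and flagged. The default gate is 5× the largest expected
  per-frame displacement from the model. Tracks cannot share detections.
  Tests verify the assignment against exhaustive enumeration on all
  instances with ≤ 6 detections per frame.
* Velocities: per-point approach speeds by central finite differences
  (one-sided at track ends), y excluded. At 24 fps the truncation error is
  below 1% and second order (halving dt cuts it ~4×; tested).
* Profiles: speeds binned by distance from the magnet face (default bin
  100 μm); per-bin mean, sd, count; empty bins omitted. The pooled
  (per-point) mean is the default summary statistic; a per-track-mean
  variant is computed alongside, and every output labels which was used.
* Curve fit: weighted least squares (weights = counts) of
  v(x) = A·exp(−2x/x0), the shape the exponential field forces on the
  terminal velocity; x0 can be held at a known field decay length.

## Calibration

`calibrate_susceptibility` inverts the closed form against a measured
profile by weighted least squares over χ_eff, seeded by the linearized
(dilute) closed-form estimate. Standard errors come from the Jacobian at
the optimum; with count weights and the pipeline's homoscedastic per-bin
noise, ±2 SE intervals achieve ~90–95% empirical coverage in the Monte-Carlo
tests.

`invert_for_target_mean_speed` finds the χ_eff whose window-averaged model
speed equals a target mean (bracketed Brent root find; the average is
strictly increasing in χ_eff, so the root is unique). Two averaging
conventions exist, and the distinction matters:

* `spatial` — the arithmetic mean of |v_t(x)| over the window.
* `observed` — the expectation of what the pipeline actually measures: a
  capsule sampled at a fixed frame rate spends time ∝ 1/|v| at each
  position, so pooled per-point means down-weight the fast region near the
  magnet. The observed average is computed by noiselessly simulating a dense
  grid of start positions and pooling finite-difference speeds exactly as
  the tracking code does. For this field the two differ by roughly 2×.

The packaged conditions anchor χ_eff to mean approach speeds of 80, 200 and
130 μm/s (5/10/20 nm at 500 ppm) using the `observed` convention over the
0.5–5 mm window, so that the calibrated quantity is the same statistic the
pipeline reports. The stored per-size intrinsic susceptibilities are derived
from these χ_eff values through the mixing rule at the 500 ppm volume
fraction and are annotated "calibrated, not measured" in the config files.
The magnet's decay length is likewise an assumption (3 mm, typical of
mm-scale NdFeB magnets) — only the 0.27 T surface field is a measured input.

## Numerical choices and degenerate inputs

* Field fitting: log-linear OLS first (exact on clean data, stable across
  the decay's dynamic range), then nonlinear least squares with relative
  (1/B²) weights, whose standard errors are calibrated under multiplicative
  measurement noise; both estimates are reported. Fewer than 3 distinct
  positions, non-positive fluxes, or non-decaying data raise typed errors.
* Root finds and fits raise typed exceptions (`InfeasibleTargetError`,
  `FitFailureError`, `CalibrationError`) carrying diagnostics rather than
  returning sentinel values.
* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; identical seeds give byte-identical outputs.
* File writes are atomic (temp + rename); every CSV/JSON written carries the
  config hash, seed and the coordinate/sign convention in its header, and is
  re-readable by the package's own readers with round-trip float parsing.

## Problem sizes

The shipped configurations use 12–15 tracks, 24 fps, 60 s recordings and a
192-start grid for the observed-average calibration; each condition's
calibrate→generate→track→profile round trip takes on the order of a second.
The Monte-Carlo studies in the test suite use 100–200 replications. These
sizes were chosen so the statistical checks (bias, coverage, round-trip
tolerances) are well resolved while the whole suite stays interactive.

## Known limitations

* The 1-D field model cannot represent transverse gradients or the full 2-D
  field map near magnet edges.
* The mixing rule and the Richardson–Zaki exponent are principled defaults,
  not measured laws for these particular shells.
* Near-wall hydrodynamics ("wall drag") is not modelled; real trajectories
  deviate from the model near their endpoints, and in this package such
  deviations can only be absorbed by the hindrance correction.
* The per-size intrinsic susceptibilities are calibrated to reported means,
  so the packaged configurations reproduce those means by construction; the
  informative content of the round trip is that the full noisy
  simulate→detect→link→profile pipeline returns the calibrated value, not
  an independent measurement of susceptibility.
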