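# Methods

## Model and assumptions

The package solves the coupled one-dimensional dual-phase-lag (DPL)
thermoelastic system for a homogeneous, single-layer tissue slab. The energy
balance is the Pennes bioheat equation — conduction, a blood-perfusion sink
`W_b C_b rho_b (T − T_b)` and a constant metabolic source `Q_met` — with the
DPL constitutive law `q(x, t + tau_q) = −K ∇T(x, t + tau_T)` expanded to
first order in both lags. Mechanics is linear (small-strain) thermoelasticity
with a single longitudinal mode; the thermal expansion enters through the
coupling modulus `gamma` in the stress and through `gamma T_0` as a strain
source in the heat equation. The external heat source is identically zero.

All computation is done on the dimensionless form. Lengths scale by
`1/(c0 eta)` and times by `1/(c0^2 eta)` with `c0 = sqrt((lambda+2mu)/rho)`
and `eta = rho C / K`; temperature increments scale by the reference absolute
temperature `T_0` and stress by `lambda + 2mu`. The governing dimensionless
groups are `beta1` (perfusion), `beta2` (strain-to-heat), `beta3`
(temperature-to-stress), `Q` (metabolic), the two lags `tau_q`, `tau_T`, and
the thickness `L`.

## Default parameters and calibration

Thermal properties are the standard skin/blood set
(`K = 0.628 W/m°C`, `rho = 1000`, `C = 4187`, `rho_b = 1060`, `C_b = 3860`,
`W_b = 0.00187 s^-1`, `T_b = 37 °C`, `Q_met = 368.1 W/m^3`). The lags and
geometry are taken directly in dimensionless form: `tau_q = 0.02`,
`tau_T = 0.04`, `L = 0.3`, with the reference evaluation time `t = 0.05`.
`W_b` is interpreted in `1/s`, the standard perfusion unit.

The mechanical constants (`lambda`, `mu`, `gamma`, `T_0`) are not uniquely
fixed by the thermal data, so the package ships a documented calibration:

* `beta3 = 0.00773`. With the boundary conditions used here,
  `sigma(0,t) = 0` and `theta(0,t) = g(t)` force `e(0,t) = beta3 g(t)`
  exactly, so the surface strain under a unit step pins `beta3` directly.
  The default dimensional set (`lambda = 7e5 Pa`, `mu = 1.5e5 Pa`,
  `T_0 = 310.15 K`, `gamma = beta3 (lambda+2mu)/T_0 ≈ 24.9 Pa/K`) realises
  this value with a soft-tissue longitudinal modulus of 1 MPa and an implied
  linear expansion coefficient of about `1e-5 /K` — physically sensible for
  hydrated tissue.
* `beta2 = beta3 = 0.00773` (symmetric weak coupling). The strain feedback on
  the temperature field is a sub-percent effect at these magnitudes, and the
  symmetric choice keeps the coupled system well conditioned.
* `beta1 = 1.0` and `Q = Q_met/(W_b C_b rho_b) * beta1 ≈ 0.0481`. The ratio
  `Q/beta1` equals the physical ratio of metabolic heating to perfusion
  cooling, which is independent of the unknown mechanical scale; `beta1 = 1`
  places the perfusion relaxation on the dimensionless O(1) time scale.

All four groups are directly overridable (constructor arguments, config-file
`dimensionless-override` section, CLI flags), since the solved system depends
only on the dimensionless set. The calibration reproduces not only the
boundary identities but also reported interior curve features (surface
displacements, stress carried at the wavefront, strain jump values) to within
a few tens of percent or better, which the loose consistency tests in
`tests/test_simulation.py` record.

## Laplace-domain solution

Eliminating either field yields `[D^4 − ℓD^2 + m] f = source` with
`ℓ = a1 + s^2 + a2 beta3`, `m = a1 s^2`, and
`a1 = (1+tau_q s)(s+beta1)/(1+tau_T s)`, `a2 = (1+tau_q s) beta2/(1+tau_T s)`,
`Q~ = Q/(s(1+tau_T s))`. Two numerical choices matter on the inversion
contour, where `|s|` reaches `10^5`–`10^7`:

* **Stable quartic roots.** One root of `z^2 − ℓz + m` shadows `a1` and the
  other `s^2`; forming the smaller root as `(ℓ − sqrt(ℓ^2−4m))/2` cancels
  catastrophically. The larger root is formed without cancellation and the
  smaller recovered from the product `m` (Vieta). Square roots are mapped to
  the `Re k ≥ 0` half-plane and ordered by modulus.
* **Stable strain weights.** The strain amplitudes carry factors
  `d_i = k_i^2 − a1`, which for the thermal mode is a difference of nearly
  equal large numbers. At the quartic roots
  `(z − a1)(z − s^2) = a2 beta3 z` holds exactly, so whichever difference is
  small is evaluated through the identity (`strain_mode_weights`).

The growing-mode amplitudes are stored rescaled as coefficients of
`exp(−k_i (L − x))`, so every matrix entry and basis function on the contour
is bounded by one and `exp(+k L)` overflow never occurs; the 4×4 boundary
system is row-equilibrated and solved with LAPACK, and a solve whose residual
exceeds `1e-6` relative is rejected as singular.

Displacement is recovered constant-free from the transformed motion balance,
`u_bar = (1/s^2) d(sigma_bar)/dx`, differentiated analytically on the
exponential modes; this reproduces the nonzero boundary displacements and is
consistent with `e = u_x` through the strain equation.

`beta2 = 0` makes the strain representation `e_bar = (1/a2)Σ d_i(...)`
indeterminate, so that limit is solved on a dedicated branch: the decoupled
conduction two-point problem first, then the elastic equation with the
thermal modes as a source term. A unit test checks the branch is the
continuous limit of the coupled solve.

## Numerical Laplace inversion

The Riemann-sum contour method evaluates
`f(t) ≈ (e^{κt}/t) [F(κ)/2 + Re Σ_{n=1}^{N} (−1)^n F(κ + inπ/t)]` with
`κ = 4.7/t`; the product `κt ≈ 4.7` sets the aliasing error near
`e^{−2κt} ≈ 1e-4`. The anchor term is `F(κ)/2` (the standard half-weight of
the contour midpoint). Two modes are exposed: fixed `N` (default 5000,
deterministic, used for profile tables and trend studies) and adaptive
(doubling `N` from 5000 until successive values agree to `rel_tol = 1e-6`,
capped at `2^20` terms, used for boundary-value checks). Transforms of
discontinuous signals converge slowly near their jumps; the adaptive mode
reports the terms used and flags hitting the cap instead of failing. For
profile runs all grid points and all four fields are inverted simultaneously
on the shared contour, with the per-`s` boundary solves batched.

The hyperbolic (`as_printed`) harmonic dialect inverts `ω/(s^2−ω^2)`, the
transform of `sinh(ωt)`; that inversion is well posed only while
`κ = 4.7/t > ω`, i.e. for `t < 4.7/ω`. The reference boundary values for the
harmonic program (0.51, 0.81, 1.16 at `t = 0.05`) match the sinh pair, not
the `sin` stated alongside it, so the hyperbolic dialect is the default for
reproduction; `standard_sine` (`ω/(s^2+ω^2)`) is provided for genuinely
periodic loading.

## Finite-difference oracle

The validator marches the dimensionless system directly in time: the
conduction equation implicitly (BDF2-type differences; the mixed
`tau_T ∂t θ_xx` term as the BDF2 difference of the second-difference
stencil), giving one constant tridiagonal solve per step, and the motion
equation by explicit leapfrog under `dt ≤ dx` (dimensionless wave speed one).
Each step advances strain first, then temperature with the fresh strain.

One subtlety is deliberate: row 0 of the stored fields is the zero initial
state *including the boundary node*. With `tau_T > 0` a step change in the
boundary temperature carries an impulsive initial layer — the mixed term
integrates `g'(t)`, a Dirac delta for shock loading — which instantaneously
lifts the interior field. Starting the march with the boundary already at
its post-jump value silently discards that layer and converges to a
different (classical zero-start) solution; resolving the jump as a one-step
transition recovers the distributional solution the Laplace transform
represents. Cross-method agreement on the decoupled shock case drops from
~25% disagreement to `~1e-4` with this treatment.

Reference problem sizes: decoupled checks use 301 spatial points, coupled
checks 151–601, with `dt = dx/2`; at these sizes the full cross-check runs in
seconds and the discrepancy against the semi-analytic solution is 0.4–2% of
peak amplitude for stress and `~1e-4` for temperature, shrinking under
refinement.

## Jump detection and parameter studies

Wavefronts are located from first differences exceeding the mean plus three
standard deviations of all difference magnitudes, with adjacent flags merged
to the steepest interval. On a strictly linear profile the rule flags
nothing. Parameter sweeps (`nu ∈ {0, 0.02, 0.04}`, `t0 ∈ {0.03, 0.05, 0.07}`,
`omega ∈ {10, 15, 20}` at `t = 0.05`) are tabulated in long format with
provenance columns (parameter hash, inversion terms, harmonic dialect) and
are bit-deterministic for fixed options.

One directional claim needs care: with the surface strain pinned at
`beta3 g(t)` and the surface stress at zero, the stress carried *behind* the
front necessarily grows as the shock delay increases (the temperature there
is lower while the strain is unchanged), so the stress does not decrease
pointwise at fixed near-surface positions. What does decrease — and what the
reported jump values (0.00118, 0.00077, 0.00023) actually trace — is the
stress at the wavefront itself, which sits closer to the surface for larger
delays. The trend tests assert exactly that front-value ordering, alongside
pointwise temperature ordering and curve-level (L1) ordering for strain and
displacement.

## What the tests do and do not show

All checks run on the dimensionless model with the calibrated defaults. They
validate the closed-form solution, its numerical inversion and the mutual
consistency of two independent solution routes; they do not validate the
physiological parameter values themselves, temperature-dependent or layered
tissue properties, 2-D/3-D geometry, finite-strain mechanics, or
thermal-damage dosimetry, all of which are outside the model. Interior curve
magnitudes depend on the calibration of `beta1`, `beta2`, `Q`; only the
boundary-forced quantities are treated as quantitative references.
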