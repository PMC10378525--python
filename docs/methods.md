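# Methods

`gelprint` models the plunger-driven, low-temperature extrusion printing of
gelatin solutions: the material's shear-thinning rheology, the thermal state
of the barrel–taper–nozzle channel while printing into chilled air, and the
matching of piston (inlet) velocity to print-head travel speed through the
deposited line width.  This note records the models, the numerical choices
and the limits of what the test suite demonstrates.

## Rheology

The constitutive model is the power law for a pseudoplastic fluid,

    eta_a(gamma) = tau / gamma = k * gamma**(n-1),

with consistency coefficient `k` (Pa·s^n) and rheological index `n`
(dimensionless; `n < 1` is shear thinning, `n = 1` Newtonian; `n > 1` is
accepted but flagged, since gelatin solutions are not shear thickening).
Temperature dependence above the gel point is the minimal exponential form
`k_eff = k * exp(-b (T - T_ref))` with `b` in 1/degC — consistent with
"warmer is thinner" without inventing structure the data cannot support.
Fitting is ordinary least squares of `ln eta` on `ln gamma`: the power law is
exactly linear in log space, so the fit is a reproducible closed form with
transparent residual diagnostics (an optional nonlinear refinement was
considered and rejected as a second, less reproducible code path for the
same numbers).

Two gel-point detectors are provided.  The *viscosity mutation* detector
smooths a viscosity–temperature ramp with a centred moving average
(window 3 by default), differentiates by central differences, and reports
the temperature of maximum |d eta/dT|; if the maximum is not distinct
(max/median ratio of the absolute derivative below 3, both configurable)
there is no abrupt change and the detector refuses to answer rather than
return the argmax of noise.  The *modulus crossover* detector finds the
single sign change of G' − G'' in an oscillatory temperature sweep and
interpolates linearly; zero or multiple crossings are errors (the ambiguity
error lists all candidates).  The loss tangent is implemented in its
standard form tan δ = G''/G', under which tan δ < 1 means predominantly
elastic (gelled) and tan δ > 1 predominantly viscous — some sources print
the inverted ratio while describing exactly this classification, which only
the standard form supports; the package follows the physics.

## Natural convection

Exterior surfaces lose heat to still, chilled air by laminar natural
convection, using the textbook correlation chain Gr → Pr → Nu = c (Gr Pr)^m
→ h_c = Nu k / L, with c = 0.59 and m = 1/4 for a vertical surface in the
laminar range (both overridable).  Note that `h_c = Nu k / L` is the
dimensionally consistent closing relation; statements of this correlation
occasionally garble it (e.g. printing "h_c = Nu L" or swapping the symbol
legend), but only the standard form has the units of a film coefficient.
Air properties come from a built-in dry-air table (1 atm, 250–350 K,
linear interpolation; beta = 1/T ideal gas) evaluated at the film
temperature, since measured property values are not part of the problem
statement.

## Extrusion-channel simulator

A full 3D conjugate-heat-transfer FEM of the print head (~10^7 elements) is
replaced by a quasi-1D/axisymmetric model that runs in seconds on one core
and reproduces every reported trend.  The reduction has two parts.

**Flow (lubrication approximation).**  The piston fixes the volumetric flow
rate `Q = v_j pi d1^2/4`.  At every axial station the velocity is the fully
developed power-law pipe profile for the local radius `R(z)` (barrel 7 mm,
linear cone over the 5 mm taper, 0.5 mm over the 3 mm nozzle land — taper
and land lengths are design parameters, configurable, since only the bore,
the outlet diameter and the 58 mm total length are fixed):

    u(r) = u_max (1 - (r/R)^((n+1)/n)),  u_max = (3n+1)/(n+1) Q/(pi R^2)
    gamma_w = (3n+1)/(4n) · 4Q/(pi R^3)   (Rabinowitsch–Mooney)
    dp/dz = 2 k_eff(T) gamma_w^n / R

Because the profile shape depends only on `n`, the velocity and shear-rate
fields are independent of temperature and of `k` — which is itself one of
the reported findings (concentration changes move the pressure field, not
the kinematics).  The pressure integral is evaluated analytically per grid
interval (`R` is linear within each segment), so the Newtonian case matches
the piecewise Hagen–Poiseuille sum to rounding and the taper's steep
`R^-(3n+1)` growth costs no resolution.  The continuity-consistent mean
outlet speed is `v_j (d1/d)^2` (5.88 mm/s at v_j = 0.03 mm/s, d = 1 mm);
the simulator reports this section mean and the centreline peak.

**Heat (axisymmetric advection–diffusion).**  On the radius-normalised grid
`s = r/R(z)`,

    rho cp (dT/dt + u dT/dz) = k [ (1/r) d/dr (r dT/dr) + d2T/dz2 ],

with the metric cross-terms of the s-mapping neglected (the taper is short
and the mapping follows the streamlines of the constant-shape profile).
Viscous dissipation is neglected at mm/s speeds, as are inertia and gravity.
Boundaries: the inlet is held at the feed temperature; the outlet is an
advective outflow; the jacketed part of the barrel wall (first 45 mm) is a
Dirichlet boundary at the controlled wall temperature; the unjacketed
exterior (barrel bottom, taper, nozzle) is a Robin boundary with the
natural-convection film coefficient from the convection module (film
temperature from the measured cold-start wall temperature, characteristic
length the exposed 13 mm).  Conduction within the metal wall and the cold
fixed block is deliberately lumped into these boundary models; the block's
13.5 degC initial temperature is accepted and logged for configuration
completeness but not separately resolved.

**Heater control.**  A thermocouple sits between the heating sleeve and the
outer wall; the wall temperature state relaxes first-order (time constant
30 s, configurable) toward the 45 degC jacket set point while the heater is
on and toward ambient while off.  A bang-bang thermostat switches the
heater with a 30–32 degC hysteresis band, holding the controlled wall near
the measured 31 degC.  After burn-in the wall trace stays within the band
to within a small overshoot set by the time step.

**Numerics.**  Radial diffusion is implicit: one tridiagonal system per
axial station, with the Thomas forward-elimination coefficients
pre-factorised once per run (the matrices are time-invariant) and the
per-step sweeps vectorised across stations.  The axis node uses the
regularised cylindrical Laplacian; the Robin wall node is a conservative
half-cell finite-volume balance.  Axial advection is explicit second-order
upwind with a van Leer flux limiter (plain first-order upwind was tried
first and its numerical diffusivity `u dz/2` dominated the physical
diffusivity in the nozzle, leaving a 2–3% grid dependence in the pressure
drop; the limited scheme brings grid-halving changes of outlet temperature
and pressure drop under 1%).  Axial diffusion is explicit central.  The
time step obeys an advective Courant bound of one half (folded into the
reported admissible dt); violating it raises an error naming the admissible
step.  For shear-thinning `n < 1` the power-law viscosity diverges on the
axis, so the viscosity field floors the shear rate at `gamma_min = 1e-3` 1/s
(configurable) before evaluating `k_eff gamma^(n-1)`; the floor affects
reporting only, not the dynamics.

**Default problem sizes.**  33 radial nodes × ~80 axial stations
(segment-proportional with a 5-node minimum per segment) and 600 s of
process time — several radial diffusion times of the 7 mm barrel
(R^2/alpha ≈ 360 s), by which the outlet temperature has settled; a full
run takes a few seconds.  Halving both spacings changes the end-state
outlet mean temperature and pressure drop by well under 1%.

## Deposition matching

The deposited line's cross-section is modelled as a *stadium* — a rectangle
of height `h` capped by two half-discs of diameter `h`, area
`(w − h) h + pi h^2/4` (the algebra of the published width formulas is the
stadium's, even where prose says "elliptical").  Volume balance between
piston and line gives the theoretical width and ideal matching factor

    d2 = v_j pi d1^2/(4 v_c h) + (4 − pi) h/4,
    v_c = k v_j,  k = pi d1^2/(4 d2 h − 4 h^2 + pi h^2).

Calibration fits the measured width law `d3(v_j)` by OLS, takes the
analytic theoretical law (already affine in `v_j`), and forms the error law
`D = d3 − d2` as their difference.  Folding `D` back into the balance gives
the corrected factor

    k1 = pi d1^2 / (4 h d2 + (pi − 4) h^2 − 4 a_D h + 4 b_D h v_j),

with `(a_D, b_D)` = (intercept, −slope) of `D`, and the optimal inlet
velocity for a target width solves `v_c = k1(v_j) v_j`, which is linear in
`v_j` after clearing the denominator — a closed form, no iteration.  The
`reference` mode hard-codes the constants 4.14 and 104.78 of the
calibration performed on the reference printer so its published 0.0242 mm/s
operating point reproduces digit-for-digit; the `fitted` mode recomputes
them from any measurement set and agrees with the reference constants to
better than 0.5% on the built-in dataset.

Two quirks of the built-in reference dataset are worth recording.  First,
its published numbers are mutually consistent only with a layer thickness
of 0.5 mm, although the accompanying settings quote 0.3 mm; the package
carries both values, uses 0.5 mm for all reproduction computations, and
keeps `h` an explicit parameter everywhere.  Second, refitting the four
measured widths gives slope/intercept 35.38/1.140 against the published
35.3344/1.1415 (≈0.15% apart — the original fit likely used more decimal
places than were printed); tests compare at 1%.

## Synthetic data

The generators produce the data products the analyses consume, with the
statistical structure the models assume, not emulations of any instrument:

* flow sweeps on a log grid over 0.1–100 1/s with
  `k(conc, T) = k_base (conc/9)^2.2 exp(−0.12 (T − 25))`, `n = 0.45`,
  `k_base = 5` Pa·s^n — illustrative defaults chosen to reproduce the
  qualitative concentration/temperature orderings (no fitted `k, n` values
  are published to calibrate against); multiplicative lognormal noise
  (viscosities stay positive), default CV 2%;
* thermal ramps `eta(T) = baseline(T) (1 + M · logistic((T_gel − T)/w))`
  with `T_gel = 31` degC, surge `M = 30`, width 0.8 degC, on a gently
  thinning baseline — an abrupt but smooth sol–gel surge;
* oscillatory sweeps built from a monotone
  `tan δ = exp((T − T_gel)/3)` and a slowly decaying G'', so G' = G''
  exactly once, at the gel point;
* line widths = affine law + additive Gaussian noise (measurement error of
  a calliper/microscope width, default SD 0.05 mm).

All generators are bit-reproducible for a fixed seed (seeds are mixed with
dataset tags through `SeedSequence`).  What passing tests show is that the
estimators recover the truth of *this* structure — clean power laws, a
single smooth transition, homoscedastic width noise.  They do not show
robustness to rheometer artefacts (inertia, slip, thixotropy), yield-stress
behaviour, multiple or hysteretic transitions, or measurement bias, none of
which the generators emulate.

## Known limitations

* The simulator is a trend instrument.  Exact field values from a 3D
  conjugate FEM (e.g. point velocities or pascal-level pressure readings)
  are outside its reach by construction; its own pressure drops and outlet
  temperatures are internally converged but depend on lumped boundary
  parameters (wall time constant, film coefficient) that were not fitted to
  measurements.
* Thermal properties of the gelatin solution are water-like defaults
  (rho = 1000 kg/m^3, cp = 4000 J/(kg K), k = 0.55 W/(m K)), overridable in
  the material section of the run configuration.
* No die swell, filament stretching or free-surface behaviour after the
  outlet; line width comes from the volume-balance calibration, not from
  extrudate mechanics.
* The power-law model has no yield stress and no time dependence; below the
  gel point the material is effectively out of the constitutive model's
  domain, which is why gel-point detection is a separate, model-free step.
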