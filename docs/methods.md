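# Methods

## Scope and model structure

`vesselcav` is a desk-scale, reduced-order model of one or two
acoustically driven gas microbubbles inside a compliant microvessel and
of the endothelial permeability response their wall loading produces.
It deliberately replaces a full fluid–structure (FEM/ALE) solution with
a one-way chain of four cheap sub-models:

    bubble ODEs  →  wall stress estimators  →  lumped wall element  →  permeability

Each downstream stage is pure post-processing of the stage before it;
nothing feeds back upstream. In particular the vessel wall does **not**
confine the bubbles: the radial dynamics are those of bubbles in
unbounded liquid. This keeps every scenario to seconds of CPU and makes
parameter orderings and trends trustworthy, at the cost of absolute
stress levels (see Limitations).

## Bubble dynamics

The radial motion follows the incompressible Rayleigh–Plesset equation,
extended for a pair at fixed centre distance d with the standard
radiation-coupling term (1/d)·d/dt(Rj²Ṙj). The internal pressure is
polytropic, `pg = pg0 (R0/R)^{3κ}` with `pg0 = p0 + 2σg/R0 − pv`, which
makes the quiescent state an exact equilibrium. Vapour pressure adds to
the gas pressure; surface tension and viscous normal stress 4ηṘ/R act at
the interface. The far-field pressure is `p0 − Pd sin(2πft + φ)` (the
sign convention only shifts phase; φ defaults to 0). Because the
coupling term contains the neighbour's acceleration, each evaluation
solves the 2×2 linear system in (R̈1, R̈2) in closed form; its
determinant `R1R2(1 − R1R2/d²)` is positive whenever the bubbles do not
overlap, so the solve cannot go singular. Bubble positions are fixed at
z = ∓d/2 on the axis; translation and coalescence are out of scope. The
single-bubble reduction simply drops bubble 2 and keeps bubble 1 at
z = −d/2, so single/dual comparisons probe the same geometry minus one
source.

The small-oscillation resonance used for interpretation is the
surface-tension-corrected Minnaert frequency
`f0 = (1/2πR0)·sqrt[(3κ pg0 − 2σg/R0)/ρf]`; at the 2 µm default this is
1.6247 MHz, and the linearized pair (symmetric mode) resonates at
`f0/sqrt(1 + R0/d)`.

**Integration.** SciPy's Radau (adaptive, stiff) with rtol 1e-8, atol
1e-14 on radius and 1e-8 on velocity, from R(0) = R0, Ṙ(0) = 0. Output
is resampled on a uniform grid of 200 samples per acoustic period. A
terminal event at R < R0/50 flags an inertial-regime exit and returns
the partial trajectory; the model is intended for stable cavitation
(tens of kPa at MHz frequencies), and the guard only engages near
~0.5 MPa. Implicit trial steps may probe unphysically small radii
inside a step, so the RHS clips radii at 1e-3 of the guard value; the
event, not an exception, ends the run. Default run length is 30 cycles
with all metrics over the last 10, which discards the startup transient
(the linear decay time 2ρfR0²/4η is about one acoustic period here).

## Blood rheology

Viscosity is either constant (Newtonian, 0.0035 Pa·s default) or
Carreau–Yasuda with the blood parameter set η0 = 0.0519 Pa·s,
η∞ = 0.00476 Pa·s, λ = 0.438 s, n = 0.191, a = 0.409. The exponent is
the standard (n−1)/a grouping. The full viscous stress tensor field is
never assembled; the scalar law is evaluated at two characteristic
rates: the bubble-interface rate 2√3|Ṙ|/R (the invariant √(2D:D) of the
purely radial flow at r = R) inside the damping term, and the local
wall velocity-gradient magnitude in the wall shear stress. For rates
above 1e11 1/s the law is evaluated in log space, dropping the "+1"
inside the bracket; at that rate this perturbs the result by ~1e-12
relative. At the interface rates the oscillating bubbles generate
(~10⁶–10⁷ 1/s) the law sits near its infinite-shear plateau, so the
shear-thinning damping is close to — but measurably different from —
the Newtonian 0.0035 Pa·s case (trajectories diverge by ~5% of R0 at
the defaults).

## Wall stresses

The liquid velocity at the wall is approximated by superposing
free-space pulsating point sources of strength Ri²Ṙi at the bubble
centres. On the axial grid (81 points over the 40 µm segment, at
r = RV):

* shear: τ_ex = η(|∂u_z/∂r|) · ∂u_z/∂r, with the radial derivative
  analytic: ∂u_z/∂r = −3 Σ mi (z−zi) r / si⁵;
* normal: σ_n = ρf Σ d/dt(Ri²Ṙi)/si − ρf|u|²/2 (unsteady Bernoulli;
  positive = outward push, negative = suction).

No image system corrects for the cylindrical boundary, and there is no
no-slip boundary layer; both mainly rescale absolute magnitudes along
the wall line. For a perfectly symmetric in-phase pair, τ_ex is exactly
antisymmetric about the midplane and vanishes at z = 0; shear metrics
are therefore reported as wall-line maxima, while normal-stress and
permeability metrics use the midplane observation point (r = RV, z = 0),
the symmetric point between the bubbles.

## Wall response

Each axial point carries an independent lumped element
`ρs h ẅ + c ẇ + k_w w = σ_n(t)` with thin-shell hoop stiffness
`k_w = E h/RV²` (optionally E/(1−ν²) under a plane-strain flag, off by
default) and damping `c = 2ζ√(k_w ρs h)`. Wall thickness h = 1 µm and
damping ratio ζ = 0.1 are modelling choices (not material data);
both are configurable and echoed into every output summary. The hoop
strain is ε = w/RV. The LTI element is advanced with the exact
matrix-exponential propagator for piecewise-linear forcing, so the only
discretisation error is the sampling of σ_n itself; against the
closed-form forced-oscillator solution the integrator is accurate to
<1e-6 at 8000 samples per forcing period.

## Permeability

Effective endothelial stress is τ = τ_ex − Eε with E = 4 MPa. Negative
τ (strain-dominated phases) is clamped to zero before the empirical
shape-index regression SI(τ) = 0.38e^{−0.79τ} + 0.225e^{−0.043τ}, which
is defined for non-negative shear stress; SI(0) = 0.605. Permeability is
K(SI) = [4×10⁸/(3π R_cell)]·w³·(0.479 + 0.00593e^{−14.75·SI}) with
junction half-width w = 20 nm and cell radius R_cell = 15 µm as
configurable defaults; the dimensional prefactor is exposed as a single
constant because every comparison metric is a ratio in which it
cancels (asserted by recomputation with perturbed geometry). Metrics
over the steady window: excess permeability ΔK = K − K(SI(0)) and its
trapezoidal time integral over whole acoustic periods; pulse rate as
upward crossings of K_baseline + 0.1·max ΔK per second; and the
dual/single enhancement ratio of integrated excess permeability.

## Scenario drivers and reproducibility

`default_scenario()` encodes the reference conditions: R1 = R2 = 2 µm,
d = 10 µm, RV = 5 µm, L = 40 µm, Pd = 30 kPa, f = 1.5 MHz, κ = 1.07,
pv = 2330 Pa, σg = 0.056 N/m, p0 = 1.013×10⁵ Pa, ρf = 1059 kg/m³,
ρs = 1049 kg/m³, E = 4 MPa, ν = 0.49, Carreau–Yasuda rheology. Sweep
grids: Pd ∈ {50, 100, 150} kPa, f ∈ {0.25, 0.5, 0.75, 1.0} MHz,
R10 ∈ {1, 2, 3, 4} µm (R20 fixed at 2 µm), d ∈ {10, 16, 26, 36} µm —
the two smaller spacings fill in the grid around the studied 26/36 µm
pair. Everything is deterministic: no random numbers are drawn anywhere,
identical configs produce byte-identical outputs, and the full
configuration (including every filled-in default) is echoed into each
summary so a run is reproducible from its metadata alone.

These scenario definitions are also what the test suite exercises; they
emulate idealised study conditions, not real data. Real microvessels add
confinement, wall no-slip, bubble translation in flow, shelled contrast
agents and biological variability, none of which the generator
represents — so green tests certify the reduced model's internal
consistency and its parameter trends, not quantitative agreement with
in vivo stresses.

## Numerical choices summarised

* Radau, rtol 1e-8, atol (1e-14, 1e-8); 200 output samples/cycle;
  30-cycle runs, 10-cycle metric window.
* Collapse guard R0/50, RHS radius clip at 1e-3 of the guard.
* Exact 2×2 acceleration solve (no lagging of the coupling term).
* Exact LTI propagator for the wall element (first-order-hold forcing).
* Trapezoidal quadrature over whole periods for all time integrals.
* Clamp-at-zero for negative effective stress ahead of the SI
  regression (configurable off, with a warning on extrapolation).
* Unit-suffixed config keys (µm, kPa, MHz); reverse conversions divide
  rather than multiply so round-trips are float-exact.

## Known limitations

* **Absolute stress levels are overestimated.** The unbounded-liquid
  bubble model plus free-space sources ignore vessel confinement, which
  both suppresses oscillation amplitude and screens the velocity field.
  At the 30 kPa / 1.5 MHz defaults the single 2 µm bubble is driven just
  below resonance and reaches ±20% radial amplitude, giving midplane
  wall shear of order 10² Pa and normal stress of order 10⁴ Pa.
  Orderings across Pd, d, R10 and f are robust; magnitudes are not.
* **The shape-index regression saturates.** With E = 4 MPa and hoop
  strains of order 0.1, the effective stress swings by ~10⁵ Pa while
  SI(τ) decays on a scale of ~1–70 Pa. Both single- and dual-bubble
  scenarios therefore drive the permeability to its ceiling for roughly
  half of each cycle, the excess-permeability pulse train looks nearly
  identical in the two cases, and the dual/single enhancement ratio
  computes to ≈1 at the defaults. A confined-flow model with realistic
  (much smaller) streaming stresses, or a regression recalibrated to
  the local stress scale, would be needed for a discriminating
  permeability endpoint.
* **Near-resonance coupling can amplify the pair.** The pair's
  symmetric-mode resonance f0/√(1 + R0/d) = 1.48 MHz sits almost
  exactly at the 1.5 MHz drive for the default geometry, so the coupled
  pair oscillates ~5% more than the isolated bubble rather than less;
  the wall stresses of the pair exceed the single-bubble values either
  way.
* The positive (push) normal-stress peak exceeds the suction peak at
  the defaults: rebound after each contraction produces sharp positive
  d/dt(R²Ṙ) spikes that dominate in an unconfined liquid, whereas
  confined systems tend to show invagination dominance.
* No drug transport, pore-closure kinetics, thermal effects, shell
  rheology, or acoustic re-radiation.
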