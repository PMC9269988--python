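# Methods

This note records the model equations as implemented, the default
parameters and why they were chosen, what the built-in scenario generators
emulate, the numerical methods, and the design decisions taken where the
formulation left choices open.

## Scope and state

Both models are isothermal, compositional, macroscale continuum models of
tumor-bearing tissue.  The state of each phase α is its volume fraction
ε^α, intrinsic density ρ^α (constant: incompressible phases), species mass
fractions ω_i with Σ_i ω_i = 1, pressure p^α, and velocity v^α.  Interfaces
are massless; their state enters through specific areas (1/m), curvatures
and tensions.  Energy balances are not solved (isothermal restriction);
kinetic-energy and common-curve contributions are treated as higher order
and omitted.

Two-phase configuration: a fluid `f` = {g, o, c, w, x} with water `w` as
reference species, and a solid `s` = {l, n, e, g, o, c, w, y} with ECM `e`
as reference.  Three-phase configuration: wetting fluid `w` = {g, o, c, w,
z} (reference: water), non-wetting tumor fluid `n` = {l, n, g, o, c, w, x}
(reference: living tumor l), solid `s` = {e, g, o, w, y} (reference: ECM).
The reference species of a phase is eliminated by the mass-fraction
constraint and its diffusive flux is completed as minus the sum of the
others, so Σ_i ω_i u_i = 0 holds exactly rather than approximately.

## Thermodynamics

μ_i^α = μ0_i^α + (R_g θ / MW_i) ln x_i^α with unit activity coefficients,
θ = 310 K, R_g = 8.314 J/(mol·K).  μ0 is a per-(species, phase) constant
supplied by the scenario; an isothermal liquid/tissue system does not need
its pressure dependence for the processes modeled here, and no functional
form for it is available.  Mole fractions are floored at x_floor = 1e-12
*inside the logarithm only*, keeping potentials finite for vanishing
species without touching any mass balance.  Mass fractions in [−1e-12, 0)
are zeroed with a warning; anything more negative is an error.

Cross-phase reference-potential *offsets* encode the different solvation /
binding environments of a species in different phases.  The scenario
generators use them to place transfer equilibria: the offset for species i
between phases is set so that μ_i + ψ matches at a chosen reference
composition.  This is the physically meaningful construction — a dense
solid cannot match a dilute fluid's water mole fraction, so equilibrium
cannot (and should not) be encoded by equating mole fractions.

## Kinetics

Reactions are linear in chemical affinity, R_k = −K̂_k A_k, with A_k =
Σ_i μ_i ν_ik MW_i and Σ_i ν_ik MW_i = 0 enforced to 1e-12 (one
stoichiometric coefficient per reaction is solved from the balance given
the configured molar masses).  Mass balance makes the affinity invariant
under uniform potential shifts, and R·A ≤ 0 makes the reaction entropy
production ε K̂ A²/θ ≥ 0 identically.

The coefficient K̂ may be modulated by nonnegative state-dependent factors
— any such factor preserves the entropy sign:

* `oxygen_switch(ω_crit, δ)` — the sigmoid σ((ω_crit − ω_o)/δ) activating
  necrotic formation as the local oxygen fraction drops.  The necrosis
  reaction itself (l → n) contains no oxygen; its hypoxia dependence lives
  entirely in this rate modulation.
* `monod(species, K_half)` — ω/(ω + K_half), freezing a reaction as a
  required reactant vanishes.  Strictly linear affinity closures can run a
  reaction backwards when a product's potential is floored; the saturable
  factor is the standard way to represent substrate limitation and keeps
  the network biologically directed.

The tumor network (both models): tumor formation g + o → l; drug-mediated
destruction l + c → products; necrotic formation l → n; necrotic lysis
n → products + water.  In the three-phase model all reactions occur in the
non-wetting tumor-fluid phase; because that phase's declared composition
does not include the ECM species, the destruction/lysis debris is lumped
into the non-wetting background species x together with water (the solid's
ECM species is a separate pool).

Interphase transfer is conjugate flux–force:
M_i^{α→β} = K̂_M (μ_i^α + ψ^α − μ_i^β − ψ^β), antisymmetric in the pair,
with entropy production K̂_M Δ²/θ ≥ 0.  In the three-phase model any of
the three phase pairs may exchange a shared species.

## Closures

* Fluid stress t = −pI; solid stress is carried as a user-supplied
  effective normal stress (finite-strain solid mechanics is out of scope);
  interfacial stress t = γ(I − G) with G the orientation tensor, I/3 for
  the isotropic case (trace 1).
* Diffusion: D̂_i = d_i ω_i MW_i/(R_g θ)·I.  This mobility
  parameterization makes the closure degenerate to Fick's law with
  diffusivity d_i in the dilute limit (the standard Maxwell–Stefan-to-Fick
  reduction), which supplies an analytic benchmark.
* Momentum: R̂·(v_f − v_s) balances ε∇p − ερg plus the transfer-momentum
  term Σ_i M_i (v_f + u_i).  The transfer term is retained by default: the
  Σ M_i v part folds into an effective resistance and the Σ M_i u_i part is
  lagged one evaluation (it is quadratic in small quantities; a config
  switch drops it).  Cross-coupled fluid–fluid resistance in the
  three-phase momentum closure defaults to diagonal.
* Porosity rate ĉ[p + σ_n + γJ_s] with ĉ ≥ 0; evaluated as a diagnostic
  (with σ_n = −p by default, giving mechanical equilibrium).  The solid
  volume fraction itself is evolved from the solid-phase overall mass
  balance — the porosity closure and the solid mass balance both constrain
  ε_s when v_s and ρ_s are fixed and are not reconciled by the
  formulation; the package evolves the mass balance and reports the
  closure, rather than resolving the open question.
* Capillary relaxation ĉ^{wn}(p_w − p_n − γ^{wn}J_w^{wn}), zero exactly at
  Young–Laplace equilibrium.  In the 0-D model the capillary pressure is
  *obtained* each step by inverting this closure given the mass-balance
  value of dε_w/dt (linear inversion when the area-coupling coefficient
  k̂_1^{wn} is zero, else the quadratic root continuous with that limit).

## Geometric evolution (three-phase)

The fluid–fluid area evolves as dε^{wn}/dt = J_w^{wn}(dε^w/dt +
χ_s^{ws} dε^s/dt) + k̂^{wn}(ε_eq^{wn} − ε^{wn}) + cos φ (ε^{ws}+ε^{ns})
dχ_s^{ws}/dt, the well-mixed reduction with common-curve terms dropped.
The Gaussian curvature follows the 0-D transport reduction d(ε^{wn}
K)/dt = 0, so the product area × curvature is a conserved invariant at
fixed topology — consistent with Gauss–Bonnet, which for dilute sphere
packs (ε^{wn} = 4πr²N, K = 1/r², χ̄ = N) holds exactly.  The mean curvature
is derived from the Gaussian one as J = 2√K (exact for spherical
interfaces; a config constant can override).  Topological events
(vanishing area) terminate a run with an error; they are not modeled.
The equilibrium area ε_eq^{wn}(s_w) is user-supplied: a quadratic bump
a·s_w(1 − s_w) by default, or a constant.  The wetted fraction χ_s^{ws},
the solid-contact areas ε^{ws}, ε^{ns} and the ns-interface curvature are
config constants (no closed evolution equations are available for them at
this level).  The contact angle is constant.  The average interface normal
in the normal-velocity identity is zero (isotropic case), overridable.

The integral-geometry state function ε^n = F(ε^{wn}+ε^{ns},
ε^{wn}J_w^{wn}+ε^{ns}J_s^{ns}, χ̄^n) is fitted from tabulated states
(≥ 30): a log-linear regressor by default — exact for power-law families
such as sphere packs, where ε^n = (32π/3)·a₁³a₃/a₂³ — or a thin-plate RBF
interpolant for general smooth data.

## Entropy auditor

Each ledger group is the closure-substituted quadratic form of its
flux–force pair, divided by θ: reaction ε K̂ A², transfer K̂_M Δ²,
diffusion ε ρ ∇Δμ·D̂·∇Δμ, momentum (v−v_s)·R̂·(v−v_s), porosity
ĉ[bracket]², capillary ĉ^{wn}[diseq]².  Groups eliminated by zero-order
closures (phase and interface stresses) are reported as structural zeros so
the ledger mirrors the inequality's line structure.  The audit therefore
certifies exactly what the inequality constrains: nonnegative coefficients
⇒ nonnegative production, and a negative group pinpoints the violating
closure.  For field runs the groups are volume-integrated over the domain
(each cell-wise contribution is itself sign-definite).

## Numerical methods

* **Discretization** — cell-centered finite volumes on 1-D Cartesian or
  spherical grids (exact shell volumes and face areas; cells half-open,
  index origin 0); two-point flux for diffusion and Darcy terms with
  harmonic-mean face mobilities and arithmetic-mean face compositions;
  first-order upwinding for advection.
* **Pressure** — with incompressible phases the overall fluid mass balance
  is an elliptic (tridiagonal) problem solved at every right-hand-side
  evaluation, making the discrete face fluxes exactly consistent with the
  transfer/reaction volume sources.  Dirichlet pressure at the outer
  boundary by default; r = 0 is a natural symmetry boundary (zero face
  area); an all-Neumann problem requires a gauge cell, and is only
  volumetrically compatible when interphase transfer is volume-neutral
  (equal phase densities) — a rigid closed box of incompressible phases
  admits nothing else.
* **Time integration** — method of lines with SciPy's adaptive implicit
  BDF (configurable rtol/atol, defaults 1e-8/1e-10; the geometry-sensitive
  three-phase scenarios use 1e-11/1e-16).  Each evaluation performs the
  sequential update pressure solve → Darcy velocity → transport +
  kinetics; because the pressure is eliminated inside the evaluation, no
  operator-splitting error is introduced.  The finite-difference Jacobian
  uses a block-tridiagonal sparsity pattern (the weak global coupling
  through the pressure solve is left to the error controller).
* **Conservation bookkeeping** — per-(species, phase) storage and
  integrated boundary/reaction/transfer rates are recorded at every output
  time; the balance report integrates rates with Simpson's rule, so its
  residual is quadrature-limited for transients faster than the output
  spacing (the solution itself is not: closed-domain total mass is
  conserved to machine precision independent of output resolution).
* **Degenerate inputs** — zero interfacial area, volume fractions leaving
  [0, 1], singular resistance with a nonzero driving force, and
  all-Neumann pressure without a gauge are errors, not silent repairs.

## Scenario generators

`build_spheroid_fixture` emulates a 1-mm avascular spheroid: spherical
grid (32 cells), solid fraction 0.3, an ECM-dominated solid with a living
tumor mass-fraction bump at the center (base 0.08, amplitude 0.04, width
0.3 R, 0.1 % seeded relative noise), glucose 5·10⁻⁴ and oxygen 10⁻⁵ held
at the outer fluid boundary (physiological interstitial levels), transfer
coefficients giving sub-second solute equilibration across the
fluid–solid interface, and reaction coefficients sized so the tumor grows
measurably (~0.06 % over the 2·10⁴ s default horizon) without depleting
boundary-fed nutrients.  Molar masses: literature values for glucose,
oxygen and water; effective lumped values (0.09–0.3 kg/mol) for the
macromolecular tumor/ECM/drug species.  Reference-potential offsets place
the tumor network in the exergonic regime with enough margin that tumor
formation remains forward-directed over the whole feasible composition
range.

What the generators emulate: boundary-fed nutrient diffusion, interfacial
mass exchange, affinity-directed growth/necrosis/lysis/drug kinetics,
capillary and interfacial-area dynamics.  What they do not: vascularized
tissue, mechanical deformation of the solid, 2-D/3-D geometry, patient
heterogeneity, or measured rate constants — passing tests certify the
mathematical structure (conservation, the second law, analytic limits,
identifiability), not clinical realism.

The equilibrium generators construct *exact* fixed points: transfer
equilibria via reference-potential offsets, reaction equilibria by solving
a small linear system for the μ0 of species unique to the reacting phase
(affinities vanish at the constructed composition), uniform pressure with
matching Dirichlet data, Young–Laplace capillary balance and ε^{wn} =
ε_eq.  These states are stationary to integrator precision and exercise
every closure's zero simultaneously.

The calibration generator produces an informative two-compartment
relaxation: a 3× initial enrichment of the fluid-side oxygen and sampling
concentrated within ~3 relaxation times, which pins the transfer
coefficient to ~1 % under 1 % multiplicative measurement noise.

## Known limitations

* Solid momentum is not solved; v_s is prescribed (zero by default).
* The porosity closure vs. solid mass balance tension is reported, not
  resolved.
* Three-phase transport is well-mixed only; the spatially resolved
  three-phase system is out of scope.
* Orientation tensors are constant isotropic; no evolution equation is
  implemented (none is available in closed form).
* The linear-in-affinity kinetics require modulation factors to represent
  substrate saturation; rate coefficients are illustrative, not fitted to
  data.
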