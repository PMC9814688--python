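# Methods

`cononsol` implements a desk-scale free-energy pipeline for polymer
cononsolvency: the collapse of a single hydrophobic chain in a binary
solvent at intermediate cosolvent fractions. This note records the
models, the numerical choices, and — importantly — what the desk-scale
reductions do and do not demonstrate.

## The model

**Polymer.** A bead chain of N = 32 uncharged Lennard-Jones beads,
σ_p = 0.4 nm, ε_p = 1.0 kJ·mol⁻¹, connected by harmonic bonds and
angles. The literature source of this bead model does not print its
bonded constants, so the package ships configurable placeholders:
k_bond = 30 000 kJ·mol⁻¹·nm⁻², r₀ = 0.4 nm (tangent beads),
k_angle = 2 kJ·mol⁻¹·rad⁻², θ₀ = 180°. The small angle constant keeps
the chain flexible enough to collapse; these are package defaults, not
literature values.

**Interactions.** Lorentz–Berthelot mixing everywhere; polymer–water
and polymer–alcohol well depths are scaled by λ_pw = 1.095 and
λ_pa = 0.949 (diameters untouched), the solvent-quality tuning of the
published protocol (alternative λ_pa = 0.849/1.149 are accepted by the
config). Full LJ is truncated without shift at 1.4 nm (0.9 nm in the
short-ranged reduced solvent); no tail corrections — all reported
quantities are free-energy *differences* at fixed composition, where
the truncation constant largely cancels, but absolute cavity works do
depend on this model definition. The unshifted cutoff has one visible
consequence: the mechanical (virial) pressure of the truncated model
contains an attractive impulsive term at the cutoff, which
`virial_pressure` estimates by counting pairs in a thin shell.

**Units.** kJ·mol⁻¹, nm, ps, amu, K; R = 0.0083145 kJ·mol⁻¹·K⁻¹.
In these units 1 amu·nm²·ps⁻² = 1 kJ·mol⁻¹.

**Reduced binary solvent.** Atomistic SPC/E water and united-atom
alcohols are far outside a desk-scale budget, so the solvent is a
one-site "water-like" liquid (σ = 0.35 nm, ε = 3.0 kJ·mol⁻¹,
ε/RT ≈ 1.2 at 300 K) plus an amphiphile that is either one
"methanol-like" site (σ = 0.45 nm, ε = 2.6) or two bonded
"ethanol-like" sites (σ = 0.40 nm, ε = 2.2, bond 0.25 nm). The design
rule: both species are comfortably liquid and miscible (cross
interactions at plain Lorentz–Berthelot), but the alcohol's
cohesive-energy *density* (ε/σ³ ≈ 29 kJ·mol⁻¹·nm⁻³) is far below
water's (≈ 70), so placing it at an interface costs the mixture least —
that is the microscopic premise of the surfactant mechanism, and it is
verified directly (slab test: the alcohol mole fraction in the contact
layer of a repulsive wall exceeds the bulk fraction). An earlier,
more aggressive parameterisation (weaker alcohol cohesion plus a
sub-LB cross term) produced near-critical partial volumes and
wall-condensation artefacts and was rejected; the `cross_eps_scale`
knob remains available but defaults to 1.

What the reduced model does **not** represent: hydrogen bonding,
electrostatics, water's anomalous equation of state, and real
water–alcohol activity coefficients. Passing the mechanism tests shows
that the *excluded-volume/surfactant* pathway operates in a generic
size- and cohesion-asymmetric liquid; it is not a quantitative
prediction for any specific alcohol.

## Collapse free energy: umbrella sampling + WHAM

The collective variable is the equal-mass radius of gyration (all
beads are identical, so this coincides with the mass-weighted one).
Windows follow the published protocol: harmonic bias
V = k_b/2 (R_g − R_g°)² with k_b = 20 000 kJ·mol⁻¹·nm⁻²
(the literature prints the unit as kJ mol⁻¹ nm²; the only
dimensionally valid reading of the bias is per nm², which is what is
implemented), targets 0.4–1.2 nm spaced 0.025 nm (33 windows).
WHAM: self-consistent iteration in log space, bin width 0.01 nm,
tolerance 1e-8 RT on the window free energies, bins with zero
aggregate counts masked. Errors by Bayesian bootstrap over windows
(Dirichlet weights, 50 replicates, warm-started) — the error protocol
is a package decision; so are the bin width and tolerance.

The two-state collapse free energy integrates e^{−w/RT} below and
above the coil/globule divider R_g^# = 0.7 nm by trapezoid on the
tabulated grid; the "infinite" upper bound truncates at the last
finite bin, where the integrand is negligible on every fixture we
generate (checked in tests). The result is invariant to the PMF
anchor.

Validation is oracle-first: biased samples drawn by inverse-CDF from
analytic double-well profiles (with the two-state gap prescribed
exactly by root-finding against adaptive quadrature) must be
reconstructed by WHAM to < 0.1 RT RMSD, and the prescribed gaps
in {−4, −2, 0, +2} kJ·mol⁻¹ recovered within 0.2 kJ·mol⁻¹; an
MD-in-the-loop check runs umbrella windows on a harmonically bonded
dimer, whose R_g distribution has the closed form
p(d) ∝ d² e^{−βk(d−r₀)²/2}.

## Conformers

The most probable coil is selected at R_g = 1.0 nm per the published
protocol. The published globule target of 0.5 nm is *geometrically
unreachable* for 32 beads of σ = 0.4 nm — an FCC cluster at tangent
spacing already has R_g = 0.561 nm, and the relaxed amorphous globule
(beads near LJ-minimum spacing) sits near 0.66 nm — so the package
targets the model's own compact-basin mode, 0.66 nm (override
available). Conformers are generated by steering a straight chain
with a moving R_g restraint and equilibrating under the stiff
production restraint, which pins R_g within
sqrt(RT/k_b) ≈ 0.011 nm of the target.

## Cavity (solvent-excluded-volume) free energy: TI

For fixed conformations (position restraints,
k = 10⁵ kJ·mol⁻¹·nm⁻², which holds the chain to < 0.02 nm RMSD),
polymer–solvent interactions are purely repulsive WCA, grown through a
Beutler soft core r_sc = (α σ_sc⁶ (1−λ)^p + r⁶)^{1/6} with the
published parameters α = 0.5, p = 1, σ_sc = 0.3 nm as defaults; λ = 0
is the cavity-free binary solvent (the restrained ghost chain keeps
its λ-independent intramolecular terms, which cancel in every
difference). ⟨∂U/∂λ⟩ is integrated by trapezoid over 21 evenly spaced
λ by default; the propagated error is the quadrature-weighted sum of
block-averaged per-λ variances.

Desk-scale campaign protocol (all numbers configurable; they are the
package's study conditions, chosen once):

* ~450 water-equivalent solvent molecules in a ~3 nm box; compositions
  enter at matched packing fraction (ideal mixing of molecular
  volumes) so that the bulkier amphiphile does not artificially
  compress the starting box.
* The campaign state point is 300 K and **1000 bar** — a package
  decision, not the atomistic protocol's 1 atm. At 1 atm the reduced
  (truncated-LJ) liquid sits essentially on a drying transition around
  the large purely repulsive 32-bead cavity: wetted and dried states
  trade places run-to-run and the cavity work becomes bistable (coil
  and globule can even swap order). Real water avoids this through a
  far higher surface tension. A kbar of overpressure keeps the liquid
  firmly on the wetted branch for every composition and conformation
  while leaving the mechanism — interfacial screening by the
  amphiphile — intact.
* Each run relaxes its own volume by an MC-barostat (NPT) stage at
  the fully coupled state, started from a *dense* lattice (the dense
  start selects the wetted branch; from dilute starts the repulsive
  surface can nucleate a vapour film), and the box is then fixed at
  the NPT-*average* volume for the descending NVT λ-sweep. The
  averaging matters: the instantaneous final box carries ~0.3 %
  volume noise, and the cavity work is so density-sensitive that this
  noise would otherwise dominate every comparison. Each conformation
  thus sits at its own isobaric volume — including any depletion
  layer its surface induces, which is part of the excluded-volume
  physics being measured. The λ = 0 end is the cavity-free solvent in
  that box, slightly dilute of the bulk isobaric density by ~V_cav/V;
  this offset is conformation-consistent and largely cancels in
  differences and trends.
* The NPT stage (~16 ps) doubles as adsorption equilibration of the
  cosolvent shell — shell↔bulk exchange is the slowest process in the
  system, and an unequilibrated shell suppresses exactly the
  adsorption physics the campaign is meant to resolve.
* Volume moves dilate *raw* (unwrapped) molecular centres about the
  frozen solute: a uniform dilation about a fixed point scales
  periodic-image offsets consistently with the box, which a
  minimum-image variant would not (validated against the exact
  second-virial pressure of a dilute gas and against the virial route
  in a supercritical fluid).
* The λ-points are visited as a *descending* sweep (1 → 0), each λ
  inheriting the previous configuration: solvent seeps gradually into
  the softening core. Independent per-λ starts trap solvent in the
  core (large bias and variance); an ascending sweep over-fills it
  (the soft-core plateau at intermediate λ is sticky) — the
  descending sweep showed by far the smallest hysteresis in
  bidirectional tests.
* Campaign λ-grid: 11 points refined at low λ
  (0, 0.03, 0.06, 0.1, 0.15, 0.2, 0.3, 0.45, 0.6, 0.8, 1),
  with doubled equilibration and 1.5× production below λ = 0.35,
  where the integrand is steep and the refilling dynamics slow.
* Campaign soft core uses each pair's own σ_ij as the soft-core σ
  (`sc_pair_sigma`). The published σ_sc = 0.3 nm is matched to
  ~0.3 nm atomistic sites; with the reduced model's 0.375–0.425 nm
  pairs it leaves an enormous, noisy λ≈0 integrand. The soft-core
  parameters shape only the integration *path* — the endpoints, and
  hence ΔG, are rigorously independent of them — so this is purely a
  variance-reduction choice. The published parameter set remains the
  default and is the path used in the TI-vs-Widom validation.

Validation: TI of a single WCA site into a 100-particle supercritical
LJ fluid (published soft-core parameters, 21 uniform λ) agrees with a
Widom test-particle insertion oracle on the λ = 0 ensemble within
combined 2σ. The fixture's ghost site is sized so the mixed pair
diameter equals the published soft-core σ (0.3 nm) — the regime those
parameters were designed for; with a size-mismatched core the
integrand develops a cliff below λ = 0.025 that a 21-point grid
cannot resolve (verified against an 81-point reference). At a frozen
separation the λ-quadrature of the analytic ∂U/∂λ recovers V_WCA(r)
exactly.

## Adsorption analysis

First-shell counts use a molecule-level criterion (any site within the
cutoff of any bead). The shell cutoff defaults to 0.65 nm, the
plateau of Γ(cutoff) just beyond the first minimum of the
polymer–solvent nearest-approach distribution for both solvent sizes
(an RDF-based estimator with a 0.55 nm fallback is provided). The
preferential-binding coefficient is the standard
Γ = ⟨n_a⟩ − (N_a^bulk/N_w^bulk)⟨n_w⟩ with bulk counts taken outside
the shell per frame; the source protocol defines its estimator in
supplementary material not available here, so this standard form is a
documented package decision.

Shell↔bulk exchange of adsorbed cosolvent is slow (tens of ps), which
has two consequences baked into the protocol: Γ is measured in
dedicated long runs (~8 ps equilibration + ~50 ps production), not
from the TI sweep; and the TI sweep's first leg carries a long
equilibration so that the sweep starts from an
adsorption-equilibrated shell.

Saturation: mean shell cosolvent count vs. X is fitted to a Langmuir
form n_max X/(K+X); saturation is declared at the smallest grid X
where the fitted local slope falls below 10 % of its initial value
(X ≥ K(1/√0.1 − 1)); profiles that never flatten return a
none-sentinel.

SASA uses Shrake–Rupley golden-spiral quadrature (bead radius σ/2,
probe 0.14 nm, 960 points by default; an isolated sphere is exact to
< 1 %). Chain-length scaling fits log SASA vs. log N for an extended
rod and a compact FCC-cluster conformer over N ∈ {16, 32, 64, 128},
giving exponents near 1 and 2/3 respectively; the extended exponent
exceeding the collapsed one is what makes the surfactant mechanism
strengthen with molecular weight.

## Dynamics

BAOAB-form leapfrog Langevin at 300 K with the published friction time
0.1 ps and 2 fs step; deterministic given the seed (one master seed,
per-window/per-λ streams derived by fixed offsets, all below 2³¹).
In the zero-noise limit the map reduces to velocity Verlet (energy
drift < 1e-5 kJ·mol⁻¹ per step on a dimer); a tethered particle
reproduces the exact Gaussian position distribution (KS test), and an
LJ fluid satisfies equipartition within 2 %. The published protocol's
Nosé–Hoover/Parrinello–Rahman NPT machinery is deliberately replaced
by Langevin + MC volume moves: same ensembles, far less machinery at
this scale; the published thermostat/barostat time constants apply to
algorithms not implemented here. Pair interactions use an O(N²)
minimum-image kernel (numba): below ~700 particles it outperforms
neighbor-list maintenance and is verified against a brute-force
double loop.

Position-restrained (frozen) solutes: the MC barostat excludes
restrained molecules from volume scaling and scales the solvent about
the solute; note that the plain virial pressure is *not* meaningful in
the presence of position restraints (the tether's external-force
virial is not part of the pair sum), so pressure checks are done on
unrestrained systems only.

## Problem sizes

Default test/validation sizes: WHAM validation at 33 windows ×
2·10⁴ samples; TI-vs-Widom at 100 solvent particles, 21 λ ×
(2 + 16) ps; mechanism campaigns at 32 beads + ≤ 450 solvent
molecules, the 11-point low-λ-refined grid, ~(1–2.4 + 2.4–4.5) ps per
λ plus an 8–10 ps NPT/adsorption stage, compositions
X ∈ {0, 0.1, 0.2, 0.3, 0.45}; dedicated adsorption runs 40–60 ps.
These are the package's desk-scale study conditions.

## What the mechanism campaign does and does not show

At the desk-scale study conditions the reduced model reproduces
robustly: a decrease of the coil's cavity work with cosolvent
fraction far above the noise floor; a ΔΔG^C→G_Excl-Vol that is
negative at every composition, for both amphiphiles, by many standard
errors; strongly positive preferential adsorption Γ on the purely
repulsive chain (the surfactant effect needs no attractions); deeper
ΔΔG at given X for the bulkier 2-site amphiphile; and globule-first
shell saturation in the raw occupancies.

Several of the finer signatures sit at or below the desk-scale noise
floor, and the suite reports them honestly rather than guaranteeing
them. The globule's cavity work responds only weakly to the 1-site
cosolvent (its fitted slope is negative but not always significantly
so). The *location* of the ΔΔG(X) minimum — the quantity behind the
re-entrant collapse window — is not reproducible between desk-scale
realizations: individual runs have shown a clear interior minimum for
the 2-site amphiphile (e.g. at X ≈ 0.2, rising again by X = 0.3) while
other seeds place the deepest point at the high-X end of the grid
within error. Run-to-run scatter of ΔΔG at high X is several times
the per-run block error (slow shell-composition modes that single
short runs cannot average). Resolving the minimum location would
require replicated runs several-fold longer than the desk budget.
The conformational contrast of this model (R_g 0.685 vs 1.0, SASA
ratio ≈ 1.2) is also much weaker than the atomistic system's
(R_g 0.5 vs 1.0), which damps every coil-vs-globule difference.

## Known limitations

* The mechanism results live on the reduced solvent model; magnitudes
  (hundreds of kJ·mol⁻¹ of cavity work for a 32-bead chain) are not
  comparable to atomistic numbers, only signs, orderings and trends
  are meaningful — and they are stochastic, asserted within bootstrap
  error bars.
* The full atomistic benchmark — the unscaled bead polymer in SPC/E
  water, whose collapse free energy is ≈ −2 kJ/mol at 300 K and
  1 atm — requires the atomistic stack (PME electrostatics, thousands
  of waters, tens of ns per window) and is out of desk scope; the
  package documents this gap rather than emulating it.
* NVT λ-sweeps at the λ = 1-relaxed volume slightly under-pressurise
  the λ = 0 end (the cavity volume is redistributed); this affects
  coil and globule nearly equally and cancels to first order in every
  ΔΔG.
* The coil conformer (R_g ≈ 1 nm) spans most of the 3 nm box; its
  extremities interact weakly with periodic images through the
  0.9 nm solvent cutoff. A larger box would remove this at roughly
  (L/3)⁶ cost.
* Umbrella campaigns of the *solvated* chain (the full ΔG^C→G(X)
  curve) are implemented and exercised in vacuum/dimer form, but a
  solvated 33-window campaign at meaningful statistics does not fit a
  desk budget; the package's validation therefore concentrates on the
  WHAM estimator's correctness and on the cavity-work mechanism.
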