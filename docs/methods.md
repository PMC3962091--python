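# Methods

## Scope and model

`memflux` models steady solute transport of middle-molecule uremic toxins
across two idealized membrane geometries:

* **open-area wall** — a hollow-fiber capillary wall reduced to a single
  descriptor, the open-area fraction ε of its blood-side surface. The
  diffusion hindrance is K_diff = (ε/(2−ε))². Everything else about the
  wall (tortuosity, layered morphology) is deliberately outside the model.
* **cylindrical nanopore sheet** — a thin membrane pierced by straight
  cylindrical pores of radius *b*. Hindrance follows the Renkin
  polynomial K_diff = 1 − 2.3λ + 1.154λ² + 0.224λ³ in the size ratio λ.

The flux across a wall of thickness *x* and area *A* is a sum of five
uncoupled terms (diffusion, electromigration, pH, convection,
ultrafiltration); gradients are uniform (dV/dx = ΔV/x, dc/dx = Δc/x) —
there is no spatial discretization and no coupling between species, ions
or space charge. This is a term-wise, design-oriented model, not a
Poisson–Nernst–Planck solver.

## Maximal molecular dimension

A molecule's hindrance-relevant size is taken to be its maximal linear
dimension d_max: the diameter of the atom point set, i.e. the maximum
pairwise Euclidean distance. It is computed exactly — brute force over
all pairs below 3,000 atoms, and above that via the convex hull (the
diameter's endpoints are necessarily hull vertices) followed by an
all-pairs pass over the vertices; degenerate (coplanar/collinear) sets
fall back to brute force. Both paths are cross-tested for equality.

Default atom selection, recorded in every result: first model of the
file, all chains of the deposited asymmetric unit, all non-hydrogen
amino-acid atoms; waters excluded; alternate locations resolved to the
highest-occupancy conformer. Published measurements of this kind rarely
state their selection, so this default is a documented convention of this
package, and chains/hydrogens/heteroatoms/model are all selectable per
call. Coordinates are Å throughout the structure module; conversion to nm
happens at the result boundary.

## λ convention

λ compares solute size with pore radius. The package uses the solute
**radius**, λ = (d_max/2)/b, because that convention makes the two
hindrance formulas mutually consistent on the bundled panel: a free
diffusivity inferred from each toxin's measured wall value via the
open-area hindrance, re-hindered with the Renkin factor at b = 10 nm,
reproduces the independently published nanopore diffusivities within
0.6–3.2%. The literal alternative λ = d_max/b (which some texts write) is
available behind `lam_literal=True` and misses those values by tens of
percent. A solute with d_max/2 ≥ b is sterically excluded and raises an
error. The polynomial is evaluated for λ ∈ [0, 1) with a warning above
0.6, the edge of its fitted range.

## Free diffusivity and viscosity

D₀ = 13.26×10⁻⁵ / (η^p · V_M^0.589), with η the water viscosity in cP and
V_M the molar volume in cm³/mol. Two details are genuinely open and are
therefore exposed as parameters rather than fixed silently:

* **viscosity exponent p** — the source form of this correlation is
  typeset ambiguously between 1.4 and the classical Hayduk–Laudie 1.14;
  back-calculated D₀ values for this panel are consistent with either at
  the 10–20% level. Default 1.4, `eta_exponent=1.14` selectable, always
  logged in report headers.
* **molar volume** — V_M = M·v̄ with the partial specific volume
  v̄ = 0.73 cm³/g typical of globular proteins, as a documented stand-in
  for a crystallographic volume computation. Molar masses are literature
  values bundled in the catalog TSV with per-entry source notes,
  overridable by user catalogs.

Water viscosity uses a Vogel-type fit η(cP) = exp(−3.7188 +
578.919/(T−137.546)), within a few tenths of a percent of tabulated
values over 0–100 °C (1.002 cP at 20 °C, 0.694 cP at 37 °C); valid input
range 273.15–373.15 K.

Because of the V_M and exponent uncertainty, forward D₀ predictions carry
~10–20% uncertainty; the cross-membrane route (infer D₀ from a measured
D_eff, carry it to the other geometry) is exact in the inputs and is the
default (`d0_source = "reference"`) for the bundled panel.

## Flux decomposition: conventions

* **Sign**: positive flux = blood → dialysate. The leading minus signs of
  the diffusion/electromigration/pH terms are kept as written; pass
  differences as (dialysate − blood) for clearance to come out positive.
  Every report header states this.
* **Double hindrance**: the composed diffusion term multiplies D_eff
  (which already contains K_diff) by K_diff again. This literal form is
  the default so reported numbers match the composed equation;
  `double_hindrance=False` drops the extra factor for users who consider
  it double counting. Flag state is logged.
* **Valence**: net protein charge depends on pH and site chemistry and is
  not bundled; with z unset the electromigration term is reported per
  unit valence (positive for positive ΔV). Setting z in a catalog row
  restores the signed term −z·D_eff·A·C_m·F/(RT)·ΔV/x.
* **pH term**: the bracket −4.606·pH₁ − 2.303·log₁₀(pH₂²) is evaluated
  literally; its algebraic origin is opaque (it is not a clean ΔpH form),
  so the package exposes it as-is, with the side-pairing (default
  pH₁ = blood, pH₂ = dialysate) configurable and logged. At pH 7.4 both
  sides, the bracket is −38.09, making this term large in magnitude
  relative to realistic ΔpH effects — a reason it is reported as its own
  column and never folded invisibly into totals.
* **Terms 4–5**: K_conv defaults to 1; Ω and L_p are unset by default and
  the ultrafiltration term only evaluates when both are configured — a
  pressure difference without them is a configuration error, not a silent
  zero.
* Constants: F = 96485 C/mol, R = 8.314 J/(mol·K), T defaults to
  310.15 K. All internal computation is SI; diffusivities are carried in
  cm²/s at the reporting boundary because the field's comparison values
  are printed in cm²/s.

### Per-toxin sweep coefficients are derived, not stored

Published per-toxin flux-vs-potential and flux-vs-pH coefficients of the
form J = k·ΔV exist for this panel, but reconstruction attempts failed:
no single unit/molar-mass/valence convention reproduces them jointly
(their spread across toxins is six orders of magnitude while the
underlying D_eff·C_m products differ by a factor of ~4). The package
therefore treats such printed constants as non-normative: every sweep
coefficient is computed from the configured inputs through the formulas
above, and the unit conventions are logged in each report header so a
user can trace any coefficient to its inputs.

## Synthetic data

The generator produces two kinds of ground-truth fixtures:

* **structures of exactly known diameter** — two anchor atoms placed
  exactly `diameter` apart; all other atoms rejection-free sampled
  strictly inside the ball they span, with margin (radius ≤ 0.49·d − 0.01 Å)
  so that PDB's 3-decimal coordinate rounding cannot create a longer
  pair. The diameter is analytic, not searched for. Fixtures are written
  as standard fixed-column ATOM records so they double as parser tests.
  They emulate nothing about real protein shape, packing or chemistry —
  passing tests certify the measurement and parsing chain, not biology.
* **transport scenarios** — a known D₀ plus membrane/toxin/forces, with
  expected fluxes computed by a straight-line arithmetic oracle written
  independently of the flux module (auditable by eye). Pipeline-vs-oracle
  agreement is required to 1e-12 relative, and D₀ recovery through the
  inverse hindrance is exact.

Structure-dimension checks at the size scales of the real panel run on
synthetic stand-ins with the corresponding known diameters; deposited PDB
coordinates are not bundled, and `fetch_pdb` exists as an untested
network convenience for users who want to measure real entries.

## Numerical and degenerate-input choices

* Diameter ties (several pairs at the maximum distance) resolve to the
  first pair found in scan order; the endpoints always exactly realize
  the reported distance.
* Parsing rejects malformed ATOM/HETATM coordinate fields with the line
  number; empty selections raise instead of returning empty models.
* Reports render numbers with fixed formats (`%.6e`) so byte-identical
  golden-file comparisons hold across platforms; a run is fully
  determined by its configuration.
* Problem sizes in the test suite (≤ a few hundred atoms per synthetic
  structure, ~100 property-test cases per invariant) keep the full suite
  in the tens of seconds while still exercising both diameter code paths
  past the hull threshold in dedicated cases.

## Known limitations

* Adsorption/fouling of proteins to the membrane and its feedback on
  membrane properties are not modelled.
* Term-wise and uncoupled: no electroneutrality, multi-ion coupling or
  space-charge effects; convective/hydraulic hindrance beyond the two
  K_diff formulas is out of scope.
* Plasma concentrations bundled are normal reference values; uremic
  patient concentrations vary and should be supplied via user catalogs.
* The pH term's literal bracket should be treated as an upper-bound-style
  sensitivity handle, not a validated proton-motive model.
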