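# Methods

## Formulation

The model is a metabolism-and-expression (ME) constraint system: protein
synthesis, translocation, complex formation and lipid allocation are
explicit flux variables alongside metabolic fluxes.  At a fixed growth
rate μ the steady-state enzyme level is the synthesis flux diluted by
growth, `e = v_synth / μ`, so every constraint can be written linearly
in fluxes and the growth optimum found by bisection on LP feasibility
(bracket [10⁻⁶, 3] h⁻¹, auto-extended if still feasible, width
tolerance 10⁻⁶ h⁻¹).  Each feasibility LP minimizes total flux
(reversible reactions are split into two non-negative directions), which
in practice removes degeneracy: witness fluxes, leaflet reports and
compartment mass fractions are reproducible run to run.  Witnesses are
re-verified against every row outside the LP backend at a normalized
tolerance of 10⁻⁹; the backend is HiGHS (dual simplex) through SciPy
with primal/dual tolerances of 10⁻¹⁰.

Row families, and the units chosen once at the module boundary:

* **Mass balance** (= 0) per metabolite, fluxes in mmol gDW⁻¹ h⁻¹.
* **Coupling** (≤ 0): `v_rxn − (k_cat·3600/μ)·v_synth ≤ 0`, k_cat in
  s⁻¹, converted to h⁻¹ exactly once.  Each catalyzed reaction
  direction yields one row per (machinery, k_cat) pair with exactly two
  nonzero coefficients.  One deliberate exception: translation capacity
  is a single aggregated row, `Σᵢ Lᵢ·v_synth,ᵢ ≤ (k_aa·3600/μ)·v_ribosome`,
  making the ribosome a shared resource.  With per-reaction ribosome
  rows the ribosome requirement would be set by the largest single
  demand and inhibiting it would barely move growth; the aggregated pool
  reproduces the observed near-proportional response of growth to
  translation inhibition, while translocases (per-event rows, small
  traffic) respond hyperbolically — they must be nearly eliminated
  before growth halves.
* **Membrane** (=, μ-dependent right-hand sides): one equality per
  leaflet, `Σ areas = SA(μ)`, written in μm² (a pure row scaling for LP
  conditioning; per-molecule areas are carried in nm²).  Molecule counts
  convert from fluxes by `count = (v/μ)·N_A·m_cell` with
  m_cell = 2.8×10⁻¹³ g dry weight per cell.  Summing the four leaflet
  rows recovers the aggregate four-leaflet balance.  Per-leaflet
  balances are deliberately stronger than the aggregate: they pin LPS
  to the outer leaflet of the outer membrane, which an aggregate-only
  constraint would not.  Phospholipid composition rows enforce the
  77/18/5 PE/PG/CLPN area shares (the μ-dependent count factor is
  common to every term and divides out).  Optional occupancy caps (≤)
  and floors (≥) bound the protein share of each membrane; the floor is
  the "forced nonfunctional membrane protein" option and is what the
  occupancy scan uses to pin occupancy at a grid value.
* **Demand** (mixed): murein demand = 0.01389·μ with the AmpG transport
  flux tied to 45 % of it; GAM = 34.98·μ (the growth-associated
  maintenance after subtracting the ATP that translocation now accounts
  for explicitly); Braun's-lipoprotein synthesis ≥ (7×10⁵ / (N_A·m_cell·10⁻³))·μ;
  the out-of-scope protein pinned to 0.36 of proteome mass flux; and a
  dry-mass closure `Σ gross mass synthesis = 750·μ mg gDW⁻¹`, counting
  protein (synthesis flux × MW) plus every mass-bearing metabolite
  (lipids, LPS, murein) at its gross production.  The closure is the
  growth law of the desk-scale model: each new gram of cells must be
  built from the modeled macromolecules, and the solver chooses the
  composition, disposing of surplus capacity as whichever macromolecule
  is cheapest.  Making it an equality (rather than a minimum on protein
  alone) is what gives membrane-protein over-production a real carbon
  cost and keeps membranes lipid-filled at their natural occupancy.

All demands scale linearly with μ — the simplest reading of
growth-rate-scalable demands, isolated in one function.

## Geometry and areas

`SA(μ) = 0.456π·f·(3.9f − 0.456f) + (0.912π·f)²` μm² with
`f = 2^{μ·ln2/3}` (both terms scale as f²; SA quadruples at μ = 3/ln 2).
The squared end-cap term is implemented exactly as formulated, π²
included; the config switch `membrane.corrected_cap_term` substitutes
the spherical-cap reading `π·(0.912f)²` for users who prefer the
physical interpretation.  The constants 0.456 and 3.9 are treated as the
cell radius and length in μm and are configurable.

Protein cross-sections come from the same mass-to-volume rule used for
Tat channel sizing: volume = 1.21·MW Å³, sphere shape.  An integral
membrane protein spans the bilayer and contributes its cross-section to
*both* leaflets of its membrane (hence occupies twice the calculated
area); a lipoprotein contributes only the configured cross-section of
its lipid moieties (default 1.0 nm²) to a single leaflet — the
periplasmic face of the inner membrane, or the inner face of the outer
membrane where Braun's lipoprotein bridges to the murein layer.

Per-molecule areas (PE/PG 0.6 nm², CLPN 1.2 nm², LPS 1.6 nm²) are
order-of-magnitude placeholders for head-group areas, not curated
values; they are config entries surfaced in the model document.

## Translocation

Pathway assignment is rule-based after compartment assignment, with
per-protein overrides taking precedence (overrides stand in for direct
experimental evidence): integral inner-membrane proteins take SRP/Sec;
cofactor-folding periplasmic or outer-membrane proteins take Tat;
outer-membrane β-barrels take SecB/Sec then Bam; lipoproteins take
SecB/Sec plus Lgt/Lsp/Lnt biogenesis, plus Lol when bound for the outer
membrane; remaining periplasmic proteins take SecB/Sec.  The three
SRP/Sec variants (with YidC and/or SecA assistance) are override-only,
never rule-inferred, because they rest on case-by-case evidence.

Energetics: SecB/Sec (and SecA-assisted variants) hydrolyze
⌈length/25⌉ ATP per event — the "~25" is resolved as ceiling, once,
configurably, as conservative accounting.  Lol adds one ATP per LolCDE
release event.  Tat is proton-motive-force driven; the pmf stoichiometry
is configurable and defaults to 0, with the Tat cost instead carried by
machinery occupancy: each event engages ⌈N(d)⌉ TatA subunits, N(d) the
configured polynomial in substrate diameter (placeholder 2 + 0.5·d,
floored at a tetramer — the published fit is not reproduced here and
the coefficients are inputs, not asserted defaults).  A TatBC capacity
multiplier (default 1) exposes the multi-channel variant.

Lipoprotein biogenesis draws its acyl groups from any available
phospholipid: one reaction variant per species, the solver chooses.

## Porins

Per-solute capacity through a porin: Stokes–Einstein diffusivity at
310 K in water (viscosity 6.9×10⁻⁴ Pa·s) times the Renkin hindrance
`H(λ) = (1−λ)²(1 − 2.104λ + 2.09λ³ − 0.95λ⁵)`, clamped to 0 at λ ≥ 1,
times the open-pore conductance πr²/L, times ΔC·N_A.  ΔC is taken in
mol L⁻¹ with default 6.5×10⁻⁴ (a calibrated default, user-adjustable);
temperature and viscosity are config values.  The capacity enters the
standard coupling form, so the growth-rate dependence of porin transport
arises solely from enzyme dilution — no extra mechanism.  Capacity-zero
solutes have their transport pinned to zero.  All solutes through one
porin reference the same porin synthesis flux.

## The toy cell

The generator emulates a glucose-excess minimal-medium culture of a
two-membrane bacterium at desk scale: ~30 pORFs, one substrate per
translocation pathway, full machinery, murein recycling, and a
respiration-vs-fermentation choice.  Kinetic and stoichiometric values
are chosen to reproduce behavior classes, not E. coli magnitudes:

* the electron-transport complex is large (heterotrimer, ~430 kDa) and
  slow (k_cat 3 s⁻¹), so respiration is area-hungry but ATP-efficient;
* fermentation enzymes are cytoplasmic and fast, so acetate overflow is
  area-light but carbon-hungry, and the acetate porin capacity is ~8×
  below that of O₂/CO₂;
* an alternative NADH oxidase is small and low-yield, available when
  the electron-transport complex no longer fits;
* glucose uptake is capped at 5 mmol gDW⁻¹ h⁻¹ (the excess-glucose
  batch condition at toy scale).

Under the default configuration the toy cell solves to μ* ≈ 0.80 h⁻¹,
fully respiratory, with inner-membrane protein occupancy ≈ 0.18.
Forcing occupancy reproduces the crowding phenomenology: an interior
growth maximum, a steeper decline under under-production (respiration
displaced, acetate secretion returns, and at very small caps the large
electron-transport complex gives way to the small alternative oxidase)
than over-production (surplus nonfunctional membrane protein merely
wastes carbon).

The generator is deterministic; the seed controls only the invented
protein sequences (residue composition, hence a few-percent jitter in
molecular masses).  What passing tests on the toy cell do **not** show:
agreement with measured E. coli fluxes or proteome fractions, realistic
pathway traffic shares, elemental balancing (metabolites are lumped
pools), or transcription/tRNA costs (translation is a lumped
amino-acid-plus-ATP cost under one ribosome pool).

## Numerical choices and degenerate inputs

* Bisection 10⁻⁶ h⁻¹; LP tolerances 10⁻¹⁰; independent witness re-check
  at 10⁻⁹ (normalized).  Desk-scale problems are tiny (~140 columns),
  so tight tolerances cost nothing.
* Canonical lexicographic ordering of rows and columns makes assembly
  deterministic and documents byte-reproducible.
* Infeasibility is diagnosed by re-solving with row families dropped
  cumulatively (coupling → membrane → demand) and reporting the family
  whose removal restores feasibility.
* A model with zero flux variables is feasible iff every row is
  satisfied at the origin; a model with membrane rows but no membrane
  species is infeasible at any μ > 0 (the area budget cannot be met) —
  both paths are exercised in tests.
* The log-log regression utility removes non-positive pairs first,
  requires ≥ 3 remaining pairs, and screens outliers on the normal
  probability plot of standardized residuals: points whose deviation
  from the first/third-quartile line exceeds 1.5× the residual IQR
  (configurable) are removed and the model refit.  Effectively exact
  fits (residual SD below 10⁻⁹ of the data scale) skip screening.

## Known limitations

Translation machinery is lumped (no rRNA/tRNA species); metabolite
pools are not elementally balanced; the murein recycling benefit is a
single amino-acid-equivalent return; secreted proteins and
beyond-the-outer-membrane transport are out of scope; porin transport
has no charge selectivity or saturation; membrane curvature and lipid
tail diversity are ignored.  The per-molecule lipid areas, machinery
turnover numbers other than SecA's, and the TatA polynomial are
placeholders that users with curated values should override in the
model document.
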