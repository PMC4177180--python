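# envme

Desk-scale **m**etabolism-and-**e**xpression modeling of a Gram-negative
cell **env**elope: every protein is compartmentalized, routed through an
explicit translocation pathway (SRP/Sec, SecB/Sec, Tat, YidC, Lol, Bam,
lipoprotein biogenesis), coupled to its machinery's turnover rate, and
charged against a growth-rate-dependent membrane surface-area budget.
Growth rate is maximized by bisection over a μ-parameterized linear
feasibility problem.

The package is aimed at systems biologists who want to study how protein
translocation costs, porin diffusion limits, and membrane crowding shape
growth and pathway choice (respiration vs. acetate overflow) without a
genome-scale reconstruction: a deterministic synthetic "toy cell"
exercising every pathway and constraint ships as the built-in fixture.

## The model

At a fixed growth rate μ (h⁻¹) every constraint is linear in the fluxes
`v` (mmol gDW⁻¹ h⁻¹); enzyme levels follow from dilution, `e = v_synth/μ`.

* **Coupling constraints** tie each catalyzed flux to its enzyme's
  synthesis flux: `v_rxn ≤ (k_cat · 3600 / μ) · v_synth`.  Translocation
  stages carry the turnover of their rate-limiting machinery (SecA at
  4.0 s⁻¹; Tat events occupy a substrate-sized count of TatA subunits,
  computed from the protein diameter `d = 2·(3·1.21·MW/4π)^{1/3}` Å).
* **SecA ATP cost**: 1 ATP per 25 residues, rounded up, is hydrolyzed
  per post-translational translocation event.
* **Porins** are passive diffusion channels whose per-solute capacity
  follows hindered (Renkin) diffusion through a cylindrical pore,
  `D·H(λ)·(πr²/L)·ΔC·N_A` with λ = solute radius / pore radius and a
  default transmembrane concentration difference ΔC = 6.5×10⁻⁴ mol L⁻¹
  — so gases cross cheaply while acetate is expensive to secrete.
* **Membrane budget**: the geometric surface area
  `SA(μ) = 0.456π f(3.9f − 0.456f) + (0.912π f)²` μm², with
  `f = 2^{μ ln2/3}`, must be tiled exactly, leaflet by leaflet (four
  leaflets): integral proteins occupy twice their mass-derived
  cross-section (one per leaflet), lipoproteins one lipid-moiety
  cross-section, LPS fills the outer leaflet of the outer membrane, and
  phospholipid area is split 77/18/5 between PE, PG and CLPN.
  Occupancy caps (and floors, for forced nonfunctional membrane
  protein) bound the protein share per membrane.
* **Demands**: murein demand 0.01389·μ mmol gDW⁻¹ h⁻¹ with 45 % of it
  recycled through AmpG; growth-associated maintenance 34.98·μ mmol ATP
  gDW⁻¹ h⁻¹; a Braun's-lipoprotein demand of 7×10⁵ copies per cell; an
  out-of-scope protein fixed at 0.36 of proteome mass.

`maximize_growth` brackets μ* between a feasible and an infeasible
growth rate and bisects to 10⁻⁶ h⁻¹, minimizing total flux at each step
so the reported witness is deterministic.

## Worked example

```sh
envme toycell generate --out toy.json
envme solve toy.json
#   status: optimal
#   mu*: 0.800060 1/h
envme report compartments toy.json
#   compartment      mass_flux  fraction
#   cytoplasm        112.934    0.541693
#   inner_membrane   63.8169    0.3061
#   outer_membrane   31.7186    0.152139
#   periplasm        0.0142063  6.8141e-05
envme scan inhibit toy.json --target ribosome --grid 1.0,0.5
#   value  mu_star   status
#   1      0.80006   optimal
#   0.5    0.727357  optimal
```

The toy cell grows at μ* = 0.80 h⁻¹ on 5 mmol gDW⁻¹ h⁻¹ of glucose,
fully respiratory (no acetate secretion) because porin diffusion makes
gas exchange cheaper than acetate export.  Halving the ribosome's
elongation rate cuts growth by 9 %, while halving SecA's turnover leaves
it unchanged — SecA must be inhibited >99.9 % before growth halves.
Forcing the inner-membrane protein occupancy across a grid
(`envme scan occupancy toy.json --grid 0.05,0.1,...`) shows an interior
growth optimum near 20 % occupancy, a steep decline when membrane
protein is under-produced (the electron-transport chain no longer fits
and acetate overflow returns) and a gentle one when it is over-produced.

See `docs/methods.md` for the full formulation, parameter defaults, and
what the synthetic toy cell does and does not emulate.

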