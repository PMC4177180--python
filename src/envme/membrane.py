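"""Cell-morphology membrane constraints.

The geometric cell surface area SA(mu) grows with the growth rate (a
spherocylinder whose dimensions scale with the culture's doubling-time
volume law).  A two-membrane cell exposes four leaflets, and each leaflet
must be completely tiled by protein cross-sections and lipid head-group
areas: integral membrane proteins span the bilayer and appear in both
leaflets of their membrane (hence occupy twice their cross-section),
lipoproteins occupy a single leaflet with the cross-section of their
lipid moieties, the outer leaflet of the outer membrane is filled with
LPS (kdo2 lipid IV) only, and the other three leaflets carry a fixed
77/18/5 PE/PG/CLPN phospholipid area composition.  Optional occupancy
caps (and floors, for forced nonfunctional membrane protein) bound the
protein share of each membrane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from envme.model import (
    ConfigurationError,
    Metabolite,
    Model,
    NM2_TO_UM2,
    ProteinComplex,
    Reaction,
    Row,
    ValidationError,
)

LEAFLETS = ("im_cyt", "im_peri", "om_in", "om_out")
PHOSPHOLIPID_LEAFLETS = ("im_cyt", "im_peri", "om_in")
MEMBRANE_LEAFLETS = {
    "inner_membrane": ("im_cyt", "im_peri"),
    "outer_membrane": ("om_in", "om_out"),
}
PHOSPHOLIPIDS = ("pe", "pg", "clpn")


@dataclass
class MembraneSpec:
    """Per-species areas (nm^2/molecule), composition and occupancy caps."""

    areas_nm2: dict[str, float]
    fractions: dict[str, float]
    caps: dict[str, float]
    floors: dict[str, float] = field(default_factory=dict)
    corrected_cap_term: bool = False
    radius_um: float = 0.456
    length_um: float = 3.9

    def __post_init__(self) -> None:
        total = sum(self.fractions.get(s, 0.0) for s in PHOSPHOLIPIDS)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"phospholipid fractions must sum to 1, got {total}"
            )
        for key, a in self.areas_nm2.items():
            if a <= 0:
                raise ValidationError(f"area for {key} must be > 0")
        for mem, cap in self.caps.items():
            if not (0.0 < cap <= 1.0):
                raise ValidationError(f"occupancy cap for {mem} must be in (0,1]")

    @classmethod
    def from_parameters(cls, params: dict) -> "MembraneSpec":
        m = params["membrane"]
        return cls(
            areas_nm2=dict(m["areas_nm2"]),
            fractions=dict(m["fractions"]),
            caps=dict(m["caps"]),
            floors=dict(m.get("floors", {})),
            corrected_cap_term=bool(m.get("corrected_cap_term", False)),
            radius_um=m.get("geometry", {}).get("radius_um", 0.456),
            length_um=m.get("geometry", {}).get("length_um", 3.9),
        )


def surface_area(mu: float, spec: MembraneSpec | None = None) -> float:
    """Geometric cell surface area in um^2 at growth rate mu (h^-1).

    With the size factor f = 2^(mu ln2 / 3):

        SA = r pi f (l f - r f) + (2 r pi f)^2

    with default radius r = 0.456 um and length l = 3.9 um.  The squared
    cap term is kept exactly as formulated (it carries pi^2); setting
    ``corrected_cap_term`` replaces it by the spherical-cap reading
    pi (2 r f)^2.
    """
    if mu < 0:
        raise ValidationError(f"mu must be >= 0, got {mu}")
    r = spec.radius_um if spec else 0.456
    length = spec.length_um if spec else 3.9
    corrected = spec.corrected_cap_term if spec else False
    f = 2.0 ** (mu * math.log(2.0) / 3.0)
    body = r * math.pi * f * (length * f - r * f)
    if corrected:
        cap = math.pi * (2.0 * r * f) ** 2
    else:
        cap = (2.0 * r * math.pi * f) ** 2
    return body + cap


def protein_cross_section(molecular_weight: float) -> float:
    """Membrane cross-section of a protein in nm^2: the great-circle area
    of a sphere of volume 1.21 * MW cubic Angstrom."""
    if molecular_weight < 0:
        raise ValidationError(f"negative molecular weight {molecular_weight}")
    volume_A3 = 1.21 * molecular_weight
    radius_A = (3.0 * volume_A3 / (4.0 * math.pi)) ** (1.0 / 3.0)
    return math.pi * radius_A**2 / 100.0  # A^2 -> nm^2


def _is_lipoprotein_complex(cplx: ProteinComplex, model: Model) -> bool:
    return all(model.porfs[p].is_lipoprotein for p in cplx.composition)


def complex_mass(cplx: ProteinComplex, model: Model) -> float:
    return sum(model.porfs[p].molecular_weight * n
               for p, n in cplx.composition.items())


def protein_area(entity, model: Model, spec: MembraneSpec) -> float:
    """Total membrane surface area (nm^2) occupied by one molecule of a
    membrane protein or complex: twice the mass-derived cross-section for
    bilayer-spanning species, the configured lipid-moiety cross-section
    for lipoproteins.  Soluble entities are a domain error.
    """
    if isinstance(entity, ProteinComplex):
        comp = entity.compartment
        lipo = _is_lipoprotein_complex(entity, model)
        mass = complex_mass(entity, model)
    else:
        comp = model.assignments[entity.id].compartment
        lipo = entity.is_lipoprotein
        mass = entity.molecular_weight
    if comp not in MEMBRANE_LEAFLETS:
        raise ValidationError(
            f"{getattr(entity, 'id', entity)}: not a membrane protein "
            f"(compartment {comp})"
        )
    if lipo:
        return spec.areas_nm2["lipoprotein_moiety"]
    return 2.0 * protein_cross_section(mass)


def complex_leaflet_areas(
    cplx: ProteinComplex, model: Model, spec: MembraneSpec
) -> dict[str, float]:
    """nm^2 contributed to each leaflet by one complex molecule.

    Integral complexes span their membrane: the cross-section appears in
    both leaflets.  Lipoprotein complexes sit in a single leaflet: the
    periplasmic face of the inner membrane, or the inner face of the
    outer membrane (where Braun's lipoprotein bridges to the murein
    layer).
    """
    comp = cplx.compartment
    if comp not in MEMBRANE_LEAFLETS:
        return {}
    if _is_lipoprotein_complex(cplx, model):
        moiety = spec.areas_nm2["lipoprotein_moiety"] * sum(
            cplx.composition.values()
        )
        leaflet = "im_peri" if comp == "inner_membrane" else "om_in"
        return {leaflet: moiety}
    cs = protein_cross_section(complex_mass(cplx, model))
    first, second = MEMBRANE_LEAFLETS[comp]
    return {first: cs, second: cs}


def lipid_area(met: Metabolite, species: str, spec: MembraneSpec) -> float:
    if met.membrane_area is not None:
        return met.membrane_area
    if species in spec.areas_nm2:
        return spec.areas_nm2[species]
    raise ConfigurationError(f"no per-molecule area for lipid {met.id}")


# ---------------------------------------------------------------------------
# generated allocation reactions
# ---------------------------------------------------------------------------

def allocation_reactions(model: Model) -> list[Reaction]:
    """Leaflet-allocation sinks: ALLOC_<lipid>_<leaflet> consumes one
    lipid molecule flux-wise; its flux carries the leaflet area
    accounting.  Phospholipids may enter the three phospholipid leaflets;
    LPS only the outer leaflet of the outer membrane."""
    lipid_species = model.parameters["membrane"]["lipid_species"]
    out = []
    for lip in sorted(PHOSPHOLIPIDS):
        met = lipid_species.get(lip)
        if met is None or met not in model.metabolites:
            continue
        for leaflet in PHOSPHOLIPID_LEAFLETS:
            out.append(Reaction(
                id=f"ALLOC_{lip}_{leaflet}",
                stoichiometry={met: -1.0},
                kind="allocation",
            ))
    lps = lipid_species.get("lps")
    if lps is not None and lps in model.metabolites:
        out.append(Reaction(
            id="ALLOC_lps_om_out",
            stoichiometry={lps: -1.0},
            kind="allocation",
        ))
    return out


# ---------------------------------------------------------------------------
# constraint rows
# ---------------------------------------------------------------------------

def build_membrane_rows(model: Model, mu: float) -> list[Row]:
    """Membrane rows at growth rate mu.

    (a) one equality per leaflet: protein area + lipid area = SA(mu),
        written on the um^2 scale with molecule counts converted from
        fluxes by count = (v/mu) * N_A * m_cell;
    (b) phospholipid composition rows enforcing the 77/18/5 area shares;
    (c) occupancy cap rows (<=) and optional floor rows (>=) per membrane.

    The four leaflet equalities sum to the aggregate four-leaflet balance
    4 SA(mu) = total protein + LPS + phospholipid area.
    """
    if mu <= 0:
        raise ValidationError(f"mu must be > 0, got {mu}")
    spec = MembraneSpec.from_parameters(model.parameters)
    sa = surface_area(mu, spec)
    scale = model.counts_per_flux() * NM2_TO_UM2 / mu  # flux -> um^2 of counts

    leaflet_coefs: dict[str, dict[str, float]] = {lf: {} for lf in LEAFLETS}
    protein_by_membrane: dict[str, dict[str, float]] = {
        "inner_membrane": {}, "outer_membrane": {}
    }

    for cid in sorted(model.complexes):
        cplx = model.complexes[cid]
        areas = complex_leaflet_areas(cplx, model, spec)
        if not areas:
            continue
        col = model.formation_flux(cid)
        for leaflet, a in areas.items():
            leaflet_coefs[leaflet][col] = (
                leaflet_coefs[leaflet].get(col, 0.0) + a * scale
            )
        mem = cplx.compartment
        total = sum(areas.values())
        protein_by_membrane[mem][col] = (
            protein_by_membrane[mem].get(col, 0.0) + total * scale
        )

    lipid_species = model.parameters["membrane"]["lipid_species"]
    alloc_cols: dict[str, list[tuple[str, float]]] = {s: [] for s in PHOSPHOLIPIDS}
    for lip in PHOSPHOLIPIDS:
        met_id = lipid_species.get(lip)
        if met_id is None or met_id not in model.metabolites:
            continue
        a = lipid_area(model.metabolites[met_id], lip, spec)
        for leaflet in PHOSPHOLIPID_LEAFLETS:
            col = f"ALLOC_{lip}_{leaflet}"
            if col in model.expression_reactions:
                leaflet_coefs[leaflet][col] = a * scale
                alloc_cols[lip].append((col, a))
    lps_id = lipid_species.get("lps")
    if lps_id is not None and lps_id in model.metabolites:
        a = lipid_area(model.metabolites[lps_id], "lps", spec)
        if "ALLOC_lps_om_out" in model.expression_reactions:
            leaflet_coefs["om_out"]["ALLOC_lps_om_out"] = a * scale

    rows: list[Row] = []
    for leaflet in LEAFLETS:
        rows.append(Row(
            name=f"mem_leaflet_{leaflet}",
            kind="membrane",
            sense="E",
            rhs=sa,
            coefs=dict(leaflet_coefs[leaflet]),
        ))

    # composition rows (area-share form; the mu-dependent count factor is
    # common to every term and divides out)
    any_pl = any(alloc_cols[s] for s in PHOSPHOLIPIDS)
    if any_pl:
        for lip in PHOSPHOLIPIDS:
            frac = spec.fractions[lip]
            coefs: dict[str, float] = {}
            for other in PHOSPHOLIPIDS:
                for col, a in alloc_cols[other]:
                    share = (1.0 - frac) if other == lip else -frac
                    coefs[col] = coefs.get(col, 0.0) + share * a
            rows.append(Row(
                name=f"mem_composition_{lip}",
                kind="membrane",
                sense="E",
                rhs=0.0,
                coefs=coefs,
            ))

    for mem, leafs in MEMBRANE_LEAFLETS.items():
        cap = spec.caps.get(mem, 1.0)
        floor = spec.floors.get(mem, 0.0)
        coefs = dict(protein_by_membrane[mem])
        if cap < 1.0 and coefs:
            rows.append(Row(
                name=f"mem_cap_{mem}", kind="membrane", sense="L",
                rhs=cap * 2.0 * sa, coefs=dict(coefs),
            ))
        if floor > 0.0 and coefs:
            rows.append(Row(
                name=f"mem_floor_{mem}", kind="membrane", sense="G",
                rhs=floor * 2.0 * sa, coefs=dict(coefs),
            ))
    return rows


def builder_leaflet_totals(model: Model, fluxes: dict[str, float],
                           mu: float) -> dict[str, float]:
    """Evaluate the constraint-builder's own leaflet rows at a flux
    vector: total area (um^2) accounted per leaflet."""
    totals = {}
    for row in build_membrane_rows(model, mu):
        if row.name.startswith("mem_leaflet_"):
            leaflet = row.name[len("mem_leaflet_"):]
            totals[leaflet] = sum(
                coef * fluxes.get(col, 0.0) for col, coef in row.coefs.items()
            )
    return totals


def murein_recycling_rows(model: Model) -> list[Row]:
    """Murein recycling: the AmpG transport flux equals the configured
    fraction (default 45%) of the murein demand flux."""
    d = model.parameters["demands"]
    dm = d.get("murein_demand_reaction")
    tr = d.get("murein_transport_reaction")
    if dm is None or dm not in model.reactions:
        return []
    if tr is None or tr not in model.reactions:
        raise ConfigurationError(
            f"murein demand {dm!r} present but transport reaction "
            f"{tr!r} is missing"
        )
    frac = d["murein_recycle_fraction"]
    return [Row(
        name="dm_murein_recycling",
        kind="demand",
        sense="E",
        rhs=0.0,
        coefs={tr: 1.0, dm: -frac},
    )]


def demand_rows(model: Model, params: dict, mu: float) -> list[Row]:
    """Growth-rate scalable demand rows.

    Murein demand flux = murein_mmol_per_gdw * mu; GAM ATP hydrolysis =
    gam * mu; lipoprotein synthesis >= per-cell count (converted to flux)
    * mu; proteome budget sum(MW_i v_i) = proteome mass * mu; the
    out-of-scope dummy protein carries its fixed proteome mass fraction.
    """
    if mu <= 0:
        raise ValidationError(f"mu must be > 0, got {mu}")
    d = params["demands"]
    rows: list[Row] = []

    dm = d.get("murein_demand_reaction")
    if dm is not None and dm in model.reactions:
        rows.append(Row("dm_murein_demand", "demand", "E",
                        d["murein_mmol_per_gdw"] * mu, {dm: 1.0}))

    gam_rxn = d.get("gam_reaction")
    if gam_rxn is not None and gam_rxn in model.reactions:
        rows.append(Row("dm_gam", "demand", "E",
                        d["gam_mmol_atp_per_gdw"] * mu, {gam_rxn: 1.0}))

    lpp = d.get("lipoprotein_porf")
    if lpp is not None and lpp in model.porfs:
        flux_per_mu = d["lipoprotein_per_cell"] / model.counts_per_flux()
        rows.append(Row("dm_lipoprotein", "demand", "G",
                        flux_per_mu * mu, {model.synthesis_flux(lpp): 1.0}))

    # dry-mass closure: every gram of new cells is made of the modeled
    # macromolecules, so the gross mass-synthesis flux (protein from pORF
    # synthesis; lipids, LPS and murein from the gross production of
    # mass-bearing metabolites) equals the accounted dry mass times mu.
    # The solver chooses the composition; surplus capacity is disposed of
    # as whichever macromolecule is cheapest to make.
    biomass = params["cell"].get("biomass_mg_per_gdw", 0.0)
    if biomass and model.porfs:
        coefs = {model.synthesis_flux(p): model.porfs[p].molecular_weight
                 for p in sorted(model.porfs)}
        for rid in sorted(model.reactions):
            rxn = model.reactions[rid]
            produced = sum(
                coef * model.metabolites[met].mass_da
                for met, coef in rxn.stoichiometry.items()
                if coef > 0 and model.metabolites[met].mass_da is not None
            )
            if produced:
                coefs[rid] = coefs.get(rid, 0.0) + produced
        rows.append(Row("dm_biomass_closure", "demand", "E",
                        biomass * mu, coefs))

    frac = d.get("out_of_scope_fraction", 0.0)
    dummy = d.get("out_of_scope_porf")
    if dummy is not None and dummy in model.porfs:
        if not (0.0 <= frac < 1.0):
            raise ValidationError(
                f"out-of-scope fraction must be in [0,1), got {frac}"
            )
        coefs = {}
        for p in sorted(model.porfs):
            mw = model.porfs[p].molecular_weight
            if p == dummy:
                coefs[model.synthesis_flux(p)] = (1.0 - frac) * mw
            else:
                coefs[model.synthesis_flux(p)] = -frac * mw
        rows.append(Row("dm_out_of_scope", "demand", "E", 0.0, coefs))
    return rows
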