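"""Core domain types and assembly of the mu-parameterized constraint system.

The model couples metabolism and gene expression: protein synthesis fluxes
are ordinary LP variables, enzyme levels follow from dilution at growth
rate mu (e = v_synth / mu), and every constraint row is linear in the
fluxes once mu is fixed.  Growth maximization is therefore a bisection
over an LP feasibility problem (see :mod:`envme.solver`).

Units
-----
Fluxes are mmol gDW^-1 h^-1 (protein-synthesis fluxes: mmol protein
gDW^-1 h^-1).  Turnover numbers are s^-1 and converted once, here, with
the factor 3600.  Per-molecule areas are carried in nm^2; the geometric
cell surface area is mu m^2 and membrane rows are written on the mu m^2
scale (a pure row scaling chosen for LP conditioning).
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field
from typing import Optional

from Bio.SeqUtils import molecular_weight as _bio_mw

AVOGADRO = 6.02214076e23
KCAT_PER_HOUR = 3600.0  # s^-1 -> h^-1
NM2_TO_UM2 = 1e-6

COMPARTMENTS = ("cytoplasm", "inner_membrane", "periplasm", "outer_membrane")
MET_COMPARTMENTS = COMPARTMENTS + ("extracellular",)

COMPARTMENT_SUFFIX = {
    "cytoplasm": "c",
    "periplasm": "p",
    "inner_membrane": "im",
    "outer_membrane": "om",
    "extracellular": "e",
}


class ModelError(Exception):
    """Base class for model construction problems."""


class SchemaError(ModelError):
    """The input document violates the model schema."""


class ValidationError(ModelError):
    """A field value is out of its allowed domain."""


class ConfigurationError(ModelError):
    """A required parameter or machinery entry is missing."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PORF:
    """One protein-coding ORF with its physical properties.

    ``length`` is the residue count; ``molecular_weight`` is in Da.  When a
    sequence is supplied the length and mass are derived from it, and a
    conflicting explicit length is rejected.
    """

    id: str
    name: str = ""
    length: int = 0
    molecular_weight: float = 0.0
    annotated_location: Optional[str] = None
    is_lipoprotein: bool = False
    is_beta_barrel: bool = False
    folds_with_cofactor: bool = False
    tm_segment_count: int = 0
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sequence is not None:
            if self.length and self.length != len(self.sequence):
                raise ValidationError(
                    f"pORF {self.id}: explicit length {self.length} does not "
                    f"match sequence length {len(self.sequence)}"
                )
            self.length = len(self.sequence)
            self.molecular_weight = porf_mass_from_sequence(self.sequence)
        if self.length < 1:
            raise ValidationError(f"pORF {self.id}: length must be >= 1")
        if self.molecular_weight <= 0:
            raise ValidationError(f"pORF {self.id}: molecular weight must be > 0")
        if self.tm_segment_count < 0:
            raise ValidationError(f"pORF {self.id}: negative tm_segment_count")
        if (
            self.annotated_location is not None
            and self.annotated_location not in COMPARTMENTS
        ):
            raise ValidationError(
                f"pORF {self.id}: unknown location {self.annotated_location!r}"
            )


@dataclass
class ProteinComplex:
    """A protein complex: pORF composition with positive copy numbers."""

    id: str
    composition: dict[str, int]
    compartment: Optional[str] = None  # derived, see envme.compartments

    def __post_init__(self) -> None:
        if not self.composition:
            raise ValidationError(f"complex {self.id}: empty composition")
        for porf_id, n in self.composition.items():
            if not (isinstance(n, int) and n > 0):
                raise ValidationError(
                    f"complex {self.id}: copy number for {porf_id} must be a "
                    f"positive integer, got {n!r}"
                )


@dataclass
class Metabolite:
    id: str
    compartment: str
    solute_radius: Optional[float] = None  # hydrodynamic, Angstrom
    membrane_area: Optional[float] = None  # nm^2 per molecule (lipid species)
    mass_da: Optional[float] = None        # counts toward the dry-mass closure

    def __post_init__(self) -> None:
        if self.compartment not in MET_COMPARTMENTS:
            raise ValidationError(
                f"metabolite {self.id}: unknown compartment {self.compartment!r}"
            )
        if self.solute_radius is not None and self.solute_radius <= 0:
            raise ValidationError(f"metabolite {self.id}: solute_radius must be > 0")
        if self.membrane_area is not None and self.membrane_area <= 0:
            raise ValidationError(f"metabolite {self.id}: membrane_area must be > 0")
        if self.mass_da is not None and self.mass_da <= 0:
            raise ValidationError(f"metabolite {self.id}: mass_da must be > 0")


@dataclass
class Reaction:
    """A flux variable with stoichiometry and optional enzymatic coupling.

    ``coupling`` lists (complex id, kcat s^-1) pairs; when absent but
    ``catalyst`` and ``kcat`` are set, a single pair is derived from them.
    ``mu_scaled_bounds`` marks growth-rate scalable demands: effective
    bounds are bound * mu at assembly time.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    catalyst: Optional[str] = None
    kcat: Optional[float] = None
    coupling: list[tuple[str, float]] = field(default_factory=list)
    mu_scaled_bounds: bool = False
    kind: str = "metabolic"

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ValidationError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    def effective_coupling(self) -> list[tuple[str, float]]:
        if self.coupling:
            return list(self.coupling)
        if self.catalyst is not None and self.kcat is not None:
            return [(self.catalyst, self.kcat)]
        return []


@dataclass
class Row:
    """One linear constraint row: sum(coefs) <sense> rhs."""

    name: str
    kind: str  # mass_balance | coupling | membrane | demand
    sense: str  # "E", "L", "G"
    rhs: float
    coefs: dict[str, float]


@dataclass
class MEProblem:
    """The constraint system at a fixed growth rate, ready for the LP."""

    mu: float
    columns: list[str]
    col_bounds: dict[str, tuple[float, float]]
    rows: list[Row]
    # maps a split column back to (reaction id, +1/-1)
    col_direction: dict[str, tuple[str, float]] = field(default_factory=dict)

    def rows_of_kind(self, kind: str) -> list[Row]:
        return [r for r in self.rows if r.kind == kind]


# ---------------------------------------------------------------------------
# default parameters
# ---------------------------------------------------------------------------

DEFAULT_PARAMETERS: dict = {
    "kcats": {
        # SecA turnover from the literature; the remaining machinery values
        # are placeholders standing in for unpublished pathway tables.
        "seca": 4.0,
        "secyegdf": 20.0,
        "tatbc": 1.0,
        "yidc": 5.0,
        "lolcde": 1.0,
        "bam": 0.5,
        "lgt": 2.0,
        "ribosome_aa_per_s": 15.0,
    },
    "kcat_multipliers": {"seca": 1.0, "secyegdf": 1.0, "ribosome": 1.0},
    "translation": {"atp_per_aa": 2.0},
    "translocation": {
        "atp_per_residues": 25,
        "tat_pmf_cost": 0.0,
        "tatbc_multiplier": 1.0,
        "tata_polynomial": [2.0, 0.5],  # placeholder linear fit N(d) = 2 + 0.5 d
        "tata_min": 4,
    },
    "porins": {},
    "porin_diffusion": {
        "delta_c_M": 6.5e-4,
        "temperature_K": 310.0,
        "viscosity_Pa_s": 6.9e-4,
    },
    "membrane": {
        "areas_nm2": {
            "pe": 0.6,
            "pg": 0.6,
            "clpn": 1.2,
            "lps": 1.6,
            "lipoprotein_moiety": 1.0,
        },
        "fractions": {"pe": 0.77, "pg": 0.18, "clpn": 0.05},
        "caps": {"inner_membrane": 1.0, "outer_membrane": 1.0},
        "floors": {"inner_membrane": 0.0, "outer_membrane": 0.0},
        "corrected_cap_term": False,
        "geometry": {"radius_um": 0.456, "length_um": 3.9},
        "lipid_species": {"pe": "pe_im", "pg": "pg_im", "clpn": "clpn_im",
                          "lps": "lps_om"},
    },
    "demands": {
        "murein_mmol_per_gdw": 0.01389,
        "murein_recycle_fraction": 0.45,
        "murein_demand_reaction": "DM_murein",
        "murein_transport_reaction": "AMPG",
        "gam_mmol_atp_per_gdw": 34.98,
        "gam_reaction": "GAM",
        "out_of_scope_fraction": 0.36,
        "out_of_scope_porf": None,
        "lipoprotein_per_cell": 7.0e5,
        "lipoprotein_porf": None,
    },
    "cell": {"dry_mass_g": 2.8e-13, "biomass_mg_per_gdw": 750.0},
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


# ---------------------------------------------------------------------------
# the model container
# ---------------------------------------------------------------------------

@dataclass
class Model:
    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]
    porfs: dict[str, PORF]
    complexes: dict[str, ProteinComplex]
    pathways: dict
    parameters: dict

    # derived state, populated by expand()
    assignments: dict = field(default_factory=dict)   # entity id -> CompartmentAssignment
    routes: dict = field(default_factory=dict)        # porf id -> TranslocationRoute
    expression_reactions: dict[str, Reaction] = field(default_factory=dict)
    expanded: bool = False

    def counts_per_flux(self) -> float:
        """Molecules per cell per (mmol gDW^-1) of steady-state amount."""
        return AVOGADRO * self.parameters["cell"]["dry_mass_g"] * 1e-3

    def all_reactions(self) -> dict[str, Reaction]:
        merged = dict(self.reactions)
        merged.update(self.expression_reactions)
        return merged

    # convenience lookups -------------------------------------------------
    def synthesis_flux(self, porf_id: str) -> str:
        return f"PSYN_{porf_id}"

    def formation_flux(self, complex_id: str) -> str:
        return f"FORM_{complex_id}"

    def machinery_complex(self, name: str) -> str:
        mapping = self.pathways.get("machinery", {})
        if name not in mapping:
            raise ConfigurationError(f"no machinery complex mapped for {name!r}")
        return mapping[name]


# ---------------------------------------------------------------------------
# loading / writing
# ---------------------------------------------------------------------------

def porf_mass_from_sequence(sequence: str) -> float:
    """Average molecular mass (Da) of a protein from its sequence.

    Sum of average residue masses plus one water; computed with Biopython's
    average amino-acid mass table.
    """
    if not sequence:
        raise ValidationError("empty protein sequence")
    try:
        return float(_bio_mw(sequence, seq_type="protein"))
    except ValueError as exc:  # unknown residue letter
        raise ValidationError(str(exc)) from exc


def load_model(document: dict) -> Model:
    """Validate a model document and build the in-memory model.

    Cross-references (reaction metabolites, complex members, catalysts) are
    resolved here; derived state (compartments, routes, expression
    reactions) is computed later by :func:`expand`.
    """
    if not isinstance(document, dict):
        raise SchemaError("model document must be a JSON object")
    for key in ("metabolites", "reactions", "porfs", "complexes"):
        if key not in document:
            raise SchemaError(f"missing top-level key {key!r}")

    metabolites = {}
    for m in document["metabolites"]:
        met = Metabolite(**m)
        if met.id in metabolites:
            raise SchemaError(f"duplicate metabolite id {met.id!r}")
        metabolites[met.id] = met

    porfs = {}
    for p in document["porfs"]:
        porf = PORF(**p)
        if porf.id in porfs:
            raise SchemaError(f"duplicate pORF id {porf.id!r}")
        porfs[porf.id] = porf

    complexes = {}
    for c in document["complexes"]:
        cplx = ProteinComplex(**c)
        if cplx.id in complexes:
            raise SchemaError(f"duplicate complex id {cplx.id!r}")
        for member in cplx.composition:
            if member not in porfs:
                raise SchemaError(
                    f"complex {cplx.id} references unknown pORF {member!r}"
                )
        complexes[cplx.id] = cplx

    reactions = {}
    for r in document["reactions"]:
        r = dict(r)
        if "coupling" in r:
            r["coupling"] = [tuple(x) for x in r["coupling"]]
        rxn = Reaction(**r)
        if rxn.id in reactions:
            raise SchemaError(f"duplicate reaction id {rxn.id!r}")
        for met in rxn.stoichiometry:
            if met not in metabolites:
                raise SchemaError(
                    f"reaction {rxn.id} references unknown metabolite {met!r}"
                )
        if rxn.catalyst is not None and rxn.catalyst not in complexes:
            raise SchemaError(
                f"reaction {rxn.id} references unknown catalyst {rxn.catalyst!r}"
            )
        reactions[rxn.id] = rxn

    parameters = _deep_merge(DEFAULT_PARAMETERS, document.get("parameters", {}))
    pathways = copy.deepcopy(document.get("pathways", {}))

    return Model(
        metabolites=metabolites,
        reactions=reactions,
        porfs=porfs,
        complexes=complexes,
        pathways=pathways,
        parameters=parameters,
    )


def _porf_doc(p: PORF) -> dict:
    doc = {
        "id": p.id,
        "name": p.name,
        "length": p.length,
        "molecular_weight": round(p.molecular_weight, 4),
        "annotated_location": p.annotated_location,
        "is_lipoprotein": p.is_lipoprotein,
        "is_beta_barrel": p.is_beta_barrel,
        "folds_with_cofactor": p.folds_with_cofactor,
        "tm_segment_count": p.tm_segment_count,
    }
    if p.sequence is not None:
        doc["sequence"] = p.sequence
        del doc["length"]
        del doc["molecular_weight"]
    return doc


def write_model(model: Model) -> dict:
    """Serialize a model back to a canonical (sorted-id) document."""
    doc = {
        "metabolites": [
            {k: v for k, v in {
                "id": m.id,
                "compartment": m.compartment,
                "solute_radius": m.solute_radius,
                "membrane_area": m.membrane_area,
                "mass_da": m.mass_da,
            }.items() if v is not None}
            for m in sorted(model.metabolites.values(), key=lambda m: m.id)
        ],
        "porfs": [
            _porf_doc(p) for p in sorted(model.porfs.values(), key=lambda p: p.id)
        ],
        "complexes": [
            {"id": c.id, "composition": dict(sorted(c.composition.items()))}
            for c in sorted(model.complexes.values(), key=lambda c: c.id)
        ],
        "reactions": [],
        "pathways": model.pathways,
        "parameters": model.parameters,
    }
    for r in sorted(model.reactions.values(), key=lambda r: r.id):
        rd = {
            "id": r.id,
            "stoichiometry": dict(sorted(r.stoichiometry.items())),
            "lower_bound": r.lower_bound,
            "upper_bound": r.upper_bound,
        }
        if r.catalyst is not None:
            rd["catalyst"] = r.catalyst
        if r.kcat is not None:
            rd["kcat"] = r.kcat
        if r.coupling:
            rd["coupling"] = [list(x) for x in r.coupling]
        if r.mu_scaled_bounds:
            rd["mu_scaled_bounds"] = True
        doc["reactions"].append(rd)
    return doc


def dumps_canonical(document: dict) -> str:
    """Canonical JSON text used for byte-identity round-trip checks."""
    return json.dumps(document, sort_keys=True, indent=1)


# ---------------------------------------------------------------------------
# expansion: compartments, routes, expression reactions
# ---------------------------------------------------------------------------

def expand(model: Model) -> Model:
    """Instantiate derived state in place: compartment assignments,
    translocation routes, and the expression reactions (protein synthesis,
    translocation stages, complex formation, lipid leaflet allocation).
    """
    from envme import compartments as _cmp
    from envme import coupling as _coupling
    from envme import translocation as _tl

    model.assignments = {}
    for porf in model.porfs.values():
        model.assignments[porf.id] = _cmp.assign_porf(porf)
    for cplx in model.complexes.values():
        asn = _cmp.assign_complex(cplx, model.assignments)
        model.assignments[cplx.id] = asn
        cplx.compartment = asn.compartment

    model.routes = {}
    overrides = model.pathways.get("overrides", {})
    for porf in model.porfs.values():
        model.routes[porf.id] = _tl.assign_pathway(
            porf, model.assignments[porf.id], overrides.get(porf.id), model
        )

    expr: dict[str, Reaction] = {}

    def add(rxn: Reaction) -> None:
        if rxn.id in expr or rxn.id in model.reactions:
            raise SchemaError(f"duplicate generated reaction id {rxn.id!r}")
        expr[rxn.id] = rxn

    params = model.parameters
    atp_per_aa = params["translation"]["atp_per_aa"]

    # protein synthesis: aa pool + ATP -> cytoplasmic precursor species
    aa_met = model.pathways.get("species", {}).get("amino_acid", "aa_c")
    atp = model.pathways.get("species", {}).get("atp", "atp_c")
    adp = model.pathways.get("species", {}).get("adp", "adp_c")
    for porf in sorted(model.porfs.values(), key=lambda p: p.id):
        prec = f"prot_{porf.id}_c"
        model.metabolites.setdefault(prec, Metabolite(prec, "cytoplasm"))
        stoich = {aa_met: -float(porf.length), prec: 1.0}
        if atp_per_aa:
            stoich[atp] = -atp_per_aa * porf.length
            stoich[adp] = atp_per_aa * porf.length
        add(Reaction(
            id=model.synthesis_flux(porf.id),
            stoichiometry=stoich,
            kind="synthesis",
        ))

    # translocation stages
    for porf in sorted(model.porfs.values(), key=lambda p: p.id):
        for rxn in _tl.instantiate_route(porf, model.routes[porf.id], model):
            add(rxn)

    # complex formation (the formation flux is also the dilution sink; at
    # steady state the enzyme level is v_form / mu)
    member_of = {pid: False for pid in model.porfs}
    for cplx in sorted(model.complexes.values(), key=lambda c: c.id):
        stoich = {}
        for pid, n in cplx.composition.items():
            loc = model.assignments[pid].compartment
            species = f"prot_{pid}_{COMPARTMENT_SUFFIX[loc]}"
            stoich[species] = stoich.get(species, 0.0) - float(n)
            member_of[pid] = True
        add(Reaction(id=model.formation_flux(cplx.id), stoichiometry=stoich,
                     kind="formation"))

    # implicit monomer "complex" for pORFs not in any declared complex,
    # so every synthesized protein has a dilution sink
    for pid, used in sorted(member_of.items()):
        if used:
            continue
        cplx = ProteinComplex(id=f"MONO_{pid}", composition={pid: 1})
        cplx.compartment = model.assignments[pid].compartment
        model.complexes[cplx.id] = cplx
        model.assignments[cplx.id] = model.assignments[pid]
        loc = COMPARTMENT_SUFFIX[cplx.compartment]
        add(Reaction(id=model.formation_flux(cplx.id),
                     stoichiometry={f"prot_{pid}_{loc}": -1.0},
                     kind="formation"))

    # lipid leaflet allocation pseudo-reactions (sinks whose fluxes carry
    # the membrane area accounting)
    from envme import membrane as _mem
    for rxn in _mem.allocation_reactions(model):
        add(rxn)

    # porin diffusion coupling on transport reactions catalyzed by porins
    _coupling.attach_porin_coupling(model)

    model.expression_reactions = expr
    model.expanded = True
    return model


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def assemble(model: Model, mu: float, drop_families: set[str] | None = None) -> MEProblem:
    """Build the full constraint system at growth rate ``mu``.

    Rows: mass balance (=0) for every metabolite; coupling rows (<=0,
    mu-dependent coefficients); membrane rows (mu-dependent right-hand
    sides); demand rows (murein recycling link, proteome budget,
    out-of-scope proteome).  ``drop_families`` omits whole row families,
    used for relaxation tests and infeasibility diagnosis.
    """
    from envme import coupling as _coupling
    from envme import membrane as _mem

    if mu <= 0:
        raise ValidationError(f"mu must be > 0, got {mu}")
    if not model.expanded:
        expand(model)
    drop = drop_families or set()

    reactions = model.all_reactions()
    columns: list[str] = []
    col_bounds: dict[str, tuple[float, float]] = {}
    col_direction: dict[str, tuple[str, float]] = {}

    for rid in sorted(reactions):
        rxn = reactions[rid]
        lb, ub = rxn.lower_bound, rxn.upper_bound
        if rxn.mu_scaled_bounds:
            lb, ub = lb * mu, ub * mu
        fwd_ub = max(ub, 0.0)
        fwd_lb = max(lb, 0.0)
        columns.append(rid)
        col_bounds[rid] = (fwd_lb, fwd_ub)
        col_direction[rid] = (rid, 1.0)
        if lb < 0:
            rev = f"{rid}__rev"
            columns.append(rev)
            col_bounds[rev] = (max(-ub, 0.0), -lb)
            col_direction[rev] = (rid, -1.0)

    rows: list[Row] = []

    # mass balance
    if "mass_balance" not in drop:
        balance: dict[str, dict[str, float]] = {}
        for rid in sorted(reactions):
            rxn = reactions[rid]
            for met, coef in rxn.stoichiometry.items():
                row = balance.setdefault(met, {})
                row[rid] = row.get(rid, 0.0) + coef
                rev = f"{rid}__rev"
                if rev in col_bounds:
                    row[rev] = row.get(rev, 0.0) - coef
        for met in sorted(balance):
            rows.append(Row(f"mb_{met}", "mass_balance", "E", 0.0, balance[met]))

    # coupling
    if "coupling" not in drop:
        rows.extend(_coupling.coupling_rows(model, mu))

    # membrane
    if "membrane" not in drop:
        rows.extend(_mem.build_membrane_rows(model, mu))

    # demands
    if "demand" not in drop:
        rows.extend(_mem.murein_recycling_rows(model))
        rows.extend(_mem.demand_rows(model, model.parameters, mu))

    # keep only rows whose columns all exist (defensive; all should)
    for row in rows:
        for col in row.coefs:
            if col not in col_bounds:
                raise ConfigurationError(
                    f"row {row.name} references unknown flux {col!r}"
                )
        if not all(math.isfinite(c) for c in row.coefs.values()):
            raise ValidationError(f"row {row.name} has non-finite coefficients")

    return MEProblem(
        mu=mu,
        columns=columns,
        col_bounds=col_bounds,
        rows=rows,
        col_direction=col_direction,
    )


def net_fluxes(problem: MEProblem, x) -> dict[str, float]:
    """Fold split forward/backward columns back into net reaction fluxes."""
    net: dict[str, float] = {}
    for j, col in enumerate(problem.columns):
        rid, sign = problem.col_direction[col]
        net[rid] = net.get(rid, 0.0) + sign * float(x[j])
    return net
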