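"""Translocation pathway assignment and per-pORF route instantiation.

Six canonical pathways (SRP/Sec, SecB/Sec, Tat, YidC, Lol, Bam) plus
three SRP/Sec variants and lipoprotein biogenesis (Lgt/Lsp/Lnt) are
represented as templates.  Each non-cytoplasmic pORF is assigned an
ordered list of templates by rule (or by explicit override, standing in
for per-protein experimental evidence), and the route is instantiated as
mechanistic reactions that move exactly one protein copy from the
cytoplasm to its destination compartment, paying the pathway's energetic
costs and carrying the pathway's rate-limiting machinery for coupling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from envme.model import (
    COMPARTMENT_SUFFIX,
    ConfigurationError,
    Metabolite,
    Model,
    PORF,
    Reaction,
    ValidationError,
)
from envme.compartments import CompartmentAssignment


class AssignmentError(ValidationError):
    """A non-cytoplasmic pORF matched no pathway rule."""


@dataclass(frozen=True)
class PathwayTemplate:
    name: str
    machinery: tuple[str, ...]      # logical machinery names
    energy_rule: str                # ATP_per_residue | translation_driven | pmf_driven | none
    kcat_source: str                # which machinery member's turnover limits the route
    kcat_key: str                   # key into parameters["kcats"]


TEMPLATES: dict[str, PathwayTemplate] = {
    "SRP_Sec": PathwayTemplate(
        "SRP_Sec", ("SRP", "FtsY", "SecYEGDF"), "translation_driven",
        "SecYEGDF", "secyegdf"),
    "SecB_Sec": PathwayTemplate(
        "SecB_Sec", ("SecB", "SecA", "SecYEGDF"), "ATP_per_residue",
        "SecA", "seca"),
    "Tat": PathwayTemplate(
        "Tat", ("TatBC", "TatA"), "pmf_driven", "TatBC", "tatbc"),
    "YidC": PathwayTemplate(
        "YidC", ("YidC",), "translation_driven", "YidC", "yidc"),
    "Lol": PathwayTemplate(
        "Lol", ("LolCDE", "LolB"), "ATP_per_residue", "LolCDE", "lolcde"),
    "Bam": PathwayTemplate(
        "Bam", ("SurA", "Bam"), "none", "Bam", "bam"),
    # alternative SRP/Sec variants: override-only, never rule-inferred
    "SRP_Sec_YidC": PathwayTemplate(
        "SRP_Sec_YidC", ("SRP", "FtsY", "SecYEGDF", "YidC"),
        "translation_driven", "SecYEGDF", "secyegdf"),
    "SRP_Sec_SecA": PathwayTemplate(
        "SRP_Sec_SecA", ("SRP", "FtsY", "SecYEGDF", "SecA"),
        "ATP_per_residue", "SecA", "seca"),
    "SRP_Sec_SecA_YidC": PathwayTemplate(
        "SRP_Sec_SecA_YidC", ("SRP", "FtsY", "SecYEGDF", "SecA", "YidC"),
        "ATP_per_residue", "SecA", "seca"),
    "lipoprotein_biogenesis": PathwayTemplate(
        "lipoprotein_biogenesis", ("Lgt", "Lsp", "Lnt"), "none", "Lgt", "lgt"),
}


@dataclass
class TranslocationRoute:
    porf_id: str
    pathways: list[str]             # ordered template names
    atp_cost: int = 0               # ATP molecules per translocation event
    tata_count: Optional[int] = None
    destination: str = "cytoplasm"


# ---------------------------------------------------------------------------
# elementary calculators
# ---------------------------------------------------------------------------

def seca_atp_cost(length: int, residues_per_atp: int = 25) -> int:
    """ATP hydrolyzed by SecA per translocation event: 1 ATP per ~25
    residues, rounded up (conservative accounting)."""
    if length < 0:
        raise ValidationError(f"negative protein length {length}")
    if length == 0:
        return 0
    return math.ceil(length / residues_per_atp)


def protein_diameter(molecular_weight: float) -> float:
    """Protein diameter in Angstrom from mass: volume = 1.21 * MW (A^3),
    assuming a sphere."""
    if molecular_weight < 0:
        raise ValidationError(f"negative molecular weight {molecular_weight}")
    volume = 1.21 * molecular_weight
    radius = (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)
    return 2.0 * radius


def tata_count(
    diameter: float, polynomial_coefficients, minimum: int = 1
) -> int:
    """Number of TatA subunits recruited for a substrate of the given
    channel diameter (Angstrom): the configured polynomial (ascending
    coefficients) evaluated at the diameter, rounded up to the nearest
    integer and floored at the minimum oligomer size."""
    coeffs = list(polynomial_coefficients or [])
    if not coeffs:
        raise ConfigurationError("empty TatA polynomial coefficient list")
    if diameter < 0:
        raise ValidationError(f"negative diameter {diameter}")
    value = sum(c * diameter**k for k, c in enumerate(coeffs))
    return max(int(math.ceil(value)), int(minimum))


# ---------------------------------------------------------------------------
# pathway assignment
# ---------------------------------------------------------------------------

def assign_pathway(
    porf: PORF,
    assignment: CompartmentAssignment,
    override: Optional[list[str]],
    model: Optional[Model] = None,
) -> TranslocationRoute:
    """Assign the ordered pathway list for one pORF.

    Explicit overrides win.  Default rules: integral inner-membrane
    protein -> SRP/Sec; cofactor-folding periplasmic or outer-membrane
    protein -> Tat; outer-membrane beta-barrel -> SecB/Sec then Bam;
    lipoprotein -> SecB/Sec + biogenesis (+ Lol when bound for the outer
    membrane); remaining periplasmic -> SecB/Sec; cytoplasmic -> empty.
    """
    comp = assignment.compartment
    if override is not None:
        for name in override:
            if name not in TEMPLATES:
                raise AssignmentError(
                    f"pORF {porf.id}: unknown pathway {name!r} in override"
                )
        pathways = list(override)
    elif comp == "cytoplasm":
        pathways = []
    elif porf.is_lipoprotein:
        pathways = ["SecB_Sec", "lipoprotein_biogenesis"]
        if comp == "outer_membrane":
            pathways.append("Lol")
    elif comp in ("periplasm", "outer_membrane") and porf.folds_with_cofactor:
        pathways = ["Tat"]
    elif comp == "outer_membrane" and porf.is_beta_barrel:
        pathways = ["SecB_Sec", "Bam"]
    elif comp == "inner_membrane":
        pathways = ["SRP_Sec"]
    elif comp == "periplasm":
        pathways = ["SecB_Sec"]
    else:
        raise AssignmentError(
            f"pORF {porf.id}: no pathway rule matches compartment {comp}"
        )

    route = TranslocationRoute(porf_id=porf.id, pathways=pathways,
                               destination=comp)
    params = model.parameters if model is not None else None
    residues_per_atp = 25
    if params is not None:
        residues_per_atp = params["translocation"]["atp_per_residues"]
    for name in pathways:
        tpl = TEMPLATES[name]
        if tpl.energy_rule == "ATP_per_residue" and name != "Lol":
            route.atp_cost += seca_atp_cost(porf.length, residues_per_atp)
        elif name == "Lol":
            route.atp_cost += 1  # LolCDE ATPase: one ATP per release event
        if name == "Tat":
            poly = [2.0, 0.5]
            tmin = 1
            if params is not None:
                poly = params["translocation"]["tata_polynomial"]
                tmin = params["translocation"]["tata_min"]
            route.tata_count = tata_count(
                protein_diameter(porf.molecular_weight), poly, tmin
            )
    return route


# ---------------------------------------------------------------------------
# route instantiation
# ---------------------------------------------------------------------------

def _species(model: Model, name: str, compartment: str) -> str:
    model.metabolites.setdefault(name, Metabolite(name, compartment))
    return name


def _machinery_cplx(model: Model, name: str, porf_id: str) -> str:
    mapping = model.pathways.get("machinery", {})
    if name not in mapping:
        raise ConfigurationError(
            f"route for pORF {porf_id}: machinery complex for {name!r} "
            f"is not mapped in the model"
        )
    cid = mapping[name]
    if cid not in model.complexes:
        raise ConfigurationError(
            f"route for pORF {porf_id}: machinery complex {cid!r} ({name}) "
            f"does not exist in the model"
        )
    return cid


def instantiate_route(
    porf: PORF, route: TranslocationRoute, model: Model
) -> list[Reaction]:
    """Instantiate the translocation reactions for one pORF.

    One reaction per pathway stage; each consumes the precursor species of
    the previous stage and produces the next, ending at the destination
    compartment.  SecB/Sec stages hydrolyze the route's SecA ATP cost; Tat
    stages occupy ``tata_count`` TatA equivalents through their coupling
    row; lipoprotein biogenesis acylates the prolipoprotein with fatty
    acids drawn from any available phospholipid (one reaction variant per
    species, the solver chooses).
    """
    if not route.pathways:
        return []
    params = model.parameters
    kcats = params["kcats"]
    mults = params["kcat_multipliers"]
    species = model.pathways.get("species", {})
    atp = species.get("atp", "atp_c")
    adp = species.get("adp", "adp_c")

    dest_suffix = COMPARTMENT_SUFFIX[route.destination]
    final = _species(model, f"prot_{porf.id}_{dest_suffix}", route.destination)
    current = f"prot_{porf.id}_c"  # created by the synthesis reaction

    reactions: list[Reaction] = []
    n = len(route.pathways)
    for i, name in enumerate(route.pathways):
        tpl = TEMPLATES[name]
        for m in tpl.machinery:
            _machinery_cplx(model, m, porf.id)
        last = i == n - 1

        # stage product species and compartment
        if last:
            product, prod_comp = final, route.destination
        elif name in ("SecB_Sec", "Tat"):
            prod_comp = "periplasm"
            product = _species(model, f"prot_{porf.id}_s{i}_p", prod_comp)
        elif name == "lipoprotein_biogenesis":
            prod_comp = "inner_membrane"
            product = _species(model, f"prot_{porf.id}_s{i}_im", prod_comp)
        else:
            prod_comp = route.destination
            product = _species(model, f"prot_{porf.id}_s{i}", prod_comp)

        stoich = {current: -1.0, product: 1.0}
        coupling: list[tuple[str, float]] = []
        catalyst = None

        if name in ("SecB_Sec", "SRP_Sec_SecA", "SRP_Sec_SecA_YidC"):
            cost = float(seca_atp_cost(
                porf.length, params["translocation"]["atp_per_residues"]))
            if cost:
                stoich[atp] = stoich.get(atp, 0.0) - cost
                stoich[adp] = stoich.get(adp, 0.0) + cost
            catalyst = _machinery_cplx(model, "SecYEGDF", porf.id)
            coupling.append((_machinery_cplx(model, "SecA", porf.id),
                             kcats["seca"] * mults["seca"]))
        elif name in ("SRP_Sec", "SRP_Sec_YidC"):
            catalyst = _machinery_cplx(model, "SecYEGDF", porf.id)
            coupling.append((catalyst, kcats["secyegdf"] * mults["secyegdf"]))
        elif name == "Tat":
            catalyst = _machinery_cplx(model, "TatBC", porf.id)
            k_tat = kcats["tatbc"] * params["translocation"]["tatbc_multiplier"]
            coupling.append((catalyst, k_tat))
            # TatA occupancy: an event engages tata_count subunit equivalents
            coupling.append((_machinery_cplx(model, "TatA", porf.id),
                             kcats["tatbc"] / float(route.tata_count)))
            pmf = params["translocation"]["tat_pmf_cost"]
            if pmf:
                pmf_met = species.get("pmf", "h_p")
                stoich[pmf_met] = stoich.get(pmf_met, 0.0) - pmf
        elif name == "YidC":
            catalyst = _machinery_cplx(model, "YidC", porf.id)
            coupling.append((catalyst, kcats["yidc"]))
        elif name == "Lol":
            stoich[atp] = stoich.get(atp, 0.0) - 1.0
            stoich[adp] = stoich.get(adp, 0.0) + 1.0
            catalyst = _machinery_cplx(model, "LolCDE", porf.id)
            coupling.append((catalyst, kcats["lolcde"]))
        elif name == "Bam":
            catalyst = _machinery_cplx(model, "Bam", porf.id)
            coupling.append((catalyst, kcats["bam"]))
        elif name == "lipoprotein_biogenesis":
            catalyst = _machinery_cplx(model, "Lgt", porf.id)
            coupling.append((catalyst, kcats["lgt"]))
            # acyl donor: one variant per available phospholipid species
            lipid_species = params["membrane"]["lipid_species"]
            variants = []
            for lip in sorted(("pe", "pg", "clpn")):
                met = lipid_species.get(lip)
                if met is not None and met in model.metabolites:
                    variants.append((lip, met))
            if not variants:
                raise ConfigurationError(
                    f"route for pORF {porf.id}: no phospholipid available "
                    f"as acyl donor for lipoprotein biogenesis"
                )
            for lip, met in variants:
                vst = dict(stoich)
                vst[met] = vst.get(met, 0.0) - 1.0
                reactions.append(Reaction(
                    id=f"TL_{porf.id}_{i}_{name}_{lip}",
                    stoichiometry=vst,
                    catalyst=catalyst,
                    coupling=list(coupling),
                    kind="translocation",
                ))
            current = product
            continue
        else:  # pragma: no cover - template table is closed
            raise ConfigurationError(f"no stage builder for pathway {name}")

        reactions.append(Reaction(
            id=f"TL_{porf.id}_{i}_{name}",
            stoichiometry=stoich,
            catalyst=catalyst,
            coupling=coupling,
            kind="translocation",
        ))
        current = product
    return reactions


def parse_override_tsv(text: str) -> dict[str, list[str]]:
    """Parse a pathway-override table: one line per pORF, tab-separated
    pORF id then ordered pathway names."""
    overrides: dict[str, list[str]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        pid, names = parts[0], [n for n in parts[1:] if n]
        for n in names:
            if n not in TEMPLATES:
                raise AssignmentError(f"unknown pathway {n!r} for {pid}")
        overrides[pid] = names
    return overrides


def route_report_tsv(model: Model) -> str:
    """TSV of pORF, route, atp_cost, tatA count."""
    lines = ["porf\troute\tatp_cost\ttata_count\tdestination"]
    for pid in sorted(model.routes):
        r = model.routes[pid]
        lines.append(
            f"{pid}\t{'+'.join(r.pathways) or '-'}\t{r.atp_cost}\t"
            f"{r.tata_count if r.tata_count is not None else '-'}\t{r.destination}"
        )
    return "\n".join(lines) + "\n"
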