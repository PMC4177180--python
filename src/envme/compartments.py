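"""Compartment assignment for pORFs and complexes, and membrane-crossing
checks on reactions.

Every protein ends up in exactly one of four compartments: cytoplasm,
inner membrane, periplasm, outer membrane.  Membrane evidence (predicted
transmembrane segments or a lipid anchor) overrides a soluble annotation;
complexes take the "highest" compartment of their members, with the outer
membrane taking precedence over the inner (the AcrAB-TolC rule), so that
e.g. an ATP synthase with cytoplasmic subunits is still an inner-membrane
complex.
"""

from __future__ import annotations

from dataclasses import dataclass

from envme.model import (
    COMPARTMENTS,
    Metabolite,
    PORF,
    ProteinComplex,
    Reaction,
    ValidationError,
)

# total precedence order used for complex assignment
PRECEDENCE = {
    "cytoplasm": 0,
    "periplasm": 1,
    "inner_membrane": 2,
    "outer_membrane": 3,
}


class UnassignableError(ValidationError):
    """A pORF carries neither an annotation nor membrane flags."""


@dataclass(frozen=True)
class CompartmentAssignment:
    entity_id: str
    compartment: str
    provenance: str  # annotation | tm_rule | lipid_anchor_rule | complex_precedence


def assign_porf(porf: PORF) -> CompartmentAssignment:
    """Assign one pORF to a compartment.

    A transmembrane segment places the protein in a membrane (the annotated
    membrane if one is given, else the inner membrane); a lipid anchor
    places a lipoprotein in its annotated membrane (default outer).
    Soluble pORFs keep their annotation.
    """
    membranes = ("inner_membrane", "outer_membrane")
    if porf.tm_segment_count > 0:
        compartment = (
            porf.annotated_location
            if porf.annotated_location in membranes
            else "inner_membrane"
        )
        return CompartmentAssignment(porf.id, compartment, "tm_rule")
    if porf.is_lipoprotein:
        compartment = (
            porf.annotated_location
            if porf.annotated_location in membranes
            else "outer_membrane"
        )
        return CompartmentAssignment(porf.id, compartment, "lipid_anchor_rule")
    if porf.annotated_location is None:
        raise UnassignableError(
            f"pORF {porf.id}: no annotated location and no membrane flags"
        )
    return CompartmentAssignment(porf.id, porf.annotated_location, "annotation")


def assign_complex(
    cplx: ProteinComplex, porf_assignments: dict[str, CompartmentAssignment]
) -> CompartmentAssignment:
    """Assign a complex to the maximal member compartment under the
    precedence order outer_membrane > inner_membrane > periplasm > cytoplasm.
    """
    if not cplx.composition:
        raise ValidationError(f"complex {cplx.id}: empty composition")
    best = None
    for pid in cplx.composition:
        if pid not in porf_assignments:
            raise ValidationError(
                f"complex {cplx.id}: member {pid} has no compartment assignment"
            )
        comp = porf_assignments[pid].compartment
        if best is None or PRECEDENCE[comp] > PRECEDENCE[best]:
            best = comp
    return CompartmentAssignment(cplx.id, best, "complex_precedence")


@dataclass(frozen=True)
class LocalityViolation:
    reaction_id: str
    compartments: tuple[str, ...]
    catalyst_compartment: str | None
    rule: str


# membrane-crossing rules: a reaction touching both compartments of a pair
# needs a catalyst residing in the separating membrane
_CROSSING_RULES = [
    ({"cytoplasm", "periplasm"}, "inner_membrane",
     "cytoplasm<->periplasm requires an inner-membrane catalyst"),
    ({"periplasm", "extracellular"}, "outer_membrane",
     "periplasm<->extracellular requires an outer-membrane catalyst"),
]


def check_reaction_locality(
    reaction: Reaction,
    assignments: dict[str, CompartmentAssignment],
    metabolites: dict[str, Metabolite],
) -> list[LocalityViolation]:
    """Report (never repair) membrane-crossing violations for one reaction."""
    touched = {
        metabolites[m].compartment
        for m in reaction.stoichiometry
        if m in metabolites
    }
    cat_comp = None
    if reaction.catalyst is not None and reaction.catalyst in assignments:
        cat_comp = assignments[reaction.catalyst].compartment
    violations = []
    for pair, needed, rule in _CROSSING_RULES:
        if pair <= touched and cat_comp != needed:
            violations.append(
                LocalityViolation(
                    reaction.id, tuple(sorted(touched)), cat_comp, rule
                )
            )
    return violations


def locality_report(model) -> list[LocalityViolation]:
    """Run the crossing check over every reaction of a model."""
    out: list[LocalityViolation] = []
    for rid in sorted(model.all_reactions() if model.expanded else model.reactions):
        rxn = (model.all_reactions() if model.expanded else model.reactions)[rid]
        out.extend(check_reaction_locality(rxn, model.assignments, model.metabolites))
    return out


def violations_tsv(violations: list[LocalityViolation]) -> str:
    lines = ["reaction\tcompartments\tcatalyst_compartment\trule"]
    for v in violations:
        lines.append(
            f"{v.reaction_id}\t{','.join(v.compartments)}\t"
            f"{v.catalyst_compartment or '-'}\t{v.rule}"
        )
    return "\n".join(lines) + "\n"
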