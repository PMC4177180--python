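"""Domain types, document loading, and problem assembly."""

import json

import pytest
from hypothesis import given, strategies as st

from envme import model as M


def minimal_doc(**over):
    doc = {
        "metabolites": [{"id": "x_c", "compartment": "cytoplasm"}],
        "reactions": [],
        "porfs": [],
        "complexes": [],
    }
    doc.update(over)
    return doc


class TestLoading:
    def test_degenerate_document_with_no_reactions_is_valid(self):
        m = M.load_model(minimal_doc())
        assert m.reactions == {} and "x_c" in m.metabolites

    def test_unknown_metabolite_reference_names_the_offender(self):
        doc = minimal_doc(reactions=[
            {"id": "R1", "stoichiometry": {"X": -1.0}}])
        with pytest.raises(M.SchemaError, match="'X'"):
            M.load_model(doc)

    def test_unknown_complex_member_rejected(self):
        doc = minimal_doc(complexes=[{"id": "C1", "composition": {"nope": 1}}])
        with pytest.raises(M.SchemaError, match="nope"):
            M.load_model(doc)

    def test_missing_top_level_key_rejected(self):
        with pytest.raises(M.SchemaError, match="reactions"):
            M.load_model({"metabolites": [], "porfs": [], "complexes": []})

    def test_negative_length_and_mass_rejected(self):
        with pytest.raises(M.ValidationError):
            M.PORF(id="p", length=0, molecular_weight=100.0)
        with pytest.raises(M.ValidationError):
            M.PORF(id="p", length=10, molecular_weight=-1.0)

    def test_sequence_overrides_and_checks_length(self):
        p = M.PORF(id="p", sequence="GGG")
        assert p.length == 3
        with pytest.raises(M.ValidationError, match="length"):
            M.PORF(id="p", length=5, sequence="GGG")

    def test_inverted_bounds_rejected(self):
        with pytest.raises(M.ValidationError):
            M.Reaction(id="r", stoichiometry={}, lower_bound=1.0,
                       upper_bound=-1.0)


class TestSerialization:
    def test_round_trip_is_byte_identical(self, toy_doc):
        m1 = M.load_model(toy_doc)
        text1 = M.dumps_canonical(M.write_model(m1))
        m2 = M.load_model(json.loads(text1))
        text2 = M.dumps_canonical(M.write_model(m2))
        assert text1 == text2


class TestProteinMass:
    def test_glycine_is_residue_mass_plus_water(self):
        assert M.porf_mass_from_sequence("G") == pytest.approx(75.07, abs=0.01)

    def test_empty_sequence_rejected(self):
        with pytest.raises(M.ValidationError):
            M.porf_mass_from_sequence("")

    def test_unknown_residue_rejected(self):
        with pytest.raises(M.ValidationError):
            M.porf_mass_from_sequence("GJX?")

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30))
    def test_mass_is_monotone_in_length(self, seq):
        assert (M.porf_mass_from_sequence(seq + "G")
                > M.porf_mass_from_sequence(seq))


class TestAssembly:
    def test_rejects_nonpositive_mu(self, toy_model):
        with pytest.raises(M.ValidationError):
            M.assemble(toy_model, 0.0)
        with pytest.raises(M.ValidationError):
            M.assemble(toy_model, -1.0)

    def test_row_family_counts(self, toy_model):
        prob = M.assemble(toy_model, 0.5)
        reactions = toy_model.all_reactions()
        n_pairs = sum(
            len(r.effective_coupling()) for r in reactions.values()
        )
        coupling = prob.rows_of_kind("coupling")
        # one row per (catalyzed direction, machinery pair) plus the
        # aggregated translation-capacity row
        assert len(coupling) == n_pairs + 1
        # 4 leaflet balances + 3 composition rows at default (vacuous) caps
        assert len(prob.rows_of_kind("membrane")) == 7
        assert len(prob.rows_of_kind("mass_balance")) == len(
            {m for r in reactions.values() for m in r.stoichiometry}
        )

    def test_assembly_is_deterministic(self, toy_model):
        p1 = M.assemble(toy_model, 0.7)
        p2 = M.assemble(toy_model, 0.7)
        assert p1.columns == p2.columns
        assert [(r.name, r.sense, r.rhs, sorted(r.coefs.items()))
                for r in p1.rows] == \
               [(r.name, r.sense, r.rhs, sorted(r.coefs.items()))
                for r in p2.rows]

    def test_doubling_mu_touches_only_mu_dependent_rows(self, toy_model):
        p1 = M.assemble(toy_model, 0.4)
        p2 = M.assemble(toy_model, 0.8)
        mb1 = {r.name: (r.rhs, sorted(r.coefs.items()))
               for r in p1.rows_of_kind("mass_balance")}
        mb2 = {r.name: (r.rhs, sorted(r.coefs.items()))
               for r in p2.rows_of_kind("mass_balance")}
        assert mb1 == mb2
        cp1 = {r.name: sorted(r.coefs.items())
               for r in p1.rows_of_kind("coupling")}
        cp2 = {r.name: sorted(r.coefs.items())
               for r in p2.rows_of_kind("coupling")}
        assert set(cp1) == set(cp2) and cp1 != cp2
        sa1 = {r.name: r.rhs for r in p1.rows_of_kind("membrane")
               if r.name.startswith("mem_leaflet")}
        sa2 = {r.name: r.rhs for r in p2.rows_of_kind("membrane")
               if r.name.startswith("mem_leaflet")}
        assert all(sa2[k] > sa1[k] for k in sa1)

    def test_every_coupling_row_references_existing_fluxes(self, toy_model):
        prob = M.assemble(toy_model, 0.5)
        cols = set(prob.col_bounds)
        for row in prob.rows_of_kind("coupling"):
            assert set(row.coefs) <= cols

    def test_membrane_rows_infeasible_without_membrane_species(self):
        # a cell with surface area but nothing to build membranes from
        from envme import solver
        doc = minimal_doc()
        m = M.load_model(doc)
        ok, _, prob = solver.feasible(m, 0.5)
        assert not ok
        leaflets = [r for r in prob.rows_of_kind("membrane")
                    if r.name.startswith("mem_leaflet")]
        assert leaflets and all(r.rhs > 0 and not r.coefs for r in leaflets)
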