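"""Pathway assignment rules, energetic calculators, route instantiation."""

import math

import pytest
from hypothesis import given, strategies as st

from envme import model as M
from envme import translocation as T
from envme.compartments import CompartmentAssignment


def _asn(comp):
    return CompartmentAssignment("p", comp, "annotation")


def porf(pid="p", length=250, loc="periplasm", **kw):
    return M.PORF(id=pid, length=length, molecular_weight=length * 110.0,
                  annotated_location=loc, **kw)


class TestSecaAtpCost:
    @pytest.mark.parametrize("length,expected", [
        (25, 1), (0, 0), (100, 4), (26, 2), (1, 1), (250, 10),
    ])
    def test_one_atp_per_25_residues_rounded_up(self, length, expected):
        assert T.seca_atp_cost(length) == expected

    def test_negative_length_rejected(self):
        with pytest.raises(M.ValidationError):
            T.seca_atp_cost(-1)

    @given(st.integers(min_value=0, max_value=5000))
    def test_cost_monotone_in_length(self, n):
        assert T.seca_atp_cost(n + 1) >= T.seca_atp_cost(n)


class TestProteinDiameter:
    def test_zero_mass_zero_diameter(self):
        assert T.protein_diameter(0.0) == 0.0

    def test_1kda_sphere(self):
        # V = 1.21 * 1000 = 1210 A^3 -> d = 2 (3V/4pi)^(1/3)
        assert T.protein_diameter(1000.0) == pytest.approx(13.23, abs=0.01)

    def test_doubling_mass_scales_diameter_by_cuberoot_two(self):
        assert (T.protein_diameter(2000.0) / T.protein_diameter(1000.0)
                == pytest.approx(2.0 ** (1.0 / 3.0)))

    def test_negative_rejected(self):
        with pytest.raises(M.ValidationError):
            T.protein_diameter(-1.0)


class TestTataCount:
    def test_fractional_value_rounds_up(self):
        # polynomial evaluating to 6.2 at d=1
        assert T.tata_count(1.0, [6.2]) == 7

    def test_integral_value_stays(self):
        assert T.tata_count(1.0, [6.0]) == 6

    def test_floored_at_minimum_oligomer(self):
        assert T.tata_count(0.0, [1.0], minimum=4) == 4

    def test_empty_coefficients_rejected(self):
        with pytest.raises(M.ConfigurationError):
            T.tata_count(10.0, [])

    def test_nondecreasing_on_grid_for_monotone_polynomial(self):
        counts = [T.tata_count(d, [2.0, 0.5]) for d in
                  [i * 0.5 for i in range(100)]]
        assert counts == sorted(counts)


class TestPathwayRules:
    def test_cofactor_folding_periplasmic_protein_takes_tat(self):
        r = T.assign_pathway(porf(folds_with_cofactor=True),
                             _asn("periplasm"), None)
        assert r.pathways == ["Tat"] and r.tata_count >= 1

    def test_beta_barrel_goes_sec_then_bam(self):
        r = T.assign_pathway(porf(loc="outer_membrane", is_beta_barrel=True),
                             _asn("outer_membrane"), None)
        assert r.pathways == ["SecB_Sec", "Bam"]

    def test_cytoplasmic_porf_has_empty_route(self):
        r = T.assign_pathway(porf(loc="cytoplasm"), _asn("cytoplasm"), None)
        assert r.pathways == [] and r.atp_cost == 0

    def test_inner_membrane_integral_protein_takes_srp_sec(self):
        r = T.assign_pathway(porf(loc="inner_membrane", tm_segment_count=3),
                             _asn("inner_membrane"), None)
        assert r.pathways == ["SRP_Sec"]

    def test_outer_membrane_lipoprotein_adds_lol(self):
        r = T.assign_pathway(porf(loc="outer_membrane", is_lipoprotein=True),
                             _asn("outer_membrane"), None)
        assert r.pathways == ["SecB_Sec", "lipoprotein_biogenesis", "Lol"]
        # Sec threading plus one LolCDE release event
        assert r.atp_cost == T.seca_atp_cost(250) + 1

    def test_override_wins_over_rules(self):
        r = T.assign_pathway(porf(loc="inner_membrane", tm_segment_count=2),
                             _asn("inner_membrane"), ["SRP_Sec_YidC"])
        assert r.pathways == ["SRP_Sec_YidC"]

    def test_unknown_override_pathway_rejected(self):
        with pytest.raises(T.AssignmentError):
            T.assign_pathway(porf(), _asn("periplasm"), ["NotAPathway"])

    def test_periplasmic_default_is_secb_sec_with_atp(self):
        r = T.assign_pathway(porf(length=250), _asn("periplasm"), None)
        assert r.pathways == ["SecB_Sec"]
        assert r.atp_cost == 10  # ceil(250 / 25)


class TestRouteInstantiation:
    def test_periplasmic_route_consumes_seca_atp(self, toy_model):
        rxns = [r for r in toy_model.expression_reactions.values()
                if r.id.startswith("TL_sura_")]
        assert len(rxns) == 1
        (rxn,) = rxns
        assert rxn.stoichiometry["atp_c"] == -float(
            math.ceil(toy_model.porfs["sura"].length / 25))

    def test_beta_barrel_route_has_two_stages_with_periplasmic_intermediate(
            self, toy_model):
        stages = sorted(r for r in toy_model.expression_reactions
                        if r.startswith("TL_ompx_"))
        assert len(stages) == 2
        sec, bam = (toy_model.expression_reactions[s] for s in stages)
        intermediate = next(m for m, c in sec.stoichiometry.items()
                            if c > 0 and m.startswith("prot_ompx"))
        assert toy_model.metabolites[intermediate].compartment == "periplasm"
        assert bam.stoichiometry[intermediate] == -1.0
        assert bam.stoichiometry["prot_ompx_om"] == 1.0

    def test_cytoplasmic_porf_generates_no_translocation(self, toy_model):
        assert not [r for r in toy_model.expression_reactions
                    if r.startswith("TL_dummy_")]

    def test_lipoprotein_biogenesis_offers_one_variant_per_phospholipid(
            self, toy_model):
        variants = [r for r in toy_model.expression_reactions.values()
                    if r.id.startswith("TL_lpp_1_")]
        donors = {m for r in variants for m, c in r.stoichiometry.items()
                  if c < 0 and m.endswith("_im")}
        assert donors == {"pe_im", "pg_im", "clpn_im"}

    def test_missing_machinery_raises_naming_the_complex(self):
        p = porf(length=100)
        route = T.assign_pathway(p, _asn("periplasm"), None)
        bare = M.load_model({
            "metabolites": [], "reactions": [], "porfs": [], "complexes": [],
        })
        with pytest.raises(M.ConfigurationError, match="SecB|SecA|SecYEGDF"):
            T.instantiate_route(p, route, bare)

    def test_every_route_moves_exactly_one_copy_to_destination(self, toy_model):
        """Conservation: per pORF, translocation stages chain losslessly
        from the cytoplasmic precursor to the destination species."""
        for pid, route in toy_model.routes.items():
            if not route.pathways:
                continue
            by_stage: dict[str, list] = {}
            for r in toy_model.expression_reactions.values():
                if r.id.startswith(f"TL_{pid}_"):
                    idx = r.id[len(f"TL_{pid}_"):].split("_")[0]
                    by_stage.setdefault(idx, []).append(r)
            net = {}
            for idx in sorted(by_stage):
                # alternative acyl-donor variants are interchangeable for
                # the protein species: pick one representative per stage
                r = min(by_stage[idx], key=lambda r: r.id)
                for met, c in r.stoichiometry.items():
                    if met.startswith(f"prot_{pid}"):
                        net[met] = net.get(met, 0.0) + c
            suffix = M.COMPARTMENT_SUFFIX[route.destination]
            assert net.pop(f"prot_{pid}_c") == -1.0
            assert net.pop(f"prot_{pid}_{suffix}") == 1.0
            assert all(abs(v) < 1e-12 for v in net.values())

    def test_every_noncytoplasmic_porf_has_exactly_one_route(self, toy_model):
        for pid, asn in toy_model.assignments.items():
            if pid not in toy_model.porfs:
                continue
            route = toy_model.routes[pid]
            if asn.compartment == "cytoplasm":
                assert route.pathways == []
            else:
                assert route.pathways
                assert route.destination == asn.compartment


class TestOverrideTable:
    def test_parse_override_tsv(self):
        text = "# comment\nompx\tSecB_Sec\tBam\nacch\tYidC\n"
        out = T.parse_override_tsv(text)
        assert out == {"ompx": ["SecB_Sec", "Bam"], "acch": ["YidC"]}

    def test_parse_rejects_unknown_pathway(self):
        with pytest.raises(T.AssignmentError):
            T.parse_override_tsv("p1\tNope\n")
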