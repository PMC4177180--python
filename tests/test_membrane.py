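"""Surface-area law, protein/lipid area accounting, membrane and demand rows."""

import math

import pytest

from envme import membrane as MB
from envme import model as M


class TestSurfaceArea:
    def test_value_at_zero_growth(self):
        # 0.456 pi (3.9 - 0.456) + (0.912 pi)^2
        expected = 0.456 * math.pi * 3.444 + (0.912 * math.pi) ** 2
        assert MB.surface_area(0.0) == pytest.approx(expected, rel=1e-12)
        assert MB.surface_area(0.0) == pytest.approx(13.143, abs=5e-3)

    def test_quadruples_when_size_factor_doubles(self):
        # the size factor f = 2^(mu ln2 / 3) reaches 2 at mu = 3/ln 2,
        # and both terms of the formula scale as f^2
        assert MB.surface_area(3.0 / math.log(2.0)) == pytest.approx(
            4.0 * MB.surface_area(0.0), rel=1e-12)

    def test_strictly_increasing(self):
        assert MB.surface_area(1.0) > MB.surface_area(0.0)
        grid = [0.1 * i for i in range(30)]
        vals = [MB.surface_area(mu) for mu in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_negative_mu_rejected(self):
        with pytest.raises(M.ValidationError):
            MB.surface_area(-0.1)

    def test_corrected_cap_term_option(self):
        spec = MB.MembraneSpec(
            areas_nm2={"pe": 0.6, "pg": 0.6, "clpn": 1.2, "lps": 1.6,
                       "lipoprotein_moiety": 1.0},
            fractions={"pe": 0.77, "pg": 0.18, "clpn": 0.05},
            caps={"inner_membrane": 1.0, "outer_membrane": 1.0},
            corrected_cap_term=True,
        )
        as_printed = MB.surface_area(0.0)
        corrected = MB.surface_area(0.0, spec)
        # the spherical-cap reading replaces pi^2 by pi in the end-cap term
        assert corrected == pytest.approx(
            as_printed - (0.912 * math.pi) ** 2 + math.pi * 0.912**2)


class TestProteinArea:
    def test_cross_section_scaling_with_mass(self):
        # area ~ MW^(2/3): eightfold mass -> fourfold area
        assert MB.protein_cross_section(8000.0) == pytest.approx(
            4.0 * MB.protein_cross_section(1000.0))

    def test_integral_protein_occupies_twice_its_cross_section(self, toy_model):
        spec = MB.MembraneSpec.from_parameters(toy_model.parameters)
        porf = toy_model.porfs["pts"]
        assert MB.protein_area(porf, toy_model, spec) == pytest.approx(
            2.0 * MB.protein_cross_section(porf.molecular_weight))

    def test_lipoprotein_uses_moiety_area_in_single_leaflet(self, toy_model):
        spec = MB.MembraneSpec.from_parameters(toy_model.parameters)
        lpp = toy_model.porfs["lpp"]
        assert MB.protein_area(lpp, toy_model, spec) == pytest.approx(
            spec.areas_nm2["lipoprotein_moiety"])
        areas = MB.complex_leaflet_areas(
            toy_model.complexes["MONO_lpp"], toy_model, spec)
        assert list(areas) == ["om_in"]

    def test_soluble_protein_is_a_domain_error(self, toy_model):
        spec = MB.MembraneSpec.from_parameters(toy_model.parameters)
        with pytest.raises(M.ValidationError):
            MB.protein_area(toy_model.porfs["glyc"], toy_model, spec)

    def test_integral_complex_contributes_to_both_leaflets(self, toy_model):
        spec = MB.MembraneSpec.from_parameters(toy_model.parameters)
        areas = MB.complex_leaflet_areas(
            toy_model.complexes["CPLX_ets"], toy_model, spec)
        assert set(areas) == {"im_cyt", "im_peri"}
        assert areas["im_cyt"] == pytest.approx(areas["im_peri"])


class TestMembraneRows:
    def test_four_leaflet_rows_and_three_composition_rows(self, toy_model):
        rows = MB.build_membrane_rows(toy_model, 0.5)
        names = [r.name for r in rows]
        assert sum(n.startswith("mem_leaflet_") for n in names) == 4
        assert sum(n.startswith("mem_composition_") for n in names) == 3

    def test_leaflet_rhs_is_geometric_surface_area(self, toy_model):
        mu = 0.5
        rows = MB.build_membrane_rows(toy_model, mu)
        sa = MB.surface_area(mu, MB.MembraneSpec.from_parameters(
            toy_model.parameters))
        for r in rows:
            if r.name.startswith("mem_leaflet_"):
                assert r.rhs == pytest.approx(sa)

    def test_outer_leaflet_has_lps_and_no_phospholipid(self, toy_model):
        rows = {r.name: r for r in MB.build_membrane_rows(toy_model, 0.5)}
        om_out = rows["mem_leaflet_om_out"].coefs
        assert "ALLOC_lps_om_out" in om_out
        assert not any(c.startswith(("ALLOC_pe", "ALLOC_pg", "ALLOC_clpn"))
                       for c in om_out)

    def test_default_caps_generate_no_cap_rows(self, toy_model):
        rows = MB.build_membrane_rows(toy_model, 0.5)
        assert not any(r.name.startswith("mem_cap_") for r in rows)

    def test_tight_cap_generates_inequality_row(self, toy_model):
        import copy
        m = copy.deepcopy(toy_model)
        m.parameters["membrane"]["caps"]["inner_membrane"] = 0.3
        rows = {r.name: r for r in MB.build_membrane_rows(m, 0.5)}
        cap = rows["mem_cap_inner_membrane"]
        sa = MB.surface_area(0.5, MB.MembraneSpec.from_parameters(m.parameters))
        assert cap.sense == "L" and cap.rhs == pytest.approx(0.3 * 2 * sa)

    def test_bad_fractions_rejected(self):
        with pytest.raises(M.ValidationError):
            MB.MembraneSpec(
                areas_nm2={"pe": 0.6}, fractions={"pe": 0.5, "pg": 0.2,
                                                  "clpn": 0.05},
                caps={"inner_membrane": 1.0})


class TestMureinAndDemands:
    def test_recycling_row_links_transport_to_45_percent_of_demand(
            self, toy_model):
        (row,) = MB.murein_recycling_rows(toy_model)
        assert row.sense == "E" and row.rhs == 0.0
        assert row.coefs == {"AMPG": 1.0, "DM_murein": -0.45}

    def test_missing_transport_reaction_is_a_configuration_error(self,
                                                                 toy_model):
        import copy
        m = copy.deepcopy(toy_model)
        del m.reactions["AMPG"]
        with pytest.raises(M.ConfigurationError):
            MB.murein_recycling_rows(m)

    def test_murein_demand_scales_with_growth_rate(self, toy_model):
        rows = {r.name: r for r in MB.demand_rows(
            toy_model, toy_model.parameters, 1.0)}
        assert rows["dm_murein_demand"].rhs == pytest.approx(0.01389)
        rows2 = {r.name: r for r in MB.demand_rows(
            toy_model, toy_model.parameters, 0.5)}
        assert rows2["dm_murein_demand"].rhs == pytest.approx(0.01389 * 0.5)

    def test_gam_demand_row_uses_corrected_value(self, toy_model):
        rows = {r.name: r for r in MB.demand_rows(
            toy_model, toy_model.parameters, 1.0)}
        assert rows["dm_gam"].rhs == pytest.approx(34.98)

    def test_out_of_scope_fraction_domain(self, toy_model):
        import copy
        m = copy.deepcopy(toy_model)
        m.parameters["demands"]["out_of_scope_fraction"] = 1.2
        with pytest.raises(M.ValidationError):
            MB.demand_rows(m, m.parameters, 0.5)

    def test_zero_out_of_scope_fraction_silences_dummy(self, toy_model):
        import copy
        m = copy.deepcopy(toy_model)
        m.parameters["demands"]["out_of_scope_fraction"] = 0.0
        rows = {r.name: r for r in MB.demand_rows(m, m.parameters, 0.5)}
        row = rows["dm_out_of_scope"]
        # with fraction 0 the row reads MW_dummy * v_dummy = 0
        assert row.coefs["PSYN_dummy"] > 0
        assert all(v == 0.0 for k, v in row.coefs.items()
                   if k != "PSYN_dummy")
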