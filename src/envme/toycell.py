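"""Deterministic generator of a small synthetic cell model.

The toy cell stands in for a genome-scale reconstruction: ~30 pORFs
covering a cytoplasmic ribosome analog, fermentative and respiratory
energy metabolism, a glucose PTS transporter, an electron-transport
complex (large, membrane-crowding), an alternative NADH oxidase (small,
low-yield), every translocation machinery (SecYEGDF, SecA, SecB, SRP,
FtsY, TatA, TatBC, YidC, LolCDE, LolB, SurA, Bam, Lgt, Lsp, Lnt), one
substrate per pathway (periplasmic SecB/Sec protein, Tat cofactor
protein, YidC-inserted channel, outer-membrane beta-barrel porin,
Braun's-lipoprotein analog), murein synthesis with recycling, and
PE/PG/CLPN/LPS lipid synthesis.

The stoichiometry and turnover numbers are chosen to reproduce behavior
classes of a real cell-envelope-constrained model — respiration is
area-hungry but ATP-efficient, fermentation is area-light but
carbon-hungry, gases diffuse through porins faster than acetate — not to
match E. coli flux magnitudes.  The generator is deterministic: the same
config yields a byte-identical document (the seed controls only the
invented protein sequences).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, asdict

from envme.model import Model, ModelError, load_model

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class GenerationError(ModelError):
    pass


@dataclass
class ToyCellConfig:
    glucose_uptake: float = 5.0          # mmol gDW^-1 h^-1 cap on uptake
    oxygen_uptake: float = 1000.0
    include_tat: bool = True
    include_yidc: bool = True
    include_lipoprotein: bool = True
    include_ndh2: bool = True
    include_tat_substrate: bool = True
    include_yidc_substrate: bool = True
    include_lipoprotein_substrate: bool = True
    seed: int = 0
    metabolic_kcats: dict = field(default_factory=lambda: {
        "PTS": 50.0, "GLYC": 100.0, "FERM": 150.0, "ETSR": 3.0,
        "NADHOX": 10.0, "NDH2": 30.0, "AASYN": 50.0, "PLSYN": 20.0,
        "LPSSYN": 10.0, "MURSYN": 10.0, "AMPG": 10.0, "AMIDASE": 5.0,
        "ACT": 100.0,
    })
    parameters: dict = field(default_factory=dict)  # extra overrides


# (id, length, location, tm_segments, lipoprotein, beta_barrel, cofactor)
_PORF_TABLE = [
    ("ribo",   7459, "cytoplasm",      0, False, False, False),
    ("glyc",    450, "cytoplasm",      0, False, False, False),
    ("aasyn",   520, "cytoplasm",      0, False, False, False),
    ("ferm",    380, "cytoplasm",      0, False, False, False),
    ("etsA",   1600, "inner_membrane", 12, False, False, False),
    ("etsB",    700, "cytoplasm",      0, False, False, False),
    ("ndh2",    434, "inner_membrane", 2, False, False, False),
    ("pts",     477, "inner_membrane", 10, False, False, False),
    ("acch",    188, "inner_membrane", 2, False, False, False),
    ("mursyn",  600, "inner_membrane", 2, False, False, False),
    ("ampg",    491, "inner_membrane", 10, False, False, False),
    ("plsb",    774, "inner_membrane", 1, False, False, False),
    ("lpsb",    640, "inner_membrane", 1, False, False, False),
    ("cofq",    250, "periplasm",      0, False, False, True),
    ("ompx",    362, "outer_membrane", 0, False, True, False),
    ("lpp",      78, "outer_membrane", 0, True, False, False),
    ("nfma",    300, "inner_membrane", 4, False, False, False),
    ("dummy",   350, "cytoplasm",      0, False, False, False),
    # translocation machinery
    ("secy",    950, "inner_membrane", 10, False, False, False),
    ("seca",    901, "cytoplasm",      0, False, False, False),
    ("secb",    155, "cytoplasm",      0, False, False, False),
    ("srp",     453, "cytoplasm",      0, False, False, False),
    ("ftsy",    497, "inner_membrane", 1, False, False, False),
    ("tata",     89, "inner_membrane", 1, False, False, False),
    ("tatbc",   800, "inner_membrane", 7, False, False, False),
    ("yidc",    548, "inner_membrane", 6, False, False, False),
    ("lolcde", 1100, "inner_membrane", 4, False, False, False),
    ("lolb",    207, "outer_membrane", 0, True, False, False),
    ("sura",    428, "periplasm",      0, False, False, False),
    ("bam",     810, "outer_membrane", 0, False, True, False),
    ("lgt",     291, "inner_membrane", 7, False, False, False),
    ("lsp",     164, "inner_membrane", 4, False, False, False),
    ("lnt",     512, "inner_membrane", 8, False, False, False),
]

_TAT_IDS = {"tata", "tatbc"}
_YIDC_IDS = {"yidc"}
_LIPO_IDS = {"lgt", "lsp", "lnt", "lolcde", "lolb"}


def _sequence(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(length))


def generate(config: ToyCellConfig | None = None) -> dict:
    """Build the toy-cell model document."""
    cfg = config or ToyCellConfig()
    rng = random.Random(cfg.seed)
    kc = cfg.metabolic_kcats

    skip: set[str] = set()
    if not cfg.include_tat:
        if cfg.include_tat_substrate:
            raise GenerationError("Tat machinery disabled but its substrate "
                                  "(cofq) is still included")
        skip |= _TAT_IDS
    if not cfg.include_tat_substrate:
        skip.add("cofq")
    if not cfg.include_yidc:
        if cfg.include_yidc_substrate:
            raise GenerationError("YidC disabled but its substrate (acch) "
                                  "is still included")
        skip |= _YIDC_IDS
    if not cfg.include_yidc_substrate:
        skip.add("acch")
    if not cfg.include_lipoprotein:
        if cfg.include_lipoprotein_substrate:
            raise GenerationError("lipoprotein biogenesis disabled but its "
                                  "substrate (lpp) is still included")
        skip |= _LIPO_IDS
    if not cfg.include_lipoprotein_substrate:
        skip.add("lpp")
    if not cfg.include_ndh2:
        skip.add("ndh2")

    porfs = []
    for pid, length, loc, tm, lipo, barrel, cof in _PORF_TABLE:
        if pid in skip:
            continue
        porfs.append({
            "id": pid,
            "name": pid,
            "annotated_location": loc,
            "tm_segment_count": tm,
            "is_lipoprotein": lipo,
            "is_beta_barrel": barrel,
            "folds_with_cofactor": cof,
            "sequence": _sequence(rng, length),
        })
    present = {p["id"] for p in porfs}

    metabolites = [
        {"id": "glc_e", "compartment": "extracellular", "solute_radius": 3.65},
        {"id": "glc_p", "compartment": "periplasm"},
        {"id": "glc_c", "compartment": "cytoplasm"},
        {"id": "o2_e", "compartment": "extracellular", "solute_radius": 1.4},
        {"id": "o2_p", "compartment": "periplasm"},
        {"id": "co2_e", "compartment": "extracellular", "solute_radius": 1.6},
        {"id": "co2_p", "compartment": "periplasm"},
        {"id": "ac_e", "compartment": "extracellular", "solute_radius": 2.3},
        {"id": "ac_p", "compartment": "periplasm"},
        {"id": "ac_c", "compartment": "cytoplasm"},
        {"id": "pyr_c", "compartment": "cytoplasm"},
        {"id": "atp_c", "compartment": "cytoplasm"},
        {"id": "adp_c", "compartment": "cytoplasm"},
        {"id": "nad_c", "compartment": "cytoplasm"},
        {"id": "nadh_c", "compartment": "cytoplasm"},
        {"id": "aa_c", "compartment": "cytoplasm"},
        {"id": "murein_p", "compartment": "periplasm", "mass_da": 980.0},
        {"id": "anhm_raw_p", "compartment": "periplasm"},
        {"id": "anh_p", "compartment": "periplasm"},
        {"id": "anh_c", "compartment": "cytoplasm"},
        {"id": "pe_im", "compartment": "inner_membrane", "membrane_area": 0.6,
         "mass_da": 744.0},
        {"id": "pg_im", "compartment": "inner_membrane", "membrane_area": 0.6,
         "mass_da": 749.0},
        {"id": "clpn_im", "compartment": "inner_membrane", "membrane_area": 1.2,
         "mass_da": 1430.0},
        {"id": "lps_om", "compartment": "outer_membrane", "membrane_area": 1.6,
         "mass_da": 2300.0},
    ]

    complexes = [{"id": f"CPLX_{pid}", "composition": {pid: 1}}
                 for pid in sorted(present - {"etsA", "etsB", "nfma", "dummy",
                                              "lpp"})]
    complexes.append({"id": "CPLX_ets", "composition": {"etsA": 2, "etsB": 1}})

    def rxn(rid, stoich, lb=0.0, ub=1000.0, catalyst=None, kcat=None, **kw):
        r = {"id": rid, "stoichiometry": stoich, "lower_bound": lb,
             "upper_bound": ub}
        if catalyst:
            r["catalyst"] = catalyst
        if kcat:
            r["kcat"] = kcat
        r.update(kw)
        return r

    reactions = [
        rxn("EX_glc", {"glc_e": -1}, lb=-cfg.glucose_uptake, ub=0.0),
        rxn("EX_o2", {"o2_e": -1}, lb=-cfg.oxygen_uptake, ub=0.0),
        rxn("EX_co2", {"co2_e": -1}, lb=0.0),
        rxn("EX_ac", {"ac_e": -1}, lb=0.0),
        # outer-membrane porin diffusion (capacities attached from geometry)
        rxn("PORT_glc", {"glc_e": -1, "glc_p": 1}, catalyst="CPLX_ompx"),
        rxn("PORT_o2", {"o2_e": -1, "o2_p": 1}, catalyst="CPLX_ompx"),
        rxn("PORT_co2", {"co2_p": -1, "co2_e": 1}, catalyst="CPLX_ompx"),
        rxn("PORT_ac", {"ac_p": -1, "ac_e": 1}, catalyst="CPLX_ompx"),
        # central metabolism
        rxn("PTS", {"glc_p": -1, "atp_c": -1, "glc_c": 1, "adp_c": 1},
            catalyst="CPLX_pts", kcat=kc["PTS"]),
        rxn("GLYC", {"glc_c": -1, "adp_c": -2, "nad_c": -2,
                     "pyr_c": 2, "atp_c": 2, "nadh_c": 2},
            catalyst="CPLX_glyc", kcat=kc["GLYC"]),
        rxn("FERM", {"pyr_c": -1, "nadh_c": -1, "adp_c": -1,
                     "ac_c": 1, "nad_c": 1, "atp_c": 1},
            catalyst="CPLX_ferm", kcat=kc["FERM"]),
        rxn("ETSR", {"pyr_c": -1, "o2_p": -2.5, "adp_c": -12,
                     "co2_p": 3, "atp_c": 12},
            catalyst="CPLX_ets", kcat=kc["ETSR"]),
        rxn("NADHOX", {"nadh_c": -1, "o2_p": -0.5, "adp_c": -2,
                       "nad_c": 1, "atp_c": 2},
            catalyst="CPLX_ets", kcat=kc["NADHOX"]),
        rxn("AASYN", {"pyr_c": -2, "atp_c": -4, "aa_c": 1, "adp_c": 4},
            catalyst="CPLX_aasyn", kcat=kc["AASYN"]),
        # lipid synthesis
        rxn("PLSYN_pe", {"pyr_c": -10, "atp_c": -10, "nadh_c": -4,
                         "adp_c": 10, "nad_c": 4, "pe_im": 1},
            catalyst="CPLX_plsb", kcat=kc["PLSYN"]),
        rxn("PLSYN_pg", {"pyr_c": -10, "atp_c": -10, "nadh_c": -4,
                         "adp_c": 10, "nad_c": 4, "pg_im": 1},
            catalyst="CPLX_plsb", kcat=kc["PLSYN"]),
        rxn("PLSYN_clpn", {"pyr_c": -20, "atp_c": -20, "nadh_c": -8,
                           "adp_c": 20, "nad_c": 8, "clpn_im": 1},
            catalyst="CPLX_plsb", kcat=kc["PLSYN"]),
        rxn("LPSSYN", {"pyr_c": -20, "atp_c": -20, "nadh_c": -5,
                       "adp_c": 20, "nad_c": 5, "lps_om": 1},
            catalyst="CPLX_lpsb", kcat=kc["LPSSYN"]),
        # murein demand and recycling loop
        rxn("MURSYN", {"glc_c": -1, "aa_c": -2, "atp_c": -2,
                       "adp_c": 2, "murein_p": 1},
            catalyst="CPLX_mursyn", kcat=kc["MURSYN"]),
        rxn("DM_murein", {"murein_p": -1, "anhm_raw_p": 1}),
        rxn("AMPG", {"anh_p": -1, "atp_c": -1, "anh_c": 1, "adp_c": 1},
            catalyst="CPLX_ampg", kcat=kc["AMPG"]),
        rxn("ANHUSE", {"anh_c": -1, "aa_c": 1}),
        rxn("SK_anh", {"anh_p": -1}),
        # growth-associated maintenance
        rxn("GAM", {"atp_c": -1, "adp_c": 1}),
    ]
    if "ndh2" in present:
        reactions.append(
            rxn("NDH2", {"nadh_c": -1, "o2_p": -0.5, "adp_c": -1,
                         "nad_c": 1, "atp_c": 1},
                catalyst="CPLX_ndh2", kcat=kc["NDH2"]))
    if "acch" in present:
        reactions.append(
            rxn("ACT", {"ac_c": -1, "ac_p": 1},
                catalyst="CPLX_acch", kcat=kc["ACT"]))
    if "cofq" in present:
        reactions.append(
            rxn("AMIDASE", {"anhm_raw_p": -1, "anh_p": 1},
                catalyst="CPLX_cofq", kcat=kc["AMIDASE"]))
    else:
        reactions.append(rxn("AMIDASE", {"anhm_raw_p": -1, "anh_p": 1}))

    machinery = {
        "SecYEGDF": "CPLX_secy", "SecA": "CPLX_seca", "SecB": "CPLX_secb",
        "SRP": "CPLX_srp", "FtsY": "CPLX_ftsy", "SurA": "CPLX_sura",
        "Bam": "CPLX_bam", "ribosome": "CPLX_ribo",
    }
    if cfg.include_tat:
        machinery.update({"TatA": "CPLX_tata", "TatBC": "CPLX_tatbc"})
    if cfg.include_yidc:
        machinery["YidC"] = "CPLX_yidc"
    if cfg.include_lipoprotein:
        machinery.update({"LolCDE": "CPLX_lolcde", "LolB": "CPLX_lolb",
                          "Lgt": "CPLX_lgt", "Lsp": "CPLX_lsp",
                          "Lnt": "CPLX_lnt"})

    overrides = {}
    if "acch" in present:
        overrides["acch"] = ["YidC"]

    parameters = {
        "porins": {"CPLX_ompx": {"pore_radius_A": 4.5, "thickness_nm": 4.0}},
        "demands": {
            "out_of_scope_porf": "dummy",
            "lipoprotein_porf": "lpp" if "lpp" in present else None,
        },
    }
    # deep-merge user overrides on top
    def merge(dst, src):
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                merge(dst[k], v)
            else:
                dst[k] = v
    merge(parameters, cfg.parameters)

    return {
        "metabolites": metabolites,
        "porfs": porfs,
        "complexes": complexes,
        "reactions": reactions,
        "pathways": {"machinery": machinery, "overrides": overrides},
        "parameters": parameters,
    }


def generate_model(config: ToyCellConfig | None = None) -> Model:
    """Generate, load and validate the toy cell in one step."""
    return load_model(generate(config))


def write_fasta(document: dict) -> str:
    """FASTA of the invented protein sequences (ids match pORF ids)."""
    lines = []
    for p in document["porfs"]:
        if "sequence" in p:
            lines.append(f">{p['id']} {p.get('name', '')}".rstrip())
            seq = p["sequence"]
            lines.extend(seq[i:i + 60] for i in range(0, len(seq), 60))
    return "\n".join(lines) + "\n"


def config_to_dict(cfg: ToyCellConfig) -> dict:
    return asdict(cfg)
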