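"""Enzymatic coupling rows and porin diffusion capacities.

A coupling constraint ties a catalyzed flux to its enzyme's synthesis
flux: at steady state the enzyme level is e = v_synth / mu (dilution), so
v_rxn <= kcat * 3600 * e becomes the purely linear row

    v_rxn - (kcat * 3600 / mu) * v_synth <= 0.

Outer-membrane porins are passive diffusion channels whose per-solute
turnover is computed from pore geometry and hindered (Renkin) diffusion,
then used in exactly the same coupling form.
"""

from __future__ import annotations

import math

from envme.model import (
    ConfigurationError,
    KCAT_PER_HOUR,
    AVOGADRO,
    Model,
    Reaction,
    Row,
    ValidationError,
)

BOLTZMANN = 1.380649e-23  # J/K


def couple(
    reaction_id: str,
    enzyme_synthesis_flux: str,
    kcat: float,
    mu: float,
    direction_suffix: str = "",
) -> Row:
    """One coupling row: v_rxn - (kcat*3600/mu) * v_synth <= 0."""
    if kcat <= 0:
        raise ValidationError(f"kcat must be > 0, got {kcat}")
    if mu <= 0:
        raise ValidationError(f"mu must be > 0, got {mu}")
    col = reaction_id + direction_suffix
    return Row(
        name=f"cp_{col}_{enzyme_synthesis_flux}",
        kind="coupling",
        sense="L",
        rhs=0.0,
        coefs={col: 1.0, enzyme_synthesis_flux: -kcat * KCAT_PER_HOUR / mu},
    )


def hindrance(lam: float) -> float:
    """Renkin hindered-diffusion factor in [0, 1].

    lam = solute radius / pore radius.  (1-lam)^2 accounts for the reduced
    cross-section a finite solute can enter; the polynomial accounts for
    wall drag.  Clamped to 0 for lam >= 1 (excluded solute).
    """
    if lam < 0:
        raise ValidationError(f"lambda must be >= 0, got {lam}")
    if lam >= 1.0:
        return 0.0
    partition = (1.0 - lam) ** 2
    drag = 1.0 - 2.104 * lam + 2.09 * lam**3 - 0.95 * lam**5
    return max(partition * drag, 0.0)


def stokes_einstein_diffusivity(
    radius_A: float, temperature_K: float, viscosity_Pa_s: float
) -> float:
    """Solute diffusivity in water, m^2/s, from the hydrodynamic radius."""
    if radius_A <= 0:
        raise ConfigurationError("solute radius must be positive")
    radius_m = radius_A * 1e-10
    return BOLTZMANN * temperature_K / (6.0 * math.pi * viscosity_Pa_s * radius_m)


def porin_capacity(
    solute_radius_A: float,
    pore_radius_A: float,
    thickness_nm: float,
    delta_c_M: float = 6.5e-4,
    temperature_K: float = 310.0,
    viscosity_Pa_s: float = 6.9e-4,
) -> float:
    """Per-porin translocation capacity for one solute, events s^-1.

    Steady diffusion through a water-filled cylindrical pore of radius
    r_pore and length equal to the membrane thickness, driven by the
    transmembrane concentration difference delta_c (mol/L) and reduced by
    the Renkin hindrance factor:

        capacity = D * H(lam) * (pi r^2 / L) * delta_c * N_A
    """
    if solute_radius_A is None or solute_radius_A <= 0:
        raise ConfigurationError("solute has no hydrodynamic radius")
    if pore_radius_A <= 0 or thickness_nm <= 0:
        raise ConfigurationError("porin needs positive pore radius and thickness")
    lam = solute_radius_A / pore_radius_A
    h = hindrance(lam)
    if h == 0.0:
        return 0.0
    diff = stokes_einstein_diffusivity(solute_radius_A, temperature_K,
                                       viscosity_Pa_s)
    area_over_length = math.pi * (pore_radius_A * 1e-10) ** 2 / (thickness_nm * 1e-9)
    delta_c_mol_m3 = delta_c_M * 1e3
    return diff * h * area_over_length * delta_c_mol_m3 * AVOGADRO


def couple_porin(
    exchange_reaction_id: str,
    porin_synthesis_flux: str,
    capacity: float,
    mu: float,
    direction_suffix: str = "",
) -> Row:
    """Porin coupling: same form as :func:`couple` with the per-solute
    capacity as the turnover number."""
    if capacity <= 0:
        raise ValidationError(f"capacity must be > 0, got {capacity}")
    row = couple(exchange_reaction_id, porin_synthesis_flux, capacity, mu,
                 direction_suffix)
    row.name = "pn" + row.name[2:]
    return row


# ---------------------------------------------------------------------------
# model-level wiring
# ---------------------------------------------------------------------------

def attach_porin_coupling(model: Model) -> None:
    """Compute per-solute capacities for every transport reaction whose
    catalyst is a configured porin, and attach them as coupling entries.
    A solute too large for the pore (capacity 0) pins the flux to zero.
    """
    porins = model.parameters.get("porins", {})
    if not porins:
        return
    diff = model.parameters["porin_diffusion"]
    for rid in sorted(model.reactions):
        rxn = model.reactions[rid]
        if rxn.catalyst not in porins:
            continue
        geom = porins[rxn.catalyst]
        radii = [
            model.metabolites[m].solute_radius
            for m in rxn.stoichiometry
            if model.metabolites[m].solute_radius is not None
        ]
        if not radii:
            raise ConfigurationError(
                f"porin transport {rid}: no transported metabolite has a "
                f"hydrodynamic radius"
            )
        capacity = porin_capacity(
            max(radii),
            geom["pore_radius_A"],
            geom["thickness_nm"],
            diff["delta_c_M"],
            diff["temperature_K"],
            diff["viscosity_Pa_s"],
        )
        if capacity == 0.0:
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
            rxn.coupling = []
        else:
            rxn.coupling = [(rxn.catalyst, capacity)]


def coupling_rows(model: Model, mu: float) -> list[Row]:
    """All coupling rows of the assembled problem.

    Per catalyzed reaction (metabolic, transport, translocation): one row
    per (machinery complex, kcat) pair and flux direction.  Translation is
    coupled in aggregate: the summed residue synthesis flux is bounded by
    the ribosome pool, sum_i L_i v_i <= (k_aa*3600/mu) * v_ribosome.
    """
    rows: list[Row] = []
    reactions = model.all_reactions()
    for rid in sorted(reactions):
        rxn = reactions[rid]
        for cplx_id, kcat in rxn.effective_coupling():
            synth = model.formation_flux(cplx_id)
            rows.append(couple(rid, synth, kcat, mu))
            if rxn.lower_bound < 0 or (rxn.mu_scaled_bounds and rxn.lower_bound < 0):
                rows.append(couple(rid, synth, kcat, mu, "__rev"))

    ribo = model.pathways.get("machinery", {}).get("ribosome")
    if ribo is not None:
        k_aa = (model.parameters["kcats"]["ribosome_aa_per_s"]
                * model.parameters["kcat_multipliers"]["ribosome"])
        coefs = {}
        for pid in sorted(model.porfs):
            coefs[model.synthesis_flux(pid)] = float(model.porfs[pid].length)
        coefs[model.formation_flux(ribo)] = (
            coefs.get(model.formation_flux(ribo), 0.0)
            - k_aa * KCAT_PER_HOUR / mu
        )
        rows.append(Row("cp_translation_capacity", "coupling", "L", 0.0, coefs))
    return rows
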