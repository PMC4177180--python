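"""Solution reports: compartment proteome mass fractions, translocase
expression, leaflet area accounting, and the log-log regression with
rankit-based outlier screening used for expression comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from envme import membrane as _mem
from envme.model import Model, ValidationError
from envme.solver import Solution


@dataclass
class CompartmentMassReport:
    masses: dict[str, float]       # mg gDW^-1 h^-1 of protein mass flux
    fractions: dict[str, float]

    def tsv(self) -> str:
        lines = ["compartment\tmass_flux\tfraction"]
        for comp in sorted(self.fractions):
            lines.append(f"{comp}\t{self.masses[comp]:.6g}\t"
                         f"{self.fractions[comp]:.6g}")
        return "\n".join(lines) + "\n"


def compartment_masses(solution: Solution, model: Model,
                       by_tag: dict[str, str] | None = None) -> CompartmentMassReport:
    """Proteome mass flux grouped by compartment (optionally by a
    free-form functional tag): synthesis flux times molecular weight."""
    masses: dict[str, float] = {}
    for pid in sorted(model.porfs):
        flux = solution.fluxes.get(model.synthesis_flux(pid), 0.0)
        mass = flux * model.porfs[pid].molecular_weight
        key = by_tag[pid] if by_tag else model.assignments[pid].compartment
        masses[key] = masses.get(key, 0.0) + mass
    total = sum(masses.values())
    fractions = {k: (v / total if total else 0.0) for k, v in masses.items()}
    return CompartmentMassReport(masses=masses, fractions=fractions)


def translocase_summary(solution: Solution, model: Model) -> list[dict]:
    """Expression of each translocation machinery complex: formation flux,
    steady-state level, mass concentration."""
    rows = []
    for name, cid in sorted(model.pathways.get("machinery", {}).items()):
        if cid not in model.complexes:
            continue
        flux = solution.fluxes.get(model.formation_flux(cid), 0.0)
        level = solution.enzyme_levels.get(cid, 0.0)
        mass = level * _mem.complex_mass(model.complexes[cid], model)
        rows.append({"machinery": name, "complex": cid,
                     "formation_flux": flux, "level_mmol_gdw": level,
                     "mass_mg_gdw": mass})
    return rows


# ---------------------------------------------------------------------------
# independent leaflet accounting (oracle for the constraint builder)
# ---------------------------------------------------------------------------

def accumulate_leaflet_areas(model: Model, fluxes: dict[str, float],
                             mu: float) -> dict[str, dict[str, float]]:
    """Recompute per-leaflet areas (nm^2 per cell) from raw fluxes by
    direct accumulation, independent of the constraint-row builder.

    Walks every complex and lipid-allocation flux, converts it to a
    molecule count via count = (v / mu) * N_A * m_cell, and adds the
    species' area to its leaflet(s): bilayer-spanning complexes add one
    mass-derived cross-section to each leaflet of their membrane;
    lipoprotein species add their moiety area to a single leaflet.
    """
    if mu <= 0:
        raise ValidationError("mu must be > 0")
    cpf = model.counts_per_flux()
    areas_cfg = model.parameters["membrane"]["areas_nm2"]
    out = {lf: {"protein": 0.0, "lipid": 0.0}
           for lf in ("im_cyt", "im_peri", "om_in", "om_out")}

    for cid in sorted(model.complexes):
        cplx = model.complexes[cid]
        comp = cplx.compartment
        if comp not in ("inner_membrane", "outer_membrane"):
            continue
        count = fluxes.get(model.formation_flux(cid), 0.0) / mu * cpf
        if all(model.porfs[p].is_lipoprotein for p in cplx.composition):
            a = areas_cfg["lipoprotein_moiety"] * sum(cplx.composition.values())
            leaflet = "im_peri" if comp == "inner_membrane" else "om_in"
            out[leaflet]["protein"] += count * a
        else:
            mw = sum(model.porfs[p].molecular_weight * n
                     for p, n in cplx.composition.items())
            radius_A = (3.0 * 1.21 * mw / (4.0 * math.pi)) ** (1.0 / 3.0)
            cross_nm2 = math.pi * radius_A**2 / 100.0
            if comp == "inner_membrane":
                out["im_cyt"]["protein"] += count * cross_nm2
                out["im_peri"]["protein"] += count * cross_nm2
            else:
                out["om_in"]["protein"] += count * cross_nm2
                out["om_out"]["protein"] += count * cross_nm2

    lipid_species = model.parameters["membrane"]["lipid_species"]
    for lip in ("pe", "pg", "clpn"):
        met = lipid_species.get(lip)
        if met is None or met not in model.metabolites:
            continue
        a = model.metabolites[met].membrane_area or areas_cfg[lip]
        for leaflet in ("im_cyt", "im_peri", "om_in"):
            v = fluxes.get(f"ALLOC_{lip}_{leaflet}", 0.0)
            out[leaflet]["lipid"] += v / mu * cpf * a
    lps = lipid_species.get("lps")
    if lps is not None and lps in model.metabolites:
        a = model.metabolites[lps].membrane_area or areas_cfg["lps"]
        v = fluxes.get("ALLOC_lps_om_out", 0.0)
        out["om_out"]["lipid"] += v / mu * cpf * a
    return out


def leaflet_report_tsv(model: Model, solution: Solution) -> str:
    mu = solution.mu_star
    areas = accumulate_leaflet_areas(model, solution.fluxes, mu)
    sa_nm2 = _mem.surface_area(mu, _mem.MembraneSpec.from_parameters(
        model.parameters)) / 1e-6
    lines = ["leaflet\tprotein_nm2\tlipid_nm2\ttotal_nm2\tfraction_of_SA"]
    for lf in ("im_cyt", "im_peri", "om_in", "om_out"):
        prot, lip = areas[lf]["protein"], areas[lf]["lipid"]
        lines.append(f"{lf}\t{prot:.6g}\t{lip:.6g}\t{prot + lip:.6g}\t"
                     f"{(prot + lip) / sa_nm2:.6g}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# log-log regression with rankit outlier screening
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    outliers: list[int]            # indices into the nonzero-filtered pairs
    refit_slope: float
    refit_intercept: float
    refit_r_squared: float
    kept: int


def loglog_regression_with_outliers(
    x_series, y_series, band: float = 1.5
) -> RegressionResult:
    """Simple linear regression of log(y) on log(x) with normal-probability
    outlier screening.

    Zero (or negative) pairs are removed first.  Standardized residuals
    are plotted against rankit scores; a line through the first and third
    quartiles of that plot defines the expected normal trend, and points
    whose vertical deviation from it exceeds ``band`` times the IQR of
    the deviations are flagged as outliers and removed for a refit.
    """
    x = np.asarray(x_series, dtype=float)
    y = np.asarray(y_series, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y series must have equal length")
    keep = (x > 0) & (y > 0)
    x, y = np.log(x[keep]), np.log(y[keep])
    n = x.size
    if n < 3:
        raise ValidationError(f"need at least 3 nonzero pairs, got {n}")

    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    sd = resid.std(ddof=1)
    # an (effectively) exact fit has no residual structure to screen
    if sd <= 1e-9 * max(1.0, float(np.abs(y).max())):
        flagged_sorted = np.zeros(n, dtype=bool)
        order = np.arange(n)
    else:
        std_resid = resid / sd
        order = np.argsort(std_resid, kind="stable")
        rankits = stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
        sorted_resid = std_resid[order]
        q1_r, q3_r = np.percentile(sorted_resid, [25, 75])
        q1_k, q3_k = np.percentile(rankits, [25, 75])
        slope_q = (q3_r - q1_r) / (q3_k - q1_k) if q3_k > q1_k else 1.0
        inter_q = 0.5 * ((q1_r - slope_q * q1_k) + (q3_r - slope_q * q3_k))
        deviation = sorted_resid - (inter_q + slope_q * rankits)
        iqr = q3_r - q1_r
        threshold = band * iqr if iqr > 0 else np.inf
        flagged_sorted = np.abs(deviation) > threshold
    outliers = sorted(int(order[i]) for i in range(n) if flagged_sorted[i])

    mask = np.ones(n, dtype=bool)
    mask[outliers] = False
    if mask.sum() >= 3:
        refit = stats.linregress(x[mask], y[mask])
    else:
        refit = fit
    return RegressionResult(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2), outliers=outliers,
        refit_slope=float(refit.slope), refit_intercept=float(refit.intercept),
        refit_r_squared=float(refit.rvalue**2), kept=int(mask.sum()),
    )
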