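"""Growth-rate maximization by bisection over LP feasibility.

At a fixed growth rate mu the constraint system is linear, so optimal
growth is found by bracketing: mu is feasible below the optimum and
infeasible above it (coupling coefficients tighten and membrane/demand
right-hand sides grow monotonically with mu on the models built here).
Each feasibility check minimizes total flux as a secondary objective so
the witness solution, and everything reported from it, is deterministic.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import csr_matrix

from envme import model as _model
from envme.model import MEProblem, Model, ValidationError

BISECTION_TOL = 1e-6
DEFAULT_BRACKET = (1e-6, 3.0)
ROW_CHECK_TOL = 1e-9


class SolverError(RuntimeError):
    pass


@dataclass
class Solution:
    mu_star: float
    fluxes: dict[str, float]
    enzyme_levels: dict[str, float]
    status: str
    problem: MEProblem | None = None
    diagnostics: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "mu_star": self.mu_star,
            "status": self.status,
            "fluxes": {k: v for k, v in sorted(self.fluxes.items())},
            "enzyme_levels": {k: v for k, v in sorted(self.enzyme_levels.items())},
            "diagnostics": self.diagnostics,
        }


def _linprog_arrays(problem: MEProblem):
    ncol = len(problem.columns)
    col_index = {c: j for j, c in enumerate(problem.columns)}
    eq_rows, eq_rhs, ub_rows, ub_rhs = [], [], [], []
    for row in problem.rows:
        entries = [(col_index[c], v) for c, v in row.coefs.items() if v != 0.0]
        if row.sense == "E":
            eq_rows.append(entries)
            eq_rhs.append(row.rhs)
        elif row.sense == "L":
            ub_rows.append(entries)
            ub_rhs.append(row.rhs)
        elif row.sense == "G":
            ub_rows.append([(j, -v) for j, v in entries])
            ub_rhs.append(-row.rhs)
        else:  # pragma: no cover
            raise SolverError(f"unknown row sense {row.sense!r}")

    def to_csr(rows):
        data, indices, indptr = [], [], [0]
        for entries in rows:
            for j, v in entries:
                indices.append(j)
                data.append(v)
            indptr.append(len(indices))
        return csr_matrix((data, indices, indptr), shape=(len(rows), ncol))

    bounds = [problem.col_bounds[c] for c in problem.columns]
    return to_csr(eq_rows), np.array(eq_rhs), to_csr(ub_rows), np.array(ub_rhs), bounds


def feasible(
    model: Model, mu: float, drop_families: set[str] | None = None
):
    """LP feasibility of the assembled problem at mu.

    Returns (is_feasible, witness fluxes or None, MEProblem).  The witness
    minimizes total (absolute) flux, which makes degenerate optima unique
    in practice and the reported leaflet/compartment accounting
    reproducible.
    """
    if mu <= 0:
        raise ValidationError(f"mu must be > 0, got {mu}")
    problem = _model.assemble(model, mu, drop_families=drop_families)
    if not problem.columns:
        # degenerate model: feasible iff every row is satisfied at x = 0
        ok = all(
            (row.sense == "E" and row.rhs == 0.0)
            or (row.sense == "L" and row.rhs >= 0.0)
            or (row.sense == "G" and row.rhs <= 0.0)
            for row in problem.rows
        )
        return ok, (np.zeros(0) if ok else None), problem
    a_eq, b_eq, a_ub, b_ub, bounds = _linprog_arrays(problem)
    c = np.ones(len(problem.columns))
    res = linprog(
        c,
        A_ub=a_ub if a_ub.shape[0] else None,
        b_ub=b_ub if len(b_ub) else None,
        A_eq=a_eq if a_eq.shape[0] else None,
        b_eq=b_eq if len(b_eq) else None,
        bounds=bounds,
        method="highs-ds",
        options={
            "primal_feasibility_tolerance": 1e-10,
            "dual_feasibility_tolerance": 1e-10,
        },
    )
    if res.status == 0:
        return True, res.x, problem
    if res.status == 2:
        return False, None, problem
    raise SolverError(f"LP backend failure at mu={mu}: {res.message}")


def verify_witness(problem: MEProblem, x, tol: float = ROW_CHECK_TOL) -> float:
    """Re-check every row outside the LP backend; returns the maximum
    normalized violation (raises if above tol)."""
    col_index = {c: j for j, c in enumerate(problem.columns)}
    worst = 0.0
    for row in problem.rows:
        lhs = sum(v * x[col_index[c]] for c, v in row.coefs.items())
        scale = 1.0 + abs(row.rhs) + sum(
            abs(v * x[col_index[c]]) for c, v in row.coefs.items()
        )
        if row.sense == "E":
            viol = abs(lhs - row.rhs)
        elif row.sense == "L":
            viol = max(0.0, lhs - row.rhs)
        else:
            viol = max(0.0, row.rhs - lhs)
        worst = max(worst, viol / scale)
    if worst > tol:
        raise SolverError(f"witness violates rows by {worst:.3e} (> {tol:.0e})")
    return worst


def diagnose_infeasibility(model: Model, mu: float) -> list[str]:
    """Identify which constraint families make mu infeasible: a family is
    implicated when dropping it (on top of previously dropped ones)
    restores feasibility."""
    families = ["coupling", "membrane", "demand"]
    implicated: list[str] = []
    dropped: set[str] = set()
    for fam in families:
        dropped.add(fam)
        ok, _, _ = feasible(model, mu, drop_families=set(dropped))
        if ok:
            implicated.append(fam)
            return implicated
        implicated.append(fam)
    return ["mass_balance"]


def _make_solution(model: Model, mu: float, x, problem: MEProblem,
                   status: str) -> Solution:
    fluxes = _model.net_fluxes(problem, x)
    enzymes = {
        cid: fluxes.get(model.formation_flux(cid), 0.0) / mu
        for cid in sorted(model.complexes)
    }
    return Solution(mu_star=mu, fluxes=fluxes, enzyme_levels=enzymes,
                    status=status, problem=problem)


def maximize_growth(
    model: Model,
    bracket: tuple[float, float] = DEFAULT_BRACKET,
    tol: float = BISECTION_TOL,
    drop_families: set[str] | None = None,
) -> Solution:
    """Bisection on mu between a feasible low and an infeasible high.

    If the top of the bracket is still feasible it is doubled a few times
    before giving up; if the bottom is infeasible a "no_growth" solution
    is returned together with the implicated constraint families.
    """
    lo, hi = bracket
    if hi <= lo:
        raise ValidationError("bracket high must exceed bracket low")
    ok, x, problem = feasible(model, lo, drop_families)
    if not ok:
        diag = diagnose_infeasibility(model, lo) if drop_families is None else []
        return Solution(0.0, {}, {}, "no_growth", None,
                        [f"infeasible at bracket low mu={lo}"] + diag)
    best = (lo, x, problem)

    ok_hi, x_hi, p_hi = feasible(model, hi, drop_families)
    extensions = 0
    while ok_hi and extensions < 6:
        best = (hi, x_hi, p_hi)
        hi *= 2.0
        extensions += 1
        ok_hi, x_hi, p_hi = feasible(model, hi, drop_families)
    if ok_hi:
        sol = _make_solution(model, hi, x_hi, p_hi, "feasible_at_bracket_top")
        sol.diagnostics.append(f"still feasible at mu={hi}")
        return sol

    lo = best[0]
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        ok, x, problem = feasible(model, mid, drop_families)
        if ok:
            lo, best = mid, (mid, x, problem)
        else:
            hi = mid
    mu_star, x, problem = best
    return _make_solution(model, mu_star, x, problem, "optimal")


# ---------------------------------------------------------------------------
# parameter scans
# ---------------------------------------------------------------------------

def set_parameter(document: dict, path: str, value) -> dict:
    """Return a copy of a model document with one parameters entry
    replaced, addressed by a dotted path (e.g. 'kcat_multipliers.seca')."""
    doc = copy.deepcopy(document)
    params = doc.setdefault("parameters", {})
    keys = path.split(".")
    node = params
    for key in keys[:-1]:
        node = node.setdefault(key, {})
        if not isinstance(node, dict):
            raise ValidationError(f"parameter path {path!r} is not addressable")
    node[keys[-1]] = value
    return doc


def _resolve_default(document: dict, path: str):
    node = _model._deep_merge(_model.DEFAULT_PARAMETERS,
                              document.get("parameters", {}))
    for key in path.split("."):
        if not isinstance(node, dict) or key not in node:
            raise ValidationError(f"unknown parameter path {path!r}")
        node = node[key]
    return node


def scan(
    document: dict,
    parameter_path: str,
    grid,
    bracket: tuple[float, float] = DEFAULT_BRACKET,
    tol: float = BISECTION_TOL,
    tracked_fluxes: tuple[str, ...] = (),
    extra_paths: tuple[str, ...] = (),
) -> list[dict]:
    """One growth maximization per grid value of a numeric parameter.

    ``extra_paths`` are set to the same grid value (used to force
    occupancy: cap and floor move together).  Infeasible points are
    recorded with mu_star = 0.
    """
    _resolve_default(document, parameter_path)  # validate the path early
    results = []
    for value in grid:
        doc = set_parameter(document, parameter_path, value)
        for p in extra_paths:
            doc = set_parameter(doc, p, value)
        m = _model.load_model(doc)
        sol = maximize_growth(m, bracket=bracket, tol=tol)
        entry = {"value": float(value), "mu_star": sol.mu_star,
                 "status": sol.status}
        for fid in tracked_fluxes:
            entry[fid] = sol.fluxes.get(fid, 0.0)
        results.append(entry)
    return results


def scan_occupancy(
    document: dict,
    membrane: str,
    grid,
    force: bool = True,
    **kwargs,
) -> list[dict]:
    """Scan the protein occupancy of one membrane.

    With ``force`` the occupancy is pinned (cap = floor = value), padding
    with nonfunctional membrane protein when the useful proteome does not
    fill the quota; otherwise only the cap moves.
    """
    cap = f"membrane.caps.{membrane}"
    extra = (f"membrane.floors.{membrane}",) if force else ()
    return scan(document, cap, grid, extra_paths=extra, **kwargs)
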