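"""Linear programming layer: FBA, FVA, parsimonious FBA and a brute-force
vertex-enumeration reference for small models.

All LPs are solved with HiGHS (scipy.optimize.linprog) at fixed primal and
dual feasibility tolerances of 1e-9 so that repeated runs are
deterministic. Infeasible and unbounded problems are reported in the
returned status, never as silent zeros.
"""

from __future__ import annotations

import itertools
import logging
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linprog

from .model import FluxDistribution, MetabolicModel

logger = logging.getLogger(__name__)

#: solver settings recorded in run manifests
SOLVER_SETTINGS = {
    "solver": "highs",
    "primal_feasibility_tolerance": 1e-9,
    "dual_feasibility_tolerance": 1e-9,
}

_HIGHS_OPTIONS = {
    "presolve": True,
    "primal_feasibility_tolerance": 1e-9,
    "dual_feasibility_tolerance": 1e-9,
}

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "error"}


def solve_lp(
    c: np.ndarray,
    A_eq: np.ndarray,
    b_eq: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    A_ub: Optional[np.ndarray] = None,
    b_ub: Optional[np.ndarray] = None,
):
    """Minimise ``c.x`` subject to ``A_eq x = b_eq``, ``A_ub x <= b_ub``,
    ``lb <= x <= ub``. Returns the scipy result object."""
    return linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=np.column_stack([lb, ub]),
        method="highs",
        options=_HIGHS_OPTIONS,
    )


def fba(
    model: MetabolicModel,
    objective: Optional[str] = None,
    sense: str = "max",
) -> FluxDistribution:
    """Flux balance analysis: optimise one reaction's flux at steady state.

    Maximise (or minimise) ``v_obj`` subject to ``S v = 0`` and
    ``lb <= v <= ub``.
    """
    objective = objective or model.objective
    if not objective:
        raise ValueError("no objective reaction given and model declares none")
    ridx = model.rxn_index()
    if objective not in ridx:
        raise KeyError(f"objective reaction {objective!r} not in model")
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    c = np.zeros(len(model.reactions))
    c[ridx[objective]] = -1.0 if sense == "max" else 1.0
    res = solve_lp(c, S, np.zeros(S.shape[0]), lb, ub)
    status = _STATUS.get(res.status, "error")
    if status != "optimal":
        return FluxDistribution(flux={}, objective_value=float("nan"), status=status)
    flux = dict(zip(model.reaction_ids, res.x))
    return FluxDistribution(
        flux=flux, objective_value=float(flux[objective]), status="optimal"
    )


def pfba(
    model: MetabolicModel,
    objective: Optional[str] = None,
    sense: str = "max",
    rel_tol: float = 1e-6,
) -> FluxDistribution:
    """Parsimonious FBA: optimise the objective, then minimise total
    absolute flux holding the objective within ``rel_tol`` relative.

    Works on models of any reversibility by splitting each flux into
    positive and negative parts for the second stage.
    """
    first = fba(model, objective, sense)
    if first.status != "optimal":
        return first
    objective = objective or model.objective
    ridx = model.rxn_index()
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    n = len(model.reactions)
    obj_val = first.objective_value
    # v = p - q, p,q >= 0; minimise sum(p + q)
    S2 = np.hstack([S, -S])
    lb2 = np.concatenate([np.maximum(lb, 0.0), np.maximum(-ub, 0.0)])
    ub2 = np.concatenate([np.maximum(ub, 0.0), np.maximum(-lb, 0.0)])
    c2 = np.ones(2 * n)
    slack = abs(obj_val) * rel_tol + 1e-9
    row = np.zeros(2 * n)
    row[ridx[objective]] = 1.0
    row[n + ridx[objective]] = -1.0
    if sense == "max":
        A_ub = -row[None, :]
        b_ub = np.array([-(obj_val - slack)])
    else:
        A_ub = row[None, :]
        b_ub = np.array([obj_val + slack])
    res = solve_lp(c2, S2, np.zeros(S.shape[0]), lb2, ub2, A_ub=A_ub, b_ub=b_ub)
    if res.status != 0:
        logger.warning("pFBA second stage failed (%s); returning FBA solution",
                       _STATUS.get(res.status))
        return first
    v = res.x[:n] - res.x[n:]
    flux = dict(zip(model.reaction_ids, v))
    return FluxDistribution(
        flux=flux, objective_value=float(flux[objective]), status="optimal"
    )


def fva(
    model: MetabolicModel,
    reactions: Optional[Sequence[str]] = None,
    objective: Optional[str] = None,
    fraction_of_optimum: Optional[float] = None,
) -> Dict[str, Tuple[float, float]]:
    """Per-reaction flux minima/maxima, optionally at a fixed fraction of
    the objective optimum."""
    reactions = list(reactions or model.reaction_ids)
    ridx = model.rxn_index()
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    A_ub = b_ub = None
    if fraction_of_optimum is not None:
        sol = fba(model, objective)
        if sol.status != "optimal":
            raise RuntimeError(f"FVA reference FBA is {sol.status}")
        obj = objective or model.objective
        row = np.zeros(len(model.reactions))
        row[ridx[obj]] = -1.0
        A_ub = row[None, :]
        b_ub = np.array([-fraction_of_optimum * sol.objective_value])
    out: Dict[str, Tuple[float, float]] = {}
    for rid in reactions:
        c = np.zeros(len(model.reactions))
        c[ridx[rid]] = 1.0
        lo = solve_lp(c, S, np.zeros(S.shape[0]), lb, ub, A_ub=A_ub, b_ub=b_ub)
        hi = solve_lp(-c, S, np.zeros(S.shape[0]), lb, ub, A_ub=A_ub, b_ub=b_ub)
        if lo.status != 0 or hi.status != 0:
            raise RuntimeError(f"FVA subproblem for {rid!r} not optimal")
        out[rid] = (float(lo.x[ridx[rid]]), float(hi.x[ridx[rid]]))
    return out


# -- brute-force reference -------------------------------------------------

def fba_brute_force(
    model: MetabolicModel,
    objective: Optional[str] = None,
    sense: str = "max",
    max_reactions: int = 14,
) -> FluxDistribution:
    """Reference FBA by exhaustive enumeration of basic feasible solutions.

    For a bounded LP over the polytope ``{v: S v = 0, lb <= v <= ub}`` the
    optimum is attained at a vertex, i.e. a basic solution where n - rank(S)
    variables sit at a bound. This enumerates all bases and bound
    assignments; exponential, so restricted to small models. Shares no code
    with :func:`fba` and serves as its independent validation oracle.
    """
    n = len(model.reactions)
    if n > max_reactions:
        raise ValueError(f"brute force limited to {max_reactions} reactions, got {n}")
    objective = objective or model.objective
    ridx = model.rxn_index()
    j_obj = ridx[objective]
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    if not (np.all(np.isfinite(lb)) and np.all(np.isfinite(ub))):
        raise ValueError("brute force requires finite bounds")
    r = int(np.linalg.matrix_rank(S)) if S.size else 0
    best_val = -np.inf
    best_v = None
    sign = 1.0 if sense == "max" else -1.0
    cols = range(n)
    for basis in itertools.combinations(cols, r):
        B = list(basis)
        N = [j for j in cols if j not in basis]
        SB = S[:, B]
        for pattern in itertools.product((0, 1), repeat=len(N)):
            vN = np.array([lb[j] if p == 0 else ub[j] for j, p in zip(N, pattern)])
            rhs = -S[:, N] @ vN if N else np.zeros(S.shape[0])
            if B:
                vB, res_, rank_, _ = np.linalg.lstsq(SB, rhs, rcond=None)
                if np.linalg.norm(SB @ vB - rhs) > 1e-7:
                    continue
            else:
                vB = np.zeros(0)
                if np.linalg.norm(rhs) > 1e-7:
                    continue
            v = np.empty(n)
            v[B] = vB
            v[N] = vN
            if np.any(v < lb - 1e-7) or np.any(v > ub + 1e-7):
                continue
            val = sign * v[j_obj]
            if val > best_val + 1e-12:
                best_val = val
                best_v = v.copy()
    if best_v is None:
        return FluxDistribution(flux={}, objective_value=float("nan"), status="infeasible")
    flux = dict(zip(model.reaction_ids, best_v))
    return FluxDistribution(
        flux=flux, objective_value=float(best_v[j_obj]), status="optimal"
    )


def steady_state_residual(model: MetabolicModel, flux: Dict[str, float]) -> float:
    """max |S v| over metabolites for a flux vector given as a dict."""
    ridx = model.rxn_index()
    v = np.zeros(len(model.reactions))
    for rid, val in flux.items():
        if rid in ridx:
            v[ridx[rid]] = val
    S = model.stoichiometric_matrix()
    return float(np.max(np.abs(S @ v))) if S.size else 0.0
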