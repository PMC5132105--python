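"""Thin deterministic LP/MILP layer over scipy's HiGHS interface.

Variables are always ordered by sorted reaction id (lexicographic), and
metabolite rows by sorted metabolite id, so repeated solves of the same
problem produce identical solutions across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import LinearConstraint, linprog, milp

from .model import MetabolicModel

LP_TOL = 1e-9


@dataclass
class LPProblem:
    """Structural LP data for a model: S·v = 0 with per-reaction bounds."""

    reaction_ids: list[str]
    metabolite_ids: list[str]
    S: sparse.csr_matrix
    lb: np.ndarray
    ub: np.ndarray

    @property
    def n(self) -> int:
        return len(self.reaction_ids)

    def index(self, reaction_id: str) -> int:
        return self.reaction_ids.index(reaction_id)


def build_problem(model: MetabolicModel) -> LPProblem:
    rids = sorted(model.reactions)
    mids = sorted(model.metabolites)
    row = {m: i for i, m in enumerate(mids)}
    data, ri, ci = [], [], []
    lb = np.zeros(len(rids))
    ub = np.zeros(len(rids))
    for j, rid in enumerate(rids):
        r = model.reactions[rid]
        lb[j], ub[j] = r.lower_bound, r.upper_bound
        for met, coeff in r.stoichiometry.items():
            ri.append(row[met])
            ci.append(j)
            data.append(coeff)
    S = sparse.csr_matrix(
        (data, (ri, ci)), shape=(len(mids), len(rids)), dtype=float
    )
    return LPProblem(rids, mids, S, lb, ub)


def solve_lp(
    prob: LPProblem,
    objective: dict[str, float],
    sense: str = "max",
    extra_A_ub=None,
    extra_b_ub=None,
):
    """Solve max/min of a linear objective over the flux polytope.

    ``objective`` maps reaction id -> coefficient.  Optional extra
    inequality rows (over the same variables) are appended.
    Returns ``(status, objective_value, flux_vector)`` with status
    ``"optimal"`` or ``"infeasible"``.
    """
    c = np.zeros(prob.n)
    for rid, coeff in objective.items():
        c[prob.index(rid)] = coeff
    sign = -1.0 if sense == "max" else 1.0
    res = linprog(
        sign * c,
        A_eq=prob.S,
        b_eq=np.zeros(prob.S.shape[0]),
        A_ub=extra_A_ub,
        b_ub=extra_b_ub,
        bounds=list(zip(prob.lb, prob.ub)),
        method="highs",
    )
    if not res.success:
        return "infeasible", None, None
    return "optimal", float(c @ res.x), res.x


def solve_min_total_flux(prob: LPProblem, fixed: list[tuple[str, float]]):
    """Minimize Σ|v| subject to S·v = 0, bounds, and ``v_rid >= value`` rows.

    Used for the parsimonious second stage.  Returns the flux vector or
    ``None`` if infeasible.
    """
    n = prob.n
    # split v = p - q, p,q >= 0
    lb_p = np.maximum(prob.lb, 0.0)
    ub_p = np.maximum(prob.ub, 0.0)
    lb_q = np.maximum(-prob.ub, 0.0)
    ub_q = np.maximum(-prob.lb, 0.0)
    S = prob.S
    A_eq = sparse.hstack([S, -S]).tocsr()
    c = np.ones(2 * n)
    A_ub_rows = []
    b_ub = []
    for rid, value in fixed:
        row = np.zeros(2 * n)
        j = prob.index(rid)
        row[j] = -1.0
        row[n + j] = 1.0  # -(p - q) <= -value  i.e.  v >= value
        A_ub_rows.append(row)
        b_ub.append(-value)
    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=np.zeros(A_eq.shape[0]),
        A_ub=np.array(A_ub_rows) if A_ub_rows else None,
        b_ub=np.array(b_ub) if b_ub else None,
        bounds=list(zip(np.concatenate([lb_p, lb_q]), np.concatenate([ub_p, ub_q]))),
        method="highs",
    )
    if not res.success:
        return None
    return res.x[:n] - res.x[n:]


@dataclass
class MILPResult:
    status: str
    objective: float | None
    x: np.ndarray | None


def solve_milp(
    c: np.ndarray,
    integrality: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    A_eq=None,
    A_ub=None,
    b_ub=None,
) -> MILPResult:
    """Minimize ``c·x`` with binary/continuous variables (HiGHS branch & bound).

    ``A_eq x = 0``; optional ``A_ub x <= b_ub``.  MILP gap is 0 (proven
    optimum) — instances here are desk-scale.
    """
    constraints = []
    if A_eq is not None and A_eq.shape[0]:
        constraints.append(LinearConstraint(A_eq, 0.0, 0.0))
    if A_ub is not None and A_ub.shape[0]:
        constraints.append(LinearConstraint(A_ub, -np.inf, b_ub))
    from scipy.optimize import Bounds

    res = milp(
        c,
        constraints=constraints,
        integrality=integrality,
        bounds=Bounds(lb, ub),
        options={"mip_rel_gap": 0.0},
    )
    if not res.success:
        return MILPResult("infeasible", None, None)
    return MILPResult("optimal", float(res.fun), res.x)
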