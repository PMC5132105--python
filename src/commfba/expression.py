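"""Expression-driven activity calls, transcriptomic flux fitting, and
flux/expression consistency reports.

Gene on/off calling follows the universal-role percentile rule: collect the
expression of genes annotated with universally active housekeeping roles
(translation/transcription machinery), take the value at the 10th lowest
percentile, and call every gene at or above that threshold "on", below it
"off".  Three-valued GPR evaluation lifts gene calls to reaction
activity; transcriptomic flux fitting then looks for a flux state that
agrees with as many reaction activity calls as possible — forcing reactions
with inactive genes off and reactions with active genes on — without
preventing biomass production.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import sparse

from .fba import FluxSolution
from .model import MediaCondition, MetabolicModel, apply_media
from .solver import build_problem, solve_milp

FLUX_ACTIVITY_DELTA = 1e-3
DEFAULT_PERCENTILE = 10.0


@dataclass
class ExpressionProfile:
    """Per-gene expression with threshold-derived on/off calls."""

    values: dict[str, float]
    universal_role_gene_ids: list[str]
    percentile: float
    threshold: float
    calls: dict[str, str]  # gene id -> "on" | "off" (absent genes: unknown)

    def call(self, gene: str) -> str:
        return self.calls.get(gene, "unknown")


def call_gene_activity(
    values: Mapping[str, float],
    universal_role_gene_ids: list[str],
    percentile: float = DEFAULT_PERCENTILE,
) -> ExpressionProfile:
    """Threshold genes on/off at a percentile of universal-role expression.

    The threshold is the given percentile (linear interpolation between
    order statistics: the k-th of n sorted values sits at quantile
    (k-1)/(n-1)) of the expression of the universal-role genes present in
    the profile.  Genes at or above the threshold are "on", below "off";
    genes absent from the profile are unknown.  Requires at least two
    universal-role genes with values.
    """
    uni_vals = [values[g] for g in universal_role_gene_ids if g in values]
    if len(uni_vals) < 2:
        raise ValueError(
            f"need >= 2 universal-role genes with expression values, got {len(uni_vals)}"
        )
    threshold = float(np.percentile(uni_vals, percentile))
    calls = {g: ("on" if v >= threshold else "off") for g, v in values.items()}
    return ExpressionProfile(
        values=dict(values),
        universal_role_gene_ids=list(universal_role_gene_ids),
        percentile=percentile,
        threshold=threshold,
        calls=calls,
    )


def reaction_activity(
    model: MetabolicModel, profile: ExpressionProfile
) -> dict[str, str]:
    """Lift gene calls to reactions through three-valued GPR evaluation.

    OR needs any subunit on; AND needs all on; an unknown gene that is
    decisive makes the reaction unknown.  Reactions with no gene rule
    (gapfilled, exchange, biomass, spontaneous) are unknown.
    """
    return {
        rid: r.gene_association.evaluate(profile.calls)
        for rid, r in model.reactions.items()
    }


def transcriptomic_fba(
    model: MetabolicModel,
    media: MediaCondition | None,
    activity: Mapping[str, str],
    epsilon: float = 0.01,
    delta: float = FLUX_ACTIVITY_DELTA,
    objective_id: str | None = None,
) -> tuple[FluxSolution, dict[str, bool]]:
    """Fit fluxes to reaction activity calls (MILP, maximum agreement).

    For each reaction called active, an indicator is rewarded when
    ``|flux| >= delta``; for each inactive reaction, when its flux is zero.
    Mass balance, bounds, and ``objective >= epsilon`` (biomass must stay
    producible) always hold; unknown reactions are unconstrained.  A second
    stage minimizes total flux at the fixed maximum agreement.  Returns the
    flux solution plus per-reaction agreement flags.
    """
    if media is not None:
        model = apply_media(model, media)
    if objective_id is None:
        objective_id = model.biomass_reaction_ids[0]
    prob = build_problem(model)
    n = prob.n
    active = sorted(
        r for r, a in activity.items() if a == "active" and r in model.reactions
    )
    inactive = sorted(
        r for r, a in activity.items() if a == "inactive" and r in model.reactions
    )
    na, ni = len(active), len(inactive)

    # variables: p (n), q (n), y_active (na), d_active (na), y_inactive (ni)
    ub_p = np.maximum(prob.ub, 0.0)
    ub_q = np.maximum(-prob.lb, 0.0)
    lb_p = np.maximum(prob.lb, 0.0)
    lb_q = np.maximum(-prob.ub, 0.0)
    nv = 2 * n + 2 * na + ni
    lb = np.concatenate([lb_p, lb_q, np.zeros(2 * na + ni)])
    ub = np.concatenate([ub_p, ub_q, np.ones(2 * na + ni)])
    integrality = np.concatenate([np.zeros(2 * n), np.ones(2 * na + ni)])

    S = prob.S
    A_eq = sparse.hstack(
        [S, -S, sparse.csr_matrix((S.shape[0], 2 * na + ni))]
    ).tocsr()

    rows = []

    def row(entries, rhs):
        r = np.zeros(nv)
        for idx, coeff in entries:
            r[idx] = coeff
        rows.append((r, rhs))

    i_obj = prob.index(objective_id)
    row([(i_obj, -1.0), (n + i_obj, 1.0)], -epsilon)  # v_obj >= epsilon
    for a, rid in enumerate(active):
        j = prob.index(rid)
        y = 2 * n + a
        d = 2 * n + na + a
        cap_p = max(ub_p[j], delta)
        cap_q = max(ub_q[j], delta)
        row([(j, 1.0), (d, -cap_p)], 0.0)            # p <= cap_p * d
        row([(n + j, 1.0), (d, cap_q)], cap_q)       # q <= cap_q * (1 - d)
        row([(j, -1.0), (n + j, -1.0), (y, delta)], 0.0)  # p + q >= delta * y
    for b, rid in enumerate(inactive):
        j = prob.index(rid)
        y = 2 * n + 2 * na + b
        cap = ub_p[j] + ub_q[j]
        row([(j, 1.0), (n + j, 1.0), (y, cap)], cap)  # p + q <= cap * (1 - y)

    A_ub = np.array([r for r, _ in rows])
    b_ub = np.array([rhs for _, rhs in rows])
    c1 = np.zeros(nv)
    c1[2 * n : 2 * n + na] = -1.0
    c1[2 * n + 2 * na :] = -1.0  # maximize agreements
    res = solve_milp(c1, integrality, lb, ub, A_eq=A_eq, A_ub=A_ub, b_ub=b_ub)
    if res.status != "optimal":
        raise ValueError(
            f"transcriptomic flux fitting infeasible for {model.id} "
            f"(biomass {objective_id} cannot reach {epsilon})"
        )
    best_agreement = -res.objective

    # stage 2: minimum total flux at the fixed maximum agreement
    agree_row = np.zeros(nv)
    agree_row[2 * n : 2 * n + na] = -1.0
    agree_row[2 * n + 2 * na :] = -1.0
    A_ub2 = np.vstack([A_ub, agree_row])
    b_ub2 = np.concatenate([b_ub, [-(best_agreement - 0.5)]])
    c2 = np.concatenate([np.ones(2 * n), np.zeros(2 * na + ni)])
    res2 = solve_milp(c2, integrality, lb, ub, A_eq=A_eq, A_ub=A_ub2, b_ub=b_ub2)
    if res2.status == "optimal":
        res = res2
    v = res.x[:n] - res.x[n : 2 * n]
    fluxes = {rid: float(v[i]) for i, rid in enumerate(prob.reaction_ids)}
    solution = FluxSolution("optimal", fluxes[objective_id], fluxes, objective_id)
    agreement = {}
    for rid in active:
        agreement[rid] = abs(fluxes[rid]) >= delta - 1e-9
    for rid in inactive:
        agreement[rid] = abs(fluxes[rid]) < delta
    return solution, agreement


@dataclass
class ConsistencyReport:
    """Flux/expression confusion matrix over classified reactions.

    Percentages are over reactions with a definite activity call; a
    reaction "has flux" when ``|v| >= delta``.  Accuracy for active genes =
    (+F+E)/((+F+E)+(-F+E)); for inactive = (-F-E)/((-F-E)+(+F-E)); overall
    = (+F+E)+(-F-E).  Per-pathway tallies add a fifth category: gapfilled
    reactions carrying flux.
    """

    pct_flux_exp: float
    pct_noflux_noexp: float
    pct_flux_noexp: float
    pct_noflux_exp: float
    accuracy_active: float | None
    accuracy_inactive: float | None
    accuracy_overall: float
    n_classified: int
    per_pathway: dict[str, dict[str, int]] = field(default_factory=dict)

    def summary_row(self) -> dict:
        na = float("nan")
        return {
            "+Flux,+Exp(%)": round(self.pct_flux_exp, 1),
            "-Flux,-Exp(%)": round(self.pct_noflux_noexp, 1),
            "+Flux,-Exp(%)": round(self.pct_flux_noexp, 1),
            "-Flux,+Exp(%)": round(self.pct_noflux_exp, 1),
            "accuracy_active(%)": round(self.accuracy_active, 1)
            if self.accuracy_active is not None else na,
            "accuracy_inactive(%)": round(self.accuracy_inactive, 1)
            if self.accuracy_inactive is not None else na,
            "accuracy_overall(%)": round(self.accuracy_overall, 1),
        }


def accuracies_from_categories(
    pct_flux_exp: float,
    pct_noflux_noexp: float,
    pct_flux_noexp: float,
    pct_noflux_exp: float,
) -> tuple[float | None, float | None, float]:
    """(active, inactive, overall) accuracies from the four category shares.

    Works on percentages or raw counts alike; degenerate denominators give
    ``None`` (not applicable).
    """
    act_den = pct_flux_exp + pct_noflux_exp
    inact_den = pct_noflux_noexp + pct_flux_noexp
    acc_active = 100.0 * pct_flux_exp / act_den if act_den > 0 else None
    acc_inactive = 100.0 * pct_noflux_noexp / inact_den if inact_den > 0 else None
    total = act_den + inact_den
    overall = 100.0 * (pct_flux_exp + pct_noflux_noexp) / total if total > 0 else 0.0
    return acc_active, acc_inactive, overall


def consistency_report(
    solution: FluxSolution,
    activity: Mapping[str, str],
    model: MetabolicModel,
    delta: float = FLUX_ACTIVITY_DELTA,
) -> ConsistencyReport:
    """Score a flux solution against reaction activity calls."""
    counts = {"fe": 0, "nn": 0, "fn": 0, "ne": 0}
    per_pathway: dict[str, dict[str, int]] = {}

    def pw_bucket(r):
        pw = r.pathway or "unassigned"
        return per_pathway.setdefault(
            pw, {"flux_exp": 0, "noflux_noexp": 0, "flux_noexp": 0,
                 "noflux_exp": 0, "gapfilled_active": 0, "n_reactions": 0}
        )

    for rid, r in model.reactions.items():
        bucket = pw_bucket(r)
        bucket["n_reactions"] += 1
        has_flux = abs(solution.fluxes.get(rid, 0.0)) >= delta
        if r.source_tag == "gapfilled" and has_flux:
            bucket["gapfilled_active"] += 1
        call = activity.get(rid, "unknown")
        if call == "active":
            key = "fe" if has_flux else "ne"
        elif call == "inactive":
            key = "fn" if has_flux else "nn"
        else:
            continue
        counts[key] += 1
        bucket[
            {"fe": "flux_exp", "nn": "noflux_noexp",
             "fn": "flux_noexp", "ne": "noflux_exp"}[key]
        ] += 1

    total = sum(counts.values())
    pct = {k: (100.0 * v / total if total else 0.0) for k, v in counts.items()}
    acc_active, acc_inactive, overall = accuracies_from_categories(
        pct["fe"], pct["nn"], pct["fn"], pct["ne"]
    )
    return ConsistencyReport(
        pct_flux_exp=pct["fe"],
        pct_noflux_noexp=pct["nn"],
        pct_flux_noexp=pct["fn"],
        pct_noflux_exp=pct["ne"],
        accuracy_active=acc_active,
        accuracy_inactive=acc_inactive,
        accuracy_overall=overall,
        n_classified=total,
        per_pathway=per_pathway,
    )
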