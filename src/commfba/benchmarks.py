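"""Validation benchmarks: deterministic instance generators and brute-force
oracles used to certify the optimizers.

Everything here is an *independent* route to the same answers the main
implementation computes: subset enumeration for gapfilling, and explicit
vertex enumeration of the flux polytope for (parsimonious) FBA.
"""

from __future__ import annotations

import itertools

import numpy as np

from .fixtures import (
    FixtureSpec,
    make_glucose_minimal_media,
    make_rich_media,
    make_autotrophic_media,
    make_toy_database,
    make_toy_heterotroph,
    make_toy_phototroph,
)
from .gapfill import brute_force_gapfill, gapfill
from .model import Compartment, MetabolicModel, Metabolite, Reaction
from .solver import build_problem


def gapfill_benchmark_instances():
    """>= 25 deterministic gapfilling instances over the toy consortium.

    Heterotroph variants drop pathway combinations and are repaired on
    glucose-minimal or rich media; phototroph variants each lose a single
    internal reaction and are repaired autotrophically.  All instances stay
    within reach of the subset-enumeration oracle.
    """
    instances = []
    het_deletions = [
        (),
        ("vitamin_synthesis",),
        ("aa_synthesis",),
        ("glucose_transport",),
        ("vitamin_synthesis", "aa_synthesis"),
        ("vitamin_synthesis", "glucose_transport"),
        ("aa_synthesis", "glucose_transport"),
    ]
    db = make_toy_database()
    for deleted in het_deletions:
        model = make_toy_heterotroph(
            FixtureSpec(heterotroph_deleted=("nitrate_assimilation",) + deleted)
        )
        for media in (make_glucose_minimal_media(), make_rich_media()):
            instances.append((f"het-{'+'.join(deleted) or 'none'}-{media.name}",
                              model, db, media))
    pho_removals = ["LIGHT", "CFIX", "NRED", "AASYN", "VITSYN1", "VITSYN2",
                    "VITSYN3", "T_no3", "T_photon", "T_nh3", "T_glc"]
    for rid in pho_removals:
        model = make_toy_phototroph()
        del model.reactions[rid]
        instances.append((f"pho-minus-{rid}", model, db, make_autotrophic_media()))
    return instances


def verify_gapfill_optimality(instances=None):
    """Fraction of instances where the MILP cost equals the oracle minimum."""
    if instances is None:
        instances = gapfill_benchmark_instances()
    matches, results = 0, []
    for name, model, db, media in instances:
        res = gapfill(model, db, media)
        oracle = brute_force_gapfill(
            model, db, media, max_size=max(int(round(res.total_cost)), 1)
        )
        oracle_min = min(
            (sum(c.cost for c in s) for s in oracle), default=float("inf")
        )
        if res.total_cost == 0.0:
            ok = True  # already growing: zero is trivially minimal
        else:
            ok = abs(res.total_cost - oracle_min) < 1e-9
        matches += ok
        results.append((name, res.total_cost, oracle_min, ok))
    return matches / len(instances), results


# ---------------------------------------------------------------------------
# Tiny LP instances and the vertex-enumeration oracle
# ---------------------------------------------------------------------------

def tiny_chain_model(with_cycle: bool = False) -> MetabolicModel:
    """Uptake-limited linear pathway, optionally with a futile cycle."""
    m = MetabolicModel(
        "chain",
        [Compartment("c1", "cytosol", 1), Compartment("e0", "extracellular", 0)],
        [
            Metabolite("A_e0", "e0", formula="C"),
            Metabolite("A_c1", "c1", formula="C"),
            Metabolite("B_c1", "c1", formula="C"),
        ],
    )
    m.add_reaction(Reaction("EX_A_e0", {"A_e0": -1.0}, -10.0, 0.0, source_tag="exchange"))
    m.add_reaction(Reaction("T_A", {"A_e0": -1.0, "A_c1": 1.0}, 0.0, 100.0,
                            source_tag="transport"))
    m.add_reaction(Reaction("R1", {"A_c1": -1.0, "B_c1": 1.0}, 0.0, 100.0))
    m.add_reaction(Reaction("BIO", {"B_c1": -1.0}, 0.0, 100.0, source_tag="biomass"))
    m.biomass_reaction_ids = ["BIO"]
    if with_cycle:
        m.metabolites["C_c1"] = Metabolite("C_c1", "c1", formula="C")
        m.add_reaction(Reaction("R2", {"B_c1": -1.0, "C_c1": 1.0}, 0.0, 100.0))
        m.add_reaction(Reaction("R3", {"C_c1": -1.0, "B_c1": 1.0}, 0.0, 100.0))
    return m


def tiny_branch_model() -> MetabolicModel:
    """Two parallel routes of different length to the same product; the
    parsimonious solution must use only the short one."""
    m = MetabolicModel(
        "branch",
        [Compartment("c1", "cytosol", 1), Compartment("e0", "extracellular", 0)],
        [
            Metabolite("A_e0", "e0", formula="C"),
            Metabolite("A_c1", "c1", formula="C"),
            Metabolite("M_c1", "c1", formula="C"),
            Metabolite("B_c1", "c1", formula="C"),
        ],
    )
    m.add_reaction(Reaction("EX_A_e0", {"A_e0": -1.0}, -5.0, 0.0, source_tag="exchange"))
    m.add_reaction(Reaction("T_A", {"A_e0": -1.0, "A_c1": 1.0}, 0.0, 100.0,
                            source_tag="transport"))
    m.add_reaction(Reaction("SHORT", {"A_c1": -1.0, "B_c1": 1.0}, 0.0, 100.0))
    m.add_reaction(Reaction("LONG1", {"A_c1": -1.0, "M_c1": 1.0}, 0.0, 100.0))
    m.add_reaction(Reaction("LONG2", {"M_c1": -1.0, "B_c1": 1.0}, 0.0, 100.0))
    m.add_reaction(Reaction("BIO", {"B_c1": -1.0}, 0.0, 100.0, source_tag="biomass"))
    m.biomass_reaction_ids = ["BIO"]
    return m


def enumerate_vertices(A, b, lb, ub):
    """All vertices of {x : A x = b, lb <= x <= ub} by explicit enumeration
    of active bound sets (independent of any LP solver)."""
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    n = A.shape[1]
    rank = np.linalg.matrix_rank(A) if A.size else 0
    k = n - rank
    vertices = []
    for fixed_idx in itertools.combinations(range(n), k):
        free_idx = [j for j in range(n) if j not in fixed_idx]
        for sides in itertools.product([0, 1], repeat=k):
            x = np.empty(n)
            for j, s in zip(fixed_idx, sides):
                x[j] = lb[j] if s == 0 else ub[j]
            rhs = b - A[:, list(fixed_idx)] @ x[list(fixed_idx)]
            if free_idx:
                sol, *_ = np.linalg.lstsq(A[:, free_idx], rhs, rcond=None)
                x[free_idx] = sol
            if np.max(np.abs(A @ x - b), initial=0.0) > 1e-7:
                continue
            if np.any(x < lb - 1e-7) or np.any(x > ub + 1e-7):
                continue
            if not any(np.allclose(x, v, atol=1e-6) for v in vertices):
                vertices.append(x.copy())
    return vertices


def vertex_fba_oracle(model: MetabolicModel, objective_id: str):
    """Maximum objective flux over all polytope vertices."""
    prob = build_problem(model)
    verts = enumerate_vertices(
        prob.S.toarray(), np.zeros(prob.S.shape[0]), prob.lb, prob.ub
    )
    j = prob.index(objective_id)
    return max(v[j] for v in verts), prob, verts


def vertex_pfba_oracle(model: MetabolicModel, objective_id: str):
    """Minimum total |flux| at the optimal objective, enumerated over the
    vertices of the split-variable (v = p - q) polytope."""
    best, prob, _ = vertex_fba_oracle(model, objective_id)
    n = prob.n
    S = prob.S.toarray()
    j = prob.index(objective_id)
    obj_row = np.zeros(2 * n)
    obj_row[j], obj_row[n + j] = 1.0, -1.0
    A = np.vstack([np.hstack([S, -S]), obj_row])
    b = np.concatenate([np.zeros(S.shape[0]), [best]])
    lb = np.concatenate([np.maximum(prob.lb, 0), np.maximum(-prob.ub, 0)])
    ub = np.concatenate([np.maximum(prob.ub, 0), np.maximum(-prob.lb, 0)])
    verts = enumerate_vertices(A, b, lb, ub)
    totals = [float(np.sum(v)) for v in verts]
    i = int(np.argmin(totals))
    fluxes = dict(zip(prob.reaction_ids, verts[i][:n] - verts[i][n:]))
    return best, totals[i], fluxes
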