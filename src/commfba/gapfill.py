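"""Parsimony gapfilling of single-species and community models.

Gapfilling finds a minimum-cost set of candidate database reactions whose
addition lets the model reach a target objective flux (biomass >= epsilon)
on a given medium.  The formulation is the standard indicator MILP::

    minimize    sum_j cost_j * z_j            z_j in {0, 1}
    subject to  S v = 0
                v_objective >= epsilon
                0 <= v_j <= M * z_j           for every directed candidate j
                lb <= v <= ub                 for native reactions

solved exactly (branch and bound, zero MIP gap), so the result is provably
minimal and can be checked against the brute-force subset-enumeration
oracle.  Reversible database reactions become two directed candidates (one
per direction, each with its own cost).

Community-level gapfilling instantiates the entire candidate database once
per species compartment (plus transporter templates linking each cytosol to
the shared extracellular compartment), so the optimizer may delegate a
function to a partner species and connect it by transport — it proposes
cross-feeding whenever that is the most parsimonious repair.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy import sparse

from .community import CommunityModel, build_compartmentalized
from .fba import run_fba
from .model import (
    DatabaseReaction,
    MediaCondition,
    MetabolicModel,
    Metabolite,
    Reaction,
    ReactionDatabase,
    apply_media,
    canonical_stoichiometry,
)
from .solver import build_problem, solve_lp, solve_milp

BIG_M = 100.0
EPSILON = 0.01


@dataclass
class Candidate:
    """A directed, compartment-instantiated candidate reaction."""

    instance_id: str
    db_id: str
    compartment: str
    direction: str  # "fwd" | "rev"
    cost: float
    stoichiometry: dict[str, float]
    new_metabolites: dict[str, str]  # met id -> compartment
    pathway: str | None = None

    def sort_key(self):
        return (self.compartment, self.db_id, self.direction)

    def to_reaction(self) -> Reaction:
        return Reaction(
            id=self.instance_id,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=0.0,
            upper_bound=BIG_M,
            pathway=self.pathway,
            source_tag="gapfilled",
            meta={
                "db_id": self.db_id,
                "compartment": self.compartment,
                "direction": self.direction,
            },
        )


@dataclass
class GapfillResult:
    """Outcome of one gapfilling run: what to add, at what cost, and proof."""

    added: list[Candidate]
    total_cost: float
    strategy: str  # "igf" | "cgf" | "igf+cgf"
    media_name: str
    objective_id: str
    objective_achieved: float

    @property
    def added_ids(self) -> list[str]:
        return sorted(c.instance_id for c in self.added)

    def __len__(self):
        return len(self.added)


def _formula_for(model: MetabolicModel, db: ReactionDatabase, compound: str):
    if compound in db.transportable_compounds:
        return db.transportable_compounds[compound]
    for met in model.metabolites.values():
        if met.compound == compound and met.formula is not None:
            return met.formula
    return None


def instantiate_candidates(
    model: MetabolicModel,
    database: ReactionDatabase,
    compartments: list[str] | None = None,
    include_transporters: bool = True,
) -> list[Candidate]:
    """Bind database templates to concrete compartments of ``model``.

    Template metabolite roles ``<compound>_c`` / ``<compound>_e`` map to
    ``<compound>_<comp>`` / ``<compound>_e0``.  Transporter templates (a
    reversible uniport per transportable compound per compartment) are
    emitted as two directed candidates.  Candidates identical to a reaction
    already in the model are skipped.
    """
    if compartments is None:
        compartments = sorted(
            c.id for c in model.compartments.values() if c.label == "cytosol"
        )
    e0 = model.extracellular_compartment
    existing = {
        canonical_stoichiometry(r.stoichiometry)[0] for r in model.reactions.values()
    }
    out: list[Candidate] = []

    def emit(db_id, comp, direction, cost, stoich, pathway=None):
        canon, _ = canonical_stoichiometry(stoich)
        if canon in existing:
            return
        new_mets = {
            m: (comp if not m.endswith(f"_{e0}") else e0)
            for m in stoich
            if m not in model.metabolites
        }
        out.append(
            Candidate(
                instance_id=f"gf_{db_id}_{comp}_{direction}",
                db_id=db_id,
                compartment=comp,
                direction=direction,
                cost=cost,
                stoichiometry=dict(stoich),
                new_metabolites=new_mets,
                pathway=pathway,
            )
        )

    for comp in compartments:
        for dbr in database.reactions:
            stoich = {}
            for role, coeff in dbr.stoichiometry.items():
                compound, suffix = role.rsplit("_", 1)
                target = comp if suffix == "c" else e0
                stoich[f"{compound}_{target}"] = coeff
            emit(dbr.id, comp, "fwd", dbr.cost_forward, stoich, dbr.pathway)
            if dbr.reversible:
                emit(
                    dbr.id, comp, "rev", dbr.cost_backward,
                    {m: -c for m, c in stoich.items()}, dbr.pathway,
                )
        if include_transporters:
            for compound in sorted(database.transportable_compounds):
                cyt_met = f"{compound}_{comp}"
                ext_met = f"{compound}_{e0}"
                emit(
                    f"tp_{compound}", comp, "fwd", 1.0,
                    {cyt_met: -1.0, ext_met: 1.0}, "transport",
                )
                emit(
                    f"tp_{compound}", comp, "rev", 1.0,
                    {ext_met: -1.0, cyt_met: 1.0}, "transport",
                )
    out.sort(key=Candidate.sort_key)
    return out


def integrate_gapfill(model: MetabolicModel, result: GapfillResult) -> MetabolicModel:
    """Return a copy of ``model`` with the gapfilled reactions added.

    Forward/backward pairs of the same database reaction in the same
    compartment are merged into one reversible reaction.  New metabolites
    are created as needed; added reactions carry ``source_tag="gapfilled"``.
    """
    out = model.copy()
    by_pair: dict[tuple[str, str], list[Candidate]] = {}
    for cand in result.added:
        by_pair.setdefault((cand.db_id, cand.compartment), []).append(cand)
    for (db_id, comp), cands in sorted(by_pair.items()):
        cand = next((c for c in cands if c.direction == "fwd"), cands[0])
        rxn = cand.to_reaction()
        for met_id in rxn.stoichiometry:
            if met_id not in out.metabolites:
                compound, comp_id = met_id.rsplit("_", 1)
                formula = None
                for met in model.metabolites.values():
                    if met.compound == compound and met.formula is not None:
                        formula = met.formula
                        break
                out.metabolites[met_id] = Metabolite(
                    met_id, comp_id, name=compound, formula=formula
                )
        if len(cands) > 1:  # both directions selected -> reversible
            rxn.lower_bound = -BIG_M
            rxn.meta["direction"] = "both"
        if cand.direction == "rev" and len(cands) == 1:
            pass  # keep the directed orientation as instantiated
        if rxn.id in out.reactions:
            continue
        # exchange-like candidates (only extracellular metabolites) keep
        # validity under the exchange tagging invariant
        e0 = out.extracellular_compartment
        if all(out.metabolites[m].compartment_id == e0 for m in rxn.stoichiometry):
            rxn.source_tag = "exchange"
        out.add_reaction(rxn)
    return out


def _ensure_media_compounds(model, database, media):
    """Extracellular metabolites (with formulas) for media compounds, so
    transporter candidates can reach compounds the draft never touched."""
    out = model.copy()
    e0 = out.extracellular_compartment
    for compound in media.entries:
        met_id = f"{compound}_{e0}"
        if met_id not in out.metabolites:
            out.metabolites[met_id] = Metabolite(
                met_id, e0, name=compound, formula=_formula_for(model, database, compound)
            )
    return out


def gapfill(
    model: MetabolicModel,
    database: ReactionDatabase,
    media: MediaCondition,
    objective_id: str | None = None,
    epsilon: float = EPSILON,
    compartments: list[str] | None = None,
    include_transporters: bool = True,
    strategy_label: str = "igf",
) -> GapfillResult:
    """Minimum-cost reaction additions making ``objective_id`` reach epsilon.

    Returns an empty result (cost 0) if the model already grows.  Raises
    ``ValueError("no gapfill solution")`` if even the full database cannot
    restore growth.  Ties between equal-cost optima are broken
    deterministically in favour of the lexicographically smallest sorted
    (compartment, database id, direction) tuple.
    """
    if objective_id is None:
        objective_id = model.biomass_reaction_ids[0]
    base = _ensure_media_compounds(model, database, media)
    constrained = apply_media(base, media)
    sol = run_fba(constrained, objective_id=objective_id)
    if sol.status == "optimal" and sol.objective_value >= epsilon:
        return GapfillResult([], 0.0, strategy_label, media.name, objective_id,
                             sol.objective_value)

    candidates = instantiate_candidates(
        constrained, database, compartments, include_transporters
    )
    extended = constrained.copy()
    for cand in candidates:
        for met_id, comp in cand.new_metabolites.items():
            if met_id not in extended.metabolites:
                compound = met_id[: -(len(comp) + 1)]
                extended.metabolites[met_id] = Metabolite(
                    met_id, comp, name=compound,
                    formula=_formula_for(model, database, compound),
                )
        extended.add_reaction(cand.to_reaction())

    prob = build_problem(extended)
    n = prob.n
    k = len(candidates)
    # variables: [v (n), z (k)]
    lb = np.concatenate([prob.lb, np.zeros(k)])
    ub = np.concatenate([prob.ub, np.ones(k)])
    integrality = np.concatenate([np.zeros(n), np.ones(k)])
    A_eq = sparse.hstack([prob.S, sparse.csr_matrix((prob.S.shape[0], k))]).tocsr()
    rows, cols, data = [], [], []
    for j, cand in enumerate(candidates):
        vi = prob.index(cand.instance_id)
        rows += [j, j]
        cols += [vi, n + j]
        data += [1.0, -BIG_M]  # v_j - M z_j <= 0
    obj_row = sparse.csr_matrix(
        ([-1.0], ([0], [prob.index(objective_id)])), shape=(1, n + k)
    )  # -v_obj <= -epsilon
    A_ub = sparse.vstack(
        [sparse.csr_matrix((data, (rows, cols)), shape=(k, n + k)), obj_row]
    ).tocsr()
    b_ub = np.concatenate([np.zeros(k), [-epsilon]])
    # infinitesimal rank perturbation: deterministic lexicographic tie-break
    costs = np.array([c.cost for c in candidates])
    perturb = 1e-7 * np.arange(k) / max(k, 1)
    c_vec = np.concatenate([np.zeros(n), costs + perturb])

    res = solve_milp(c_vec, integrality, lb, ub, A_eq=A_eq, A_ub=A_ub, b_ub=b_ub)
    if res.status != "optimal":
        raise ValueError(
            f"no gapfill solution for {model.id} on {media.name} "
            f"(objective {objective_id} cannot reach {epsilon})"
        )
    chosen = [candidates[j] for j in range(k) if res.x[n + j] > 0.5]
    # safety: drop selected-but-idle candidates (all costs are > 0, so an
    # optimal solution never pays for a zero-flux indicator)
    chosen = [c for c in chosen if abs(res.x[prob.index(c.instance_id)]) > 1e-9]
    total = sum(c.cost for c in chosen)
    result = GapfillResult(
        sorted(chosen, key=Candidate.sort_key), total, strategy_label,
        media.name, objective_id, 0.0,
    )
    # feasibility proof: integrate and re-run FBA
    check = apply_media(integrate_gapfill(base, result), media)
    proof = run_fba(check, objective_id=objective_id)
    if proof.status != "optimal" or proof.objective_value < epsilon - 1e-9:
        raise RuntimeError(
            f"gapfill verification failed for {model.id} on {media.name}"
        )
    result.objective_achieved = proof.objective_value
    return result


def community_gapfill(
    community: CommunityModel,
    database: ReactionDatabase,
    media: MediaCondition,
    epsilon: float = EPSILON,
) -> GapfillResult:
    """Gapfill a community model against its community biomass.

    The candidate database is instantiated once per species compartment
    (with transporter templates per species), so repairs may be delegated
    across members and wired through the shared extracellular compartment.
    """
    return gapfill(
        community,
        database,
        media,
        objective_id=community.community_biomass_id,
        epsilon=epsilon,
        strategy_label="cgf",
    )


def gapfill_iterative(
    model: MetabolicModel,
    database: ReactionDatabase,
    media_list: list[MediaCondition],
    epsilon: float = EPSILON,
) -> tuple[MetabolicModel, list[GapfillResult]]:
    """Gapfill on several media in sequence, integrating after each round.

    Reactions added in earlier rounds are part of the model (cost already
    paid) in later rounds; the returned model grows on every listed medium.
    """
    if not media_list:
        raise ValueError("media_list must be non-empty")
    current = model
    results = []
    for media in media_list:
        res = gapfill(current, database, media, epsilon=epsilon)
        current = integrate_gapfill(current, res)
        results.append(res)
    return current, results


def run_strategy(
    members: list[MetabolicModel],
    database: ReactionDatabase,
    member_media: list[MediaCondition] | MediaCondition,
    community_media: MediaCondition,
    strategy: str,
    epsilon: float = EPSILON,
) -> tuple[CommunityModel, list[GapfillResult]]:
    """The three community-construction strategies.

    * ``"A"`` — gapfill each member individually on its own medium, then
      merge; no community-level gapfilling (the *pre* model).
    * ``"B"`` — merge the ungapfilled drafts, then gapfill the community
      (the *mix* model).
    * ``"C"`` — pre-gapfill members on a rich medium, merge, then
      post-gapfill the community (the *post* model).

    For strategies A and C, ``member_media`` is one medium per member (or a
    single medium used for all — for C typically the rich medium).
    """
    if strategy not in ("A", "B", "C"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if isinstance(member_media, MediaCondition):
        member_media = [member_media] * len(members)
    results: list[GapfillResult] = []
    working = list(members)
    if strategy in ("A", "C"):
        label = "igf" if strategy == "A" else "igf+cgf"
        gapfilled = []
        for member, media in zip(working, member_media):
            try:
                res = gapfill(member, database, media, epsilon=epsilon,
                              strategy_label=label)
            except ValueError as err:
                raise ValueError(
                    f"strategy {strategy}: member {member.id} cannot be "
                    f"gapfilled alone on {media.name} ({err})"
                ) from err
            results.append(res)
            gapfilled.append(integrate_gapfill(member, res))
        working = gapfilled
    community, _ = build_compartmentalized(working)
    if strategy in ("B", "C"):
        label = "cgf" if strategy == "B" else "igf+cgf"
        res = community_gapfill(community, database, community_media, epsilon=epsilon)
        res.strategy = label
        results.append(res)
        community = integrate_gapfill(community, res)
    return community, results


def brute_force_gapfill(
    model: MetabolicModel,
    database: ReactionDatabase,
    media: MediaCondition,
    objective_id: str | None = None,
    epsilon: float = EPSILON,
    max_size: int | None = None,
    compartments: list[str] | None = None,
    include_transporters: bool = True,
) -> list[list[Candidate]]:
    """Exhaustive subset-enumeration oracle for gapfill optimality.

    Enumerates candidate subsets in increasing cardinality and returns all
    minimum-cost feasibility-minimal subsets (supersets of a feasible
    solution are pruned).  Guard: at most 15 instantiated candidates unless
    ``max_size`` caps the enumeration at a tractable subset count.
    """
    if objective_id is None:
        objective_id = model.biomass_reaction_ids[0]
    base = _ensure_media_compounds(model, database, media)
    constrained = apply_media(base, media)
    candidates = instantiate_candidates(
        constrained, database, compartments, include_transporters
    )
    n = len(candidates)
    limit = max_size if max_size is not None else n
    if n > 15 and (max_size is None or comb(n, min(max_size, n // 2)) > 200_000):
        raise ValueError(
            f"{n} candidates exceeds the brute-force guard (pass a smaller max_size)"
        )
    extended = constrained.copy()
    for cand in candidates:
        for met_id, comp in cand.new_metabolites.items():
            if met_id not in extended.metabolites:
                extended.metabolites[met_id] = Metabolite(met_id, comp)
        extended.add_reaction(cand.to_reaction())
    prob = build_problem(extended)
    cand_var = [prob.index(c.instance_id) for c in candidates]
    base_ub = prob.ub.copy()

    def feasible(subset: tuple[int, ...]) -> bool:
        prob.ub[cand_var] = 0.0
        for j in subset:
            prob.ub[cand_var[j]] = base_ub[cand_var[j]]
        status, obj, _ = solve_lp(prob, {objective_id: 1.0}, sense="max")
        prob.ub[cand_var] = base_ub[cand_var]
        return status == "optimal" and obj >= epsilon - 1e-9

    solutions: list[tuple[int, ...]] = []
    for k in range(0, limit + 1):
        for subset in itertools.combinations(range(n), k):
            chosen = set(subset)
            if any(set(s) <= chosen for s in solutions):
                continue  # superset of a known solution: not minimal
            if feasible(subset):
                solutions.append(subset)
        if solutions and all(c.cost == candidates[0].cost for c in candidates):
            break  # uniform costs: larger subsets cannot cost less
    if not solutions:
        return []
    best = min(sum(candidates[j].cost for j in s) for s in solutions)
    return [
        [candidates[j] for j in s]
        for s in solutions
        if abs(sum(candidates[j].cost for j in s) - best) < 1e-9
    ]
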