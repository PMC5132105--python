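"""Steady-state flux analyses.

Flux balance analysis (FBA) maximizes an objective flux (normally biomass)
subject to mass balance S·v = 0 and flux bounds.  Parsimonious FBA (pFBA)
adds a second stage that minimizes total absolute flux Σ|v| at the fixed
optimal objective, removing futile cycles and giving a deterministic,
biologically sparing exchange pattern — which is why interspecies
interaction extraction runs on pFBA solutions by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .community import CommunityModel
from .model import MediaCondition, MetabolicModel, apply_media
from .solver import build_problem, solve_lp, solve_min_total_flux

GROWTH_THRESHOLD = 1e-6
INTERACTION_TOL = 1e-6


@dataclass
class FluxSolution:
    status: str  # "optimal" | "infeasible"
    objective_value: float | None
    fluxes: dict[str, float] = field(default_factory=dict)
    objective_id: str | None = None

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]


@dataclass
class Interaction:
    compound: str
    producer: str  # species id (e.g. "sp1") or member model id
    consumer: str
    flux: float
    mode: str = "pfba"  # "pfba" | "obligatory" | "possible"


@dataclass
class InteractionMap:
    interactions: list[Interaction] = field(default_factory=list)

    def compounds(self) -> set[str]:
        return {i.compound for i in self.interactions}

    def __len__(self):
        return len(self.interactions)

    def __iter__(self):
        return iter(self.interactions)


def run_fba(
    model: MetabolicModel,
    media: MediaCondition | None = None,
    objective_id: str | None = None,
    parsimonious: bool = False,
) -> FluxSolution:
    """Maximize ``objective_id`` flux (default: the model's biomass).

    With ``parsimonious=True`` a second LP minimizes Σ|v| while holding the
    objective at its optimum.
    """
    if media is not None:
        model = apply_media(model, media)
    if objective_id is None:
        if not model.biomass_reaction_ids:
            raise ValueError(f"model {model.id}: no biomass reaction to optimize")
        objective_id = model.biomass_reaction_ids[0]
    if objective_id not in model.reactions:
        raise KeyError(f"objective reaction {objective_id!r} not in model")
    prob = build_problem(model)
    status, obj, x = solve_lp(prob, {objective_id: 1.0}, sense="max")
    if status != "optimal":
        return FluxSolution("infeasible", None, {}, objective_id)
    if parsimonious:
        x2 = solve_min_total_flux(prob, [(objective_id, obj - 1e-9)])
        if x2 is not None:
            x = x2
    fluxes = {rid: float(v) for rid, v in zip(prob.reaction_ids, x)}
    return FluxSolution("optimal", obj, fluxes, objective_id)


def predict_growth(
    model: MetabolicModel,
    media: MediaCondition | None = None,
    threshold: float = GROWTH_THRESHOLD,
    objective_id: str | None = None,
):
    """Growth call: optimal biomass flux >= threshold.  Returns (bool, objective)."""
    sol = run_fba(model, media, objective_id)
    if sol.status != "optimal":
        return False, 0.0
    return sol.objective_value >= threshold, sol.objective_value


def predict_auxotrophies(
    model: MetabolicModel,
    rich_media: MediaCondition,
    threshold: float = GROWTH_THRESHOLD,
) -> list[str]:
    """Compounds whose single removal from the media abolishes growth.

    For each compound allowed for uptake, growth is re-tested with that
    compound's uptake closed.  A compound rescued by an alternative source
    (e.g. two interchangeable nitrogen sources) is not reported.
    """
    grows, _ = predict_growth(model, rich_media, threshold)
    if not grows:
        raise ValueError(
            f"model {model.id} does not grow on media {rich_media.name}; "
            "auxotrophy testing requires a growing baseline"
        )
    required = []
    for compound, (up, ex) in sorted(rich_media.entries.items()):
        if up <= 0:
            continue
        entries = dict(rich_media.entries)
        entries[compound] = (0.0, ex)
        reduced = MediaCondition(f"{rich_media.name}-minus-{compound}", entries)
        still_grows, _ = predict_growth(model, reduced, threshold)
        if not still_grows:
            required.append(compound)
    return required


def _species_net_secretion(
    community: CommunityModel, fluxes: dict[str, float]
) -> dict[str, dict[str, float]]:
    """Per extracellular compound, each species' net flux into ``e0``."""
    comp_species = {
        cid: info["species_id"] for cid, info in community.species_index.items()
    }
    net: dict[str, dict[str, float]] = {}
    for rid, r in community.reactions.items():
        if r.source_tag in ("exchange", "biomass"):
            continue
        species = {
            comp_species[community.metabolites[m].compartment_id]
            for m in r.stoichiometry
            if community.metabolites[m].compartment_id in comp_species
        }
        if len(species) != 1:
            continue  # not attributable to a single species
        sp = species.pop()
        v = fluxes.get(rid, 0.0)
        for m, coeff in r.stoichiometry.items():
            met = community.metabolites[m]
            if met.compartment_id == "e0":
                cpd = met.compound
                net.setdefault(cpd, {}).setdefault(sp, 0.0)
                net[cpd][sp] += coeff * v
    return net


def identify_interactions(
    community: CommunityModel,
    media: MediaCondition | None = None,
    tolerance: float = INTERACTION_TOL,
    mode: str = "pfba",
) -> InteractionMap:
    """Predict interspecies metabolite exchanges in a community model.

    Runs pFBA on the community biomass, then for every extracellular
    compound computes each species' net transport flux between its cytosol
    and the shared compartment.  A compound is an interaction when one
    species' net secretion and another's net uptake both exceed the
    tolerance; the reported transfer is min(secretion, uptake), so the
    share supplied by the media is never attributed to cross-feeding.

    ``mode="fva"`` additionally classifies each reported exchange as
    ``obligatory`` (transfer persists in every optimal flux state) or
    ``possible``.
    """
    if community.mode == "mixed_bag":
        raise ValueError(
            "interaction extraction requires a compartmentalized community "
            "(a mixed-bag model has no species boundaries)"
        )
    sol = run_fba(community, media, community.community_biomass_id, parsimonious=True)
    if sol.status != "optimal" or sol.objective_value < GROWTH_THRESHOLD:
        raise ValueError(
            f"community {community.id} does not grow on "
            f"{media.name if media else 'current bounds'}; no interactions to extract"
        )
    net = _species_net_secretion(community, sol.fluxes)
    out = InteractionMap()
    for cpd in sorted(net):
        producers = {s: v for s, v in net[cpd].items() if v > tolerance}
        consumers = {s: -v for s, v in net[cpd].items() if v < -tolerance}
        for p, sec in sorted(producers.items()):
            for q, upt in sorted(consumers.items()):
                if p == q:
                    continue
                out.interactions.append(
                    Interaction(cpd, p, q, min(sec, upt))
                )
    if mode == "fva":
        _classify_obligatory(community, media, out, tolerance)
    return out


def _classify_obligatory(community, media, imap: InteractionMap, tolerance):
    """Mark each interaction obligatory/possible by minimizing the producer's
    net secretion at the optimal community objective."""
    model = apply_media(community, media) if media is not None else community
    prob = build_problem(model)
    obj_id = community.community_biomass_id
    status, opt, _ = solve_lp(prob, {obj_id: 1.0}, sense="max")
    if status != "optimal":
        return
    comp_of_species = {
        info["species_id"]: cid for cid, info in community.species_index.items()
    }
    n = prob.n
    row_opt = np.zeros(n)
    row_opt[prob.index(obj_id)] = -1.0
    for inter in imap.interactions:
        comp = comp_of_species[inter.producer]
        objective: dict[str, float] = {}
        for rid, r in model.reactions.items():
            if r.source_tag in ("exchange", "biomass"):
                continue
            comps = {model.metabolites[m].compartment_id for m in r.stoichiometry}
            if comp not in comps:
                continue
            for m, coeff in r.stoichiometry.items():
                met = model.metabolites[m]
                if met.compartment_id == "e0" and met.compound == inter.compound:
                    objective[rid] = objective.get(rid, 0.0) + coeff
        status, min_sec, _ = solve_lp(
            prob,
            objective,
            sense="min",
            extra_A_ub=row_opt.reshape(1, -1),
            extra_b_ub=np.array([-(opt - 1e-9)]),
        )
        inter.mode = (
            "obligatory" if status == "optimal" and min_sec > tolerance else "possible"
        )
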