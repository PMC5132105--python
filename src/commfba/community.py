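"""Merging single-species models into community models.

Two community architectures are supported:

* **mixed-bag** — all species are pooled into one "supra-organism" with a
  single cytosol ``c0``; identical reactions from different members collapse
  into one (gene rules OR-combined, bounds union), and the member biomass
  equations are averaged into a single community biomass.
* **compartmentalized** — each member keeps its own cytosolic compartment
  ``c<i>``; all members share one extracellular compartment ``e0`` through
  which metabolites can be exchanged.  Each member keeps its own biomass
  reaction (producing a ``biomass_sp<i>`` pseudo-metabolite) and a community
  biomass reaction couples them with equal 1/N weights, so the community can
  only grow if every member grows.

Reaction identity for duplicate detection is the canonical (direction
normalized) stoichiometry over compartment-normalized metabolite ids, not
reaction-id equality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import (
    Compartment,
    GeneAssociation,
    MetabolicModel,
    Metabolite,
    Reaction,
    canonical_stoichiometry,
)

COMMUNITY_BIOMASS_ID = "biomass_community"


class CommunityModel(MetabolicModel):
    """A merged multi-species model.

    Attributes beyond :class:`MetabolicModel`:

    ``species_index``
        mapping cytosolic compartment id -> ``{"species_id", "member_model_id"}``
        (mixed-bag maps the single ``c0`` to all members).
    ``member_biomass_ids``
        mapping member model id -> its biomass reaction id in this model.
    ``community_biomass_id``
        the default objective.
    ``n_members``
        number of member models merged.
    ``mode``
        ``"mixed_bag"`` or ``"compartmentalized"``.
    """

    def __init__(self, *args, **kwargs):
        super().__init__(*args, **kwargs)
        self.species_index: dict[str, dict] = {}
        self.member_biomass_ids: dict[str, str] = {}
        self.community_biomass_id: str = COMMUNITY_BIOMASS_ID
        self.n_members: int = 0
        self.mode: str = ""

    @property
    def community_info(self) -> dict:
        return {
            "species": self.species_index,
            "member_biomass_ids": self.member_biomass_ids,
            "community_biomass_id": self.community_biomass_id,
            "n_members": self.n_members,
            "mode": self.mode,
        }

    def copy(self) -> "CommunityModel":
        base = super().copy()
        out = CommunityModel(base.id)
        out.compartments = base.compartments
        out.metabolites = base.metabolites
        out.reactions = base.reactions
        out.biomass_reaction_ids = base.biomass_reaction_ids
        out.species_index = {k: dict(v) for k, v in self.species_index.items()}
        out.member_biomass_ids = dict(self.member_biomass_ids)
        out.community_biomass_id = self.community_biomass_id
        out.n_members = self.n_members
        out.mode = self.mode
        return out


@dataclass
class MergeReport:
    """Bookkeeping of a merge: how many reactions collapsed as duplicates."""

    duplicates_merged: int = 0
    gpr_unions: int = 0
    member_reaction_counts: dict[str, int] = field(default_factory=dict)
    merged_reaction_count: int = 0


def _rehome(met_id: str, old_comp: str, new_comp: str) -> str:
    suffix = "_" + old_comp
    base = met_id[: -len(suffix)] if met_id.endswith(suffix) else met_id
    return f"{base}_{new_comp}"


def merge_biomass(biomass_reactions: list[Reaction], n: int) -> Reaction:
    """Combine member biomass equations into one community biomass.

    Coefficients are summed per metabolite across members and rescaled by
    the number of member models ``n``, so each member contributes its
    precursor demands at 1/n weight.
    """
    if n <= 0:
        raise ValueError("number of member models must be >= 1")
    stoich: dict[str, float] = {}
    for r in biomass_reactions:
        for met, coeff in r.stoichiometry.items():
            stoich[met] = stoich.get(met, 0.0) + coeff
    stoich = {m: c / n for m, c in stoich.items()}
    return Reaction(
        id=COMMUNITY_BIOMASS_ID,
        name="community biomass",
        stoichiometry=stoich,
        lower_bound=0.0,
        upper_bound=max(r.upper_bound for r in biomass_reactions),
        source_tag="biomass",
    )


def _member_parts(member: MetabolicModel):
    """Split a member's compartments into (cytosol id, extracellular id)."""
    cyt = [c.id for c in member.compartments.values() if c.label == "cytosol"]
    if len(cyt) != 1:
        raise ValueError(
            f"member {member.id}: expected exactly one cytosolic compartment, got {cyt}"
        )
    return cyt[0], member.extracellular_compartment


def build_mixed_bag(members: list[MetabolicModel]):
    """Merge members into a single-cytosol "gene soup" community model.

    Returns ``(community, report)``.  Duplicate reactions (identical
    canonical stoichiometry after compartment normalization) collapse into
    one reaction whose gene rule is the OR of the members' rules and whose
    bounds are the union interval; the member biomass reactions are averaged
    by :func:`merge_biomass`.
    """
    if not members:
        raise ValueError("at least one member model is required")
    out = CommunityModel("mb_" + "_".join(m.id for m in members))
    out.mode = "mixed_bag"
    out.n_members = len(members)
    out.compartments = {
        "c0": Compartment("c0", "cytosol", 1),
        "e0": Compartment("e0", "extracellular", 0),
    }
    out.species_index = {
        "c0": {"species_id": "community", "member_model_ids": [m.id for m in members]}
    }
    report = MergeReport()
    by_canon: dict[tuple, Reaction] = {}
    biomasses: list[Reaction] = []

    for member in members:
        cyt, ext = _member_parts(member)
        remap = {}
        for met in member.metabolites.values():
            new_comp = "e0" if met.compartment_id == ext else "c0"
            new_id = _rehome(met.id, met.compartment_id, new_comp)
            remap[met.id] = new_id
            if new_id not in out.metabolites:
                out.metabolites[new_id] = Metabolite(
                    new_id, new_comp, name=met.name, formula=met.formula, charge=met.charge
                )
        report.member_reaction_counts[member.id] = len(member.reactions)
        for r in member.reactions.values():
            stoich = {remap[m]: c for m, c in r.stoichiometry.items()}
            if r.id in member.biomass_reaction_ids:
                bio = r.copy()
                bio.stoichiometry = stoich
                biomasses.append(bio)
                continue
            canon, flip = canonical_stoichiometry(stoich)
            lb, ub = r.lower_bound, r.upper_bound
            if flip == -1:
                lb, ub = -ub, -lb
            if canon in by_canon:
                ex = by_canon[canon]
                ex.lower_bound = min(ex.lower_bound, lb)
                ex.upper_bound = max(ex.upper_bound, ub)
                if not r.gene_association.is_empty():
                    merged_gpr = GeneAssociation.or_join(
                        [ex.gene_association, r.gene_association]
                    )
                    if merged_gpr != ex.gene_association:
                        report.gpr_unions += 1
                    ex.gene_association = merged_gpr
                ex.meta.setdefault("members", []).append(member.id)
                report.duplicates_merged += 1
                continue
            new = r.copy()
            canon_stoich = dict(canon)
            new.stoichiometry = canon_stoich
            new.lower_bound, new.upper_bound = lb, ub
            if new.id in out.reactions:
                new.id = f"{new.id}__{member.id}"
            new.meta["members"] = [member.id]
            new.meta["orig_id"] = r.id
            by_canon[canon] = new
            out.add_reaction(new)

    community_biomass = merge_biomass(biomasses, len(members))
    out.add_reaction(community_biomass)
    out.biomass_reaction_ids = [community_biomass.id]
    out.community_biomass_id = community_biomass.id
    out.member_biomass_ids = {}
    report.merged_reaction_count = len(out.reactions)
    return out, report


def build_compartmentalized(members: list[MetabolicModel]):
    """Merge members keeping one cytosolic compartment per species.

    Species ``i`` (1-based, in member order) occupies compartment ``c<i>``;
    extracellular metabolites merge by compound identity into the shared
    ``e0``, and duplicate exchange reactions collapse.  Each member keeps
    its biomass reaction, now also producing ``biomass_sp<i>_c<i>``; the
    community biomass consumes 1/N of each and is the default objective.
    """
    if len(members) < 2:
        raise ValueError("compartmentalized merge requires >= 2 member models")
    n = len(members)
    out = CommunityModel("cc_" + "_".join(m.id for m in members))
    out.mode = "compartmentalized"
    out.n_members = n
    out.compartments = {"e0": Compartment("e0", "extracellular", 0)}
    report = MergeReport()
    exchange_by_canon: dict[tuple, Reaction] = {}
    coupling: dict[str, float] = {}

    for i, member in enumerate(members, start=1):
        comp = f"c{i}"
        out.compartments[comp] = Compartment(comp, "cytosol", i)
        out.species_index[comp] = {
            "species_id": f"sp{i}",
            "member_model_id": member.id,
        }
        cyt, ext = _member_parts(member)
        remap = {}
        for met in member.metabolites.values():
            new_comp = "e0" if met.compartment_id == ext else comp
            new_id = _rehome(met.id, met.compartment_id, new_comp)
            remap[met.id] = new_id
            if new_id not in out.metabolites:
                out.metabolites[new_id] = Metabolite(
                    new_id, new_comp, name=met.name, formula=met.formula, charge=met.charge
                )
        report.member_reaction_counts[member.id] = len(member.reactions)
        for r in member.reactions.values():
            stoich = {remap[m]: c for m, c in r.stoichiometry.items()}
            if r.source_tag == "exchange":
                canon, flip = canonical_stoichiometry(stoich)
                lb, ub = r.lower_bound, r.upper_bound
                if flip == -1:
                    lb, ub = -ub, -lb
                if canon in exchange_by_canon:
                    ex = exchange_by_canon[canon]
                    ex.meta["member_bounds"][member.id] = (lb, ub)
                    ex.lower_bound = min(ex.lower_bound, lb)
                    ex.upper_bound = max(ex.upper_bound, ub)
                    report.duplicates_merged += 1
                    continue
                new = r.copy()
                new.stoichiometry = dict(canon)
                new.lower_bound, new.upper_bound = lb, ub
                met_id = next(iter(new.stoichiometry))
                compound = out.metabolites[met_id].compound
                new.id = f"EX_{compound}_e0"
                new.meta["member_bounds"] = {member.id: (lb, ub)}
                exchange_by_canon[canon] = new
                out.add_reaction(new)
                continue
            new = r.copy()
            new.stoichiometry = stoich
            new.id = f"{r.id}_{comp}"
            new.meta["member"] = member.id
            new.meta["orig_id"] = r.id
            if r.id in member.biomass_reaction_ids:
                pseudo = f"biomass_sp{i}_{comp}"
                out.metabolites[pseudo] = Metabolite(pseudo, comp, formula=None)
                new.stoichiometry[pseudo] = new.stoichiometry.get(pseudo, 0.0) + 1.0
                out.member_biomass_ids[member.id] = new.id
                coupling[pseudo] = -1.0 / n
            out.add_reaction(new)

    # community biomass couples the members at equal 1/N weight
    bc_met = f"{COMMUNITY_BIOMASS_ID}_e0"
    out.metabolites[bc_met] = Metabolite(bc_met, "e0", formula=None)
    coupling[bc_met] = 1.0
    out.add_reaction(
        Reaction(
            id=COMMUNITY_BIOMASS_ID,
            name="community biomass",
            stoichiometry=coupling,
            lower_bound=0.0,
            upper_bound=1000.0,
            source_tag="biomass",
        )
    )
    out.add_reaction(
        Reaction(
            id=f"EX_{COMMUNITY_BIOMASS_ID}_e0",
            stoichiometry={bc_met: -1.0},
            lower_bound=0.0,
            upper_bound=1000.0,
            source_tag="exchange",
        )
    )
    out.biomass_reaction_ids = [COMMUNITY_BIOMASS_ID]
    out.community_biomass_id = COMMUNITY_BIOMASS_ID
    report.merged_reaction_count = len(out.reactions)
    return out, report


def extract_member(community: CommunityModel, member_model_id: str) -> MetabolicModel:
    """Recover a member model from a compartmentalized community.

    Returns the member's reactions (original ids and bounds), its cytosol
    re-labelled ``c1`` and its extracellular metabolites under ``e0`` —
    the inverse of :func:`build_compartmentalized` up to id suffixing.
    Gapfilled reactions added to the member's compartment are included.
    """
    if community.mode != "compartmentalized":
        raise ValueError("member extraction requires a compartmentalized community")
    comp = None
    for cid, info in community.species_index.items():
        if info.get("member_model_id") == member_model_id:
            comp = cid
    if comp is None:
        raise KeyError(f"no member model {member_model_id!r} in community")

    out = MetabolicModel(
        member_model_id,
        [Compartment("c1", "cytosol", 1), Compartment("e0", "extracellular", 0)],
    )

    def remap(met_id: str) -> str:
        met = community.metabolites[met_id]
        if met.compartment_id == comp:
            return _rehome(met_id, comp, "c1")
        return met_id

    sp = community.species_index[comp]["species_id"]
    pseudo = f"biomass_{sp}_{comp}"
    for r in community.reactions.values():
        mets = set(r.stoichiometry)
        if r.meta.get("member") == member_model_id:
            new = r.copy()
            new.id = r.meta.get("orig_id", r.id)
            new.stoichiometry = {remap(m): c for m, c in r.stoichiometry.items()}
            # strip the community-coupling pseudo-metabolite from the biomass
            new.stoichiometry.pop(f"biomass_{sp}_c1", None)
            new.stoichiometry.pop(pseudo, None)
            out.add_reaction(new)
            if r.id in community.member_biomass_ids.values():
                out.biomass_reaction_ids.append(new.id)
        elif r.source_tag == "exchange" and "member_bounds" in r.meta:
            if member_model_id in r.meta["member_bounds"]:
                new = r.copy()
                lb, ub = r.meta["member_bounds"][member_model_id]
                new.lower_bound, new.upper_bound = lb, ub
                new.meta = {}
                out.add_reaction(new)
        elif r.source_tag == "gapfilled" and mets and all(
            community.metabolites[m].compartment_id in (comp, "e0") for m in mets
        ):
            new = r.copy()
            new.stoichiometry = {remap(m): c for m, c in r.stoichiometry.items()}
            out.add_reaction(new)
    for r in out.reactions.values():
        for m in r.stoichiometry:
            if m not in out.metabolites:
                src = community.metabolites.get(m)
                if src is None:  # re-homed cytosolic metabolite
                    orig = m[: -len("_c1")] + f"_{comp}"
                    src = community.metabolites[orig]
                comp_id = "c1" if src.compartment_id == comp else "e0"
                out.metabolites[m] = Metabolite(
                    m, comp_id, name=src.name, formula=src.formula, charge=src.charge
                )
    return out
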