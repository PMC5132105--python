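"""Core data model for constraint-based metabolic networks.

A :class:`MetabolicModel` is a plain in-memory network: compartments,
metabolites, reactions (with flux bounds and gene associations), and one or
more biomass reactions.  Flux units are mmol·gDW⁻¹·h⁻¹ throughout.

Conventions
-----------
* Compartment ids: ``c<i>`` is the cytosol of species ``i`` (``i >= 1``),
  ``e0`` the single shared extracellular compartment, ``c0`` the merged
  cytosol of a mixed-bag community model.
* Metabolite ids carry their compartment as a suffix: ``glc_c1``, ``o2_e0``.
* Exchange reactions are written in export orientation
  (``compound_e0 -> ∅``); uptake is negative flux.
* Default bounds: reversible (-100, 100), irreversible (0, 100).
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

DEFAULT_BOUND = 100.0

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

# source_tag vocabulary for reactions
SOURCE_TAGS = ("draft", "gapfilled", "exchange", "biomass", "transport")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula like ``C6H12O6`` into ``{element: count}``.

    The empty string parses to ``{}`` (a massless species such as a photon
    or an abstract energy token).  Raises ``ValueError`` on malformed input.
    """
    if formula is None:
        raise ValueError("formula is None")
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"malformed formula {formula!r}")
        pos = m.end()
        n = int(m.group(2)) if m.group(2) else 1
        counts[m.group(1)] = counts.get(m.group(1), 0) + n
    if pos != len(formula):
        raise ValueError(f"malformed formula {formula!r}")
    return counts


# ---------------------------------------------------------------------------
# Gene associations (GPR rules)
# ---------------------------------------------------------------------------

class GeneAssociation:
    """Boolean expression tree over gene ids with AND/OR internal nodes.

    The tree is stored as nested lists: a leaf is a gene-id string, an
    internal node is ``["and", child, ...]`` or ``["or", child, ...]``.
    ``None`` tree means no gene is associated (spontaneous / gapfilled /
    boundary reaction).
    """

    __slots__ = ("tree",)

    def __init__(self, tree=None):
        self.tree = _normalize_gpr(tree)

    @classmethod
    def from_string(cls, rule: str) -> "GeneAssociation":
        """Parse a rule like ``"g1 and (g2 or g3)"`` (case-insensitive)."""
        rule = (rule or "").strip()
        if not rule:
            return cls(None)
        return cls(_parse_gpr_string(rule))

    def is_empty(self) -> bool:
        return self.tree is None

    def genes(self) -> set[str]:
        out: set[str] = set()
        _collect_genes(self.tree, out)
        return out

    def evaluate(self, calls: Mapping[str, str]) -> str:
        """Three-valued evaluation against per-gene ``on``/``off``/``unknown``.

        Returns ``"active"``, ``"inactive"`` or ``"unknown"``.  Empty rules
        evaluate to ``"unknown"``.
        """
        if self.tree is None:
            return "unknown"
        val = _eval3(self.tree, calls)
        return {"on": "active", "off": "inactive", "unknown": "unknown"}[val]

    def to_string(self) -> str:
        return _gpr_to_string(self.tree)

    @staticmethod
    def or_join(assocs: Iterable["GeneAssociation"]) -> "GeneAssociation":
        """OR-combine several associations (duplicate-reaction merging)."""
        parts = [a.tree for a in assocs if a.tree is not None]
        if not parts:
            return GeneAssociation(None)
        if len(parts) == 1:
            return GeneAssociation(parts[0])
        return GeneAssociation(["or", *parts])

    def __eq__(self, other):
        return isinstance(other, GeneAssociation) and self.tree == other.tree

    def __repr__(self):
        return f"GeneAssociation({self.to_string()!r})"


def _normalize_gpr(tree):
    if tree is None:
        return None
    if isinstance(tree, str):
        return tree
    op = tree[0].lower()
    if op not in ("and", "or"):
        raise ValueError(f"bad GPR operator {tree[0]!r}")
    children = [_normalize_gpr(c) for c in tree[1:]]
    if not children:
        raise ValueError("empty GPR operator node")
    # flatten nested same-operator nodes and deduplicate leaves
    flat = []
    for c in children:
        if isinstance(c, list) and c[0] == op:
            flat.extend(c[1:])
        else:
            flat.append(c)
    dedup = []
    for c in flat:
        if c not in dedup:
            dedup.append(c)
    if len(dedup) == 1:
        return dedup[0]
    return [op, *dedup]


def _collect_genes(tree, out: set[str]):
    if tree is None:
        return
    if isinstance(tree, str):
        out.add(tree)
        return
    for c in tree[1:]:
        _collect_genes(c, out)


def _eval3(tree, calls: Mapping[str, str]) -> str:
    if isinstance(tree, str):
        return calls.get(tree, "unknown")
    vals = [_eval3(c, calls) for c in tree[1:]]
    if tree[0] == "or":
        if "on" in vals:
            return "on"
        if "unknown" in vals:
            return "unknown"
        return "off"
    # and
    if "off" in vals:
        return "off"
    if "unknown" in vals:
        return "unknown"
    return "on"


def _gpr_to_string(tree, parent_op=None) -> str:
    if tree is None:
        return ""
    if isinstance(tree, str):
        return tree
    op = tree[0]
    inner = f" {op} ".join(_gpr_to_string(c, op) for c in tree[1:])
    if parent_op is not None and parent_op != op:
        return f"({inner})"
    return inner


_GPR_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def _parse_gpr_string(rule: str):
    tokens = _GPR_TOKEN.findall(rule)
    pos = 0

    def parse_or():
        nonlocal pos
        terms = [parse_and()]
        while pos < len(tokens) and tokens[pos].lower() == "or":
            pos += 1
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else ["or", *terms]

    def parse_and():
        nonlocal pos
        terms = [parse_atom()]
        while pos < len(tokens) and tokens[pos].lower() == "and":
            pos += 1
            terms.append(parse_atom())
        return terms[0] if len(terms) == 1 else ["and", *terms]

    def parse_atom():
        nonlocal pos
        if pos >= len(tokens):
            raise ValueError(f"truncated GPR rule {rule!r}")
        tok = tokens[pos]
        if tok == "(":
            pos += 1
            node = parse_or()
            if pos >= len(tokens) or tokens[pos] != ")":
                raise ValueError(f"unbalanced parentheses in GPR {rule!r}")
            pos += 1
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise ValueError(f"unexpected token {tok!r} in GPR {rule!r}")
        pos += 1
        return tok

    node = parse_or()
    if pos != len(tokens):
        raise ValueError(f"trailing tokens in GPR {rule!r}")
    return node


# ---------------------------------------------------------------------------
# Network entities
# ---------------------------------------------------------------------------

@dataclass
class Compartment:
    id: str
    label: str  # "cytosol" | "extracellular" | "biomass"
    species_index: int = 0  # 0 = shared/extracellular


@dataclass
class Metabolite:
    id: str
    compartment_id: str
    name: str = ""
    formula: str | None = None  # elemental composition; "" = massless
    charge: int | None = None

    @property
    def compound(self) -> str:
        """Compartment-free compound identity (id with suffix stripped)."""
        suffix = "_" + self.compartment_id
        if self.id.endswith(suffix):
            return self.id[: -len(suffix)]
        return self.id


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]  # metabolite id -> coefficient (<0 consumed)
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    name: str = ""
    gene_association: GeneAssociation = field(default_factory=GeneAssociation)
    pathway: str | None = None
    source_tag: str = "draft"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        # canonical form: drop zero coefficients (needed for identity hashing)
        self.stoichiometry = {
            m: float(c) for m, c in self.stoichiometry.items() if c != 0
        }

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def copy(self) -> "Reaction":
        r = replace(self)
        r.stoichiometry = dict(self.stoichiometry)
        r.gene_association = GeneAssociation(copy.deepcopy(self.gene_association.tree))
        r.meta = copy.deepcopy(self.meta)
        return r


def canonical_stoichiometry(
    stoich: Mapping[str, float],
) -> tuple[tuple[tuple[str, float], ...], int]:
    """Direction-normalized canonical form for duplicate detection.

    The reaction is oriented so that the lexicographically smallest
    participating metabolite id has a negative coefficient; returns the
    sorted coefficient tuple plus the sign flip applied (+1 or -1).
    """
    items = sorted(stoich.items())
    if not items:
        return (), 1
    flip = 1 if items[0][1] < 0 else -1
    return tuple((m, flip * c) for m, c in items), flip


@dataclass
class MediaCondition:
    """Growth environment: allowed extracellular compounds with flux limits.

    ``entries`` maps a compartment-free compound id (e.g. ``"glc"``) to
    ``(max_uptake, max_excretion)``, both nonnegative.
    """

    name: str
    entries: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        for cpd, (up, ex) in self.entries.items():
            if up < 0 or ex < 0:
                raise ValueError(f"negative media limit for {cpd}")


@dataclass
class DatabaseReaction:
    """Candidate reaction template, unbound to a specific model compartment.

    Stoichiometry is written over compound ids with role suffixes ``_c``
    (cytosolic) and ``_e`` (extracellular); instantiation substitutes the
    target compartment (and ``e0``).
    """

    id: str
    stoichiometry: dict[str, float]
    reversible: bool = False
    name: str = ""
    pathway: str | None = None
    cost_forward: float = 1.0
    cost_backward: float = 1.0

    def __post_init__(self):
        if self.cost_forward <= 0 or (self.reversible and self.cost_backward <= 0):
            raise ValueError(f"database reaction {self.id}: costs must be > 0")


@dataclass
class ReactionDatabase:
    reactions: list[DatabaseReaction] = field(default_factory=list)
    # compounds for which per-species transporter templates are generated
    transportable_compounds: dict[str, str] = field(default_factory=dict)  # compound -> formula

    def __len__(self):
        return len(self.reactions)


class MetabolicModel:
    """A genome-scale (or toy) metabolic network."""

    def __init__(
        self,
        id: str,
        compartments: Iterable[Compartment] = (),
        metabolites: Iterable[Metabolite] = (),
        reactions: Iterable[Reaction] = (),
        biomass_reaction_ids: Iterable[str] = (),
    ):
        self.id = id
        self.compartments: dict[str, Compartment] = {c.id: c for c in compartments}
        self.metabolites: dict[str, Metabolite] = {m.id: m for m in metabolites}
        self.reactions: dict[str, Reaction] = {r.id: r for r in reactions}
        self.biomass_reaction_ids: list[str] = list(biomass_reaction_ids)

    # -- basic accessors ---------------------------------------------------
    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for r in self.reactions.values():
            out |= r.gene_association.genes()
        return out

    @property
    def extracellular_compartment(self) -> str:
        for c in self.compartments.values():
            if c.label == "extracellular":
                return c.id
        raise ValueError(f"model {self.id}: no extracellular compartment")

    def extracellular_metabolites(self) -> list[Metabolite]:
        e = self.extracellular_compartment
        return [m for m in self.metabolites.values() if m.compartment_id == e]

    def exchange_reaction_for(self, compound: str) -> str | None:
        """Id of the exchange reaction exporting ``compound`` if present."""
        e = self.extracellular_compartment
        met = f"{compound}_{e}"
        for r in self.reactions.values():
            if r.source_tag == "exchange" and r.stoichiometry.get(met) is not None:
                if set(r.stoichiometry) == {met}:
                    return r.id
        return None

    def add_reaction(self, reaction: Reaction):
        if reaction.id in self.reactions:
            raise ValueError(f"duplicate reaction id {reaction.id}")
        self.reactions[reaction.id] = reaction

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            self.id,
            [replace(c) for c in self.compartments.values()],
            [replace(m) for m in self.metabolites.values()],
            [r.copy() for r in self.reactions.values()],
            list(self.biomass_reaction_ids),
        )

    def __repr__(self):
        return (
            f"<MetabolicModel {self.id}: {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions, {len(self.genes)} genes>"
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def validate_model(model: MetabolicModel) -> list[str]:
    """Check every structural invariant; return human-readable violations.

    An empty list means the model is well-formed.  Violations are returned
    (never raised) so callers can report them all at once.
    """
    problems: list[str] = []
    n_extra = sum(1 for c in model.compartments.values() if c.label == "extracellular")
    if n_extra != 1:
        problems.append(
            f"model {model.id}: expected exactly one extracellular compartment, found {n_extra}"
        )
    for m in model.metabolites.values():
        if m.compartment_id not in model.compartments:
            problems.append(
                f"metabolite {m.id}: unknown compartment {m.compartment_id}"
            )
        if m.formula is not None:
            try:
                parse_formula(m.formula)
            except ValueError:
                problems.append(f"metabolite {m.id}: malformed formula {m.formula!r}")
    extra = {
        m.id
        for m in model.metabolites.values()
        if model.compartments.get(m.compartment_id, Compartment("", "")).label
        == "extracellular"
    }
    for r in model.reactions.values():
        if r.lower_bound > r.upper_bound:
            problems.append(
                f"reaction {r.id}: lower_bound {r.lower_bound} > upper_bound {r.upper_bound}"
            )
        if not r.stoichiometry:
            problems.append(f"reaction {r.id}: empty stoichiometry")
        for met in r.stoichiometry:
            if met not in model.metabolites:
                problems.append(f"reaction {r.id}: references missing metabolite {met}")
        if r.source_tag not in SOURCE_TAGS:
            problems.append(f"reaction {r.id}: unknown source_tag {r.source_tag!r}")
        mets = set(r.stoichiometry)
        only_extracellular = bool(mets) and mets <= extra
        if r.source_tag == "exchange" and not only_extracellular:
            problems.append(
                f"reaction {r.id}: tagged exchange but involves intracellular metabolites"
            )
        if only_extracellular and r.source_tag not in ("exchange", "biomass"):
            problems.append(
                f"reaction {r.id}: involves only extracellular metabolites but is not tagged exchange"
            )
    for b in model.biomass_reaction_ids:
        if b not in model.reactions:
            problems.append(f"biomass reaction {b} not present in model")
    if not model.biomass_reaction_ids:
        problems.append(f"model {model.id}: no biomass reaction declared")
    return problems


def apply_media(
    model: MetabolicModel,
    media: MediaCondition,
    create_missing: bool = True,
) -> MetabolicModel:
    """Return a copy of ``model`` with exchange bounds set from ``media``.

    Every exchange reaction is written in export orientation, so a compound
    allowed for uptake gets ``lower_bound = -max_uptake`` and
    ``upper_bound = +max_excretion``.  Exchanges for compounds absent from
    the media are closed for uptake (``lower_bound = 0``); their excretion
    bound is left open.  Idempotent; the input model is not modified.

    If ``create_missing`` is true, a compound named in the media with no
    extracellular metabolite gets one (massless formula unknown -> None)
    plus an exchange reaction; otherwise that situation is an error.
    """
    out = model.copy()
    e = out.extracellular_compartment
    exchange_by_compound: dict[str, Reaction] = {}
    for r in out.reactions.values():
        if r.source_tag != "exchange":
            continue
        mets = list(r.stoichiometry)
        if len(mets) == 1:
            met = out.metabolites[mets[0]]
            exchange_by_compound[met.compound] = r

    for compound, (up, ex) in media.entries.items():
        rxn = exchange_by_compound.get(compound)
        if rxn is None:
            met_id = f"{compound}_{e}"
            if met_id not in out.metabolites:
                if not create_missing:
                    raise KeyError(
                        f"media {media.name}: compound {compound!r} has no "
                        f"extracellular metabolite in model {model.id}"
                    )
                out.metabolites[met_id] = Metabolite(met_id, e)
            rxn = Reaction(
                id=f"EX_{met_id}",
                stoichiometry={met_id: -1.0},
                lower_bound=0.0,
                upper_bound=DEFAULT_BOUND,
                source_tag="exchange",
            )
            out.add_reaction(rxn)
            exchange_by_compound[compound] = rxn
        rxn.lower_bound = -float(up)
        rxn.upper_bound = float(ex)

    for compound, rxn in exchange_by_compound.items():
        if compound not in media.entries:
            rxn.lower_bound = 0.0
    return out


def ensure_exchanges(model: MetabolicModel) -> MetabolicModel:
    """Return a copy with an export-oriented exchange for every
    extracellular metabolite that lacks one (bounds (0, +100): free excretion,
    no uptake until a media grants it)."""
    out = model.copy()
    for met in list(out.extracellular_metabolites()):
        if out.exchange_reaction_for(met.compound) is None:
            out.add_reaction(
                Reaction(
                    id=f"EX_{met.id}",
                    stoichiometry={met.id: -1.0},
                    lower_bound=0.0,
                    upper_bound=DEFAULT_BOUND,
                    source_tag="exchange",
                )
            )
    return out


EXEMPT = "exempt"


def elemental_balance(reaction: Reaction, model: MetabolicModel):
    """Net elemental balance of a reaction: ``{element: Σ coeff × count}``.

    An all-zero mapping (here: ``{}`` after dropping zeros) means balanced.
    Exchange and biomass reactions are exempt by convention and return the
    marker string ``"exempt"``.  A participating metabolite without a
    formula raises ``ValueError`` naming it.
    """
    if reaction.source_tag in ("exchange", "biomass"):
        return EXEMPT
    totals: dict[str, float] = {}
    for met_id, coeff in reaction.stoichiometry.items():
        met = model.metabolites[met_id]
        if met.formula is None:
            raise ValueError(
                f"reaction {reaction.id}: metabolite {met_id} has no formula"
            )
        for el, n in parse_formula(met.formula).items():
            totals[el] = totals.get(el, 0.0) + coeff * n
    return {el: v for el, v in totals.items() if abs(v) > 1e-9}
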