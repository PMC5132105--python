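"""Synthetic phototroph–heterotroph consortium fixtures.

Generates a toy model of a thermophilic mat community: a photoautotrophic
cyanobacterium (fixes CO₂ and nitrate, evolves O₂, can leak sugar and
ammonia) and an obligate aerobic heterotroph that cannot assimilate nitrate
and, by default, cannot synthesize its vitamin cofactor — so on autotrophic
media it strictly depends on phototroph-derived organic carbon, fixed
nitrogen, vitamins, and O₂.

All internal reactions are elementally balanced over real formulas at a
CH₂O level of abstraction; photons and the abstract energy token are
massless.  Biomass reactions are pure precursor drains.  Everything is
deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fba import run_fba
from .model import (
    Compartment,
    DatabaseReaction,
    GeneAssociation,
    MediaCondition,
    MetabolicModel,
    Metabolite,
    Reaction,
    ReactionDatabase,
)

# compound -> elemental formula ("" = massless)
FORMULAS = {
    "photon": "",
    "nrg": "",       # abstract energy token (ATP equivalent)
    "red": "H",      # reducing equivalent
    "co2": "CO2",
    "h2o": "H2O",
    "o2": "O2",
    "no3": "HNO3",
    "nh3": "NH3",
    "glc": "C6H12O6",
    "aa": "C3H7NO2",
    "vitp1": "C6H10O5",
    "vitp2": "C6H13NO5",
    "vit": "C6H13NO5",
    "dxa": "C2H4O2",
    "dxb": "C2H4O2",
    "dxc": "C4H8O4",
    "dxd": "C4H10O5",
}

# pathway label -> heterotroph reaction ids removable via FixtureSpec.deleted
HETEROTROPH_PATHWAYS = {
    "vitamin_synthesis": ["VITSYN1", "VITSYN2", "VITSYN3"],
    "nitrate_assimilation": ["T_no3", "NRED"],
    "aa_synthesis": ["AASYN"],
    "glucose_transport": ["T_glc"],
}


@dataclass
class FixtureSpec:
    """Knobs of the synthetic consortium.

    Defaults encode the study conditions: the heterotroph lacks nitrate
    assimilation and the (3-step) vitamin pathway; the phototroph leaks
    sugar and ammonia through native transporters.
    """

    seed: int = 42
    heterotroph_deleted: tuple[str, ...] = ("vitamin_synthesis", "nitrate_assimilation")
    phototroph_secreted: tuple[str, ...] = ("glc", "nh3")
    noise: float = 1.0  # log-scale SD of expression bands (0 = separated)
    active_fraction: float | None = None  # None -> flux-consistent active set


def _met(compound: str, comp: str) -> Metabolite:
    return Metabolite(f"{compound}_{comp}", comp, name=compound, formula=FORMULAS.get(compound))


def _add_compound(model: MetabolicModel, compound: str, comp: str) -> str:
    mid = f"{compound}_{comp}"
    if mid not in model.metabolites:
        model.metabolites[mid] = _met(compound, comp)
    return mid


def _reaction(model, rid, stoich_compounds, comp_map, lb, ub, gene=None,
              pathway=None, tag="draft"):
    """Add a reaction given compound-level stoichiometry and a compartment map."""
    stoich = {}
    for cpd, coeff in stoich_compounds.items():
        comp = comp_map[cpd]
        stoich[_add_compound(model, cpd, comp)] = coeff
    model.add_reaction(
        Reaction(
            id=rid,
            stoichiometry=stoich,
            lower_bound=lb,
            upper_bound=ub,
            gene_association=GeneAssociation(gene) if gene else GeneAssociation(),
            pathway=pathway,
            source_tag=tag,
        )
    )


def _add_exchange(model: MetabolicModel, compound: str):
    mid = _add_compound(model, compound, "e0")
    model.add_reaction(
        Reaction(
            id=f"EX_{mid}",
            stoichiometry={mid: -1.0},
            lower_bound=0.0,
            upper_bound=100.0,
            source_tag="exchange",
        )
    )


# core enzymatic chemistry shared by models and the candidate database;
# written over compound ids, compartment decided at instantiation
CORE_REACTIONS = {
    "LIGHT": ({"photon": -1, "h2o": -2, "o2": 1, "red": 4, "nrg": 4}, "photosynthesis"),
    "CFIX": ({"co2": -6, "red": -24, "nrg": -6, "glc": 1, "h2o": 6}, "carbon fixation"),
    "NRED": ({"no3": -1, "red": -8, "nh3": 1, "h2o": 3}, "nitrogen assimilation"),
    "AASYN": ({"glc": -1, "nh3": -2, "aa": 2, "h2o": 2}, "amino acid biosynthesis"),
    "VITSYN1": ({"glc": -1, "vitp1": 1, "h2o": 1}, "vitamin biosynthesis"),
    "VITSYN2": ({"vitp1": -1, "nh3": -1, "vitp2": 1}, "vitamin biosynthesis"),
    "VITSYN3": ({"vitp2": -1, "nrg": -1, "vit": 1}, "vitamin biosynthesis"),
    "RESP": ({"glc": -1, "o2": -6, "co2": 6, "h2o": 6, "nrg": 30}, "respiration"),
    # futile energy dissipation (maintenance): photosynthesis and
    # respiration produce energy in fixed ratios, so excess must be burnable
    "NRG_DISS": ({"nrg": -1}, "energy metabolism"),
    "DIST1": ({"dxa": -1, "dxb": 1}, "distractor"),
    "DIST2": ({"dxb": -2, "dxc": 1}, "distractor"),
    "DIST3": ({"dxc": -1, "h2o": -1, "dxd": 1}, "distractor"),
}


def make_toy_phototroph(spec: FixtureSpec | None = None) -> MetabolicModel:
    """~15-reaction photoautotroph: photon/CO₂/NO₃ uptake, carbon fixation,
    nitrate reduction, O₂ evolution, full amino-acid and vitamin synthesis;
    grows on autotrophic media."""
    spec = spec or FixtureSpec()
    m = MetabolicModel(
        "toy_phototroph",
        [Compartment("c1", "cytosol", 1), Compartment("e0", "extracellular", 0)],
    )
    cyt = {cpd: "c1" for cpd in FORMULAS}
    for rid in ("LIGHT", "CFIX", "NRED", "AASYN", "VITSYN1", "VITSYN2", "VITSYN3"):
        stoich, pw = CORE_REACTIONS[rid]
        _reaction(m, rid, stoich, cyt, 0, 100, gene=f"pho_{rid.lower()}", pathway=pw)
    _reaction(m, "NRG_DISS", CORE_REACTIONS["NRG_DISS"][0], cyt, 0, 1000,
              pathway="energy metabolism")
    transports = {
        "T_photon": ("photon", 0, 100, -1),   # import only
        "T_co2": ("co2", -100, 100, -1),
        "T_h2o": ("h2o", -100, 100, -1),
        "T_o2": ("o2", -100, 100, +1),        # written as export
        "T_no3": ("no3", 0, 100, -1),
    }
    for cpd in spec.phototroph_secreted:
        transports[f"T_{cpd}"] = (cpd, -100, 100, +1)
    for rid, (cpd, lb, ub, orient) in transports.items():
        # orient -1: e0 -> c1 (import orientation), +1: c1 -> e0
        stoich = (
            {f"{cpd}_e0": -1.0, f"{cpd}_c1": 1.0}
            if orient == -1
            else {f"{cpd}_c1": -1.0, f"{cpd}_e0": 1.0}
        )
        for mid in stoich:
            comp = mid.rsplit("_", 1)[1]
            _add_compound(m, cpd, comp)
        m.add_reaction(
            Reaction(rid, stoich, lb, ub,
                     gene_association=GeneAssociation(f"pho_t{cpd}"),
                     pathway="transport", source_tag="transport")
        )
    _reaction(
        m, "BIOMASS_pho",
        {"glc": -0.5, "aa": -1.0, "vit": -0.1, "nrg": -2.0},
        cyt, 0, 100, pathway="biomass", tag="biomass",
    )
    m.biomass_reaction_ids = ["BIOMASS_pho"]
    for met in list(m.extracellular_metabolites()):
        _maybe_exchange(m, met.compound)
    return m


def make_toy_heterotroph(spec: FixtureSpec | None = None) -> MetabolicModel:
    """~12-reaction obligate aerobic heterotroph (glucose + ammonia + O₂).

    Pathways named in ``spec.heterotroph_deleted`` are absent; with the
    default deletions the draft cannot make its vitamin cofactor anywhere
    (vitamin auxotroph) and never assimilates nitrate, so it cannot grow on
    autotrophic media.
    """
    spec = spec or FixtureSpec()
    m = MetabolicModel(
        "toy_heterotroph",
        [Compartment("c1", "cytosol", 1), Compartment("e0", "extracellular", 0)],
    )
    cyt = {cpd: "c1" for cpd in FORMULAS}
    deleted_rxns = set()
    for pw in spec.heterotroph_deleted:
        deleted_rxns.update(HETEROTROPH_PATHWAYS[pw])
    enzymatic = ["RESP", "AASYN", "VITSYN1", "VITSYN2", "VITSYN3", "NRED"]
    for rid in enzymatic:
        if rid in deleted_rxns:
            continue
        stoich, pw = CORE_REACTIONS[rid]
        _reaction(m, rid, stoich, cyt, 0, 100, gene=f"het_{rid.lower()}", pathway=pw)
    _reaction(m, "NRG_DISS", CORE_REACTIONS["NRG_DISS"][0], cyt, 0, 1000,
              pathway="energy metabolism")
    transports = {
        "T_glc": ("glc", 0, 100, -1),
        "T_o2": ("o2", -100, 100, -1),
        "T_nh3": ("nh3", -100, 100, -1),
        "T_co2": ("co2", -100, 100, +1),
        "T_h2o": ("h2o", -100, 100, -1),
        "T_aa": ("aa", 0, 100, -1),
        "T_no3": ("no3", 0, 100, -1),
    }
    for rid, (cpd, lb, ub, orient) in transports.items():
        if rid in deleted_rxns:
            continue
        stoich = (
            {f"{cpd}_e0": -1.0, f"{cpd}_c1": 1.0}
            if orient == -1
            else {f"{cpd}_c1": -1.0, f"{cpd}_e0": 1.0}
        )
        for mid in stoich:
            _add_compound(m, cpd, mid.rsplit("_", 1)[1])
        m.add_reaction(
            Reaction(rid, stoich, lb, ub,
                     gene_association=GeneAssociation(f"het_t{cpd}"),
                     pathway="transport", source_tag="transport")
        )
    _reaction(
        m, "BIOMASS_het",
        {"glc": -0.5, "aa": -1.0, "vit": -0.1, "nrg": -10.0},
        cyt, 0, 100, pathway="biomass", tag="biomass",
    )
    m.biomass_reaction_ids = ["BIOMASS_het"]
    for met in list(m.extracellular_metabolites()):
        _maybe_exchange(m, met.compound)
    return m


def _maybe_exchange(model: MetabolicModel, compound: str):
    if model.exchange_reaction_for(compound) is None:
        _add_exchange(model, compound)


# ---------------------------------------------------------------------------
# Media
# ---------------------------------------------------------------------------

def make_autotrophic_media() -> MediaCondition:
    """Light, CO₂, nitrate, water; no organic carbon, no fixed N, no O₂ supply."""
    return MediaCondition(
        "autotrophic",
        {
            "photon": (100.0, 0.0),
            "co2": (50.0, 100.0),
            "no3": (20.0, 100.0),
            "h2o": (100.0, 100.0),
            "o2": (0.0, 100.0),
        },
    )


def make_glucose_minimal_media() -> MediaCondition:
    return MediaCondition(
        "glucose_minimal",
        {
            "glc": (10.0, 0.0),
            "nh3": (10.0, 100.0),
            "o2": (20.0, 100.0),
            "co2": (0.0, 100.0),
            "h2o": (100.0, 100.0),
        },
    )


def make_rich_media() -> MediaCondition:
    """Everything on offer (LB-like), including light for phototrophs."""
    return MediaCondition(
        "rich",
        {
            "glc": (10.0, 0.0),
            "nh3": (10.0, 100.0),
            "aa": (10.0, 100.0),
            "vit": (1.0, 100.0),
            "o2": (20.0, 100.0),
            "no3": (10.0, 100.0),
            "photon": (100.0, 0.0),
            "co2": (50.0, 100.0),
            "h2o": (100.0, 100.0),
        },
    )


# ---------------------------------------------------------------------------
# Candidate reaction database
# ---------------------------------------------------------------------------

def make_toy_database(spec: FixtureSpec | None = None) -> ReactionDatabase:
    """Candidate database: the heterotroph's missing pathways, a full
    autotrophy alternative, transporter templates, and three distractors.

    Cytosolic templates use role suffixes ``_c``/``_e``; 10 enzymatic
    candidates plus 5 transportable compounds, so single-model gapfilling
    instantiates at most 15 directed cytosolic candidates and stays inside
    the brute-force oracle's reach.
    """
    spec = spec or FixtureSpec()
    reactions = []
    for rid in ("LIGHT", "CFIX", "NRED", "AASYN", "VITSYN1", "VITSYN2",
                "VITSYN3", "RESP", "DIST1", "DIST2", "DIST3"):
        stoich, pw = CORE_REACTIONS[rid]
        reactions.append(
            DatabaseReaction(
                id=f"db_{rid}",
                stoichiometry={f"{cpd}_c": c for cpd, c in stoich.items()},
                reversible=False,
                pathway=pw,
            )
        )
    transportable = {
        cpd: FORMULAS[cpd] for cpd in ("glc", "nh3", "vit", "photon", "no3")
    }
    return ReactionDatabase(reactions=reactions, transportable_compounds=transportable)


# ---------------------------------------------------------------------------
# Synthetic expression profiles
# ---------------------------------------------------------------------------

@dataclass
class SyntheticExpression:
    values: dict[str, float]
    universal_role_genes: list[str]
    active_genes: set[str] = field(default_factory=set)
    inactive_genes: set[str] = field(default_factory=set)


def make_expression_profile(
    model: MetabolicModel,
    spec: FixtureSpec | None = None,
    media: MediaCondition | None = None,
    n_universal: int = 12,
    delta: float = 1e-3,
) -> SyntheticExpression:
    """Synthetic RNA-seq-like expression table for ``model``'s genes.

    The designated "truly active" gene set is flux-consistent: genes whose
    reactions carry flux in a pFBA solution on ``media`` (unless
    ``spec.active_fraction`` overrides with a random subset).  Active genes
    draw from a high log-normal band, inactive from a low band;
    ``spec.noise`` is the log-scale SD controlling band overlap.  Universal
    housekeeping genes (translation/transcription stand-ins, not part of
    the metabolic network) draw from a slightly lower active band, so the
    10th-percentile threshold rule sits below nearly all active genes.
    """
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    genes = sorted(model.genes)
    if not genes:
        raise ValueError(f"model {model.id} has no genes")

    if spec.active_fraction is not None:
        k = max(1, int(round(spec.active_fraction * len(genes))))
        active = set(rng.choice(genes, size=k, replace=False).tolist())
    else:
        if media is None:
            raise ValueError("media required to designate a flux-consistent active set")
        sol = run_fba(model, media, parsimonious=True)
        if sol.status != "optimal" or sol.objective_value < 1e-6:
            raise ValueError(
                f"model {model.id} does not grow on {media.name}; cannot "
                "designate a flux-consistent active set"
            )
        active = set()
        for rid, r in model.reactions.items():
            if abs(sol.fluxes.get(rid, 0.0)) >= delta:
                active |= r.gene_association.genes()

    mu_active, mu_universal, mu_inactive = np.log(400.0), np.log(150.0), np.log(2.0)
    sigma = float(spec.noise)
    values: dict[str, float] = {}
    for g in genes:
        mu = mu_active if g in active else mu_inactive
        values[g] = float(np.exp(mu + sigma * rng.standard_normal()))
    universal = [f"uni_g{i:02d}" for i in range(1, n_universal + 1)]
    for g in universal:
        values[g] = float(np.exp(mu_universal + sigma * rng.standard_normal()))
    return SyntheticExpression(
        values=values,
        universal_role_genes=universal,
        active_genes=active,
        inactive_genes=set(genes) - active,
    )
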