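"""Hand-built micro-instances for gapfilling tests."""

from commfba.model import (
    Compartment,
    DatabaseReaction,
    MediaCondition,
    MetabolicModel,
    Metabolite,
    Reaction,
    ReactionDatabase,
)


def two_route_model():
    """A -> B is missing; the database offers two equal-cost alternatives."""
    m = MetabolicModel(
        "tworoute",
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
    m.add_reaction(Reaction("BIO", {"B_c1": -1.0}, 0.0, 100.0, source_tag="biomass"))
    m.biomass_reaction_ids = ["BIO"]
    db = ReactionDatabase(
        reactions=[
            DatabaseReaction("route1", {"A_c": -1.0, "B_c": 1.0}),
            DatabaseReaction("route2", {"A_c": -1.0, "B_c": 1.0}),
            DatabaseReaction("noise", {"Z_c": -1.0, "W_c": 1.0}),
        ],
        transportable_compounds={},
    )
    media = MediaCondition("mA", {"A": (10.0, 0.0)})
    return m, db, media
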