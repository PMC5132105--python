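"""Readers and writers: native JSON models, media TSV, expression tables, SBML.

The native model format is flat JSON (schema below); SBML Level 3 with the
``fbc`` flux-bounds package is supported through COBRApy's reader/writer.

JSON model schema::

    {
      "id": str,
      "compartments": [{"id", "label", "species_index"}],
      "metabolites":  [{"id", "compartment", "name"?, "formula"?, "charge"?}],
      "reactions":    [{"id", "stoichiometry": {met: coeff}, "lower_bound",
                        "upper_bound", "gpr"?: nested list or string,
                        "name"?, "pathway"?, "source_tag"?, "meta"?}],
      "biomass_reaction_ids": [str],
      "community"?: {"species": {compartment: {"species_id", "member_model_id"}},
                     "member_biomass_ids": {...}, "community_biomass_id": str,
                     "n_members": int, "mode": "mixed_bag"|"compartmentalized"}
    }

Media TSV: three columns ``compound  max_uptake  max_excretion`` with
``#`` comment lines.  Expression TSV: ``gene_id  value``.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

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


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def model_to_dict(model: MetabolicModel) -> dict:
    d = {
        "id": model.id,
        "compartments": [
            {"id": c.id, "label": c.label, "species_index": c.species_index}
            for c in model.compartments.values()
        ],
        "metabolites": [
            {
                "id": m.id,
                "compartment": m.compartment_id,
                **({"name": m.name} if m.name else {}),
                **({"formula": m.formula} if m.formula is not None else {}),
                **({"charge": m.charge} if m.charge is not None else {}),
            }
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                **({"name": r.name} if r.name else {}),
                **({"gpr": r.gene_association.tree} if not r.gene_association.is_empty() else {}),
                **({"pathway": r.pathway} if r.pathway else {}),
                "source_tag": r.source_tag,
                **({"meta": r.meta} if r.meta else {}),
            }
            for r in model.reactions.values()
        ],
        "biomass_reaction_ids": model.biomass_reaction_ids,
    }
    community = getattr(model, "community_info", None)
    if community:
        d["community"] = community
    return d


def model_from_dict(d: dict) -> MetabolicModel:
    model = MetabolicModel(
        d["id"],
        [
            Compartment(c["id"], c["label"], int(c.get("species_index", 0)))
            for c in d["compartments"]
        ],
        [
            Metabolite(
                m["id"],
                m["compartment"],
                name=m.get("name", ""),
                formula=m.get("formula"),
                charge=m.get("charge"),
            )
            for m in d["metabolites"]
        ],
        [],
        d.get("biomass_reaction_ids", []),
    )
    for r in d["reactions"]:
        gpr = r.get("gpr")
        if isinstance(gpr, str):
            assoc = GeneAssociation.from_string(gpr)
        else:
            assoc = GeneAssociation(gpr)
        model.add_reaction(
            Reaction(
                id=r["id"],
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=float(r["lower_bound"]),
                upper_bound=float(r["upper_bound"]),
                name=r.get("name", ""),
                gene_association=assoc,
                pathway=r.get("pathway"),
                source_tag=r.get("source_tag", "draft"),
                meta=r.get("meta", {}),
            )
        )
    if "community" in d:
        model.community_info = d["community"]
    return model


def write_model_json(model: MetabolicModel, path: str | Path):
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1))


def read_model_json(path: str | Path) -> MetabolicModel:
    return model_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Reaction database
# ---------------------------------------------------------------------------

def database_to_dict(db: ReactionDatabase) -> dict:
    return {
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": r.stoichiometry,
                "reversible": r.reversible,
                **({"name": r.name} if r.name else {}),
                **({"pathway": r.pathway} if r.pathway else {}),
                "cost_forward": r.cost_forward,
                "cost_backward": r.cost_backward,
            }
            for r in db.reactions
        ],
        "transportable_compounds": db.transportable_compounds,
    }


def database_from_dict(d: dict) -> ReactionDatabase:
    return ReactionDatabase(
        reactions=[
            DatabaseReaction(
                id=r["id"],
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                reversible=bool(r.get("reversible", False)),
                name=r.get("name", ""),
                pathway=r.get("pathway"),
                cost_forward=float(r.get("cost_forward", 1.0)),
                cost_backward=float(r.get("cost_backward", 1.0)),
            )
            for r in d["reactions"]
        ],
        transportable_compounds=dict(d.get("transportable_compounds", {})),
    )


def write_database_json(db: ReactionDatabase, path: str | Path):
    Path(path).write_text(json.dumps(database_to_dict(db), indent=1))


def read_database_json(path: str | Path) -> ReactionDatabase:
    return database_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Media / expression tables
# ---------------------------------------------------------------------------

def read_media_tsv(path: str | Path, name: str | None = None) -> MediaCondition:
    path = Path(path)
    entries = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0].lower() in ("compound", "cpd"):
            continue  # header row
        if len(parts) != 3:
            raise ValueError(f"{path}: expected 3 tab-separated columns, got {line!r}")
        entries[parts[0]] = (float(parts[1]), float(parts[2]))
    return MediaCondition(name or path.stem, entries)


def write_media_tsv(media: MediaCondition, path: str | Path):
    lines = [f"# media: {media.name}", "compound\tmax_uptake\tmax_excretion"]
    for cpd, (up, ex) in sorted(media.entries.items()):
        lines.append(f"{cpd}\t{up:g}\t{ex:g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_expression_tsv(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["gene", "value"])
    if df.iloc[0]["gene"].lower() in ("gene", "gene_id"):
        df = df.iloc[1:]
    return {str(g): float(v) for g, v in zip(df["gene"], df["value"])}


def write_expression_tsv(values: dict[str, float], path: str | Path):
    lines = ["gene_id\tvalue"]
    for g, v in sorted(values.items()):
        lines.append(f"{g}\t{v:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; '#' comments allowed (universal-role lists)."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_gene_list(genes, path: str | Path):
    Path(path).write_text("\n".join(genes) + "\n")


# ---------------------------------------------------------------------------
# SBML via COBRApy, and cobra interconversion
# ---------------------------------------------------------------------------

def to_cobra(model: MetabolicModel):
    """Convert to a ``cobra.Model`` (objective = first biomass reaction)."""
    import cobra

    cm = cobra.Model(model.id)
    cm.compartments = {c.id: c.label for c in model.compartments.values()}
    mets = {}
    for m in model.metabolites.values():
        met = cobra.Metabolite(
            m.id, formula=m.formula or None, name=m.name, compartment=m.compartment_id
        )
        if m.charge is not None:
            met.charge = m.charge
        mets[m.id] = met
    cm.add_metabolites(list(mets.values()))
    rxns = []
    for r in model.reactions.values():
        rx = cobra.Reaction(r.id, name=r.name, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        rxns.append(rx)
    cm.add_reactions(rxns)
    for r in model.reactions.values():
        rx = cm.reactions.get_by_id(r.id)
        rx.add_metabolites({mets[m]: c for m, c in r.stoichiometry.items()})
        rule = r.gene_association.to_string()
        if rule:
            rx.gene_reaction_rule = rule
        if r.pathway:
            rx.subsystem = r.pathway
        rx.notes["source_tag"] = r.source_tag
    if model.biomass_reaction_ids:
        cm.objective = model.biomass_reaction_ids[0]
    return cm


def from_cobra(cm, biomass_reaction_ids=None) -> MetabolicModel:
    """Convert a ``cobra.Model`` back to the native representation."""
    comps = []
    for cid, label in cm.compartments.items():
        lab = label if label in ("cytosol", "extracellular", "biomass") else (
            "extracellular" if cid.startswith("e") else "cytosol"
        )
        idx = 0
        if lab == "cytosol":
            digits = "".join(ch for ch in cid if ch.isdigit())
            idx = int(digits) if digits else 1
        comps.append(Compartment(cid, lab, idx))
    model = MetabolicModel(
        cm.id or "model",
        comps,
        [
            Metabolite(
                m.id, m.compartment, name=m.name or "",
                formula=m.formula if m.formula is not None else None,
                charge=getattr(m, "charge", None),
            )
            for m in cm.metabolites
        ],
        [],
    )
    objective_ids = {
        v.name for v in cm.objective.variables if not v.name.endswith("_reverse_" + "0" * 0)
    }
    for rx in cm.reactions:
        tag = rx.notes.get("source_tag")
        if tag is None:
            tag = "exchange" if rx.boundary else "draft"
        model.add_reaction(
            Reaction(
                id=rx.id,
                stoichiometry={m.id: c for m, c in rx.metabolites.items()},
                lower_bound=rx.lower_bound,
                upper_bound=rx.upper_bound,
                name=rx.name or "",
                gene_association=GeneAssociation.from_string(rx.gene_reaction_rule),
                pathway=rx.subsystem or None,
                source_tag=tag,
            )
        )
    if biomass_reaction_ids is None:
        biomass_reaction_ids = [
            rx.id
            for rx in cm.reactions
            if rx.objective_coefficient or rx.id.lower().startswith("biomass")
            or rx.notes.get("source_tag") == "biomass"
        ]
        # keep declared biomass reactions first, deduplicated
        seen = set()
        biomass_reaction_ids = [
            b for b in biomass_reaction_ids if not (b in seen or seen.add(b))
        ]
    model.biomass_reaction_ids = list(biomass_reaction_ids)
    _ = objective_ids
    return model


def write_model_sbml(model: MetabolicModel, path: str | Path):
    from cobra.io import write_sbml_model

    write_sbml_model(to_cobra(model), str(path))


def read_model_sbml(path: str | Path) -> MetabolicModel:
    from cobra.io import read_sbml_model

    return from_cobra(read_sbml_model(str(path)))
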