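"""Compare individual vs. community gapfilling and the three strategies.

Community-level gapfilling instantiates the candidate database once per
species compartment, so it can delegate a missing function to the partner
and wire it through the shared compartment with transporters — the most
parsimonious repair when cross-feeding is possible.
"""

import commfba as cf

pho, het = cf.make_toy_phototroph(), cf.make_toy_heterotroph()
db = cf.make_toy_database()
auto = cf.make_autotrophic_media()
glcmin = cf.make_glucose_minimal_media()
rich = cf.make_rich_media()

het_alone = cf.gapfill(het, db, auto)
print(f"heterotroph gapfilled alone on autotrophic media: cost "
      f"{het_alone.total_cost:g} — it must become an autotroph itself:")
for c in het_alone.added:
    print(f"  + {c.db_id} ({c.direction}) in {c.compartment}")

comm, _ = cf.build_compartmentalized([pho, het])
cgf = cf.community_gapfill(comm, db, auto)
print(f"\ncommunity-level gapfill: cost {cgf.total_cost:g} — cross-feeding wins:")
for c in cgf.added:
    print(f"  + {c.db_id} ({c.direction}) in {c.compartment}")

print("\nstrategy comparison (exchanged metabolites on autotrophic media):")
member_media = {"A": [auto, glcmin], "B": auto, "C": rich}
for strat, label in (("A", "pre-gapfill members, then merge"),
                     ("B", "merge drafts, then gapfill community"),
                     ("C", "pre-gapfill on rich, merge, post-gapfill")):
    strat_comm, results = cf.run_strategy([pho, het], db, member_media[strat],
                                          auto, strat)
    n = len(cf.identify_interactions(strat_comm, auto).compounds())
    cost = sum(r.total_cost for r in results)
    print(f"  strategy {strat} ({label}): {n} compounds exchanged, "
          f"gapfill cost {cost:g}")
print("gapfilling after merging exposes more interactions than pre-gapfilling.")
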