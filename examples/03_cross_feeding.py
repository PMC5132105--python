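"""Predict interspecies metabolite exchanges with parsimonious FBA.

After community gapfilling, the flux state that maximizes community biomass
with minimum total flux reveals which compounds one species secretes and
the other consumes.  The transfer flux is min(secretion, uptake), so
media-supplied consumption is never counted as cross-feeding.
"""

import commfba as cf

pho, het = cf.make_toy_phototroph(), cf.make_toy_heterotroph()
db = cf.make_toy_database()
auto = cf.make_autotrophic_media()

comm, _ = cf.run_strategy([pho, het], db, auto, auto, "B")
imap = cf.identify_interactions(comm, auto, mode="fva")

print(f"{'compound':10s} {'producer':9s} {'consumer':9s} {'flux':>8s}  class")
for i in imap:
    print(f"{i.compound:10s} {i.producer:9s} {i.consumer:9s} {i.flux:8.3f}  {i.mode}")
print("\nsp1 = phototroph, sp2 = heterotroph.  The phototroph supplies organic "
      "carbon (glc), fixed nitrogen (nh3), O2, and the vitamin; the "
      "heterotroph returns CO2 and water.  'obligatory' transfers persist in "
      "every optimal flux state.")
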