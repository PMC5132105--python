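"""Score model flux predictions against expression-derived activity calls.

Genes are called on/off at the 10th percentile of universal housekeeping
gene expression; three-valued GPR evaluation lifts the calls to reactions;
transcriptomic flux fitting then finds the flux state agreeing with as many
calls as possible while keeping biomass producible, and the consistency
report tabulates the four flux-vs-expression categories.
"""

import commfba as cf

pho = cf.make_toy_phototroph()
auto = cf.make_autotrophic_media()

expr = cf.make_expression_profile(pho, cf.FixtureSpec(seed=2, noise=1.0), auto)
profile = cf.call_gene_activity(expr.values, expr.universal_role_genes)
print(f"on/off threshold (10th pct of {len(expr.universal_role_genes)} "
      f"universal genes): {profile.threshold:.1f}")

activity = cf.reaction_activity(pho, profile)
n_active = sum(1 for a in activity.values() if a == "active")
n_inactive = sum(1 for a in activity.values() if a == "inactive")
print(f"reaction calls: {n_active} active, {n_inactive} inactive, "
      f"{len(activity) - n_active - n_inactive} unknown (no gene rule or unmeasured)")

sol, agreement = cf.transcriptomic_fba(pho, auto, activity)
print(f"flux fitting: {sum(agreement.values())}/{len(agreement)} calls satisfied, "
      f"biomass kept at {sol.objective_value:.3f}")

report = cf.consistency_report(sol, activity, pho)
for k, v in report.summary_row().items():
    print(f"  {k:22s} {v}")
print("accuracy_overall is the share of reactions whose flux state matches "
      "their expression state.")
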