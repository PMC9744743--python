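"""Remove HS-binding sites by mutating basic residues to glutamine.

The mimic structure carries a spatial cluster {K42, K43, K239} and a linear
B-XXX-B-B motif {K239, K243, R244}; K239 is masked (it must be kept).
Per-site removal neutralizes every free cluster member; minimal-set removal
finds the smallest mutation set after which no targeted site keeps a
binding-competent basic pair.
"""

import hsgraft as hg

model, truth = hg.hs_minus_mimic()
surface = hg.surface_profile(model)
masks = hg.MaskRanges([hg.MaskRange("A", 239, 239, "keep-shared-anchor")])
constraints = hg.DesignConstraints(masks=masks)
pattern = [hg.MotifPattern("BXXXBB", "BXXXBB", "user")]

clusters = hg.find_spatial_clusters(model, surface)
per_site = hg.propose_removals(model, [], clusters, constraints, mode="per_site")
print("cluster removal (per site):", "_".join(p.notation for p in per_site))

hits = hg.scan_linear_motifs({"A": model.sequence("A")}, pattern)
minimal = hg.propose_removals(
    model, hits, [], constraints,
    mode="minimal_set", surface=surface, patterns=pattern,
)
print("motif removal (minimal set):", "_".join(p.notation for p in minimal))

report = hg.verify_design(model, surface, per_site + minimal, constraints, pattern)
print(f"re-scan after mutation: all sites gone = {report.ok}, "
      f"net charge delta {report.net_charge_delta:+.2f}")
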