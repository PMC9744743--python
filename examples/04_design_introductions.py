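"""Graft a new HS-binding cluster with one point mutation.

A surface pair of lysines 6 Å apart is one basic residue short of a
cluster. The designer finds the surface position whose mutated lysine tip
would land in band of both anchors — respecting masks, burial and the
no-hydrophobic-swap rule — and verifies the mutant.
"""

import hsgraft as hg

spec = hg.FixtureSpec(
    n_residues=30,
    planted_pairs=[hg.PlantedPair("K", "K", 6.0)],
    planted_candidate=hg.PlantedCandidate("S"),
    seed=7,
)
model, truth = hg.generate_fixture(spec)
surface = hg.surface_profile(model)

proposals = hg.propose_introductions(model, surface)
for p in proposals:
    anchors = ", ".join(f"{s.label} at {d:.2f} Å" for s, d in p.anchors)
    print(f"{p.notation}  score {p.score:.2f}  anchors: {anchors}")

report = hg.verify_design(model, surface, proposals[:1])
print(f"\nverification: ok={report.ok}, net charge delta "
      f"{report.net_charge_delta:+.2f}")
print(f"(ground truth planted the candidate at position "
      f"{truth['candidate']['position']})")
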