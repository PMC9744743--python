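# hsgraft

Detection and single-point-mutation design of heparan-sulfate (HS) binding
sites on protein structures.

## The problem

Heparan sulfate proteoglycans coat essentially every cell surface —
including brain endothelium — with long, negatively charged glycosaminoglycan
chains. Proteins bind HS through patches of basic residues (B = Arg, Lys,
His): either **linear motifs** such as `XBBXBX`, `BBBXXBB`, `BBXXXBB` (and
the short `BB-X-B` / `BB-XX-B` spacings), or **spatial clusters** — basic
residues that are far apart in sequence but brought within ~5–10 Å (or
~20 Å) of each other by the fold. Tuning a biologic's HS avidity — e.g.
making an antibody fragment stickier or stealthier at the blood–brain
barrier — comes down to grafting or deleting such sites with the fewest
possible mutations while leaving the functional (receptor-binding) regions
untouched.

`hsgraft` implements that workflow on a user-supplied structure (PDB/mmCIF,
typically a homology model) plus an optional full-length sequence:

* **surface** — deterministic Shrake–Rupley SASA (golden-spiral sampling),
  relative exposure against a self-consistent per-residue reference, and an
  outward-orientation test (side chain pointing away from the protein
  centroid). Only exposed, outward residues count.
* **motif scan** — symbolic scan of the sequence for B/X patterns,
  overlap-complete, with configurable B alphabet and X-slot strictness.
* **cluster scan** — graph of exposed basic residues whose charged-group
  centroids (Lys NZ, Arg guanidinium, His imidazole) fall in a distance
  band; connected components ≥ 2 are clusters, size ≥ 3 are complete.
* **design** — *introduce*: neutral→Lys mutations whose projected side-chain
  tip (5.5 Å along Cα→Cβ) lands in band of ≥ 2 existing anchors; *remove*:
  basic→Gln mutations, per-site or as a provably minimal set after which no
  targeted site keeps a binding-competent basic pair. Masked ranges
  (antibody variable regions), buried positions and highly hydrophobic
  residues ({I,V,L,F,M,W}) are never mutated.
* **charge** — Henderson–Hasselbalch net charge and mutation deltas
  (cationization accounting).
* **fixtures** — synthetic structures with planted geometry, so the whole
  pipeline is testable without any deposited structure.

## Worked example

```python
import hsgraft as hg

spec = hg.FixtureSpec(
    n_residues=30,
    planted_pairs=[hg.PlantedPair("K", "K", 6.0)],   # an adjacent surface K-K pair
    planted_candidate=hg.PlantedCandidate("S"),      # one completable serine
    seed=7,
)
model, truth = hg.generate_fixture(spec)
surface = hg.surface_profile(model)
for p in hg.propose_introductions(model, surface):
    print(p.notation, f"{p.score:.2f}",
          [(s.label, round(d, 2)) for s, d in p.anchors])
```

prints

```
S10K 2.19 [('K7', 9.6), ('K8', 5.99)]
```

— mutate Ser10 to lysine and its charged tip sits 9.60 Å and 5.99 Å from
the two existing lysines: a complete three-membered HS-binding cluster,
created by one mutation, worth +1 elementary charge at pH 7. The removal
direction is shown in `examples/05_design_removals.py`, which reproduces a
published four-mutation decationization (`K42Q_K43Q` for a spatial cluster,
`K243Q_R244Q` for a linear motif with the shared anchor K239 preserved,
net charge −4).

Each script in `examples/` is a runnable one-capability walkthrough.

## Acceptance script

`scripts/acceptance.py` re-runs the pipeline end-to-end from generated
inputs — the published-design mimic (detection, both removal modes,
verification, charge deltas) and a seeded batch of planted-introduction
fixtures (rank-1 recovery) — and writes its JSON result file:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
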