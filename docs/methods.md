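# Methods

## Scope and model

`hsgraft` operationalizes a qualitative structure-inspection workflow —
"find positively charged residues on the surface with their R-groups facing
outward, within HS-binding distance of each other, and change them with
single point mutations" — as a deterministic, testable pipeline. It does
not build structures (it consumes a model), does not dock glycans, and does
not predict stability changes.

## Surface exposure

**SASA.** Shrake–Rupley with a golden-spiral (Fibonacci-lattice) point set:
each atom's expanded sphere (van der Waals radius + probe, probe default
1.4 Å) is sampled at `n_points` deterministic directions; a point survives
if it is outside every neighbor's expanded sphere. Element radii are the
common single-atom values (C 1.70, N 1.55, O 1.52, S 1.80, H 1.20 Å).
The point set is fixed in the lab frame, so areas carry a small
pose-dependent sampling error; at the default `n_points = 1920` the worst
per-residue deviation under rigid rotation measured on the test fixtures is
~0.8 % (960 points breached the 1 % design bound, which is why the default
is 1920). Two coincident equal spheres count their shared surface exactly
once (index tie-break), matching the geometric expectation for degenerate
input.

**Relative SASA** divides the residue's absolute area by a per-type
reference: the same engine run on the isolated ideal heavy-atom residue
(hydrogens and OXT stripped). Numerator and denominator share radii, probe
and point set, so the ratio is convention-free; the default table is frozen
into the source (`reference_max_sasa(..., use_frozen=False)` recomputes it
live from the bundled component dictionary, and a test keeps the two in
agreement). Unknown residues (X) get 0. Values slightly above 1 can occur
for distorted or reduced-atom geometries and are clamped only in reports.

**Orientation.** A side chain "faces outward" when the angle between
(Cα → side-chain tip) and (protein centroid → Cα) is under 90°. The
original judgement was made by eye in a molecular viewer; no threshold is
recoverable from it, so the centroid test is a convention chosen for
robustness on small models. Glycine is outward by definition; a missing Cα
yields "not outward" plus a flag.

**Verdict.** `exposed = rel_sasa ≥ threshold (default 0.20) AND outward`,
except unmodeled residues (below).

## Unmodeled residues

Homology modelling servers drop disordered termini. Those residues are kept
as sequence-only records: they participate in motif scanning and may be
mutated (a disordered tail is assumed surface-located and without secondary
structure), but they have no coordinates and are excluded from every
distance computation. This mirrors the judgment made for a C-terminal
motif residue in the workflow this package systematizes.

## Motif scanning

Patterns are strings over {B, X}; B requires a residue from the basic
alphabet (default {R, K, H}; His can be dropped — it is mostly neutral at
pH 7.4). X-slots are permissive by default (`x_mode="any"`): an extra basic
residue inside a motif does not weaken HS binding, so it never disqualifies
a match. `"nonbasic"` and `"neutral"` (also excluding D/E) are stricter
options; each finds a subset of the previous mode's hits. All offsets are
reported, overlaps included; reverse-reading scan is opt-in. The scanner is
purely symbolic — Å semantics live in the cluster layer.

## Spatial clusters

Distances are tip-to-tip between charged-group centroids (Lys NZ; mean of
Arg NH1/NH2/NE; mean of His ND1/NE2; fallback Cβ then Cα with a flag): HS
sulfates contact the charged groups, not the backbone. An edge joins two
exposed basic residues whose distance falls in a band; clusters are
connected components with ≥ 2 members, `complete` at ≥ 3 (a pair is a seed
one mutation can complete). Bands default to short [5, 10] Å; the ~20 Å
literature spacing is operationalized as [18, 22] Å and enabled for
detection reports but disabled for design, because both published grafts
used the short range. Sequence-adjacent member pairs are annotated as the
classic "adjacent basic pair" seeds.

## Introduction design

For every exposed, modeled, unmasked, non-basic, non-hydrophobic position,
a pseudo-tip is projected 5.5 Å from Cα along the Cα→Cβ unit vector
(≈ Cα–NZ span of an extended lysine; no rotamer search — a deliberate
single-conformation approximation). Glycine gets a tetrahedral Cβ
synthesized from its backbone. Exposed basic residues whose tips land in
band of the projected tip are the proposal's anchors; `min_anchors`
defaults to 2 (the strict "third basic completes a pair" reading; 1 admits
single-anchor grafts). Score =
(anchor count, His anchors weighted 0.5) + 0.1·rel_SASA + 0.05·(in-band
pairs in the completed cluster); ties break by ascending residue number.
The weights are a constructed heuristic — the source workflow reports no
ranking — chosen so anchor count strictly dominates. Proline sites are
allowed (a published graft mutated a proline) but flagged. Lysine is the
default graft (published precedent); Arg is available.

## Removal design

Targets are detected motifs/clusters. `per_site` mutates every unmasked
basic member to Gln (polar-neutral, respecting the hydrophobicity rule; Asn
is an alternative). `minimal_set` finds the smallest mutation set such that
(a) no targeted site retains two or more basic members — a surviving
in-range basic *pair* is still a binding-competent HS contact even when the
full pattern is gone — and (b) re-scanning the mutated sequence and
structure finds no hit or cluster overlapping a targeted site. Criterion
(a) is the pairwise (vertex-cover) reading of "remove the site"; it is what
makes a 3-basic motif with one immutable member require both remaining
mutations rather than one. Exact subset search is used up to 20 candidate
residues; beyond that a greedy cover runs and flags its proposals. Sites
whose members are all masked are reported unresolvable.

## Verification and charge

`verify_design` applies proposals to a copy (projected tips materialized
for introductions), re-detects, and checks introductions created a cluster
containing the new residue and removals left no targeted site; it also
reports the net-charge delta. Charges are Henderson–Hasselbalch fractional
charges with side-chain pKa values D 3.65, E 4.25, C 8.18, Y 10.07, H 6.00,
K 10.54, R 12.48 (termini 9.0/2.3, off by default so mutation deltas equal
sequence-recomputation deltas exactly). No structure-aware pKa shifts.

## Synthetic fixtures

The generator emulates what the pipeline needs from a homology model and
nothing more: line/helix/sphere-shell backbones with idealized N/CA/C/O
placement, minimal side chains (Cβ plus one correctly named charged-tip
atom), planted basic pairs whose tip–tip distance is solved to ±0.1 Å by
deterministic tilt families, a candidate residue whose projected mutant tip
is placed in band of both anchors by a deterministic direction search
(0.25 Å margin from band edges), optional occluder shells that bury the
candidate below any sensible exposure threshold, and masks. Ground truth
records everything planted; the same spec yields byte-identical output.

These fixtures are *geometric* ground truth, not proteins: no rotamers, no
packing, no realistic dihedrals. A green planted-recovery test establishes
that detection and design invert the generator's geometry under the stated
constraints — it does not establish accuracy on real folds, where side-chain
orientation uncertainty (acknowledged even in the source workflow) dominates.

## Numerical and interface choices

* Author residue numbering is the only numbering ever surfaced; the
  full-length sequence defines it (position *i* of the FASTA is residue
  *i*). Insertion codes are rejected.
* Alternate locations resolve to highest occupancy; first model only;
  heteroatoms/waters dropped; non-standard residues map to X and are
  ineligible for mutation.
* Reports (JSON/TSV) format distances and charges to 2 decimals and sort
  keys, so identical config + seed reproduces byte-identical files.
* Status codes: 0 ok, 3 no proposal satisfied the constraints, 4
  verification failed.

## Known limitations

Single-conformation tip projection (no rotamer or flexibility modelling);
centroid-based orientation can misjudge residues in concave regions of
large irregular shapes; His protonation is treated by a single pKa; the
minimal-set search is exponential past 20 candidates and falls back to
greedy; no electrostatic-potential or docking evidence is computed.
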