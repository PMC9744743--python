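"""Single point-mutation design: graft or remove HS-binding sites.

Two directions, mirroring how a binder is engineered:

* **introduce** — mutate a surface, outward-facing, non-basic residue to
  lysine so that its projected side-chain tip lands in band of existing
  basic anchors, completing an HS-binding cluster;
* **remove** — mutate basic members of detected motifs/clusters to
  glutamine so that no binding-competent pair of basic residues survives.

Constraints enforced throughout: masked regions (e.g. antibody variable
regions, which must keep their receptor binding) are never mutated; highly
hydrophobic residues are never mutated to charged ones (and vice versa) to
avoid destabilizing the fold; buried or inward-facing residues are not
design sites.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .clusters import (
    BASIC_AAS,
    BasicSite,
    DistanceBands,
    SpatialCluster,
    collect_basic_sites,
    find_spatial_clusters,
)
from .errors import CannotProjectError, ParameterError
from .geometry import LYS_TIP_LENGTH, project_tip, synthesize_gly_cb
from .motifs import LinearMotifHit, MotifPattern, scan_linear_motifs
from .structure import MaskRanges, ResidueRecord, StructureModel, format_mutation
from .surface import SurfaceProfile

#: "Highly hydrophobic" residues, excluded as introduction sites (strongly
#: hydrophobic side chains anchor the fold; swapping one for a charge is a
#: stability gamble). Kyte–Doolittle strongly hydrophobic set plus Trp.
HYDROPHOBIC_SET = frozenset("IVLFMW")

CHARGED_AAS = frozenset("DEKRH")


@dataclass
class DesignConstraints:
    """All knobs that gate and shape mutation proposals."""

    masks: MaskRanges = field(default_factory=MaskRanges)
    bands: DistanceBands = field(
        default_factory=lambda: DistanceBands(use_long=False)
    )
    rel_sasa_threshold: float = 0.20
    min_anchors: int = 2
    forbidden_from_aas: frozenset[str] = HYDROPHOBIC_SET
    removal_to_aa: str = "Q"
    introduce_to_aa: str = "K"
    max_proposals: int = 50
    his_anchor_weight: float = 0.5
    min_cluster_size: int = 3
    b_alphabet: frozenset[str] = BASIC_AAS

    def __post_init__(self):
        if self.introduce_to_aa not in BASIC_AAS:
            raise ParameterError("introduce_to_aa must be basic (K/R/H)")
        if self.removal_to_aa in BASIC_AAS or self.removal_to_aa in "DE":
            raise ParameterError("removal_to_aa must be non-basic, non-acidic")
        if self.removal_to_aa in HYDROPHOBIC_SET:
            # charged → hydrophobic is the "vice versa" of the stability rule
            raise ParameterError("removal_to_aa may not be highly hydrophobic")


@dataclass
class MutationProposal:
    """One point mutation, with its evidence and constraint notes."""

    chain: str
    position: int
    from_aa: str
    to_aa: str
    kind: str  # "introduce" | "remove"
    affected_sites: list[str] = field(default_factory=list)
    anchors: list[tuple[BasicSite, float]] = field(default_factory=list)
    score: float = 0.0
    flags: list[str] = field(default_factory=list)

    @property
    def notation(self) -> str:
        return format_mutation(self.from_aa, self.position, self.to_aa)

    def __repr__(self):
        return (
            f"MutationProposal({self.notation}, {self.kind}, "
            f"score={self.score:.2f})"
        )


def project_mutant_tip(residue: ResidueRecord, to_aa: str = "K") -> np.ndarray:
    """Projected charged-group position of a not-yet-existing side chain.

    Placed along the Cα→Cβ unit vector, 5.5 Å from Cα for lysine (the
    approximate Cα–NZ span of an extended Lys; Arg/His use the same length
    — a deliberate simplification, no rotamer search). Glycine gets an
    ideal Cβ synthesized from its backbone first.
    """
    ca = residue.coord("CA")
    if ca is None:
        raise CannotProjectError(
            f"residue {residue.auth_seq_num}: missing CA"
        )
    cb = residue.coord("CB")
    if cb is None:
        if residue.aa == "G":
            n, c = residue.coord("N"), residue.coord("C")
            if n is None or c is None:
                raise CannotProjectError(
                    f"Gly {residue.auth_seq_num}: incomplete backbone"
                )
            cb = synthesize_gly_cb(n, ca, c)
        else:
            raise CannotProjectError(
                f"residue {residue.auth_seq_num}: missing CB"
            )
    if np.linalg.norm(cb - ca) < 1e-9:
        raise CannotProjectError(
            f"residue {residue.auth_seq_num}: CA and CB coincide"
        )
    return project_tip(ca, cb, LYS_TIP_LENGTH)


def _anchor_score(anchors, his_weight: float) -> float:
    return sum(his_weight if site.aa == "H" else 1.0 for site, _d in anchors)


def score_introduction(
    proposal: MutationProposal,
    rel_sasa: float,
    bands: DistanceBands,
) -> float:
    """Heuristic rank score for an introduction.

    Anchor count dominates (His anchors count 0.5 — mostly neutral at
    pH 7.4); relative SASA (weight 0.1) prefers well-exposed sites; the
    number of in-band pairs in the completed cluster (weight 0.05) prefers
    geometrically tight clusters.
    """
    anchor_term = _anchor_score(proposal.anchors, 0.5)
    tips = [np.asarray(s.tip) for s, _ in proposal.anchors]
    pairs_created = len(proposal.anchors)
    for a, b in itertools.combinations(tips, 2):
        if bands.classify(float(np.linalg.norm(a - b))) is not None:
            pairs_created += 1
    return anchor_term + 0.1 * rel_sasa + 0.05 * pairs_created


def rank_proposals(proposals: list[MutationProposal]) -> list[MutationProposal]:
    """Sort by descending score; ties broken by chain then ascending author
    number. Stable and deterministic."""
    return sorted(proposals, key=lambda p: (-p.score, p.chain, p.position))


def propose_introductions(
    model: StructureModel,
    surface: SurfaceProfile,
    constraints: DesignConstraints | None = None,
    return_audit: bool = False,
):
    """Propose neutral→Lys mutations that complete HS-binding clusters.

    Every exposed, modeled, unmasked, non-basic, non-hydrophobic position
    whose projected mutant tip lands in band of ≥ ``min_anchors`` exposed
    basic anchors yields a proposal. Proposals are ranked and capped at
    ``max_proposals``. With ``return_audit`` a list of (position, reason)
    for rejected candidate positions is returned alongside.
    """
    c = constraints or DesignConstraints()
    bands = c.bands
    anchors_all = collect_basic_sites(model, surface, True, c.b_alphabet)
    anchor_tips = (
        np.array([s.tip for s in anchors_all]) if anchors_all else np.empty((0, 3))
    )
    proposals: list[MutationProposal] = []
    audit: list[tuple[tuple[str, int], str]] = []
    for res in model.residues():
        key = (res.chain_id, res.auth_seq_num)
        if res.aa in c.b_alphabet or res.aa == "X":
            continue
        if not res.modeled:
            audit.append((key, "unmodeled"))
            continue
        if c.masks.covers(*key):
            audit.append((key, "masked"))
            continue
        if res.aa in c.forbidden_from_aas:
            audit.append((key, "hydrophobic"))
            continue
        rs = surface[key]
        if not rs.exposed:
            audit.append((key, "buried" if rs.outward else "inward-facing"))
            continue
        try:
            tip = project_mutant_tip(res, c.introduce_to_aa)
        except CannotProjectError as exc:
            audit.append((key, f"cannot-project: {exc}"))
            continue
        if len(anchors_all) == 0:
            continue
        d = np.linalg.norm(anchor_tips - tip, axis=1)
        anchors = [
            (anchors_all[i], float(d[i]))
            for i in range(len(anchors_all))
            if bands.classify(float(d[i])) is not None
        ]
        if len(anchors) < c.min_anchors:
            if anchors:
                audit.append((key, "insufficient-anchors"))
            continue
        flags = ["proline-site"] if res.aa == "P" else []
        p = MutationProposal(
            res.chain_id,
            res.auth_seq_num,
            res.aa,
            c.introduce_to_aa,
            "introduce",
            affected_sites=[s.label for s, _ in anchors],
            anchors=anchors,
            flags=flags,
        )
        p.score = score_introduction(p, rs.rel_sasa or 0.0, bands)
        proposals.append(p)
    ranked = rank_proposals(proposals)[: c.max_proposals]
    return (ranked, audit) if return_audit else ranked


def _site_members(site) -> list[tuple[str, int]]:
    if isinstance(site, SpatialCluster):
        return sorted(site.member_keys)
    if isinstance(site, LinearMotifHit):
        return [(site.chain_id, p) for p in site.basic_positions]
    raise ParameterError(f"unknown site type: {type(site)!r}")


def _site_id(site) -> str:
    if isinstance(site, SpatialCluster):
        return f"cluster:{site.id}"
    return f"motif:{site.pattern_id}@{site.chain_id}{site.start}-{site.end}"


def _removal_ok(
    model: StructureModel,
    surface: SurfaceProfile,
    sites,
    mutated: set[tuple[str, int]],
    constraints: DesignConstraints,
    patterns: list[MotifPattern] | None,
) -> bool:
    """True when, after mutating ``mutated`` to the removal residue, no
    targeted site remains binding-competent.

    Two checks: (a) no targeted site keeps ≥2 basic members — a surviving
    in-range basic *pair* is still an HS contact, even if the full motif
    pattern is gone; (b) re-scanning the mutated sequence finds no motif
    hit overlapping a targeted span, and re-finding clusters on the mutated
    structure finds none sharing a member with a targeted cluster.
    """
    for site in sites:
        members = _site_members(site)
        if sum(1 for m in members if m not in mutated) >= 2:
            return False
    # (b) re-scan
    mutated_model = model.copy()
    for chain, pos in mutated:
        res = mutated_model.get(chain, pos)
        res.aa = constraints.removal_to_aa
    motif_sites = [s for s in sites if isinstance(s, LinearMotifHit)]
    if motif_sites and patterns:
        sequences = {c: mutated_model.sequence(c) for c in mutated_model.chains}
        offsets = {
            c: rs[0].auth_seq_num for c, rs in mutated_model.chains.items() if rs
        }
        rescan = scan_linear_motifs(
            sequences, patterns, constraints.b_alphabet, chain_offsets=offsets
        )
        for h in rescan:
            for site in motif_sites:
                if h.chain_id == site.chain_id and not (
                    h.end < site.start or h.start > site.end
                ):
                    return False
    cluster_sites = [s for s in sites if isinstance(s, SpatialCluster)]
    if cluster_sites:
        targeted_keys = set().union(*(s.member_keys for s in cluster_sites))
        new_clusters = find_spatial_clusters(
            mutated_model,
            surface,
            constraints.bands,
            constraints.min_cluster_size,
            constraints.b_alphabet,
        )
        for nc in new_clusters:
            if nc.member_keys & targeted_keys:
                return False
    return True


def propose_removals(
    model: StructureModel,
    motifs: list[LinearMotifHit],
    clusters: list[SpatialCluster],
    constraints: DesignConstraints | None = None,
    mode: str = "per_site",
    surface: SurfaceProfile | None = None,
    patterns: list[MotifPattern] | None = None,
    return_audit: bool = False,
):
    """Propose basic→Gln mutations that remove targeted sites.

    ``per_site``: every unmasked basic member of every targeted site gets a
    removal proposal (the exhaustive, site-by-site neutralization).

    ``minimal_set``: the smallest set of mutations after which no targeted
    site is left binding-competent (see :func:`_removal_ok`); exact subset
    search for ≤20 candidate residues, greedy beyond (flagged). A site
    whose members are all masked is reported as unresolvable.
    """
    c = constraints or DesignConstraints()
    sites = list(motifs) + list(clusters)
    if not sites:
        raise ParameterError("no sites to remove")
    unresolvable = []
    proposals: list[MutationProposal] = []

    def make_proposal(chain, pos, site_ids):
        res = model.get(chain, pos)
        return MutationProposal(
            chain,
            pos,
            res.aa,
            c.removal_to_aa,
            "remove",
            affected_sites=sorted(site_ids),
            score=float(len(site_ids)),
        )

    if mode == "per_site":
        chosen: dict[tuple[str, int], set[str]] = {}
        for site in sites:
            members = _site_members(site)
            free = [m for m in members if not c.masks.covers(*m)]
            if not free:
                unresolvable.append(_site_id(site))
                continue
            for m in free:
                chosen.setdefault(m, set()).add(_site_id(site))
        for (chain, pos), site_ids in sorted(chosen.items()):
            proposals.append(make_proposal(chain, pos, site_ids))
    elif mode == "minimal_set":
        if surface is None:
            raise ParameterError("minimal_set mode needs the surface profile")
        candidates = sorted(
            {
                m
                for site in sites
                for m in _site_members(site)
                if not c.masks.covers(*m)
            }
        )
        for site in sites:
            if all(c.masks.covers(*m) for m in _site_members(site)):
                unresolvable.append(_site_id(site))
        targeted = [s for s in sites if _site_id(s) not in unresolvable]
        best: tuple[tuple[str, int], ...] | None = None
        greedy_flag = False
        if len(candidates) <= 20:
            for k in range(len(candidates) + 1):
                for combo in itertools.combinations(candidates, k):
                    if _removal_ok(model, surface, targeted, set(combo), c, patterns):
                        best = combo
                        break
                if best is not None:
                    break
        else:
            greedy_flag = True
            remaining = set()
            combo: list[tuple[str, int]] = []
            while not _removal_ok(model, surface, targeted, set(combo), c, patterns):
                # pick the candidate occurring in most still-competent sites
                def gain(m):
                    return sum(
                        1 for s in targeted if m in _site_members(s)
                    )
                pool = [m for m in candidates if m not in combo]
                if not pool:
                    break
                combo.append(max(pool, key=gain))
            best = tuple(combo)
        if best is None:
            unresolvable.extend(
                _site_id(s) for s in targeted if _site_id(s) not in unresolvable
            )
        else:
            for chain, pos in best:
                site_ids = {
                    _site_id(s)
                    for s in targeted
                    if (chain, pos) in _site_members(s)
                }
                p = make_proposal(chain, pos, site_ids)
                if greedy_flag:
                    p.flags.append("greedy-search")
                proposals.append(p)
    else:
        raise ParameterError(f"unknown removal mode {mode!r}")

    proposals = sorted(proposals, key=lambda p: (p.chain, p.position))
    return (proposals, unresolvable) if return_audit else proposals


def apply_proposals(
    model: StructureModel, proposals: list[MutationProposal]
) -> StructureModel:
    """Apply proposals to a copy of the model (sequence identity changes;
    coordinates untouched except that a removed basic loses its charged-
    group identity by virtue of the new residue type)."""
    out = model.copy()
    for p in proposals:
        res = out.get(p.chain, p.position)
        if res is None:
            raise ParameterError(f"no residue {p.chain}{p.position}")
        if res.aa != p.from_aa:
            raise ParameterError(
                f"{p.notation}: residue is {res.aa}, proposal is stale"
            )
        res.aa = p.to_aa
    if out.full_sequence:
        for chain, seq in list(out.full_sequence.items()):
            seq_list = list(seq)
            for p in proposals:
                if p.chain == chain and 1 <= p.position <= len(seq_list):
                    seq_list[p.position - 1] = p.to_aa
            out.full_sequence[chain] = "".join(seq_list)
    return out


def revert_proposals(
    model: StructureModel, proposals: list[MutationProposal]
) -> StructureModel:
    """Inverse of :func:`apply_proposals`."""
    inverted = [
        replace(p, from_aa=p.to_aa, to_aa=p.from_aa) for p in proposals
    ]
    return apply_proposals(model, inverted)


@dataclass
class VerificationReport:
    ok: bool
    entries: list[dict]
    net_charge_delta: float


def verify_design(
    model: StructureModel,
    surface: SurfaceProfile,
    proposals: list[MutationProposal],
    constraints: DesignConstraints | None = None,
    patterns: list[MotifPattern] | None = None,
    pH: float = 7.0,
) -> VerificationReport:
    """Apply the proposals to a copy and re-detect.

    Introductions must produce a new cluster containing the mutated
    position (its mutant tip is projected into the structure); removals
    must leave their targeted sites undetectable. The report also carries
    the net-charge delta of the full proposal set.
    """
    from .charge import mutation_charge_delta  # local: avoid cycle

    c = constraints or DesignConstraints()
    mutated = apply_proposals(model, proposals)
    # materialize projected tips for introduced lysines so cluster
    # detection can see them
    for p in proposals:
        if p.kind == "introduce":
            res_orig = model.get(p.chain, p.position)
            res_new = mutated.get(p.chain, p.position)
            if res_orig.modeled:
                tip = project_mutant_tip(res_orig, p.to_aa)
                tip_atom = {"K": "NZ", "R": "NH1", "H": "NE2"}[p.to_aa]
                res_new.atoms[tip_atom] = tip
    new_surface = surface.with_threshold(surface.rel_sasa_threshold)
    new_clusters = find_spatial_clusters(
        mutated, new_surface, c.bands, c.min_cluster_size, c.b_alphabet
    )
    sequences = {ch: mutated.sequence(ch) for ch in mutated.chains}
    offsets = {ch: rs[0].auth_seq_num for ch, rs in mutated.chains.items() if rs}
    new_motifs = (
        scan_linear_motifs(sequences, patterns, c.b_alphabet, chain_offsets=offsets)
        if patterns
        else []
    )
    entries = []
    all_ok = True
    for p in proposals:
        key = (p.chain, p.position)
        if p.kind == "introduce":
            found = [cl for cl in new_clusters if key in cl.member_keys]
            ok = any(cl.size >= c.min_cluster_size for cl in found) or (
                c.min_anchors < 2 and any(cl.size >= 2 for cl in found)
            )
            entries.append(
                {
                    "mutation": p.notation,
                    "kind": p.kind,
                    "verified": ok,
                    "new_clusters": [cl.id for cl in found],
                }
            )
        else:
            bad_motifs = [
                h
                for h in new_motifs
                if h.chain_id == p.chain
                and p.position in h.basic_positions
            ]
            bad_clusters = [
                cl for cl in new_clusters if key in cl.member_keys
            ]
            ok = not bad_motifs and not bad_clusters
            entries.append(
                {
                    "mutation": p.notation,
                    "kind": p.kind,
                    "verified": ok,
                    "residual_sites": [h.pattern_id for h in bad_motifs]
                    + [cl.id for cl in bad_clusters],
                }
            )
        all_ok &= ok
    delta = mutation_charge_delta([p.notation for p in proposals], pH=pH)
    return VerificationReport(all_ok, entries, delta)


def proposals_tsv(proposals: list[MutationProposal]) -> str:
    lines = ["chain\tmutation\tkind\tscore\tanchors\tdistances\tsites\tflags"]
    for p in proposals:
        anchors = ",".join(s.label for s, _ in p.anchors)
        dists = ",".join(f"{d:.2f}" for _, d in p.anchors)
        lines.append(
            f"{p.chain}\t{p.notation}\t{p.kind}\t{p.score:.2f}\t{anchors}"
            f"\t{dists}\t{';'.join(p.affected_sites)}\t{','.join(p.flags)}"
        )
    return "\n".join(lines) + "\n"
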