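"""Run configuration and file reports tying the pipeline together.

The package is used from Python; these functions are the equivalent of a
tool's subcommands: each takes explicit inputs plus a :class:`RunConfig`,
runs the pipeline, writes deterministic JSON/TSV artifacts into an output
directory (config echoed alongside, so a run is exactly reproducible from
its own output), and returns a summary with a status code:

* 0 — sites/proposals found and verified
* 3 — no proposal satisfied the constraints
* 4 — verification failed

All numeric output uses fixed decimal formatting (distances 2 dp, charges
2 dp) so reports diff cleanly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

from . import __version__ as _version
from .charge import charge_profile, charge_vs_ph_tsv
from .clusters import DistanceBands, clusters_tsv, find_spatial_clusters
from .design import (
    DesignConstraints,
    propose_introductions,
    propose_removals,
    proposals_tsv,
    verify_design,
)
from .motifs import MotifPattern, default_pattern_set, hits_tsv, scan_linear_motifs
from .structure import (
    MaskRanges,
    StructureModel,
    read_fasta,
    read_structure,
    reconcile_sequence,
    write_mutant_fasta,
)
from .surface import surface_profile, surface_table_tsv

EXIT_OK = 0
EXIT_NO_PROPOSALS = 3
EXIT_VERIFICATION_FAILED = 4


@dataclass
class RunConfig:
    """Serializable run parameters; echoed into every output directory."""

    band_short: tuple[float, float] = (5.0, 10.0)
    band_long: tuple[float, float] | None = (18.0, 22.0)
    use_long_band_for_detection: bool = True
    rel_sasa_threshold: float = 0.20
    sasa_probe_radius: float = 1.4
    sasa_n_points: int = 960
    min_anchors: int = 2
    min_cluster_size: int = 3
    include_histidine: bool = True
    x_mode: str = "any"  # motif X-slot semantics: any | nonbasic | neutral
    introduce_to_aa: str = "K"
    removal_to_aa: str = "Q"
    max_proposals: int = 50
    pH: float = 7.0
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @property
    def b_alphabet(self) -> frozenset[str]:
        return frozenset("RKH") if self.include_histidine else frozenset("RK")

    def detection_bands(self) -> DistanceBands:
        return DistanceBands(
            self.band_short, self.band_long, self.use_long_band_for_detection
        )

    def design_bands(self) -> DistanceBands:
        return DistanceBands(self.band_short, self.band_long, use_long=False)

    def constraints(self, masks: MaskRanges | None = None) -> DesignConstraints:
        return DesignConstraints(
            masks=masks or MaskRanges(),
            bands=self.design_bands(),
            rel_sasa_threshold=self.rel_sasa_threshold,
            min_anchors=self.min_anchors,
            removal_to_aa=self.removal_to_aa,
            introduce_to_aa=self.introduce_to_aa,
            max_proposals=self.max_proposals,
            min_cluster_size=self.min_cluster_size,
            b_alphabet=self.b_alphabet,
        )


def _load_model(
    structure, fasta=None
) -> StructureModel:
    model = (
        structure
        if isinstance(structure, StructureModel)
        else read_structure(structure)
    )
    if fasta is not None:
        seqs = fasta if isinstance(fasta, dict) else read_fasta(fasta)
        model = reconcile_sequence(model, seqs)
    return model


def _write(out_dir: Path, name: str, text: str) -> None:
    (out_dir / name).write_text(text)


def _prepare(out_dir, config: RunConfig):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _write(out_dir, "config.json", config.to_json() + "\n")
    return out_dir


def scan_report(
    structure,
    out_dir,
    config: RunConfig | None = None,
    fasta=None,
    patterns: list[MotifPattern] | None = None,
) -> dict:
    """Detect linear motifs and spatial clusters; write the site report.

    Writes ``motifs.tsv``, ``clusters.tsv``, ``surface.tsv`` and
    ``scan.json``; returns the summary dict (also the content of the JSON).
    """
    config = config or RunConfig()
    out_dir = _prepare(out_dir, config)
    model = _load_model(structure, fasta)
    patterns = patterns or default_pattern_set()
    surface = surface_profile(
        model,
        config.sasa_probe_radius,
        config.sasa_n_points,
        config.rel_sasa_threshold,
    )
    sequences = {c: model.sequence(c) for c in model.chains}
    offsets = {c: rs[0].auth_seq_num for c, rs in model.chains.items() if rs}
    hits = scan_linear_motifs(
        sequences,
        patterns,
        config.b_alphabet,
        x_mode=config.x_mode,
        chain_offsets=offsets,
    )
    clusters = find_spatial_clusters(
        model,
        surface,
        config.detection_bands(),
        config.min_cluster_size,
        config.b_alphabet,
    )
    _write(out_dir, "motifs.tsv", hits_tsv(hits))
    _write(out_dir, "clusters.tsv", clusters_tsv(clusters))
    _write(out_dir, "surface.tsv", surface_table_tsv(model, surface))
    summary = {
        "version": _version,
        "n_motif_hits": len(hits),
        "n_clusters": len(clusters),
        "n_complete_clusters": sum(c.complete for c in clusters),
        "clusters": [
            {
                "id": c.id,
                "size": c.size,
                "complete": c.complete,
                "pairs": [
                    [f"{a[0]}{a[1]}", f"{b[0]}{b[1]}", f"{d:.2f}", band]
                    for a, b, d, band in c.pair_distances
                ],
            }
            for c in clusters
        ],
        "motifs": [
            {
                "chain": h.chain_id,
                "span": [h.start, h.end],
                "pattern": h.pattern_id,
                "match": h.matched_subsequence,
            }
            for h in hits
        ],
        "status": EXIT_OK,
    }
    _write(out_dir, "scan.json", json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary


def design_report(
    structure,
    mode: str,
    out_dir,
    config: RunConfig | None = None,
    fasta=None,
    masks: MaskRanges | None = None,
    patterns: list[MotifPattern] | None = None,
    removal_mode: str = "minimal_set",
) -> dict:
    """Run add/remove design; write proposals, mutant FASTA, verification.

    ``mode`` is ``"add"`` (graft clusters by neutral→Lys) or ``"remove"``
    (delete detected sites by basic→Gln). Returns a summary whose
    ``status`` follows the module's exit-code convention.
    """
    if mode not in ("add", "remove"):
        raise ValueError(f"mode must be add|remove, got {mode!r}")
    config = config or RunConfig()
    out_dir = _prepare(out_dir, config)
    model = _load_model(structure, fasta)
    patterns = patterns or default_pattern_set()
    constraints = config.constraints(masks)
    surface = surface_profile(
        model,
        config.sasa_probe_radius,
        config.sasa_n_points,
        config.rel_sasa_threshold,
    )
    audit: list = []
    if mode == "add":
        proposals, audit = propose_introductions(
            model, surface, constraints, return_audit=True
        )
    else:
        sequences = {c: model.sequence(c) for c in model.chains}
        offsets = {c: rs[0].auth_seq_num for c, rs in model.chains.items() if rs}
        hits = scan_linear_motifs(
            sequences,
            patterns,
            config.b_alphabet,
            x_mode=config.x_mode,
            chain_offsets=offsets,
        )
        clusters = find_spatial_clusters(
            model,
            surface,
            config.detection_bands(),
            config.min_cluster_size,
            config.b_alphabet,
        )
        if not hits and not clusters:
            summary = {"status": EXIT_NO_PROPOSALS, "proposals": [], "reason": "no sites detected"}
            _write(
                out_dir,
                "design.json",
                json.dumps(summary, indent=2, sort_keys=True) + "\n",
            )
            return summary
        proposals, audit = propose_removals(
            model,
            hits,
            clusters,
            constraints,
            mode=removal_mode,
            surface=surface,
            patterns=patterns,
            return_audit=True,
        )
    _write(out_dir, "proposals.tsv", proposals_tsv(proposals))
    if not proposals:
        summary = {
            "status": EXIT_NO_PROPOSALS,
            "proposals": [],
            "audit": [f"{c}{p}: {r}" for (c, p), r in audit]
            if mode == "add"
            else list(audit),
        }
        _write(
            out_dir, "design.json", json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
        return summary
    verification = verify_design(
        model, surface, proposals, constraints, patterns, pH=config.pH
    )
    write_mutant_fasta(model, proposals, out_dir / "mutant.fasta")
    summary = {
        "status": EXIT_OK if verification.ok else EXIT_VERIFICATION_FAILED,
        "proposals": [
            {
                "chain": p.chain,
                "mutation": p.notation,
                "kind": p.kind,
                "score": f"{p.score:.2f}",
                "anchors": [
                    [s.label, f"{d:.2f}"] for s, d in p.anchors
                ],
                "sites": p.affected_sites,
                "flags": p.flags,
            }
            for p in proposals
        ],
        "verification": {
            "ok": verification.ok,
            "entries": verification.entries,
            "net_charge_delta": f"{verification.net_charge_delta:.2f}",
        },
    }
    _write(out_dir, "design.json", json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary


def charge_report(
    sequence_or_fasta,
    out_dir,
    mutations=None,
    config: RunConfig | None = None,
    include_termini: bool = False,
) -> dict:
    """Net charge / composition report, optionally with a mutation delta.

    Accepts a raw sequence string or a FASTA path; writes ``charge.json``
    and a charge-versus-pH TSV.
    """
    config = config or RunConfig()
    out_dir = _prepare(out_dir, config)
    if isinstance(sequence_or_fasta, str) and set(
        sequence_or_fasta.upper()
    ) <= set("ACDEFGHIKLMNPQRSTVWYX"):
        sequences = {"seq": sequence_or_fasta.upper()}
    else:
        sequences = read_fasta(sequence_or_fasta)
    out = {"status": EXIT_OK, "records": {}}
    for name, seq in sequences.items():
        prof = charge_profile(
            seq, config.pH, mutations, include_termini=include_termini
        )
        out["records"][name] = {
            "length": len(seq),
            "pH": f"{prof.pH:.2f}",
            "net_charge": f"{prof.net_charge:.2f}",
            "basic_count": prof.basic_count,
            "acidic_count": prof.acidic_count,
            "mutation_delta": None
            if prof.mutation_delta is None
            else f"{prof.mutation_delta:.2f}",
            "mutations": prof.mutations,
        }
        _write(
            out_dir,
            f"charge_vs_ph_{name}.tsv",
            charge_vs_ph_tsv(seq, include_termini=include_termini),
        )
    _write(out_dir, "charge.json", json.dumps(out, indent=2, sort_keys=True) + "\n")
    return out
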