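"""Structure and sequence I/O.

Reads PDB/mmCIF models into a light-weight per-residue representation,
reconciles the modeled structure with a full-length sequence (homology
models routinely omit disordered termini, yet those residues still matter
for sequence-level motif analysis and mutation design), and writes mutated
sequences as FASTA.

All user-facing residue numbering is author numbering (the numbers printed
on a structure figure, e.g. ``K42``); internal list indices are never
surfaced.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from bisect import bisect_right
from pathlib import Path

import numpy as np
from biotite.structure.io.pdb import PDBFile
from biotite.structure.io.pdbx import CIFFile, get_structure as _cif_get_structure
from biotite.sequence import ProteinSequence
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    EmptyStructureError,
    InsertionCodeError,
    MutationParseError,
    ParameterError,
    SequenceMismatchError,
    StaleProposalError,
    StructureFormatError,
)

STANDARD_AAS = set("ACDEFGHIKLMNPQRSTVWY")
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


def parse_mutation(notation: str) -> tuple[str, int, str]:
    """Parse ``K42Q`` notation into ``(from_aa, position, to_aa)``.

    The inverse of :func:`format_mutation`; the two form a bijection on
    valid strings.
    """
    m = _MUTATION_RE.match(notation)
    if m is None:
        raise MutationParseError(f"not valid mutation notation: {notation!r}")
    return m.group(1), int(m.group(2)), m.group(3)


def format_mutation(from_aa: str, position: int, to_aa: str) -> str:
    if len(from_aa) != 1 or len(to_aa) != 1 or position < 0:
        raise MutationParseError(
            f"cannot format mutation ({from_aa!r}, {position!r}, {to_aa!r})"
        )
    return f"{from_aa}{position}{to_aa}"


@dataclass
class ResidueRecord:
    """One residue: author number, one-letter code, and its atoms.

    ``atoms`` maps atom name to a length-3 coordinate array (Å). A residue
    absent from the coordinate model (``modeled=False``) carries no atoms
    but still participates in sequence-level analysis.
    """

    chain_id: str
    auth_seq_num: int
    aa: str
    atoms: dict[str, np.ndarray] = field(default_factory=dict)
    modeled: bool = True

    def coord(self, atom_name: str) -> np.ndarray | None:
        return self.atoms.get(atom_name)

    @property
    def is_basic(self) -> bool:
        return self.aa in ("R", "K", "H")

    def copy(self) -> "ResidueRecord":
        return ResidueRecord(
            self.chain_id,
            self.auth_seq_num,
            self.aa,
            {k: v.copy() for k, v in self.atoms.items()},
            self.modeled,
        )


@dataclass
class StructureModel:
    """Parsed polymer chains plus optional full-length sequence context."""

    chains: dict[str, list[ResidueRecord]]
    full_sequence: dict[str, str] | None = None
    provenance: str = ""

    def residues(self, chain_id: str | None = None):
        if chain_id is not None:
            yield from self.chains[chain_id]
        else:
            for records in self.chains.values():
                yield from records

    def get(self, chain_id: str, auth_seq_num: int) -> ResidueRecord | None:
        for r in self.chains.get(chain_id, ()):
            if r.auth_seq_num == auth_seq_num:
                return r
        return None

    def sequence(self, chain_id: str) -> str:
        """One-letter sequence over all residues (modeled or not), in order."""
        return "".join(r.aa for r in self.chains[chain_id])

    def copy(self) -> "StructureModel":
        return StructureModel(
            {c: [r.copy() for r in rs] for c, rs in self.chains.items()},
            dict(self.full_sequence) if self.full_sequence else None,
            self.provenance,
        )

    def all_atom_coords(self) -> np.ndarray:
        coords = [
            xyz for r in self.residues() if r.modeled for xyz in r.atoms.values()
        ]
        if not coords:
            return np.empty((0, 3))
        return np.vstack(coords)


@dataclass(frozen=True)
class MaskRange:
    chain_id: str
    start: int
    end: int  # inclusive
    label: str = ""


class MaskRanges:
    """Residue ranges excluded from mutation (e.g. antibody variable regions).

    Containment queries are O(log n): per chain, ranges are sorted by start
    and paired with a running maximum of ends, so a binary search plus one
    comparison decides membership even for overlapping ranges.
    """

    def __init__(self, ranges: list[MaskRange] | None = None):
        self.ranges = list(ranges or [])
        for r in self.ranges:
            if r.start > r.end:
                raise ParameterError(f"mask range start > end: {r}")
        self._by_chain: dict[str, tuple[list[int], list[int]]] = {}
        by_chain: dict[str, list[MaskRange]] = {}
        for r in self.ranges:
            by_chain.setdefault(r.chain_id, []).append(r)
        for chain, rs in by_chain.items():
            rs.sort(key=lambda r: (r.start, r.end))
            starts = [r.start for r in rs]
            max_ends = []
            running = -(10**9)
            for r in rs:
                running = max(running, r.end)
                max_ends.append(running)
            self._by_chain[chain] = (starts, max_ends)

    def __contains__(self, key: tuple[str, int]) -> bool:
        chain, pos = key
        entry = self._by_chain.get(chain)
        if entry is None:
            return False
        starts, max_ends = entry
        i = bisect_right(starts, pos)
        return i > 0 and max_ends[i - 1] >= pos

    def covers(self, chain: str, pos: int) -> bool:
        return (chain, pos) in self

    def __len__(self) -> int:
        return len(self.ranges)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MaskRanges":
        """Read a mask file: TSV columns chain, start, end, label (1-based,
        inclusive). Lines starting with ``#`` are comments."""
        ranges = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParameterError(f"{path}:{lineno}: expected ≥3 TSV columns")
            label = parts[3] if len(parts) > 3 else ""
            ranges.append(MaskRange(parts[0], int(parts[1]), int(parts[2]), label))
        return cls(ranges)


def _three_to_one(res_name: str) -> str:
    try:
        one = ProteinSequence.convert_letter_3to1(res_name)
    except Exception:
        return "X"
    return one if one in STANDARD_AAS else "X"


def one_to_three(aa: str) -> str:
    if aa == "X":
        return "UNK"
    return ProteinSequence.convert_letter_1to3(aa)


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Only the first model of a multi-model file is used. Heteroatoms and
    waters are excluded; alternate locations are resolved by highest
    occupancy (biotite's ``altloc="occupancy"`` rule). Residues with
    insertion codes are rejected: homology models do not carry them and
    author numbering is the tool's coordinate system.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    try:
        if format == "pdb":
            pdb_file = PDBFile.read(str(path))
            arr = pdb_file.get_structure(model=1, altloc="occupancy")
        elif format == "mmcif":
            cif_file = CIFFile.read(str(path))
            arr = _cif_get_structure(cif_file, model=1, altloc="occupancy")
        else:
            raise ParameterError(f"unknown format {format!r}")
    except ParameterError:
        raise
    except Exception as exc:
        raise StructureFormatError(f"cannot parse {path} as {format}: {exc}") from exc

    arr = arr[~arr.hetero]
    if arr.array_length() == 0:
        raise EmptyStructureError(f"{path}: no polymer residues")
    if np.any(arr.ins_code != ""):
        raise InsertionCodeError(f"{path}: insertion codes are not supported")

    chains: dict[str, list[ResidueRecord]] = {}
    seen: set[tuple[str, int]] = set()
    current: ResidueRecord | None = None
    for i in range(arr.array_length()):
        chain = str(arr.chain_id[i])
        num = int(arr.res_id[i])
        if current is None or current.chain_id != chain or current.auth_seq_num != num:
            key = (chain, num)
            if key in seen:
                raise StructureFormatError(
                    f"{path}: duplicate residue {chain}{num}"
                )
            seen.add(key)
            current = ResidueRecord(chain, num, _three_to_one(str(arr.res_name[i])))
            chains.setdefault(chain, []).append(current)
        current.atoms[str(arr.atom_name[i])] = np.asarray(
            arr.coord[i], dtype=float
        ).copy()

    for chain, records in chains.items():
        records.sort(key=lambda r: r.auth_seq_num)
    return StructureModel(chains, provenance=f"{path}:{format}")


def reconcile_sequence(
    model: StructureModel, fasta_sequence: dict[str, str] | str
) -> StructureModel:
    """Extend a model with residues present in the full-length sequence but
    absent from the coordinates (e.g. a disordered C-terminal tail the
    modelling software dropped).

    Author numbering is taken as the 1-based index into the full sequence,
    so every modeled residue must satisfy ``fasta[auth_seq_num - 1] == aa``.
    The returned model covers the full sequence; added residues carry
    ``modeled=False`` and no atoms. Coordinates of modeled residues are
    never touched.
    """
    if isinstance(fasta_sequence, str):
        if len(model.chains) != 1:
            raise ParameterError(
                "a bare sequence string is only valid for single-chain models"
            )
        fasta_sequence = {next(iter(model.chains)): fasta_sequence}

    out_chains: dict[str, list[ResidueRecord]] = {}
    for chain_id, records in model.chains.items():
        seq = fasta_sequence.get(chain_id)
        if seq is None:
            out_chains[chain_id] = [r.copy() for r in records]
            continue
        seq = seq.upper()
        by_num = {r.auth_seq_num: r for r in records}
        for r in records:
            if r.auth_seq_num < 1 or r.auth_seq_num > len(seq):
                raise SequenceMismatchError(
                    f"chain {chain_id}: residue {r.auth_seq_num} outside "
                    f"sequence of length {len(seq)}",
                    position=r.auth_seq_num,
                )
            if seq[r.auth_seq_num - 1] != r.aa:
                raise SequenceMismatchError(
                    f"chain {chain_id}: modeled {r.aa}{r.auth_seq_num} vs "
                    f"sequence {seq[r.auth_seq_num - 1]} at position "
                    f"{r.auth_seq_num}",
                    position=r.auth_seq_num,
                )
        full = []
        for i, aa in enumerate(seq, start=1):
            if i in by_num:
                full.append(by_num[i].copy())
            else:
                full.append(ResidueRecord(chain_id, i, aa, {}, modeled=False))
        out_chains[chain_id] = full

    full_seqs = dict(model.full_sequence or {})
    full_seqs.update({c: s.upper() for c, s in fasta_sequence.items()})
    return StructureModel(out_chains, full_seqs, model.provenance)


def apply_mutations_to_sequence(sequence: str, mutations, chain_offset: int = 1) -> str:
    """Apply ``(from_aa, position, to_aa)`` tuples or ``K42Q`` strings to a
    sequence whose first residue has author number ``chain_offset``."""
    seq = list(sequence)
    for mut in mutations:
        from_aa, pos, to_aa = (
            parse_mutation(mut) if isinstance(mut, str) else mut
        )
        idx = pos - chain_offset
        if idx < 0 or idx >= len(seq):
            raise StaleProposalError(f"position {pos} outside sequence")
        if seq[idx] != from_aa:
            raise StaleProposalError(
                f"expected {from_aa} at {pos}, found {seq[idx]}"
            )
        seq[idx] = to_aa
    return "".join(seq)


def write_mutant_fasta(model: StructureModel, proposals, out: str | Path) -> Path:
    """Write per-chain FASTA with the proposals applied.

    ``proposals`` is a list of objects with ``chain``, ``position``,
    ``from_aa`` and ``to_aa`` attributes (e.g. :class:`~hsgraft.design.
    MutationProposal`) or ``(chain_id, "K42Q")`` tuples. Headers carry the
    applied mutations in ``K42Q`` notation; the mutation list order follows
    ascending author number.
    """
    by_chain: dict[str, list[tuple[str, int, str]]] = {}
    for p in proposals:
        if isinstance(p, tuple) and len(p) == 2 and isinstance(p[1], str):
            chain, notation = p
            by_chain.setdefault(chain, []).append(parse_mutation(notation))
        else:
            by_chain.setdefault(p.chain, []).append(
                (p.from_aa, p.position, p.to_aa)
            )
    out = Path(out)
    records_out = []
    for chain_id, records in model.chains.items():
        muts = sorted(by_chain.get(chain_id, []), key=lambda m: m[1])
        seq = model.sequence(chain_id)
        offset = records[0].auth_seq_num if records else 1
        mutated = apply_mutations_to_sequence(seq, muts, chain_offset=offset)
        tag = "_".join(format_mutation(*m) for m in muts)
        records_out.append(
            SeqRecord(Seq(mutated), id=str(chain_id), description=tag)
        )
    with open(out, "w") as fh:
        SeqIO.write(records_out, fh, "fasta")
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into ``{record id: sequence}`` (uppercased)."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }
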