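"""Linear heparan-sulfate binding motif scanning.

HS-binding motifs in the literature are linear arrangements of basic
residues (B = Arg, Lys, His) interleaved with non-basic residues (X), in
patterns such as XBBXBX, BBBXXBB or BBXXXBB, plus the shorter BB-X-B and
BB-XX-B spacings used when grafting clusters. The scanner is purely
symbolic: positions and patterns, no geometry — Å-scale semantics live in
:mod:`hsgraft.clusters`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .errors import ParameterError

#: Basic residues as the literature defines B. Histidine is included by
#: default (mostly neutral at physiological pH; drop it via ``b_alphabet``).
DEFAULT_B_ALPHABET = frozenset("RKH")

#: In strict mode X must be a neutral residue: acidic D/E are excluded too.
ACIDIC = frozenset("DE")


@dataclass(frozen=True)
class MotifPattern:
    """A motif pattern over the alphabet {B, X}."""

    id: str
    pattern: str
    source: str = "user"  # intro_pattern | methods_pattern | user

    def __post_init__(self):
        if not self.pattern:
            raise ParameterError("empty motif pattern")
        if any(c not in "BX" for c in self.pattern):
            raise ParameterError(f"pattern {self.pattern!r} not over {{B,X}}")
        if self.pattern.count("B") < 2:
            raise ParameterError(
                f"pattern {self.pattern!r} needs at least 2 B positions"
            )


@dataclass(frozen=True)
class LinearMotifHit:
    """One motif match, in author numbering (inclusive ends)."""

    chain_id: str
    start: int
    end: int
    pattern_id: str
    pattern: str
    matched_subsequence: str
    basic_positions: tuple[int, ...]

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def default_pattern_set() -> list[MotifPattern]:
    """The five stock patterns: the three classic literature motifs plus the
    two short cluster-mimicking spacings (BB-X-B, BB-XX-B)."""
    return [
        MotifPattern("XBBXBX", "XBBXBX", "intro_pattern"),
        MotifPattern("BBBXXBB", "BBBXXBB", "intro_pattern"),
        MotifPattern("BBXXXBB", "BBXXXBB", "intro_pattern"),
        MotifPattern("BBXB", "BBXB", "methods_pattern"),
        MotifPattern("BBXXB", "BBXXB", "methods_pattern"),
    ]


def load_pattern_tsv(path: str | Path) -> list[MotifPattern]:
    """User patterns from TSV columns (id, pattern)."""
    patterns = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ParameterError(f"{path}:{lineno}: expected 2 TSV columns")
        patterns.append(MotifPattern(parts[0], parts[1], "user"))
    return patterns


X_MODES = ("any", "nonbasic", "neutral")


def _matches(
    window: str, pattern: str, b_alphabet: frozenset[str], x_mode: str
) -> bool:
    for aa, sym in zip(window, pattern):
        if sym == "B":
            if aa not in b_alphabet:
                return False
        elif x_mode != "any":
            if aa in b_alphabet:
                return False
            if x_mode == "neutral" and aa in ACIDIC:
                return False
    return True


def scan_linear_motifs(
    sequences: dict[str, str] | str,
    patterns: list[MotifPattern] | None = None,
    b_alphabet=DEFAULT_B_ALPHABET,
    x_mode: str = "any",
    include_reverse: bool = False,
    chain_offsets: dict[str, int] | None = None,
) -> list[LinearMotifHit]:
    """All motif matches at all offsets, overlaps included.

    ``sequences`` maps chain id to one-letter sequence (a bare string is
    treated as chain ``A``). ``B`` positions must hold a residue from
    ``b_alphabet``. ``X`` positions are permissive by default (``x_mode=
    "any"``): an extra basic residue inside a motif does not weaken HS
    binding, so it never disqualifies a match. ``x_mode="nonbasic"``
    requires X slots to be non-basic; ``"neutral"`` additionally excludes
    the acidic D/E — each stricter mode finds a subset of the previous
    one's hits. Matching is case-insensitive. The unknown residue ``X``
    never satisfies a ``B`` position. Results are ordered by (chain, start,
    pattern id) and reported in author numbering, using ``chain_offsets``
    (default: first residue is 1).

    With ``include_reverse`` each pattern is additionally matched in its
    reversed reading; hits are still reported on forward coordinates.
    """
    if patterns is None:
        patterns = default_pattern_set()
    if not patterns:
        raise ParameterError("empty pattern list")
    if isinstance(sequences, str):
        sequences = {"A": sequences}
    b_alphabet = frozenset(a.upper() for a in b_alphabet)
    hits: list[LinearMotifHit] = []
    for chain_id, seq in sequences.items():
        seq = seq.upper()
        offset = (chain_offsets or {}).get(chain_id, 1)
        for pat in patterns:
            variants = {pat.pattern}
            if include_reverse:
                variants.add(pat.pattern[::-1])
            for variant in variants:
                plen = len(variant)
                for i in range(len(seq) - plen + 1):
                    window = seq[i : i + plen]
                    if _matches(window, variant, b_alphabet, x_mode):
                        basics = tuple(
                            offset + i + k
                            for k, sym in enumerate(variant)
                            if sym == "B"
                        )
                        hits.append(
                            LinearMotifHit(
                                chain_id,
                                offset + i,
                                offset + i + plen - 1,
                                pat.id,
                                pat.pattern,
                                window,
                                basics,
                            )
                        )
    hits.sort(key=lambda h: (h.chain_id, h.start, h.pattern_id))
    # reverse-reading duplicates of palindromic patterns collapse here
    seen = set()
    unique = []
    for h in hits:
        key = (h.chain_id, h.start, h.pattern_id, h.basic_positions)
        if key not in seen:
            seen.add(key)
            unique.append(h)
    return unique


def hits_tsv(hits: list[LinearMotifHit]) -> str:
    lines = ["chain\tstart\tend\tpattern_id\tmatch\tbasic_positions"]
    for h in hits:
        lines.append(
            f"{h.chain_id}\t{h.start}\t{h.end}\t{h.pattern_id}"
            f"\t{h.matched_subsequence}\t{','.join(map(str, h.basic_positions))}"
        )
    return "\n".join(lines) + "\n"
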