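"""Net-charge accounting for sequences and mutation sets.

Cationization — raising a protein's net positive charge — is the classical
route to adsorptive interactions with negatively charged cell surfaces;
grafting or removing basic residues moves the net charge by whole units.
Charges are Henderson–Hasselbalch fractional charges summed over ionizable
groups at a given pH; no structure-aware pKa shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ParameterError
from .structure import parse_mutation

#: Side-chain pKa values (Lehninger convention), plus free termini.
DEFAULT_PKA = {
    "D": 3.65,
    "E": 4.25,
    "C": 8.18,
    "Y": 10.07,
    "H": 6.00,
    "K": 10.54,
    "R": 12.48,
    "N_term": 9.0,
    "C_term": 2.3,
}

NEGATIVE_GROUPS = ("D", "E", "C", "Y")
POSITIVE_GROUPS = ("R", "K", "H")


def _positive_charge(pH: float, pKa: float) -> float:
    return 1.0 / (1.0 + 10.0 ** (pH - pKa))


def _negative_charge(pH: float, pKa: float) -> float:
    return -1.0 / (1.0 + 10.0 ** (pKa - pH))


def sidechain_charge(aa: str, pH: float, pka_table: dict | None = None) -> float:
    """Fractional side-chain charge of one residue type at ``pH``."""
    pka = pka_table or DEFAULT_PKA
    if aa in POSITIVE_GROUPS:
        return _positive_charge(pH, pka[aa])
    if aa in NEGATIVE_GROUPS:
        return _negative_charge(pH, pka[aa])
    return 0.0


def net_charge(
    sequence: str,
    pH: float = 7.0,
    pka_table: dict | None = None,
    include_termini: bool = False,
) -> float:
    """Net charge (elementary charges) of a sequence at ``pH``.

    Henderson–Hasselbalch sum over ionizable side chains (D, E, C, Y
    negative; R, K, H positive); unknown residues ``X`` contribute zero.
    Termini are off by default — point mutations never change them, so the
    side-chain-only convention makes sequence deltas and mutation deltas
    directly comparable.
    """
    if not 0.0 <= pH <= 14.0:
        raise ParameterError(f"pH {pH} outside [0, 14]")
    pka = pka_table or DEFAULT_PKA
    total = sum(sidechain_charge(aa, pH, pka) for aa in sequence.upper())
    if include_termini and sequence:
        total += _positive_charge(pH, pka["N_term"])
        total += _negative_charge(pH, pka["C_term"])
    return total


def mutation_charge_delta(
    mutations, pH: float = 7.0, pka_table: dict | None = None
) -> float:
    """Summed side-chain charge change of a mutation set at ``pH``.

    ``mutations`` are ``K42Q`` strings or ``(from, pos, to)`` tuples. The
    delta is additive over disjoint sets and equals
    ``net_charge(mutant) - net_charge(original)`` exactly (side-chain
    convention).
    """
    if not 0.0 <= pH <= 14.0:
        raise ParameterError(f"pH {pH} outside [0, 14]")
    total = 0.0
    for mut in mutations:
        from_aa, _pos, to_aa = (
            parse_mutation(mut) if isinstance(mut, str) else mut
        )
        total += sidechain_charge(to_aa, pH, pka_table) - sidechain_charge(
            from_aa, pH, pka_table
        )
    return total


@dataclass
class ChargeProfile:
    sequence: str
    pH: float
    net_charge: float
    basic_count: int
    acidic_count: int
    mutation_delta: float | None = None
    mutations: list[str] = field(default_factory=list)


def charge_profile(
    sequence: str,
    pH: float = 7.0,
    mutations=None,
    pka_table: dict | None = None,
    include_termini: bool = False,
) -> ChargeProfile:
    """Composition and net charge of a sequence, optionally with the delta
    of a mutation set."""
    seq = sequence.upper()
    delta = (
        mutation_charge_delta(mutations, pH, pka_table)
        if mutations
        else None
    )
    return ChargeProfile(
        seq,
        pH,
        net_charge(seq, pH, pka_table, include_termini),
        sum(seq.count(a) for a in POSITIVE_GROUPS),
        sum(seq.count(a) for a in "DE"),
        delta,
        [m if isinstance(m, str) else "".join(map(str, m)) for m in (mutations or [])],
    )


def charge_vs_ph_tsv(
    sequence: str,
    ph_values=None,
    pka_table: dict | None = None,
    include_termini: bool = False,
) -> str:
    """Charge-versus-pH table as TSV text (2 decimal places)."""
    if ph_values is None:
        ph_values = [x / 2 for x in range(2, 25)]  # 1.0 .. 12.0
    lines = ["pH\tnet_charge"]
    for ph in ph_values:
        lines.append(
            f"{ph:.1f}\t{net_charge(sequence, ph, pka_table, include_termini):.2f}"
        )
    return "\n".join(lines) + "\n"
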