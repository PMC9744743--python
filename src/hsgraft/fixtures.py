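"""Synthetic structure generation with planted HS-binding geometry.

No deposited structure exists for the system this tool was built around, so
every capability is exercised on generated models: small coil/helix-like
backbones with basic residues planted at controlled pairwise side-chain
distances, an optional "completable" candidate residue whose hypothetical
lysine tip lands at controlled distances from the planted anchors, and
optional occluding shells that bury the candidate.

The models are deliberately minimal — backbone N/CA/C/O, a Cβ, and a single
charged-tip atom with the correct name (NZ, NH1, NE2) where needed — which
is exactly the atom set every downstream operation consumes. They are not
physically realistic proteins; they are geometric ground truth.

Every generated feature is recorded in a ground-truth dict so end-to-end
tests can assert the pipeline recovers exactly what was planted. Same seed,
same bytes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import InfeasibleSpecError, ParameterError, SerialOverflowError
from .geometry import unit
from .structure import (
    MaskRange,
    ResidueRecord,
    StructureModel,
    one_to_three,
)

CA_SPACING = 3.8  # Å, trans-peptide Cα–Cα distance
TIP_LENGTH = 5.3  # Å, Cα→charged-tip used for planted basic side chains

#: Tip atom name per basic residue type (single-atom side-chain tip; the
#: charged-group centroid of a one-atom group is the atom itself).
TIP_ATOM = {"K": "NZ", "R": "NH1", "H": "NE2"}


@dataclass
class PlantedPair:
    """A sequence-adjacent basic pair whose tip–tip distance is controlled."""

    aa1: str = "K"
    aa2: str = "K"
    distance: float = 6.0
    positions: tuple[int, int] | None = None  # auto if None


@dataclass
class PlantedCandidate:
    """A non-basic residue whose projected mutant tip is in band of the
    planted anchors."""

    aa: str = "S"
    buried: bool = False
    position: int | None = None  # auto: right after the pair


@dataclass
class FixtureSpec:
    n_residues: int = 30
    geometry: str = "line"  # line | helix | sphere_shell
    planted_pairs: list[PlantedPair] = field(default_factory=list)
    planted_candidate: PlantedCandidate | None = None
    masked_ranges: list[MaskRange] = field(default_factory=list)
    filler_aa: str = "L"
    chain_id: str = "A"
    seed: int = 0
    band: tuple[float, float] = (5.0, 10.0)


def _layout(spec: FixtureSpec):
    """Cα positions plus per-residue side-chain (u) and binormal (b) unit
    vectors for the chosen geometry."""
    n = spec.n_residues
    if spec.geometry == "line":
        ca = np.column_stack(
            [CA_SPACING * np.arange(n), np.zeros(n), np.zeros(n)]
        ).astype(float)
        u = np.tile([0.0, 1.0, 0.0], (n, 1))
        b = np.tile([0.0, 0.0, 1.0], (n, 1))
    elif spec.geometry == "helix":
        # idealized alpha-like helix: radius 2.3 Å, rise 1.5 Å, 100°/res
        t = np.arange(n) * math.radians(100.0)
        ca = np.column_stack(
            [2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * np.arange(n)]
        )
        u = np.column_stack([np.cos(t), np.sin(t), np.zeros(n)])
        b = np.tile([0.0, 0.0, 1.0], (n, 1))
    elif spec.geometry == "sphere_shell":
        # Fibonacci lattice on a sphere sized for ~6 Å neighbor spacing,
        # side chains radially outward
        radius = 6.0 * math.sqrt(n / (4.0 * math.pi))
        pts = []
        phi = math.pi * (3.0 - math.sqrt(5.0))
        for k in range(n):
            z = 1.0 - 2.0 * (k + 0.5) / n
            r = math.sqrt(max(1.0 - z * z, 0.0))
            pts.append([r * math.cos(phi * k), r * math.sin(phi * k), z])
        u = np.asarray(pts)
        ca = radius * u
        b = np.zeros_like(u)
        for i in range(n):
            ref = np.array([0.0, 0.0, 1.0])
            if abs(np.dot(u[i], ref)) > 0.9:
                ref = np.array([1.0, 0.0, 0.0])
            b[i] = unit(np.cross(u[i], ref))
    else:
        raise ParameterError(f"unknown geometry {spec.geometry!r}")
    return ca, u, b


def _backbone_atoms(ca, u, tangent):
    """Minimal backbone: N and C fore/aft along the chain, O opposite the
    side chain."""
    return {
        "N": ca - 1.2 * tangent - 0.5 * u,
        "CA": ca.copy(),
        "C": ca + 1.2 * tangent - 0.5 * u,
        "O": ca + 1.2 * tangent - 1.7 * u,
    }


def _splay_tips(ca1, ca2, u1, u2, b, distance):
    """Place two side-chain tips (|tip−Cα| = TIP_LENGTH) realizing a
    requested tip–tip distance.

    Three deterministic tilt families are tried in order — symmetric
    ±binormal splay (widens a parallel pair), tilt toward each other, tilt
    away — and the first family whose reachable range brackets the target
    is solved by root finding. Raises :class:`InfeasibleSpecError` when no
    family can reach the distance.
    """
    from scipy.optimize import brentq

    h1 = unit(ca2 - ca1)
    h2 = -h1
    families = [
        (b, -b),  # binormal splay
        (h1, h2),  # toward each other
        (-h1, -h2),  # away from each other
    ]
    lo, hi = 0.0, math.radians(80.0)
    reachable = []
    for d1, d2 in families:
        def tips(phi, d1=d1, d2=d2):
            t1 = ca1 + TIP_LENGTH * unit(math.cos(phi) * u1 + math.sin(phi) * d1)
            t2 = ca2 + TIP_LENGTH * unit(math.cos(phi) * u2 + math.sin(phi) * d2)
            return t1, t2

        def f(phi, tips=tips):
            t1, t2 = tips(phi)
            return float(np.linalg.norm(t1 - t2))

        grid = [lo + (hi - lo) * k / 32 for k in range(33)]
        vals = [f(p) for p in grid]
        reachable.append((min(vals), max(vals)))
        for a, bb in zip(grid, grid[1:]):
            fa, fb = f(a), f(bb)
            if (fa - distance) * (fb - distance) <= 0:
                phi = brentq(lambda p: f(p) - distance, a, bb, xtol=1e-10)
                return tips(phi)
    ranges = ", ".join(f"[{a:.2f}, {b:.2f}]" for a, b in reachable)
    raise InfeasibleSpecError(
        f"tip distance {distance:.2f} Å unreachable (family ranges {ranges})"
    )


def _candidate_tip_direction(ca_c, u_c, anchor_tips, band):
    """Deterministic grid search for a mutant-tip direction putting the
    projected tip in band (with margin) of every anchor."""
    margin = 0.25
    toward = unit(np.mean(anchor_tips, axis=0) - ca_c)
    for theta_deg in range(0, 85, 5):
        for sign in (1.0, -1.0):
            theta = math.radians(theta_deg) * sign
            w = unit(math.cos(theta) * u_c + math.sin(theta) * toward)
            tip = ca_c + 5.5 * w
            dists = [float(np.linalg.norm(tip - a)) for a in anchor_tips]
            if all(band[0] + margin <= d <= band[1] - margin for d in dists):
                return w, dists
    raise InfeasibleSpecError(
        "no mutant-tip direction puts the candidate in band of all anchors"
    )


def _occluder_points(centers, rng_free_points, radius, n_points):
    phi = math.pi * (3.0 - math.sqrt(5.0))
    pts = []
    for c in centers:
        for k in range(n_points):
            z = 1.0 - 2.0 * (k + 0.5) / n_points
            r = math.sqrt(max(1.0 - z * z, 0.0))
            pts.append(
                c + radius * np.array([r * math.cos(phi * k), r * math.sin(phi * k), z])
            )
    return pts


def generate_fixture(spec: FixtureSpec) -> tuple[StructureModel, dict]:
    """Generate a model and its ground truth.

    Planted pairs are sequence-adjacent basic residues with tips splayed to
    the requested distance (±0.1 Å verified by recomputation); the planted
    candidate's Cβ is oriented so its projected lysine tip is in band of
    both anchors. A buried candidate gains shells of occluding carbon
    pseudo-atoms (appended as extra residues) that push its relative SASA
    below any sensible exposure threshold while leaving the anchors free.

    Deterministic: the same spec (including seed) yields byte-identical
    coordinates.
    """
    n = spec.n_residues
    if n < 5:
        raise ParameterError("need at least 5 residues")
    rng = np.random.default_rng(spec.seed)
    ca, u, b = _layout(spec)
    tangent = np.zeros_like(ca)
    for i in range(n):
        j = min(i, n - 2)
        tangent[i] = unit(ca[j + 1] - ca[j])

    aas = [spec.filler_aa] * n
    tips: dict[int, np.ndarray] = {}  # 0-based index -> planted tip
    cbs: dict[int, np.ndarray] = {}
    truth: dict = {
        "seed": spec.seed,
        "geometry": spec.geometry,
        "chain": spec.chain_id,
        "pairs": [],
        "candidate": None,
        "masked": [
            [m.chain_id, m.start, m.end, m.label] for m in spec.masked_ranges
        ],
    }

    # --- planted pairs (positions are 1-based author numbers) ---
    next_auto = max(2, n // 4)
    pair_indices: list[tuple[int, int]] = []
    for pair in spec.planted_pairs:
        if pair.positions is not None:
            p1, p2 = pair.positions
        elif spec.geometry == "sphere_shell":
            # lattice neighbors on a Fibonacci sphere are not sequence
            # neighbors: pick the spatially closest index pair
            from scipy.spatial.distance import pdist, squareform

            dm = squareform(pdist(ca))
            np.fill_diagonal(dm, np.inf)
            i0, j0 = np.unravel_index(np.argmin(dm), dm.shape)
            p1, p2 = sorted((int(i0) + 1, int(j0) + 1))
        else:
            p1, p2 = next_auto, next_auto + 1
            next_auto += 8
        if not (1 <= p1 < p2 <= n):
            raise InfeasibleSpecError("pair positions outside the chain")
        i, j = p1 - 1, p2 - 1
        t1, t2 = _splay_tips(ca[i], ca[j], u[i], u[j], b[i], pair.distance)
        for idx, aa, tip in ((i, pair.aa1, t1), (j, pair.aa2, t2)):
            if aa not in TIP_ATOM:
                raise ParameterError(f"planted pair residue {aa!r} not basic")
            aas[idx] = aa
            tips[idx] = tip
            cbs[idx] = ca[idx] + 1.53 * unit(tip - ca[idx])
        achieved = float(np.linalg.norm(t1 - t2))
        pair_indices.append((i, j))
        truth["pairs"].append(
            {
                "positions": [p1, p2],
                "aas": [pair.aa1, pair.aa2],
                "distance": round(achieved, 3),
            }
        )

    # --- planted candidate ---
    occluders: list[np.ndarray] = []
    cand = spec.planted_candidate
    if cand is not None:
        if not pair_indices:
            raise InfeasibleSpecError("candidate needs at least one planted pair")
        # two residues past the pair: from there the in-band tip direction
        # tilts back toward the anchors, i.e. outward-facing for a chain
        # segment left of the protein centroid
        i, j = pair_indices[0]
        c_pos = cand.position if cand.position is not None else (j + 1) + 2
        ci = c_pos - 1
        if not (0 <= ci < n) or ci in tips:
            raise InfeasibleSpecError(f"candidate position {c_pos} unavailable")
        anchor_tips = [tips[i], tips[j]]
        w, dists = _candidate_tip_direction(ca[ci], u[ci], anchor_tips, spec.band)
        aas[ci] = cand.aa
        cbs[ci] = ca[ci] + 1.53 * w
        if cand.buried:
            centers = [ca[ci], cbs[ci]]
            raw = _occluder_points(centers, rng, 3.3, 32) + _occluder_points(
                centers, rng, 4.8, 32
            )
            keep_clear = [tips[i], tips[j]]
            for p in raw:
                if all(np.linalg.norm(p - t) > 3.0 for t in keep_clear):
                    occluders.append(p)
        truth["candidate"] = {
            "position": c_pos,
            "aa": cand.aa,
            "anchor_positions": [i + 1, j + 1],
            "anchor_distances": [round(d, 3) for d in dists],
            "buried": cand.buried,
        }

    # --- assemble residues ---
    records = []
    for idx in range(n):
        atoms = _backbone_atoms(ca[idx], u[idx], tangent[idx])
        if idx in cbs:
            atoms["CB"] = cbs[idx]
        elif aas[idx] != "G":
            atoms["CB"] = ca[idx] + 1.53 * u[idx]
        if idx in tips:
            atoms[TIP_ATOM[aas[idx]]] = tips[idx]
        records.append(
            ResidueRecord(
                spec.chain_id,
                idx + 1,
                aas[idx],
                {k: np.asarray(v, dtype=float) for k, v in atoms.items()},
            )
        )
    # occluders ride along as extra single-atom residues of the filler type
    for k, p in enumerate(occluders):
        records.append(
            ResidueRecord(
                spec.chain_id,
                n + 1 + k,
                spec.filler_aa,
                {"C": np.asarray(p, dtype=float)},
            )
        )
    model = StructureModel(
        {spec.chain_id: records}, provenance=f"fixture:seed={spec.seed}"
    )
    truth["n_occluders"] = len(occluders)
    return model, truth


def hs_minus_mimic() -> tuple[StructureModel, dict]:
    """A fixture mimicking the published removal-design topology.

    Chain of 244 residues: an adjacent surface lysine pair at 42/43 forming
    a spatial cluster with a third anchor K239 (relocated next to the pair,
    as a fold would do), and a linear B-XXX-B-B motif on K239/K243/R244
    whose final three residues (242–244) are sequence-only — the modelled
    structure ends at 241, as when modelling software drops a disordered
    tail. K239 doubles as a member of both sites, which is why removal
    designs exclude it.
    """
    n_seq = 244
    n_modeled = 241
    spec = FixtureSpec(
        n_residues=n_modeled,
        geometry="line",
        planted_pairs=[PlantedPair("K", "K", 6.0, positions=(42, 43))],
        filler_aa="A",
        seed=8,
    )
    model, truth = generate_fixture(spec)
    records = model.chains["A"]
    ca42 = records[41].coord("CA")
    ca43 = records[42].coord("CA")
    mid = 0.5 * (ca42 + ca43)
    # relocate K239 beside the pair: side chain parallel to the pair's,
    # tip in band of K43's tip
    ca239 = np.array([mid[0], 0.5, 6.5])
    rec239 = records[238]
    rec239.aa = "K"
    rec239.atoms = {
        "N": ca239 + np.array([-1.2, -0.5, 0.0]),
        "CA": ca239,
        "C": ca239 + np.array([1.2, -0.5, 0.0]),
        "O": ca239 + np.array([1.2, -1.7, 0.0]),
        "CB": ca239 + np.array([0.0, 1.53, 0.0]),
        "NZ": ca239 + np.array([0.0, 5.3, 0.0]),
    }
    # full sequence: alanine background, K42/K43 pair, K239-XXX-K243-R244 tail
    seq = list("A" * n_seq)
    seq[41], seq[42] = "K", "K"
    seq[238], seq[242], seq[243] = "K", "K", "R"
    full = "".join(seq)
    from .structure import reconcile_sequence

    model = reconcile_sequence(model, {"A": full})
    truth["full_sequence_length"] = n_seq
    truth["motif"] = {"pattern": "BXXXBB", "positions": [239, 243, 244]}
    truth["cluster"] = {"positions": [42, 43, 239]}
    truth["unmodeled"] = [242, 243, 244]
    return model, truth


def write_fixture_pdb(model: StructureModel, path: str | Path) -> Path:
    """Write the model's modeled residues as a standards-conformant PDB.

    Raises :class:`SerialOverflowError` when the model exceeds the PDB
    fixed-width fields (residue numbers > 9999 or atom serials > 99999).
    """
    names, elements, coords, res_ids, res_names, chain_ids = [], [], [], [], [], []
    for res in model.residues():
        if not res.modeled:
            continue
        if res.auth_seq_num > 9999:
            raise SerialOverflowError(
                f"residue number {res.auth_seq_num} exceeds PDB capacity"
            )
        for name, xyz in res.atoms.items():
            names.append(name)
            elements.append(name.lstrip("0123456789")[0])
            coords.append(xyz)
            res_ids.append(res.auth_seq_num)
            res_names.append(one_to_three(res.aa))
            chain_ids.append(res.chain_id)
    if len(names) > 99999:
        raise SerialOverflowError(f"{len(names)} atoms exceed PDB serial capacity")
    arr = struc.AtomArray(len(names))
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.atom_name = np.asarray(names)
    arr.element = np.asarray(elements)
    arr.res_id = np.asarray(res_ids)
    arr.res_name = np.asarray(res_names)
    arr.chain_id = np.asarray(chain_ids)
    arr.hetero = np.zeros(len(names), dtype=bool)
    pdb_file = PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(path))
    return Path(path)
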