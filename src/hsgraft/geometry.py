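"""Small geometric primitives shared by the surface, cluster and design layers."""

from __future__ import annotations

import math

import numpy as np

from .errors import CannotProjectError, InfeasibleSpecError

#: Distance (Å) from Cα to the charged-group tip of an extended lysine
#: side chain (approximate Cα–NZ distance).
LYS_TIP_LENGTH = 5.5

#: Cα–Cβ bond length (Å).
CA_CB_LENGTH = 1.53


def unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n < 1e-9:
        raise CannotProjectError("zero-length direction vector")
    return v / n


def project_tip(
    ca: np.ndarray, cb: np.ndarray, length: float = LYS_TIP_LENGTH
) -> np.ndarray:
    """Pseudo-tip at ``length`` Å from Cα along the Cα→Cβ unit vector.

    A cheap stand-in for the charged group of a side chain that does not
    exist yet; no rotamer search is attempted.
    """
    return ca + unit(cb - ca) * length


def synthesize_gly_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Place an ideal Cβ for glycine from its backbone N, Cα, C atoms.

    The Cβ sits at tetrahedral geometry: in the plane bisecting N–Cα–C it is
    tilted out of the N–Cα–C plane, ~1.53 Å from Cα.
    """
    u_n = unit(n - ca)
    u_c = unit(c - ca)
    bisector = unit(u_n + u_c)
    normal_ = np.cross(u_c, u_n)
    if np.linalg.norm(normal_) < 1e-9:
        raise CannotProjectError("degenerate backbone: N, CA, C collinear")
    normal_ = unit(normal_)
    # ~125.3° split of the tetrahedral angle between the backbone-plane
    # component and the out-of-plane component.
    direction = unit(-bisector * math.cos(0.9599) + normal_ * math.sin(0.9599))
    return ca + direction * CA_CB_LENGTH


def trilaterate(
    centers: np.ndarray, radii: np.ndarray, prefer_direction: np.ndarray | None = None
) -> np.ndarray:
    """Point at given distances from three centers (sphere intersection).

    Of the (up to) two solutions, the one with the larger projection on
    ``prefer_direction`` is returned. Raises :class:`InfeasibleSpecError`
    when the spheres do not intersect.
    """
    p1, p2, p3 = (np.asarray(c, dtype=float) for c in centers)
    r1, r2, r3 = (float(r) for r in radii)
    ex = unit(p2 - p1)
    d = float(np.linalg.norm(p2 - p1))
    i = float(np.dot(ex, p3 - p1))
    ey_raw = p3 - p1 - i * ex
    if np.linalg.norm(ey_raw) < 1e-9:
        raise InfeasibleSpecError("trilateration centers are collinear")
    ey = unit(ey_raw)
    ez = np.cross(ex, ey)
    j = float(np.dot(ey, p3 - p1))
    x = (r1 * r1 - r2 * r2 + d * d) / (2 * d)
    y = (r1 * r1 - r3 * r3 + i * i + j * j) / (2 * j) - (i / j) * x
    z_sq = r1 * r1 - x * x - y * y
    if z_sq < -1e-6:
        raise InfeasibleSpecError("spheres do not intersect")
    z = math.sqrt(max(z_sq, 0.0))
    a = p1 + x * ex + y * ey + z * ez
    b = p1 + x * ex + y * ey - z * ez
    if prefer_direction is None:
        return a
    return a if np.dot(a, prefer_direction) >= np.dot(b, prefer_direction) else b


def rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about ``axis`` by ``angle`` radians."""
    ax = unit(np.asarray(axis, dtype=float))
    k = np.array(
        [[0, -ax[2], ax[1]], [ax[2], 0, -ax[0]], [-ax[1], ax[0], 0]]
    )
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)
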