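"""Geometric primitives under orthorhombic periodic boundary conditions.

All routines operate on coordinates in nm. Periodic boxes are restricted
to orthorhombic cells (three positive edge lengths); triclinic input is
rejected explicitly. Angles are reported in degrees in (-180, 180].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Superposition",
    "minimum_image",
    "minimum_image_distance",
    "unwrap_group",
    "center_of_mass",
    "angle",
    "dihedral",
    "kabsch",
]


def _check_box(box: np.ndarray) -> np.ndarray:
    box = np.asarray(box, dtype=float)
    if box.shape != (3,):
        raise ValueError(
            "only orthorhombic boxes (three edge lengths) are supported; "
            f"got shape {box.shape}"
        )
    if not np.all(box > 0):
        raise ValueError(f"box edges must be positive, got {box}")
    return box


def minimum_image(p, q, box) -> np.ndarray:
    """Minimum-image displacement ``p - q`` in an orthorhombic box.

    Each component of the result lies in ``(-box/2, +box/2]``.
    Accepts single points or ``(..., 3)`` arrays (broadcast).
    """
    box = _check_box(box)
    d = np.asarray(p, dtype=float) - np.asarray(q, dtype=float)
    d = d - box * np.floor(d / box + 0.5)
    # floor convention yields [-box/2, box/2); move the lower edge to +box/2
    lower = d <= -box / 2
    if np.any(lower):
        d = np.where(lower, d + box, d)
    return d


def minimum_image_distance(p, q, box) -> np.ndarray:
    """Euclidean norm of the minimum-image displacement."""
    return np.linalg.norm(minimum_image(p, q, box), axis=-1)


def unwrap_group(coords: np.ndarray, box, reference: np.ndarray) -> np.ndarray:
    """Unwrap ``coords`` so each point is the image nearest ``reference``.

    Suitable for compact groups (a protomer) whose physical extent is
    below half the box in every direction.
    """
    reference = np.asarray(reference, dtype=float)
    return reference + minimum_image(coords, reference, box)


def center_of_mass(
    coords: np.ndarray,
    box=None,
    reference: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Center of mass of a bead group, PBC-aware.

    When ``box`` is given, every bead is first mapped to its image
    nearest ``reference`` (default: the first bead), so a group split
    across the boundary yields a physically meaningful center. Weights
    default to uniform: MARTINI backbone beads carry near-identical
    masses, so the backbone center of mass is taken as the plain mean.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] == 0:
        raise ValueError("center_of_mass requires a non-empty (n, 3) array")
    if box is not None:
        if reference is None:
            reference = coords[0]
        coords = unwrap_group(coords, box, reference)
    return np.average(coords, axis=0, weights=weights)


def angle(p1, p2, p3) -> float:
    """Planar angle p1-p2-p3 in degrees, in [0, 180]."""
    v1 = np.asarray(p1, float) - np.asarray(p2, float)
    v2 = np.asarray(p3, float) - np.asarray(p2, float)
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("angle undefined: coincident points")
    c = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed IUPAC torsion angle about the p2-p3 axis, degrees in (-180, 180].

    Zero for the cis (eclipsed) arrangement; positive for a clockwise
    rotation of the far bond when sighting from p2 to p3.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n2 = np.linalg.norm(b2)
    if n2 == 0:
        raise ValueError("dihedral undefined: p2 and p3 coincide")
    n_a = np.cross(b1, b2)
    n_b = np.cross(b2, b3)
    if np.linalg.norm(n_a) < 1e-12 or np.linalg.norm(n_b) < 1e-12:
        raise ValueError("dihedral undefined: collinear bonded triple")
    x = np.dot(n_a, n_b)
    y = np.dot(np.cross(n_a, n_b), b2) / n2
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


def wrap_angle(a):
    """Wrap angle(s) in degrees into (-180, 180]."""
    a = np.asarray(a, dtype=float)
    w = a - 360.0 * np.floor(a / 360.0 + 0.5)
    w = np.where(w <= -180.0, w + 360.0, w)
    if w.ndim == 0:
        return float(w)
    return w


@dataclass(frozen=True)
class Superposition:
    """Optimal rigid-body superposition ``x ~ rotation @ y + translation``."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=float)
        if r.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-10):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation must be proper (det = +1)")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ np.asarray(self.rotation).T + self.translation


def kabsch(
    x: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None
) -> Superposition:
    """Least-squares proper superposition of ``y`` onto ``x`` (Kabsch).

    Reflections are suppressed: mirror-image point sets retain a
    non-zero RMSD. Raises on fewer than three points or on point sets
    of rank < 2 (all points collinear), for which the rotation is not
    unique.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("kabsch requires matching (n, 3) arrays")
    n = x.shape[0]
    if n < 3:
        raise ValueError("kabsch requires at least 3 points")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()
    xc = x - np.sum(w[:, None] * x, axis=0)
    yc = y - np.sum(w[:, None] * y, axis=0)
    h = (w[:, None] * yc).T @ xc
    u, s, vt = np.linalg.svd(h)
    # rank < 2 leaves the rotation about the degenerate axis undetermined
    if s[1] < 1e-12 * max(s[0], 1e-300):
        raise ValueError("degenerate (collinear) point set: rotation not unique")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    y_fit = yc @ rot.T
    rmsd = float(np.sqrt(np.sum(w[:, None] * (y_fit - xc) ** 2)))
    translation = np.sum(w[:, None] * x, axis=0) - rot @ np.sum(w[:, None] * y, axis=0)
    return Superposition(rotation=rot, translation=translation, rmsd=rmsd)


def superposed_rmsd(x: np.ndarray, y: np.ndarray) -> float:
    """RMSD of ``y`` on ``x`` after optimal proper superposition."""
    return kabsch(x, y).rmsd
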