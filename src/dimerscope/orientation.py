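"""Relative protomer orientation via the virtual bond construction.

Two rigid bodies with anchor triples (a, b, c) on protomer A and
(A, B, C) on protomer B are described by the six internal coordinates
of the chain c-b-a-A-B-C over the virtual bond a-A:

    d      = |a - A|
    theta1 = angle(b, a, A)        theta2 = angle(a, A, B)
    phi1   = dihedral(c, b, a, A)  phi3   = dihedral(a, A, B, C)
    phi2   = dihedral(b, a, A, B)

The anchors are the backbone beads of three structurally fixed
residues (Leu322, Ile393 and Thr456 in the dopamine transporter). For
a dimer that is exactly C2-symmetric about the membrane normal,
phi1 = phi3; swapping the protomer labels exchanges phi1 and phi3.
phi2 is bounded by the membrane (the protomers cannot tilt freely) and
is reported but rarely informative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import angle, dihedral
from .topology import Topology

__all__ = ["OrientationAngles", "vba_angles", "record_orientation"]


@dataclass(frozen=True)
class OrientationAngles:
    d: float          # nm
    theta1: float     # degrees, [0, 180]
    theta2: float
    phi1: float       # degrees, (-180, 180]
    phi2: float
    phi3: float

    def __post_init__(self):
        if self.d <= 0:
            raise ValueError("anchor distance must be positive")


def vba_angles(anchors_a: np.ndarray, anchors_b: np.ndarray) -> OrientationAngles:
    """Six rigid-body internal coordinates from two (3, 3) anchor sets.

    ``anchors_a`` rows are the (a, b, c) positions of protomer A,
    ``anchors_b`` the (A, B, C) positions of protomer B, in nm.
    Raises when a bonded anchor triple is collinear (torsion undefined).
    """
    anchors_a = np.asarray(anchors_a, dtype=float)
    anchors_b = np.asarray(anchors_b, dtype=float)
    if anchors_a.shape != (3, 3) or anchors_b.shape != (3, 3):
        raise ValueError("anchor sets must be (3, 3) arrays")
    a, b, c = anchors_a
    A, B, C = anchors_b
    return OrientationAngles(
        d=float(np.linalg.norm(a - A)),
        theta1=angle(b, a, A),
        theta2=angle(a, A, B),
        phi1=dihedral(c, b, a, A),
        phi2=dihedral(b, a, A, B),
        phi3=dihedral(a, A, B, C),
    )


def record_orientation(record, topology: Topology) -> OrientationAngles:
    """VBA angles of a :class:`~dimerscope.cluster.DimerRecord`."""
    i, j = record.pair
    ia = topology.proteins[i].anchor_bb_indices()
    ib = topology.proteins[j].anchor_bb_indices()
    return vba_angles(record.coords_a[ia], record.coords_b[ib])
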