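"""Lipid-accessible surface area (LASA) of coarse-grained beads.

Shrake-Rupley accessible surface: each bead is a sphere of its bead
radius plus a probe of 0.26 nm (the effective size of a lipid tail
bead); test points on the expanded sphere count as accessible when
outside every other expanded sphere. Per-bead areas are attributed to
the helix owning the bead. Interface burial of a dimer is

    dLASA = LASA(A alone) + LASA(B alone) - LASA(A u B),

which tends to zero as the protomers separate. Coordinates must be
whole (unwrapped); periodicity is deliberately not applied to surface
calculations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .topology import Topology, TM_LABELS

__all__ = ["SurfaceResult", "sphere_points", "shrake_rupley", "lasa",
           "lasa_profile", "delta_lasa"]

DEFAULT_PROBE = 0.26      # nm
DEFAULT_N_POINTS = 960


def sphere_points(n: int) -> np.ndarray:
    """~Uniform unit-sphere points (Fibonacci spiral), shape (n, 3)."""
    if n < 1:
        raise ValueError("need at least one sphere point")
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


def shrake_rupley(coords: np.ndarray, radii: np.ndarray,
                  probe: float = DEFAULT_PROBE,
                  n_points: int = DEFAULT_N_POINTS) -> np.ndarray:
    """Per-bead accessible surface areas (nm^2)."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.shape[0] != radii.shape[0]:
        raise ValueError("one radius per bead required")
    if probe < 0:
        raise ValueError("probe radius must be >= 0")
    n = coords.shape[0]
    expanded = radii + probe
    unit = sphere_points(n_points)
    areas = np.empty(n)
    # neighbor prescreen on expanded spheres
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt(np.sum(diff**2, axis=-1))
    for i in range(n):
        reach = expanded[i] + expanded
        neigh = np.flatnonzero((dist[i] < reach) & (np.arange(n) != i))
        full = 4.0 * np.pi * expanded[i] ** 2
        if neigh.size == 0:
            areas[i] = full
            continue
        pts = coords[i] + expanded[i] * unit
        d2 = np.sum((pts[:, None, :] - coords[neigh][None, :, :]) ** 2, axis=-1)
        buried = np.any(d2 < expanded[neigh][None, :] ** 2, axis=1)
        areas[i] = full * float(np.mean(~buried))
    return areas


@dataclass
class SurfaceResult:
    """Per-helix LASA with across-frame statistics (nm^2)."""

    per_helix_mean: dict
    per_helix_sd: dict
    total_mean: float
    n_frames: int
    probe: float
    n_points: int


def lasa(coords: np.ndarray, topology: Topology, protein: int,
         probe: float = DEFAULT_PROBE, n_points: int = DEFAULT_N_POINTS,
         selection: np.ndarray | None = None) -> dict:
    """Per-helix LASA of one protein in one frame.

    ``coords`` are that protein's bead coordinates (whole). The
    occluding environment is the protein itself (plus any extra
    ``selection`` coordinates appended by the caller beforehand is not
    supported here; see :func:`delta_lasa` for dimer burial).
    """
    model = topology.proteins[protein]
    if coords.shape[0] != model.n_beads:
        raise ValueError("coords must cover exactly this protein's beads")
    radii = topology.radii_array(protein)
    areas = shrake_rupley(coords, radii, probe=probe, n_points=n_points)
    out = {}
    for label in TM_LABELS:
        if label not in model.helix_map:
            continue
        idx = model.helix_bb_indices(label)
        out[label] = float(areas[idx].sum())
    return out


def lasa_profile(frames, topology: Topology, protein: int = 0,
                 probe: float = DEFAULT_PROBE,
                 n_points: int = DEFAULT_N_POINTS,
                 stride: int = 1) -> SurfaceResult:
    """Across-frame mean and SD of per-helix LASA for one protein."""
    per_frame: list[dict] = []
    for k, frame in enumerate(frames):
        if k % stride:
            continue
        coords = frame.coords[topology.protein_slice(protein)]
        # make the protomer whole relative to its first bead
        from .geometry import unwrap_group

        coords = unwrap_group(coords, frame.box, coords[0])
        per_frame.append(lasa(coords, topology, protein, probe=probe,
                              n_points=n_points))
    if not per_frame:
        raise ValueError("no frames to analyze")
    labels = list(per_frame[0])
    stacked = {lb: np.array([pf[lb] for pf in per_frame]) for lb in labels}
    return SurfaceResult(
        per_helix_mean={lb: float(v.mean()) for lb, v in stacked.items()},
        per_helix_sd={lb: float(v.std(ddof=0)) for lb, v in stacked.items()},
        total_mean=float(np.sum([v.mean() for v in stacked.values()])),
        n_frames=len(per_frame),
        probe=probe,
        n_points=n_points,
    )


def delta_lasa(coords_a: np.ndarray, coords_b: np.ndarray,
               radii_a: np.ndarray, radii_b: np.ndarray,
               probe: float = DEFAULT_PROBE,
               n_points: int = DEFAULT_N_POINTS) -> float:
    """Interface burial LASA(A) + LASA(B) - LASA(A u B) in nm^2."""
    a = shrake_rupley(coords_a, radii_a, probe=probe, n_points=n_points).sum()
    b = shrake_rupley(coords_b, radii_b, probe=probe, n_points=n_points).sum()
    both = shrake_rupley(
        np.vstack([coords_a, coords_b]),
        np.concatenate([radii_a, radii_b]),
        probe=probe, n_points=n_points,
    ).sum()
    return float(a + b - both)


def record_delta_lasa(record, topology: Topology,
                      probe: float = DEFAULT_PROBE,
                      n_points: int = DEFAULT_N_POINTS) -> float:
    """dLASA of a :class:`~dimerscope.cluster.DimerRecord`."""
    i, j = record.pair
    return delta_lasa(record.coords_a, record.coords_b,
                      topology.radii_array(i), topology.radii_array(j),
                      probe=probe, n_points=n_points)
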