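"""3D occupancy grids (fraction of frames a selection occupies a voxel).

A voxel counts as occupied in a frame when its center lies within the
bead radius (default 0.26 nm, i.e. system beads rendered at 2.6 A) of
any selected bead center. Frames are expected to be superposed onto a
common reference (e.g. a cluster's central structure) by the caller.
Grids are written in OpenDX format for rendering in VMD/PyMOL.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["OccupancyGrid", "occupancy_grid", "write_opendx"]


@dataclass
class OccupancyGrid:
    origin: np.ndarray        # nm, lower corner of the grid
    voxel: float              # nm, cubic voxel edge
    values: np.ndarray        # (nx, ny, nz) occupancy fractions in [0, 1]

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("occupancy values must lie in [0, 1]")

    def centers(self):
        """Voxel center coordinate axes (three 1D arrays)."""
        return tuple(
            self.origin[k] + (np.arange(self.values.shape[k]) + 0.5) * self.voxel
            for k in range(3)
        )


def occupancy_grid(coord_frames, voxel: float = 0.1,
                   bead_radius: float = 0.26,
                   bounds=None) -> OccupancyGrid:
    """Occupancy grid over a sequence of per-frame bead coordinates.

    ``coord_frames`` is an iterable of (n_i, 3) arrays (the selected
    beads of each frame, already aligned). The grid covers the
    selection's bounding box expanded by the bead radius unless
    explicit ``bounds`` (lo, hi) are given.
    """
    if voxel <= 0:
        raise ValueError("voxel edge must be positive")
    frames = [np.atleast_2d(np.asarray(c, dtype=float)) for c in coord_frames]
    if not frames or any(c.size == 0 for c in frames):
        raise ValueError("empty selection")
    if bounds is None:
        lo = np.min([c.min(axis=0) for c in frames], axis=0) - bead_radius
        hi = np.max([c.max(axis=0) for c in frames], axis=0) + bead_radius
    else:
        lo, hi = (np.asarray(b, dtype=float) for b in bounds)
    shape = np.maximum(np.ceil((hi - lo) / voxel).astype(int), 1)
    counts = np.zeros(shape, dtype=np.int64)
    r2 = bead_radius**2
    reach = int(np.ceil(bead_radius / voxel)) + 1
    axes = [lo[k] + (np.arange(shape[k]) + 0.5) * voxel for k in range(3)]
    for coords in frames:
        occupied = np.zeros(shape, dtype=bool)
        for p in coords:
            idx = np.floor((p - lo) / voxel).astype(int)
            sl = [slice(max(idx[k] - reach, 0), min(idx[k] + reach + 1, shape[k]))
                  for k in range(3)]
            dx = axes[0][sl[0]] - p[0]
            dy = axes[1][sl[1]] - p[1]
            dz = axes[2][sl[2]] - p[2]
            d2 = (dx[:, None, None] ** 2 + dy[None, :, None] ** 2
                  + dz[None, None, :] ** 2)
            occupied[sl[0], sl[1], sl[2]] |= d2 <= r2
        counts += occupied
    return OccupancyGrid(origin=lo, voxel=voxel,
                         values=counts / float(len(frames)))


def write_opendx(grid: OccupancyGrid, path, comment: str = "") -> None:
    """Write the grid as an OpenDX scalar field (lengths in Angstrom)."""
    nx, ny, nz = grid.values.shape
    scale = 10.0  # nm -> Angstrom, the unit volumetric viewers expect
    origin = grid.origin * scale
    delta = grid.voxel * scale
    flat = grid.values.reshape(-1)  # x fastest-varying last (C order: z fastest)
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {origin[0]:.6f} {origin[1]:.6f} {origin[2]:.6f}\n")
        fh.write(f"delta {delta:.6f} 0 0\n")
        fh.write(f"delta 0 {delta:.6f} 0\n")
        fh.write(f"delta 0 0 {delta:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {flat.size} "
            "data follows\n"
        )
        for k in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.6g}" for v in flat[k:k + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "occupancy" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')
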