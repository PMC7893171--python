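"""Dimer extraction, symmetrization and GROMOS conformational clustering.

Every protein pair within a 5.3 nm backbone center-of-mass cutoff is
extracted from every frame as a :class:`DimerRecord` (protomer B made
whole relative to protomer A). Records are symmetrized by swapping the
A/B labels, so symmetry-related dimer pairs cluster together; the
combined set is clustered with the GROMOS (Daura) algorithm at a
0.4 nm RMSD cutoff: the record with the most neighbors within the
cutoff seeds a cluster, it and its neighbors are removed, and the
procedure repeats. RMSD uses optimal whole-dimer superposition on all
backbone beads of both protomers. Clusters whose central members map
onto each other under the A/B swap are reported as symmetry pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import center_of_mass, kabsch, minimum_image, unwrap_group
from .topology import Topology

__all__ = [
    "DimerRecord",
    "ClusterInfo",
    "ClusterResult",
    "extract_dimers",
    "symmetrize",
    "gromos_cluster",
    "symmetry_pairs",
    "name_interface",
]

DEFAULT_COM_CUTOFF = 5.3   # nm
DEFAULT_RMSD_CUTOFF = 0.4  # nm


@dataclass
class DimerRecord:
    """An unwrapped protomer pair from one frame; the clustering unit."""

    frame_index: int
    time: float
    pair: tuple[int, int]       # protein indices, i < j
    coords_a: np.ndarray        # whole protomer A (nm)
    coords_b: np.ndarray        # whole protomer B, image nearest A
    com_distance: float
    swapped: bool = False

    def swap(self) -> "DimerRecord":
        return replace(self, coords_a=self.coords_b, coords_b=self.coords_a,
                       swapped=not self.swapped)


def extract_dimers(frames, topology: Topology,
                   com_cutoff: float = DEFAULT_COM_CUTOFF,
                   stride: int = 1) -> list[DimerRecord]:
    """All protein pairs within the backbone-COM cutoff, every frame.

    Each protomer is made whole by minimum-image unwrapping relative to
    its first bead; protomer B is then shifted to the periodic image
    nearest protomer A's center of mass.
    """
    if topology.n_proteins < 2:
        raise ValueError("dimer extraction requires at least two proteins")
    bb_local = [p.bb_indices() for p in topology.proteins]
    records: list[DimerRecord] = []
    for k, frame in enumerate(frames):
        if k % stride:
            continue
        frame.validate(topology)
        whole = []
        coms = []
        for i in range(topology.n_proteins):
            c = frame.coords[topology.protein_slice(i)]
            c = unwrap_group(c, frame.box, c[0])
            whole.append(c)
            coms.append(center_of_mass(c[bb_local[i]]))
        for i in range(topology.n_proteins):
            for j in range(i + 1, topology.n_proteins):
                sep = minimum_image(coms[j], coms[i], frame.box)
                dist = float(np.linalg.norm(sep))
                if dist > com_cutoff:
                    continue
                shift = (coms[i] + sep) - coms[j]
                records.append(DimerRecord(
                    frame_index=k, time=frame.time, pair=(i, j),
                    coords_a=whole[i].copy(), coords_b=whole[j] + shift,
                    com_distance=dist,
                ))
    return records


def symmetrize(records) -> list[DimerRecord]:
    """Append the A/B label-swapped copy of every record (count doubles)."""
    records = list(records)
    return records + [r.swap() for r in records]


def _fit_coords(record: DimerRecord, topology: Topology,
                fit_selection: str = "bb") -> np.ndarray:
    i, j = record.pair
    if fit_selection == "bb":
        la = topology.proteins[i].bb_indices()
        lb = topology.proteins[j].bb_indices()
    elif fit_selection == "all":
        la = np.arange(record.coords_a.shape[0])
        lb = np.arange(record.coords_b.shape[0])
    else:
        raise ValueError(f"unknown fit selection {fit_selection!r}")
    # for swapped records, A holds protein j's coordinates; identical
    # protomer models make the index sets interchangeable
    return np.vstack([record.coords_a[la], record.coords_b[lb]])


@dataclass
class ClusterInfo:
    cluster_id: int
    members: np.ndarray         # record indices
    central: int                # record index of the central member
    size_pct: float             # % of the clustered record count


@dataclass
class ClusterResult:
    assignment: np.ndarray      # record index -> cluster id
    clusters: list[ClusterInfo]
    rmsd_cutoff: float
    rmsd_matrix: np.ndarray = field(repr=False, default=None)
    symmetry_pairs: list[tuple[int, int]] = field(default_factory=list)
    interface_labels: dict = field(default_factory=dict)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([c.size_pct for c in self.clusters])


def pairwise_rmsd_matrix(records, topology: Topology,
                         fit_selection: str = "bb") -> np.ndarray:
    """Dense pairwise RMSD after optimal whole-dimer superposition."""
    fits = [_fit_coords(r, topology, fit_selection) for r in records]
    m = len(fits)
    rmsd = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            rmsd[i, j] = rmsd[j, i] = kabsch(fits[i], fits[j]).rmsd
    return rmsd


def gromos_cluster(records, topology: Topology,
                   rmsd_cutoff: float = DEFAULT_RMSD_CUTOFF,
                   fit_selection: str = "bb",
                   rmsd_matrix: np.ndarray | None = None) -> ClusterResult:
    """GROMOS (Daura) neighbor-count clustering of dimer records.

    Ties in the neighbor count are broken toward the lowest record
    index, making the result deterministic and order-independent up to
    exact ties.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to cluster")
    if rmsd_cutoff <= 0:
        raise ValueError("rmsd_cutoff must be positive")
    if rmsd_matrix is None:
        rmsd_matrix = pairwise_rmsd_matrix(records, topology, fit_selection)
    m = len(records)
    neighbors = rmsd_matrix < rmsd_cutoff
    np.fill_diagonal(neighbors, False)
    alive = np.ones(m, dtype=bool)
    assignment = np.full(m, -1, dtype=int)
    clusters: list[ClusterInfo] = []
    cid = 0
    while alive.any():
        counts = (neighbors & alive[None, :]).sum(axis=1)
        counts[~alive] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(alive & (neighbors[center] |
                                          (np.arange(m) == center)))
        assignment[members] = cid
        clusters.append(ClusterInfo(
            cluster_id=cid, members=members, central=center,
            size_pct=100.0 * members.size / m,
        ))
        alive[members] = False
        cid += 1
    return ClusterResult(assignment=assignment, clusters=clusters,
                         rmsd_cutoff=rmsd_cutoff, rmsd_matrix=rmsd_matrix)


def symmetry_pairs(result: ClusterResult, records, topology: Topology,
                   rmsd_cutoff: float | None = None,
                   fit_selection: str = "bb"):
    """Identify clusters mapped onto each other by the A/B swap.

    Returns (pairs, self_symmetric): mutually paired cluster-id tuples
    and the ids whose central member superposes onto its own swap
    (a C2-symmetric interface). Results are stored on ``result``.
    """
    cutoff = result.rmsd_cutoff if rmsd_cutoff is None else rmsd_cutoff
    records = list(records)
    centrals = {c.cluster_id: records[c.central] for c in result.clusters}
    fit = {cid: _fit_coords(r, topology, fit_selection)
           for cid, r in centrals.items()}
    fit_swap = {cid: _fit_coords(r.swap(), topology, fit_selection)
                for cid, r in centrals.items()}
    pairs = []
    self_symmetric = []
    ids = sorted(centrals)
    for i in ids:
        if kabsch(fit[i], fit_swap[i]).rmsd < cutoff:
            self_symmetric.append(i)
    # a self-paired (C2) cluster is its own partner; only clusters that do
    # not map onto themselves can form mutual swap pairs
    candidates = [i for i in ids if i not in self_symmetric]
    for a_i, i in enumerate(candidates):
        for j in candidates[a_i + 1:]:
            if kabsch(fit[j], fit_swap[i]).rmsd < cutoff:
                pairs.append((i, j))
    result.symmetry_pairs = pairs
    return pairs, self_symmetric


def name_interface(record: DimerRecord, topology: Topology,
                   cutoff: float = 0.7) -> str:
    """Interface label: contacting helices of A, "/", then of B.

    Helices are listed ascending and comma-joined, e.g.
    ``"TM4,TM9/TM11"``; ``"none"`` when no interprotein helix contact
    exists within the cutoff. Backbone beads only.
    """
    i, j = record.pair
    model_a = topology.proteins[i]
    model_b = topology.proteins[j]
    bb_b = record.coords_b[model_b.bb_indices()]
    bb_a = record.coords_a[model_a.bb_indices()]

    def contacting(model, own, other):
        out = []
        for label in sorted(model.helix_map,
                            key=lambda s: int(s[2:]) if s[2:].isdigit() else 99):
            if not label.startswith("TM"):
                continue
            idx = model.helix_bb_indices(label)
            d = np.linalg.norm(own[idx][:, None, :] - other[None, :, :], axis=-1)
            if d.min() < cutoff:
                out.append(label)
        return out

    helices_a = contacting(model_a, record.coords_a, bb_b)
    helices_b = contacting(model_b, record.coords_b, bb_a)
    if not helices_a and not helices_b:
        return "none"
    return ",".join(helices_a) + "/" + ",".join(helices_b)
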