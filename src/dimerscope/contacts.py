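"""Interprotein contact analysis: helix contact maps, contact time
series, interface lifetime events and residue-exclusion statistics.

A contact between two bead groups means their minimum bead-bead
center distance (minimum image) is strictly below the cutoff, 0.7 nm
by default. Helix contact maps tally presence/absence per helix pair
per frame per ordered protein pair and are symmetric by construction;
the per-helix marginals report each helix's share of unique contacts
in %, so the marginals sum to 200% of the map total (every contact has
two participating helices).

The neighbor search uses periodic cell lists with cell edge >= cutoff;
its results are exactly equal to the brute-force double loop, which is
kept available (``brute_force=True``) as the validation oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import minimum_image
from .topology import Topology, TM_LABELS

__all__ = [
    "ContactMap",
    "ContactSeries",
    "min_distance",
    "contact_pairs",
    "helix_contact_map",
    "normalize_map",
    "helix_group",
    "contact_series",
    "interface_events",
    "exclusion_frame_drop",
]


# ------------------------------------------------------------ neighbor search

def min_distance(ca: np.ndarray, cb: np.ndarray, box=None) -> float:
    """Minimum bead-bead distance between two coordinate sets."""
    ca = np.atleast_2d(ca)
    cb = np.atleast_2d(cb)
    if box is None:
        diff = ca[:, None, :] - cb[None, :, :]
    else:
        diff = minimum_image(ca[:, None, :], cb[None, :, :], box)
    return float(np.sqrt(np.min(np.sum(diff**2, axis=-1))))


def _brute_pairs(ca, cb, box, cutoff):
    if box is None:
        diff = ca[:, None, :] - cb[None, :, :]
    else:
        diff = minimum_image(ca[:, None, :], cb[None, :, :], box)
    d2 = np.sum(diff**2, axis=-1)
    ia, ib = np.nonzero(d2 < cutoff**2)
    return ia, ib


def _cell_pairs(ca, cb, box, cutoff):
    box = np.asarray(box, dtype=float)
    n_cells = np.maximum(np.floor(box / cutoff).astype(int), 1)
    if np.any(n_cells < 3):
        # too few cells for a unique 27-neighborhood; fall back
        return _brute_pairs(ca, cb, box, cutoff)
    edge = box / n_cells
    cb_wrapped = np.mod(cb, box)
    cells_b = np.minimum((cb_wrapped / edge).astype(int), n_cells - 1)
    flat_b = np.ravel_multi_index(cells_b.T, n_cells)
    order = np.argsort(flat_b, kind="stable")
    sorted_flat = flat_b[order]
    starts = np.searchsorted(sorted_flat, np.arange(np.prod(n_cells)))
    ends = np.searchsorted(sorted_flat, np.arange(np.prod(n_cells)), side="right")

    ca_wrapped = np.mod(ca, box)
    cells_a = np.minimum((ca_wrapped / edge).astype(int), n_cells - 1)
    offsets = np.array([(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                        for k in (-1, 0, 1)])
    out_a, out_b = [], []
    cut2 = cutoff**2
    for ia in range(ca.shape[0]):
        neigh = np.mod(cells_a[ia] + offsets, n_cells)
        flat = np.ravel_multi_index(neigh.T, n_cells)
        cand = np.concatenate([order[starts[f]:ends[f]] for f in np.unique(flat)])
        if cand.size == 0:
            continue
        diff = minimum_image(ca[ia], cb[cand], box)
        hit = np.sum(diff**2, axis=-1) < cut2
        for ib in cand[hit]:
            out_a.append(ia)
            out_b.append(int(ib))
    return np.asarray(out_a, dtype=int), np.asarray(out_b, dtype=int)


def contact_pairs(ca: np.ndarray, cb: np.ndarray, box, cutoff: float,
                  brute_force: bool = False):
    """Index pairs (i, j) with |ca_i - cb_j| < cutoff (minimum image)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ca = np.atleast_2d(np.asarray(ca, float))
    cb = np.atleast_2d(np.asarray(cb, float))
    if brute_force or box is None:
        return _brute_pairs(ca, cb, box, cutoff)
    return _cell_pairs(ca, cb, box, cutoff)


# -------------------------------------------------------------- contact maps

@dataclass
class ContactMap:
    """Symmetrized 12x12 interprotein helix-pair contact tallies."""

    counts: np.ndarray
    normalization_total: float
    cutoff: float
    n_frames: int
    labels: tuple[str, ...] = TM_LABELS

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.labels),) * 2:
            raise ValueError("counts must be n_helix x n_helix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(self.counts, self.counts.T):
            raise ValueError("counts must be symmetric")

    @property
    def total(self) -> float:
        """Unique-contact total: half the ordered-pair tally sum."""
        return float(self.counts.sum()) / 2.0

    @property
    def per_helix_totals(self) -> np.ndarray:
        """Each helix's share of unique contacts in % (sums to 200%)."""
        t = self.total
        if t == 0:
            return np.zeros(len(self.labels))
        return 100.0 * self.counts.sum(axis=1) / t


def helix_contact_map(frames, topology: Topology, cutoff: float = 0.7,
                      brute_force: bool = False) -> ContactMap:
    """Per-helix interprotein contact map over all protein pairs/frames.

    A helix pair (i, j) tallies one count per frame per ordered protein
    pair whose minimum inter-helix BB bead distance is below the
    cutoff; palm beads are never part of helix groups here.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if topology.n_proteins < 2:
        raise ValueError("contact maps require at least two proteins")
    n_h = len(TM_LABELS)
    # per-protein bead -> helix id (-1 for non-TM / palm beads)
    model = topology.proteins[0]
    helix_of = np.full(model.n_beads, -1, dtype=int)
    for h, label in enumerate(TM_LABELS):
        if label in model.helix_map:
            helix_of[model.helix_bb_indices(label)] = h
    counts = np.zeros((n_h, n_h))
    n_frames = 0
    for frame in frames:
        frame.validate(topology)
        n_frames += 1
        for m in range(topology.n_proteins):
            cm = frame.coords[topology.protein_slice(m)]
            for n in range(m + 1, topology.n_proteins):
                cn = frame.coords[topology.protein_slice(n)]
                ia, ib = contact_pairs(cm, cn, frame.box, cutoff,
                                       brute_force=brute_force)
                if ia.size == 0:
                    continue
                ha, hb = helix_of[ia], helix_of[ib]
                ok = (ha >= 0) & (hb >= 0)
                seen = np.zeros((n_h, n_h))
                seen[ha[ok], hb[ok]] = 1.0
                counts += seen + seen.T  # ordered-pair accumulation
    return ContactMap(counts=counts, normalization_total=counts.sum(),
                      cutoff=cutoff, n_frames=n_frames)


def normalize_map(cmap: ContactMap, reference_total: float) -> ContactMap:
    """Divide every tally by ``reference_total`` (cross-system reference)."""
    if reference_total <= 0:
        raise ValueError("reference_total must be positive")
    return ContactMap(
        counts=cmap.counts / reference_total,
        normalization_total=reference_total,
        cutoff=cmap.cutoff,
        n_frames=cmap.n_frames,
        labels=cmap.labels,
    )


# ------------------------------------------------------------ contact series

def helix_group(topology: Topology, protein: int, label: str,
                include_attached: bool = True) -> np.ndarray:
    """Global bead indices of one helix of one protein.

    With ``include_attached`` (default) all beads of the helix residues
    are selected, so a palm chain anchored on a helix residue is part
    of that helix's contact group; set False for backbone beads only.
    """
    model = topology.proteins[protein]
    if include_attached:
        local = model.bead_indices(residues=model.helix_map[label])
    else:
        local = model.helix_bb_indices(label)
    return topology.global_indices(protein, local)


@dataclass
class ContactSeries:
    """Per-frame minimum distance between two bead groups."""

    pair: str
    times: np.ndarray
    min_distance: np.ndarray
    cutoff: float
    excluded_residues: tuple[int, ...] = ()

    @property
    def flags(self) -> np.ndarray:
        return self.min_distance < self.cutoff


def _apply_exclusion(topology: Topology, group: np.ndarray,
                     exclude_residues) -> np.ndarray:
    if not exclude_residues:
        return group
    excl = set(exclude_residues)
    resid_of = np.empty(topology.n_beads_total, dtype=int)
    for i, prot in enumerate(topology.proteins):
        off = topology.protein_offset(i)
        for b in prot.beads:
            resid_of[off + b.bead_id] = b.residue_number
    keep = np.array([resid_of[g] not in excl for g in group])
    return group[keep]


def contact_series(frames, topology: Topology, group_a, group_b,
                   cutoff: float = 0.7, exclude_residues=(),
                   pair: str = "") -> ContactSeries:
    """Minimum-distance time series between two bead groups.

    ``exclude_residues`` removes every bead carrying those residue
    numbers from both groups (palm beads inherit their anchor's residue
    number, so excluding the palmitoylation site also removes the
    chain).
    """
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if np.intersect1d(group_a, group_b).size:
        raise ValueError("contact groups must be disjoint")
    group_a = _apply_exclusion(topology, group_a, exclude_residues)
    group_b = _apply_exclusion(topology, group_b, exclude_residues)
    if group_a.size == 0 or group_b.size == 0:
        raise ValueError("a contact group is empty after residue exclusion")
    times, dists = [], []
    for frame in frames:
        times.append(frame.time)
        dists.append(min_distance(frame.coords[group_a],
                                  frame.coords[group_b], frame.box))
    return ContactSeries(pair=pair, times=np.asarray(times),
                         min_distance=np.asarray(dists), cutoff=cutoff,
                         excluded_residues=tuple(sorted(exclude_residues)))


@dataclass
class InterfaceEvent:
    start_frame: int
    end_frame: int          # inclusive
    start: float            # ns
    end: float              # ns, time of the last in-contact frame
    duration: float         # ns, n_frames * frame spacing

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


def interface_events(series: ContactSeries, min_duration: float = 500.0):
    """Maximal runs of consecutive in-contact frames lasting at least
    ``min_duration`` ns.

    A run of k frames at spacing dt counts as k*dt ns of contact.
    Returns (events, summary) where summary reports the qualifying
    event count and the total number of in-contact frames inside
    qualifying events. Frames must be uniformly spaced.
    """
    t = series.times
    if t.size > 1:
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("frames are not uniformly spaced; resample upstream")
        spacing = float(dt[0])
    else:
        spacing = 0.0
    flags = series.flags
    events = []
    start = None
    for i, f in enumerate(np.append(flags, False)):
        if f and start is None:
            start = i
        elif not f and start is not None:
            n = i - start
            dur = n * spacing if spacing else 0.0
            if dur >= min_duration:
                events.append(InterfaceEvent(
                    start_frame=start, end_frame=i - 1,
                    start=float(t[start]), end=float(t[i - 1]), duration=dur,
                ))
            start = None
    summary = {
        "n_events": len(events),
        "contact_frames": int(sum(e.n_frames for e in events)),
        "total_contact_frames": int(flags.sum()),
        "min_duration": min_duration,
    }
    return events, summary


def exclusion_frame_drop(frames, topology: Topology, pairs, residue: int,
                         cutoff: float = 0.7, min_duration: float = 0.0) -> float:
    """Percent loss of in-contact frames when one residue is excluded.

    ``pairs`` is a sequence of (group_a, group_b) global-index pairs.
    For every pair the series is computed with and without ``residue``
    (and the palm beads carrying its residue number); pairs qualify via
    the inclusive series when ``min_duration`` > 0. Returns
    ``100 * (F_incl - F_excl) / F_incl`` over qualifying pairs.
    """
    frames = list(frames)
    f_incl = 0
    f_excl = 0
    for k, (ga, gb) in enumerate(pairs):
        s_in = contact_series(frames, topology, ga, gb, cutoff=cutoff,
                              pair=f"pair{k}")
        if min_duration > 0:
            events, _ = interface_events(s_in, min_duration)
            if not events:
                continue
        try:
            s_ex = contact_series(frames, topology, ga, gb, cutoff=cutoff,
                                  exclude_residues=(residue,), pair=f"pair{k}")
            excl_frames = int(s_ex.flags.sum())
        except ValueError:
            excl_frames = 0  # group vanished entirely with the residue
        f_incl += int(s_in.flags.sum())
        f_excl += excl_frames
    if f_incl == 0:
        raise ValueError("no in-contact frames: the frame drop is undefined")
    return 100.0 * (f_incl - f_excl) / f_incl
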