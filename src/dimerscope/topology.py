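"""Bead-resolved coarse-grained protein models and system topology.

A system is an ordered collection of structurally identical proteins
(protomers). Each protein knows its beads, its transmembrane-helix
assignment (labels ``TM1``..``TM12`` plus optional ``loop``, ``C-term``
and ``palm`` entries), its three orientation-anchor residues and any
named special residues (e.g. the palmitoylation site). Bead indices are
0-based internally; file formats (GRO/NDX) use 1-based indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np

__all__ = ["Bead", "ProteinModel", "Topology", "Frame", "IndexGroups", "TM_LABELS"]

#: Canonical transmembrane helix labels in order.
TM_LABELS = tuple(f"TM{i}" for i in range(1, 13))


class Bead(NamedTuple):
    bead_id: int          # 0-based index within the protein
    residue_number: int   # 1-based residue number within the protein
    residue_name: str
    bead_name: str        # "BB" for backbone beads


@dataclass(frozen=True)
class ProteinModel:
    """One protomer: beads plus helix/anchor annotation."""

    beads: tuple[Bead, ...]
    helix_map: Mapping[str, frozenset[int]]
    anchors: tuple[int, int, int]
    special_residues: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        residues = {b.residue_number for b in self.beads}
        for label, resids in self.helix_map.items():
            missing = set(resids) - residues
            if missing:
                raise ValueError(
                    f"helix {label!r} references residues absent from the "
                    f"protein: {sorted(missing)}"
                )
        if len(set(self.anchors)) != 3:
            raise ValueError(f"anchors must be three distinct residues, got {self.anchors}")
        for a in self.anchors:
            if not any(b.residue_number == a and b.bead_name == "BB" for b in self.beads):
                raise ValueError(f"anchor residue {a} has no BB bead")
        # helix assignments must not overlap between TM labels
        seen: dict[int, str] = {}
        for label, resids in self.helix_map.items():
            if not label.startswith("TM"):
                continue
            for r in resids:
                if r in seen:
                    raise ValueError(
                        f"residue {r} assigned to both {seen[r]} and {label}"
                    )
                seen[r] = label

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    def bead_indices(
        self,
        residues: Iterable[int] | None = None,
        bead_names: Iterable[str] | None = None,
    ) -> np.ndarray:
        """Local 0-based bead indices filtered by residue and/or bead name."""
        res = None if residues is None else set(residues)
        names = None if bead_names is None else set(bead_names)
        out = [
            b.bead_id
            for b in self.beads
            if (res is None or b.residue_number in res)
            and (names is None or b.bead_name in names)
        ]
        return np.asarray(out, dtype=int)

    def bb_indices(self) -> np.ndarray:
        return self.bead_indices(bead_names=("BB",))

    def helix_bb_indices(self, label: str) -> np.ndarray:
        """BB beads of one helix; palm/side-chain beads never included."""
        return self.bead_indices(residues=self.helix_map[label], bead_names=("BB",))

    def anchor_bb_indices(self) -> np.ndarray:
        out = []
        for a in self.anchors:
            idx = self.bead_indices(residues=(a,), bead_names=("BB",))
            out.append(int(idx[0]))
        return np.asarray(out, dtype=int)


@dataclass(frozen=True)
class Topology:
    """Ordered homo-oligomeric system of identical protomers."""

    proteins: tuple[ProteinModel, ...]
    bead_radius_map: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.proteins:
            raise ValueError("topology requires at least one protein")
        first = self.proteins[0]
        for i, p in enumerate(self.proteins):
            if p.n_beads != first.n_beads:
                raise ValueError(
                    f"protein {i} has {p.n_beads} beads, expected {first.n_beads}"
                )
            if set(p.helix_map) != set(first.helix_map):
                raise ValueError(f"protein {i} helix labels differ from protein 0")

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def n_beads_total(self) -> int:
        return sum(p.n_beads for p in self.proteins)

    def protein_offset(self, i: int) -> int:
        return sum(p.n_beads for p in self.proteins[:i])

    def protein_slice(self, i: int) -> slice:
        off = self.protein_offset(i)
        return slice(off, off + self.proteins[i].n_beads)

    def global_indices(self, i: int, local: np.ndarray) -> np.ndarray:
        return np.asarray(local, dtype=int) + self.protein_offset(i)

    def bead_radius(self, bead_name: str) -> float:
        try:
            return self.bead_radius_map[bead_name]
        except KeyError:
            raise KeyError(f"no radius defined for bead type {bead_name!r}") from None

    def radii_array(self, protein: int | None = None) -> np.ndarray:
        """Per-bead radii (nm), for one protein or the whole system."""
        prots = self.proteins if protein is None else (self.proteins[protein],)
        return np.asarray(
            [self.bead_radius(b.bead_name) for p in prots for b in p.beads],
            dtype=float,
        )


@dataclass
class Frame:
    """One coordinate set: time (ns), orthorhombic box (nm), coords (nm)."""

    time: float
    box: np.ndarray
    coords: np.ndarray

    def __post_init__(self):
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if not np.all(self.box > 0):
            raise ValueError(f"box edges must be positive, got {self.box}")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")

    def validate(self, topology: Topology) -> None:
        if self.coords.shape[0] != topology.n_beads_total:
            raise ValueError(
                f"frame has {self.coords.shape[0]} beads, topology expects "
                f"{topology.n_beads_total}"
            )


class IndexGroups(dict):
    """Named bead-index groups with NDX semantics (0-based internally)."""

    def validate(self, topology: Topology) -> None:
        n = topology.n_beads_total
        for name, idx in self.items():
            arr = np.asarray(sorted(idx), dtype=int)
            if arr.size and (arr[0] < 0 or arr[-1] >= n):
                raise ValueError(
                    f"group {name!r} contains indices outside the topology "
                    f"(0..{n - 1})"
                )

    @classmethod
    def per_helix(cls, topology: Topology) -> "IndexGroups":
        """The n_helix x n_protein groups used for contact analysis."""
        groups = cls()
        for i, prot in enumerate(topology.proteins):
            for label in prot.helix_map:
                if not label.startswith("TM"):
                    continue
                local = prot.helix_bb_indices(label)
                groups[f"{label}_p{i}"] = set(
                    int(k) for k in topology.global_indices(i, local)
                )
        return groups
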