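"""File I/O: GRO/PDB coordinates, trajectories, NDX groups, helix configs.

Standard formats (GRO, PDB, XTC) are read and written through MDAnalysis;
this module only converts them to the package's internal convention
(nm, ns, 0-based indices) and attaches the helix/anchor annotation,
which GROMACS-dialect coordinate files cannot carry and therefore comes
from a small YAML sidecar config::

    helices:
      TM1: "1-3"          # residue ranges, comma separated, inclusive
      TM2: "4-6"
      palm: "37"          # optional non-TM entries: loop, C-term, palm
    anchors: [13, 19, 28] # residue numbers of the a, b, c orientation anchors
    palm_site: 37         # optional: palmitoylation site residue
    bead_radii:
      BB: 0.264           # nm
      PALM: 0.264

Because GRO files carry no chain identifiers, protomer boundaries are
detected where the residue number decreases; all protomers must have
identical bead counts.

A plain columnar text trajectory format is provided so the whole
pipeline is testable without binary files. The format is::

    # dimerscope-traj 1
    # nbeads <N>
    t <time_ns> <box_x> <box_y> <box_z>
    <x> <y> <z>          (N lines, nm)
    t <time_ns> ...
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import yaml

from .topology import Bead, Frame, IndexGroups, ProteinModel, Topology

__all__ = [
    "load_helix_config",
    "save_helix_config",
    "read_coordinates",
    "write_coordinates",
    "read_trajectory",
    "write_trajectory",
    "read_ndx",
    "write_ndx",
]

_A_PER_NM = 10.0


class ParseError(ValueError):
    """Malformed record in an input file."""


# ---------------------------------------------------------------- helix config

def _parse_ranges(spec) -> frozenset[int]:
    if isinstance(spec, int):
        return frozenset([spec])
    out: set[int] = set()
    for part in str(spec).split(","):
        part = part.strip()
        if "-" in part:
            lo, hi = part.split("-")
            out.update(range(int(lo), int(hi) + 1))
        elif part:
            out.add(int(part))
    return frozenset(out)


def load_helix_config(path_or_dict) -> dict:
    """Load and normalize a helix/anchor YAML config (see module docs)."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = dict(path_or_dict)
    if "helices" not in raw or "anchors" not in raw:
        raise ValueError("helix config requires 'helices' and 'anchors' keys")
    helices = {str(k): _parse_ranges(v) for k, v in raw["helices"].items()}
    anchors = tuple(int(a) for a in raw["anchors"])
    if len(anchors) != 3:
        raise ValueError("anchors must list exactly three residues")
    cfg = {
        "helices": helices,
        "anchors": anchors,
        "special_residues": {},
        "bead_radii": {str(k): float(v) for k, v in raw.get("bead_radii", {}).items()},
    }
    if "palm_site" in raw and raw["palm_site"] is not None:
        cfg["special_residues"]["palm_site"] = int(raw["palm_site"])
    return cfg


def save_helix_config(cfg: dict, path) -> None:
    def fmt(resids: frozenset[int]) -> str:
        # compress sorted residues into "a-b,c" range notation
        rs = sorted(resids)
        parts, start, prev = [], rs[0], rs[0]
        for r in rs[1:]:
            if r == prev + 1:
                prev = r
                continue
            parts.append(f"{start}-{prev}" if prev > start else f"{start}")
            start = prev = r
        parts.append(f"{start}-{prev}" if prev > start else f"{start}")
        return ",".join(parts)

    raw = {
        "helices": {k: fmt(v) for k, v in cfg["helices"].items()},
        "anchors": list(cfg["anchors"]),
        "bead_radii": dict(cfg.get("bead_radii", {})),
    }
    if cfg.get("special_residues", {}).get("palm_site") is not None:
        raw["palm_site"] = cfg["special_residues"]["palm_site"]
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def _build_topology(
    resids: np.ndarray,
    resnames: Sequence[str],
    names: Sequence[str],
    cfg: dict,
) -> Topology:
    # protomer boundary where the numbering restarts at the file's first
    # residue number (a mere decrease is not enough: chains appended to a
    # protein, e.g. a palm group, carry their anchor's residue number)
    breaks = [0]
    for i in range(1, len(resids)):
        if resids[i] < resids[i - 1] and resids[i] <= resids[0]:
            breaks.append(i)
    breaks.append(len(resids))
    proteins = []
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        beads = tuple(
            Bead(j, int(resids[lo + j]), str(resnames[lo + j]), str(names[lo + j]))
            for j in range(hi - lo)
        )
        proteins.append(
            ProteinModel(
                beads=beads,
                helix_map=cfg["helices"],
                anchors=cfg["anchors"],
                special_residues=cfg["special_residues"],
            )
        )
    return Topology(proteins=tuple(proteins), bead_radius_map=cfg["bead_radii"])


# ---------------------------------------------------------------- coordinates

def _mda():
    import MDAnalysis as mda

    return mda


def read_coordinates(path, helix_config, fmt: str | None = None):
    """Read a GRO or PDB file into ``(Topology, Frame)``.

    ``helix_config`` is a YAML path or dict (see module docs). Units are
    normalized to nm; bead order is preserved from the file.
    """
    cfg = load_helix_config(helix_config)
    mda = _mda()
    path = str(path)
    kwargs = {} if fmt is None else {"topology_format": fmt, "format": fmt}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(path, **kwargs)
        except Exception as exc:  # noqa: BLE001 - normalize parser errors
            raise ParseError(f"could not parse {path}: {exc}") from exc
    dims = u.dimensions
    if dims is None or not np.all(dims[:3] > 0):
        raise ParseError(f"{path}: missing or invalid box")
    if not np.allclose(dims[3:], 90.0, atol=1e-3):
        raise ValueError(
            f"{path}: triclinic box (angles {dims[3:]}) is unsupported; "
            "only orthorhombic cells are handled"
        )
    topology = _build_topology(
        u.atoms.resids, u.atoms.resnames, u.atoms.names, cfg
    )
    frame = Frame(
        time=0.0,
        box=dims[:3] / _A_PER_NM,
        coords=u.atoms.positions.astype(float) / _A_PER_NM,
    )
    frame.validate(topology)
    return topology, frame


def write_coordinates(topology: Topology, frame: Frame, path, fmt: str | None = None):
    """Write one frame as GRO or PDB (format inferred from the suffix)."""
    mda = _mda()
    frame.validate(topology)
    n_atoms = topology.n_beads_total
    resindex = []
    resids, resnames = [], []
    names = []
    ridx = -1
    prev = None
    for p_i, prot in enumerate(topology.proteins):
        for b in prot.beads:
            key = (p_i, b.residue_number)
            if key != prev:
                ridx += 1
                resids.append(b.residue_number)
                resnames.append(b.residue_name)
                prev = key
            resindex.append(ridx)
            names.append(b.bead_name)
    u = mda.Universe.empty(
        n_atoms, n_residues=ridx + 1, atom_resindex=np.asarray(resindex),
        residue_segindex=np.zeros(ridx + 1, dtype=int), trajectory=True,
    )
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("resids", resids)
    u.add_TopologyAttr("resnames", resnames)
    u.atoms.positions = frame.coords * _A_PER_NM
    u.dimensions = np.concatenate([frame.box * _A_PER_NM, [90.0, 90.0, 90.0]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kwargs = {} if fmt is None else {"format": fmt}
        u.atoms.write(str(path), **kwargs)


# ---------------------------------------------------------------- trajectories

def write_trajectory(frames: Iterable[Frame], path, fmt: str = "text",
                     topology: Topology | None = None, precision: int = 6) -> int:
    """Write frames as columnar text (default) or XTC. Returns frame count."""
    if fmt == "text":
        n_written = 0
        nbeads = None
        with open(path, "w") as fh:
            for fr in frames:
                if nbeads is None:
                    nbeads = fr.coords.shape[0]
                    fh.write("# dimerscope-traj 1\n")
                    fh.write(f"# nbeads {nbeads}\n")
                if fr.coords.shape[0] != nbeads:
                    raise ValueError("inconsistent bead count across frames")
                fh.write(
                    f"t {fr.time:.6f} {fr.box[0]:.6f} {fr.box[1]:.6f} {fr.box[2]:.6f}\n"
                )
                np.savetxt(fh, fr.coords, fmt=f"%.{precision}f")
                n_written += 1
        return n_written
    if fmt == "xtc":
        if topology is None:
            raise ValueError("XTC output requires a topology")
        return _write_xtc(frames, path, topology)
    raise ValueError(f"unknown trajectory format {fmt!r}")


def _write_xtc(frames: Iterable[Frame], path, topology: Topology) -> int:
    mda = _mda()
    n_atoms = topology.n_beads_total
    u = mda.Universe.empty(n_atoms, trajectory=True)
    n = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms) as w:
            for fr in frames:
                u.atoms.positions = fr.coords * _A_PER_NM
                u.dimensions = np.concatenate([fr.box * _A_PER_NM, [90.0] * 3])
                u.trajectory.ts.time = fr.time * 1000.0  # ns -> ps
                u.trajectory.ts.frame = n
                w.write(u.atoms)
                n += 1
    return n


def read_trajectory(path, fmt: str = "text",
                    topology: Topology | None = None) -> Iterator[Frame]:
    """Lazily yield :class:`Frame` objects from a trajectory file.

    Frames must be in strictly increasing time order. A truncated final
    frame yields a warning and a clean stop; NaN coordinates raise,
    naming the frame index.
    """
    if fmt == "text":
        return _read_text_trajectory(path, topology)
    if fmt == "xtc":
        return _read_xtc(path, topology)
    raise ValueError(f"unknown trajectory format {fmt!r}")


def _read_text_trajectory(path, topology: Topology | None) -> Iterator[Frame]:
    with open(path) as fh:
        nbeads = None
        last_time = -np.inf
        frame_index = 0
        while True:
            line = fh.readline()
            if not line:
                return
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts[:1] == ["nbeads"]:
                    nbeads = int(parts[1])
                continue
            if not line.startswith("t "):
                raise ParseError(f"{path}: expected frame header, got {line!r}")
            if nbeads is None:
                raise ParseError(f"{path}: missing '# nbeads' header")
            vals = line.split()
            time, box = float(vals[1]), np.asarray(vals[2:5], dtype=float)
            rows = []
            for k in range(nbeads):
                row = fh.readline()
                if not row:
                    warnings.warn(
                        f"{path}: truncated final frame {frame_index} dropped",
                        RuntimeWarning,
                        stacklevel=2,
                    )
                    return
                rows.append(row.split())
            coords = np.asarray(rows, dtype=float)
            if np.isnan(coords).any():
                raise ValueError(f"{path}: NaN coordinate in frame {frame_index}")
            if time <= last_time:
                raise ValueError(
                    f"{path}: non-monotonic time at frame {frame_index} "
                    f"({time} after {last_time})"
                )
            last_time = time
            frame = Frame(time=time, box=box, coords=coords)
            if topology is not None:
                frame.validate(topology)
            yield frame
            frame_index += 1


def _read_xtc(path, topology: Topology | None) -> Iterator[Frame]:
    if topology is None:
        raise ValueError("XTC input requires a topology for the bead count")
    mda = _mda()
    u = mda.Universe.empty(topology.n_beads_total, trajectory=True)
    u.load_new(str(path))
    last_time = -np.inf
    for i, ts in enumerate(u.trajectory):
        coords = ts.positions.astype(float) / _A_PER_NM
        if np.isnan(coords).any():
            raise ValueError(f"{path}: NaN coordinate in frame {i}")
        time = float(ts.time) / 1000.0  # ps -> ns
        if time <= last_time:
            raise ValueError(f"{path}: non-monotonic time at frame {i}")
        last_time = time
        yield Frame(time=time, box=ts.dimensions[:3] / _A_PER_NM, coords=coords)


# ------------------------------------------------------------------------ NDX

def read_ndx(path) -> IndexGroups:
    """Read a GROMACS NDX file; indices converted 1-based -> 0-based."""
    groups = IndexGroups()
    current = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split(";")[0].strip()
            if not line:
                continue
            if line.startswith("[") and line.endswith("]"):
                current = line[1:-1].strip()
                groups[current] = set()
                continue
            if current is None:
                raise ParseError(f"{path}:{lineno}: index data before any [ group ]")
            try:
                groups[current].update(int(tok) - 1 for tok in line.split())
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return groups


def write_ndx(groups: IndexGroups, path) -> None:
    with open(path, "w") as fh:
        for name, idx in groups.items():
            fh.write(f"[ {name} ]\n")
            ordered = [i + 1 for i in sorted(idx)]
            for k in range(0, len(ordered), 15):
                fh.write(" ".join(f"{i}" for i in ordered[k:k + 15]) + "\n")
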