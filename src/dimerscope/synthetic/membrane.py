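"""Toy membrane self-assembly generator with known ground truth.

Each protein is a rigid body of 12 vertical "helix" rods (one backbone
bead per residue) arranged on a ring, so helix labels, contacts,
surface areas and interface names are all meaningful without any force
field. Proteins translate in the membrane plane and rotate about the
membrane normal by overdamped Langevin dynamics; designed helix-pair
attractions (Gaussian wells between helix axis sites) steer which
interfaces form. The generator records every designed-interface contact
event, giving an independent ground truth for the contact, event and
clustering analyses.

Defaults emulate the study conditions this package targets: 16 proteins
in a ~50 nm membrane patch observed for 30 us. Tests and the demo use
smaller systems via an explicit :class:`SyntheticSystemSpec`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from ..constants import kt
from ..geometry import minimum_image
from ..topology import Bead, Frame, ProteinModel, Topology

__all__ = [
    "SyntheticSystemSpec",
    "DimerEvent",
    "GroundTruth",
    "build_protein_model",
    "body_frame_coords",
    "generate_membrane_system",
    "attach_palm_chain",
    "generate_palm_bridge_pair",
    "make_c2_dimer_frames",
]

N_HELICES = 12
DEFAULT_BEAD_RADIUS = 0.264  # nm, single-radius CG bead model


@dataclass
class SyntheticSystemSpec:
    """Parameters of the toy self-assembly system."""

    n_proteins: int = 16
    box: tuple[float, float, float] = (50.0, 50.0, 10.0)
    n_frames: int = 3000
    dt_frame: float = 10.0          # ns between saved frames
    beads_per_helix: int = 3
    ring_radius: float = 2.0        # nm, helix axes sit on this ring
                                    # (hDAT-like footprint: bound dimers sit
                                    # near 4.5 nm COM distance, inside the
                                    # 5.3 nm pair-extraction cutoff)
    z_spacing: float = 0.3          # nm between beads along a helix
    #: helix-pair attraction strengths, e.g. {(9, 9): 30.0} (kJ/mol)
    interface_design: Mapping[tuple[int, int], float] = field(
        default_factory=lambda: {(9, 9): 50.0}
    )
    attraction_r0: float = 0.45     # nm, preferred helix-axis separation
    attraction_sigma: float = 0.5   # nm, width of the Gaussian well
    d_trans: float = 0.01           # nm^2/ns, in-plane diffusion coefficient
    d_rot: float = 0.01             # rad^2/ns, rotational diffusion
    dt_step: float = 0.06           # ns, Langevin integration step; keeps
                                    # (D/kT)*k*dt <= 0.4 for the stiffest
                                    # mode (the torsional stiffness of a
                                    # bound dimer), so the Euler-Maruyama
                                    # variance inflation stays small
    repulsion_k: float = 100.0      # kJ/mol/nm^2, soft core stiffness
    temperature: float = 310.0
    palm: bool = False
    palm_chain_length: int = 4
    palm_bond: float = 0.47         # nm, MARTINI-like bond length
    contact_cutoff: float = 0.7     # nm, for ground-truth event recording
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if any(e <= 0 for e in self.box):
            raise ValueError("box edges must be positive")
        for pair, eps in self.interface_design.items():
            if eps < 0:
                raise ValueError(f"attraction strength for {pair} must be >= 0")
            if not all(1 <= h <= N_HELICES for h in pair):
                raise ValueError(f"helix labels must be 1..{N_HELICES}, got {pair}")
        if self.palm and self.palm_chain_length < 1:
            raise ValueError("palm_chain_length must be >= 1")


@dataclass(frozen=True)
class DimerEvent:
    pair: tuple[int, int]     # protein indices, i < j
    start: float              # ns (time of first in-contact frame)
    end: float                # ns (time of last in-contact frame)
    label: str                # designed interface, e.g. "TM9/TM9"

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class GroundTruth:
    """What the generator knows and the analyses should recover."""

    dimer_events: list[DimerEvent] = field(default_factory=list)
    true_pmf: object | None = None   # AnalyticPMFSpec for umbrella data
    extras: dict = field(default_factory=dict)

    def save(self, path) -> None:
        payload = {
            "dimer_events": [asdict(e) for e in self.dimer_events],
            "true_pmf": None if self.true_pmf is None else self.true_pmf.to_dict(),
            "extras": self.extras,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path) -> "GroundTruth":
        from .umbrella import AnalyticPMFSpec

        with open(path) as fh:
            payload = json.load(fh)
        events = [
            DimerEvent(pair=tuple(e["pair"]), start=e["start"], end=e["end"],
                       label=e["label"])
            for e in payload["dimer_events"]
        ]
        pmf = payload.get("true_pmf")
        return cls(
            dimer_events=events,
            true_pmf=None if pmf is None else AnalyticPMFSpec.from_dict(pmf),
            extras=payload.get("extras", {}),
        )


# ------------------------------------------------------------------- geometry

def body_frame_coords(beads_per_helix: int, ring_radius: float,
                      z_spacing: float) -> np.ndarray:
    """Body-frame bead coordinates: 12 vertical rods on a ring, (n, 3)."""
    h = beads_per_helix
    coords = np.empty((N_HELICES * h, 3))
    alphas = 2.0 * np.pi * np.arange(N_HELICES) / N_HELICES
    for k in range(N_HELICES):
        x = ring_radius * np.cos(alphas[k])
        y = ring_radius * np.sin(alphas[k])
        for j in range(h):
            coords[k * h + j] = (x, y, (j - (h - 1) / 2.0) * z_spacing)
    return coords


def _anchor_residues(h: int) -> tuple[int, int, int]:
    # bottom of TM1, middle of TM5, top of TM9: spread over the ring AND
    # over z, so the anchor triples are never coplanar (well-conditioned
    # orientation dihedrals)
    return (1, 4 * h + (h + 1) // 2, 8 * h + h)


def palm_site_residue(h: int) -> int:
    """Middle residue of TM12 — the palmitoylation-site analogue."""
    return 11 * h + (h + 1) // 2


def build_protein_model(beads_per_helix: int = 3) -> ProteinModel:
    h = beads_per_helix
    beads = tuple(
        Bead(k * h + j, k * h + j + 1, "CGR", "BB")
        for k in range(N_HELICES)
        for j in range(h)
    )
    helix_map = {
        f"TM{k + 1}": frozenset(range(k * h + 1, (k + 1) * h + 1))
        for k in range(N_HELICES)
    }
    return ProteinModel(
        beads=beads,
        helix_map=helix_map,
        anchors=_anchor_residues(h),
        special_residues={"palm_site": palm_site_residue(h)},
    )


def _rotz(theta: float | np.ndarray) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _frame_coords(centers: np.ndarray, thetas: np.ndarray, body: np.ndarray,
                  box: np.ndarray) -> np.ndarray:
    """World coordinates for all proteins, wrapped into [0, box)."""
    n = centers.shape[0]
    out = np.empty((n * body.shape[0], 3))
    for m in range(n):
        rot = _rotz(thetas[m])
        world = body @ rot.T
        world[:, 0] += centers[m, 0]
        world[:, 1] += centers[m, 1]
        world[:, 2] += box[2] / 2.0
        out[m * body.shape[0]:(m + 1) * body.shape[0]] = world
    return np.mod(out, box)


# ------------------------------------------------------------------- dynamics

def _expand_designs(design: Mapping[tuple[int, int], float]):
    """Ordered (helix_on_m, helix_on_n, eps) list covering both assignments."""
    out = []
    for (hi, hj), eps in design.items():
        if eps == 0:
            continue
        out.append((hi - 1, hj - 1, eps))
        if hi != hj:
            out.append((hj - 1, hi - 1, eps))
    return out


def generate_membrane_system(spec: SyntheticSystemSpec):
    """Simulate the toy system; returns ``(Topology, frames, GroundTruth)``.

    Deterministic for a fixed spec (including its seed).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_proteins
    box = np.asarray(spec.box, dtype=float)
    box2 = box[:2]

    # initial placement on a square grid, random orientations
    k = int(np.ceil(np.sqrt(n)))
    spacing = box2 / k
    min_spacing = 2.0 * (spec.ring_radius + DEFAULT_BEAD_RADIUS) + 0.5
    if min(spacing) < min_spacing:
        raise ValueError(
            f"box too small: grid spacing {spacing} below the "
            f"non-overlap minimum {min_spacing:.2f} nm"
        )
    centers = np.hstack([
        (np.arange(n) % k + 0.5).reshape(-1, 1) * spacing[0],
        (np.arange(n) // k + 0.5).reshape(-1, 1) * spacing[1],
    ])
    thetas = rng.uniform(0.0, 2.0 * np.pi, size=n)

    model = build_protein_model(spec.beads_per_helix)
    body = body_frame_coords(spec.beads_per_helix, spec.ring_radius, spec.z_spacing)
    alphas = 2.0 * np.pi * np.arange(N_HELICES) / N_HELICES
    designs = _expand_designs(spec.interface_design)
    kbt = kt(spec.temperature)
    rep_radius = 2.0 * spec.ring_radius
    dt = spec.dt_step
    steps_per_frame = max(1, int(round(spec.dt_frame / dt)))
    mob_t = spec.d_trans / kbt
    mob_r = spec.d_rot / kbt
    noise_t = np.sqrt(2.0 * spec.d_trans * dt)
    noise_r = np.sqrt(2.0 * spec.d_rot * dt)

    def helix_sites(c, th):
        # (n, 12, 2) world positions of the helix axes
        ang = th[:, None] + alphas[None, :]
        return c[:, None, :] + spec.ring_radius * np.stack(
            [np.cos(ang), np.sin(ang)], axis=-1
        )

    # designed helix-pair attraction matrix (helix of m, helix of n); the
    # soft helix-helix repulsion is switched off on designed pairs so the
    # head-on designed pose is the energy minimum (spin-restoring walls)
    eps_mat = np.zeros((N_HELICES, N_HELICES))
    for hi, hj, eps in designs:
        eps_mat[hi, hj] = eps
    helix_rep_r0 = 0.8      # nm, onset of helix-helix soft repulsion
    helix_rep_k = 1000.0    # kJ/mol/nm^2; walls keep the bound pose head-on
                            # (thermal penetration ~0.07 nm)
    r_active = 2.0 * spec.ring_radius + spec.attraction_r0 \
        + 3.0 * spec.attraction_sigma + 0.5

    def forces(c, th):
        f = np.zeros((n, 2))
        tq = np.zeros(n)
        if n == 1:
            return f, tq
        d = c[:, None, :] - c[None, :, :]
        d -= box2 * np.round(d / box2)
        r = np.linalg.norm(d, axis=-1)
        np.fill_diagonal(r, np.inf)
        overlap = rep_radius - r
        mag = np.where(overlap > 0, spec.repulsion_k * overlap, 0.0)
        f += np.einsum("mn,mnk->mk", mag / r, d)
        close_m, close_n = np.nonzero(np.triu(r < r_active, k=1))
        if close_m.size == 0:
            return f, tq
        sites = helix_sites(c, th)
        for m, nn in zip(close_m, close_n):
            dd = sites[m][:, None, :] - sites[nn][None, :, :]
            dd -= box2 * np.round(dd / box2)
            rr = np.linalg.norm(dd, axis=-1)
            # g > 0 pushes the sites apart (along site_m - site_n)
            with np.errstate(invalid="ignore", over="ignore"):
                dudr = eps_mat * (rr - spec.attraction_r0) \
                    / spec.attraction_sigma**2 \
                    * np.exp(-((rr - spec.attraction_r0) ** 2)
                             / (2.0 * spec.attraction_sigma**2))
            rep = np.where((eps_mat == 0) & (rr < helix_rep_r0),
                           helix_rep_k * (helix_rep_r0 - rr), 0.0)
            g = rep - dudr
            fvec = (g / rr)[:, :, None] * dd          # on m's sites, per pair
            fm = fvec.sum(axis=1)                      # (12, 2)
            fn = -fvec.sum(axis=0)
            f[m] += fm.sum(axis=0)
            f[nn] += fn.sum(axis=0)
            lever_m = sites[m] - c[m]
            lever_n = sites[nn] - c[nn]
            tq[m] += np.sum(lever_m[:, 0] * fm[:, 1] - lever_m[:, 1] * fm[:, 0])
            tq[nn] += np.sum(lever_n[:, 0] * fn[:, 1] - lever_n[:, 1] * fn[:, 0])
        return f, tq

    frames: list[Frame] = []
    n_beads = body.shape[0]
    proteins = tuple(model for _ in range(n))
    topology = Topology(
        proteins=proteins,
        bead_radius_map={"BB": DEFAULT_BEAD_RADIUS, "PALM": DEFAULT_BEAD_RADIUS},
    )
    for i_frame in range(spec.n_frames):
        if i_frame > 0:
            for _ in range(steps_per_frame):
                f, tq = forces(centers, thetas)
                centers = centers + mob_t * f * dt \
                    + noise_t * rng.standard_normal((n, 2))
                thetas = thetas + mob_r * tq * dt + noise_r * rng.standard_normal(n)
                centers = np.mod(centers, box2)
        coords = _frame_coords(centers, thetas, body, box)
        frames.append(Frame(time=i_frame * spec.dt_frame, box=box.copy(),
                            coords=coords))

    truth = GroundTruth(
        dimer_events=_designed_events(frames, topology, spec),
        extras={"spec_seed": spec.seed, "n_proteins": n},
    )
    if spec.palm:
        topology, frames = attach_palm_chain(
            topology, frames,
            anchor_residue=palm_site_residue(spec.beads_per_helix),
            chain_length=spec.palm_chain_length,
            bond_length=spec.palm_bond,
            seed=spec.seed + 1,
        )
    return topology, frames, truth


def _designed_events(frames: Sequence[Frame], topology: Topology,
                     spec: SyntheticSystemSpec) -> list[DimerEvent]:
    """Contact events of the designed helix pairs, straight from the frames."""
    events: list[DimerEvent] = []
    n = topology.n_proteins
    if n < 2 or not spec.interface_design:
        return events
    h = spec.beads_per_helix
    times = np.array([fr.time for fr in frames])
    for (hi, hj), eps in spec.interface_design.items():
        label = f"TM{min(hi, hj)}/TM{max(hi, hj)}"
        for m in range(n):
            for nn in range(m + 1, n):
                flags = np.zeros(len(frames), dtype=bool)
                for t, fr in enumerate(frames):
                    flags[t] = _designed_contact(fr, topology, m, nn, hi, hj, h,
                                                 spec.contact_cutoff)
                for lo, hi_ in _runs(flags):
                    events.append(DimerEvent(
                        pair=(m, nn), start=float(times[lo]),
                        end=float(times[hi_ - 1]), label=label,
                    ))
    return events


def _designed_contact(frame, topology, m, nn, hi, hj, h, cutoff) -> bool:
    for a, b in (((m, hi), (nn, hj)), ((m, hj), (nn, hi))):
        ca = frame.coords[topology.protein_offset(a[0]) + (a[1] - 1) * h:
                          topology.protein_offset(a[0]) + a[1] * h]
        cb = frame.coords[topology.protein_offset(b[0]) + (b[1] - 1) * h:
                          topology.protein_offset(b[0]) + b[1] * h]
        d = minimum_image(ca[:, None, :], cb[None, :, :], frame.box)
        if np.min(np.linalg.norm(d, axis=-1)) < cutoff:
            return True
    return False


def _runs(flags: np.ndarray):
    """(start, stop) index pairs of maximal True runs."""
    out = []
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(flags)))
    return out


# ----------------------------------------------------------------- palm chain

def attach_palm_chain(topology: Topology, frames: Sequence[Frame],
                      anchor_residue: int | None = None, chain_length: int = 4,
                      bond_length: float = 0.47, seed: int = 0,
                      directions: np.ndarray | None = None):
    """Append a freely-jointed palmitoyl-like chain to every protein.

    The chain (bead name ``PALM``) is re-sampled each frame with fixed
    bond length, its first bead bonded to the BB bead of
    ``anchor_residue``; palm beads inherit the anchor's residue number
    so residue-level exclusion removes the chain along with its
    attachment site. ``directions`` overrides the random bond vectors
    (shape ``(n_frames, n_proteins, chain_length, 3)``, unit vectors)
    for deterministic constructions.
    """
    if chain_length < 1:
        raise ValueError("chain_length must be >= 1")
    model = topology.proteins[0]
    if anchor_residue is None:
        anchor_residue = model.special_residues.get("palm_site")
        if anchor_residue is None:
            raise ValueError("no anchor residue given and no palm_site defined")
    anchor_local = model.bead_indices(residues=(anchor_residue,), bead_names=("BB",))
    if anchor_local.size == 0:
        raise ValueError(f"anchor residue {anchor_residue} has no BB bead")
    anchor_local = int(anchor_local[0])

    n_old = model.n_beads
    beads = model.beads + tuple(
        Bead(n_old + j, anchor_residue, "PALM", "PALM") for j in range(chain_length)
    )
    helix_map = dict(model.helix_map)
    helix_map["palm"] = frozenset([anchor_residue])
    new_model = ProteinModel(
        beads=beads, helix_map=helix_map, anchors=model.anchors,
        special_residues=model.special_residues,
    )
    radius_map = dict(topology.bead_radius_map)
    radius_map.setdefault("PALM", DEFAULT_BEAD_RADIUS)
    new_topology = Topology(
        proteins=tuple(new_model for _ in topology.proteins),
        bead_radius_map=radius_map,
    )

    rng = np.random.default_rng(seed)
    n_prot = topology.n_proteins
    new_frames = []
    for t, fr in enumerate(frames):
        blocks = []
        for m in range(n_prot):
            block = fr.coords[topology.protein_slice(m)]
            anchor = block[anchor_local]
            if directions is not None:
                dirs = np.asarray(directions[t, m], dtype=float)
            else:
                v = rng.standard_normal((chain_length, 3))
                dirs = v / np.linalg.norm(v, axis=1, keepdims=True)
            chain = anchor + bond_length * np.cumsum(dirs, axis=0)
            blocks.append(np.vstack([block, np.mod(chain, fr.box)]))
        new_frames.append(Frame(time=fr.time, box=fr.box.copy(),
                                coords=np.vstack(blocks)))
    return new_topology, new_frames


# ------------------------------------------------- designed two-protein fixtures

def generate_palm_bridge_pair(n_frames: int = 200, dt_frame: float = 10.0,
                              beads_per_helix: int = 3, ring_radius: float = 2.0,
                              z_spacing: float = 0.3, gap_close: float = 0.4,
                              gap_far: float = 0.9, palm_fraction: float = 0.5,
                              chain_length: int = 4, bond_length: float = 0.47,
                              box_edge: float = 15.0, seed: int = 0):
    """Two proteins facing TM9 (A) against TM12 (B), palm on B's TM12.

    A labeled fraction of frames holds the protomers at ``gap_far``
    (surface gap above the 0.7 nm contact cutoff) where only the palm
    chain, laid toward protein A, bridges the gap; the remaining frames
    sit at ``gap_close`` with direct protein-protein contact. Ground
    truth records which frames are palm-only, so the
    residue-exclusion frame-drop equals ``100 * palm_only_fraction``
    exactly.
    """
    rng = np.random.default_rng(seed)
    h = beads_per_helix
    model = build_protein_model(h)
    body = body_frame_coords(h, ring_radius, z_spacing)
    box = np.array([box_edge, box_edge, 10.0])
    alphas = 2.0 * np.pi * np.arange(N_HELICES) / N_HELICES
    theta_a = -alphas[8]              # TM9 site of A points along +x
    theta_b = np.pi - alphas[11]      # TM12 site of B points along -x

    palm_flags = rng.random(n_frames) < palm_fraction
    base_topology = Topology(
        proteins=(model, model),
        bead_radius_map={"BB": DEFAULT_BEAD_RADIUS, "PALM": DEFAULT_BEAD_RADIUS},
    )
    frames = []
    for t in range(n_frames):
        gap = gap_far if palm_flags[t] else gap_close
        sep = 2.0 * ring_radius + gap
        centers = np.array([
            [box_edge / 2.0 - sep / 2.0, box_edge / 2.0],
            [box_edge / 2.0 + sep / 2.0, box_edge / 2.0],
        ])
        coords = _frame_coords(centers, np.array([theta_a, theta_b]), body, box)
        frames.append(Frame(time=t * dt_frame, box=box.copy(), coords=coords))

    # palm chain on both proteins (identical models); only B's matters here.
    # Bonds run straight along -x, bridging the gap toward protein A.
    dirs = np.tile(np.array([-1.0, 0.0, 0.0]), (n_frames, 2, chain_length, 1))
    topology, frames = attach_palm_chain(
        base_topology, frames, chain_length=chain_length,
        bond_length=bond_length, seed=seed + 1, directions=dirs,
    )
    truth = GroundTruth(extras={
        "palm_only_fraction": float(np.mean(palm_flags)),
        "palm_only_frames": [int(i) for i in np.flatnonzero(palm_flags)],
        "gap_close": gap_close,
        "gap_far": gap_far,
    })
    return topology, frames, truth


def make_c2_dimer_frames(separation: float = 4.6, spin: float = 0.3,
                         beads_per_helix: int = 3, ring_radius: float = 2.0,
                         z_spacing: float = 0.3, box_edge: float = 20.0,
                         n_frames: int = 1, jitter: float = 0.0, seed: int = 0):
    """An exactly C2-symmetric dimer: protomer B is protomer A rotated
    180 deg about the membrane normal through the midpoint.

    ``spin`` sets protomer A's rotation about its own axis and thereby
    the relative orientation (and the phi1 = phi3 dihedral). With
    ``jitter`` > 0, small rigid-body noise is applied to both protomers
    jointly (C2 symmetry is preserved exactly in each frame).
    """
    rng = np.random.default_rng(seed)
    model = build_protein_model(beads_per_helix)
    body = body_frame_coords(beads_per_helix, ring_radius, z_spacing)
    box = np.array([box_edge, box_edge, 10.0])
    frames = []
    for t in range(n_frames):
        d = separation + (jitter * rng.standard_normal() if jitter else 0.0)
        sp = spin + (jitter * rng.standard_normal() if jitter else 0.0)
        a = body @ _rotz(sp).T + np.array([-d / 2.0, 0.0, 0.0])
        b = a @ _rotz(np.pi).T  # C2 about the z axis through the origin
        coords = np.vstack([a, b])
        coords[:, 0] += box_edge / 2.0
        coords[:, 1] += box_edge / 2.0
        coords[:, 2] += box[2] / 2.0
        frames.append(Frame(time=float(t), box=box.copy(), coords=coords))
    topology = Topology(
        proteins=(model, model),
        bead_radius_map={"BB": DEFAULT_BEAD_RADIUS, "PALM": DEFAULT_BEAD_RADIUS},
    )
    return topology, frames
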