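# Methods

This note documents the models, algorithms, default parameters and
numerical choices behind `dimerscope`, and what the synthetic ground
truth does and does not establish about real coarse-grained (CG)
simulation data.

## Scope and coordinate conventions

The package analyzes dimerization of 12-transmembrane-helix (TM1–TM12)
membrane proteins in CG representation: one backbone (BB) bead per
residue, optional side/lipid-anchor beads, proteins embedded in a
membrane normal to z. Internal units are nm, ns, kJ/mol; angles are
degrees in (−180, 180]; bead indices are 0-based internally and
1-based in GRO/NDX files. Periodic boxes are orthorhombic only;
triclinic input is rejected explicitly rather than silently mishandled.
Thermal energy defaults to kT at 310 K = 0.0083145 × 310 =
2.5775 kJ/mol.

Protomers are made whole by minimum-image unwrapping of each bead
relative to the protein's first bead, which is exact whenever a
protein's extent is below half the box in every direction (true for
all systems considered here); a dimer is made whole by shifting
protomer B to the periodic image nearest protomer A's backbone center
of mass. Centers of mass are unweighted means over BB beads: CG
backbone beads carry near-identical masses, so mass weighting is a
negligible correction (a `weights` argument exists for users who want
it).

## Contact analysis

A contact between two bead groups exists when the minimum bead–bead
center distance (minimum image) is strictly below the cutoff,
0.7 nm by default — the conventional CG contact criterion of "within
7 Å". The per-helix contact map tallies, for every ordered protein
pair and frame, one count per helix pair in contact
(presence/absence, not bead-pair counts; raw bead-pair tallies would
weight long helices quadratically while the normalized map patterns
are nearly identical either way). Accumulating over *ordered* pairs
makes the 12×12 map symmetric by construction; the per-helix marginal
reports each helix's share of unique contacts in %, so marginals sum
to 200% (each contact has two participating helices). Maps are
normalized by a reference total — by convention the contact total of a
designated reference system — so two related systems (e.g. with and
without palmitoylation) are directly comparable.

For helix *contact maps* the palm chain is excluded (helix groups are
BB beads only). For contact *time series* the helix groups include all
beads of the helix residues, so a palm chain anchored on a TM12
residue counts as part of TM12's group; excluding a residue removes
its BB bead *and* the attached chain (palm beads inherit their
anchor's residue number). This asymmetry mirrors how the two analyses
are used: maps characterize protein–protein interfaces, series ask
whether any contact — including palm-mediated — persists.

Interface lifetime events are maximal runs of consecutive in-contact
frames; a run of k frames at spacing dt counts as k·dt ns and
qualifies when that is at least the threshold (500 ns by default).
The residue-exclusion frame drop is
100 × (F_incl − F_excl)/F_incl, where F is the total number of
in-contact frames over the monitored pairs computed with and without
the excluded residue. By default all monitored pairs contribute
(min_duration = 0); a lifetime filter can restrict to pairs with a
qualifying event.

The neighbor search uses periodic cell lists with cell edge ≥ cutoff,
falling back to the brute-force double loop when a box dimension holds
fewer than three cells. Exact equality with the brute-force loop on
randomized instances is a release gate, enforced in the test suite
(1000 randomized instances).

## Lipid-accessible surface area (LASA)

Accessible surface areas use the Shrake–Rupley construction: each bead
is expanded by the probe radius (0.26 nm, an effective lipid-tail bead
radius), and test points on a Fibonacci sphere (960 points by default)
count as accessible when outside every other expanded bead. All CG
beads share one radius, 0.264 nm, configurable per bead type. Per-bead
areas are attributed to the helix owning the bead. No membrane-slab
restriction is applied by default: per-helix areas are computed for the
whole helix. Periodicity is deliberately not applied — surfaces are
computed on whole (unwrapped) molecules.

Interface burial is ΔLASA = LASA(A) + LASA(B) − LASA(A∪B), which is
non-negative up to the surface-point discretization (~4πR²/960 per
flipped test point) and decays to zero with separation.

Accuracy at the 960-point default: an isolated bead is exact to
< 0.5%, two overlapping spheres match the spherical-cap closed form to
< 1%.

## Dimer extraction, symmetrization and GROMOS clustering

Every unordered protein pair within 5.3 nm backbone-COM separation
(minimum image, boundary inclusive) is extracted from every frame (at
an optional stride) as one dimer record. Records are *symmetrized*:
each record is duplicated with the A/B labels swapped, so that
symmetry-related conformations — (helices X of A) against (helices Y
of B) and vice versa — cluster together. Population percentages are
reported over the symmetrized (doubled) record set.

Clustering is the GROMOS (Daura) neighbor-count algorithm at a 0.4 nm
RMSD cutoff: the record with the most neighbors within the cutoff
seeds a cluster, it and its neighbors are removed, and the procedure
repeats. RMSD is computed after optimal proper superposition (Kabsch,
reflections suppressed) of the whole dimer on all BB beads of both
protomers; fit and measure selections coincide, matching common
`gmx cluster` usage, and are configurable. Ties in the neighbor count
break toward the lowest record index, making the output deterministic
and order-independent in the absence of exact ties. The pairwise RMSD
matrix is computed once and can be passed in explicitly; for very
large record sets the CLI strides records down to a configurable cap
(2000) rather than attempting an O(M²) matrix.

Clusters whose central member superposes onto its own A/B swap within
the cutoff are *self-paired* (a C2-symmetric interface); among the
remaining clusters, pairs whose centrals map onto each other's swaps
are mutual symmetry pairs and are additionally reported merged. On a
symmetrized record set, mutual pairs differ in size by at most one
record. Self-paired clusters are excluded from mutual pairing: a
central that equals its own swap would otherwise spuriously "pair"
with any nearby small cluster.

Interfaces are named by the helices of protomer A within the contact
cutoff of protomer B's backbone, ascending and comma-joined, then
"/", then likewise for B — e.g. `TM4,TM9/TM11`; `none` when no helix
contact exists. The label is evaluated on the cluster's central
member.

## Relative orientation (virtual bond construction)

Two rigid protomers are described by the six internal coordinates of
the chain c–b–a–A–B–C over the virtual bond a–A, where (a, b, c) and
(A, B, C) are the BB beads of three structurally fixed anchor residues
in each protomer (in the dopamine transporter: Leu322, Ile393,
Thr456):

    d      = |a − A|
    θ1     = angle(b, a, A)          θ2 = angle(a, A, B)
    φ1     = dihedral(c, b, a, A)    φ3 = dihedral(a, A, B, C)
    φ2     = dihedral(b, a, A, B)

The assignment of φ1 vs φ3 follows the standard Z-matrix reading of
the chain and is validated by the C2 property: for a dimer mapped onto
itself by a 180° rotation about the membrane normal, φ1 = φ3 exactly
(machine precision in the tests), and swapping the protomer labels
exchanges φ1 and φ3 for any dimer. θ1/θ2 are computed and stored even
though membrane embedding makes φ2 (and largely θ) uninformative —
upright protomers restrict them to a narrow band.

Anchor equivalences for other transporters (e.g. the bacterial leucine
transporter) are user-supplied configuration, not hard-coded; the
package ships a code path that builds a crystallographic dimer from a
user-provided PDB/mmCIF file (gemmi symmetry expansion choosing the
mate with the most interchain Cα contacts) plus an explicitly
*synthetic* C2 stand-in whose designed orientation (default
φ1 = φ3 = −7.3°, the magnitude of the crystallographic
leucine-transporter dimer) is set during construction against an
independent dihedral routine (MDAnalysis) and then recovered through
the package's own virtual-bond path.

## Multi-restraint umbrella sampling and binless WHAM

Umbrella windows restrain up to three coordinates simultaneously: the
separation d (½k_d(d−d₀)², k_d in kJ/mol/nm²) and the orientation
dihedrals φ1, φ3 (½k_φ·Δφ² on the wrapped difference, k_φ in
kJ/mol/deg² unless declared in rad). Because the bias lives on three
coordinates while the free-energy axis is one, unbiasing uses the
binless (per-sample-bias) formulation: with u_i(x) = bias_i(x)/kT, the
window free energies solve

    f_i = −ln Σ_n exp(−u_i(x_n)) / Σ_j N_j exp(f_j − u_j(x_n))

over all pooled samples, and each sample receives weight
w_n ∝ 1/Σ_j N_j exp(f_j − u_j(x_n)). The PMF is the weighted histogram
F(d) = −kT ln(p(d)/Δd), offset so its minimum is zero; empty interior
bins are flagged (NaN), never interpolated. A conventional binned
distance-only WHAM ships alongside purely as a cross-check; the two
agree within discretization error on distance-only data.

Numerics: f is solved by 20 damped (0.8) self-consistent iterations
followed by Newton steps on the equivalent convex objective (its
Hessian is only n_windows × n_windows), then self-consistent polish to
the tolerance (10⁻¹⁰ kT on max|Δf_i| by default); f_1 = 0 pins the
gauge, making the solution unique and the solver deterministic, and
weights are numerically gauge-invariant under constant bias shifts.
Per-bin weighted sums use digitize+bincount rather than numpy's
weighted histogram: the latter accumulates through a cumulative sum
and silently cancels bins whose total weight is ≲10⁻¹⁶ of the pooled
weight — exactly the regime of a plateau 20 kT above the well.

Restraint force constants are mandatory inputs in window manifests —
there are no hidden defaults. The synthetic generator's defaults are
k_d = 1000 kJ/mol/nm² and k_φ = 0.5 kJ/mol/deg², windows spaced
0.1 nm. Equilibration handling: each window carries a discard
fraction; the pipeline default discards the first 30% of each window
(matching the convention of discarding the initial ~3 of 10 µs of
such runs), while the Monte-Carlo generator, which has its own
burn-in, writes windows with 0.

Bootstrap errors resample frames with replacement *within* each window
(n_boot = 10 by default), rerunning the full unbias; replicate solves
warm-start from the full-data f. This treats frames as independent; no
autocorrelation correction is applied (none is standard for these
data), so errors on strongly correlated samples are underestimates.
Convergence is assessed by re-solving WHAM on contiguous time blocks
and comparing the last two block profiles per bin.

The dissociation free energy is the mean profile value over a
user-chosen plateau range minus the global minimum (zero under the
min-offset convention); the plateau spread (max − min) is reported
alongside and triggers a warning when the "plateau" is not flat —
profiles without a true asymptote at long distance do not define a
clean ΔG. Known accuracy at the synthetic study scale (25 windows,
5000–20000 samples each): the recovered ΔG of a designed well carries
a small negative offset of ~0.1–0.3 kJ/mol from bin-averaging at the
well minimum plus the noise of the window-free-energy ladder across
the steep slope; both shrink with samples and bin width and stay well
inside ±0.5 kJ/mol at the tested conditions.

Bias-corrected observable profiles (e.g. residue contact counts) are
weighted means per bin of d − d_min, where d_min is the PMF minimum of
the same dataset; bootstrap errors as above.

## Occupancy grids

A voxel (0.1 nm edge by default) counts as occupied in a frame when
its center lies within the bead radius (0.26 nm, i.e. beads rendered
at 2.6 Å) of any selected bead center; the grid value is the occupied
fraction of frames, in [0, 1]. Voxel centers are tested — no partial
volume rasterization. Frames must be superposed onto a common
reference (typically a cluster's central structure) by the caller.
Grids are written in OpenDX (lengths in Å) for VMD/PyMOL rendering.

## Synthetic ground truth

### Membrane self-assembly

The toy protein is a rigid body of 12 vertical 3-bead rods on a ring,
so helix labels, contacts, surface areas and interface names are all
meaningful without a force field. The footprint matches a transporter:
ring radius 2.0 nm puts bound dimers near 4.5 nm backbone-COM
separation, inside the 5.3 nm pair-extraction cutoff with a realistic
unbound shell. Proteins translate in-plane and rotate about z by
overdamped Langevin dynamics (D_t = 0.01 nm²/ns,
D_r = 0.01 rad²/ns — µm²/s-scale membrane-protein mobility);
designed helix-pair attractions (Gaussian wells between helix-axis
sites, default TM9–TM9 at 50 kJ/mol, r₀ = 0.45 nm, σ = 0.5 nm) steer
which interface forms, soft walls (onset 0.8 nm, 1000 kJ/mol/nm²)
between all *other* helix pairs keep the bound pose head-on and supply
excluded volume, and a soft center-center core prevents
interpenetration. The integration step (0.06 ns) keeps
(D/kT)·k·dt ≤ 0.4 for the stiffest mode — the torsional stiffness of
a bound dimer — because Euler–Maruyama inflates the variance of
stiffer modes and an overdriven bound dimer would dissociate at an
artificially high rate. Anchors sit at the bottom of TM1, the middle
of TM5 and the top of TM9, spread over the ring *and* over z so anchor
triples are never coplanar.

The generator records ground-truth events: maximal runs of frames in
which a designed helix pair of a protein pair is within the contact
cutoff, labeled e.g. `TM9/TM9`. Defaults emulate the target study
scale (16 proteins, ~50 nm patch, 30 µs at 10 ns/frame); tests and
the demo run 2-protein, ~10 nm, 3–4 µs systems where a designed dimer
forms within the first microsecond in every tested seed.

The optional palm chain is a freely-jointed chain (4 beads, 0.47 nm
bonds) re-sampled each frame from the anchor residue (middle of TM12),
i.e. an orientational average rather than a dynamical chain — correct
end-to-end statistics (⟨R²⟩ = n b²), no chain memory. A dedicated
two-protein construction holds the protomers at a surface gap of
0.4 nm (direct contact) in a labeled fraction of frames and 0.9 nm
(bridgeable only by the palm chain laid toward the partner) in the
rest, so the residue-exclusion frame drop has an exact known value.

What the toy does *not* emulate: explicit lipids (no encapsulated-
lipid counts, no lipid-mediated interfaces), internal protein
flexibility, binding/unbinding equilibrium at realistic rates (the
designed well is ~19 kT, so binding is effectively irreversible, as in
the sticky CG force fields this mimics), or competition between many
interfaces. Passing tests therefore demonstrate that the *analyses*
recover designed truth, not that any real protein behaves this way.

### Umbrella windows

Windows are drawn by Markov-chain Monte Carlo directly in the
restrained coordinates (d, φ1, φ3) from
exp(−[U₀(d) + U_orient(φ) + bias]/kT): the unbiasing stage only ever
sees per-frame (d, φ1, φ3) samples plus restraint specifications, so
nothing is lost by not simulating beads. U₀ is an
analytic PMF (harmonic well; double well — two Gaussian wells of
depth 40/25 kJ/mol at 0.25/1.0 nm on a zero plateau; single well plus
plateau of designed depth). Well widths (0.2–0.25 nm) are chosen so
U₀'' never exceeds the default k_d, keeping every window's biased
marginal unimodal — steeper wells than the restraints can hold would
make the windows themselves multimodal and the MC chains (like real
umbrella runs) prone to trapping. U_orient is a pair of independent
harmonic wells (0.5 kJ/mol/deg², a few degrees of wobble — the
orientational stiffness of a bound interface), so the target is
separable and the marginal over d is *exactly* exp(−U₀/kT): the
unbiasing has a closed-form truth to recover.

Because the target is separable, the chain uses Metropolis-within-
Gibbs sub-steps (d alone, then the φ pair) with independently tuned
proposal widths (30–50% acceptance, tuned during the burn-in — the
first 10% of steps — then frozen). A single joint proposal with one
shared width is measurably wrong here: the stiff dihedrals force the
shared width down and the d coordinate then random-walks with visible
trends across a flat potential. Domain bounds act as hard walls
(reject moves outside); the wall is part of the common unbiased
density, so WHAM remains exact. Acceptance rates are reported and a
window below 5% triggers a warning. An optional per-sample observable
(a smooth decreasing "contact count" c(d), plus optional noise) is
attached to exercise the bias-corrected observable profile.

## Defaults at a glance

| Parameter | Default | Unit | Where |
|---|---|---|---|
| contact cutoff | 0.7 (strict <) | nm | contacts, naming |
| LASA probe / bead radius | 0.26 / 0.264 | nm | surface |
| sphere points | 960 | – | surface |
| COM pair cutoff | 5.3 (inclusive) | nm | dimer extraction |
| cluster RMSD cutoff | 0.4 | nm | GROMOS clustering |
| event lifetime threshold | 500 | ns | interface events |
| occupancy voxel / radius | 0.1 / 0.26 | nm | occupancy |
| temperature | 310 | K | WHAM |
| WHAM tolerance | 1e-10 | kT | solver |
| bootstrap replicates | 10 | – | errors |
| window spacing / k_d / k_φ | 0.1 / 1000 / 0.5 | nm, kJ/mol/nm², kJ/mol/deg² | generator |
| equilibration discard | 0.3 (pipeline) | fraction | WHAM input |

## Known limitations

* Clustering is O(M²) in records; the CLI strides above a record cap
  instead of streaming.
* Bootstrap ignores autocorrelation; block bootstrap is not
  implemented.
* The LASA has no membrane-slab restriction and no explicit lipid
  environment; "lipid-accessible" means accessible to a lipid-sized
  probe.
* GRO protomer boundaries are detected by residue-number restarts at
  the file's first residue; exotic numbering schemes need explicit
  per-protein files.
* Only orthorhombic boxes are supported.
* The self-assembly toy cannot reproduce population *values* of any
  real system; it validates machinery against designed truth.
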