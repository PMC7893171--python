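# dimerscope

Dimer-interface and free-energy analysis for coarse-grained (CG)
simulations of membrane-protein self-assembly and umbrella sampling —
built around the analysis chain used to characterize dimerization of
12-transmembrane-helix neurotransmitter transporters (dopamine /
serotonin / leucine transporter family) and the effect of
S-palmitoylation on their interfaces.

## Who this is for

Simulators running CG (MARTINI-style) multi-copy membrane systems who
need to answer: *which helices form the dimer interfaces, how are the
protomers oriented, how strong is each interface, and what does a
lipid anchor (palmitoyl chain) change?* The package takes standard
coordinate/trajectory formats (GRO, PDB, XTC, plus a documented plain
text trajectory), a small YAML file mapping residues to helices and
anchors, and umbrella-window sample tables.

## What it computes

* **Helix contact maps** — 12×12 interprotein helix-pair contact
  tallies (minimum bead–bead distance < 0.7 nm), per-helix marginals
  in %, cross-system normalization.
* **LASA / ΔLASA** — lipid-accessible surface area per helix
  (Shrake–Rupley, probe 0.26 nm) and interface burial
  ΔLASA = LASA(A) + LASA(B) − LASA(A∪B).
* **Dimer clustering** — all protomer pairs within a 5.3 nm
  backbone-COM cutoff, A/B-swap symmetrization, GROMOS (Daura)
  clustering at 0.4 nm RMSD, symmetry-paired clusters, interface
  labels like `TM4,TM9/TM11`.
* **Relative orientation** — the virtual-bond internal coordinates
  (d, θ1, θ2, φ1, φ2, φ3) over anchor triples (a,b,c)/(A,B,C);
  φ1 = φ3 identifies C2-symmetric dimers.
* **Potentials of mean force** — binless WHAM for umbrella windows with
  *simultaneous* restraints on separation d and the orientation
  dihedrals φ1, φ3:

      f_i = −ln Σ_n exp(−u_i(x_n)) / Σ_j N_j exp(f_j − u_j(x_n)),
      F(d) = −kT ln p̂(d),  p̂(d) = Σ_{n∈bin} w_n,  w_n ∝ 1/Σ_j N_j e^{f_j−u_j(x_n)}

  with bootstrap errors, time-block convergence checks, dissociation
  free energies and bias-corrected observable profiles.
* **Interface dynamics** — continuous-contact lifetime events
  (≥ 500 ns), the % frame drop when one residue (plus its attached
  palmitoyl chain) is excluded, and 3D occupancy grids (OpenDX).
* **Synthetic ground truth** — generators for toy self-assembly
  trajectories with designed interfaces and recorded contact events,
  palm-bridged dimers with known palm-only fractions, and umbrella
  windows drawn from analytic PMFs, so every stage is validated
  against an exact answer.

## Worked example

The five-minute end-to-end demo simulates a four-protein membrane
system with a designed TM9/TM9 interface, maps its contacts, clusters
the dimers and recovers a double-well separation PMF from synthetic
umbrella windows:

```bash
dimerscope demo --out demo_run --seed 1
```

prints (abridged):

```
$ dimerscope simulate membrane --config demo_run/membrane.yaml --out demo_run/membrane --seed 1
wrote 300 frames, 4 proteins, 52 designed-interface events -> demo_run/membrane
$ dimerscope contacts --traj demo_run/membrane/traj.txt ...
contact map: 196 unique contacts, marginal peak at TM9
$ dimerscope cluster --traj demo_run/membrane/traj.txt ...
37 clusters from 150 symmetrized records; top: TM9/TM9 (64.0%)
$ dimerscope pmf --windows demo_run/windows --out demo_run/pmf --plateau 1.8:2.4 --seed 1
dissociation dG = 39.2 kJ/mol (plateau spread 0.3)
PMF over 25 bins; minimum at d = 0.25 nm
```

Reading the output: the designed TM9/TM9 attraction dominates both the
per-helix contact marginal and the top (merged) cluster, whose label is
computed from the cluster's central structure; the umbrella stage
recovers the analytic double-well ground truth — the generator's PMF
has its global minimum 40.0 kJ/mol below the plateau at d = 0.25 nm,
and the recovered profile (1000 samples per window in the demo) puts
the minimum at 0.25 nm with a dissociation free energy of
39.2 kJ/mol. `demo_run/cluster/clusters.tsv` holds the
interface table (label, merged cluster ids, size %, φ1/φ3, ΔLASA);
`demo_run/pmf/pmf.tsv` the profile with bootstrap errors.

The numbered scripts under `analysis/` run the same chain as a
narrative study on slightly larger systems — generation
(`01_simulate_systems.py`), contact maps and LASA for plain vs
palmitoylated systems (`02_contact_maps.py`), the Table-style cluster
report (`03_cluster_interfaces.py`), PMF recovery with convergence and
contact profiles (`04_pmf_wham.py`), interface lifetimes, the
palm-exclusion frame drop and palm occupancy grids
(`05_interface_dynamics.py`), and the C2 reference-dimer orientation
(`06_reference_dimer.py`) — writing their tables under `results/`.

Every subcommand also works on user MD data: point `--coords/--traj`
at a GRO/XTC pair, supply the helix/anchor YAML
(see `dimerscope.io` docs), and for PMFs a window directory with a
`manifest.yaml` declaring restraint centers and force constants
(mandatory — there are no hidden defaults) plus per-window sample
tables `time d phi1 phi3 [observable]`.

## Layout

```
src/dimerscope/     library: geometry, topology, io, contacts, surface,
                    occupancy, cluster, orientation, wham, synthetic/, cli
analysis/           numbered study drivers writing results/
tests/              pytest suite incl. ground-truth acceptance tests
scripts/            acceptance.py
docs/methods.md     models, algorithms, defaults, limitations
```
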