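#!/usr/bin/env python
"""Per-helix interprotein contact maps and helix surface exposure.

Computes the 12x12 helix-pair contact map (0.7 nm cutoff, palm
excluded), its per-helix marginals and the per-helix lipid-accessible
surface areas for the plain and the palmitoylated system, normalizing
both maps by the plain system's contact total so they are directly
comparable. Writes results/contacts/ and prints the dominant helix.
"""

import sys
from pathlib import Path

from click.testing import CliRunner

from dimerscope.cli import main as cli
from dimerscope.contacts import helix_contact_map
from dimerscope.io import read_coordinates, read_trajectory

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results" / "contacts"


def run(argv):
    print(f"$ dimerscope {' '.join(argv)}")
    res = CliRunner().invoke(cli, argv, catch_exceptions=False)
    print(res.output.rstrip())
    if res.exit_code != 0:
        sys.exit(res.exit_code)


def main():
    if not (DATA / "membrane").exists():
        sys.exit("run analysis/01_simulate_systems.py first")
    # reference total from the plain system, mirroring how two related
    # systems are normalized against one of them
    topology, _ = read_coordinates(DATA / "membrane/system.gro",
                                   DATA / "membrane/helix.yaml")
    frames = list(read_trajectory(DATA / "membrane/traj.txt",
                                  topology=topology))
    reference_total = helix_contact_map(frames[::2], topology).counts.sum()
    print(f"reference contact total (plain system): {reference_total:.0f}")

    for name in ("membrane", "membrane_palm"):
        run(["contacts",
             "--traj", str(DATA / name / "traj.txt"),
             "--coords", str(DATA / name / "system.gro"),
             "--helix-config", str(DATA / name / "helix.yaml"),
             "--out", str(OUT / name), "--stride", "2",
             "--reference-total", str(reference_total)])
    print(f"\ncontact maps, marginals and LASA tables under {OUT}")


if __name__ == "__main__":
    main()
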