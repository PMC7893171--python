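#!/usr/bin/env python
"""Orientation of a crystallographic-style C2 reference dimer.

Builds the synthetic C2 reference dimer at the leucine-transporter
crystal orientation (phi1 = phi3 = -7.3 deg, forced equal by the exact
two-fold) and measures its virtual-bond angles through the package's
own orientation path. If a local copy of the LeuT structure (PDB 2A65,
PDB/mmCIF) is passed as the first argument together with three anchor
residue numbers, the real crystallographic dimer is analyzed instead.

Usage:
    python analysis/06_reference_dimer.py                 # synthetic stand-in
    python analysis/06_reference_dimer.py 2a65.cif A B C  # real crystal
"""

import sys
from pathlib import Path

from dimerscope.leut import crystal_dimer_orientation, \
    synthetic_c2_reference_dimer
from dimerscope.orientation import vba_angles

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "reference_dimer"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    if len(sys.argv) >= 5:
        path = sys.argv[1]
        anchors = tuple(int(a) for a in sys.argv[2:5])
        ori = crystal_dimer_orientation(path, anchors)
        source = f"crystal structure {path}, anchors {anchors}"
    else:
        _, _, anchors_a, anchors_b = synthetic_c2_reference_dimer(-7.3)
        ori = vba_angles(anchors_a, anchors_b)
        source = "synthetic C2 stand-in designed at -7.3 deg"
    print(f"source: {source}")
    print(f"d      = {ori.d:8.3f} nm")
    print(f"phi1   = {ori.phi1:8.3f} deg")
    print(f"phi3   = {ori.phi3:8.3f} deg")
    print(f"|phi1 - phi3| = {abs(ori.phi1 - ori.phi3):.2e} deg "
          "(zero for an exact two-fold)")
    with open(OUT / "orientation.txt", "w") as fh:
        fh.write(f"source\t{source}\n")
        for name in ("d", "theta1", "theta2", "phi1", "phi2", "phi3"):
            fh.write(f"{name}\t{getattr(ori, name):.6f}\n")
    print(f"\nwritten to {OUT / 'orientation.txt'}")


if __name__ == "__main__":
    main()
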