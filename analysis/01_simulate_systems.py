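#!/usr/bin/env python
"""Generate the synthetic study systems with recorded ground truth.

Produces, under results/data/:
  * ``membrane/``      — a two-protein self-assembly run with a designed
    TM9/TM9 interface (coordinates, text trajectory, helix config,
    ground-truth events);
  * ``membrane_palm/`` — the same system palmitoylated on the TM12 site;
  * ``windows_dw/``    — umbrella windows drawn from the analytic
    double-well separation PMF under simultaneous d/phi1/phi3 restraints,
    with a synthetic residue-contact observable attached.

These are the inputs every later analysis step consumes.
"""

import sys
from pathlib import Path

import yaml
from click.testing import CliRunner

from dimerscope.cli import main as cli

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "data"
SEED = 2024


def run(argv):
    print(f"$ dimerscope {' '.join(argv)}")
    res = CliRunner().invoke(cli, argv, catch_exceptions=False)
    print(res.output.rstrip())
    if res.exit_code != 0:
        sys.exit(res.exit_code)


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    mem_cfg = OUT / "membrane.yaml"
    mem_cfg.write_text(yaml.safe_dump({
        "n_proteins": 2, "box": [10.5, 10.5, 10.0], "n_frames": 400,
        "interface_design": {"9-9": 50.0},
    }))
    run(["simulate", "membrane", "--config", str(mem_cfg),
         "--out", str(OUT / "membrane"), "--seed", str(SEED)])

    palm_cfg = OUT / "membrane_palm.yaml"
    palm_cfg.write_text(yaml.safe_dump({
        "n_proteins": 2, "box": [10.5, 10.5, 10.0], "n_frames": 400,
        "interface_design": {"9-9": 50.0}, "palm": True,
    }))
    run(["simulate", "membrane", "--config", str(palm_cfg),
         "--out", str(OUT / "membrane_palm"), "--seed", str(SEED)])

    umb_cfg = OUT / "umbrella_dw.yaml"
    umb_cfg.write_text(yaml.safe_dump({
        "pmf": {"form": "double-well"},
        "n_samples_per_window": 5000,
        "observable": True,
    }))
    run(["simulate", "umbrella", "--config", str(umb_cfg),
         "--out", str(OUT / "windows_dw"), "--seed", str(SEED)])
    print(f"\nall inputs under {OUT}")


if __name__ == "__main__":
    main()
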