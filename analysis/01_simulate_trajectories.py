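"""Generate the three synthetic peptide trajectories the analyses run on.

Three two-state backbone runs of 10^4 frames each (0.8 ps/frame):

* native    — 11 residues (INYWLAHAKAG-like backbone), stationary folded
              fraction 0.80, hyper-mobile tail on residues 8-11;
* truncated — 7 residues (INYWLAH), folded fraction 0.15 with short-lived
              (50-frame) folding events;
* nonamer   — 9 residues (INYWLAHAK), folded fraction 0.15: removing even
              the two most disordered residues destabilizes the helix.

Each run is written as DCD + topology TSV + ground-truth labels TSV + the
generator config (JSON) under results/data/<name>/.
"""
import json

import numpy as np

from _common import DATA_DIR
from helixtail.generate import TwoStateGeneratorConfig, simulate_two_state
from helixtail.trajectory_io import write_dcd, write_labels_tsv, write_multimodel_pdb

N_FRAMES = 10_000

CONFIGS = {
    "native": TwoStateGeneratorConfig(seed=2010, with_nonbonded_params=True),
    "truncated": TwoStateGeneratorConfig(
        n_residues=7,
        p_folded_target=0.15,
        mean_dwell_folded=50.0,
        mobile_tail_range=None,
        seed=2011,
    ),
    "nonamer": TwoStateGeneratorConfig(
        n_residues=9,
        p_folded_target=0.15,
        mean_dwell_folded=50.0,
        mobile_tail_range=(8, 9),
        seed=2012,
    ),
}


def main() -> None:
    for name, config in CONFIGS.items():
        out = DATA_DIR / name
        out.mkdir(parents=True, exist_ok=True)
        trajectory = simulate_two_state(config, N_FRAMES)
        write_dcd(trajectory, out / "trajectory.dcd")
        trajectory.topology.to_tsv(out / "topology.tsv")
        write_labels_tsv(trajectory, out / "labels.tsv")
        # a short multi-model PDB excerpt for quick visual inspection
        write_multimodel_pdb(
            trajectory.slice_frames(slice(0, 10)), out / "first_frames.pdb"
        )
        (out / "config.json").write_text(
            json.dumps(config.to_dict(), indent=2) + "\n"
        )
        frac = float(np.mean(trajectory.labels == "folded"))
        print(
            f"{name:>9}: {trajectory.n_frames} frames, "
            f"{trajectory.topology.n_residues} residues, "
            f"realized folded fraction {frac:.3f} "
            f"(target {config.p_folded_target})"
        )


if __name__ == "__main__":
    main()
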