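"""Shared paths and loaders for the numbered analysis scripts."""
from pathlib import Path

from helixtail.trajectory_io import Topology, Trajectory, read_dcd

ROOT = Path(__file__).resolve().parent.parent
DATA_DIR = ROOT / "results" / "data"
RESULTS_DIR = ROOT / "results"

RUNS = ("native", "truncated", "nonamer")


def run_dir(name: str) -> Path:
    return DATA_DIR / name


def load_run(name: str) -> Trajectory:
    """Load a generated run (DCD + topology TSV + labels TSV) by name."""
    import pandas as pd

    directory = run_dir(name)
    topology = Topology.from_tsv(directory / "topology.tsv")
    trajectory = read_dcd(directory / "trajectory.dcd", topology)
    labels_path = directory / "labels.tsv"
    if labels_path.exists():
        labels = pd.read_csv(labels_path, sep="\t")["label"].to_numpy(object)
        trajectory = Trajectory(
            topology, trajectory.coordinates, trajectory.frame_interval_ps, labels
        )
    return trajectory


def ensure_generated() -> None:
    missing = [n for n in RUNS if not (run_dir(n) / "trajectory.dcd").exists()]
    if missing:
        raise SystemExit(
            f"runs {missing} not found under {DATA_DIR}; "
            "run analysis/01_simulate_trajectories.py first"
        )
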