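"""Plain-text exports: PGM images, landscape grids, projection tables."""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .pca import FreeEnergyLandscape
from .secondary_structure import CODES, SSTimeline

# grayscale levels for the secondary-structure codes (white = coil)
_CODE_LEVELS = {"H": 0, "G": 85, "T": 170, "C": 255}


def matrix_to_pgm(
    matrix: np.ndarray, path: str | Path, vmax: float | None = None
) -> None:
    """Write a matrix as an 8-bit ASCII PGM image (P2), 0 = black = 0.0."""
    matrix = np.asarray(matrix, dtype=float)
    if vmax is None:
        vmax = matrix.max() or 1.0
    levels = np.clip(matrix / vmax * 255.0, 0, 255).astype(int)
    lines = [f"P2", f"{matrix.shape[1]} {matrix.shape[0]}", "255"]
    lines += [" ".join(map(str, row)) for row in levels]
    Path(path).write_text("\n".join(lines) + "\n")


def matrix_to_tsv(matrix: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(matrix), delimiter="\t", fmt="%.6g")


def timeline_to_pgm(timeline: SSTimeline, path: str | Path) -> None:
    """Secondary-structure timeline as a residues x frames grayscale strip."""
    levels = np.vectorize(_CODE_LEVELS.get)(timeline.codes).T
    lines = ["P2", f"{levels.shape[1]} {levels.shape[0]}", "255"]
    lines += [" ".join(map(str, row)) for row in levels]
    Path(path).write_text("\n".join(lines) + "\n")


def landscape_to_tsv(landscape: FreeEnergyLandscape, path: str | Path) -> None:
    """Flat TSV of (x_center, y_center, count, free_energy)."""
    xc = (landscape.edges_x[:-1] + landscape.edges_x[1:]) / 2
    yc = (landscape.edges_y[:-1] + landscape.edges_y[1:]) / 2
    xx, yy = np.meshgrid(xc, yc, indexing="ij")
    pd.DataFrame(
        {
            "x_center": xx.ravel(),
            "y_center": yy.ravel(),
            "count": landscape.counts.ravel(),
            "free_energy_kj_mol": landscape.free_energy.ravel(),
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def series_to_tsv(series: np.ndarray, path: str | Path, name: str = "value") -> None:
    pd.DataFrame(
        {"frame": np.arange(len(series)), name: np.asarray(series)}
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
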