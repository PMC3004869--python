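"""Two-state folding thermodynamics from an RMSD order parameter.

The central statistic is the population free energy of folding,

    ΔG_folding = -R T ln(p_folded / p_unfolded),

with R = 8.314e-3 kJ/(mol K) and the natural logarithm. Frames are
classified folded/unfolded by thresholding their RMSD to a representative
folded structure; the threshold is read off the minimum between the first
two peaks of the RMSD histogram (default bin width 0.05 Å).
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks

from .constants import rt_kj
from .errors import InfiniteFreeEnergyError, NoCutoffError, TemperatureMismatchError


@dataclass(frozen=True)
class RmsdHistogram:
    """Half-open-bin histogram [k*w, (k+1)*w) of a non-negative RMSD series."""

    bin_width: float
    edges: np.ndarray
    counts: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0

    def smoothed_counts(self, window: int = 3) -> np.ndarray:
        """Moving-average smoothing used for peak/valley detection."""
        kernel = np.ones(window) / window
        return np.convolve(self.counts.astype(float), kernel, mode="same")


@dataclass(frozen=True)
class TwoStateResult:
    """Folded/unfolded populations and the implied folding free energy."""

    cutoff: float
    n_folded: int
    n_unfolded: int
    temperature: float
    representative_frame: int | None = None

    @property
    def p_folded(self) -> float:
        return self.n_folded / (self.n_folded + self.n_unfolded)

    @property
    def delta_g(self) -> float:
        return delta_g(self.p_folded, self.temperature)

    def to_dict(self) -> dict:
        return {
            "cutoff_angstrom": self.cutoff,
            "n_folded": self.n_folded,
            "n_unfolded": self.n_unfolded,
            "p_folded": self.p_folded,
            "temperature_K": self.temperature,
            "delta_g_kj_per_mol": self.delta_g,
            "representative_frame": self.representative_frame,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def rmsd_histogram(series: np.ndarray, bin_width: float = 0.05) -> RmsdHistogram:
    """Histogram an RMSD series into half-open bins of the given width."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty RMSD series")
    if np.any(series < 0):
        raise ValueError("RMSD series contains negative values")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(np.floor(series.max() / bin_width)) + 1
    idx = np.floor(series / bin_width).astype(int)
    counts = np.bincount(idx, minlength=n_bins)
    edges = np.arange(n_bins + 1) * bin_width
    return RmsdHistogram(bin_width=bin_width, edges=edges, counts=counts)


def find_cutoff(
    histogram: RmsdHistogram,
    smoothing_window: int = 3,
    min_peak_fraction: float = 1e-3,
) -> float:
    """Folded/unfolded RMSD cutoff from the valley between the first two peaks.

    The histogram is smoothed with a short moving average, the first two
    local maxima are located, and the center of the lowest bin strictly
    between them is returned (leftmost bin on ties). Maxima smaller than
    ``min_peak_fraction`` of the series length are ignored — without this
    guard a stray single count (e.g. the representative structure's own
    zero RMSD) would register as the first peak. A histogram without two
    peaks raises :class:`NoCutoffError`; callers may then supply a manual
    cutoff instead.
    """
    smoothed = histogram.smoothed_counts(smoothing_window)
    # pad so maxima at the histogram edges are eligible
    padded = np.concatenate([[-1.0], smoothed, [-1.0]])
    peaks, _ = find_peaks(padded, height=min_peak_fraction * histogram.counts.sum())
    peaks -= 1
    if len(peaks) < 2:
        raise NoCutoffError(
            "RMSD histogram has fewer than two peaks after smoothing; "
            "supply a manual cutoff"
        )
    left, right = peaks[0], peaks[1]
    if right - left < 2:
        raise NoCutoffError("first two histogram peaks are adjacent")
    between = slice(left + 1, right)
    valley = left + 1 + int(np.argmin(smoothed[between]))  # argmin: leftmost tie
    return float(histogram.centers[valley])


def classify_frames(series: np.ndarray, cutoff: float) -> np.ndarray:
    """Boolean folded mask: folded iff rmsd < cutoff (equality -> unfolded)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return np.asarray(series, dtype=float) < cutoff


def delta_g(p_folded: float, temperature: float) -> float:
    """Two-state folding free energy -RT ln(p/(1-p)) in kJ/mol."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if not 0.0 < p_folded < 1.0:
        raise InfiniteFreeEnergyError(
            f"p_folded={p_folded}: free energy diverges; consider adding "
            "pseudocounts to the state populations"
        )
    return -rt_kj(temperature) * np.log(p_folded / (1.0 - p_folded))


def delta_delta_g(variant: TwoStateResult, reference: TwoStateResult) -> float:
    """ΔΔG = ΔG(variant) - ΔG(reference); positive means destabilized."""
    if variant.temperature != reference.temperature:
        raise TemperatureMismatchError(
            f"{variant.temperature} K vs {reference.temperature} K"
        )
    return variant.delta_g - reference.delta_g


def two_state_result(
    series: np.ndarray,
    cutoff: float,
    temperature: float,
    representative_frame: int | None = None,
) -> TwoStateResult:
    """Classify a series at a cutoff and bundle populations + temperature."""
    folded = classify_frames(series, cutoff)
    return TwoStateResult(
        cutoff=float(cutoff),
        n_folded=int(folded.sum()),
        n_unfolded=int(len(folded) - folded.sum()),
        temperature=float(temperature),
        representative_frame=representative_frame,
    )


def bootstrap_delta_g(
    labels: np.ndarray,
    temperature: float,
    block_length: int = 50,
    n_boot: int = 500,
    seed: int = 0,
    ci: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Moving-block bootstrap CI for ΔG from a boolean folded-label series.

    Blocks of ``block_length`` consecutive labels are resampled with
    replacement to the original length, preserving short-range
    autocorrelation. Returns (point estimate, (lo, hi) percentile CI).
    """
    labels = np.asarray(labels, dtype=bool)
    n = len(labels)
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if block_length < 1 or block_length >= n:
        raise ValueError("block_length must be in [1, series length)")
    point = delta_g(labels.mean(), temperature)
    rng = np.random.default_rng(seed)
    n_blocks = int(np.ceil(n / block_length))
    starts_max = n - block_length + 1
    estimates = np.empty(n_boot)
    for b in range(n_boot):
        starts = rng.integers(0, starts_max, size=n_blocks)
        sample = np.concatenate(
            [labels[s : s + block_length] for s in starts]
        )[:n]
        p = sample.mean()
        if p in (0.0, 1.0):
            raise InfiniteFreeEnergyError(
                "a bootstrap replicate had a single-state population; "
                "series too short for the requested block length"
            )
        estimates[b] = delta_g(p, temperature)
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(estimates, [alpha, 1.0 - alpha])
    return point, (float(lo), float(hi))
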