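"""End-to-end orchestration of the trajectory analyses.

``run_full_analysis`` chains the stages on one trajectory: burn-in
removal, iterative average and representative-structure selection, RMSD
series/histogram/cutoff/classification and the two-state ΔG, RMSF of core
vs tail, a strided frame-to-frame RMSD matrix, Cartesian and dihedral PCA
with split-half convergence and the dPCA free-energy landscape, the
secondary-structure timeline, and (when the topology carries charges/LJ
parameters) the core-tail interaction-energy decomposition. Stage failures
are recorded by name in the report and dependent stages are skipped rather
than crashing the run.

``run_compare`` mirrors the two-simulation comparison: the representative
structure is taken from the reference trajectory, a single cutoff (by
default read off the variant's histogram, which is where the two-peak
structure is clearest) is applied to both runs, and the ΔΔG of folding is
reported both from the RMSD order parameter and from basin occupancy in a
shared dihedral-PCA landscape.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import pca as _pca
from . import secondary_structure as _ss
from . import superposition as sup
from . import two_state as ts
from .energetics import NonbondedParams, interaction_energy_series, residue_atom_set
from .errors import HelixtailError, NoCutoffError
from .trajectory_io import SelectionSpec, Trajectory


@dataclass
class AnalysisConfig:
    """Settings for the full analysis; defaults are the study's standard ones.

    The RMSD/state selection is Cα of residues 1-7, the temperature 320 K,
    the histogram bin width 0.05 Å. ``burn_in_ps`` of None applies an
    80 ns burn-in whenever the trajectory is long enough to afford it
    (at least twice that long) and none otherwise — synthetic trajectories
    start in the stationary distribution and need no equilibration.
    """

    selection_atoms: tuple[str, ...] = ("CA",)
    selection_residues: tuple[int, int] = (1, 7)
    temperature: float = 320.0
    bin_width: float = 0.05
    burn_in_ps: float | None = None
    k_cartesian: int = 3
    k_dihedral: int = 6
    dihedral_residues: tuple[int, int] | None = None  # default: selection range
    landscape_bins: int = 100
    rmsd_matrix_max_frames: int = 400
    manual_cutoff: float | None = None
    external_representative: np.ndarray | None = None
    relative_dielectric: float = 20.0
    bootstrap_blocks: int = 50
    n_boot: int = 200
    seed: int = 0

    def selection(self) -> SelectionSpec:
        return SelectionSpec(self.selection_atoms, self.selection_residues)

    def burn_in_frames(self, trajectory: Trajectory) -> int:
        if self.burn_in_ps is not None:
            return int(round(self.burn_in_ps / trajectory.frame_interval_ps))
        frames_80ns = int(round(80_000.0 / trajectory.frame_interval_ps))
        return frames_80ns if trajectory.n_frames >= 2 * frames_80ns else 0

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["external_representative"] is not None:
            d["external_representative"] = "provided"
        return d


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def report_to_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(_jsonable(report), indent=2, sort_keys=True) + "\n"
    )


def run_full_analysis(trajectory: Trajectory, config: AnalysisConfig) -> dict:
    """Run every analysis stage on one trajectory; returns the report dict."""
    report: dict = {"config": config.to_dict(), "errors": {}}
    selection = config.selection()
    burn = config.burn_in_frames(trajectory)
    work = trajectory.slice_frames(slice(burn, None))
    report["n_frames"] = work.n_frames
    report["burn_in_frames"] = burn

    # --- representative structure ------------------------------------------
    representative = None
    try:
        if config.external_representative is not None:
            representative = np.asarray(config.external_representative, float)
            report["representative"] = {"source": "external"}
        else:
            frame, rmsd_to_avg = sup.representative_structure(work, selection)
            representative = work.coordinates[frame]
            report["representative"] = {
                "source": "trajectory",
                "frame": frame,
                "time_ps": frame * work.frame_interval_ps,
                "rmsd_to_average": rmsd_to_avg,
            }
    except HelixtailError as exc:
        report["errors"]["representative"] = str(exc)

    # --- two-state thermodynamics ------------------------------------------
    series = None
    if representative is not None:
        try:
            series = sup.rmsd_series(work, representative, selection)
            histogram = ts.rmsd_histogram(series, config.bin_width)
            if config.manual_cutoff is not None:
                cutoff = config.manual_cutoff
                cutoff_source = "manual"
            else:
                cutoff = ts.find_cutoff(histogram)
                cutoff_source = "histogram"
            result = ts.two_state_result(
                series, cutoff, config.temperature,
                representative_frame=report["representative"].get("frame"),
            )
            point, ci = ts.bootstrap_delta_g(
                ts.classify_frames(series, cutoff),
                config.temperature,
                block_length=min(config.bootstrap_blocks, max(1, work.n_frames // 10)),
                n_boot=config.n_boot,
                seed=config.seed,
            )
            report["two_state"] = result.to_dict() | {
                "cutoff_source": cutoff_source,
                "delta_g_ci_kj_per_mol": list(ci),
            }
            if work.labels is not None:
                agreement = float(
                    np.mean(
                        (work.labels == "folded")
                        == ts.classify_frames(series, cutoff)
                    )
                )
                report["two_state"]["label_agreement"] = agreement
        except (HelixtailError, ValueError) as exc:
            report["errors"]["two_state"] = str(exc)

    # --- fluctuations of the folded ensemble -------------------------------
    # RMSF is reported for the folded-state frames (the major cluster);
    # mixing in unfolded frames would swamp the core/tail contrast.
    aligned = None
    if representative is not None:
        try:
            aligned = sup.align_trajectory(work, representative, selection)
            if series is not None and "two_state" in report:
                folded_mask = ts.classify_frames(
                    series, report["two_state"]["cutoff_angstrom"]
                )
                ensemble = aligned.slice_frames(slice(None)) if folded_mask.all() \
                    else Trajectory(
                        aligned.topology,
                        aligned.coordinates[folded_mask],
                        aligned.frame_interval_ps,
                    )
            else:
                ensemble = aligned
            core_sel = SelectionSpec(["CA"], (1, min(7, work.topology.n_residues)))
            report["rmsf"] = {
                "ensemble": "folded frames" if series is not None else "all frames",
                "core_mean": float(sup.rmsf(ensemble, core_sel).mean()),
            }
            if work.topology.n_residues > 7:
                tail_sel = SelectionSpec(["CA"], (8, work.topology.n_residues))
                report["rmsf"]["tail_mean"] = float(
                    sup.rmsf(ensemble, tail_sel).mean()
                )
        except HelixtailError as exc:
            report["errors"]["rmsf"] = str(exc)

    # --- frame-to-frame RMSD matrix ----------------------------------------
    try:
        stride = max(1, int(np.ceil(work.n_frames / config.rmsd_matrix_max_frames)))
        matrix = sup.rmsd_matrix(work, selection, stride=stride)
        report["rmsd_matrix"] = {
            "stride": stride,
            "shape": list(matrix.shape),
            "max": float(matrix.max()) if matrix.size else 0.0,
        }
        report["_rmsd_matrix"] = matrix
    except HelixtailError as exc:
        report["errors"]["rmsd_matrix"] = str(exc)

    # --- Cartesian PCA ------------------------------------------------------
    if aligned is not None:
        try:
            from .trajectory_io import resolve_selection

            idx = resolve_selection(work.topology, selection)
            flat = aligned.coordinates[:, idx, :].reshape(work.n_frames, -1)
            cmodel = _pca.cartesian_pca(aligned, selection)
            overlap, curve = _pca.split_half_convergence(
                flat, config.k_cartesian, "cartesian"
            )
            report["cartesian_pca"] = {
                "variance_fraction_top3": cmodel.variance_fraction[:3].tolist(),
                "split_half_overlap": overlap,
                "overlap_curve": curve.tolist(),
            }
        except (HelixtailError, ValueError) as exc:
            report["errors"]["cartesian_pca"] = str(exc)

    # --- dihedral PCA and landscape ----------------------------------------
    try:
        dih_range = config.dihedral_residues or (
            1, min(7, work.topology.n_residues)
        )
        angles = _pca.backbone_dihedrals(work, dih_range)
        dmodel = _pca.dihedral_pca(angles)
        scores = _pca.project(dmodel, _pca.embed_dihedrals(angles))
        overlap_d, curve_d = _pca.split_half_convergence(
            angles, config.k_dihedral, "dihedral"
        )
        landscape = _pca.free_energy_landscape(
            scores[:, :2], config.landscape_bins, config.temperature
        )
        report["dihedral_pca"] = {
            "n_angles": angles.shape[1],
            "variance_fraction_top2": dmodel.variance_fraction[:2].tolist(),
            "split_half_overlap": overlap_d,
            "overlap_curve": curve_d.tolist(),
            "landscape_occupied_bins": int(landscape.occupied.sum()),
        }
        report["_dihedral_model"] = dmodel
        report["_dihedral_scores"] = scores
        report["_landscape"] = landscape
    except (HelixtailError, ValueError) as exc:
        report["errors"]["dihedral_pca"] = str(exc)

    # --- secondary structure ------------------------------------------------
    try:
        tl = _ss.timeline(work)
        occ = tl.occupancy()
        report["secondary_structure"] = {
            "occupancy": {
                code: occ[code].round(6).tolist() for code in _ss.CODES
            },
            "residues": occ.index.tolist(),
        }
        report["_timeline"] = tl
    except (HelixtailError, ValueError) as exc:
        report["errors"]["secondary_structure"] = str(exc)

    # --- nonbonded energetics ----------------------------------------------
    if work.topology.has_nonbonded_params and work.topology.n_residues > 7:
        try:
            params = NonbondedParams(config.relative_dielectric)
            core = residue_atom_set(work.topology, 1, 7)
            n_res = work.topology.n_residues
            partners = {"residue_8": (8, 8)}
            if n_res >= 9:
                partners["residue_9"] = (9, 9)
            if n_res >= 10:
                partners[f"residues_10_{n_res}"] = (10, n_res)
            energies = {}
            for name, (lo, hi) in partners.items():
                df = interaction_energy_series(
                    work, core, residue_atom_set(work.topology, lo, hi), params
                )
                # medians accompany the means: the r^-12 repulsion makes the
                # mean LJ term hypersensitive to rare close contacts
                energies[name] = {
                    "mean_coulomb_kcal": float(df["coulomb"].mean()),
                    "mean_lj_kcal": float(df["lj"].mean()),
                    "mean_total_kcal": float(df["total"].mean()),
                    "median_total_kcal": float(df["total"].median()),
                }
            report["interaction_energies"] = energies
        except (HelixtailError, ValueError) as exc:
            report["errors"]["interaction_energies"] = str(exc)

    return report


def summary(report: dict) -> dict:
    """JSON-serializable view of a report (internal arrays stripped)."""
    return _jsonable(
        {k: v for k, v in report.items() if not k.startswith("_")}
    )


def run_compare(
    trajectory_reference: Trajectory,
    trajectory_variant: Trajectory,
    config: AnalysisConfig,
    cutoff_policy: str = "variant",
) -> dict:
    """Two-trajectory ΔΔG comparison with a shared representative and cutoff.

    ``cutoff_policy`` chooses whose RMSD histogram defines the shared
    cutoff: "variant" (default), "reference", or "manual" (uses
    ``config.manual_cutoff``).
    """
    selection = config.selection()
    ref = trajectory_reference.slice_frames(
        slice(config.burn_in_frames(trajectory_reference), None)
    )
    var = trajectory_variant.slice_frames(
        slice(config.burn_in_frames(trajectory_variant), None)
    )

    frame, rmsd_to_avg = sup.representative_structure(ref, selection)
    representative = ref.coordinates[frame]
    series_ref = sup.rmsd_series(ref, representative, selection)
    # the variant may have a different topology (e.g. a truncated peptide);
    # pass the representative restricted to the shared selection atoms
    from .trajectory_io import resolve_selection

    rep_sel = representative[resolve_selection(ref.topology, selection)]
    series_var = sup.rmsd_series(var, rep_sel, selection)

    if cutoff_policy == "manual":
        if config.manual_cutoff is None:
            raise NoCutoffError("manual cutoff policy but no cutoff configured")
        cutoff = config.manual_cutoff
    elif cutoff_policy in ("variant", "reference"):
        series = series_var if cutoff_policy == "variant" else series_ref
        cutoff = ts.find_cutoff(ts.rmsd_histogram(series, config.bin_width))
    else:
        raise ValueError(f"unknown cutoff_policy {cutoff_policy!r}")

    result_ref = ts.two_state_result(
        series_ref, cutoff, config.temperature, representative_frame=frame
    )
    result_var = ts.two_state_result(series_var, cutoff, config.temperature)
    ddg_rmsd = ts.delta_delta_g(result_var, result_ref)

    report = {
        "config": config.to_dict(),
        "cutoff_policy": cutoff_policy,
        "cutoff_angstrom": float(cutoff),
        "representative_frame": frame,
        "representative_rmsd_to_average": rmsd_to_avg,
        "reference": result_ref.to_dict(),
        "variant": result_var.to_dict(),
        "delta_delta_g_rmsd_kj_per_mol": float(ddg_rmsd),
        "errors": {},
    }

    # dihedral-PCA basin estimate on a shared model and grid
    try:
        dih_range = (1, min(7, min(ref.topology.n_residues,
                                   var.topology.n_residues)))
        ang_ref = _pca.backbone_dihedrals(ref, dih_range)
        ang_var = _pca.backbone_dihedrals(var, dih_range)
        dmodel = _pca.dihedral_pca(ang_ref)
        scores_ref = _pca.project(dmodel, _pca.embed_dihedrals(ang_ref))[:, :2]
        scores_var = _pca.project(dmodel, _pca.embed_dihedrals(ang_var))[:, :2]
        both = np.vstack([scores_ref, scores_var])
        span = both.max(axis=0) - both.min(axis=0)
        edges = (
            np.linspace(both[:, 0].min() - 0.05 * span[0],
                        both[:, 0].max() + 0.05 * span[0],
                        config.landscape_bins + 1),
            np.linspace(both[:, 1].min() - 0.05 * span[1],
                        both[:, 1].max() + 0.05 * span[1],
                        config.landscape_bins + 1),
        )
        land_ref = _pca.free_energy_landscape(
            scores_ref, temperature=config.temperature, edges=edges
        )
        land_var = _pca.free_energy_landscape(
            scores_var, temperature=config.temperature, edges=edges
        )
        basin = _pca.basin_from_landscape(land_ref)
        ddg_dpca = _pca.basin_delta_delta_g(
            land_ref, land_var, basin, config.temperature
        )
        report["delta_delta_g_dpca_kj_per_mol"] = float(ddg_dpca)
        report["dpca_basin_bins"] = int(basin.sum())
    except (HelixtailError, ValueError) as exc:
        report["errors"]["dpca_ddg"] = str(exc)

    return report
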