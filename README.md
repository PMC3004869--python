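# helixtail

Trajectory-analysis pipeline for quantifying how an intrinsically
disordered C-terminal tail affects the thermodynamic stability of a short
helical peptide, exercised end-to-end on synthetic two-state trajectories
with known ground truth.

## The problem

Short helical peptides such as the 11-mer INYWLAHAKAG (residues 101–111 of
human α-lactalbumin) show a striking order–disorder pattern: a stably
folded helical N-terminal part and a hyper-mobile four-residue C-terminal
tail. Microsecond MD folding simulations of the full-length peptide and of
tail-truncated variants can be compared thermodynamically to ask whether
the disordered tail contributes to the stability of the folded core. The
core statistic is the two-state folding free energy estimated from state
populations,

    ΔG_folding = −R T ln(p_folded / p_unfolded),

with R = 8.314×10⁻³ kJ mol⁻¹ K⁻¹ and the natural logarithm. Frames are
classified folded/unfolded by their Cα RMSD (residues 1–7) to a
representative helical structure, with the cutoff read off the valley of
the 0.05 Å-binned RMSD histogram. Destabilization by a deletion is the
difference ΔΔG = ΔG_variant − ΔG_reference.

Around this statistic the package implements the full analysis chain used
in such studies:

* **trajectory_io** — multi-model PDB and CHARMM/NAMD DCD read/write
  (via biotite and mdtraj), topology side-tables (TSV), Cα-range atom
  selections;
* **superposition** — SVD-based Kabsch fits, trajectory alignment, RMSD
  series and frame-to-frame RMSD matrices, iterative average structures,
  RMSF, representative-structure selection;
* **two_state** — RMSD histograms, automatic folded/unfolded cutoff,
  classification, ΔG/ΔΔG, moving-block bootstrap confidence intervals;
* **pca** — Cartesian PCA of aligned coordinates and dihedral PCA of
  (cos θ, sin θ)-embedded φ/ψ torsions, projections, split-half eigenspace
  overlap as a convergence diagnostic, free-energy landscapes
  −RT ln(n/n_max) over the first two components, basin-occupancy ΔΔG;
* **secondary_structure** — a simplified α/3₁₀/turn/coil assigner
  (geometric amide-H rebuild + Kabsch–Sander H-bond energy + helix
  patterns), producing per-residue timelines;
* **nonbonded energetics** — screened Coulomb + Lennard-Jones interaction
  energy between disjoint atom sets (core vs tail residues) at a relative
  dielectric of 20;
* **generate** — a synthetic two-state trajectory generator: ideal α/3₁₀
  helices, extended chains and clash-free random coils built from internal
  coordinates (NeRF), switched by a Markov chain with an exactly
  controlled stationary folded fraction;
* **pipeline** — `run_full_analysis` / `run_compare` orchestrating all of
  the above with per-stage error reporting and JSON reports.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (roughly a minute each; outputs land under `results/`):

```
cd analysis
python 01_simulate_trajectories.py
python 03_two_state_free_energy.py
python 07_compare_variants.py
```

`01` generates three 10⁴-frame runs: an 11-residue native-like peptide
with stationary folded fraction 0.80 and a hyper-mobile tail, plus
7-residue (truncated) and 9-residue (nonamer) variants with folded
fraction 0.15. `03` then prints, for one native run:

```
cutoff from histogram valley: 0.775 A
native: p_folded 0.732 (7318/10000 frames), ground-truth agreement 1.000
dG_folding(native, 320 K) = -2.67 kJ/mol (95% CI -3.33 .. -1.99)
```

The cutoff is found automatically from the RMSD histogram; classification
agrees perfectly with the generator's ground-truth labels, so the
recovered ΔG is exactly the free energy of the realized folded fraction
(0.732 for this seed; the stationary target 0.80 corresponds to
−3.7 kJ/mol, inside the bootstrap CI's neighbourhood — a single 10⁴-frame
run carries ≈0.6 kJ/mol of sampling noise). `07` compares variants under a
shared representative and cutoff:

```
truncated - native: ddG(rmsd) = +7.86 kJ/mol, ddG(dPCA basin) = +6.97 kJ/mol  [shared cutoff 0.725 A]
  nonamer - native: ddG(rmsd) = +7.88 kJ/mol, ddG(dPCA basin) = +6.92 kJ/mol  [shared cutoff 0.725 A]
```

Both ΔΔG routes — the RMSD order parameter and basin occupancy in a
shared dihedral-PCA landscape — agree that deleting the disordered tail
destabilizes the folded state by ≈8 kJ/mol (population ratio 0.80/0.15 at
320 K corresponds to +8.3 kJ/mol). Scripts `02`, `04`, `05` and `06` cover
structural stability (RMSF, RMSD matrices), PCA landscapes and
convergence, secondary-structure timelines, and core–tail interaction
energies.

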