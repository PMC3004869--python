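# Methods

This note documents the models, conventions and design choices behind
helixtail: what each stage computes, which knobs matter, what the
synthetic generator does and does not emulate, and where the numerical
edge cases are.

## Two-state thermodynamics

The folding free energy is the population statistic

    ΔG_folding(T) = −R T ln(p_folded / p_unfolded),

with R = 8.314×10⁻³ kJ mol⁻¹ K⁻¹ and the **natural** logarithm (this
convention reproduces the standard worked values, e.g. p = 0.80 at 320 K
→ −3.7 kJ/mol; a base-10 logarithm would give −1.6). kcal outputs use
1 kcal = 4.184 kJ. ΔΔG of a variant versus a reference is the difference
of their ΔG at a common temperature; a temperature mismatch is an error,
not a silent conversion.

Frames are classified by the Cα RMSD (default residues 1–7, inclusive and
1-based) to a representative folded structure:

* the **representative** is the frame with the smallest fitted RMSD to
  the iterative average structure (align all frames to the current
  average on the selection, recompute the all-atom mean, repeat until the
  average moves < 1e-6 Å RMSD or 50 iterations; non-convergence is
  reported via a flag). Ties break to the earliest frame.
* the **cutoff** is found on the 0.05 Å-binned RMSD histogram: smooth
  with a 3-bin moving average, locate the first two local maxima, return
  the center of the lowest bin strictly between them (leftmost on ties).
  Peaks smaller than 0.1% of the series length are ignored — without
  this guard a stray single count (typically the representative's own
  zero RMSD) would masquerade as the first peak. A unimodal histogram
  raises an error; a manual cutoff can then be supplied. A frame with
  RMSD exactly equal to the cutoff counts as unfolded (the defining
  inequalities are strict on both sides, so the boundary had to be
  assigned by convention).
* in two-run comparisons the representative comes from the reference run
  and a single shared cutoff is applied to both; by default the cutoff is
  derived from the variant's histogram, where the folded/unfolded peaks
  are most clearly separated. Both policies are parameters.

Uncertainty on ΔG uses a moving-block bootstrap over the binary
folded/unfolded label series (default block 50 frames, 200–500
replicates, percentile CI), which respects the autocorrelation a Markov
switching process imposes; an i.i.d. bootstrap would understate the
error several-fold at the default dwell times.

## Superposition machinery

All fits are SVD-based Kabsch superpositions with the usual determinant
sign correction, so reflections are excluded; fits require at least three
non-collinear points. Pairwise RMSDs (series and frame-to-frame matrices)
are *fitted* per pair, not measured after a single global alignment. RMSD
is computed from the rotated residuals rather than the singular-value
identity, which loses half the significant digits near zero. The RMSD
matrix takes a stride parameter so microsecond-scale matrices stay in
memory; the pipeline auto-strides to ≤400 rows. RMSF is √⟨|r−⟨r⟩|²⟩ per
atom over an already-aligned trajectory; the pipeline reports it over the
folded-classified frames only, because fluctuations mixed across folded
and coil frames would swamp the rigid-core/mobile-tail contrast the
statistic is meant to expose.

## PCA, landscapes, convergence

Cartesian PCA diagonalizes the sample covariance (ddof = 1) of the
flattened selection coordinates of an aligned trajectory; dihedral PCA
first maps every torsion θ → (cos θ, sin θ), interleaved per angle, which
removes the ±180° wrap. Backbone torsions for residues first..last are φ
for first+1..last and ψ for first..last−1 (terminal torsions need atoms
outside the range), i.e. 12 angles for a 7-residue window, ordered all φ
then all ψ. Angles are degrees in (−180, 180] at every interface and
radians internally. Eigenvector signs are fixed (largest-magnitude
element positive) so projections are reproducible; eigenvalues are
clipped at zero and sorted descending.

Sampling convergence uses the split-half eigenspace overlap
(1/k) Σᵢⱼ (aᵢ·bⱼ)² between PCAs of two non-overlapping halves (defaults
k = 3 Cartesian, k = 6 dihedral), which is symmetric, sign-invariant and
bounded in [0, 1]. Free-energy landscapes histogram the first two
component scores (default 100×100 bins over the data range padded 5%)
and set F = −RT ln(n/n_max): the most occupied bin is exactly 0,
unoccupied bins are NaN-flagged rather than ±∞, and raw counts are kept
so any other reference state can be recomputed. The basin-occupancy ΔΔG
defines the native basin as the occupied bins within 2 RT of the
landscape minimum of the reference run (both runs projected with the
reference's dihedral-PCA model and binned on a common grid) and applies
the same −RT ln(p/(1−p)) arithmetic to the basin populations. The basin
depth is a genuinely open choice; 2 RT captures ≈86% of a quadratic
basin's population and gave cross-method agreement (RMSD-based vs
basin-based ΔΔG within 3 kJ/mol) on well-separated synthetic states.

## Secondary structure (simplified)

A deliberately reduced assigner, not a STRIDE/DSSP reimplementation.
Amide hydrogens are rebuilt geometrically (N–H 1.01 Å along the external
bisector of C(i−1)–N and CA–N, first residue none). Hydrogen bonds use
the Kabsch–Sander electrostatic energy
E = 0.42·0.20·332·[1/r(ON) + 1/r(CH) − 1/r(OH) − 1/r(CN)] kcal/mol with
the standard −0.5 kcal/mol threshold; any distance below 0.5 Å is a
steric clash (no bond). Patterns: two consecutive i→i+4 bonds mark the
spanned residues α (H); else two consecutive i→i+3 bonds mark 3₁₀ (G);
any isolated helical bond marks a turn (T); the rest is coil (C), with
precedence H > G > T. On ideal geometries the calls are unambiguous: the
generator's α-helix (φ, ψ = −57°, −47°) forms only i→i+4 bonds
(−2.2 kcal/mol; the i→i+3 energy is +0.2) and the 3₁₀ helix (−49°, −26°)
only i→i+3 bonds (−2.9 vs −0.2), so α-built frames never read as G and
vice versa. Torsional propensity terms, π-helices and β-structure are out
of scope; on noisy real data this assigner is an approximation.

## Nonbonded energetics

Interaction energy between two disjoint atom sets:
Coulomb Σ 332.0636 qᵢqⱼ/(ε_r rᵢⱼ) with a relative dielectric (default 20)
and CHARMM-style Lennard-Jones εᵢⱼ[(Rmin/r)¹² − 2(Rmin/r)⁶] with
εᵢⱼ = √(εᵢεⱼ), Rminᵢⱼ = rmin_half_i + rmin_half_j. No distance cutoff and
no 1–4 exclusions are applied, but covalently bonded and 1–3 pairs
(inferred from standard backbone atom naming) are excluded: when the
interface splits adjacent residues, the peptide bond C(i)–N(i+1) lies
across it and its LJ term would diverge. Charges and LJ parameters come
from the topology TSV; there is no force-field file parsing. Both terms
are reported separately so a screened-Coulomb-only reading remains
recoverable.

## The synthetic generator

The generator emulates the study conditions of a two-state helical
peptide at a controlled stationary folded fraction:

* idealized backbone only (N, CA, C, O per residue; no side chains) with
  fixed bond geometry (N–CA 1.458, CA–C 1.525, C–N 1.329, C=O 1.229 Å;
  angles 111.2°, 116.2°, 121.7°; ω = 180°), built by NeRF chain
  extension. Ideal torsions: α (−57°, −47°), 3₁₀ (−49°, −26°), extended
  (180°, 180°). Every in-scope analysis uses Cα or backbone atoms, so
  side chains would add nothing the pipeline reads.
* state switching is a two-state Markov chain parameterized by mean
  dwell times (transition probability 1/dwell out of each state); the
  unfolded dwell is solved from the stationary condition so the folded
  fraction equals the target exactly (checked to 1e-9), and the initial
  state is drawn from the stationary law, so no burn-in is needed.
  Defaults: folded fraction 0.80 with mean folded dwell 200 frames
  (native-like 11-mer); the truncated-like variant uses fraction 0.15
  with folded dwell 50 frames, matching a picture of short-lived
  transient folding events.
* folded frames are the helix template plus isotropic Gaussian jitter
  (σ = 0.2 Å, 5σ on the mobile tail, residues 8–11 by default); unfolded
  frames are freshly sampled coils: φ/ψ uniform outside ±30° of the
  eclipsed 0° values, rebuilt (≤100 attempts) until no non-bonded pair —
  graph distance ≥ 3 — is closer than 2 Å.

What the generator does **not** emulate, and hence what passing tests do
not show about real data: there are no physical kinetics (dwell times are
a modelling knob, not rates), no solvent, no side chains, and — most
importantly for the energetics stage — the per-atom jitter is
independent, so folded frames routinely contain steric overlaps a real
force field would never sample. The r⁻¹² repulsion amplifies these, so
*mean* LJ interaction energies on generator output are clash-dominated;
the analysis script reports the screened-Coulomb mean and median totals
and says so. Real-trajectory quantities that depend on CHARMM charges and
microsecond sampling (specific RMSF values, eigenspace overlaps,
landscape minima, mean interaction energies) are replaced by
property-based checks on controlled fixtures throughout the test suite.

## Pipeline defaults and problem sizes

`AnalysisConfig` defaults: selection Cα 1–7, temperature 320 K, histogram
bin 0.05 Å, PCA k = 3 (Cartesian) / 6 (dihedral), 100×100 landscape bins,
RMSD matrix auto-strided to ≤400 frames. Burn-in defaults to the frames
equivalent of 80 ns at the trajectory's frame interval whenever the
trajectory is at least twice that long, and zero otherwise (generated
trajectories start stationary). The study-scale runs used throughout the
scripts and checks are 10⁴ frames at 0.8 ps/frame; recovery checks
average the pipeline ΔG over five independently seeded runs, where the
single-run sampling noise of ≈0.6 kJ/mol shrinks to ≈0.26. Every stage of
`run_full_analysis` records failures by name in the report and skips
dependent stages instead of raising.

## Known limitations

* The secondary-structure assigner approximates STRIDE-class tools;
  agreement on real, noisy conformations is not claimed.
* The basin definition behind the dihedral-PCA ΔΔG (2 RT depth) is a
  documented choice, not a canonical one; the raw landscapes are exported
  so alternatives can be recomputed.
* Selections are atom-name sets over inclusive residue ranges only; there
  is no general selection language.
* The DCD reader/writer targets the little-endian CHARMM/NAMD dialect
  without fixed atoms; unit-cell blocks are tolerated, other DCD variants
  are not.
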