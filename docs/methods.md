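# Methods

This note documents the models implemented in `evmetrics`, their
assumptions, the parameter choices that matter, what the synthetic data
do and do not emulate, and the numerical decisions a maintainer would
want to know.

## PSD statistics

Diameters are histogrammed into half-open bins [lo, lo + 5) nm on
[0, 400) nm — 80 bins, with 400.0 itself excluded. Half-open bins are
the standard histogram convention and keep the grid disjoint; diameters
outside the range are excluded and counted, not errors. Binned counts
are treated as one multinomial draw per replicate.

* **Single-measurement relative uncertainty**: √(pᵢ(1−pᵢ)/N)/pᵢ per bin,
  reported as missing (NaN) where pᵢ = 0 — an empty bin has no finite
  relative uncertainty, and plots stay finite. It scales exactly as
  1/√N, which is why a method measuring ~10⁹ particles reports near-zero
  values while count-limited methods (~10³) do not.
* **Mean PSD**: unweighted bin-wise mean of the replicate probability
  vectors. One replicate is legal (the Cryo-EM case: a single analysis
  of ~500 particles) and the mean then equals it.
* **Replicate-to-replicate relative uncertainty**: parametric bootstrap,
  default 100,000 draws. Each draw resamples a count vector per
  replicate from Multinomial(N_r, p_r), converts to probabilities,
  averages across replicates; the per-bin SD over draws is divided by
  the **actual** mean pᵢ (not the simulated mean), keeping the estimator
  anchored to the data. The procedure deliberately resamples the fixed
  per-replicate probabilities only: between-replicate disagreement
  enters through differing p_r, and no extra replicate-resampling layer
  is added. With equal replicates the SD converges to the closed form
  (1/R)√(Σ_r p(1−p)/N_r), which the tests verify within Monte-Carlo
  error. The bootstrap is deterministic under a fixed seed (PCG64).
* **Summary statistics** (mean, SD, mode) are computed on the raw
  retained diameters, not the binned ones; SD uses n−1; the mode is the
  midpoint of the fullest 5-nm bin.

## Instrument observation rules

MRPS peak filters are applied with strict comparisons exactly as
printed: transit < 100 µs, 0.2 < symmetry < 4.0, diameter > 65 nm,
S/N > 10; the rejection tally counts every violated rule per event.
Cryo-EM areas convert to equivalent-sphere diameters d = 2√(A/π);
selection keeps single, non-overlapping vesicles with d > 30 nm in input
order (the sequential count across micrographs) and stops at the target
count (default 500). Measurement cutoffs: PTA's 25 nm is the smallest
diameter actually detected, i.e. an observed value, so it is inclusive
(d ≥ 25 retained); AF⁴'s set 30 nm bound is treated the same way; MRPS
(> 65) and Cryo-EM (> 30) are printed as strict inequalities and exclude
the boundary.

## Coated-sphere MALS model

The Rayleigh–Gans–Debye (RGD) approximation is used rather than the
exact coated-sphere (Aden–Kerker) solution: EV contrast is low (core
1.3540 and shell 1.4000 against medium ≈ 1.334), squarely inside RGD's
validity, and RGD keeps the amplitude analytic. The amplitude is the sum
of the core sphere at core contrast and the shell as the difference of
two homogeneous spheres at shell contrast; P(θ) = (A(q)/A(0))² with
q = (4π n_m/λ)sin(θ/2). A numerical-quadrature oracle (direct radial
integral of the contrast profile) confirms the closed form to 1e-6
relative in the tests, and setting the shell index equal to the core
recovers the homogeneous-sphere form factor to machine precision.

Per-particle intensity is (16π⁴n_m⁴/λ⁴)·α²·P(θ) with
α = V_core(n_core−n_m) + V_shell(n_shell−n_m), up to a configurable
instrument constant that cancels in forward-simulation/inversion round
trips. Note the strict Rayleigh d⁶ law holds only for a scale-invariant
contrast profile (homogeneous sphere); with a fixed 5.5-nm shell, α
grows slower than d³, so the coated-sphere intensity ratio between d and
2d falls below 64.

Inversion minimizes the sum of squared differences between sum-normalized
measured and model angular profiles over a 30–400 nm grid at 0.5 nm
steps, refined by a parabola through the best point's neighbours — a
grid search because the objective is cheap and can be multimodal in d.
Fits at a grid edge are flagged (`at_boundary`); an isotropic profile
(particle below the angular resolution) pins at 30 nm. Slice counts are
measured low-angle intensity over the per-particle contribution.
Noiseless round trips recover diameters to well under 0.01 nm and counts
to < 0.01%.

Unstated instrument properties are configuration, not constants: the
medium index defaults to 1.334 (PBS at 662 nm), the 16 detector angles
default to even spacing in sin(θ/2) from 20° to 160°, the reported
diameter is the outer (shell-inclusive) diameter, and the absolute
calibration constant defaults to 1 so simulations are self-consistent.

## PNC

Replicate concentrations (already dilution-corrected by multiplying by
the dilution factor ≥ 1) aggregate to mean ± sample SD (n−1); a single
replicate reports its SD as absent rather than zero. The formatted
"(m ± s) × 10^k" output takes k from the mean and rounds the SD mantissa
to one significant figure, the mean to the same decimal place.
Particles-per-µg is PNC/(c_protein × 1000 µL/mL) rounded to two
significant figures, matching the precision such figures are quoted to.

## DIA normalization

Two readings of the flattened two-factor formula are implemented, with
ā the per-protein raw mean, C̄ the per-sample-file mean and D̄ the grand
mean over the whole matrix (not the replicate group):

* `product` (default): K = (x/ā)·(C̄/D̄);
* `ratio`: K = x·D̄/(ā·C̄).

The published rendering is typographically ambiguous between them. Both
are identity on constant matrices and invariant to global rescaling, and
the product form matches the documented worked 2×2 example. They differ
on what happens to a multiplicative sample-file effect: the ratio form
removes it exactly (a noise-free protein×sample effects matrix becomes
constant), while the product form re-applies it. Users correcting
sample-loading differences should choose `mode="ratio"`; the default
remains `product` for consistency with the two-factor mean-scaling
convention adopted here. K̄ is the arithmetic mean of K over each
group's replicate files (n = 3 in the intended design; any n ≥ 1 works).
Proteins with zero raw mean are dropped with a warning — DIA matrices
routinely carry all-missing rows — rather than failing the run.

The marker roster ships as an editable TSV naming only the canonical
markers (tetraspanins CD9/CD63/CD81; cytosolic ALIX, TSG101, syntenin-1,
flotillin-1; annexins A5/A7), contamination indicators (serum albumin,
HSP90B1) and expected-absent negatives (cytochrome C1, HLA-A, calnexin,
APOA2); broader marker databases are out of scope.

## miRNA comparison

Pearson correlation is computed on log2(count + 1) by default — the
conventional scale for count heatmaps; a raw-scale option exists. Note a
*global* per-sample scale factor vanishes under the log transform, so
only per-species (per-miRNA) facility effects are detectable. The
clustering check is strict dominance — every within-facility correlation
above every between-facility one, with the margin reported — because
that is the assertable content of "samples cluster by facility" without
committing to a clustering algorithm. Top-k tables rank by group mean
with lexicographic tie-break.

## Synthetic data: what it emulates, and what it does not

True diameters are lognormal mixtures — right-skewed and positive like
observed EV PSDs. The default population (single component, ln-mean
ln 50, ln-SD 0.35 → mean ≈ 53 nm, SD ≈ 19 nm; 7×10¹¹ particles/mL) is
scaled to the morphological reference distributions of cell-line EV
stocks. Observation applies, in order: an additive hydrodynamic shift
(default +10 nm, all methods except Cryo-EM — protein corona and
hydration layers; the magnitude is a fixture choice, no measured value
exists), detection thinning with probability min(1, (d/d₅₀)^exponent)
evaluated on the physical pre-noise diameter (detection depends on the
particle, not on the recorded size), Gaussian sizing noise, then the
cutoff. The PTA-style exponent 6 encodes the d⁶ scattering-intensity
scaling that over-samples large particles; d₅₀ defaults to 120 nm, a
fixture parameter. MRPS event simulation plants a known fraction of
filter-violating events and always returns ground-truth labels, as do
all generators, enabling parameter-recovery tests.

Per-method problem sizes mirror the study design where meaningful
(~500 Cryo-EM particles, ~10³ MRPS/PTA events, triplicates); the AF⁴
particle load is scaled down to 10⁵ from the 10⁹–10¹⁰ of a real run —
the 1/√N uncertainty separation between AF⁴ and the other methods is
therefore smaller in simulation than in reality. Two-facility miRNA
counts use per-miRNA facility batch effects (log-SD 0.75) against
per-sample noise (log-SD 0.25) and facility-specific 80% detection
subsets; baseline abundances span orders of magnitude (log-SD 2).

Passing tests on these fixtures show the *statistical machinery* is
correct — binning, uncertainty propagation, inversion, filtering,
normalization — under the generative assumptions. They do not validate
instrument physics the generator does not model: no Brownian-tracking
noise model for PTA, no AF⁴ channel hydrodynamics or band broadening, no
electrical pulse shapes for MRPS, no vitrification artefacts for
Cryo-EM, and no read-level sequencing effects.

## Known limitations

* MALS counting inherits the α² contrast sensitivity: a ~2× error in
  assumed contrast moves counts ~4×. This is a property of the method,
  reproduced (and tested) rather than corrected.
* The bootstrap treats replicate probabilities as fixed; it quantifies
  sampling variability around the observed replicates, not the sampling
  of replicates themselves.
* The strict clustering criterion is conservative: a single noisy
  between-facility pair can fail a visually clustered heatmap.
* Diameters are assumed spherical-equivalent throughout; non-spherical
  or multilamellar vesicles are outside the model.
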