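# Methods

## The recognition problem

One diathermy cut ("burn") yields one centroided negative-ion mass
spectrum dominated by glycerophospholipids. The task is to assign each
burn — and, by aggregation, each tissue sample — to a tissue class
(e.g. ovarian cancer, borderline tumour, normal), and to identify which
lipid ions drive the separation. Patients contribute several samples and
each sample several burns, so observations are clustered; every
validation step must respect that clustering.

## Preprocessing

Each spectrum passes through four per-spectrum steps, in order:

1. **Lock-mass correction.** The most intense peak within ±0.3 Da of the
   reference mass (internal phospholipid lock at *m/z* 699.497 by
   default; leucine-enkephalin 554.2615 available for fresh-tissue work)
   defines a constant additive shift `observed − reference` subtracted
   from every *m/z*. A single-point additive correction suffices because
   calibration drift here is sub-0.1 Da; a ppm-scale multiplicative
   correction is out of scope. Absent lock peak → warning, spectrum left
   unchanged. The correction is idempotent.
2. **Background subtraction.** The baseline is the 5th percentile of
   in-window peak intensities; intensities are reduced by it, clipped at
   zero, emptied peaks dropped. A simple, auditable rule standing in for
   the proprietary preprocessing in vendor software.
3. **Binning.** Intensities accumulate onto a fixed grid of 0.1 Da bins
   over [600, 1000) *m/z* — 4000 bins, left-closed right-open, labelled
   by lower edge. A half-ulp nudge (1e-7 Da) keeps peaks that sit on a
   bin edge up to float representation error in the right-hand bin.
   Binning conserves total in-window intensity exactly.
4. **TIC normalisation.** Rows are divided by their total ion current.
   Spectra whose raw in-window total is below 10 counts are QC-rejected
   (no interpretable signal) and logged rather than normalised. TIC was
   chosen over median or reference-peak normalisation and is tagged on
   the matrix so alternatives can be compared.

## PC-LDA recognition model

The binned matrix is mean-centred and decomposed by SVD; the top
`n_pcs = 25` right singular vectors (orthonormal, deterministic sign:
first non-negligible loading element positive) define the PC subspace.
`n_pcs` above the matrix rank is reduced with a warning.

In PC space, classes are modelled as Gaussians with per-class means and a
single pooled within-class covariance — linear discriminant analysis.
The pooled covariance receives a ridge `1e-6 × mean(diagonal)` (with an
absolute fallback when within-class scatter is exactly zero, as happens
on degenerate noise-free inputs) because 25 PCs can approach the row
count. Priors are equal by default: class sizes in a surgical cohort
reflect tissue availability, not prevalence; proportional priors are a
flag away. LD axes for 2D/3D plots are the top generalized eigenvectors
of the between-class scatter against the pooled covariance (classes − 1
of them).

Posterior(class) ∝ prior × Gaussian density, computed via log-densities
and log-sum-exp. *Reliability* is defined as the maximum posterior — the
vendor recognition software never documents its score, so this is an
explicit interpretation — and a call is *reported* iff reliability ≥
threshold (default 0.75).

## Cross-validation and metrics

LOPOCV builds one fold per patient and refits PCA + LDA on all other
patients' spectra; preprocessing is strictly per-spectrum, so the feature
matrix can be computed once without leakage. A fold whose held-out
patient carries a class absent from its training set is logged as
degenerate and those burns are excluded from per-class metrics. The
sample-level call is the majority vote over a sample's burns, ties broken
by mean posterior — the simplest auditable burn→sample rule. Sensitivity
is per-class recall; specificity pools all other classes (one-vs-rest);
percentages are reported half-up to one decimal (38/39 → 97.4),
alongside the raw fractions. Classes without true instances report
`None`, not 0. The recognition summary reports the fraction of burns
reported at the threshold and accuracy among reported.

Cancer samples with viable-tumour content below 50% are excluded from
model building (strict inequality: exactly 50% is retained); cancer
burns with missing content fail with a warning; other classes are never
touched by this filter.

## Univariate discriminant peaks

Units default to per-sample mean spectra, avoiding pseudo-replication
across a sample's burns; spectrum-level testing is available. Two classes
→ Wilcoxon rank-sum (tie-corrected asymptotic Mann–Whitney, no
continuity correction); more → Kruskal–Wallis. Bins constant across all
units get P = 1 by convention and are logged. FDR control uses the
Benjamini–Yekutieli step-up, `q(i) = min_{j≥i} m·c(m)·p(j)/j` with
`c(m) = Σ 1/k`, valid under arbitrary dependence — neighbouring spectral
bins are strongly dependent; plain Benjamini–Hochberg is available behind
a flag for sensitivity analysis. Effect size is the median log2 fold
change with pseudo-count ε = (smallest positive matrix value)/10 to
guard zero medians. The shortlist filters to P < 0.001 and q < 0.001 and
ranks the survivors by pooled median intensity, returning the top 10 by
default.

Note that with ~4000 bins `m·c(m) ≈ 35 000`, so q < 0.001 requires
roughly p < 1e-7 at the top ranks: small pilot cohorts (a handful of
samples per class) cannot reach it with rank tests no matter how clean
the separation. The standard scenario's 20 samples per class can.

## Inter-rater agreement

Unweighted Cohen's kappa (tissue classes are nominal):
κ = (p_o − p_e)/(1 − p_e) with expected agreement from marginal
products. Significance uses the classical null-hypothesis variance from
the marginals (Cohen 1960 / Fleiss),
`var₀ = [p_e + p_e² − Σ p_i·p_·i(p_i· + p_·i)] / (n(1−p_e)²)`, two-sided
normal P — the source software's exact formula is undocumented, so the
inputs are always reported alongside z. Verbal bands: 0 no agreement,
(0, 0.20] poor, (0.20, 0.40] fair, (0.40, 0.60] moderate, (0.60, 0.80]
good, above 0.80 very good. The published banding leaves (0.80, 0.81)
unassigned; closing the gap upward ("very good" covers everything above
0.80) preserves the printed ≥ 0.81 examples. Negative κ (worse than
chance) is banded "no agreement" with a warning.

## Lipid ion database

Elemental composition rules (c = total acyl carbons, d = double bonds):
diacyl PA(c:d) = C(c+3) H(2c+5−2d) O₈P; diacyl PE(c:d) = C(c+5)
H(2c+10−2d) NO₈P; FA(c:d) = C(c)H(2c−2d)O₂; ether (O-) = diacyl − O +
2H; plasmalogen P-(c:d) shares the formula of O-(c:d+1). Even chain
totals only — odd acyl chains are rare in mammalian tissue. Monoisotopic
ion masses use proton-mass bookkeeping (electron mass included):
[M−H]⁻ = M − 1.00727646; [M−NH₃]⁻ = M − 17.02654910 − 1.00727646 (loss
of neutral ammonia *plus* deprotonation — the interpretation that places
PE(34:1) at 699.497); [M+Cl]⁻ = M + 34.96885271 + 0.00054858. The
default grid (glycerophospholipids C24–44, FA C12–26, 0–6 double bonds,
three linkages) yields ≈1300 candidate ions; queries return all ions
within ±0.1 *m/z* sorted by absolute error. Computed masses are reported
to the computed precision — e.g. PA(P-36:1) [M−H]⁻ is 685.518 at 3 dp,
one mDa above a commonly printed 685.517 — rather than silently matched.

## Synthetic cohorts

The generator emulates the features of diathermy-aerosol spectra that the
pipeline actually exercises:

- **Templates.** 20 reproducible peaks, 5 discriminant at 673.481,
  685.517, 699.497, 742.539, 744.555 *m/z*. All five are elevated
  (fold 4) in the cancer class; 685.517 and 742.539 are also elevated in
  the borderline class, mirroring its intermediate biology, so all three
  classes carry distinct signatures. 699.497 has the highest base
  intensity: it doubles as the internal lock mass and must dominate its
  ±0.3 Da neighbourhood in every class.
- **Intensity model.** `base × fold(class) × exp(patient) × exp(noise)`
  with a shared per-patient log-normal offset (SD 0.2) creating
  within-patient correlation — the reason LOPOCV is the honest
  validation — and i.i.d. per-peak log-normal burn noise (SD 0.1).
  Multiplicative noise matches MS intensity behaviour.
- **Background.** 100 peaks per spectrum at uniform *m/z*, exponential
  intensities with mean 1% of the median template intensity, regenerated
  per spectrum.
- **Calibration drift.** One N(0, 0.02 Da) constant per spectrum added to
  every *m/z* including the lock mass, so lock-mass correction can undo
  it exactly.
- **Scale.** 3 classes × 10 patients × 2 samples × 3 burns = 180 spectra
  by default; one full LOPOCV run takes a few seconds.

`ground_truth` returns the planted log2 fold ratio on the *raw* intensity
scale. TIC normalisation rescales observed fold changes by the
between-class TIC ratio (here ≈ 2.2 between cancer and normal, so a raw
log2 FC of 2 appears as ≈ 0.9 on normalised values); convergence of
empirical medians to the planted truth is therefore checked on raw binned
intensities, while normalised effect sizes are asserted directionally.

What the generator does **not** emulate: chromatographic time structure,
isotope envelopes, detector saturation, peak-shape/centroiding artefacts,
class-specific background chemistry, or histology-driven label noise.
Passing tests demonstrate that the pipeline recovers planted structure
under realistic noise — not that real tissue achieves any particular
accuracy.

## Numerical choices and degenerate inputs

- Bin assignment uses `floor((mz − lower)/width + 1e-6)`; the nudge is
  1e-7 Da, three orders below bin width and six below peak spacing.
- Equal intensities under background subtraction remove the whole
  spectrum at any quantile (flat spectra carry no signal).
- All-zero or sub-floor spectra are QC-rejected, never normalised.
- Both-raters-constant-and-identical kappa is defined as 1; constant but
  disagreeing raters make κ undefined (error).
- The empty shortlist (no bin passes the significance filters) is a valid
  result with a warning, as is the empty annotation match list.
- Seeded `numpy` Generators everywhere; the same seed reproduces a cohort
  byte-for-byte.

## Known limitations

- No vendor raw-file reading; the mzML reader covers centroided mzML 1.1
  with base64/zlib 32- or 64-bit float arrays and is a convenience path —
  the native exchange format is the peak-list + metadata CSV pair.
- No peak alignment beyond the constant lock-mass shift, no isotope
  deconvolution, no nonlinear classifiers, no per-peak feature selection
  inside the recognition model (it is deliberately a whole-spectrum
  fingerprint).
- Sensitivity/specificity carry no confidence intervals; LOPOCV is not
  nested, so hyperparameters (n_pcs, ridge) are not tuned per fold.
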