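# Methods

## Pipeline overview

`zonegrade` grades prostate-cancer lesions into ISUP Grade Groups from
single 2-D MRI slices, one zone group at a time: peripheral-zone (PZ)
lesions on the high-b-value diffusion series, transitional-zone + anterior
fibromuscular stroma (TZ+AFS) lesions on T2-weighted imaging. AFS lesions
are grouped with TZ throughout. The stages are: in-plane resampling →
intensity normalization → ROI extraction → 38-feature panel →
semi-exhaustive wrapper feature selection with a correlation-distance KNN
under stratified 3-fold cross-validation → one-vs-rest task assembly.

## Preprocessing

* **Resampling.** Slices are resampled to 0.5 mm × 0.5 mm (default;
  configurable) with bilinear interpolation and edge replication. The new
  grid covers the same physical field of view
  (`new_dim = round(old_dim · old_spacing / target)`). Bilinear was chosen
  because it preserves constants exactly and introduces no ringing; the
  quantized texture panel is insensitive to the mild smoothing it adds.
* **Coordinates.** 0-based (row, col) pixel indices; world-mm lesion
  centers map to the nearest integer index (half-up rounding). The
  convention is arbitrary but fixed and round-trip consistent.
* **Intensity normalization.** T2W slices are z-scored (mean 0,
  population SD 1 over all pixels of the slice) because T2W intensities
  have arbitrary inter-patient scaling; diffusion intensities are left
  unchanged. Per-slice rather than per-volume statistics are used so the
  pipeline operates on single exported slices; for the texture features
  the choice is immaterial (they are invariant to affine intensity maps),
  only the histogram features see it.
* **ROI.** A 61 × 61-pixel window centered on the lesion coordinate. No
  lesion delineation is assumed; the square ROI trades some healthy-tissue
  contamination for robustness and zero annotation cost. A window
  exceeding the grid is a hard error by default; replicate-edge padding is
  available behind a flag for edge lesions. No T2W/DWI co-registration is
  performed — the sequences are never combined.

## Feature panel (38 features)

Order: run-length 1–11, Haralick 12–25, histogram 26–38.

* **Quantization.** Per-ROI min–max uniform binning into G = 128 levels,
  `level(v) = floor(G(v − min)/(max − min)) + 1`, maximum mapped to G,
  constant ROI mapped to level 1. Min–max binning makes every texture
  feature invariant to positive affine intensity rescaling.
* **Run-length (Galloway).** Maximal runs of equal level along each of
  the four directions 0°/90°/180°/270°; statistics are averaged over the
  four. Opposite directions yield identical matrices (runs are
  undirected); both are still computed so the averaging protocol is
  followed literally. Run Percentage uses n_p = pixel count.
* **Haralick.** Per direction, a single-offset non-symmetric normalized
  co-occurrence matrix; the 14 statistics are averaged over the four
  offsets. Natural logarithm with 0·log 0 := 0. Sum Variance is computed
  about the Sum Average (the common correction of the original paper's
  typo). "Variance" (feature 15) is the GLCM variance Σ(i − μx)²p(i,j),
  distinct from histogram variance (feature 27). The maximal correlation
  coefficient is √(second-largest eigenvalue) of
  Q(i,j) = Σₖ p(i,k)p(j,k)/(pₓ(i)p_y(k)) after dropping zero-marginal
  rows/columns. Degenerate single-level matrices define correlation-type
  features (correlation, IMC1, IMC2, MCC) as 0, keeping every output
  finite.
* **Histogram.** Mean, population (1/N) variance, moment skewness
  g₁ = m₃/m₂^{3/2}, non-excess kurtosis m₄/m₂², min, max, median and the
  10/20/30/40/75th percentiles with linear interpolation, all on raw
  (pre-quantization) intensities; Energy = Σ pᵢ² over the 128-level
  quantized histogram (on raw continuous intensities it would be
  degenerate). Skewness/kurtosis of a constant ROI are 0 by convention.

## Classifier

KNN with per-feature z-score normalization fitted on training rows only
(constant columns normalize to 0) and correlation distance
d = 1 − Pearson ρ across the selected features. The probability score is
the unweighted fraction of positive labels among the k nearest neighbors;
distance ties break by ascending training index, so results are exactly
reproducible. Defaults: k = 5 (the source design does not fix k; 5 is a
standard small-cohort choice and every pipeline property holds for any
fixed k), decision threshold 0.5 with the boundary counted positive.

Two deliberate conventions:

* Pearson (not rank) correlation; a zero-variance vector is at distance 1
  from everything (maximally uninformative).
* **Single-feature subsets** degrade the KNN metric to absolute
  difference: correlation between length-1 vectors is undefined
  everywhere, which would make all 38 single-feature candidates blind.
  The fallback preserves nearest-by-intensity semantics so size-1 subsets
  compete meaningfully in the search. Note that with 2–3 features the
  correlation distance is intrinsically coarse (for 2-vectors it is
  binary, 0 or 2); informative rankings emerge from size ~3 upward, which
  matches the sizes the wrapper search tends to select.

## Search and validation

* **Stratified 3-fold CV.** Within each class, samples are shuffled by a
  seeded generator and dealt round-robin, so per-fold class counts differ
  by at most one. A class smaller than the fold count is a hard error —
  the remedy is merging sparse groups, exactly why GG4 and GG5 form one
  task. One fold assignment per (zone, task) is fixed from the seed and
  reused for all subsets.
* **Semi-exhaustive search.** All subsets of size 1–5 of the 38 features
  (584,934 candidates; size 6, 3,345,615 candidates, by configuration —
  the stated 1–6 range and the printed count of the source design
  disagree, and the printed count is honored as the default). Ranking is
  by mean fold AUC, descending; ties break by smaller subset, then
  lexicographic order, making the ranking total and therefore independent
  of evaluation order and of joblib chunking. Operating-point metrics
  pool the held-out scores of all folds at the 0.5 threshold.
* **AUC.** Mann–Whitney convention: ties between a positive and a
  negative score count ½. Computed from midranks (algebraically the
  all-pairs count). Folds whose test half contains a single class raise
  rather than return a default.
* **Selection optimism.** The ranking criterion is the same CV AUC that
  is reported, so the top subset's AUC is optimistically biased — the
  maximum over half a million candidates exceeds 0.5 on pure noise. This
  bias is inherited from the design being reimplemented, on purpose; the
  null-calibration helpers quantify it (per-subset AUC under label
  permutation centers on 0.5; the best-of-search does not). Nested CV,
  which would remove the bias, is deliberately out of scope.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not prostate anatomy. Each fragment is Gaussian white noise smoothed by
an isotropic Gaussian kernel (scale = `correlation_length`, pixels),
re-standardized to unit SD, scaled by `sd_intensity` and shifted by
`mean_intensity`, with an optional focal blob. Mean/SD shifts move the
histogram features only; correlation-length differences move the texture
features only (all texture features are intensity-scale invariant), so
first- and second-order class signal can be planted independently.

Defaults define the study conditions: per-zone class counts 14/21/9/3/3
(PZ) and 22/20/11/5/4 (TZ+AFS) for GG1–5 (112 lesions), base intensity
100, SD 10, and a modest graded class model (mean +5 ≈ 0.5 pooled SD and
correlation length +0.4 px per Grade Group step) — enough structure for
a realistic, imperfect grading problem. Planted-effect cohorts
(`planted_cohort_spec`) instead apply a single low-grade (GG1–2) vs
high-grade (GG3–5) mean shift in pooled-SD units and/or a
correlation-length ratio, for calibration and recovery experiments.
Per-lesion seeds are spawned from the master seed, so cohorts are
reproducible and extensible. Every third TZ+AFS lesion is labeled AFS to
exercise the AFS-grouped-with-TZ path.

What passing on synthetic data does **not** show: robustness to scanner
effects, bias fields, anatomy-dependent texture, inter-sequence geometric
distortion, or the true separability of clinical Grade Groups. The
generator validates the machinery (feature math, fold hygiene, ranking
determinism, signal recovery and null calibration), not clinical
performance.

## Problem sizes in tests and the acceptance script

The shipped test suite and `scripts/acceptance.py` run the search at
reduced subset sizes (1–2) and use the study-sized or smaller cohorts: the
ranking, determinism and recovery properties being checked are
size-independent, and the closed-form subset counts cover the full-scale
enumeration exactly. A full 584,934-subset search per task is what the
`search` CLI does when left at its defaults; it is embarrassingly parallel
(`--jobs`) and its deterministic merge makes the chunking invisible in the
output.

## Known limitations

* 2-D single-slice analysis only; no 3-D ROIs, ADC/DCE sequences, bias
  correction or segmentation.
* Best-subset AUCs carry selection optimism (see above); no held-out test
  cohort is built in.
* The KNN's k and the score threshold are design defaults, not values
  fixed by the source design.
* Correlation distance over very small feature subsets is coarse; the
  single-feature fallback is a documented extension of the stated metric.
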