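# Methods

## Pre-processing

Spectra are processed per spectrum in three steps, in this order by
default: cut to the fingerprint window, rubber-band baseline correction,
vector normalisation.

*Cut.* The fingerprint window is the closed interval [`cut_low`,
`cut_high`] in cm⁻¹, defaults 900–1800. Cutting before baselining keeps
the convex hull from anchoring on the silent high-wavenumber region; the
opposite order is available via `PreprocessConfig(cut_first=False)` since
either order is defensible and the choice is not uniquely determined by
common practice.

*Rubber band.* The baseline is the exact lower convex hull of the
(wavenumber, intensity) point set, computed by a monotone-chain scan and
linearly interpolated between hull vertices. Consequences used by the
tests: the corrected spectrum is non-negative, zero at every hull vertex
(including both endpoints), and invariant to adding any affine function of
wavenumber. No iterative windowing or smoothing is applied; the algorithm
is deterministic and parameter-free.

*Vector normalisation.* Each corrected spectrum is scaled to unit
Euclidean norm over the cut region, so only relative band intensities
remain. Normalising after the cut means the norm is not influenced by
regions that are later discarded.

## Classifiers

**PCA-LDA.** The training matrix is mean-centred and decomposed by SVD;
scores are projections on the leading `n_pcs` loadings (default 10). In
score space the model keeps per-class means, the degrees-of-freedom
weighted pooled within-class covariance Σ_pooled = Σ_k Σ_i (x−x̄_k)(x−x̄_k)ᵀ/(n−K),
and priors π_k (training proportions by default; a uniform option exists
because the convention is not universal). A spectrum is scored per class by
the quadratic discriminant L_ik = (x_i−x̄_k)ᵀΣ_pooled⁻¹(x_i−x̄_k) − 2 ln π_k
(evaluated via the Cholesky factor of Σ_pooled) and assigned to the argmin;
ties go to the first class in sorted order with a warning. A singular
pooled covariance raises an error advising fewer PCs rather than silently
regularising.

Separately from classification, `lda_projection` returns the projection of
PC scores onto the leading generalized eigenvectors of (between-class,
pooled within-class) scatter — at most K−1 axes — for score plots, box
plots and score-level ANOVA/MANOVA. The classifier and the 1-D plot score
are deliberately distinct objects: the quadratic score classifies, the
projection visualises.

**PLS-DA.** Classes are indicator-coded (a single 0/1 column for the
second of two sorted classes; one column per class otherwise) and
regressed on the spectra by NIPALS partial least squares
(`sklearn.cross_decomposition.PLSRegression`, `scale=False`) with a fixed
number of latent variables: 6 for the two-class model, 8 for the
four-group model. X and Y are centred inside the fit; the exposed
regression vectors b and intercept satisfy ŷ = Xb + intercept exactly, and
at full rank the fit reproduces ordinary least squares (tested against the
normal equations). The binary decision rule is ŷ ≥ 0.5 — the midpoint of
the 0/1 coding — with the boundary itself assigned to the positive class
under a warning; multi-group models assign by argmax. Requested components
beyond the rank of the centred training matrix are an error, not a
truncation.

Component counts are fixed by configuration, never auto-selected: the
models are meant to reproduce a fixed study configuration, and automatic
selection would change what is being validated.

## Cluster-vector discovery

Among the leading PCs the 3-combination maximising the multivariate Fisher
criterion trace(S_w⁻¹S_b) of the 3-D score projection is selected by
exhaustive search (≤ 120 combinations at 10 PCs; deterministic,
lexicographic tie-break). The scale-invariant form is used because a
trace-ratio criterion lets near-zero-variance PCs displace genuinely
separating ones.

For each class k the cluster vector is v_k = Σ_{j∈triplet} median(score_j
| class k) · loading_j, and the contrast vector is v_disease − v_control.
Peaks are local extrema of |contrast| ranked by magnitude with a greedy
minimum separation of 10 cm⁻¹ (the 12 marker bands are ≥ 31 cm⁻¹ apart, so
one broad band cannot fill several slots). Per-peak statistics are one-way
ANOVA of pre-processed intensity at the nearest axis point, with direction
the sign of the disease-minus-control mean; p-values are reported
unadjusted, matching how per-peak significance is conventionally printed,
with a Bonferroni flag left to the caller (multiply by the peak count).

## Monte Carlo cross-validation

Each iteration draws a stratified random split: per class,
round(test_fraction·n_k) spectra (at least 1, at most n_k−1) are held out,
the model is refit from scratch on the rest, and held-out spectra are
predicted. Stratification is imposed because an unstratified 20% draw of a
37-spectrum class would occasionally empty it. Defaults: 1000 iterations,
20% out, spectrum-level splits. Metrics per iteration come from the K×K
confusion table: AC = (TP+TN)/total·100; per-class one-vs-rest SENS =
TP/(TP+FN)·100 and SPEC = TN/(TN+FP)·100; multi-class accuracy is the
trace over the total (micro accuracy) and "average sensitivity/
specificity" the unweighted class mean. Undefined ratios are reported as
NaN, never as 0. Means over iterations and the mean confusion table are
returned; the whole procedure is reproducible from a seed.

Spectrum-level splitting reproduces the usual per-spectrum counting, but
with 17–20 technical replicates per subject it is optimistically biased:
replicates of one subject can sit on both sides of a split, so the
estimate partly reflects subject recognition rather than disease
signal. Subject-level splitting (`split_level="subject"`) holds out whole
subjects and is the honest generalisation estimate; with only 4 control and
8 disease subjects it is also much noisier. Both are provided; neither is
asserted as the only correct choice.

`score_manova` implements Wilks' Λ = det(W)/det(W+B) with Rao's F
approximation, hand-coded so that identical groups return exactly (1, 1)
and a single axis reduces algebraically to the one-way ANOVA F test; it is
cross-checked against `statsmodels`' MANOVA in the test suite.

## Synthetic cohort generator

The generator emulates the study conditions so the pipeline is testable
end to end without instrument data. Each spectrum is

  (Σ_b A_b(subject, replicate, class) · g_b(w) + background(w)) ·
  subject_gain · replicate_gain + ε(w)

on a 400–1800 cm⁻¹ axis with 2 cm⁻¹ steps, where g_b are Gaussian band
profiles and background is an exponentially decaying fluorescence
(amplitude 1.5, e-folding 700 cm⁻¹ — removed almost entirely by the
rubber band).

*Band library.* Sharp resolved serum bands (σ 3.5–9 cm⁻¹) include the 12
marker bands plus phenylalanine-dominated 1002 (amplitude 1.0, the
strongest resolved band), CH₂ 1452 (0.85) and several non-marker bands
(940, 1031, 1210, 1320, 1655). They ride on two very broad concave
components (centres 1300 and 1560 cm⁻¹, σ 250/220, amplitude 2.2)
modelling the congested envelope of overlapping protein/lipid bands that
dominates the integrated intensity of baseline-corrected serum spectra.
This proportion matters: vector normalisation converts any net class shift
into a small opposite "drag" on all unshifted structure, proportional to
the shifted bands' share of total spectral energy. With the envelope
dominant that share is ~5%, the drag stays ~3× below the weakest planted
contrast (verified in a noise-free skeleton analysis), and the
cluster-vector top-12 are the planted bands — as in real serum, where a
dozen marker bands are a small fraction of total scattering. A sparse
library without the envelope breaks this, which is a statement about
spectral composition, not about the discovery algorithm.

*Class effects.* Multiplicative band-amplitude shifts applied before
normalisation. Two-class default: ±3× the replicate noise SD (i.e. 6%
relative) at the 12 marker bands, positive except 1155. Four-group
default: the same shared disease effect plus subgroup-specific modulations
of 2× the replicate SD (4%) on three distinct bands per subgroup, so
subgroups separate from each other more weakly than disease separates from
control.

*Noise model, three levels.* Between subjects: a global intensity factor
(log-normal, SD 0.05; removed by vector normalisation) and per-band
amplitude jitter (SD 0.004) — inter-individual variation in serum
composition, kept below the class effect so planted-truth recovery is
well-posed. Between replicates of one subject: per-band amplitude jitter
(SD 0.02; sample drying, focus and positioning effects, which perturb band
intensities coherently) and a global gain (SD 0.02). Per point: additive
white noise (SD 0.002 relative to the strongest band), the detector floor
of a 20 s × 10 exposure average.

*Replicate design.* 4 HC subjects × 20 replicates; 8 disease subjects with
20, 20, 20, 17, 20, 20, 18, 19 replicates, grouped 2/2/4 into subgroups
totalling 40/37/77 spectra. The three sub-20 counts are fixed at 17/18/19:
only the group totals and the minimum of 17 are pinned by the design being
emulated, and this pattern meets both.

*What passing tests do and do not show.* The generator produces smooth,
low-rank, approximately Gaussian variation: the class signal lives in the
leading PCs, and near-perfect cross-validated accuracy on it shows the
pipeline is correct, not that real serum classification is this easy. Real
data adds cosmic rays, detector etaloning, water/substrate background,
day-of-measurement drift, and between-subject variation that is larger and
partly confounded with class — none of which is modelled. Spectrum-level
CV numbers on the synthetic cohort should be read as upper bounds of the
procedure under its own assumptions.

*Audit generator.* Request-level tables follow the testing cascade: ELIA
positivity (Bernoulli, default 128/600) triggers a CLIFT result (positive
with default probability 27/128, categories weak/positive/strong at
7:16:4). ELIA values are log-normal per stratum; CLIFT-positive values are
a three-component mixture (low tail above the 10 IU/mL threshold, a
100–170 IU/mL cluster, and a high cluster above ~379 IU/mL) so strong
positives concentrate at high values. Diagnosis labels (SLE / SLE-overlap /
other) are drawn per stratum (dual-positive 85/4/11%, ELIA-only
23/7.5/69.5%, ELIA-negative 4/1/95%). Marginal rates hold in expectation
only; a 600-request draw lands near, not on, the configured counts.

## Audit statistics

`summarise_cascade` uses strict > threshold ELIA positivity and reports
counts plus integer percentages (half-up rounding, matching how audit
figures are printed; full precision is kept internally). Percentages are
always recomputed from the counts. `diagnostic_metrics` builds the 2×2
table of a method against diagnosis = SLE: ELIA positive means value >
threshold; CLIFT positive means category ≥ 1, with requests lacking a
CLIFT result (cascade not triggered) counted test-negative. SLE-overlap
syndromes count as non-SLE by default (`include_overlap` flips this) —
the conservative reading, made explicit because the underlying convention
varies between audits. Zero denominators yield NaN with a warning.
Kruskal–Wallis (tie-corrected, via scipy) compares ELIA values across
CLIFT categories; Mann–Whitney U uses the exact distribution when both
groups have ≤ 8 values without ties and the tie-corrected normal
approximation otherwise.

## Numerical and design choices

- Axis orientation is ascending cm⁻¹ everywhere; descending instrument
  files are flipped on read, and duplicate wavenumbers are an error rather
  than averaged (silent averaging hides acquisition faults).
- PCA loadings use a deterministic sign convention (largest-magnitude
  element positive) so runs are bit-reproducible.
- All argmin/argmax ties break to the first class in sorted order with a
  warning; randomised tie-breaking would make confusion tables
  seed-dependent in a way that is invisible to the caller.
- Class order is sorted-unique everywhere ("HC" < "SLE" makes the disease
  class the positive/second class in binary codings).
- Problem sizes in the shipped tests: Monte Carlo runs use 200 iterations
  (or fewer for property checks) rather than 1000; with stratified 80/20
  splits of 234 spectra the iteration-mean metrics stabilise well below
  200 iterations, and `scripts/acceptance.py` runs the full 1000 for the
  two-class models.

## Known limitations

- "Rubber-band-like" baseline correction is implemented as the exact lower
  convex hull; instrument-vendor variants that window or iterate can
  differ in curved-background regions.
- The cluster-vector contrast is defined disease-minus-control from
  median-weighted PC triplet loadings; with more than two classes the
  contrast requires an explicit disease class and ignores the remaining
  classes' vectors.
- The audit module's diagnostic metrics depend on the diagnosis-set
  convention (overlap handling, untested-request handling); both switches
  are exposed because printed audit tables rarely state them.
- The MANOVA uses Rao's F approximation to Wilks' Λ, exact for ≤ 2
  response dimensions or ≤ 3 groups and approximate beyond.
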