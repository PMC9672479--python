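# Methods

`perfrad` analyses dynamic susceptibility contrast perfusion-weighted MRI
(DSC-PWI) in the *time* dimension: instead of collapsing the 4D series
into parameter maps (CBF, CBV, Tmax), it treats every timepoint as a 3D
image, extracts a full radiomics vector from each, and asks which of the
resulting time-indexed features distinguish hypoperfused tissue (HA)
from its mirror-symmetric normal counterpart (NA), and how much ischemic
tissue a hemisphere must contain before those features can flag it.

## The digital phantom

Patient DSC-PWI data are not publicly available, so the pipeline ships a
synthetic cohort generator that reproduces the *statistical* features the
method depends on, with ground truth attached.

**Signal model.** Each brain voxel carries a gamma-variate bolus
concentration curve

    C(t) = A * ((t - t0) / (alpha*beta))^alpha * exp(alpha - (t - t0)/beta),  t > t0

(peak-normalized: the maximum is `A`, reached at `t0 + alpha*beta`), and
the T2*-weighted signal is `I(t) = I0 * exp(-k * C(t))` — the transient
signal *drop* of a first-pass bolus. Defaults: baseline `I0 = 300`
(arbitrary scanner units), arrival `t0 = 8` timepoints, `alpha = 3`,
`beta = 1.5`, contrast coefficient `k = 1.2`, giving a peak signal drop
of roughly 70% in normal tissue — a deep first-pass trough typical of
gray matter.

**Lesion model.** A hypoperfusion region is grown by randomized
6-connected dilation inside one hemisphere of an ellipsoidal brain mask
until a target volume fraction is met (realized fraction within ±0.05 of
the target by construction). Inside the lesion the bolus amplitude is
multiplied by an `attenuation` factor (default 0.4) and arrival is
delayed (default 2 timepoints): the lesion's time–intensity curve drops
less and later, the qualitative signature of hypoperfused tissue. With
`attenuation = 1, delay = 0` lesion voxels are statistically identical
to normal tissue — the built-in null condition used for calibration
tests. The NA mask is the exact mirror of the HA mask about the
mid-sagittal plane.

**Heterogeneity and noise.** Per-voxel arrival time and amplitude are
jittered ±5% (uniform); the baseline carries a smooth Gaussian random
field (σ=1.5 voxels, ~6% relative amplitude) that is *mirror-symmetric*
about the mid-sagittal plane — mimicking bilaterally symmetric anatomy
and keeping the mirrored ROI pair exchangeable under the null — plus 2%
voxel-scale iid jitter so arbitrarily small ROIs have non-degenerate
texture. Measurement noise is additive Gaussian (default sd 2 signal
units, ~0.7% of baseline). This is a simplification of MR physics:
magnitude MR noise is Rician, and the phantom has no partial-volume
effects, no arterial input function, and no anatomy. Passing tests
therefore demonstrate that the *pipeline machinery* behaves as specified
under controlled conditions — not that the features would perform
identically on patient data.

**Cohorts.** `generate_cohort` draws per-subject lesion fractions
uniformly on [0.02, 0.5] and sides with equal probability, with
per-subject seeds spawned deterministically from one cohort seed. The
uniform fraction range is a stand-in: real lesion-volume distributions
are long-tailed, and no claim of distributional equivalence is made.

## Preprocessing

Temporal smoothing is a *triple moving average*: three successive passes
of a centered 1×3 mean filter along time, with repeat-padded edges
(`scipy.ndimage.uniform_filter1d`, `mode="nearest"`). The repeat-pad
choice keeps constant series exactly invariant, which is the anchor the
smoothing contract is tested against. A single-pass reading of "triple
moving average" was rejected as redundant with the 1×3 kernel; the pass
count is configurable.

Feature normalization is mean-centered range scaling,

    F* = (F - mean(F)) / (max(F) - min(F)),

applied per column; every output column has range exactly 1 and mean 0.
This differs from conventional min–max scaling (available behind
`variant="min-max"`), but both are per-column affine maps, so two-sample
t-test p-values are invariant to the choice — a property asserted
numerically at 1e-10. Constant columns cannot be scaled and are dropped
with a logged warning.

## The time-decomposed feature scheme

A T-timepoint series yields T single 3D images; each image, restricted
to an ROI, produces 1,316 features:

| bank | features |
|---|---|
| original image | 14 shape + 18 first-order + 24 GLCM + 16 GLRLM + 16 GLSZM + 5 NGTDM + 14 GLDM = 107 |
| 5 Laplacian-of-Gaussian scales (σ = 1–5 mm) | 5 × 93 non-shape = 465 |
| 8 one-level 3D wavelet sub-bands (coif1, undecimated) | 8 × 93 = 744 |

At the study geometry (T = 50) this gives 65,800 named features per ROI,
partitioned into nine reporting groups (Shape 700, First-order 900, GLCM
1,200, GLRLM 800, GLSZM 800, NGTDM 250, GLDM 700, Log-sigma 23,250,
Wavelet 37,200). Feature names follow the
`<filter>_<family>_<base>_<n>` convention with a 0-based timepoint
suffix, and parsing is the exact inverse of rendering.

The feature definitions follow the IBSI-style formulations standard in
the radiomics literature and use the conventional base names, so tables
are interoperable with other radiomics tooling. Implementation choices
worth knowing:

- Gray levels are discretized with a fixed bin width (default 25 signal
  units) starting at the ROI minimum; family cardinalities never depend
  on it. Small synthetic ROIs use a finer width (5) in the demo
  pipeline because their intensity range is narrow.
- GLCM pools symmetric co-occurrence counts over the 13 unique 3D
  directions into one matrix before computing statistics (rather than
  averaging per-angle features); GLRLM pools runs the same way.
  GLSZM zones and GLDM dependencies use 26-connectivity, dependence
  threshold α = 0 (the voxel itself counts, so dependence j ≥ 1).
- Shape features are mask-only: mesh volume and surface area from a
  marching-cubes surface in physical coordinates, axis lengths from the
  PCA of voxel coordinates, diameters from convex-hull vertices of the
  boundary voxel set.
- Everything is deterministic; identical (image, mask, config) inputs
  reproduce identical vectors bit for bit.
- The LoG response is scale-normalized (multiplied by σ²); wavelet
  sub-bands come from an undecimated transform, so masks apply
  unchanged (odd axes are edge-padded to even length and cropped back).

## Significance filtering

After normalization, each feature column is tested with an independent
two-sample t-test (HA = 1 vs NA = 0); features with p < 0.05 are
retained, with no multiple-testing correction — the retained set feeds a
multivariate selection stage, so the filter is a recall-oriented
pre-screen whose type-I rate (~5% on null features) is itself under
test. Student's equal-variance test is the default; Welch is available.
HA/NA pairs from the same subject are treated as independent samples by
design.

## The 13-method selection bank

Four families of scorers operate on the normalized, filtered table:

- **Information-theoretic (FI).** Plug-in mutual information in bits on
  discretized features (quantile binning, 5 bins, tie-aware so equal
  values always share a bin). MIM ranks by I(f;C); MIFS, MRMR, JMI and
  CMIM rank by greedy forward selection, each feature carrying its
  objective value at selection time (MIFS: relevance − β·Σ redundancy,
  β = 0.5; MRMR: relevance − mean redundancy; JMI: mean conditional MI
  given the selected set; CMIM: min conditional MI). When a ranking
  depth limit is configured, unranked candidates keep their current
  objective value.
- **Similarity (SIF).** Fisher score (between-class over within-class
  variance); Laplacian score on a k = 5 NN heat-kernel graph (kernel
  width = mean pairwise squared distance), negated so higher is better;
  ReliefF with k = 10 neighbors iterating over every sample.
- **Statistical (STF).** The F-score of the two class means against
  pooled class variances, and the (absolute) two-sample t-statistic.
- **Sparse/streaming (SSL).** MCFS: spectral embedding of a k = 10 NN
  graph into the single non-trivial eigenvector (a two-class problem
  needs K−1 = 1 embedding dimensions; more eigenvectors inject
  within-cluster noise directions into the score), followed by an L1
  (LARS) regression on standardized features, score = max |coef|.
  Alpha-investing: streaming least squares over features in column
  order, admitting a feature when the p-value of its incremental
  F-test beats the current investment α_i = w_i/(2i) (initial wealth
  0.5, payout 0.5); admitted features score 1 − p. Lasso: LassoCV
  (5-fold, seeded), scores |β| at the CV-optimal λ.

**Thresholding.** Lasso keeps coefficients with |β| > 0.02; every other
method min–max normalizes its scores to [0, 1] and keeps scores > 0.9;
all sets are truncated to the 20 best, ties broken lexicographically by
feature name so outputs are bit-reproducible. Per-member attributes
(squared Pearson correlation with the label, t-test p, information gain,
gain ratio = gain / H(binned feature)) are attached for reporting.

Unions are defined at two levels: `F_type` over each method family
(FI = {CMIM, JMI, MIFS, MIM, MRMR}, SIF = {Fisher, Lap, ReliefF},
STF = {FS, TS}, SSL = {MCFS, Alpha, Lasso}) and `F_all` over all 13,
duplicate-free in first-seen order.

## Evaluation and the composite score

Each feature set is scored by stratified tenfold cross-validation on ten
classifiers (RBF-kernel SVM with probability outputs, decision tree,
AdaBoost, an MLP with hidden layers (400, 100), L2 penalty 0.01 and up
to 10,000 iterations, random forest with 200 trees, k-NN, cross-validated logistic
regression with a liblinear solver, linear
discriminant analysis, gradient boosting, Gaussian naive Bayes), with
five metrics per fold: accuracy, precision, AUC, F1 and recall
(positive class = HA; undefined precision scores 0; AUC uses predicted
probabilities). Metric cells are unweighted fold means.

The family coefficient and composite score are

    H_type       = (1 / (K*M)) * Σ_{k,m} index(k, model(m, F_type))
    CS(F_method) = H_type * (1 / (K*M)) * Σ_{k,m} index(k, model(m, F_method))

with K = 5 metrics, M = 10 models, so CS ∈ [0, 1] and never exceeds the
set's own metric mean. The six sets with the highest CS form `F_top6`
(ties lexicographic). Samples enter folds as ROIs, not subjects,
mirroring the HA/NA design in which each subject contributes one sample
of each class.

## The lesion-proportion (RT) sweep

Each subject contributes two hemisphere samples (an 80-subject cohort
gives 160). For a slab of the middle S slices (S ∈ {3, 4, 5};
slices [⌊(Z−S)/2⌋, ⌊(Z−S)/2⌋+S)), a hemisphere is labeled positive when
its slab lesion fraction — lesion voxels over brain voxels of that
hemisphere's slab — *strictly* exceeds a reference threshold RT, swept
over {0.00, 0.01, …, 0.39} (40 values × 3 slab heights = 120 cells).
Positive counts are non-increasing in RT by construction.

Per cell, the top-6 features are *recomputed on the slab mask* (not
sliced from whole-brain features — texture statistics do not restrict),
Lasso re-selects a subset (F′_RT_S), and the ten-model CV harness scores
it. The cell's composite score uses the slab-level top-6 union as its
coefficient set, mirroring the family-union role of H_type in the HA/NA
stage. Cells whose labels collapse to a single class (or leave fewer
positives than folds) are flagged degenerate and carry no metrics.

## Numerical and design choices

- Tie-breaks are lexicographic by feature name everywhere a ranking is
  cut, and by method name in CS ranking.
- All randomness flows from one root seed through named substreams
  (phantom, selectors, CV folds), derived via CRC32-tagged
  `SeedSequence`s; reruns of the same config + seed are byte-identical.
- MI estimation uses 5 quantile bins; with tie-aware binning a binary
  feature reduces to exactly two codes, which makes small-instance
  oracles exact.
- The t-score scorer uses the absolute t-statistic: a sign-blind
  ranking is the only reading consistent with a one-sided score
  threshold on min–max normalized scores.
- Degenerate inputs fail loudly: masks with fewer than two voxels or
  one gray level raise errors naming the offending family; constant
  feature columns are dropped at normalization; single-class label
  vectors are rejected.

## Problem sizes

The package's demo scale — used by the bundled pipeline configuration,
the test suite and the acceptance script — is a 16×16×8 grid with 12
timepoints, first-order + GLCM features, 12-subject cohorts for the
HA/NA stage and 60 subjects for the proportion sweep (S = 4, nine RT
values). The full feature scheme is exercised at study geometry
(64×64×20, T = 50, all 65,800 features) on a single phantom. These sizes
were chosen so a complete run finishes in minutes on one CPU while still
exhibiting every contract the larger geometry obeys.

## Known limitations

- Gaussian (not Rician) noise; no motion, no partial volume, no AIF.
- The phantom's HA/NA contrast is governed by two parameters
  (attenuation, delay); real hypoperfusion exhibits richer
  time-curve pathology (dispersion, recirculation).
- Hemisphere splitting assigns the odd midline column to neither side.
- ROIs from the same subject share acquisition noise; the CV design
  (folds over ROIs) replicates the original analysis and is therefore
  not leakage-proof at the subject level.
- The 13 selectors expose many hyperparameters the underlying
  objectives do not fix; the defaults above are documented choices, not
  canonical constants.
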