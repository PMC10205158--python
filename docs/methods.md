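# Methods

This note documents the models, numerical choices and known limitations of
`lexrsa`, in the order data flows through the pipeline.

## Lexical similarity models

All models are square symmetric word-by-word matrices carried in a common
container with an *orientation* flag (similarity vs dissimilarity).  Rank
correlations downstream negate dissimilarity matrices, so only the sign
convention matters, never the scale — which is why the neighbourhood-density
matrix is kept as a raw count difference rather than remapped to [0, 1].

- **Affective space.**  Pairwise Euclidean distance in the (valence,
  dominance, arousal) space, **normalised by the maximum pairwise distance in
  the word set**, then `s = 1 − d`.  The normaliser is a design choice: it
  maps similarities onto [0, 1] with the most distant pair at exactly 0 and
  makes the output invariant to common shifts and scalings of the rating
  dimensions.  A word set with all-identical ratings has no defined
  normaliser and raises.
- **Embedding cosine.**  Plain cosine between embedding rows; zero-norm rows
  raise with the offending word named.
- **Phonological similarity.**  `s = 1 − lev(a, b)/max(|a|, |b|)`.  The
  Levenshtein distance is normalised by the longer string so `s` is bounded
  in [0, 1]; the distance itself is computed by `edlib` and checked against a
  naive exponential recursion in the tests.
- **Neighbourhood density.**  `|dens_i − dens_j|`, orientation =
  dissimilarity.
- **Wu–Palmer.**  `2·depth(LCS)/(depth(a) + depth(b))` with node-counting
  depth and `depth(root) = 1`, the common WordNet convention; this keeps all
  values strictly positive.  Words missing from the taxonomy raise with the
  full list, so callers drop them and the correlogram intersects labels
  across models (mirroring analyses that lose a few words to coverage gaps
  in lexical databases).

RDM vectors use one fixed pair ordering everywhere: row-major upper triangle,
`(i, j)` with `i < j`.  Ties in every rank transform use average ranks.

## Model-level statistics

- **Pearson–Filon z** for two dependent overlapping correlations `r12` vs
  `r13` with overlap `r23` on n observations (two-sided normal p).  Checked
  against the published value (z = −11.4 for 0.065 vs 0.310, overlap 0.458,
  n = 2145) and for type-I calibration under a simulated trivariate null.
- **Summary-statistics ANOVA.**  One-way F reconstructed exactly from group
  means, SDs and sizes; equals a raw-data ANOVA on any sample engineered to
  those summaries.  Used for checking arousal matching across valence
  classes from printed summaries.

## Activation extraction

- **Framewise displacement** is the sum of absolute differentiated
  realignment parameters, rotations converted to arc length on a sphere of
  configurable radius (default 50 mm, the most common convention — the FD
  definition itself does not fix one).  QC excludes whole runs whose maximum
  FD exceeds 1 mm; trials are never censored individually.
- **Trial AUC.**  Each trial's activation is the trapezoidal integral of the
  voxel signal over [onset+2 s, onset+8 s], sampling the linearly
  interpolated signal on the TR grid, minus the interpolated signal value at
  onset times the window length.  The onset-value baseline is a design
  choice (the AUC rule itself does not fix a baseline): it removes slow
  drifts and the constant offset without fitting a GLM.  With TR = 1 s the
  rule is exact for piecewise-linear signals, and the whole extraction is
  one weight-vector-per-trial matrix product, which also makes linearity
  exact.  Trials whose window runs past the end of the run are dropped with
  a warning.
- **Pooling** averages each word's retained trial maps over runs, tasks and
  modalities (overt and covert trials are pooled identically); control
  trials are excluded.  Averaging (not concatenation) is assumed, giving one
  pattern per word.
- **tSNR** is voxelwise mean/SD of a residual series; flat voxels get NaN,
  not an error.  **Grey-matter masks** binarize probability maps at a strict
  `> 0.3`.

## Searchlight RSA

- **Neighbourhoods** are the k nearest in-mask voxels by millimetre distance
  (k = 200 in the reference design), not a fixed radius: fixed k equalises
  pattern dimensionality across centers.  Ties are broken by lexicographic
  voxel index, making neighbourhoods bit-reproducible across platforms.  No
  sulcus-aware mitigation is applied: a sphere may span opposite sulcal
  walls.
- **Centring** subtracts the across-condition mean pattern within each
  searchlight before cosine similarity — the conventional centring for
  cosine-based RDMs, without which the shared activation component inflates
  all similarities.
- **Partial Spearman** is rank-then-residualize: all RDM vectors are
  rank-transformed (average ranks), target and model are residualized on the
  covariate ranks by least squares (with intercept, via QR), and the
  residuals are Pearson-correlated.  With one covariate this equals the
  closed form `(r_xy − r_xz r_zy)/√((1−r_xz²)(1−r_zy²))` on ranks, which the
  tests verify.  A vector fully explained by its covariates (e.g.
  partialling a model out of itself) has partial correlation 0 by
  definition; the implementation returns exactly 0 rather than numerical
  noise.
- **Order of operations** is fixed as ρ → Fisher z (atanh, |ρ| = 1 becomes
  missing) → Gaussian smoothing.  Smoothing (default FWHM 8 mm, configurable;
  the kernel width is a package default, not prescribed by the analysis)
  renormalizes kernel weights over valid in-mask voxels, so constants are
  preserved at mask edges and missing voxels contribute nothing.
- Degenerate searchlights (zero-variance or undefined neural RDMs) propagate
  as missing values and are excluded from group statistics.

## Group inference

- Voxelwise one-sample t (df = N−1) on z-maps; a voxel enters only if finite
  for **all** subjects; zero across-subject SD is flagged missing.  The
  paired test is the one-sample test on subjectwise differences, exactly.
- **Cluster-extent FWE** replaces random-field theory (whose smoothness
  estimation is not reproducible from a methods description) with
  **sign-flipping permutation**: under a symmetric zero-centred null,
  flipping whole subject maps is exchangeable.  The voxel-forming threshold
  is one-sided p < 0.001 (positive effects, matching the direction of RSA
  hypotheses); clusters use 18-neighbour connectivity (the SPM convention).
  All 2^N flips are enumerated when N ≤ 12, otherwise random flips drawn
  from the seed; with random flips the observed statistic is counted into
  the null (the add-one rule), keeping the test exactly valid.  Corrected p
  is the proportion of null max-cluster-sizes at least as large as the
  observed cluster.
- The max-cluster-size statistic is discrete: on unsmoothed,
  spatially-independent noise nearly all suprathreshold clusters have size
  1 and the test is strongly conservative.  Calibration (≈ 5% familywise
  rate) holds in the regime the pipeline actually produces — smoothed maps —
  and that is what the calibration tests simulate.
- Peaks are reported in voxel indices and mm (via the affine); anatomical
  labelling is out of scope.  A small utility returns the across-subject
  mean and t-based CI of a map value at a chosen voxel.

## Synthetic data generator

The generator's defaults are the reference study conditions: 66 words in
three valence classes of 22; 8 runs × 77 trials (66 word + 11 control) per
subject; ISI 8.25 s; TR 1 s.  The volume is a desk-scale 20×20×22 grid of
2 mm voxels (an ellipsoidal "brain" probability blob with mild texture), so
a full subject simulates and analyses in seconds; correspondingly the
searchlight used on this grid in the validation tests is k = 33, scaled with
the grid as k = 200 is to a whole brain.

- **Word side.**  Valence is drawn per class (positive ≈ 5.7, neutral ≈ 4.0,
  negative ≈ 2.3 on the 1–7 scale); arousal follows the U-shaped relation to
  valence with the negative end slightly higher, reproducing the typical
  slight arousal imbalance of valence-matched designs; dominance is
  class-independent.  Embeddings are a mixture `(1−λ)·G + λ·F` of a random
  base G and an affective-aligned component F (an eigenfactorization of the
  affective similarity matrix), with λ tuned by bisection until the
  embedding-cosine RDM correlates with the affective RDM at a configured
  target (±0.02; default 0.065, the published affective/co-occurrence
  overlap).  Because cosine RDMs ignore a global sign flip, negative targets
  below the random baseline are unattainable and raise.
- **Brain side.**  Each signal region's target similarity matrix
  `S = Σ w_m S_m` is factored by eigendecomposition (negative eigenvalues
  truncated — exact when the mixture is already a Gram matrix, as cosine
  matrices are) into condition scores, projected onto the region's voxels
  through a random orthonormal basis: the Gram of the planted patterns
  equals S exactly, so at zero noise the extracted neural RDM reproduces the
  planted mixture (verified at ρ > 0.99 end-to-end).  Cosine normalizes
  overall scale, so mixture weights are recoverable up to a common factor;
  recovery tests compare weights normalized to unit sum.
- **Response kernel.**  A double-gamma-like shape (peak ≈ 4 s, small late
  undershoot) brought smoothly to zero by a cosine taper and truncated at
  8 s — inside the 8.25 s ISI — so consecutive trial responses never
  overlap.  The AUC rule integrates the raw signal and never fits this
  kernel, so any plausible shape would do; compact support is what makes
  zero-noise recovery exact rather than approximate.
- **Noise and motion.**  Gaussian voxel noise (default SD 1.0 against unit
  RMS patterns — a moderate single-trial SNR, chosen once as a realistic
  regime for a validation simulator) on a baseline of 100; motion traces are
  small random walks, with a > 1 mm translation step planted exactly in the
  configured violating runs.
- All randomness flows from the seed passed to each generator call; fixtures
  derive per-subject seeds from the master seed via `SeedSequence`.

### What the generator does not emulate

Real anatomy and MNI geometry; modality- or task-specific signal
differences; articulation motion artefacts beyond FD violations;
physiological noise structure (the noise is white in space and time); scanner
drift.  Passing recovery tests therefore shows the *pipeline* is correct and
well calibrated, not that effects of this size would be detectable in real
data — real cluster sizes, t-values and peak coordinates from the original
study are expressly not reproduction targets.

## Problem sizes used in the validation suite

Planted-geometry recovery and the independence mirror run 10 independent
simulated groups of 4 subjects each at the full reference trial structure on
the 20×20×22 grid; error-rate calibration uses 12–14 subject pure-noise
groups over 500 simulations (cluster FWE) and ~10⁵ independent voxels
(voxelwise rate).  These sizes were chosen so the whole suite runs on a
single CPU in a few minutes while leaving the statistical assertions
well-powered.
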