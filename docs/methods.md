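# Methods

## Data model

All analysis operates on per-bundle matrices `Y` (subjects × voxels) of one
scalar microstructure metric, extracted from template-space maps inside
binary bundle masks. Voxel order is lexicographic in 0-based (i, j, k)
template coordinates — a pure function of the coordinates, so vectors are
comparable across subjects whenever the maps share the template grid (voxel
correspondence is assumed; registration is upstream of this package). The
bundle catalogue is fixed: 71 bundles in a TractSeg-style nomenclature, with
the corpus callosum represented only by its seven subparts (callosal
subregions are differentially vulnerable, so a whole-CC average would blur
exactly the structure of interest).

### Endpoint trimming

Track-weighted metrics are noisiest at cortical terminations. `trim_track_weighted`
retains the central 80 % (configurable) of voxels ranked by their
mean value across controls, dropping `floor((1−f)/2·V)` columns at each tail;
tail-mean voxels proxy endpoints without needing streamline geometry. The
column set is defined once, on controls, and applied to all subjects, so
voxel correspondence survives. A trimmed matrix records its retention
fraction, and re-trimming at the same fraction is a no-op by contract: no
rank- or quantile-based rule can be literally idempotent (re-application
always finds new tails), so trimming is defined relative to the untrimmed
tract and the metadata enforces one application.

### Ipsi/contra role space

Patients are analysed relative to their epileptogenic side: for a left-sided
focus, left bundles are *ipsi* and right bundles *contra*; mirrored for a
right focus; commissural bundles are unchanged. The label map is an
involution at fixed side. Group comparisons pair a patient's role tract with
the control tract on the same anatomical side as the focus. Since pooled
patient groups mix left- and right-sided foci while controls have no focus,
each control contributes the mean of its left and right values for
lateralized role tracts (a side-symmetric reference that keeps one value per
control); the reference can be pinned to one side instead.

## Stage 1: group statistics and FOI selection

Per-subject tract means are compared between patients and controls with a
bootstrapped two-sample test: the statistic is the Welch t (robust to the
unequal group sizes typical here, e.g. 37 vs 18), and the null distribution
is built by recentring both samples to the pooled mean and resampling each
group with replacement (`n_boot` = 2000 by default). The two-sided p-value
carries the add-one correction `(r+1)/(n_boot+1)`, so it is never zero and
remains a valid p-value. Bundles with `p < α/m` (strict inequality, family
α = 0.05, m = number of tested tracts; per-test threshold ≈ 7.0×10⁻⁴ for 71
tracts) are the fascicles of interest. Whether to resample subjects or
residuals is a genuinely open design point; subject resampling under a
shifted null was chosen because it preserves each group's empirical shape
while imposing the null mean difference, and its type-I error is verified by
simulation in the test suite.

## Stage 2: alteration-pattern clustering

Centered profiles (patient tract mean − control group mean, per FOI) are
clustered with Ward linkage on Euclidean distances between tract rows; a
`1 − Pearson r` distance is available for correlation-structure clustering.
The cluster count is chosen by the elbow rule: within-cluster dispersion
W(k) is evaluated at each candidate k on the same linkage tree, the scree is
anchored at k = 1 (total sum of squares) so the first real partition can be
the knee, and the knee is the point of maximum distance below the chord
joining the curve's endpoints (both axes normalized to [0, 1]; ties break
toward smaller k; a flat curve returns the smallest candidate with a
warning). Solutions are validated with silhouette scores (singleton
clusters contribute 0 and are flagged) and the matrix of inter-centroid
distances.

## Stage 3: the normative manifold

For one bundle, controls define the normative model `Y = f(x) + ε`:

- **Embedding.** `x` are control coordinates from UMAP (default:
  `n_neighbors = 15` capped at n−2, `min_dist = 0.1`, fixed `random_state`)
  or PCA (`reducer="pca"`), d = 2 by default. The model is frozen after
  `fit()`: projecting patients never mutates the stored embedding.
- **Out-of-sample projection.** A patient vector is mapped to the
  Gaussian-weighted barycentre of the k = 5 nearest controls' embedding
  coordinates, with weights Gaussian in *tract-space* distance (bandwidth =
  median of the k distances). This rule is reducer-agnostic and
  deterministic; exact copies of a training control map onto that control's
  own embedding point. The reducer's native transform is available as an
  alternative (`projection="transform"`).
- **Back-projection.** `f(x)` is the Nadaraya–Watson estimate
  `Σ K(‖x−x_i‖/h) Y_i / Σ K`, Gaussian kernel, bandwidth h = median pairwise
  latent distance among controls (scale-free; overridable). At a control's
  own embedding coordinate the regression is taken as interpolating (the
  h → 0 limit at coincident nodes), so training vectors reconstruct exactly;
  elsewhere f is a smoother, i.e. the local mean of the closest controls.
  Kernel weights are computed with a log-sum-exp shift; should every raw
  weight underflow, the nearest control's vector is returned with a warning.
- **Residual scale.** ε is standardized per voxel by the SD of leave-one-out
  control residuals: each control is projected and back-projected through
  the model restricted to the remaining controls. By default only the
  regression is refit per fold (`refit_embedding=True` re-runs the reducer —
  the slow, fully faithful mode). SDs are floored at 1e-12 and flagged.
  Note a local-constant smoother has nonzero LOO residuals even on noiseless
  low-rank data (its local-averaging bias); the scale is therefore the SD of
  *model* residuals, not of measurement noise alone, which is exactly what
  patient z-scores should be standardized by. On well-specified synthetic
  data the recovered scale is within a few percent of the generative noise
  SD and held-out control z-scores are approximately standard normal (both
  verified in the tests).
- **Latent dimension.** `choose_latent_dim` scores each d by voxel-block
  cross-validation (Eastment–Krzanowski style): the reducer is refit without
  the held-out control, a linear readout from latent to tract space is
  fitted on the remaining controls, the held-out subject's latent coordinate
  is estimated from its *observed* voxels only, and the withheld voxel block
  is predicted. Naive whole-vector reconstruction always improves with d
  (the held-out vector leaks through any out-of-sample transform); the
  block scheme makes superfluous dimensions add prediction variance instead.
  Ties break toward smaller d. Analyses use the optimized d; 2-D plots and
  latent probability maps always use a d = 2 embedding for display.
- **Group divergence.** D(A‖B) between patient and control latent clouds is
  the Wang–Kulkarni–Verdú k-NN estimator (k = 3), clipped at zero; inference
  permutes group labels (`p = (r+1)/(n_boot+1)`) with a Bonferroni-style
  corrected threshold α/m, tightened further if an explicit stricter
  threshold (e.g. 0.001) is configured. Absolute divergence magnitudes
  depend on the estimator and bandwidth choices and are not comparable
  across implementations; only the permutation inference is.
- **Agreement.** Tract-level |t| and divergence are each standardized to
  zero mean/unit SD across tracts; the Bland–Altman bias of the standardized
  difference is zero by construction, so the per-tract differences and
  their SD carry the actual disagreement and are reported alongside.

## Stage 4: lesion maps

Per-voxel z-scores are thresholded at the two-sided Bonferroni-adjusted
normal quantile z* = Φ⁻¹(1 − (α/2)/N). N defaults to the voxel count of the
analysis at hand (a single bundle, or the merged FOI family); a fixed
override (e.g. 4.8, the value for N ≈ 31,500 at α = 0.05) is available. A
decrease-only mode (`z < −z*`) exists for display of metrics where damage
lowers the value; testing defaults to two-sided. %RL = 100 × deviant/total
voxels (reported to 2 decimals) uses the trimmed voxel set — the analysis
space — as denominator. Whole-brain maps take the union of per-tract
deviance over overlapping bundles, storing the signed maximum-|z|; group
maps average binary deviance across patients.

## Stage 5: brain–behavior

Spearman correlations (average ranks for ties, t-approximation p-values)
relate tract or cluster features to covariates with pairwise deletion;
cells with fewer than 5 complete pairs are flagged, not computed, and both
raw and Bonferroni-adjusted p columns are emitted (tract-level screening is
conventionally read at raw p < .05). Latent probability maps fit a logistic
regression on 2-D latent coordinates and evaluate class probability on a
bounding-box grid (10 % margin); continuous variables are binarized at a
recorded cut (default median; 0.4 for an absolute fMRI lateralization
index, the conventional bound for "highly lateralized"). VLBM restricts to
voxels lesioned in ≥ 6 patients (≈ one-third of an 18-patient cohort),
correlates the continuous z (binary status available) with the behavioral
score, and corrects family-wise error by the permutation distribution of
the maximum |r| over analyzed voxels (5000 permutations by default; add-one
p-values; corrected ≥ uncorrected by construction).

## Synthetic cohorts

`SynthConfig` defaults encode the reference study conditions: 37 controls,
10 left- and 8 right-lateralized patients; 71 bundles of 400–700 voxels;
FA-like values (baseline ≈ 0.5, per-voxel SD 0.05, spatial correlation
length 5 voxels, exact per-voxel SD enforced via the smoother's impulse-
response norm); 25 affected role tracts in 3 alteration patterns; a
standardized tract-mean decrease of d = 2.5; one contiguous lesioned segment
per affected tract covering 5 % of its voxels at 8 residual SDs, decrease
only (damage lowers FA-like metrics; partial, contiguous tract damage is
what the pipeline is meant to resolve). Patterns differ in severity level
(spread 0.3) and in per-patient severity vectors (within-pattern spread
1/pattern_separation); covariates are rank-coupled to per-pattern structural
burden through a Gaussian copula at configured strengths (e.g. verbal-memory
score vs pattern-1 burden at ρ = 0.8). Everything planted is recorded in a
ground-truth dictionary and the cohort is a deterministic function of the
master seed.

Not emulated: diffusion signal, streamline geometry, realistic anatomy
(bundles occupy disjoint blocks of a 40×48×40 toy grid), scanner or site
effects, and registration error. Passing recovery tests therefore
demonstrates the statistical machinery under its own assumptions, not
robustness to real-world preprocessing failures.

`planted_pattern_profiles` generates centered profile matrices directly
(pattern centroids plus isotropic noise at a configured between/within
separation) for clustering-specific checks.

## Problem sizes and numerical conventions

- The lesion-recovery analyses (tests and `scripts/acceptance.py`) run 12
  bundles (10 affected) at 500 voxels per tract with the group-mean effect
  switched off, isolating focal-lesion recovery; the expected mean %RL is
  then the planted 5 %. With the global decrease active, voxel-level
  deviance is bounded-above but systematically larger than the focal
  fraction — both components are genuine signal.
- Type-I-error checks use 500 null simulations at n_boot = 1000 (bootstrap
  test) and 100 simulations at 400 permutations (VLBM FWE), compared against
  99 % binomial bounds.
- %RL rounds half-up at 2 decimals via standard rounding; a ratio such as
  66/811 = 8.138 % prints as 8.14.
- Seeds: every stochastic routine takes an explicit seed; pipeline
  orchestration derives child seeds from one master seed.

## Known limitations

- The Nadaraya–Watson back-projection is a smoother: patient residuals
  conflate measurement noise with local-averaging bias. The leave-one-out
  standardization absorbs this on average, but anomaly sensitivity degrades
  where the control cloud is sparse.
- With ~20–40 controls, UMAP neighborhoods are small and the embedding is
  largely driven by global distances; PCA gives very similar downstream
  anomaly results at these sample sizes and is the faster verification path.
- The kernel out-of-sample projection assumes a patient's vector lies near
  the control manifold except for focal damage; a globally aberrant patient
  projects to the nearest region of the control cloud and the resulting
  residual is attributed across many voxels.
- KL divergence point estimates are estimator-dependent; compare only
  within one configuration.
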