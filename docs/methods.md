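# Methods

`semrsa` implements a representational similarity analysis (RSA) stack
for studying how semantic structure — in particular the similarity
geometry of abstract concepts — is shared between brain activity
patterns and distributional-semantics models, together with a
synthetic-data generator that plants known structure so every stage can
be validated end to end without access to fMRI recordings or a
45-million-sentence corpus.

## Neural dissimilarity: the cross-validated correlation distance

The unit of neural data is a `PatternSet`: run × condition × channel
beta estimates (one activation pattern per word per run, channels =
voxels).  For a pair of conditions *(i, j)* the runs are split into two
halves in every possible unordered 50/50 way (10 runs → 126 splits; for
odd run counts, ⌊n/2⌋ vs ⌈n/2⌉ halves — a natural extension beyond the
even-run design).  Patterns are averaged within each half, and

- within = ½ [corr(i_A, i_B) + corr(j_A, j_B)]
- between = ½ [corr(i_A, j_B) + corr(j_A, i_B)]

with Pearson correlation over channels.  The dissimilarity is
within − between, averaged over splits.  Because the two halves carry
independent noise, the estimate is unbiased around zero for
indistinguishable conditions; entries may legitimately be negative and
are never clipped.  Larger values mean more discriminable conditions.
A half-averaged pattern with zero variance makes the correlation
undefined and raises a degenerate-pattern error naming the condition
and split.

Model RDMs come from feature vectors (1 − Pearson r between rows; used
for embedding vectors and DNN activation vectors alike) or from scalar
word properties (pairwise absolute differences; valence, arousal, and —
log₁₀-scaled, since frequency effects are conventionally logarithmic —
relative word frequency).

## RDM comparison

Two label-aligned RDMs are compared by correlating their
lower-triangle vectors.  Pearson is the default (it is the natural
companion of the Fisher transform applied afterwards); Spearman is
available via a flag, implemented as Pearson on ranks.  The Fisher
transform atanh(r) uses a clamp of 1e−7 from ±1 so self-comparisons
stay finite.

Partial correlation regresses both triangles (with intercept) on the
control triangles and correlates the residuals; with one control this
reduces to the textbook formula
(r_xy − r_xz r_yz)/√((1−r_xz²)(1−r_yz²)).  If an RDM is an exact linear
function of the controls the residual is numerically zero and its
direction meaningless, so the comparison raises a degenerate error
rather than returning noise.  Rank-deficient control sets raise a
collinearity error.

## Searchlight

A sphere of radius r voxels (default 3; Euclidean metric on the voxel
lattice, isotropic) is centered on every masked voxel; radius 3
contains 123 offsets.  Neighborhoods are clipped to the mask; those
smaller than `min_voxels` (default 10) are skipped and counted.  Per
neighborhood the cross-validated RDM is computed and compared —
optionally with partial-correlation controls — to the model RDM, and
the Fisher z is written at the center.  Skipped or degenerate centers
carry NaN (not zero) so group statistics can exclude them.

Two engines produce identical maps (tested to 1e−12): a `direct`
per-neighborhood loop that literally reuses the RDM functions, and the
default `fast` engine, which obtains every neighborhood's correlation
sums at once by convolving the masked half-mean volumes (and their
squares and pairwise products) with the spherical kernel.  Volumes are
centered on their within-mask mean per condition first; neighborhood
covariances are translation invariant, and the smaller magnitudes keep
the sum formulas numerically accurate.

## Group statistics

Subject Fisher-z maps are combined voxelwise with one-sided one-sample
t-tests (greater than zero).  Voxels with a NaN sentinel in any subject
are excluded listwise, so the permutation null sees a fixed voxel set.
Zero-variance voxels follow an explicit degenerate contract (t = ±inf,
p = 0/1; all-zero data gives t = 0, p = 0.5).

Cluster-extent familywise error uses a sign-flip permutation null: the
thresholded t-map (one-sided p < p_voxel, default 0.001) is labeled
into connected components (26-connectivity default; 6/18 available) and
a cluster is significant iff its extent exceeds the 1 − α quantile
(α = 0.05) of the maximum-extent distribution over sign-flipped
recomputations.  This is an assumption-light stand-in for parametric
random-field cluster inference; equivalence with SPM's numbers is not
claimed.  The one-sample sign-flip null assumes subject maps are
symmetric around zero under H0, which holds for Fisher-z maps from
independent subjects.

TFCE integrates extent^E · height^H · dh over thresholds (defaults
E = 0.5, H = 2, dh = max/100 — the toolbox-standard exponents; the
source analyses cite the toolbox without printing values).  It is
applied to the group t-map by default (the mean map is a flag), and its
null is built from sign-flip permutations.  The observed TFCE value at
each voxel is converted to p = (1 + #{null ≥ obs})/(1 + n_perm) and
then to a normal z-score.  This rank-based construction is exactly
calibrated under exchangeability — the calibration tests rely on it —
whereas z-scoring against the null mean/sd (available via a flag) is
not, because voxelwise TFCE null distributions are skewed with a point
mass at zero.  Two details protect exchangeability: the step dh is
derived from the maximum over the observed *and* permuted maps
(a symmetric function of the exchangeable set), and when the requested
permutation count reaches 2^n subjects the null is enumerated
exhaustively.

Benjamini–Hochberg FDR (step-up, with the standard monotone adjusted
values) handles ROI model families.  It is implemented in-package and
cross-checked against statsmodels and a literal brute-force step-up in
the tests.

## ROI analyses and model families

An ROI is one cluster of the group cluster table; its provenance
records the model that defined it.  The ROI RDM is the same
cross-validated computation with the ROI as a single neighborhood.
Model families (embeddings trained on nested corpus prefixes, or on
abstract-only/concrete-only corpora) are evaluated per subject by
Fisher-z comparison with the ROI RDM; each model gets a one-sided t
against zero with BH-FDR across the family, and a two-sided paired t
against the reference (full) model.  The model that defined the ROI is
never tested against zero in the same result object — a
selection-circularity guard; its row carries NaN.  Robustness checks
delete single words or random subsets (sizes uniform on 1..subset_max,
the size distribution being otherwise unspecified) from both RDMs and
report the mean r per deletion.

## Skip-gram embeddings

Because no embedding library is available in the runtime environment,
skip-gram with negative sampling is implemented in-package (numpy
bookkeeping, a sequential numba SGD kernel).  Defaults follow the
reference analysis: 300 dimensions, window 5 (dynamically shrunk per
center, as in word2vec), min_count 1, 50 epochs.  Settings the source
does not state are declared, not inferred: 5 negative samples from a
unigram^0.75 noise distribution, initial learning rate 0.025 decaying
linearly to 1e−4, no frequency subsampling, no language-specific
tokenization (corpora are pre-tokenized, one sentence per line).  All
randomness flows from one seeded generator and the kernel is
single-threaded, so training is bit-reproducible.

Corpus operations: prefix fragments (the first n sentences, so smaller
fragments are exact prefixes of larger ones) and token-level
concreteness filtering — a token survives an abstract-only corpus iff
its concreteness z < 0, a concrete-only corpus iff z > 0 (strict
inequalities; z = 0 is excluded from both), or if it is in an explicit
keep list (the target stimuli are retained in the concrete-only corpus
so their relations to concrete words stay learnable).  Deletion is
token-level, not sentence-level: removing whole sentences containing
any off-category word would destroy nearly all data.  Tokens without a
norm entry cannot be classified and are dropped and counted.

## Synthetic data: what is emulated and what is not

**Brain data.**  Latent condition vectors (row-centered Gaussians,
default 61 conditions after the stimulus set) define the reference RDM
as their correlation distance.  Each subject's signal region mixes them
through a per-subject projection with centered orthonormal columns,
fixed across runs, plus i.i.d. Gaussian noise per run (default
sd 1.0 — noise level and effect size are free desk-scale choices, not
reported quantities; `signal_scale_for_snr` converts a target per-voxel
SNR into the projection scale).  The centering/orthonormality
construction makes noiseless voxel-space correlations equal
latent-space correlations *exactly*, so geometry-recovery tests can
demand Spearman 1.0 rather than approximate rank agreement.  Not
emulated: hemodynamics, temporal autocorrelation, anatomical variation,
spatial normalization — synthetic subjects share one grid.  A green
localization test therefore establishes correctness of the analysis
chain, not robustness to fMRI artifacts.

**Corpora.**  Sentences are Markov chains over a clustered vocabulary:
token marginals are Zipfian (exponent 1.0, the natural-language
profile; rare words need far more data, which is what gives model
families a visible learning trajectory), and words sharing the previous
token's cluster have their odds boosted by `within_cluster_boost`
(default 20 for strong structure; the trajectory experiments use 2 with
a 100-word vocabulary so the structure is learned gradually).  The
two-cluster convenience spec aligns clusters with the concreteness
split and interleaves them in frequency rank.  This is deliberately not
a language model: it creates learnable co-occurrence structure and
nothing else.

**Ratings** are uniform on [1, 9] per word and scale, mirroring a 9×9
affect grid; **nuisance RDMs** mix the reference lower triangle with
orthogonalized noise to hit a requested correlation exactly; **null
maps** are i.i.d. N(0,1) subject maps used to calibrate the group
inference layer directly (a searchlight run on noise-only volumes
exercises the same null at smaller scale).

## Numerical choices

- Fisher clamp 1e−7 from ±1; correlations clipped to [−1, 1] before
  transforming.
- Constant patterns are detected exactly (all entries equal) in the
  direct path and via a relative variance floor (1e−12 of the raw sum
  of squares) in the convolution path.
- Cluster peak = maximum-t voxel; ties broken by array order.
- The pipeline derives every stage seed from the global seed through a
  seeded integer draw; artifacts are hashed into a manifest, and reruns
  with the same config are byte-identical.

## Known limitations

- Mahalanobis/crossnobis distances, noise-covariance whitening, and
  encoding models are out of scope by design.
- No surface-based searchlights, anisotropic voxels, or GPU batching.
- The convolution engine computes one pair of convolutions per
  condition pair and split; for very large condition counts on large
  grids the direct engine with a restricted mask may be preferable.
- Permutation inference assumes exchangeable, sign-symmetric subject
  maps; it does not model between-subject variance components.
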