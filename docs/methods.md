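# Methods

This note documents the models and procedures implemented in `stemnet`, the
choices made where the design was genuinely open, and what the synthetic
test surface does and does not establish.

## Functional connectome

Functional connectivity (FC) between two parcels is the Pearson correlation
of their time-series; the group connectome is the element-wise arithmetic
mean of the subject matrices, with no Fisher z-transform before averaging
(averaging raw r is the literal reading of the group-averaging convention
this pipeline follows; at typical FC magnitudes the difference is small but
not zero, so the choice is fixed and documented). Sample statistics use
n−1 denominators; Spearman correlations use average ranks on ties. Inputs
must be complete: the pipeline rejects NaNs and constant rows rather than
imputing, because silent imputation would corrupt the similarity profiles
downstream. Reported p-values are floored at 1e−300.

Quality-control analyses: temporal SNR (time-series mean over sample SD, on
series with the mean retained) and its Spearman association with parcel
size; FC as a function of Euclidean centroid distance within cortex, within
brainstem, and between; Welch's unequal-variance t-test comparing
brainstem–cortex FC against within-brainstem FC; and split-half reliability
(random disjoint halves of the subject pool, group connectome per half,
Pearson correlation of the two halves' unique FC entries and degree maps,
repeated with a seeded generator).

## Weighted degree and annotation maps

Weighted degree is the plain sum of signed FC over a seed set — no
thresholding and no absolute value, so positive and negative coupling can
cancel. Summed over the 400 cortical parcels it ranks brainstem-to-cortex
hubs; summed over the 58 brainstem nuclei it ranks cortex-to-brainstem
hubs. Degree maps are compared to per-parcel annotation maps (receptor
densities, MEG band power, meta-analytic term maps) by Pearson or Spearman
correlation, with significance from either the parametric test or the
spatial permutation null below. Batch comparisons apply Benjamini–Hochberg
FDR (no multiple-comparison procedure is canonical for small map batteries;
FDR at 0.05 is the default and is exposed as an option). Term decoding
ranks term maps by Pearson r and flags the top 10% — the flagged count uses
the floor of `top_fraction * n_terms` (at least one), matching the
convention of showing "the 12 (10%)" most correlated of 123 terms; exact
ties at the boundary are broken lexicographically by term name so output is
deterministic.

## Residual profiles and similarity matrices

Both structures couple to the brainstem through one dominant pattern: every
node's brainstem-connectivity profile is strongly correlated with the
brainstem-to-cortex weighted-degree vector. To expose structure beyond it,
that degree vector (computed once, from the same group FC) is regressed out
of each region's 58-length brainstem profile by ordinary least squares with
an intercept — the intercept matters: residuals differ without it, and
"regressing a map out" conventionally includes one. Spearman correlations
of residual profiles give a brainstem × brainstem similarity matrix (each
nucleus's 400-length residual cortical profile) and a cortex × cortex
similarity matrix (each region's 58-length residual brainstem profile).
The 58 × 58 brainstem-row residual block is computed identically when
requested (`rows="all"`) but nothing downstream consumes it.

## Signed-modularity consensus communities

The brainstem similarity matrix is a correlation matrix, so community
detection uses the asymmetric signed modularity

Q(γ) = (1/v⁺) Σᵢⱼ (w⁺ᵢⱼ − γ p⁺ᵢⱼ) δ(σᵢ,σⱼ) − (1/(v⁺+v⁻)) Σᵢⱼ (w⁻ᵢⱼ − γ p⁻ᵢⱼ) δ(σᵢ,σⱼ)

where w⁺/w⁻ are the positive part and the magnitude of the negative part,
pᵢⱼ = sᵢsⱼ/v is the configuration null within each sign, v± is the total
strength of each sign, and sums run over ordered pairs with diagonal null
terms included. For all-positive graphs this reduces exactly to
Newman–Girvan modularity at resolution γ (verified against networkx at
1e−12). Negative within-community weight is penalized at the weaker
1/(v⁺+v⁻) normalization, so the optimizer "maximizes positive correlations
within communities and negative correlations between communities". Graphs
with no negative part simply drop the second term; a graph with no positive
part is rejected (the normalization is undefined).

Optimization is a two-phase Louvain written directly against this quality
function: greedy local moves with node visitation order shuffled per sweep
from the seed (ties keep the current community; moves require a gain above
1e−12), then aggregation into super-nodes with self-loops, repeated until no
level improves. The returned quality is an exact re-evaluation of the
quality function on the final labels. On exhaustive enumerations of all
877 partitions of 7-node graphs, best-of-50-seeds Louvain attains the global
optimum in ≥95% of random signed graphs.

Consensus clustering follows the agreement-matrix procedure: the
co-assignment frequency over repeated runs is thresholded at the mean
agreement of label-permuted null partitions (100 permutations) and the
thresholded matrix — a positive-weight graph — is re-clustered at γ = 1
until all runs agree. Two details are not pinned down by the literature the
procedure comes from and were decided here: the agreement matrix is kept
weighted (not binarized) before re-clustering, and the null threshold is the
mean permuted agreement. When runs disagree only through an order-dependent
tie cycle (binary or cycling agreement matrix), the consensus is the
connected components of always-co-assigned pairs; this guarantees
termination at extreme resolutions where partitions are intrinsically
unstable. Partition stability across runs is summarized by the mean and
variance of the pairwise z-scored Rand index under the hypergeometric
pair-counting null (verified against exact enumeration over all
permutations at small n). The resolution sweep covers γ = 0.1–6.0 in steps
of 0.1 (60 values) with 250 repetitions per γ by default; validation runs
use a coarser 0.5-step grid and 50 repetitions to keep runtimes short.

## Diffusion map gradients

The cortical similarity matrix is embedded with the field-standard recipe:
per-row sparsification keeping the strongest 10% of entries, cosine
similarity between sparsified rows clamped to be nonnegative, anisotropic
normalization with α = 0.5, and a dense eigendecomposition of the resulting
Markov operator (via its symmetric conjugate, so the computation is
deterministic). Scores are the unit-normalized nontrivial right
eigenvectors scaled by their eigenvalues; the kernel, sparsity and α are
not dictated by the analysis being reproduced and are therefore exposed in
the configuration and recorded in the result. Component sign is arbitrary;
it is canonicalized against a caller-supplied reference map when comparing
gradients (flipping so r ≥ 0) and otherwise so the largest-magnitude score
is positive. A disconnected affinity graph is rejected with the component
count, and the leading eigenvalue is required to be simple. Pole-wise
degree maps sum a nucleus's FC over all negatively- or positively-scored
cortical regions; exact zero scores are excluded and counted.

## Dominance analysis

Community degree maps are modelled by OLS (with intercept) on z-scored
receptor/transporter density maps; model fit is adjusted R². Dominance
analysis partitions the full model's adjusted R² into per-predictor
contributions: a predictor's total dominance is the level-weighted
(Shapley) average of its incremental adjusted R² over all submodels —
average the increment over subsets of each size, then average across sizes.
This is the definition under which the dominances sum exactly to the full
model's adjusted R² (an unweighted average over all 2ᵖ−1 submodels does not
telescope); the empty model is assigned 0. All 2ᵖ−1 submodels are solved
from sufficient statistics (the predictor correlation matrix and
predictor–response correlations), never from raw data, which makes the
exhaustive p = 18 enumeration (262,143 submodels) run in seconds. Designs
beyond the exhaustive limit are rejected rather than silently approximated
by sampling. Rank-deficient designs are rejected with the collinear
predictors named (pivoted QR).

## Spatial permutation nulls

Correlations between cortical maps are tested against rotation nulls that
preserve spatial autocorrelation. Each hemisphere is treated as its own
full sphere (the convention of surface-based spherical projection). Per
spin, one uniform random rotation (QR-orthonormalized Gaussian matrix,
determinant +1) is applied to the left hemisphere and its x-mirror
conjugate to the right — mirroring keeps left/right spins congruent; the
alternative (independent rotations per hemisphere) is equally defensible
but less constrained, and mirroring is the deterministic choice. Within
each hemisphere, original parcels are reassigned the values of the rotated
parcels by the one-to-one assignment minimizing total Euclidean distance
(Hungarian algorithm), so permutations never cross the midline and every
permuted map is an exact rearrangement of the original. The p-value uses
the (count+1)/(n+1) estimator and is never exactly zero. Brainstem and
midline nodes are never spun; statistics involving brainstem-side maps use
parametric inference, as no brainstem-appropriate spatial null is defined.
Calibration is checked empirically: under independent spatially
autocorrelated surrogate pairs, the two-tailed rejection rate at α = 0.05
falls inside the binomial 95% interval.

## Synthetic data generator

The generator emulates the data layout of a 7T resting-state study:
400 cortical parcels and 58 brainstem nuclei (50 in bilateral mirrored
pairs, 8 midline), 20 subjects, three concatenated runs of 210 volumes at
TR = 2.5 s. Cortical parcels are quasi-uniform Fibonacci lattices on two
mirror-symmetric unit spheres (one per hemisphere) with a small seeded
jitter; anatomical centroids place the hemispheres side by side and the
brainstem in a compact inferior cluster. Brainstem parcel sizes are drawn
log-uniform on [10, 1500] voxels so size/tSNR checks are exercisable.

Time-series are zero-mean Gaussian draws from a latent-factor covariance
Σ = L diag(σ²_f) Lᵀ + σ²_n I; runs are independent draws, concatenated.
Because the pipeline consumes only correlations, no temporal
autocorrelation is simulated, and the effective sample size equals the
number of timepoints. The factors:

- **Global factor** (SD 0.9): nonnegative loadings uniform on [0.7, 1.3]
  for every node. Induces the dominant weighted-degree pattern; recovery is
  measured as the Spearman correlation between brainstem weighted degree
  and the planted loading.
- **Community factors** (one per community, SD 0.9): each loads on its
  community's nuclei (indicator with ±5% multiplicative spread) and on the
  cortex through that community's *network map*: a Gaussian bump along the
  planted axis (rank-space width 0.18, outermost bumps saturated past their
  centers so the axis has no fold-back at the poles) plus a spatially
  autocorrelated component (15 mm kernel-smoothed noise, weight 0.4)
  orthogonalized against the bumps and across communities, z-scored.
  Distinct maps make the five communities separable in the brainstem
  similarity matrix; the bump ordering plants a smooth 1D manifold in the
  cortical profiles. Cortical network labels are the argmax over maps, so
  each network is coupled 1:1 to a community.
- **Gradient factor** (SD 1.2): signed cortical loadings spanning [−1, 1]
  (tanh of the normalized z-coordinate, slope 1.2 — gentle saturation
  populates both poles without long runs of near-ties) and brainstem
  loadings scattered widely (±0.3) around 0.2 × the community's axis
  position. The small community mean keeps the gradient factor from
  coupling adjacent communities' cortical profiles (which would merge them
  under community detection); the wide within-community spread is what
  orders nuclei along the axis in the cortical similarity rows.
- Independent noise, SD 1.

These magnitudes were chosen once so that the planted structure is
recoverable by the pipeline at the study's sample size (20 × 630 frames):
weighted degree recovers the global loading at ρ ≳ 0.95, consensus
clustering recovers the five communities at ARI ≥ 0.9 at some resolution in
a coarse sweep for the large majority of seeds, and the first diffusion
gradient recovers the planted axis at |ρ| ≳ 0.96. No published effect sizes
exist to calibrate against, so the defaults aim at recoverability under the
stated design, not at matching empirical FC magnitudes.

Surrogate annotation maps are Gaussian-kernel smoothings of white noise on
the cortical centroids (within hemisphere — smoothing never crosses the
midline), z-scored; their spatial autocorrelation rises monotonically with
the kernel scale (checked with Moran's I).

What the generator does **not** emulate: temporal autocorrelation and
hemodynamics, physiological and scanner noise, motion, field
inhomogeneity near the brainstem, inter-subject anatomical variability, and
receptor maps with realistic cross-tracer correlation structure. Passing
recovery tests therefore establishes that the pipeline's inference chain is
correct and well-calibrated under its own statistical assumptions — not
that those assumptions hold in real 7T data.

## Numerical conventions

- Degenerate inputs are rejected loudly (constant rows, empty seed sets,
  rank-deficient designs, disconnected affinity graphs), never patched.
- Spearman on degenerate (constant) rank vectors reports ρ = 0, p = 1.
- One-way ANOVA with zero between-class variance reports F = 0, p = 1; zero
  within-class variance reports F = ∞, p = 0.
- The z-Rand score of two partitions whose pair-count variance is zero
  (e.g. both trivial) is NaN, flagged rather than raised, so consensus
  summaries can skip degenerate pairs.
- All stochastic procedures (Louvain order, consensus nulls, split-half
  draws, rotations, the generator itself) take explicit seeds; identical
  seeds give bit-identical results.

## Validation problem sizes

The test suite exercises exhaustive oracles at small n (877 partitions of 7
nodes; all 720 relabelings of 6 nodes for z-Rand; brute-force assignment at
5 nodes per hemisphere) and planted-structure recovery at the full study
size (458 nodes, 20 subjects, 630 frames per subject, 20 seeds), with a
coarse γ grid (0.5 steps) and 50 consensus repetitions per γ; the
calibration experiment uses 500 surrogate pairs × 1000 spins. These sizes
are the package's validation design.
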