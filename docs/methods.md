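# Methods

This note records the modeling choices behind `fermsense`: what each stage
assumes, the parameters that matter, what the synthetic data generator does
and does not emulate, and the numerical conventions adopted where the
method leaves room.

## Problem setting

Several labeled *source* working conditions (batches with offline assays of
cell concentration X and product concentration P) and one unlabeled
*target* condition are observed through six auxiliary channels
(v, T, q, pH, Do, P). The conditions induce different feature
distributions — predominantly covariate shift from instrument calibration
and environment — while the mechanism linking the process state to the
labels is assumed shared. The goal is to predict the target condition's X
and P trajectories.

## Transfer component analysis

For one source (n samples) and the target (m samples), the squared
empirical MMD is tr(KL) with K the kernel matrix of the stacked pool and
L the block-constant coefficient matrix (1/n², 1/m², −1/nm). TCA solves

    min_W  tr(Wᵀ K L K W) + μ tr(Wᵀ W)   s.t.  Wᵀ K H K W = I,

solved here as the generalized symmetric eigenproblem
(K H K) w = λ (K L K + μ I) w, keeping the m_c leading eigenvectors and
rescaling each column so the constraint holds (a generalized eigenvector's
A-quadratic form is λ times its B-form). Determinism is pinned by making
each column's largest-magnitude entry positive. The fit is transductive —
all available unlabeled target features enter the pool — and new samples
are embedded by their kernel rows against the stored pool (empirical
kernel map).

Choices and defaults:

- **Channel scaling.** Channels mix rpm, °C and MPa, so each channel is
  z-scored with pooled source+target statistics before kernel evaluation;
  the scaler is stored on the model and reapplied at transform time.
- **Kernel.** RBF with the median pairwise distance of the scaled pool as
  bandwidth; configurable (linear available).
- **μ = 1.0**; the ridge mainly conditions the pencil, results are
  insensitive over 0.1–100 (the constraint fixes the scale).
- **Centering matrix** is I − (1/N)11ᵀ — the only idempotent reading.
- **m_c.** The library default is min(8, n+m−1). The *pipeline* default is
  m_c = 2: the constraint normalizes every component to equal centered
  scatter, so components beyond the few that carry the shared
  biomass-driven variance inject equalized noise directions that differ
  between source and target and measurably degrade transfer on the
  synthetic studies. With six channels, two components retain the
  dominant shared structure.

## LSSVM regression

The dual saddle system is solved by a Schur complement on the bias: with
A = Ω + I/γ (SPD), solve A u = 1, A v = y by Cholesky, then
b = 1ᵀv / 1ᵀu and α = v − b u. This satisfies Σα = 0 to round-off and
matches a dense solve of the full (N+1)×(N+1) system to 1e−8 (tested).
Inputs are assumed pre-scaled by the upstream embedding; the module does no
internal re-scaling to avoid double-scaling.

## Goshawk optimization

Both variants are population minimizers with greedy acceptance only, so the
best-so-far trace is non-increasing by construction; box bounds are
enforced by clipping. Per iteration NGO runs the prey-identification rule
(move by r(p − I x) toward a fitter random peer, r(x − p) away otherwise;
r ~ U[0,1], I ∈ {1,2} per coordinate) and the chase rule
x + R(2r−1)x with R = 0.02(1 − t/T).

INGO replaces the first rule by a sine–cosine blend
(1−ω)x + ω·sin(r1)|r2 p − x| (cosine branch when the peer is not fitter),
initializes the population from the cubic chaos map x ← ρx(1−x²), and
perturbs the incumbent best once per iteration with
r₁(x_best − x_i) + r₂(x_rand − x_i) evaluated as a candidate point.
Scheduling of the three ingredients (sine–cosine in phase 1, chase
retained, perturbation on the incumbent) is this package's wiring; the
ingredients themselves define the variant.

Conventions where the formulation is open:

- **ω(t) = cos(π t³ / (3T³))(ω_max − ω_min) + ω_min** with ω_max = 0.9,
  ω_min = 0.4: smooth, equals ω_max at t = 0, argument capped at π/3 so
  the factor stays positive and monotone.
- **ρ = 2.595**, a standard full-range cubic-chaos coefficient
  (ρ · max x(1−x²) < 1 keeps orbits in (0,1)).
- **r1 ~ U[0, 2π], r2 ~ U[0, 2]** in the sine–cosine rule, and absolute
  values around the attraction terms (standard sine–cosine-algorithm
  form).
- Two independent r draws in the differential perturbation.

On 2-D sphere and Rastrigin at equal budget (N = 30, T = 100), INGO's
final fitness is not worse than NGO's in paired-seed comparisons; both
reach < 1e−4 on sphere in ≥ 19/20 seeds (tested).

## MIC machinery

MIC between two paired sequences is the maximum over grid shapes (a, b)
and cut placements of plug-in mutual information normalized by
log₂ min(a, b). Conventions:

- **Budget.** Shapes satisfy a·b ≤ max(4, ⌈count^0.6⌉) with a, b ≥ 2. The
  floor of 4 guarantees the 2×2 family exists even for six-point
  sequences, where a literal count^0.6 budget would forbid every grid.
- **Cut search.** Candidate cuts are midpoints between consecutive
  distinct sorted values. Up to 12 points the placement search is
  exhaustive (and the 2×2 family is evaluated exactly by a vectorized
  membership-matrix sweep at any size); beyond that, equi-quantile
  candidates with greedy local refinement.
- MIC depends only on the orderings of the two sequences, so it is
  invariant under strictly monotone transformations and indifferent to
  the channels' physical units.

**Subset centroids.** Within one source subset, every pair of samples is
MIC-scored by pairing their six channel values; the sample with the
largest off-diagonal row sum is the raw centroid Z\* (ties to the smallest
index). Per-feature information against the reference is taken as each
feature's contribution to the dependence between sample i and Z\*: the
pointwise mutual information of that feature's paired point under the
MIC-optimal grid of the (Z\*, x_i) scatter, clamped at zero. The entropy
method then converts column shares ρ_id into entropies
E_d = −Σ ρ log ρ / log n_q and weights ω_d = (1−E_d)/(d − ΣE_d), which sum
to one; log n_q (not log d) is the normalizer that keeps E_d in [0, 1]. A
"features" normalizer mode preserves the alternative reading. When every
channel's shares are uniform (e.g. an all-identical subset) the weight
denominator vanishes and the centroid falls back to uniform weights. A
constant channel scores zero information and hence maximal weight under
the literal 1−E form; `drop_constant_channels` opts out of that behavior.

**Scoring and fusion.** A test sample is MIC-scored raw against each
ω-scaled centroid (the literal reading; symmetric scaling of the test
sample is available). Sub-models with score ≥ θ are fused with
score-normalized weights; θ is a policy (median of the scores by default,
mean or a fixed value optionally) clamped into [min O, max O] so the
selection is never empty. With six-point sequences only 2×2 grids are
admissible, and for centroid-like monotone profiles a pure 2×2 split
almost always exists, so scores frequently saturate at 1.0 for every
sub-model — the weighted ensemble then coincides with the equal-weight
ensemble. This coarseness is inherent to scoring d = 6 paired points; the
ensemble's value on the synthetic studies comes mainly from averaging
adapted sub-models, with MIC weighting acting as a tie-respecting
refinement.

## Synthetic study generator

Latent kinetics: logistic growth dX/dt = μ_max X (1 − X/X_max) with
Luedeking–Piret product formation dP/dt = α dX/dt + β X, Euler-integrated
on the sampling grid (180 samples, t = 0.5 … 90 h). Defaults
μ_max = 0.12 h⁻¹, X_max = 110 g/L, α = 0.05, β = 0.002 h⁻¹, X0 = 1 g/L,
P0 = 0 give sigmoidal trajectories on realistic axes. Auxiliary channels
are driven by the biomass fraction — stirring and airflow ramp with oxygen
demand inside [300, 400] rpm and [150, 300] L/min, temperature near 28 °C,
pH near 5.0 drifting mildly acidic, dissolved oxygen declining as
Do_sat(1 − 0.7·X/X_max), pressure within [0.02, 0.05] MPa — plus Gaussian
measurement noise, then clipped to plausible physical bounds (clips
logged).

A working condition applies multiplicative kinetic perturbations
(log-normal, sd 0.02–0.03) and per-channel affine calibration shifts
(gains log-normal sd 0.08, offsets a few percent of each channel's range).
Source 0 is the unshifted reference; the target's shift is drawn at
`target_shift_scale` (default 1.5), so scale 0 reproduces the reference
distribution. Calibration dominates by design: the generator emulates the
covariate-shift structure the method addresses, with a nearly shared
feature-label mechanism.

What the generator does **not** emulate: multi-stage induction dynamics
(e.g. glycerol-to-methanol phase switches), feed-rate control loops,
autocorrelated sensor faults, missing data, or batch-to-batch variation in
the label assay itself. Passing tests therefore demonstrate the machinery
and its directional behavior under clean covariate shift, not performance
on any real campaign.

## Study harness and problem sizes

Sub-model fitness is k-fold cross-validated RMSE on the embedded source
data (contiguous time-block folds, so validation blocks are held-out
stretches of trajectory); the target's labels are never touched during
training. Hyperparameters are searched in log10 space over
γ ∈ [1e−2, 1e4], σ ∈ [1e−2, 1e2]. The pipeline defaults to a modest
budget — population 10, 20 iterations, 3 folds, a 120-sample strided
subsample per condition — which keeps a 20-study ablation at laptop scale;
the standalone optimizer defaults remain N = 30, T = 100. The ablation
ladder compares, on identical held-out target labels: a fixed mid-bounds
LSSVM, NGO- and INGO-tuned no-transfer models (trained on a
source-stratified pooled subsample capped at one condition's size, so all
rungs see comparable training sets), each single-source TCA sub-model, and
the equal-weight and MIC-weighted ensembles. The equal-weight ensemble's
RMSE is bounded by the mean single-model RMSE for every dataset (convexity
of the norm); the remaining orderings are empirical and hold in 20-seed
means on the default generator.

## Numerical conventions and degenerate inputs

- 0·log 0 = 0 throughout; empty grid cells contribute nothing.
- Values equal to a grid cut fall in the upper cell.
- TCA eigen-selection errors out if fewer than m_c eigenvalues exceed
  1e−12 rather than returning unnormalizable columns.
- The LSSVM solver reports the condition number when the regularized
  kernel matrix is not positive definite.
- A single-sample LSSVM degenerates to the constant model (α = 0, b = y₁).
- Optimizer fitness must be finite; the offending point is named
  otherwise.
- Constant channels pass through the z-scorer with unit divisor.

## Known limitations

- TCA aligns marginal distributions only; under genuine concept shift
  (changed feature-label mechanism) nothing constrains the embedding to
  preserve label relevance.
- MIC over six paired points is extremely coarse (scores quantized, often
  saturated), so sub-model weighting rarely departs from uniform; with
  more channels the scoring would sharpen.
- The per-iteration wiring of the INGO ingredients is one defensible
  choice among several; alternatives (e.g. perturbing every individual)
  would change exploration behavior.
- The transductive TCA fit requires target features at training time;
  fully inductive deployment to a never-seen condition is out of scope.
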