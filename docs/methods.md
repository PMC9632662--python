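# Methods

## Problem and data model

The observed data is a binary matrix `A` over `nm` miRNAs and `nd` drugs,
`A(m_i, d_j) = 1` when resistance of drug `d_j` has been linked to miRNA
`m_i`. The task is to rank the zero cells by their probability of being
unobserved true associations. Inputs arrive as a two-column edge list
(identifiers are sorted lexicographically to fix matrix order), an optional
FASTA of miRNA sequences (T normalized to U), and an optional precomputed
drug chemical-structure similarity matrix; all are plain text.

## Similarity channels

**GIP kernel.** `GSM(i,j) = exp(−δ_m‖A(i,:)−A(j,:)‖²)` with
`δ_m = δ′_m / mean_i‖A(i,:)‖²`, and the column analogue `GSD`. The
bandwidth primes `δ′_m = δ′_d = 1` by default; they rescale the kernel's
sensitivity to profile differences and are exposed in `GipParams` because
no principled default is singled out by the method itself. An all-zero `A`
leaves the bandwidth undefined and is an error.

**Sequence similarity.** `SSM(i,j) = 1 − d(i,j)/(len_i + len_j)` with `d`
the unit-cost Levenshtein distance (computed by `edlib`, cross-checked in
the tests against a quadratic DP oracle). The normalization bounds values
in [0, 1]; identifiers without a sequence get zero rows and fall through to
the GIP channel at fusion.

**Fusion.** `SM` takes `SSM` where nonzero and `GSM` elsewhere (drugs:
`ESD` else `GSD`), diagonal forced to 1. This is a hard switch, not a
blend: a zero in the primary channel is read as "no evidence", not
"evidence of dissimilarity".

## Inclined restart walks

The drugs associated with one miRNA form that miRNA's *drug group*, and
vice versa. Group weights sum fused similarity from a group to every
entity and are max-normalized per target entity (columns of `W_MM`
(nd×nm) and `W_DD` (nm×nd) then have maximum 1 when nonzero). For drug
walker `d_x`, the unnormalized transition score into miRNA `m_j` is the
group weight `W_DD(m_j, d_x)` when positive — the "incline" toward the
walker's own neighborhood — else the similarity `SM(m_i, m_j)`.

Columns are normalized to sum to 1, giving a column-stochastic matrix so
that the propagation `P_{t+1} = (1−r)·T·P_t + r·P_0` conserves probability
mass; the iteration contracts at rate (1−r) and is stopped when the L1
change drops below 1e-10 (max 1000 iterations; non-convergence raises with
the final residual). The restart vector is uniform over the walker's
associated partners; walkers with no associations restart uniformly over
all nodes (logged) so every feature row remains a distribution. Restart
probability defaults to r = 0.7, favoring the walker's local neighborhood;
the closed form `P = r(I − (1−r)T)^{-1}P_0` is used as the test oracle,
never in the pipeline. Per-walker transition matrices are built one at a
time, keeping peak memory at O(nm² + nd²).

The stationary vectors stack into `P_D` (nd×nm) and `P_M` (nm×nd), reduced
to `X = U_d Σ_d^{1/2}` by truncated SVD with d = 50. When rank < d the
missing columns are zero — feature width stays constant — and each singular
vector's sign is canonicalized (largest-magnitude entry positive) so
embeddings are deterministic.

## HeteSim relevance

Relation matrices are the row-normalized `A`, `Aᵀ`, `SM`, `SD`. The
reverse step `I_DM` (row-normalized `Aᵀ`) is required to reverse the right
half of a path even though only three forward matrices define the schema.
All `M…D` type sequences of length 2–4 are enumerated (2 + 4 + 8 = 14) in
a frozen order — length ascending, then lexicographic with M < D — so
trained models are portable across runs.

For an even-length path the relevance of `(a, b)` is the cosine of row `a`
of the left-half reachability product and row `b` of the reversed
right-half product; both end at the central node type, so the vectors are
commensurate. Odd-length paths have no central node: the two admissible
split points each give a well-defined per-pair cosine, and the two scores
are averaged. (Averaging the two half *matrices* instead is shape-
incompatible; averaging the scores is the natural well-defined reading and
coincides when shapes agree.) Zero-norm reachability rows score 0. All
relation entries are nonnegative, so scores live in [0, 1].

## Classifier and evaluation

Feature vector per pair: 14 HeteSim scores, then the drug's `X_D` row,
then the miRNA's `X_M` row (width 14 + 2d = 114 at defaults). Features are
z-scored with training-fold statistics (RBF kernels need commensurate
scales; toggleable). The SVM solves the soft-margin RBF dual with C = 64
and the "scale" bandwidth heuristic `γ = 1/(width · var)`; the kernel
width is a genuinely open choice and is configurable. The fitted object
exposes support vectors, dual coefficients and bias, and the tests verify
both dual feasibility (α ∈ [0, C], Σα_i y_i = 0) and that evaluating the
kernel expansion directly reproduces the solver's decision values.
Probability scores apply a sigmoid fitted to training decision values by
1-D logistic regression — monotone, so decision and probability modes rank
identically. Negatives are sampled uniformly from the zero cells at 3:1
negative:positive.

Cross-validation is stratified (plain "equal division" can produce
single-class folds at small n). Two leakage modes:

* `paper` — features computed once from the full `A` before splitting.
  This mirrors the common published protocol but lets test-pair edges
  shape their own features.
* `strict` (default) — per fold, the test positives are zeroed out of `A`
  and GIP, diffusion and HeteSim features are recomputed before training.
  Sequence and chemical similarities are association-independent and are
  computed once.

Leave-one-drug-out ranking zeroes the drug's column, excludes that column
from the training sample entirely, retrains, and scores all miRNAs against
the held-out drug; the default reporting cutoff on calibrated scores is
0.95. Ranked drugs with no remaining edges are a cold-start setting in
which only the chemical-similarity channel carries drug-side signal, and
calibrated scores can be nearly flat.

## Synthetic data generator

The generator emulates the three real inputs with one planted co-cluster
signal: round-robin assignment of 100 miRNAs and 60 drugs to 4 clusters,
edge probability 0.3 within a cluster and 0.02 across, sequences of length
22 mutated at rate 0.1 from one prototype per cluster, and drug similarity
0.8/0.2 (within/between) with ±0.05 uniform noise. Empty rows/columns get
one forced within-cluster edge so GIP bandwidths stay defined. Every
feature family therefore carries the same recoverable signal, which makes
feature-group ablations meaningful.

What the generator does **not** emulate: the heavy-tailed degree
distribution of curated resistance databases, realistic miRNA sequence
composition, and any dependence between edges beyond cluster membership.
Passing the synthetic tests shows the machinery recovers planted structure
under its stated conditions; it does not certify performance on curated
data.

### The strict-mode performance ceiling

In this generator, edges are independent Bernoulli draws given the cluster
labels. Once a test pair's edge is masked from `A`, every feature the
pipeline can compute is conditionally independent of that pair's label
given cluster co-membership, so the Bayes-optimal strict-mode ranking is a
function of co-membership alone. An oracle scoring 1(same cluster) with
the true labels achieves AUC ≈ 0.81–0.84 under the 3:1 negative-sampling
protocol (in-cluster fractions ≈ 0.83 of positives vs ≈ 0.19 of sampled
negatives). Measured strict-mode AUC is ≈ 0.68–0.75 — somewhat below the
ceiling because training positives retain their own edges in `A`, so the
SVM partly keys on a visible-edge signal that masked test positives lack
(a known pathology of transductive link-prediction features) — while
paper-mode AUC on the same data is ≈ 0.9995. The gap is the point: it
quantifies how much of a leaky protocol's headline number is leakage.

## Numerical choices and problem sizes

* Walk convergence: L1 norm, tol 1e-10, max 1000 iterations.
* Similarity symmetry enforced to 1e-12; loaded matrices symmetrized with
  a warning when asymmetry exceeds 1e-8; values outside [0, 1] beyond 1e-8
  are errors.
* Prediction ties are broken by (miRNA id, drug id) for stable output.
* Test and acceptance runs use 10×8 to 100×60 networks and 3–5 seeds —
  sizes at which the oracles (dense solves, exhaustive path enumeration)
  are exact and the full strict-mode protocol runs in seconds.

## Known limitations

* Chemical-structure similarity is consumed, never computed; pairs of
  drugs absent from the provided matrix rely purely on the GIP channel.
* The two-type schema (miRNA, drug) is fixed; no lncRNA/disease layers.
* Negative sampling treats unknown pairs as negatives; ranking metrics
  inherit that assumption.
* Alternative classifiers can be plugged in behind the same train/predict
  contract, but only the SVM is a supported deliverable.
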