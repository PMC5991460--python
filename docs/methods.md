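# Methods

## The clustering problem

Multilayer omics studies measure several molecular levels on the same
subjects.  This package handles the canonical three-layer design: copy
number variations (CNVs, `X`, n×r), gene expressions (GEs, `Y`, n×p) and
proteins (`Z`, n×q).  Biologically these layers are connected in
*regulatory channels*: a group of CNVs regulates a group of GEs, which
encode a group of proteins.  The analysis goal is to cluster the
**variables** (not the subjects) so that each cluster contains the CNVs,
GEs and proteins of one channel — single-layer clustering finds
co-expressed genes, but cannot place a gene next to the CNV that drives
it.

## The objective

For a weight matrix `W` over a set of variables and a partition
`A_1 … A_K`, the normalized cut is

    NCut = Σ_k  cut(A_k) / cutvol(A_k),

with `cut(A_k)` the total similarity between `A_k` and its complement and
`cutvol(A_k)` the total similarity of ordered pairs inside `A_k`
(self-weights included; see *Conventions*).  Small values mean clusters
that are internally similar and mutually dissimilar.

Three within-layer weight matrices `W_C`, `W_G`, `W_P` are Gaussian
kernels on the observed (column-standardized) layers.  Cross-layer
similarity cannot be read off the raw data — a CNV and the protein it
ultimately drives need not be strongly marginally correlated — so it is
routed through two sparse multi-response regressions,

    Y = X·b1 + e1,      Z = Y·b2 + e2,

fitted column-wise by the elastic net.  The predicted layers
`Ŷ = X·b̂1` and `Ẑ = Y·b̂2` live in "regulation space", and the m×m
cross-layer matrix `W~` (m = q+p+r) holds kernels between `Ẑ` and `Ŷ`
columns and between `Ŷ` and `X` columns, with zero blocks elsewhere.
The clustering objective over partitions of all m variables is

    MuNCut(A) = NCut_multi(A; W~) + γ · [NCut_C + NCut_G + NCut_P],

where γ ≥ 0 balances cross-layer against within-layer structure.  It is
minimized by simulated annealing over label vectors.

## Kernel conventions

All kernels are `w = exp(−d² / (σ·n))` with `d²` the squared Euclidean
distance between column vectors.  Dividing by n makes σ sample-size
free: for standardized columns, `d²/n = 2(1 − cor)`, so the kernel is a
monotone map of the correlation and σ is in "correlation units".  The
default σ = 0.35 maps correlation 1 → weight 1, correlation 0 → weight
e^(−2/0.35) ≈ 0.003.  This default was calibrated once against the
synthetic benchmark (below): much larger σ leaves a near-uniform
background weight whose size-balancing pressure dominates the objective
(the minimizer then splits large clusters and dissolves weakly-connected
ones); much smaller σ reduces the kernel to near-binary nearest-neighbor
indicators dominated by sampling noise in the correlations.

Unscaled distances (`scale_by_n=False`) are retained for completeness
but are not usable at realistic n: with standardized columns, `d² ≈ 2n`
drives every weight toward the bottom of the double-precision range and
NCut ratios become extreme-value noise.

**Null predictions.**  When the elastic net sets a whole coefficient
column to zero (a response with no detected regulators), the predicted
column is identically zero and the plain kernel misbehaves: the zero
vector sits at squared distance `‖v‖² = n` from every real column —
*closer* than two uncorrelated real columns are to each other (2n) — so
"no evidence of regulation" would act like correlation 0.5 with
everything.  The package instead assigns null columns an *effective
correlation* `null_cor` (default 0.25) with every informative column,
i.e. distance `2(1 − null_cor)·‖v‖²`, and distance 0 to other null
columns.  Two null predictions are genuinely indistinguishable (weight
1), which is what lets unregulated variables form their own cluster; the
0.25 default sits between the sampling-noise correlation level (~1/√n)
and the typical correlation of a variable with its own channel's
predictions (≳0.4), so unregulated CNVs are drawn toward the null
cluster without pulling regulated CNVs away from theirs.  The value was
fixed once against the synthetic benchmark and is exposed as a
parameter.

**Diagonal in cutvol.**  `cutvol` sums over all ordered pairs `j,l` in a
cluster including `j = l`, so each within-layer cluster volume is
bounded below by its size (w_jj = 1).  This is the literal reading of
the volume definition, and it matters: without self-weights, a cluster
of mutually-uncorrelated variables has cut/cutvol ≈ (d−s)/(s−1)
*independently of the kernel scale*, a constant reward for scattering
the pure-noise cluster that no bandwidth can remove.  With self-weights
the same term is ≈ cut/s, which vanishes for sharp kernels.  Both
conventions are implemented (`include_diag` / `diag_in_cutvol`);
`ncut_multi` is unaffected because `W~` has a zero diagonal.

**Degenerate clusters.**  A cluster with zero volume and zero cut
contributes 0; zero volume with positive cut contributes
`cut / epsilon_vol` (default 1e−8), a large finite penalty.  Clusters
can never empty during annealing (singletons do not donate), which keeps
the trivial one-block partition — whose NCut is identically zero — out
of the search space.

## Regression fitting

Each response column is an independent elastic-net problem

    argmin_b ‖y − M·b‖² + λ[(1−α)‖b‖² + α‖b‖₁],

with α = 0.5 by default and λ selected per response by 5-fold
cross-validation over a shared 30-point geometric grid spanning two
decades below the smallest all-zero λ.  Selection uses the one-standard-
error parsimony rule by default (`rule="1se"`; `"min"` available): the
sparser fits matter here because the coefficients are consumed by the
similarity kernels, and spurious cross-channel coefficients translate
directly into spurious cross-cluster similarity.  On the synthetic
benchmark the 1-SE rule raises the share of coefficient mass inside the
true regulation blocks from ~0.71 to ~0.93 and fits the unregulated
responses as exactly null.  Coordinate descent and the regularization
path come from scikit-learn, run with precomputed Gram matrices
(covariance updates) for speed; pure ridge (α = 0) uses the closed form
via one eigendecomposition per fold.

## Optimization

The annealer proposes single-variable moves: a donor cluster drawn with
probability ∝ s_k² (ordered within-pair count), a receiver ∝
1/(s_k² + 1), a uniformly chosen member moved.  Improving moves are
always accepted; a worsening move of size Δ at iteration t is accepted
with probability `exp(−Δ·L·log(t+1))` (default schedule `inverse_log`,
L = 1000) — the classical logarithmic schedule with temperature
`1/(L·log(t+1))`.  Two alternatives are provided for audit: `cooling`
(T = L/log(t+1)) and `heating` (T = L·log(t+1), under which the chain
accepts ever more worsening moves and degenerates to a random walk).

Objective changes are evaluated in O(1) per proposal via per-cluster
aggregates (internal weight, degree sum, self-weight sum per cluster for
both the cross-layer matrix and the block-diagonal within-layer matrix),
with an O(m) update on acceptance, periodic full recomputation to cancel
drift, and an exact recomputation of the reported incumbent.  Volumes
below 1e−9 are treated as zero inside the incremental engine — below
that level a tracked volume is indistinguishable from accumulated
floating-point error.

By default the chain starts from a spectral partition of the combined
similarity matrix `W~ + γ·blockdiag(W_P, W_G, W_C)` (normalized-
Laplacian embedding + k-means) and uses annealing as a refinement under
the exact objective; `init="random"` gives the classical uniform random
start.  On 9-variable toys with strong channels, annealing from either
start reaches the exhaustive-search minimizer over all partitions into K
nonempty blocks (verified in tests).  At m ≳ 1000 the rugged sharp-
kernel landscape makes random starts unreliable within practical
iteration counts, while the spectral start plus ~10⁵ refinement
iterations reproducibly reaches the same basin that local search started
*from the ground truth* settles in.

## Tuning (γ, K)

The tuning module scores a candidate (γ, K) by within-cluster held-out
prediction: subjects are split (default 50/50, 5 random splits), the
full pipeline is fitted on the training half, and on the test half each
GE is predicted from the CNVs sharing its cluster and each protein from
the GEs sharing its cluster (elastic-net fits trained on the training
half).  Clusters that give a response no predictors contribute the
centered test sum of squares.  Total error is summed over splits, and
ties break toward smaller K, then smaller γ.  Regressions and weight
matrices are computed once per split and reused across the grid.

## Synthetic benchmark

`muncut.simulate` generates the three-layer design with known truth:
equal layer sizes q = p = r, four clusters with per-layer sizes
(q/5, 2q/5, q/5, q/5).  CNVs are N(0, Σ) with unit variances; b1 and b2
are block-diagonal with ⌈20%⌉ of each of the first three diagonal
blocks' entries drawn Unif(h/2, h) and the fourth block zero — cluster
four is a pure-noise cluster with no regulation and (except scenario II)
no correlation.  Σ by scenario: (I) blocks 1–3 with off-diagonals ρ,
block 4 identity, zero elsewhere; (II) blocks 1–3 with 2ρ and *all*
other off-diagonals ρ; (III) covariance as in I but the generating
models add unmeasured regulators U1·g1 and U2·g2 (U drawn like X, g
like b), so the fitted two-layer regressions are mis-specified.  Errors
are N(0, 1).  Nonzero coefficient positions are redrawn per replicate.

Reference settings follow the published benchmark grid; the first row —
n = 200, q = 400, h = 0.15, ρ = 0.20 — is the package's reference
operating point, at which the defaults above yield mean clustering error
~0.005–0.05 depending on replicate (see the acceptance criteria for the
aggregated check).  Two properties of this generator matter when
interpreting scaled-down runs.  First, per-response signal strength
*grows with q*: a GE in a size-s block has ~0.2·s parents, so its signal
variance scales roughly with ρ(0.2·s·E[β])².  A q = 100 dataset at
h = 0.15 is a much harder problem than q = 400 at the same h, and test
configurations at reduced q therefore scale h to keep the per-response
signal comparable (h ∝ 400/q).  Second, what the generator does *not*
emulate: real omics layers have heavy-tailed and skewed marginals,
batch structure, missingness, and regulation that is neither linear nor
block-aligned; passing these benchmarks shows the estimator recovers the
generating channel structure under the model's own assumptions, not that
it will do so on real tumor multi-omics data.

## Evaluation measures

All comparisons run through m×m binary co-clustering (adjacency)
matrices with unit diagonal, making them invariant to label
permutations.  Clustering error is the disagreement proportion
`Σ|A_T − Â|/m²` (0 = perfect recovery).  An alternative printed form
`1 − Σ(A_T ⊙ Â)/m²` is available behind `form="overlap_complement"`
for audit; it cannot reach 0 at perfect recovery and is not used for
reporting.  Stability is the entrywise mean adjacency over N = 100
re-clusterings of random half-samples of subjects; concordance
`M(B|A) = Σ(Â⊙B̂)/ΣÂ` is the fraction of A's co-clustered pairs that B
also co-clusters (asymmetric; diagonal included in both sums).  A
distance-correlation screen (classic double-centered V-statistic,
cross-checked against an independent implementation in tests) is
provided for pre-selecting candidate variables against an anchor layer
in real-data preprocessing.

## Baselines

Pooled KM/SC/HC cluster all m variables as points in subject space **on
the raw pooled matrix** — deliberately so: applying a single-type method
directly to concatenated layers is exactly the practice these
comparators represent, and the between-layer scale differences are why
their clusters split by data type.  (`standardize=True` is available.)
Matched KM*/SC*/HC* cluster each layer separately into K clusters, then
align clusters across layers — GE↔CNV and protein↔GE — by maximizing
the total mean absolute Pearson correlation between matched cluster
pairs, exhaustively over permutations for K ≤ 6 and by optimal
assignment beyond.  HC uses average linkage on Euclidean distance;
SC uses a normalized-Laplacian embedding of the Gaussian-kernel
affinity with k-means assignment.  Louvain and fast-greedy community
detection run on the same combined similarity matrix the main objective
uses, via python-igraph (optional extra).

## Known limitations

* The bandwidth σ, `null_cor` and γ defaults are calibrated to the
  correlation scales of the synthetic benchmark; real data with very
  different dependence strength may need re-tuning (σ via inspection of
  the weight histogram, γ and K via the tuning module).
* Regulation is modelled as linear and unidirectional (CNV→GE→protein);
  feedback and nonlinearity end up in the residual.
* The annealer optimizes a non-convex objective; the spectral start
  makes runs reproducible and empirically stable, but global optimality
  at scale is not guaranteed.
* Layers must be complete (no missing entries) and row-aligned.
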