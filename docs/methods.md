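# Methods

This note documents the models, algorithms, and design choices behind
`hicwalk`, and what the synthetic benchmarks do and do not say about real
data.

## Pipeline overview

All analyses share one spine: a symmetric non-negative contact matrix is
balanced into a symmetric doubly stochastic transition probability matrix
(TPM), optionally smoothed by a random walk, fed to a TAD caller, and the
called partition is scored against a reference partition with the adjusted
Rand index (ARI). The three study harnesses differ only in where the
matrix and the reference come from.

## Synthetic generators

### Idealized block TPM

Parameters: locus count `N`, block sizes `n_1..n_k` (summing to `N`),
between-block transition probability `d ≥ 0`, noise bound `noise_high`.
The matrix has within-block entries `(1 − (N − n_i) d)/n_i` (diagonal
included) and between-block entries `d`; each row and column sums to 1
exactly by construction, and feasibility requires `1 − (N − n_i) d ≥ 0`
for every block. The standard layout used throughout the tests is
`N = 200` with blocks `50, 30, 20, 90, 10` and either `d = 0` or
`d = 1/(2N) = 0.0025`.

Observation noise is i.i.d. `Unif(0, noise_high)` with `noise_high = 0.02`
by default, sampled on the upper triangle (diagonal included) and mirrored
— every downstream stage assumes symmetric matrices, so the noise is
symmetrized even though a one-sided reading of "noise at each position"
would also be possible. The noisy matrix is no longer stochastic; KR
balancing restores that in the next stage.

### Power-decay count model

Contact frequency in real Hi-C decays with genomic distance roughly as a
power law. The generator draws, in order (upper triangle, mirrored):

1. expected counts `A_ij = exp(c + d_exp · log(j − i))` for `i < j` and
   `A_ii = exp(c1)`; natural logarithms throughout;
2. background `B_ij ~ NegBin(mean A_ij, variance z·A_ij)` with `z > 1`.
   The size/probability parameterization is `r = μ/(z − 1)`, `p = 1/z` —
   the unique negative binomial with those two moments. `z = 1` (pure
   Poisson) is rejected rather than silently substituted, since the model
   is explicitly over-dispersed;
3. a uniformly random contiguous partition of the `N` loci into `k`
   blocks, drawn as `k − 1` distinct cut points among the `N − 1`
   interior boundaries — the simplest distribution consistent with
   "randomly divided into k blocks";
4. domain boosts `D_ij ~ Poisson(λ_b · B_ij)` for `(i, j)` inside block
   `b`, with `λ_b ~ Unif(lambda_low, lambda_high)` drawn once per block
   (block-level, not per-cell, effects);
5. the observed matrix zeroes a `pi1` fraction of within-domain and `pi2`
   fraction of outside-domain upper-triangle cells (exact counts, chosen
   uniformly without replacement, mirrored).

Defaults: `N = 1000`, `c = c1 = log 20`, `d_exp = −0.4`, `z = 1.2`,
`k = 20`, `λ ~ Unif(0.5, 1.0)`, `pi1 = 0.1`, `pi2 = 0.2`. These are the
standard operating point of the replicated study harness. Unit tests
verify the first two moments of the background and recover the decay
exponent by regressing log mean count on log distance.

What the generator does **not** emulate: distance-dependent sparsity,
trans-chromosomal contacts, copy-number effects, A/B compartments,
hierarchical (nested) domains, and locus-level coverage biases beyond what
KR removes. Passing benchmarks here therefore demonstrates behavior under
a clean block-plus-decay world, not performance on any particular real
dataset.

### Multinomial subsampling

Single-cell-like depth is emulated by drawing
`round(rate × total)` contacts (totals counted over the upper triangle
including the diagonal, which participates in the draw once) from a
multinomial with cell probabilities proportional to the bulk counts, then
mirroring. Sampling is with replacement over cells, matching read-level
downsampling practice: at `rate = 1` the total is preserved but individual
cells resample. Subsampling can never place a count where the bulk matrix
is zero.

## Knight-Ruiz balancing

The balancing equations `x ∘ (M x) = 1` are solved by the KR inner-outer
scheme: an inexact Newton iteration whose linear systems are solved by
conjugate gradients, with the multiplicative update clamped to `[0.1, 3]`
per outer step so the scaling vector stays positive. The matrix is
pre-scaled by its mean row sum so the iteration starts near the solution;
the scale is folded back into `x*` afterwards (the balanced `P` is
invariant to positive rescaling of the input, and a test asserts this).

Defaults: tolerance `1e−6` measured as the maximum absolute deviation of
any row/column sum from 1, and 1000 outer iterations. The balancing of a
fully supported symmetric matrix is unique, so the contract is the
post-condition, not the algorithm; tests verify agreement with an
independent (slow) symmetric Sinkhorn iteration to `1e−8` on random
matrices. Non-convergence within the budget returns the best iterate
flagged `converged=False`; a residual that stalls catastrophically (e.g. a
support pattern admitting no positive balancing) raises
`UnbalanceableError` instead of looping. All-zero rows get their diagonal
set to 1 before balancing — always applied inside `kr_normalize` (and
exposed separately) so pipelines cannot forget it; deleting such rows
instead would splice distant loci together and create fictitious domains.

## Random walks

`rws` computes `P^s` by binary exponentiation (exact algebra, no
tie-breaking concerns). `rwr_iterate` applies the restart recursion
literally; `rwr_limit` solves `(I − (1−α)P) X = αI` rather than forming an
inverse — the system is symmetric positive definite for `α > 0` since the
spectral radius of `P` is 1. "Until convergence" for the iterative route
means successive iterates differing by less than `1e−10` in max-abs norm,
capped at 10 000 iterations; convergence is geometric at rate `1 − α`.
After every operation the result is re-symmetrized (averaging with its
transpose) and clipped at zero to remove rounding-level violations before
re-validation.

The closed block form of the RWR limit for the idealized TPM uses

    q_i     = (1−α)(d + α(1−Nd)/n_i) / (α + (1−α)Nd)
    q_{k+1} = (1−α) d / (α + (1−α)Nd)

These coefficients satisfy `α + n_i q_i + (N − n_i) q_{k+1} = 1` exactly,
reduce to `1/N` as `α → 0` (with `d > 0`) and to 0 as `α → 1`, and the
assembled matrix agrees with the resolvent to `1e−10` on the standard
layout — that cross-check is a frozen test, since the printed form of the
coefficients admits more than one typographic reading and only this one
passes all three checks.

Smoothing grids default to `s ∈ {2, 3, 4, 5, 10}` and
`α ∈ {0.05, 0.1, 0.2, 0.5}`.

## TAD callers

The insulation caller computes, for each interior boundary `b`, the mean
of the `w × w` submatrix `M[b−w:b, b:b+w]` (truncated at the edges; the
window never includes diagonal cells, which keeps the caller usable on
RWR-smoothed matrices whose diagonal dominates). Boundaries are strict
local minima of this profile that fall below `mean − 1·std` of the
profile — a deliberately simple, scale-free prominence rule; both `w`
(default 5 bins) and the minimum domain width (default 3 bins; narrower
intervals become gaps) are exposed. On noise-free block TPMs with
`d ≤ 0.1/N` and blocks at least twice the window, recovery is exact.
This caller is intentionally minimal plumbing for the benchmark harness,
not a reimplementation of any published TAD caller; published algorithms
can be attached through `ExternalCaller`, which exchanges a dense matrix
file for a partition file with any executable.

The two degenerate callers reproduce failure modes worth benchmarking
against: `pair_caller` (every two consecutive loci a domain; for the
standard 200-locus five-block layout its ARI against the truth is 0.024)
and `single_domain_caller` (one domain; ARI 0 against any non-trivial
partition).

## ARI and gap handling

The Hubert–Arabie ARI is computed from the pairwise contingency table.
The degenerate `0/0` case (e.g. both partitions a single cluster, or both
all singletons) is defined as 1 when the labelings are identical up to
relabeling and 0 otherwise. Implementation is cross-checked in tests
against scikit-learn's `adjusted_rand_score` and an independent
brute-force pair count.

How non-domain loci enter the clustering is not canonical, so it is
configurable (`gap_mode`): each maximal run of gap segments as one cluster
(default, preserving contiguity semantics), per-locus singletons, or one
pooled background cluster. The choice affects ARIs only for gap-producing
callers.

## Study harnesses and problem sizes

* **Study 1** (idealized): one noisy realization, conditions = noise-free,
  noisy, KR, RWS grid, RWR limit grid; scored against the generating
  blocks.
* **Study 2** (power-decay): replicated simulation at the default
  operating point; per replicate the conditions are raw counts, KR, and
  the two grids. The acceptance suite runs 20 replicates at `N = 1000`,
  which is enough to separate the RWS step-count trend (median ARI
  monotonically decreasing from `s = 2` to `s = 10`) from replicate noise
  while keeping a full run under two minutes on one core.
* **Study 3** (subsampling): no generative truth exists, so each caller's
  partition of the full bulk matrix is its reference; replicate seeds are
  spawned from one master seed via `numpy.random.SeedSequence` and
  recorded in the report.
* **Sparsity sweep**: study 3 across a rate grid, reporting the median
  zero percentage alongside median ARIs. By default the sweep evaluates
  raw and KR conditions only; pass the grids explicitly to include
  smoothing.

Reports are tidy tables (replicate, condition, caller, ARI) with median
accessors, CSV/JSON export, and a violin-plot convenience wrapper.

## Known limitations

* The insulation caller's fixed prominence rule is tuned for block-like
  synthetic structure; on real matrices with nested domains or gradual
  boundaries a dedicated caller (attached via the adapter) is preferable.
* KR balancing of extremely sparse matrices can be slow or flagged
  non-convergent; the zero-row repair handles empty loci but not
  near-disconnected support.
* Single intra-chromosomal matrices only: no `.hic`/cooler binary formats,
  genome coordinates, or multi-chromosome assembly, and no VC/ICE
  normalization variants.
* ARIs computed against a caller's own bulk partition (study 3) measure
  self-consistency under thinning, not correctness of the bulk partition
  itself.
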