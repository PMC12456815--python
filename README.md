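# hicwalk

**Does random-walk smoothing of Hi-C contact matrices actually help
downstream TAD detection?** `hicwalk` is a tested, reusable pipeline for
answering that question quantitatively. It generates Hi-C matrices with
*known* domain structure, balances them into transition probability
matrices, smooths them by random walks, calls topologically associating
domains (TADs), and scores how well the called domains recover the truth.

It is aimed at methods developers and analysts who want to benchmark
random-walk "data quality improvement" steps (common in single-cell Hi-C
pipelines) against a known ground truth before trusting them on real data.

## The model

A Hi-C experiment over `N` genomic bins yields a symmetric non-negative
count matrix `M`. The pipeline stages are:

1. **Knight-Ruiz (KR) balancing.** Find a positive diagonal `D = diag(x*)`
   such that `P = D M D` is doubly stochastic (every row and column sums
   to 1). `P` is a symmetric transition probability matrix. Rows of `M`
   with no contacts get their diagonal set to 1 first, which keeps those
   bins in place without inventing contacts.

2. **Random-walk smoothing.**
   - *RWS* with `s` steps: the matrix power `P^s`. For a connected chain
     `P^s → (1/N) J` as `s → ∞`, so long walks flatten every domain into a
     uniform "monolith".
   - *RWR* with restart probability `α ∈ [0,1]`: the recursion
     `P(s) = (1−α) P(s−1) P + α I`, `P(0) = I`, with limit
     `P* = α (I − (1−α) P)^{-1}`. Every diagonal entry of `P*` carries the
     restart mass `α`, so the limit's dominant feature is the main
     diagonal, not the domain blocks.

   For the idealized block TPM — `k` diagonal blocks of sizes `n_1..n_k`,
   within-block entries `(1−(N−n_i)d)/n_i`, between-block entries `d` —
   the RWR limit has a closed block form with
   `q_i = (1−α)(d + α(1−Nd)/n_i) / (α + (1−α)Nd)` inside block `i` and
   `q_{k+1} = (1−α)d / (α + (1−α)Nd)` between blocks, which the package
   implements and cross-checks against the resolvent.

3. **TAD calling.** A built-in insulation-score caller (local minima of
   mean contact intensity in a window straddling each candidate boundary),
   two degenerate reference callers (every-consecutive-pair, and
   single-domain), and an adapter for plugging in external callers.

4. **Scoring.** Called partitions are compared with the true ones using
   the Hubert–Arabie **adjusted Rand index** (ARI), a chance-corrected
   agreement score in `[−1, 1]` that is 1 exactly for identical
   partitions.

Synthetic inputs come from three generators: the idealized block TPM plus
`Unif(0, 0.02)` noise; a power-decay count model (`log A_ij = c + d·log(j−i)`,
negative-binomial background with variance `z·mean`, Poisson domain boosts,
structured zero-masking); and multinomial subsampling of a bulk matrix down
to single-cell-like depth.

## Worked example

Score the insulation caller across the smoothing grid on replicated
power-decay simulations (1000 bins, 20 true domains):

```python
import hicwalk as hw

spec = hw.BiophysicalSpec()          # N=1000 loci, 20 domains, power-decay counts
report = hw.run_study2(spec, [hw.InsulationCaller()], n_reps=10, seed=1)
for row in report.medians().itertuples():
    print(f"{row.condition:>8}  median ARI = {row.median_ari:.3f}")
```

prints

```
   count  median ARI = 0.607
      KR  median ARI = 0.505
   RWS2s  median ARI = 0.841
   RWS3s  median ARI = 0.640
   RWS4s  median ARI = 0.496
   RWS5s  median ARI = 0.393
  RWS10s  median ARI = 0.227
 RWR0.05  median ARI = 0.622
  RWR0.1  median ARI = 0.610
  RWR0.2  median ARI = 0.605
  RWR0.5  median ARI = 0.552
```

Reading the numbers: a two-step random walk helps this caller (0.841 vs
0.607 on raw counts), but performance decays steeply with more steps —
by ten steps the domains are largely erased (0.227). RWR is insensitive
to its restart probability over 0.05–0.2 and performs about like the
unsmoothed KR matrix: smoothing neither breaks nor meaningfully helps it.
That is the cautionary story in miniature — the benefit of random-walk
smoothing hinges entirely on a tuning parameter for which there is no
practical selection rule.

The same pipeline is available from the shell:

```bash
hicwalk simulate --model biophysical --seed 1 --out E.tsv --truth-out truth.bed
hicwalk normalize --in E.tsv --out P.tsv
hicwalk smooth --in P.tsv --method rwr --alpha 0.1 --limit --out S.tsv
hicwalk call-tads --in S.tsv --out tads.bed
hicwalk evaluate --study 2 --reps 20 --seed 1 --out report.csv
```

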