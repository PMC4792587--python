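# prsog

Quality of reproducibility of differential-expression gene lists, scored by
PageRank rank-sums on a thresholded co-expression network.

## The problem

Two microarray (or RNA-seq) studies of the same disease rarely report the
same differentially expressed genes (DEGs). The classical yardstick, the
percentage of overlapping genes (POG), only *counts* the shared genes: with
k genes shared between lists of lengths l₁ and l₂,

    POG₁₂ = k / l₁        POG₂₁ = k / l₂.

POG treats every gene as equally important, has no principled significance
threshold, and can rate two studies of *different* tumour subtypes as highly
concordant simply because they share many (unimportant) genes.

`prsog` instead scores the *quality* of the overlap:

1. **Gene pool** — the union of the two DEG lists, restricted to genes
   measured in both studies (N genes).
2. **Network** — an undirected graph on the pool; genes a, b are joined when
   |corr(a, b)| ≥ r (Pearson by default; r swept over 0.5…0.9).
3. **Importance** — the PageRank vector R of the network with damping
   d = 0.85, iterated from the uniform vector 1/N:

       PageRank(gᵢ) = (1 − d)/N + d Σⱼ PageRank(gⱼ)/L(gⱼ),

   where L(gⱼ) is gene j's degree; Σᵢ PageRank(gᵢ) = 1.
4. **RSOG** — the rank-sum of the k overlapping genes,
   RSOG = Σᵢ∈overlap PageRank(gᵢ): the total importance mass both studies
   agree on.
5. **PRSOG** — the p-value of RSOG under a resampling null: draw k genes
   uniformly without replacement from the pool 10,000 times, record the rank
   sums, and take the upper-tail probability of the observed RSOG (normal
   approximation with stable complementary CDF, or the empirical tail with
   the add-one correction). PRSOG < α = 0.01 ⇒ the overlap concentrates on
   the network's most important genes — high-quality reproducibility.

Companion analyses classify each pool gene by the bootstrap probability that
a random gene outranks it — *significant* (p ≤ 0.1), *common*
(0.1 < p ≤ 0.9, ~80% of a tie-free pool), *wrong* (p ≥ 0.9) — and fit
power-law / exponential / truncated log-normal models to the rank tail.

The package ships a synthetic-data generator (`prsog.datagen`) that plants
DEG lists with an exact overlap count on controllable network positions, so
the whole pipeline is testable end to end with known ground truth.

## Worked example

```python
from prsog import SimulationConfig, simulate_experiment, evaluate_experiment

cfg = SimulationConfig(n_genes=300, n_samples_1=40, n_samples_2=40,
                       n_modules=5, deg_len_1=90, deg_len_2=80, overlap_k=30,
                       overlap_placement="high_rank", missing_rate=0.0, seed=11)
exp = simulate_experiment(cfg)
report = evaluate_experiment(exp.expr_1, exp.expr_2, exp.degs_1, exp.degs_2,
                             r_values=[0.5, 0.6, 0.7], draws=10_000, seed=1)
print(report.to_frame())
```

prints

```
  r  mean_pog   rsog  null_mu  null_sigma    prsog  reproducible
0.5    0.3542 0.2800   0.2143      0.0159 1.81e-05          True
0.6    0.3542 0.3325   0.2141      0.0197 9.28e-10          True
0.7    0.3542 0.3368   0.2143      0.0207 1.63e-09          True
```

Thirty genes are shared between DEG lists of 90 and 80 (mean POG 0.35 —
unremarkable), but because the generator planted them on the network's hub
module they carry RSOG ≈ 0.28–0.34 of the total rank mass against a null
mean of ≈ 0.21, so PRSOG is far below α = 0.01 at every threshold: the
overlap is of high quality, not just moderate quantity. Re-running with
`overlap_placement="random"` leaves `reproducible` False in the typical
replicate.

The same pipeline is available from the shell:

```sh
prsog simulate --outdir sim --seed 11
prsog evaluate --expr1 sim/expr_1.tsv --expr2 sim/expr_2.tsv \
               --degs1 sim/degs_1.txt --degs2 sim/degs_2.txt \
               --r 0.5,0.6,0.7,0.8,0.9 --draws 10000 --seed 1
```

with further subcommands `impute` (kNN, k = 15), `select` (a labelled
moderated-difference DEG selector — **not** SAM; externally produced DEG
lists are first-class inputs), `network`, `pagerank`, `classify`, and
`fitdist`.

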