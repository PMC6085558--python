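# epsrank

Supervised-learning gene selection for case-control RNA-Seq.

Differential expression analysis ranks genes one at a time and ignores
gene-gene structure. `epsrank` implements two multivariate alternatives
for tumor/normal (case/control) cohorts and a survival-based benchmark to
compare them against univariate baselines:

- **Random-forest ranking** — a forest is trained to classify case vs
  control on a balanced training set; genes are ranked by out-of-bag
  permutation importance (mean decrease in accuracy): the average
  increase in a tree's out-of-bag error when gene *g*'s values are
  permuted,

      imp(g) = mean_t [ err_t(OOB_t, permute g) − err_t(OOB_t) ].

- **Extreme Pseudo-Samples (EPS)** — a variational autoencoder learns a
  latent representation z ~ N(mu(x), sigma(x)) of the expression
  profiles; a linear separator is fitted between the classes in latent
  space; from the *extreme* members of each class (top-q |signed
  distance| on their own side) new latent points are sampled and decoded
  into equal-sized sets of exaggerated case-like and control-like
  "pseudo-samples"; a regularized logistic fit on those pseudo-samples
  ranks genes by |coefficient|.

- **Baselines** — |log2 fold change| and a Welch-t/Benjamini–Hochberg
  univariate ranking (or an imported ranking from an external DE tool).

- **Evaluation** — for each ranking, nested signatures sig_i = {top i
  genes}, i = 1..20; per signature a Cox proportional-hazards risk score
  on the cases-only validation cohort, a median split, and a two-group
  log-rank test; methods are compared by counting strict p-value wins
  across the 20 sizes (60 log-rank tests for three methods). Stability
  (top-20 overlap across re-runs) and subsample experiments are included.

Everything runs end-to-end on synthetic data with planted truth:
negative-binomial counts, planted size factors, class-discriminative
genes, correlated gene blocks, and survival times tied to signal genes,
so every stage is testable without external cohorts. The intended users
are computational biologists who want to benchmark multivariate gene
selection against differential expression on their own or simulated
cohorts.

## Worked example

```python
from epsrank import simulate_dataset
from epsrank.preprocess import estimate_size_factors, normalize
from epsrank.synthetic import simulate_survival
from epsrank.workflow import RunConfig, full_comparison

matrix, metadata, truth = simulate_dataset(
    n_genes=500, n_case=150, n_control=50, n_signal=10,
    effect_log2fc=2.0, seed=42)
norm = normalize(matrix, estimate_size_factors(matrix))
metadata = simulate_survival(norm, truth, censor_rate=0.3, seed=43,
                             metadata=metadata)

result = full_comparison(matrix, metadata, RunConfig(epochs=60))
print("log-rank tests executed:", result.n_logrank_tests)
planted = set(truth.signal_genes)
for method, ranking in result.rankings.items():
    print(f"{method}: {len(set(ranking.top(20)) & planted)}/10 planted genes in top 20")
for (a, b), c in result.table.pairs.items():
    if b == "DE" and a != "DE":
        print(f"{a} beats DE on {c['wins']}/20 signatures ({c['ties']} ties)")
```

prints

```
log-rank tests executed: 60
DE: 10/10 planted genes in top 20
RF: 10/10 planted genes in top 20
EPS: 10/10 planted genes in top 20
RF beats DE on 10/20 signatures (5 ties)
EPS beats DE on 9/20 signatures (2 ties)
```

All three rankers place the 10 planted discriminative genes in their top
20 on this 500-gene cohort; the win counts compare, size by size, the
log-rank p-value of each method's signature against the DE baseline's on
the 100-case validation cohort (wins + losses + ties = 20).

The same pipeline is scriptable from the shell:

```
epsrank simulate --config sim.yaml --out data/
epsrank run --config run.yaml --out results/
epsrank rank-rf data/counts.tsv data/metadata.tsv --split-json split.json --out rf.tsv
epsrank stability data/counts.tsv data/metadata.tsv --method RF --iters 10 --out stab.tsv
```

`epsrank run` writes the rankings, per-signature log-rank table,
pairwise comparison JSON, split, config and a checksum manifest; re-runs
with the same config reproduce every ranking bit-identically.

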