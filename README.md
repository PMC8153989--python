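# mgrl — multi-graph representation learning for drug–disease association prediction

Drug repositioning asks which existing drugs might treat which
diseases. `mgrl` frames this as link prediction on the bipartite
drug–disease association graph and predicts new links by fusing two
complementary node representations:

1. **Attribute features (local view).** Drugs carry binary Morgan
   circular fingerprints (RDKit, radius 2, 1024 bits); diseases carry
   their row of a Wang-style MeSH-DAG semantic similarity matrix, where
   an ancestor `t` contributes `D_a(t) = max(mu * D_a(t'))` over its
   children (own codes contribute 1) and
   `Sim(a,b) = sum_{t shared}(D_a(t)+D_b(t)) / (DV(a)+DV(b))`.
   The unified attribute matrix X (zero-padded blocks) is propagated
   through one seeded random graph-convolution layer,
   `H = ReLU(Ã X W)` with `Ã = A + I`.
2. **Walk embedding (global view).** node2vec second-order biased
   random walks (`alpha = 1/p, 1, 1/q` for hop distance 0, 1, 2 from
   the previous vertex) embedded by skip-gram with negative sampling.

Each candidate pair is represented as
`[H_drug | H_disease | E_drug | E_disease]` and classified with a
Random Forest (500 trees) under stratified five-fold cross-validation;
reported metrics are Acc, Sen, Spec, Prec, MCC, AUC and AUPR. The
package is for computational drug-repositioning researchers who want a
reproducible, fully seeded implementation of this pipeline with honest
evaluation modes (the default transductive protocol and a per-fold
`leakage_safe` alternative are both available and labeled in reports).

Real curated benchmarks (CTD-derived association lists, DrugBank
structures, MeSH descriptors) are consumed as plain TSV; because they
are not redistributable, the package also ships a planted-block
synthetic benchmark generator whose statistical shape mirrors them, so
everything is testable offline.

## Worked example

Generate the canonical synthetic benchmark (60 drugs × 100 diseases,
4 latent blocks, ~540 known pairs) and run the full pipeline:

```python
from mgrl import SyntheticSpec, make_benchmark, RunConfig, run_pipeline

paths = make_benchmark(SyntheticSpec(), "bench")   # canonical fixture
report = run_pipeline(RunConfig(
    associations=str(paths["associations"]),
    fingerprints=str(paths["fingerprints"]),
    tree_numbers=str(paths["tree_numbers"]),
    outdir="run",
    seed=1,
))
m, s = report["mean"], report["std"]
for k in ("auc", "aupr", "acc", "mcc"):
    print(f"{k.upper():5s} {m[k]:.4f} +/- {s[k]:.4f}")
```

prints

```
AUC   0.8401 +/- 0.0144
AUPR  0.8033 +/- 0.0215
ACC   0.7798 +/- 0.0133
MCC   0.5618 +/- 0.0255
```

Mean AUC 0.84 means the fused features rank a held-out true
association above a sampled non-association 84% of the time — the
planted block structure is recovered well above the 0.5 chance level
(pure-noise features score ≈ 0.50 on the same task). `run/` now holds
the disease-similarity matrix, the GCN features and walk embedding
(word2vec text format), the per-fold report JSON and a resolved-config
snapshot; rerunning with the same config reproduces every file
byte-for-byte.

The same workflow is available from the shell, stage by stage or end
to end:

```sh
mgrl simulate --preset canonical --out bench
mgrl run --fingerprints bench/fingerprints.tsv \
         --assoc bench/associations.tsv \
         --tree-numbers bench/tree_numbers.tsv \
         --seed 1 --out run
mgrl rank --assoc bench/associations.tsv \
          --gcn-features run/gcn_features.tsv \
          --embeddings run/embeddings.txt \
          --drug d0003 --top 10 --out candidates.tsv
```

`mgrl --help` lists the individual stages (`simulate`, `disease-sim`,
`featurize`, `gcn`, `embed`, `fuse`, `cv`, `rank`, `run`); real data
drops in as the same three TSV files (drug–disease pairs; drug SMILES
via `--smiles`; disease tree numbers).

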