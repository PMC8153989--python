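# Methods

`mgrl` predicts drug–disease associations by fusing two independent
representations of the same bipartite association graph and classifying
candidate pairs with a Random Forest. This note records the model, the
choices that were genuinely open, the numerical details, and what the
synthetic benchmark does and does not establish.

## Model

### Disease semantics (Wang-style DAG similarity)

Each disease is annotated with MeSH-style tree numbers
(e.g. `C04.557.337`). Every dot-prefix of every code is an ancestor; the
prefixes and their one-component extensions form the disease's ancestor
DAG. The contribution of an ancestor `t` to disease `a` decays with a
factor `mu` per edge on the best downward path to one of `a`'s own codes:

    D_a(a) = 1
    D_a(t) = max { mu * D_a(t') : t' child of t }

The semantic value is `DV(a) = sum_t D_a(t)` and the similarity of two
diseases is the shared-ancestor overlap ratio

    Sim(a, b) = sum_{t in T_a ∩ T_b} (D_a(t) + D_b(t)) / (DV(a) + DV(b))

which is 1 for identical annotations, 0 for disjoint ones, symmetric,
and monotone in overlap. Contributions are computed by
reverse-topological dynamic programming; an exhaustive path-enumeration
oracle in the test suite confirms exact agreement. A disease with
several tree numbers contributes 1 at each of its own codes; an own
code that also has descendants stays pinned at 1 (the DP never lowers
it). `mu` defaults to 0.5, the convention of the Wang-measure lineage;
it is exposed everywhere the similarity is computed.

### Drug attributes and the unified attribute matrix

Drugs are described by hashed binary Morgan (ECFP-style) circular
fingerprints from RDKit, radius 2 and 1024 bits by default (the ECFP4
convention). An unparseable SMILES raises with the drug id — it is
never silently zero-filled. Fingerprints and disease-similarity rows
are heterogeneous, so the unified n × k attribute matrix X uses
zero-padded block concatenation: a drug row is `[fingerprint | 0]`, a
disease row `[0 | similarity row]`, k = n_bits + n_diseases. This
preserves both signals without an arbitrary projection; nothing mixes
the blocks until graph propagation does.

### Graph-convolution features

With A the unified n × n bipartite adjacency, Ã = A + I, and D̃ the
degree matrix of Ã, the attribute representation is a single layer

    H = σ(Ã X W)                      (simplified, default)
    H = σ(D̃^{-1/2} Ã D̃^{-1/2} X W)    (normalized, optional)

with σ = ReLU and W a k × 64 random projection. W is untrained: no
loss is defined for this stage, so it is a fixed, seeded random graph
filter — one round of neighborhood mixing followed by dimensionality
reduction. This is a deliberate reading of an ambiguity in the method's
provenance: the stage is sometimes described as "pre-training", but no
training objective exists for it, and we document it as what it is.
The seed is mandatory and recorded in every report. W uses
Glorot-uniform initialization (entries within ±sqrt(6/(k+m))) so the
pre-activation scale is insensitive to k.

### Walk embedding (node2vec)

Second-order biased random walks: at vertex `v`, arrived from `t`, the
unnormalized probability of stepping to neighbor `x` is
`alpha_pq(t, x) * w_vx` with `alpha = 1/p` if `x = t`, `1` if `x`
neighbors `t`, `1/q` otherwise. The first step of each walk has no
predecessor and is weight-proportional. Defaults follow the published
node2vec conventions — 10 walks of length 80 per node, window 10,
p = q = 1, 5 epochs — and the 64-dimensional output matches the
graph-convolution width so the two representations contribute equally
after fusion. None of these values is forced by the method itself; all
are config-exposed and echoed into every metrics report.

Transition distributions are cached per (prev, cur) state in cumulative
form, so each step costs one uniform draw and a binary search; each
distinct state is normalized exactly once per run. (Alias tables would
give the same distribution with a marginally faster draw; at the graph
sizes this package targets the cached-CDF form is simpler and was
chosen instead.)

The corpus is embedded by a skip-gram with negative sampling (SGNS)
trainer written for this package: classic word2vec asymmetrics —
reduced (randomly shrunk) context windows, 5 negatives drawn from the
unigram^0.75 distribution, learning rate decaying linearly from 0.025
to a floor of 2.5e-6 — implemented as a single-threaded numba kernel
with an internal xorshift generator, so identical seeds give identical
vectors bit-for-bit on any worker count. Input vectors are returned;
output vectors start at zero. Nodes absent from every walk (isolated
nodes) are absent from the embedding and are zero-filled with a logged
warning wherever vectors are requested for them.

### Pair classification and evaluation

Known associations are positives; an equal number of uniformly sampled
unobserved pairs (without replacement, seeded) are negatives. The ratio
is configurable; 1:1 is the default because the reported operating
behavior of this method family is balanced. A pair's feature row
concatenates its endpoints' representation rows:
`[H_drug | H_disease | E_drug | E_disease]` (256 columns at the
defaults); the `attribute` and `embedding` modes keep only one block
pair and serve as ablation arms.

Classification is Random Forest (500 trees, sqrt features per split,
seeded, single job) under stratified 5-fold cross-validation; SVM,
logistic regression, k-NN and gradient boosting are available for
comparison. Folds split *pairs*, not drugs or diseases. Accuracy,
sensitivity, specificity, precision and MCC come from the
0.5-thresholded confusion counts (MCC is defined as 0 when its
denominator vanishes); AUC is the midrank ROC statistic and AUPR the
step integration of the precision–recall curve. Both are checked
against brute-force O(n²) oracles in the tests.

Candidate ranking for a drug scores every disease not already
associated with it and returns the top k (default 10), sorted by
descending score with ties broken lexicographically by disease id so
output is deterministic.

### Transductive vs leakage-safe evaluation

By default representations are computed once on the **full**
association graph before cross-validation. Test edges therefore
influence the features — a transductive protocol that inflates AUC and
matches the single-pass workflow this method describes. The
`leakage_safe` flag instead rebuilds the adjacency and retrains walks
and embedding inside each fold from training positives only. Both
regimes are labeled in report metadata; the test suite asserts the
directional property that the leakage-safe AUC does not exceed the
transductive one beyond fold noise.

## Synthetic benchmark

The real curated benchmark (tens of thousands of association pairs
over a few hundred drugs and diseases) is not redistributable, so the
package ships a generator whose statistical shape mirrors it: a
bipartite planted-partition model. Drugs and diseases are assigned
uniformly to `n_blocks` latent blocks; an edge appears with probability
`density` within a matched block and `background` across blocks.
Fingerprints are per-block prototype bit patterns with independent
`attr_noise` bit flips; tree numbers share a per-block subtree root
with path components drawn from a 4-symbol pool per level, so
within-block disease similarity exceeds between-block similarity
(between-block is exactly 0 — distinct roots share no ancestor).

The canonical fixture is 60 drugs × 100 diseases, 4 blocks, density
0.30, background 0.02, 256 bits, 5% bit noise, DAG depth 3, seed 7:
~540 expected positives (~9% grid density, the sparse regime), small
enough that the full pipeline runs in well under a minute. Any node the
edge draw leaves isolated is reconnected to one same-block partner, as
in a curated association list where every listed entity appears in at
least one pair. A `ctd-scale` preset (269 × 598, 8 blocks) exercises
the benchmark scale.

What passing on this fixture shows: the pipeline recovers planted
block structure from either representation, fusion is not dominated by
either arm, and the machinery is correct end-to-end. What it does not
show: performance on real pharmacology, where block structure is far
weaker and confounded, fingerprint similarity correlates only loosely
with indication, and MeSH similarity is shared across many unrelated
association patterns. Absolute AUC values on the fixture are properties
of the generator, not of the method on real data.

## Numerical and degenerate-input choices

- Canonical node order everywhere: drugs sorted lexicographically at
  rows 0..n_d−1, diseases at n_d..n−1. Same file bytes ⇒ same order.
- Duplicate association pairs are dropped (counted); duplicate drug or
  disease ids in attribute tables are errors; an id used as both drug
  and disease is an error.
- Walk step sampling: uniform draw against the cached CDF; the
  searchsorted index is clamped to the last neighbor to guard the
  u ≈ 1.0 floating-point edge.
- Stage seeds derive from the single run seed (negatives and folds:
  seed; representations: seed + 1; null draws: seed + 2) and stay below
  2^31.
- Empty DAG, empty corpus, single-class folds, oversampled negatives,
  unknown classifier/mode names: all immediate errors naming the
  offending input, never silent degradation.
- Reports are JSON with sorted keys and no timestamps, so identical
  configurations give byte-identical reports.

## Problem sizes used by the shipped checks

The test suite and the acceptance script run entirely on generated
data: oracle comparisons use 200 random DAG pairs (≤8 nodes), 1,000
random score vectors, 50 random walk graphs (≤6 nodes, ~50,000 sampled
steps each), and the canonical fixture for the end-to-end recovery,
ablation-ordering (5 seeds), null and reproducibility checks. These
sizes keep the whole suite desk-scale while leaving every statistical
assertion several standard errors of headroom.

## Known limitations

- The graph-convolution stage is a random filter, not a learned model;
  its contribution is neighborhood smoothing, and results depend mildly
  on the projection seed (reported in every run).
- The transductive default leaks test edges into representations; use
  `leakage_safe` for honest generalization estimates on real data.
- Negative sampling treats unobserved pairs as negatives; some are
  merely undiscovered positives, which biases all metrics pessimistic
  on real data and optimistic in ranking evaluation.
- The SGNS trainer is deliberately single-threaded for determinism;
  embedding very large graphs would need a parallel trainer and a
  different reproducibility contract.
- Tree-number ingestion expects pre-extracted codes; full MeSH XML
  parsing and identifier cross-mapping between vocabularies are out of
  scope.
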