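# pathmarker

Disease-gene prioritization from two-class expression profiles and
confidence-weighted protein association networks.

Case/control expression studies (e.g. tumor vs. matched normal tissue)
yield differentially expressed genes, but expression alone misses genes
whose role is mediated through interactions. `pathmarker` implements a
two-stage strategy: first select a small, non-redundant discriminative gene
signature from the expression matrix; then expand it by tracing the
cheapest routes between the signature genes on a weighted functional
association network (STRING-style confidence scores), on the premise that
genes lying on those routes are likely involved in the same process. The
expanded candidate set is scored against curated gene lists and pathway
annotations.

## Method

**Feature selection (mRMR).** Expression values are discretized per probe
into three states at μ ± α·σ (α = 1 by default). Relevance of probe *g* to
the class label *c* and redundancy among probes are both measured by
mutual information over the discrete states,
*I(x; y) = Σ p(x,y) log₂ [p(x,y) / (p(x) p(y))]*. MaxRel ranks probes by
*I(g; c)* alone; mRMR greedily selects, round by round, the probe
maximizing *I(g; c) − (1/|S|) Σ_{s∈S} I(g; s)* over the already-selected
set *S*, demoting probes that merely duplicate what is already selected.

**Classifier and validation.** A nearest-neighbour classifier with the
nearness measure *D(a, b) = 1 − a·b / (‖a‖‖b‖)* (one minus the cosine of
the angle between two sample vectors) is evaluated by the jackknife
(leave-one-out) test, giving accuracy (TP+TN)/(TP+TN+FP+FN) — a unique,
deterministic number for a fixed dataset.

**Incremental feature selection (IFS).** Nested sets S₁ ⊂ S₂ ⊂ … are built
by adding ranked probes one at a time; the optimal signature is the
smallest prefix achieving the maximum jackknife accuracy.

**Network stage.** Each edge's confidence score *s* becomes a traversal
cost *w = C_max − s* (stronger interaction ⇒ cheaper to traverse).
Dijkstra's algorithm traces the cheapest path between every pair of
signature genes; non-seed genes on those paths are ranked by *seed-pair
betweenness* (the number of seed-pair paths through them) and assigned a
permutation p-value: the fraction of random same-size seed sets under
which the gene attains at least its observed betweenness.

**Gene-set statistics.** Candidate sets are scored by hypergeometric
upper-tail overlap tests against curated lists, term enrichment with
Benjamini–Hochberg adjustment on an explicit chip background, and
functional-profile similarity (Pearson correlation of −log₁₀ hypergeometric
p-value vectors over a term universe).

## Worked example

Everything below runs on synthetic data with planted ground truth (no
downloads). Generate a study-scale dataset — 26 tumor + 26 normal samples,
2,000 probes with 6 planted discriminative probes, and a 60-node network
whose hub gene lies on 7 of the 15 designed seed-pair backbones:

```bash
pathmarker simulate --out-dir demo --seed 11 --n-probes 2000 --n-nodes 60
pathmarker mrmr --expression demo/expression.csv --rounds 30 --out-dir demo
pathmarker ifs  --expression demo/expression.csv --ranking demo/mrmr.tsv \
                --max-i 30 --out-dir demo
# peak jackknife accuracy 1.0000 at 3 feature(s)
pathmarker permute --network demo/network.tsv \
                   --seeds SEED0,SEED1,SEED2,SEED3,SEED4,SEED5 \
                   --n-perm 1000 --rng-seed 11 --out-dir demo
# wrote permutation p-values for 9 gene(s)
```

The mRMR table's top six probes are exactly the six planted ones
(`demo/truth.json` records the ground truth):

```
kind    rank  probe_id  score
mRMR    1     P00212    0.481
mRMR    2     P00420    0.202
mRMR    3     P00638    0.239
...
```

and the IFS scan reaches perfect leave-one-out accuracy within the planted
signature (with a 5-SD effect the curve saturates after 3 probes; see
`docs/methods.md`). The betweenness table recovers the planted hub with
the designed count and the smallest permutation p-value:

```
gene    betweenness  p_value
HUB0    7            0.002
VIA0    1            0.164
VIA1    1            0.232
```

`p_value = 0.002` means 2 of the 1,000 random 6-gene seed sets produced a
betweenness of at least 7 for HUB0; the interior genes with betweenness 1
are unremarkable, exactly as designed.

The full chain (expression → mRMR → IFS → seeds → paths → permutation →
overlap/enrichment/similarity tables) runs from one config:

```bash
pathmarker run --config config.yaml
```

with a YAML config naming the expression matrix, edge list, id map, GMT
annotations and gene lists, plus parameters (`alpha`, `mrmr_rounds`,
`max_i`, `transform`, `n_perm`, `rng_seed`). Every output is a TSV with a
`run_metadata.json` recording versions, seed and parameters.

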