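# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `pathmarker`. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Discretization and mutual information

Mutual information on continuous expression requires a density model; we
use the ternary discretization conventional for mRMR on microarray data:
per probe, state −1 below μ − α·σ, +1 above μ + α·σ, 0 between, with σ the
population standard deviation (denominator n) and α = 1 by default
(`alpha` is exposed everywhere and echoed in output metadata, since the
appropriate width depends on the data's dynamic range). Constant probes
map to all-zero states and therefore carry zero relevance. MI is the
plug-in estimate in bits (log base 2; rankings are base-invariant), with
0·log(·) ≡ 0. The plug-in estimator is positively biased at small n — at
52 samples the best of ~2,000 null probes typically reaches ≈ 0.1–0.2
bits — which is why planted-signal tests use effects large enough to
dominate that noise floor rather than asserting absolute MI values.

## mRMR

Round 1 selects the MaxRel top probe (empty selected set ⇒ zero
redundancy); each later round maximizes relevance minus the *mean* MI with
the already-selected set (the difference form; the quotient form is not
implemented). Ties are broken by original column order, making every
ranking deterministic. The greedy choice is validated against exhaustive
evaluation of the criterion on random instances; the comparison is by
criterion *value* at the maximum, not argmax identity, because two
mathematically tied criteria can differ in the last floating-point bit
between the vectorized and the brute-force summation orders.

A caveat worth knowing: when a selected feature predicts the class
*perfectly*, every remaining feature's relevance equals its redundancy
with it (both measure the same partition), so all criterion values tie at
zero and column order decides. Redundancy demotion is therefore only
observable when the top feature is informative but imperfect; the unit
fixtures are built that way.

## Nearest-neighbour classification and IFS

Nearness is D(a, b) = 1 − cos∠(a, b) ∈ [0, 2]; zero-norm vectors are
rejected. Nearest-neighbour ties go to the smallest sample index. The
jackknife assigns each sample the label of its nearest other sample over
the restricted feature columns; all samples are treated independently
(tumor/normal pairing is ignored) and no per-fold re-standardization is
done — the measure is scale-free, and multiplying the matrix by a positive
constant leaves results unchanged (bit-identical for power-of-two
constants, which scale exactly in floating point). IFS evaluates every
prefix i = 1..max_i (default min(1000, N)) with an incrementally updated
Gram matrix, O(max_i · n²) total, and returns the *smallest* prefix
achieving the maximum accuracy.

Because the measure is directional, a one-feature classifier is
degenerate (all same-sign values have identical direction), and a class
shift common to all selected features is invisible. Both facts shape the
IFS curve: accuracy is near chance at i = 1 and, for strong
opposite-direction effects, saturates at 1 as soon as two
complementary-direction features are included. With the default synthetic
conditions (5-SD effects) the optimal prefix is therefore typically 2–3 of
the planted probes, not all of them — the curve has already peaked. Real
signatures with weaker, noisier effects peak later; an analysis wanting a
fixed-size signature can take the top-k ranked probes directly
(`n_seed_probes` in the pipeline config).

## Synthetic data

`simulate_expression` plants k informative probes shifted by
`effect_size` in the positive class on a Gaussian log2-scale background
(baseline 8, noise SD 1 — typical normalized microarray values). Shift
signs alternate across probes (up, down, up, …), the way real tumor
signatures mix over- and under-expressed genes; an all-up signature would
move samples along the all-ones diagonal, invisible to the cosine
classifier. Optional redundant copies (parent + small Gaussian noise)
exist specifically to exercise the redundancy penalty: MaxRel ranks copies
adjacently to their parents, mRMR must demote them. Defaults mirror a
26 + 26 paired-sample design at 2,000 probes with 6 informative probes and
no copies. What the generator does *not* emulate: probe-level dye/batch
effects, heavy-tailed noise, correlated background blocks, class-imbalance
— so passing tests show algorithmic correctness on idealized signal, not
robustness to microarray artifacts.

`simulate_network` builds a graph in which every designated seed pair has
a designed two-edge backbone that is the *strict* cost minimum. One hub
gene is wired directly to the m seeds with the smallest m such that
C(m,2) ≥ `hub_degree`; the surplus pairs among those seeds are "demoted"
with slightly cheaper private interiors, leaving the hub on exactly
`hub_degree` backbones; all other pairs get private interiors in a
slightly costlier tier. Confidence bands — backbone 700 ± 10 over
background uniform(100, 300) — are chosen so that (a) a single background
edge (cost ≥ 700) exceeds any whole backbone (cost ≤ 620), making
backbones strict minima (enforced at parameter validation and, for
n_nodes ≤ 25, verified at generation time by exhaustive enumeration of
candidate paths up to the cost-bound depth: a k-edge route costs at least
k·w_min, so deeper routes cannot compete); and (b) with background density
0.2, random node pairs have short background routes and the cheap backbone
core carries no through-traffic, so the hub's permutation p-value reflects
its designed role for the seeds rather than global centrality. At sparser
densities the core becomes a thoroughfare and the hub's p inflates — the
same phenomenon the permutation test exists to flag in real networks,
where ubiquitous hubs score high betweenness under any seed set.

`simulate_annotations` annotates each gene independently with probability
`base_prob` per term; the designated term uses
min(1, enrichment_factor · base_prob) for target genes.
`enrichment_factor = 1` is an exchangeable null under which the
hypergeometric p-values are (conservatively, being discrete) uniform.

## Network stage

The confidence-to-cost transform is a named strategy; the default
`complement` (w = C_max − score, C_max = 1000 on the thousand scale, 1 on
the unit scale) is strictly positive and strictly decreasing in
confidence. Note that Dijkstra results are preserved only up to additive
structure: two decreasing transforms can disagree about which multi-edge
route is cheapest, so the transform is part of the analysis definition and
is recorded in run metadata. Scores at or above C_max are rejected
(non-positive weight).

Equal-cost ties are resolved deterministically: among co-optimal paths the
lexicographically smallest node sequence is reported (reconstructed
greedily from the two single-source Dijkstra distance maps). An optional
`tie_mode="all"` enumerates all co-optimal paths, in which case a gene
counts once per seed pair if it lies on any of them. Cost comparisons use
a 1e-9 relative tolerance.

Permutation p-values use the ≥-observed convention (a `strict` flag gives
>-observed), draws may include the original seeds (an `exclude` flag
removes them), and no pseudo-count is added: p = 0 printed by the test
means "below 1/n_perm". Disconnected seed pairs are flagged, logged, and
excluded from betweenness. For small graphs `exact_permutation_pvalues`
enumerates every k-subset as a brute-force reference.

## Gene-set statistics

All over-representation tests are one-sided hypergeometric upper tails
(equivalent to one-sided Fisher's exact tests). The default enrichment
background is "all genes on the chip" (every gene the id map assigns to a
probe), always user-suppliable — reported p-values are only meaningful
relative to an explicitly stated background. BH adjustment is the step-up
procedure via statsmodels. Functional profiles cap −log₁₀ p at 320 to keep
correlations finite when p underflows; profiles must share a term universe
and zero-variance profiles are rejected rather than silently correlated.
`proportion_compare` is the two-proportion chi-square test with Yates
continuity correction (as in R's `prop.test`), with a pooled z-test
variant behind a flag; degenerate margins (no successes anywhere) return
p = 1.

## Pipeline

Stages run in order (load → mrmr → ifs → seeds → paths → permutation →
gene-set statistics → write); a failure aborts with the stage name,
retains partial outputs and drops a FAILED marker. Outputs are
deterministic under a fixed `rng_seed` (byte-identical TSVs on re-run; the
metadata JSON carries wall-clock timings and is the one exception). Seed
genes default to the IFS-optimal probe set mapped through the id map (gene
symbol preferred, protein id fallback); `n_seed_probes` substitutes the
top-n mRMR probes when a fixed signature size is wanted. Problem sizes
used by the test suite and the acceptance script — 2,000-probe matrices,
60-node networks, 30 selection rounds, 1,000–2,000 permutations — are
chosen to exercise every code path at desk scale; all are parameters, and
the full-scale configuration (24,526 probes, 1,000 rounds, 5,000
permutations) differs only in runtime.

## Known limitations

- Probe-level analysis throughout selection; gene mapping is applied only
  at reporting time. Probes sharing a symbol are not merged.
- Continuous (density-estimate) MI is not implemented; results depend on α.
- k = 1 nearest neighbour only; no alternative classifiers or
  independent-dataset/subsampling validation modes.
- Annotations are consumed flat (no GO DAG propagation); no pathway
  topology.
- The permutation test conditions on the network; it does not model
  uncertainty in the confidence scores themselves.
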