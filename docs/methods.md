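# Methods

## Model and procedure

`pathcrosstalk` implements a four-stage discovery chain on gene-symbol-keyed
data. Its core assumptions are: (a) expression values are log2-scale and
approximately Gaussian within class, so Welch t-tests are appropriate;
(b) the PPI is an unweighted simple graph whose largest connected component
carries the walk; (c) pathway graphs are undirected simple gene–gene graphs
(relation types and directions, where a source provides them, are ignored);
(d) identifiers match exactly across layers — no symbol aliasing is applied
(a mapping can be applied upstream of the readers).

### Resampled differential calling

With n_T tumors and n_N normals (n_T ≫ n_N), each of `n_resamples` rounds
draws `subsample_size` tumors uniformly without replacement and keeps all
normals. Per gene, a two-sided Welch t-test is BH-adjusted across genes;
a gene is significant in that round iff adjusted p < `fdr_cut` **and** the
effect criterion holds. Calling frequency is the fraction of significant
rounds; the frequency cut is strict (> `freq_cut`). Direction is the
majority sign over significant rounds; an exact tie yields no direction and
no call. Raising `freq_cut` can only remove calls.

Parameters (defaults are the study conditions): `n_resamples` 1000,
`subsample_size` 18, `fdr_cut` 0.001, `fc_cut` 2 (applied as
|Δ mean log2| > log2 2), `freq_cut` 0.10.

*Methylation effect size.* A fold change on beta values in [0, 1] is
ill-posed, so methylation uses an absolute difference of class mean betas,
|Δβ| > `delta_beta` (default 0.1). This is the one place the calling
criterion is defined per layer rather than shared.

*Numerical floors.* Per-gene standard errors below 1e-8 are clamped, so a
gene constant in both classes gives t = 0/1e-8-bounded statistics rather
than NaN/inf; degenerate Welch degrees of freedom fall back to the pooled
value. Missing matrix entries are mean-imputed per gene within class at
read time; genes over 50% missing are dropped (logged).

### Candidate integration

Group i = (up & hypomethylated) ∪ (down & hypermethylated);
group ii = (up & amplified) ∪ (down & deleted);
group iii = differentially expressed (either direction) & non-silently
mutated. Sign-inconsistent combinations (e.g. up & hypermethylated) are
excluded from group i but do not disqualify the gene elsewhere. The
candidate set is the union of the groups; the *altered* registry (any
single-level flag) is kept separately because linker eligibility only
requires one level.

### Subpathway location and enrichment

Default strategy: for every unordered pair of in-pathway candidates at
shortest-path distance ≤ n, all nodes on any of their shortest paths are
collected (x lies on one iff d(u,x) + d(x,v) = d(u,v)); the union plus all
in-pathway candidates induces a subgraph whose connected components of
size ≥ s are subpathways, suffixed `_1, _2, …` by decreasing size (ties by
smallest member id). An alternative `radius` strategy (all genes within
distance n of any candidate) and a strict `< n` cut are available behind
flags, because the merge rule admits both readings; the default is the
literal "shortest path between candidate genes" reading with ≤ n.

Enrichment is the upper-tail hypergeometric probability of k candidate
members among m members, drawn from a background of N genes containing K
candidates. The background is the union of all pathway genes intersected
with the measured genes — a deliberate choice (pathway-annotated genes,
not the whole genome), written to an audit sidecar by the pipeline.
BH adjustment is joint across all subpathways of all pathways; FDR < 0.05
defines the risk pathways.

### Random-walk cross-talk

A[i, j] = 1/deg(j) for neighbors (column-stochastic), P0 uniform over the
source genes mapped into the LCC (unmapped genes dropped with a count;
none mapping is an error). The iteration P_{t+1} = (1−r) A P_t + r P0 runs
to L1 change < `tol` (default 1e-10, max 1000 iterations; breaching the cap
is an error, not a warning). The fixed point equals
r (I − (1−r)A)^{-1} P0; the test suite verifies agreement to 1e-8.
Graphs with ≤ 300 nodes use dense linear algebra, larger ones sparse
matrices; all source sets of a study are solved as one batched iteration.

The restart probability is not dictated by the data; the default r = 0.7
follows the standard choice in RWR gene-prioritization work. The pair score
is the mean steady state over mapped targets, symmetrized as
(score_ab + score_ba)/2; per-direction scores are retained for audit.
Overlapping source/target genes stay in both roles, so self-overlap pairs
include restart mass in their score — a documented property, not a bug.

The null rewires the observed LCC by double edge swaps — 10·|E| attempted
swaps, proposals creating self-loops or duplicates rejected — which
preserves every node's degree exactly. One rewired network per permutation
index is shared by all pairs; each index is seeded by (seed, index), so
results are independent of execution order and thread count. The empirical
p-value is (b+1)/(N+1) with b = #{null ≥ observed}; add-one smoothing keeps
p > 0 so joint BH ranking stays well defined (a flag restores the literal
b/N count). The comparison is non-strict (≥) for conservatism.

### Linkers and leaders

Situation i: a gene outside both risk subpathways' member sets, altered at
≥ 1 level, adjacent in the PPI to ≥ 1 candidate of each pathway, is a
linker; its adjacent candidates are leaders. Situation ii: a direct PPI
edge between candidates of the two pathways makes both genes linker and
leader. Situation iii: shared candidates are both linker and leader.
Non-membership is tested against the *subpathway* member genes (the risk
pathways of this artifact are subpathways); a flag widens it to the parent
pathway. Situations are recorded per pair and never merged across pairs.

## Synthetic studies

The generator emulates the statistical structure the pipeline assumes,
at a desk scale chosen once: a 2000-gene preferential-attachment PPI
(mean degree ≈ 4, heavy-tailed), 20 pathways of 10–20 genes grown by
seeded random BFS on the PPI, 30 tumors and 18 normals. Ten pathways are
candidate-dense: six planted candidates each (a connected member cluster),
patterns cycling through groups i/ii/iii with both signs — expression
shifts of ±4 SD, Δβ ±0.25, amplification/deletion calls, non-silent
mutations in ~30% of tumors. Background mutation records include silent
classes (fraction 0.3) to exercise the filter. Betas are clipped to
[0.01, 0.99] to avoid degenerate tests.

Two design points deserve emphasis:

* **Pathway separation margin.** With `pathway_overlap = 0`, pathways are
  grown avoiding the one-hop neighborhood of every earlier pathway, so no
  two pathways share a PPI edge. Without the margin, chance direct
  candidate–candidate edges between touching subgraphs carry ~(1−r)/deg
  flow and dominate any two-hop bridge, making unplanted pairs a broken
  null. The margin is what makes "no planted cross-talk" mean "no
  cross-talk signal".

* **Planted cross-talk strength.** The planted pair (the first two dense
  pathways) is bridged by 8 linker genes — within the 1–18 per-pair range
  reported for real cohorts — each wired as a common direct neighbor of
  up to six candidates on both sides, and altered at exactly one level
  (mutation), so they are *altered non-candidates*, the situation-i
  eligibility class. Concentrated wiring is needed because the
  degree-preserving null has a heavy right tail: roughly one rewiring in
  ten places a direct source–target edge by chance, and the planted
  bridges must carry more flow than that event.

What the generator does **not** emulate: curated-pathway/PPI topology
disagreement (available via the `inconsistency` knob but off by default),
realistic breast-cancer effect-size spectra, probe-level methylation
structure, segment-level copy number, and correlated noise between layers.
Passing tests therefore demonstrate that the machinery recovers planted
structure under its own assumptions at desk scale — not that real-cohort
headline counts would be reproduced.

## Scaled problem sizes

The test suite and the acceptance script run the method at reduced sizes
chosen as the package's own desk-scale conditions: 100 resampling rounds
(vs 1000), 100 permutations (vs 1000), 2000-gene networks, 50 seeds for
end-to-end recovery, 500 trials for permutation-test calibration. One
consequence is worth knowing: with P pairs and N permutations the smallest
attainable BH-adjusted empirical p is P/(N+1), so at 45 pairs and 100
permutations no pair can reach FDR < 0.05 — ranking, not FDR survival, is
the end-to-end recovery criterion at that scale. At the default 1000
permutations the planted pair passes FDR < 0.05.

## Known limitations

* Exact-string gene matching; mixed identifier namespaces fail loudly but
  are not reconciled.
* The enrichment background is pathway-annotated measured genes; a
  whole-genome background would yield smaller p-values.
* The degree-preserving null conditions only on the degree sequence;
  structures correlated with degree (e.g. clustering) are attributed to
  signal.
* Pathway relation semantics (activation/inhibition, compounds) are out of
  scope; inputs are pre-flattened gene–gene edges.
* GISTIC-style CNA calling is consumed, not performed: the copy-number
  input is already a gene-level call table.
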