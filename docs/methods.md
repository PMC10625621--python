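# Methods

## Mutation catalogs and cohort comparison

A catalog row is one observed point mutation in one sample: sample id,
gene symbol, short-HGVS protein change, optional phenotype and optional
pathogenicity score in [0, 1]. The protein-change grammar accepted is
`[p.]<REF><POS><ALT>` with `REF` an amino-acid letter, `POS` ≥ 1 and
`ALT` a letter or `*` (nonsense); anything else (frameshifts, `p.?`,
indels) is treated as non-point and dropped when `point_only` is set,
with a count kept in the parse report. Duplicate (sample, gene, change)
rows collapse to one record, and carrier counts are always distinct
samples, so recurrence is per patient. Gene symbols are upper-cased and
stripped at the I/O boundary; compute functions assume harmonized
symbols and do not re-case.

Recurrence of a mutation is `log10(N + 1)` with N its number of
carriers (0 for an absent mutation). Comparing two catalogs partitions
the union of their unique (gene, protein_change) pairs into shared and
cohort-specific sets (likewise for genes) and tests the two groups'
recurrence distributions with a two-sided Welch t-test — chosen over
the pooled test because group sizes and variances differ grossly
between a de-novo and a somatic cohort; the pooled variant and
one-sided alternatives are available behind flags. Frequencies of both
groups are counted in a designated *frequency source* catalog (the
cancer-like catalog by default), and by default each group is
restricted to mutations actually observed there; an `include_absent`
flag scores absentees as 0 instead. The degenerate both-variances-zero
case resolves by convention (equal means → p = 1, unequal → p = 0) so
constant groups never raise.

Pathogenicity scores are consumed as an input column (one score per
mutation; duplicates averaged) and compared per unique mutation with
the same Welch machinery. The module also provides gene-class count
summaries (TF / tumour suppressor / oncogene, with an upset-style
combination table), a phenotype-overlap graph (edge weight = number of
commonly mutated genes), and per-residue profiles keyed by (position,
alt residue) with per-cohort carrier counts and a shared flag.

Seed genes are those mutated in at least `min_patients` (default 3)
distinct samples, ordered by descending carrier count then
lexicographically, which makes the list invariant to record order.

## Network inference

The reference interactome is an undirected graph with confidence
weights in (0, 1]; self-loops are discarded and duplicate pairs keep
the highest weight.

**Graphlet-guided network (GGN).** All connected induced subgraphs on
2–4 nodes containing at least one seed are enumerated and classified
into the nine graphlet shapes. Enumeration generates each node set
exactly once by partitioning the search per root seed (sets containing
an earlier seed are skipped) and, within a root, by how many set
members are direct neighbours of the root; shapes follow from the
(edge count, max degree) pair, so no isomorphism test is run. If one
seed's instance stream exceeds `max_per_seed` (default 50 000) a
uniform reservoir subsample is kept. Type-level significance is an
empirical one-sided z-score of the seeded instance count against
`n_rewires` (default 100) degree-preserving rewired replicas of the
whole interactome; replicas are counted with a closed-form census
(popcount identities per root neighbourhood) that avoids per-instance
work and is exhaustive by construction. Types with z ≥ 1.65 are
significant, and the GGN is the union of the induced edges of their
seeded instances. When no type is enriched — typical for very sparse
or locally tree-like seed neighbourhoods, where rewiring preserves all
counts — the GGN falls back to the seeds' incident edges with a
warning.

The rewiring null swaps random edge pairs (u,v),(x,y) → (u,x),(v,y),
skipping swaps that would create self-loops or duplicates, with 4·|E|
attempts per replica; weights travel with the rewired edges. Degree
sequences are preserved exactly.

**Node and edge scores.** Personalized PageRank solves
`pr = (1 − α) r + α Mᵀ pr` by power iteration (L1 stopping tolerance
1e-12), with `r` uniform over the seeds and `M` the weight-normalized
transition matrix over both directions of each undirected edge. α is
the probability of walking to a neighbour, so the restart probability
is 1 − α; the default α = 0.5. Zero-strength nodes return their mass
to the restart vector, keeping the scores a probability distribution.
PageRank runs on the full interactome by default (`pagerank_scope`
toggles GGN-only). The flux of an edge is the smaller of its two
directed mass flows `f(u→v) = pr(u)·w(u,v)/s(u)` (s = node strength) —
a bottleneck convention under which an edge scores high only if both
endpoints push mass through it; an additive variant is available. Flux
is invariant to a global rescaling of the weights.

**Selection.** GGN edges are ranked by flux descending, ties broken by
the higher minimum-endpoint PageRank and then the lexicographic edge
key, and added while the flux stays at or above the τ-quantile of the
GGN flux distribution (τ = 0.8 keeps the top 20 %) and the network
holds fewer than `edge_cap` = 2000 interactions. τ is implemented as a
quantile because it must scale a "top-ranked" cutoff to an arbitrary
flux distribution; the deterministic tie-break makes the cap
truncation reproducible. Node roles (seed / tf / target / other) are
attached by the regulation step.

## Shared regulation and overrepresentation

STFs of a network are its nodes that appear as TFs in the regulatory
map; the network's regulated genes are the union of its STFs' regulons
(targets need not lie in the network). Common TFs of two networks are
the STF intersection; common targets are the intersection of the two
regulated-gene unions — not the regulons of the common TFs, which is a
strictly narrower notion available behind a flag.

Overrepresentation of a query gene list in a pathway collection uses
the hypergeometric upper tail P(X ≥ k) with k the query∩set overlap,
K the set size inside the universe, n the query size and N the
universe size, followed by Benjamini–Hochberg adjustment across all
tested sets. The default universe is the regulatory map's target space
united with the collection's genes; query genes outside the universe
are dropped with a warning. Rows are sorted by p then pathway id; the
significant view applies p < 0.05 and FDR < 0.05.

## Pathway scoring

The expression score of pathway P in a disease is the mean of |z| over
P's genes with an available z-score; genes without a measurement are
excluded from numerator and denominator so sparse coverage does not
deflate the score (a full-pathway-size denominator is available as
`denominator="full"`). An unmeasured pathway returns NaN with
n_scored = 0. The propensity score divides the number of distinct
(gene, protein_change) pairs falling in the pathway by the full
pathway size, so unmutated members dilute it — "unique mutations" are
variant identities, not carrier counts.

TF profiles (TF × disease z-matrix) are clustered with agglomerative
hierarchical clustering, Euclidean distance, average linkage, cut at
k = 3 groups; only complete rows participate. A TF is *differential*
for a reference disease when |z(ref) − z(c)| ≥ δ (default 1.0 z-unit)
for at least one other disease with both values measured. Algorithm,
linkage, k and δ are deliberate parameterized choices — standard
practice where no single convention dominates.

## Synthetic benchmark

The generator emulates the statistical structure the analysis
exploits, with every output a pure function of (parameters, seed);
stage-specific child seeds make each generator independently
reproducible.

* **Interactome**: Barabási–Albert preferential attachment (m = 3) on
  2000 genes; a planted module of 40 genes additionally wired at
  intra-module edge probability 0.3; Beta(5, 2) confidence weights.
* **Cohorts** (500 samples each): 30 driver genes, 80 % from the
  module, each with 2–5 driver mutations; 600 NDD-like mutations over
  250 genes, half of the module's genes included in the NDD panel.
  Per-mutation carrier counts follow a zero-truncated negative
  binomial (dispersion 2) with underlying mean 20 for drivers and 2
  for NDD mutations — over-dispersed like real recurrence data, and
  separated enough that the recurrence Welch test has high power at
  these cohort sizes. Exactly `round(0.02 · |NDD mutations|)` NDD
  mutations are copied into the cancer catalog at NDD-like recurrence.
  Pathogenicity is Beta(8, 2) for drivers and Beta(2, 3) for NDD
  mutations.
* **Regulation and pathways**: 50 gene sets of 20–80 genes; one
  planted TF — a module gene, so it reliably appears in seed-anchored
  networks, as curated TFs do in real disease modules — draws ≥ 70 %
  of its 40 targets from the planted pathway; 80 background TFs
  (15 % module genes, rest uniform) target 10–40 uniform genes.
* **Expression**: per disease, z ~ N(0, 1); planted-pathway genes are
  shifted by ± Δ with a random sign per gene (Δ = 2.0 cancer-like,
  0.5 NDD-like), so only |z| — the statistic ES uses — separates the
  diseases; 10 % of genes are unmeasured per disease.

What the generator does **not** emulate: real marginal recurrence
spectra, gene-length or expression biases of mutation rates, correlated
pathway membership, symbol aliasing, or a cancer catalog spanning most
of the genome — its cancer cohort mutates only the driver genes, so
pathway propensity scores are *lower* in the cancer-like cohort than
in the NDD-like one unless the pathway overlaps the module. Passing
tests therefore demonstrate correctness of the machinery and
recoverability of planted signals, not performance on real cohorts.

## Problem sizes and numerics

The test suite and `scripts/acceptance.py` run the replicate studies at
these sizes: signal-recovery rates at the full default generator scale
(2000 genes, 100 and 50 replicates respectively); paired
module-recovery inferences on 1000-gene interactomes with 20 rewired
replicas per inference (50 pairs in the suite, 15 in the script);
selection-contract and determinism checks on 600-gene interactomes
with 5 replicas. The 600-gene scale is small enough that graphlet
enrichment sometimes falls back to seed-incident edges — the contracts
hold either way. PageRank iterates to an L1 tolerance of 1e-12 and is
oracle-checked against the direct linear solve at L∞ < 1e-10;
hypergeometric tails are checked against arbitrary-precision rational
sums at 1e-12. Empty GGNs, empty seed sets, zero-variance groups and
unmeasured pathways all fail loudly or return documented sentinels
rather than propagating NaNs silently.

## Known limitations

Directed or signed interactions are out of scope, as are genomic
coordinates (catalogs enter at protein level), pathogenicity
prediction, and the differential-expression meta-analysis that
produces z-scores (consumed as input). Graphlet "significance" and the
τ selection rule are parameterized interpretations of an
underspecified convention; both defaults are stated above and
configurable. The plotting layers (lollipop per-gene profiles, panel
heatmaps) are not implemented; all outputs are tabular and readily
plotted downstream.
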