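# Methods

## Problem setting

Functional enrichment analysis (FEA) condenses a gene-level result (e.g. a
differential-expression contrast) into a list of enriched terms, each
carrying a gene set and a significance statistic.  Because annotation
databases are redundant, the term lists are long and heavily overlapping.
feastkit reorganizes such a list around its genes: terms are clustered by
gene-set overlap into small communities, each community is displayed
against its genes and their quantitative data, and multiple studies can be
juxtaposed through the intersections of their enriched term sets.

## Overlap metrics and the term network

Terms are compared on their GoI-restricted gene sets with the overlap
coefficient OC(X,Y) = |X∩Y|/min(|X|,|Y|) (default) or the Jaccard index
JI(X,Y) = |X∩Y|/|X∪Y|.  OC saturates when one set contains the other and
is therefore more permissive toward parent/child term pairs; JI only
saturates on equality.  JI ≤ OC always.

The term network has an edge for every pair whose overlap is **at least**
the threshold t (default 0.5).  The comparison is inclusive: "exceeds" is
ambiguous at equality, equality is measure-zero for real data, and the
inclusive convention matches common enrichment-map practice.  Edges carry
the overlap value as weight and the weights are used in modularity
maximization — weighting preserves information at no cost.  Self-edges are
never created.

With multi-database agglomeration off (default), term pairs from different
source databases are never connected, keeping e.g. GO and KEGG communities
separate; a qualifying cross-database overlap is instead recorded as a
*cross-database strong link* and later merges the two terms' communities
into a meta-community.

## Community detection and the size cap

Communities are found by greedy (Clauset–Newman–Moore) weighted modularity
maximization at resolution 1.0.  Edgeless graphs short-circuit to
singleton parts.  All iteration orders derive from lexicographically
sorted (database, term_id) keys, so detection is fully deterministic; the
`seed` argument is accepted for interface stability but the default path
does not consume randomness.

Large communities are hard to read, so a maximum community size (default
15) is enforced by an adaptive re-partitioning: each oversized part's
induced subgraph has its local edge threshold raised in +0.05 steps
(edges below the raised threshold are dropped) until the subgraph's greedy
partition splits, and the procedure recurses into any still-oversized
pieces.  If the local threshold reaches 1.0 without a split (a clique of
weight-1.0 edges), the part is chunked into blocks of at most `max_size`
members in descending within-part weighted-degree order, ties broken
lexicographically.  The contract is that no community ever exceeds the
cap; parts reduced to singletons along the way join the unclustered terms.

Parts with ≥2 members become communities, labelled C001, C002, ... by
descending size then lexicographically smallest member; singletons are
reported as unclustered terms (they receive their own report frames).

## Meta-communities

Two communities are linked when (a) some cross-community term pair has
overlap in the residual band [t_weak, t), or (b) some cross-community term
pair is a recorded cross-database strong link.  Meta-communities are the
connected components of size ≥ 2 of this community-level graph — i.e. the
transitive closure of the pairwise link predicate.  The default
t_weak = t/2; it must lie strictly inside (0, t).  The residual band keeps
information that the hard threshold would otherwise discard: a gene set
whose overlap spans several communities still shows up as a link between
them.

## Diagnostics

**Silhouettes.**  On distances d = 1 − overlap, each clustered term i gets
s(i) = (b−a)/max(a,b), where a is the mean distance to its own community's
other members and b the smallest mean distance to another community.
s(i) ∈ [−1, 1]; the degenerate case a = b = 0 is reported as 0.  The
diagnostic needs ≥ 2 communities and is skipped (with a warning)
otherwise.  Unclustered terms are excluded.

**Grid search.**  The full detection pipeline is re-run per
(threshold, max size) pair (defaults: {0.3, 0.5, 0.7} × {10, 15}),
recording community count, size distribution, mean silhouette and the
number of unclustered terms, rendered as a panel grid with a CSV sidecar.

## Gene orderings

The split heatmap's shared gene axis supports three orderings:

* **cluster** — leaf order of an average-linkage dendrogram on Euclidean
  distances between the genes' experiment-value vectors.  Values missing
  because a gene is not GoI in an experiment are imputed as 0 *for the
  distance computation only* (they render grey, not white, in the
  heatmap).  Average linkage and Euclidean distance are conventional
  defaults; the input gene list is sorted before linkage so the order is
  input-permutation invariant.
* **annotation** — genes sorted by descending annotation count, then by
  their binary annotation pattern over the heatmap's fixed term row order
  (terms by descending gene-set size, then term id), descending
  lexicographically, then clustered within identical-pattern blocks.  This
  surfaces the gene subsets driving multiple enrichments.
* **alphabetical** — case-insensitive, case-sensitive tie-break, for easy
  lookup.

## Plots and report

Every rendered image has a machine-readable sidecar (CSV or JSON of the
plotted numbers); tests assert on sidecars, never on pixels.  The upset
plot shows exclusive intersections (each element counted in exactly one
bar); the chord plot is a pairwise-intersection approximation of a circos
diagram — higher-order structure is delegated to the upset plot shown
alongside.  The dot plot maps gene-set size to dot size and −log10 of the
adjusted p-value to colour, rows sorted by ascending p.  The heatmap's
diverging colour scale is symmetric about 0 with limits at the largest
absolute displayed value; "not GoI in this experiment" renders as neutral
grey.  Upset/chord rendering enumerates the power set and is therefore
bounded to the 14 largest input sets (communities rarely approach this).

Each report is a single HTML page with within-page anchors (one frame per
meta-community, community and unclustered term), a fixed top navigation
bar, and script-driven in-place toggling — no external requests except the
NCBI Gene / PubMed literature links, which append the user's extra search
terms AND-joined and percent-encoded.  Community frames list weakly
linked outside terms (best member overlap in [t_weak, t)); term frames
link back.  Rendering is deterministic: a fixed SVG hash salt and
suppressed timestamps make regeneration byte-identical, which the tests
exploit.  Additional per-term images (e.g. pathway diagrams exported by
other tools) are embedded by pass-through only; no annotation service is
contacted.

In comparison mode, the front page shows an upset plot of each study's
enriched term set.  Every exclusive combination of ≥ 2 studies with shared
terms — a term-set intersection — gets a complete sub-report in which
community detection is **re-run on the intersection's terms**, with each
study's GoI and values as separate experiment rows; terms enriched in only
one study appear in the front-page upset but get no sub-report.

## CSV outputs

Three RFC-4180 CSVs accompany every run: term-community membership
(term, database, community, meta-community; blank when unassigned),
term–gene pairs, and experiment–gene values.  Rows are sorted
lexicographically by all columns, and values are written with full float
precision (`repr`), so re-parsing reproduces the in-memory mappings
exactly.

## Input conventions

The FEA table reader defaults to the column convention of common ORA/GSEA
tooling (ID, Description, p.adjust, geneID with "/"-joined gene lists); a
dialect map renames columns and the gene delimiter is configurable, since
upstream pipelines vary.  Gene identifiers are opaque case-sensitive
strings — identifier mapping is upstream's job.  When a GMT file is given
it is authoritative: in-row gene lists are replaced with a warning.  The
run configuration is a flat YAML mapping; unknown keys warn, missing keys
take the documented defaults (metric OC, threshold 0.5, weak threshold
t/2, max community size 15, multi-database agglomeration off, ordering
annotation).

## Synthetic data generator

The fixtures module emulates the inputs an upstream pipeline would
produce, with planted structure so every stage is testable end to end.
Terms come in blocks: each block's terms share a gene core sized so the
expected within-block OC hits its target (default 0.8), plus draws from a
small global spill-over pool whose expected pairwise collision produces
the weak between-block overlap (default 0.1), plus term-unique filler.
Overlap targets are met in expectation, not exactly; tests use ±0.1
bands.  Per experiment, GoI values are drawn from Normal(±effect_size,
noise_sd) with a block-consistent sign (defaults 2.0 and 0.5, i.e. clear
but noisy twofold-change-like effects); each experiment covers ~90% of the
gene universe so some genes render grey.  Defaults: 4 blocks × 6 terms ×
30 genes, 2 experiments.  The generator is deterministic given its seed.

What the generator does *not* emulate: real GO/KEGG term-size
distributions, the nested parent/child structure of ontologies,
correlated noise between experiments, or p-values tied to the planted
effect sizes.  Passing tests therefore demonstrate correctness of the
algorithms on controlled structure, not that a particular biological
dataset will cluster cleanly.

## Problem sizes and numerical choices

The test suite and the acceptance script run desk-scale problems — up to
200 terms, ~2000 genes, 2 experiments, 20 replicate designs — which this
implementation summarizes end to end in well under a minute.  Threshold
comparisons use a 1e-9 tolerance so that raised local thresholds (0.55,
0.60, ...) compare reliably against stored float weights.  Degenerate
inputs are defined explicitly: empty gene sets are rejected by the
metrics, terms empty after GoI restriction are dropped with a warning,
edgeless networks yield all-unclustered output, and a single community
skips the silhouette diagnostic rather than fabricating b(i).

## Known limitations

* The size-cap schedule (+0.05 steps, degree-ordered fallback) is one
  reproducible realization of "attenuated greedy modularity"; other
  attenuation schedules would produce different (equally valid) splits of
  borderline communities.
* Only greedy modularity is offered; Louvain/Leiden variants are out of
  scope by design.
* The chord plot encodes pairwise intersections only.
* Semantic-similarity metrics (information content) are deliberately
  absent: overlap on gene sets keeps the method database-agnostic.
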