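# feastkit

Gene-centric summarization and visualization of functional enrichment
analysis (FEA) results.

A typical over-representation or GSEA run returns hundreds of enriched
terms — GO terms, KEGG pathways, signatures — with heavily overlapping gene
sets, and the biological signal drowns in redundancy. feastkit takes those
result tables (from any upstream FEA pipeline) and answers the gene-centric
question: *which sets of genes are driving which groups of enrichments, and
what do their underlying data look like?*  It is aimed at bioinformaticians
and bench scientists interpreting bulk or single-cell transcriptomics FEAs,
especially across multiple conditions.

## What it computes

Each term's gene list is first reduced to the genes of interest (GoI, e.g.
the differentially expressed genes).  For every pair of terms X, Y a
gene-set overlap is computed with either the overlap coefficient

    OC(X, Y) = |X ∩ Y| / min(|X|, |Y|)

or the Jaccard index

    JI(X, Y) = |X ∩ Y| / |X ∪ Y|,

and a term network is built with an edge wherever the overlap reaches a
user-chosen threshold t.  Communities of related terms are found by greedy
(CNM) weighted modularity maximization, attenuated by an adaptive size cap:
any community larger than a user-chosen maximum is recursively
re-partitioned at progressively higher local thresholds so that no
community exceeds the cap.  Communities are then agglomerated into
**meta-communities** wherever weaker residual overlap (in
[t_weak, t)) remains between their terms, or where strong cross-database
overlap was withheld because multi-database agglomeration is off.
Community quality is reported as silhouette widths on d = 1 − overlap, and
a grid search over (threshold, max community size) supports parameter
choice.

Each community is visualized with a **split heatmap**: binary term-by-gene
annotation rows on top and per-experiment quantitative values (e.g. log2
fold change) below, sharing one gene axis, with three gene orderings
(hierarchical clustering of the data, annotation count/pattern, or
alphabetical).  Everything is assembled into a self-contained navigable
HTML report with upset, chord, dot and silhouette plots plus three CSV
side-outputs.  In comparison mode, two or more FEAs are intersected into
exclusive term-set intersections, each of which gets its own complete
sub-report with every study's data side by side.

## Worked example

```bash
python examples/01_single_fea_report.py
```

generates a synthetic FEA with four planted blocks of six terms each
(within-block overlap 0.8, between-block 0.1, two experiments) and
summarizes it:

```
terms summarized:     24
communities detected: 4
unclustered terms:    0
mean silhouette:      0.775
report:               example_report/index.html
```

The four planted blocks reappear as exactly four communities; the mean
silhouette of 0.78 says the communities are compact and well separated on
1 − overlap distances.  Open `example_report/index.html` in a browser to
navigate the frames.  `examples/02_overlap_and_communities.py` and
`examples/03_multi_fea_comparison.py` walk through the overlap network and
the multi-study comparison mode.

## Command line

```bash
feastkit synth synth.yaml      # write a ready-to-run synthetic input dir
feastkit run CONFIG            # single-FEA summarization
feastkit compare CONFIG        # multi-FEA comparison report
feastkit grid CONFIG           # parameter grid search only
```

The config file is a flat YAML mapping naming the input files (FEA result
tables, per-experiment gene/value tables, optional GMT annotations and
extra gene lists) and the parameters (`metric`, `threshold`,
`max_community_size`, `ordering`, ...); see `docs/methods.md` for the
defaults and their rationale.

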