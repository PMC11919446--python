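"""End-to-end orchestration: from FEAResults to report, plots and CSVs.

``run_single_fea`` executes the whole single-study summarization; in
comparison mode ``run_multi_fea`` first intersects the studies' enriched
term sets and then runs a complete sub-summarization per term-set
intersection, with each study's genes of interest and quantitative data
kept as separate experiment rows in the split heatmaps.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import fea_io, report as report_mod
from .communities import (
    compute_silhouettes,
    detect_communities,
    form_meta_communities,
    grid_search_communities,
)
from .gene_ordering import (
    GeneOrdering,
    order_alphabetical,
    order_by_annotation,
    order_by_clustering,
)
from .models import (
    Community,
    ExtraAnnotation,
    FEAResult,
    GridSearchResult,
    MetaCommunity,
    RunConfig,
    SilhouetteResult,
    Term,
    TermKey,
)
from .overlap import build_term_network, pairwise_overlap_matrix
from .plots import (
    SplitHeatmapSpec,
    render_chord,
    render_dotplot,
    render_grid_search_plot,
    render_silhouette_plot,
    render_split_heatmap,
    render_upset,
)

log = logging.getLogger(__name__)

_MAX_UPSET_SETS = 14  # power-set enumeration bound


@dataclass
class RunSummary:
    """What a single-FEA run produced, for programmatic consumers."""

    out_dir: Path
    html_path: Path
    csv_paths: dict[str, Path]
    asset_paths: dict[str, Path]
    communities: list[Community]
    meta_communities: list[MetaCommunity]
    unclustered: set[TermKey]
    silhouette: Optional[SilhouetteResult]
    grid: Optional[GridSearchResult]
    n_terms: int
    n_genes: int


@dataclass
class CompareSummary:
    out_dir: Path
    front_page: Path
    intersections: list[report_mod.TermSetIntersection]
    sub_summaries: dict[str, RunSummary] = field(default_factory=dict)


def _merge_terms(fea_results: list[FEAResult]) -> list[Term]:
    """Union the FEAs' term collections; shared keys pool their gene sets."""
    merged: dict[TermKey, Term] = {}
    for fea in fea_results:
        for t in fea.terms:
            if t.key in merged:
                prev = merged[t.key]
                padj = min(
                    (p for p in (prev.padj, t.padj) if p is not None), default=None
                )
                merged[t.key] = Term(
                    term_id=t.term_id, description=prev.description or t.description,
                    database=t.database, goi_set=prev.goi_set | t.goi_set,
                    padj=padj, score=prev.score if prev.score is not None else t.score,
                )
            else:
                merged[t.key] = t
    return [merged[k] for k in sorted(merged)]


def _experiment_frame(fea_results: list[FEAResult]) -> pd.DataFrame:
    """Genes x experiments value matrix; NaN where a gene is not GoI."""
    columns: dict[str, dict[str, float]] = {}
    seen: set[str] = set()
    for fea in fea_results:
        for exp in fea.experiments:
            eid = exp.experiment_id
            if eid in seen:
                eid = f"{fea.fea_id}:{eid}"
            seen.add(eid)
            columns[eid] = dict(exp.values)
    genes = sorted({g for col in columns.values() for g in col})
    data = {
        eid: [col.get(g, np.nan) for g in genes] for eid, col in columns.items()
    }
    return pd.DataFrame(data, index=genes)


def _order_genes(
    genes: list[str],
    annot: pd.DataFrame,
    quant: pd.DataFrame,
    strategy: str,
) -> GeneOrdering:
    if strategy == "cluster":
        return order_by_clustering(genes, quant)
    if strategy == "annotation":
        return order_by_annotation(annot, quant)
    if strategy == "alphabetical":
        return order_alphabetical(genes)
    raise ValueError(f"unknown ordering {strategy!r}")


def _heatmap_spec(
    row_sets: dict[str, frozenset[str]],
    row_order: list[str],
    genes: list[str],
    quant: pd.DataFrame,
    strategy: str,
    extra_annotations: list[ExtraAnnotation],
    title: str,
) -> SplitHeatmapSpec:
    annot = pd.DataFrame(
        [[1 if g in row_sets[r] else 0 for g in genes] for r in row_order],
        index=row_order, columns=genes,
    )
    ordering = _order_genes(genes, annot, quant.loc[quant.index.intersection(genes)],
                            strategy)
    ordered = list(ordering.ordered_genes)
    annot = annot.loc[:, ordered]
    exp_rows = quant.reindex(index=ordered).T
    exp_rows.columns = ordered
    extra = None
    if extra_annotations:
        extra = pd.DataFrame(
            [[1 if g in ea.genes else 0 for g in ordered] for ea in extra_annotations],
            index=[ea.label for ea in extra_annotations], columns=ordered,
        )
    return SplitHeatmapSpec(gene_order=ordering, term_rows=annot,
                            experiment_rows=exp_rows, extra_rows=extra, title=title)


def _bounded_sets(named_sets: dict[str, set], what: str) -> dict[str, set]:
    if len(named_sets) <= _MAX_UPSET_SETS:
        return named_sets
    log.warning("%s: %d sets exceed the upset/chord bound; keeping the %d largest",
                what, len(named_sets), _MAX_UPSET_SETS)
    keep = sorted(named_sets, key=lambda n: (-len(named_sets[n]), n))[:_MAX_UPSET_SETS]
    return {n: named_sets[n] for n in keep}


def run_single_fea(
    fea_results: FEAResult | list[FEAResult],
    config: RunConfig,
    out_dir: str | Path | None = None,
    extra_annotations: list[ExtraAnnotation] | None = None,
    term_images: dict[str, Path] | None = None,
    title: str = "FEA summary report",
    filename: str = "index.html",
    home_href: str | None = None,
    seed: int = 0,
    run_grid: bool = True,
) -> RunSummary:
    """Run the full single-FEA summarization pipeline.

    Accepts several FEAResults only for intersection sub-reports, where each
    input study contributes its own experiment rows; community detection
    always operates on the merged term collection.
    """
    if isinstance(fea_results, FEAResult):
        fea_results = [fea_results]
    out_dir = Path(out_dir if out_dir is not None else config.output_dir)
    assets_dir = out_dir / "assets"
    assets_dir.mkdir(parents=True, exist_ok=True)
    extra_annotations = extra_annotations or []
    term_images = term_images or {}

    terms = _merge_terms(fea_results)
    if not terms:
        raise ValueError("no terms to summarize after GoI restriction")
    term_by_key = {t.key: t for t in terms}
    quant = _experiment_frame(fea_results)

    network = build_term_network(terms, metric=config.metric,
                                 threshold=config.threshold,
                                 multi_db_agglomeration=config.multi_db_agglomeration)
    communities, unclustered = detect_communities(
        network, config.max_community_size, seed=seed
    )
    matrix = pairwise_overlap_matrix(terms, config.metric)
    metas = form_meta_communities(
        communities, matrix, config.weak_threshold, config.threshold,
        network.cross_db_strong_links,
    )
    silhouette = compute_silhouettes(terms, communities, config.metric)
    grid = None
    if run_grid and config.grid_thresholds and config.grid_max_sizes:
        grid = grid_search_communities(
            terms, config.grid_thresholds, config.grid_max_sizes,
            metric=config.metric, seed=seed,
            multi_db_agglomeration=config.multi_db_agglomeration,
        )

    csv_paths = fea_io.write_csv_outputs(communities, metas, terms, fea_results, out_dir)

    assets: dict[str, dict[str, str]] = {"overview": {}}
    asset_paths: dict[str, Path] = {}

    def _register(scope: str, label: str, path: Path) -> None:
        rel = path.relative_to(out_dir).as_posix()
        assets.setdefault(scope, {})[label] = rel
        asset_paths[f"{scope}/{label}"] = path

    if silhouette is not None:
        p = render_silhouette_plot(silhouette, assets_dir / "silhouette.svg")
        _register("overview", "Silhouette plot", p)
    if grid is not None:
        p = render_grid_search_plot(grid, assets_dir / "grid_search.svg")
        _register("overview", "Parameter grid search", p)

    for c in communities:
        member_terms = [term_by_key[k] for k in sorted(c.members)]
        genes = sorted(c.goi_union)
        row_order = [t.label for t in
                     sorted(member_terms, key=lambda t: (-len(t.goi_set), t.key))]
        row_sets = {t.label: t.goi_set for t in member_terms}
        spec = _heatmap_spec(row_sets, row_order, genes, quant, config.ordering,
                             extra_annotations, f"Community {c.community_id}")
        p = render_split_heatmap(spec, assets_dir / f"{c.community_id}_heatmap.svg")
        _register(f"community:{c.community_id}", "Split heatmap", p)
        named = _bounded_sets({t.label: set(t.goi_set) for t in member_terms},
                              f"community {c.community_id}")
        p = render_upset(named, assets_dir / f"{c.community_id}_upset.svg")
        _register(f"community:{c.community_id}", "Upset plot", p)
        p = render_chord(named, assets_dir / f"{c.community_id}_chord.svg")
        _register(f"community:{c.community_id}", "Gene-set overlap (chord)", p)
        p = render_dotplot(member_terms, assets_dir / f"{c.community_id}_dotplot.svg")
        if p is not None:
            _register(f"community:{c.community_id}", "FEA dot plot", p)
        for t in member_terms:
            if t.term_id in term_images:
                _register(f"images:{c.community_id}", f"{t.label} (supplied)",
                          _copy_image(term_images[t.term_id], assets_dir))

    comm_by_id = {c.community_id: c for c in communities}
    for m in metas:
        member_comms = [comm_by_id[cid] for cid in sorted(m.member_communities)]
        genes = sorted(set().union(*(c.goi_union for c in member_comms)))
        row_sets = {c.community_id: c.goi_union for c in member_comms}
        row_order = [c.community_id for c in member_comms]
        spec = _heatmap_spec(row_sets, row_order, genes, quant, config.ordering,
                             extra_annotations, f"Meta-community {m.meta_id}")
        p = render_split_heatmap(spec, assets_dir / f"{m.meta_id}_heatmap.svg")
        _register(f"meta:{m.meta_id}", "Community-membership split heatmap", p)
        named = _bounded_sets({c.community_id: set(c.goi_union) for c in member_comms},
                              f"meta-community {m.meta_id}")
        p = render_upset(named, assets_dir / f"{m.meta_id}_upset.svg")
        _register(f"meta:{m.meta_id}", "Upset plot", p)
        p = render_chord(named, assets_dir / f"{m.meta_id}_chord.svg")
        _register(f"meta:{m.meta_id}", "Gene-set overlap (chord)", p)

    model = report_mod.build_report_model(
        fea_results, communities, metas, unclustered, matrix, assets, config,
        title=title, home_href=home_href,
    )
    html_path = report_mod.render_html(model, out_dir, filename=filename)

    return RunSummary(
        out_dir=out_dir, html_path=html_path, csv_paths=csv_paths,
        asset_paths=asset_paths, communities=communities, meta_communities=metas,
        unclustered=unclustered, silhouette=silhouette, grid=grid,
        n_terms=len(terms), n_genes=len(quant.index),
    )


def _copy_image(src: Path, assets_dir: Path) -> Path:
    dst = assets_dir / Path(src).name
    dst.write_bytes(Path(src).read_bytes())
    return dst


def run_multi_fea(
    fea_results: list[FEAResult],
    config: RunConfig,
    out_dir: str | Path | None = None,
    extra_annotations: list[ExtraAnnotation] | None = None,
    term_images: dict[str, Path] | None = None,
    seed: int = 0,
) -> CompareSummary:
    """Multi-FEA comparison: front page plus one sub-report per intersection."""
    out_dir = Path(out_dir if out_dir is not None else config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    intersections = report_mod.intersect_fea_term_sets(fea_results)

    named = {f.fea_id: {f"{k[0]}:{k[1]}" for k in f.term_keys()} for f in fea_results}
    assets_dir = out_dir / "assets"
    upset_rel = None
    if len(named) >= 2:
        p = render_upset(_bounded_sets(named, "FEA term sets"),
                         assets_dir / "fea_term_sets_upset.svg")
        upset_rel = p.relative_to(out_dir).as_posix()

    by_id = {f.fea_id: f for f in fea_results}
    reports = []
    sub_summaries: dict[str, RunSummary] = {}
    for inter in intersections:
        sub_inputs = []
        for fid in sorted(inter.signature):
            fea = by_id[fid]
            sub_inputs.append(
                FEAResult(
                    fea_id=fid,
                    terms=[t for t in fea.terms if t.key in inter.terms],
                    experiments=fea.experiments,
                )
            )
        sub_dir = out_dir / "intersections" / inter.slug
        sub_config = dataclasses.replace(config, output_dir=sub_dir)
        summary = run_single_fea(
            sub_inputs, sub_config, out_dir=sub_dir,
            extra_annotations=extra_annotations, term_images=term_images,
            title=f"FEA term-set intersection: {inter.title}",
            home_href="../../index.html", seed=seed,
        )
        sub_summaries[inter.slug] = summary
        reports.append({
            "href": f"intersections/{inter.slug}/index.html",
            "title": inter.title,
            "n_terms": len(inter.terms),
        })

    front = report_mod.FrontPageModel(
        title="Multi-FEA comparison",
        upset_asset=upset_rel,
        reports=reports,
        fea_summary=[{"fea_id": f.fea_id, "n_terms": len(f.terms)}
                     for f in fea_results],
    )
    front_page = report_mod.render_front_page(front, out_dir)
    return CompareSummary(out_dir=out_dir, front_page=front_page,
                          intersections=intersections, sub_summaries=sub_summaries)
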