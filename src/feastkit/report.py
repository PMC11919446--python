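"""Navigable HTML report assembly.

A report is a single self-contained HTML page (plus CSS/JS/asset files,
relative paths only) with one frame per meta-community, community and
unclustered term, a fixed top navigation bar, in-place JavaScript toggling
of figures and tables, and internal anchor links connecting related frames.
Multi-FEA comparisons get a front page whose upset plot shows the term sets
enriched per input FEA; every combination of two or more FEAs sharing terms
(a term-set intersection) links to its own complete sub-report.
"""

from __future__ import annotations

import itertools
import re
import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from jinja2 import Environment, PackageLoader, select_autoescape

from .models import Community, FEAResult, MetaCommunity, RunConfig, Term, TermKey

_EPS = 1e-9

_env = Environment(
    loader=PackageLoader("feastkit", "templates"),
    autoescape=select_autoescape(["html"]),
    keep_trailing_newline=True,
)


# ---------------------------------------------------------------------------
# External literature links

NCBI_GENE_URL = "https://www.ncbi.nlm.nih.gov/gene/"
PUBMED_URL = "https://pubmed.ncbi.nlm.nih.gov/"


def gene_search_url(gene: str, search_terms: list[str] | None = None) -> tuple[str, str]:
    """NCBI Gene and PubMed literature-search URLs for one gene.

    User-supplied search terms are AND-joined onto the query and the whole
    query is percent-encoded.
    """
    if not gene:
        raise ValueError("gene ID must be non-empty")
    tokens = [gene] + list(search_terms or [])
    query = " AND ".join(tokens)
    qs = urllib.parse.urlencode({"term": query})
    return f"{NCBI_GENE_URL}?{qs}", f"{PUBMED_URL}?{qs}"


# ---------------------------------------------------------------------------
# Multi-FEA term-set intersections

@dataclass(frozen=True)
class TermSetIntersection:
    """Terms enriched in exactly this combination of two or more FEAs."""

    signature: frozenset[str]
    terms: frozenset[TermKey]

    @property
    def slug(self) -> str:
        return _slug("__".join(sorted(self.signature)))

    @property
    def title(self) -> str:
        return " & ".join(sorted(self.signature))


def intersect_fea_term_sets(fea_results: list[FEAResult]) -> list[TermSetIntersection]:
    """Exclusive term-set intersections over >=2 input FEAs.

    For every subset S of the FEAs with |S| >= 2, the terms enriched in all
    of S and in none of the others; empty intersections are omitted.  The
    returned intersections are pairwise disjoint by construction.
    """
    if len(fea_results) < 2:
        raise ValueError("term-set intersections need >=2 FEAs; "
                         "use single-FEA mode for one input")
    ids = [f.fea_id for f in fea_results]
    if len(set(ids)) != len(ids):
        raise ValueError("FEA ids must be unique")
    term_sets = {f.fea_id: f.term_keys() for f in fea_results}
    out = []
    for r in range(2, len(ids) + 1):
        for combo in itertools.combinations(sorted(ids), r):
            inside = set.intersection(*(term_sets[i] for i in combo))
            for other in ids:
                if other not in combo:
                    inside -= term_sets[other]
            if inside:
                out.append(TermSetIntersection(signature=frozenset(combo),
                                               terms=frozenset(inside)))
    out.sort(key=lambda i: (-len(i.signature), sorted(i.signature)))
    return out


# ---------------------------------------------------------------------------
# Report model

def _slug(text: str) -> str:
    return re.sub(r"[^A-Za-z0-9_-]+", "_", text)


def meta_anchor(meta_id: str) -> str:
    return f"meta-{_slug(meta_id)}"


def community_anchor(community_id: str) -> str:
    return f"community-{_slug(community_id)}"


def term_anchor(key: TermKey) -> str:
    return f"term-{_slug(key[0])}-{_slug(key[1])}"


@dataclass
class Frame:
    frame_id: str
    kind: str  # "meta" | "community" | "term"
    title: str
    description: str = ""
    links: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    assets: list[tuple[str, str]] = field(default_factory=list)  # (label, relpath)
    images: list[tuple[str, str]] = field(default_factory=list)  # pass-through
    term_table: list[dict] = field(default_factory=list)
    gene_links: list[dict] = field(default_factory=list)


@dataclass
class ReportModel:
    title: str
    overview: dict
    frames: list[Frame]
    nav: list[tuple[str, str]]
    home_href: Optional[str] = None

    def validate(self) -> None:
        ids = {f.frame_id for f in self.frames}
        for m in self.overview.get("metas", []):
            for c in m["communities"]:
                if c["anchor"] not in ids:
                    raise ValueError(f"meta-community references missing frame {c['anchor']}")
        for f in self.frames:
            for group in f.links.values():
                for href, _ in group:
                    if href.startswith("#") and href[1:] not in ids | {"overview"}:
                        raise ValueError(f"dangling internal link {href} in {f.frame_id}")


def _weak_link_pairs(
    communities: list[Community],
    overlap_matrix,
    weak_threshold: float,
    threshold: float,
) -> dict[str, set[TermKey]]:
    """Per community: outside terms whose best member overlap is weak.

    A term outside community C is weakly linked to C when its maximum
    overlap with any member lies in [weak_threshold, threshold).
    """
    pos = {key: i for i, key in enumerate(overlap_matrix.index)}
    vals = overlap_matrix.to_numpy()
    member_of = {k: c.community_id for c in communities for k in c.members}
    all_terms = list(overlap_matrix.index)
    out: dict[str, set[TermKey]] = {c.community_id: set() for c in communities}
    for c in communities:
        rows = [pos[k] for k in sorted(c.members)]
        for t in all_terms:
            if member_of.get(t) == c.community_id:
                continue
            best = max(vals[pos[t], r] for r in rows)
            if weak_threshold - _EPS <= best < threshold - _EPS:
                out[c.community_id].add(t)
    return out


def build_report_model(
    fea_results: list[FEAResult],
    communities: list[Community],
    meta_communities: list[MetaCommunity],
    unclustered: set[TermKey],
    overlap_matrix,
    assets: dict,
    config: RunConfig,
    title: str = "FEA summary report",
    home_href: Optional[str] = None,
) -> ReportModel:
    """Assemble the frame tree and navigation model for one report.

    ``assets`` maps frame scope -> {label: relative path}; see the pipeline
    for the canonical keys ("overview", "community:<id>", "meta:<id>").
    """
    terms: dict[TermKey, Term] = {
        t.key: t for fea in fea_results for t in fea.terms
    }
    meta_of = {cid: m.meta_id for m in meta_communities
               for cid in m.member_communities}
    comm_by_id = {c.community_id: c for c in communities}
    weak = _weak_link_pairs(communities, overlap_matrix,
                            config.weak_threshold, config.threshold)
    # reverse map: weakly linked unclustered term -> communities
    weak_back: dict[TermKey, list[str]] = {}
    for cid, ts in weak.items():
        for t in ts:
            weak_back.setdefault(t, []).append(cid)

    frames: list[Frame] = []
    nav: list[tuple[str, str]] = []

    for m in meta_communities:
        members = sorted(m.member_communities)
        frame = Frame(
            frame_id=meta_anchor(m.meta_id),
            kind="meta",
            title=f"Meta-community {m.meta_id}",
            description=(f"{len(members)} member communities linked by residual "
                         "or cross-database gene-set overlap."),
            links={"members": [(f"#{community_anchor(cid)}", cid) for cid in members]},
            assets=sorted(assets.get(f"meta:{m.meta_id}", {}).items()),
        )
        frames.append(frame)
        nav.append((frame.frame_id, frame.title))

    for c in communities:
        mid = meta_of.get(c.community_id)
        links: dict[str, list[tuple[str, str]]] = {}
        if mid:
            links["parent"] = [(f"#{meta_anchor(mid)}", f"Meta-community {mid}")]
            siblings = sorted(
                cid for cid in comm_by_id
                if meta_of.get(cid) == mid and cid != c.community_id
            )
            links["siblings"] = [(f"#{community_anchor(s)}", s) for s in siblings]
        weak_terms = sorted(weak[c.community_id])
        links["weak"] = [
            (f"#{term_anchor(t)}" if t in unclustered else
             f"#{community_anchor(_community_of(t, communities))}",
             f"{t[0]}:{t[1]}")
            for t in weak_terms
        ]
        table = [
            {"term_id": k[1], "database": k[0],
             "description": terms[k].description if k in terms else "",
             "padj": "" if k not in terms or terms[k].padj is None
                     else f"{terms[k].padj:.3g}",
             "n_genes": len(terms[k].goi_set) if k in terms else 0}
            for k in sorted(c.members)
        ]
        genes = sorted(c.goi_union)
        gene_links = [
            {"gene": g, "gene_url": gene_search_url(g, config.search_terms)[0],
             "pubmed_url": gene_search_url(g, config.search_terms)[1]}
            for g in genes
        ]
        images = sorted(assets.get(f"images:{c.community_id}", {}).items())
        frame = Frame(
            frame_id=community_anchor(c.community_id),
            kind="community",
            title=f"Community {c.community_id}",
            description=(f"{len(c.members)} member terms over "
                         f"{len(c.goi_union)} genes of interest."),
            links=links,
            assets=sorted(assets.get(f"community:{c.community_id}", {}).items()),
            images=images,
            term_table=table,
            gene_links=gene_links,
        )
        frames.append(frame)
        nav.append((frame.frame_id, frame.title))

    for t in sorted(unclustered):
        term = terms.get(t)
        links = {"weak": [(f"#{community_anchor(cid)}", cid)
                          for cid in sorted(weak_back.get(t, []))]}
        gene_links = [
            {"gene": g, "gene_url": gene_search_url(g, config.search_terms)[0],
             "pubmed_url": gene_search_url(g, config.search_terms)[1]}
            for g in (sorted(term.goi_set) if term else [])
        ]
        frame = Frame(
            frame_id=term_anchor(t),
            kind="term",
            title=f"Term {t[0]}:{t[1]}",
            description=(term.description if term else ""),
            links=links,
            term_table=[{
                "term_id": t[1], "database": t[0],
                "description": term.description if term else "",
                "padj": "" if term is None or term.padj is None
                        else f"{term.padj:.3g}",
                "n_genes": len(term.goi_set) if term else 0,
            }],
            gene_links=gene_links,
        )
        frames.append(frame)
        nav.append((frame.frame_id, frame.title))

    overview = {
        "metas": [
            {
                "anchor": meta_anchor(m.meta_id),
                "title": f"Meta-community {m.meta_id}",
                "communities": [
                    {"anchor": community_anchor(cid), "title": cid,
                     "terms": [f"{k[0]}:{k[1]}"
                               for k in sorted(comm_by_id[cid].members)]}
                    for cid in sorted(m.member_communities)
                ],
            }
            for m in meta_communities
        ],
        "lone_communities": [
            {"anchor": community_anchor(c.community_id), "title": c.community_id,
             "terms": [f"{k[0]}:{k[1]}" for k in sorted(c.members)]}
            for c in communities if c.community_id not in meta_of
        ],
        "unclustered": [
            {"anchor": term_anchor(t), "title": f"{t[0]}:{t[1]}"}
            for t in sorted(unclustered)
        ],
        "assets": sorted(assets.get("overview", {}).items()),
    }
    model = ReportModel(title=title, overview=overview, frames=frames,
                        nav=nav, home_href=home_href)
    model.validate()
    return model


def _community_of(key: TermKey, communities: list[Community]) -> str:
    for c in communities:
        if key in c.members:
            return c.community_id
    raise KeyError(key)


# ---------------------------------------------------------------------------
# Rendering

def render_html(model: ReportModel, out_dir: str | Path,
                filename: str = "index.html") -> Path:
    """Render one report page plus its shared CSS/JS into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    html = _env.get_template("report.html.j2").render(model=model)
    out_path = out_dir / filename
    out_path.write_text(html, encoding="utf-8")
    _write_static(out_dir)
    return out_path


@dataclass
class FrontPageModel:
    title: str
    upset_asset: Optional[str]
    reports: list[dict]  # {href, title, n_terms}
    fea_summary: list[dict]  # {fea_id, n_terms}


def render_front_page(model: FrontPageModel, out_dir: str | Path,
                      filename: str = "index.html") -> Path:
    """Render the multi-FEA front page (term-set upset + Reports menu)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    html = _env.get_template("front.html.j2").render(model=model)
    out_path = out_dir / filename
    out_path.write_text(html, encoding="utf-8")
    _write_static(out_dir)
    return out_path


def _write_static(out_dir: Path) -> None:
    for name in ("style.css", "report.js"):
        src = _env.loader.get_source(_env, name)[0]
        (out_dir / name).write_text(src, encoding="utf-8")
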