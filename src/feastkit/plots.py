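"""Report graphics: split heatmaps, upset/chord plots, dot plots, diagnostics.

Every rendered image gets a machine-readable sidecar (CSV or JSON of the
plotted numbers) next to it, so downstream checks can assert on data rather
than pixels.  Rendering is deterministic: a fixed SVG hash salt and no
embedded timestamps make repeated renders byte-identical.
"""

from __future__ import annotations

import csv
import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from collections.abc import Mapping, Sequence
from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
matplotlib.rcParams["svg.hashsalt"] = "feastkit"

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import ListedColormap, TwoSlopeNorm
from matplotlib.path import Path as MplPath
from matplotlib.patches import PathPatch

from .gene_ordering import GeneOrdering
from .models import GridSearchResult, SilhouetteResult, Term

log = logging.getLogger(__name__)

_TERM_CMAP = ListedColormap(["#d9d9d9", "#ffd700"])   # grey / yellow (annotated)
_EXTRA_CMAP = ListedColormap(["#d9d9d9", "#ff69b4"])  # grey / pink (extra rows)
_ABSENT = "#bdbdbd"  # gene not GoI in this experiment


def _save(fig, out_path: str | Path) -> Path:
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    kwargs = {"metadata": {"Date": None}} if out_path.suffix == ".svg" else {}
    fig.savefig(out_path, bbox_inches="tight", **kwargs)
    plt.close(fig)
    return out_path


def _sidecar(out_path: str | Path, suffix: str) -> Path:
    p = Path(out_path)
    p.parent.mkdir(parents=True, exist_ok=True)
    return p.with_suffix(suffix)


# ---------------------------------------------------------------------------
# Split heatmap

@dataclass
class SplitHeatmapSpec:
    """Renderable model of the split heatmap.

    All row blocks share ``gene_order`` as their x-axis: binary
    term/community annotation rows (yellow = annotated) on top, optional
    extra-annotation rows (pink) above them, and per-experiment quantitative
    rows below on a signed diverging scale with grey for genes that are not
    GoI in that experiment.
    """

    gene_order: GeneOrdering
    term_rows: pd.DataFrame                      # binary, rows x genes
    experiment_rows: pd.DataFrame                # float (NaN = not GoI), rows x genes
    extra_rows: Optional[pd.DataFrame] = None    # binary, rows x genes
    title: str = ""

    def __post_init__(self) -> None:
        genes = list(self.gene_order.ordered_genes)
        if not genes:
            raise ValueError("split heatmap needs at least one gene")
        for name, block in (("term_rows", self.term_rows),
                            ("experiment_rows", self.experiment_rows),
                            ("extra_rows", self.extra_rows)):
            if block is None:
                continue
            if list(block.columns) != genes:
                if set(block.columns) == set(genes):
                    # align to the shared axis
                    block = block.loc[:, genes]
                    setattr(self, name, block)
                else:
                    raise ValueError(f"{name} columns do not match gene_order")


def render_split_heatmap(spec: SplitHeatmapSpec, out_path: str | Path) -> Path:
    """Render the split heatmap; JSON sidecar carries all plotted matrices."""
    genes = list(spec.gene_order.ordered_genes)
    n = len(genes)
    extra = spec.extra_rows if spec.extra_rows is not None else pd.DataFrame(columns=genes)
    n_top = len(extra) + len(spec.term_rows)
    n_bot = len(spec.experiment_rows)

    fig_w = max(4.0, min(18.0, 0.18 * n + 1.5))
    fig_h = max(2.5, 0.32 * (n_top + n_bot) + 1.2)
    fig, axes = plt.subplots(
        2, 1, figsize=(fig_w, fig_h), sharex=True,
        gridspec_kw={"height_ratios": [max(n_top, 1), max(n_bot, 1)]},
    )
    ax_top, ax_bot = axes

    top_rows = []
    if len(extra):
        top_rows.append((extra.to_numpy(dtype=float), _EXTRA_CMAP, list(extra.index)))
    top_rows.append((spec.term_rows.to_numpy(dtype=float), _TERM_CMAP,
                     list(spec.term_rows.index)))
    offset = 0
    labels_top = []
    for data, cmap, labels in top_rows:
        if data.shape[0] == 0:
            continue
        ax_top.imshow(data, aspect="auto", cmap=cmap, vmin=0, vmax=1,
                      interpolation="nearest",
                      extent=(-0.5, n - 0.5, offset + data.shape[0] - 0.5, offset - 0.5))
        labels_top.extend(labels)
        offset += data.shape[0]
    ax_top.set_ylim(n_top - 0.5, -0.5)
    ax_top.set_yticks(range(n_top))
    ax_top.set_yticklabels(labels_top, fontsize=7)
    if spec.title:
        ax_top.set_title(spec.title, fontsize=9)

    vals = spec.experiment_rows.to_numpy(dtype=float)
    vmax = np.nanmax(np.abs(vals)) if np.isfinite(vals).any() else 1.0
    vmax = vmax if vmax > 0 else 1.0
    cmap = matplotlib.colormaps["RdBu_r"].copy()
    cmap.set_bad(_ABSENT)
    im = ax_bot.imshow(np.ma.masked_invalid(vals), aspect="auto", cmap=cmap,
                       norm=TwoSlopeNorm(vcenter=0.0, vmin=-vmax, vmax=vmax),
                       interpolation="nearest",
                       extent=(-0.5, n - 0.5, n_bot - 0.5, -0.5))
    ax_bot.set_yticks(range(n_bot))
    ax_bot.set_yticklabels(list(spec.experiment_rows.index), fontsize=7)
    if n <= 60:
        ax_bot.set_xticks(range(n))
        ax_bot.set_xticklabels(genes, rotation=90, fontsize=6)
    else:
        ax_bot.set_xticks([])
    fig.colorbar(im, ax=axes, shrink=0.6, label="value")

    sidecar = {
        "genes": genes,
        "ordering": spec.gene_order.strategy,
        "term_rows": {str(i): [int(v) for v in row]
                      for i, row in spec.term_rows.iterrows()},
        "extra_rows": {str(i): [int(v) for v in row] for i, row in extra.iterrows()},
        "experiment_rows": {
            str(i): [None if pd.isna(v) else float(v) for v in row]
            for i, row in spec.experiment_rows.iterrows()
        },
    }
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    with open(_sidecar(out_path, ".json"), "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
    return _save(fig, out_path)


# ---------------------------------------------------------------------------
# Upset plot

def exclusive_intersections(named_sets: Mapping[str, set]) -> dict[frozenset[str], set]:
    """Exclusive (disjoint) intersections of named sets, empty ones omitted."""
    names = sorted(named_sets)
    out: dict[frozenset[str], set] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(set(named_sets[n]) for n in combo))
            for other in names:
                if other not in combo:
                    inside -= set(named_sets[other])
            if inside:
                out[frozenset(combo)] = inside
    return out


def render_upset(named_sets: Mapping[str, set], out_path: str | Path) -> Path:
    """Upset plot of exclusive intersections, with a CSV sidecar of sizes."""
    if len(named_sets) < 2:
        raise ValueError("upset plot needs at least 2 named sets")
    inter = exclusive_intersections(named_sets)
    names = sorted(named_sets)
    combos = sorted(inter, key=lambda c: (-len(inter[c]), sorted(c)))
    sizes = [len(inter[c]) for c in combos]

    fig, (ax_bar, ax_dot) = plt.subplots(
        2, 1, figsize=(max(4, 0.6 * len(combos) + 2), 4.5), sharex=True,
        gridspec_kw={"height_ratios": [3, 1.2]},
    )
    xs = range(len(combos))
    ax_bar.bar(xs, sizes, color="#333333")
    for x, s in zip(xs, sizes):
        ax_bar.text(x, s, str(s), ha="center", va="bottom", fontsize=8)
    ax_bar.set_ylabel("intersection size")
    for x, combo in enumerate(combos):
        for y, name in enumerate(names):
            filled = name in combo
            ax_dot.plot(x, y, "o", color="#333333" if filled else "#d9d9d9",
                        markersize=7)
        members = [y for y, name in enumerate(names) if name in combo]
        if len(members) > 1:
            ax_dot.plot([x, x], [min(members), max(members)], color="#333333")
    ax_dot.set_yticks(range(len(names)))
    ax_dot.set_yticklabels(names, fontsize=8)
    ax_dot.set_xticks([])
    ax_dot.set_ylim(len(names) - 0.5, -0.5)

    with open(_sidecar(Path(out_path), ".csv"), "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["signature", "size", "members"])
        for combo in combos:
            w.writerow(["&".join(sorted(combo)), len(inter[combo]),
                        "/".join(sorted(inter[combo]))])
    return _save(fig, out_path)


# ---------------------------------------------------------------------------
# Chord (circos-style) plot

def pairwise_intersection_matrix(named_sets: Mapping[str, set]) -> pd.DataFrame:
    names = sorted(named_sets)
    mat = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for a in names:
        for b in names:
            mat.loc[a, b] = len(set(named_sets[a]) & set(named_sets[b]))
    return mat


def render_chord(named_sets: Mapping[str, set], out_path: str | Path) -> Path:
    """Circular overlap diagram: arc length ~ set size, ribbon width ~ |X n Y|.

    A pairwise approximation of a full circos diagram; higher-order overlap
    structure is shown by the accompanying upset plot.
    """
    if len(named_sets) < 2:
        raise ValueError("chord plot needs at least 2 named sets")
    mat = pairwise_intersection_matrix(named_sets)
    names = list(mat.index)
    sizes = np.array([len(named_sets[n]) for n in names], dtype=float)
    total = sizes.sum() or 1.0
    gap = 0.03
    span = 2 * math.pi * (1 - gap * len(names))
    starts, angles = {}, {}
    a = 0.0
    for n, s in zip(names, sizes):
        width = span * (s / total)
        starts[n] = a
        angles[n] = width
        a += width + 2 * math.pi * gap

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.set_aspect("equal")
    ax.axis("off")
    cmap = matplotlib.colormaps["tab10"]
    r = 1.0
    for i, n in enumerate(names):
        theta = np.linspace(starts[n], starts[n] + angles[n], 40)
        ax.plot(r * np.cos(theta), r * np.sin(theta), lw=8, color=cmap(i % 10),
                solid_capstyle="butt")
        mid = starts[n] + angles[n] / 2
        ax.text(1.18 * math.cos(mid), 1.18 * math.sin(mid), n, ha="center",
                va="center", fontsize=8)
    # ribbons: cubic Bezier through the centre, width encoded as arc fraction
    used = {n: 0.0 for n in names}
    for i, a_name in enumerate(names):
        for b_name in names[i + 1:]:
            inter = int(mat.loc[a_name, b_name])
            if inter == 0:
                continue
            wa = angles[a_name] * (inter / max(sizes[names.index(a_name)], 1))
            wb = angles[b_name] * (inter / max(sizes[names.index(b_name)], 1))
            a0 = starts[a_name] + used[a_name]
            b0 = starts[b_name] + used[b_name]
            used[a_name] += wa
            used[b_name] += wb
            p = _ribbon_path(a0, a0 + wa, b0, b0 + wb, r=0.96)
            ax.add_patch(PathPatch(p, facecolor=cmap(i % 10), alpha=0.4, lw=0))
    ax.set_xlim(-1.3, 1.3)
    ax.set_ylim(-1.3, 1.3)

    mat.to_csv(_sidecar(Path(out_path), ".csv"))
    return _save(fig, out_path)


def _ribbon_path(a0: float, a1: float, b0: float, b1: float, r: float) -> MplPath:
    def pt(t: float) -> tuple[float, float]:
        return (r * math.cos(t), r * math.sin(t))

    verts = [pt(a0)]
    codes = [MplPath.MOVETO]
    arc = np.linspace(a0, a1, 8)[1:]
    verts.extend(pt(t) for t in arc)
    codes.extend([MplPath.LINETO] * len(arc))
    verts.extend([(0, 0), pt(b0)])
    codes.extend([MplPath.CURVE3, MplPath.CURVE3])
    arc = np.linspace(b0, b1, 8)[1:]
    verts.extend(pt(t) for t in arc)
    codes.extend([MplPath.LINETO] * len(arc))
    verts.extend([(0, 0), pt(a0)])
    codes.extend([MplPath.CURVE3, MplPath.CURVE3])
    return MplPath(verts, codes)


# ---------------------------------------------------------------------------
# FEA dot plot

def render_dotplot(terms: Sequence[Term], out_path: str | Path) -> Optional[Path]:
    """Dot plot of member terms' FEA statistics.

    One row per term, sorted by ascending adjusted p-value; dot size scales
    with the GoI-restricted gene-set size, colour with -log10(padj).  Terms
    without an adjusted p-value are omitted with a warning; returns ``None``
    when no term has one.
    """
    with_p = [t for t in terms if t.padj is not None]
    dropped = len(terms) - len(with_p)
    if dropped:
        log.warning("dot plot: %d terms without adjusted p-value omitted", dropped)
    if not with_p:
        log.warning("dot plot skipped: no term has an adjusted p-value")
        return None
    ordered = sorted(with_p, key=lambda t: (t.padj, t.key))
    neglog = [-math.log10(max(t.padj, 1e-300)) for t in ordered]
    gene_counts = [len(t.goi_set) for t in ordered]

    fig, ax = plt.subplots(figsize=(5, max(2.0, 0.3 * len(ordered) + 1)))
    ys = range(len(ordered))
    sc = ax.scatter(gene_counts, ys, s=[20 + 8 * c for c in gene_counts],
                    c=neglog, cmap="viridis", vmin=0)
    ax.set_yticks(list(ys))
    ax.set_yticklabels([t.label for t in ordered], fontsize=7)
    ax.invert_yaxis()
    ax.set_xlabel("genes of interest")
    fig.colorbar(sc, ax=ax, label="-log10 adjusted p")

    with open(_sidecar(Path(out_path), ".csv"), "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["term_id", "database", "padj", "neglog10_padj", "goi_count"])
        for t, nl, c in zip(ordered, neglog, gene_counts):
            w.writerow([t.term_id, t.database, repr(t.padj), repr(nl), c])
    return _save(fig, out_path)


# ---------------------------------------------------------------------------
# Diagnostics

def render_silhouette_plot(result: SilhouetteResult, out_path: str | Path) -> Path:
    """Horizontal silhouette bars grouped by community."""
    by_comm: dict[str, list[tuple]] = {}
    for key, s in result.values.items():
        by_comm.setdefault(result.community_of[key], []).append((key, s))
    rows = []
    for cid in sorted(by_comm):
        for key, s in sorted(by_comm[cid], key=lambda ks: (-ks[1], ks[0])):
            rows.append((cid, key, s))

    fig, ax = plt.subplots(figsize=(5, max(2.0, 0.22 * len(rows) + 1)))
    ys = range(len(rows))
    colors = matplotlib.colormaps["tab10"]
    cids = sorted(by_comm)
    ax.barh(list(ys), [r[2] for r in rows],
            color=[colors(cids.index(r[0]) % 10) for r in rows])
    ax.set_yticks(list(ys))
    ax.set_yticklabels([f"{r[0]} {r[1][0]}:{r[1][1]}" for r in rows], fontsize=6)
    ax.invert_yaxis()
    ax.set_xlabel("silhouette width")
    ax.set_xlim(-1, 1)
    ax.axvline(result.overall_mean, color="red", ls="--", lw=1,
               label=f"overall mean {result.overall_mean:.2f}")
    ax.legend(fontsize=7)

    with open(_sidecar(Path(out_path), ".csv"), "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["community_id", "database", "term_id", "silhouette"])
        for cid, key, s in rows:
            w.writerow([cid, key[0], key[1], repr(s)])
        w.writerow(["__overall__", "", "", repr(result.overall_mean)])
    return _save(fig, out_path)


def render_grid_search_plot(result: GridSearchResult, out_path: str | Path) -> Path:
    """Panel per (threshold, max size) cell summarizing detection outcomes."""
    if not result.cells:
        raise ValueError("empty grid")
    thresholds = sorted({thr for thr, _ in result.cells})
    sizes = sorted({s for _, s in result.cells})
    fig, axes = plt.subplots(
        len(sizes), len(thresholds),
        figsize=(2.4 * len(thresholds), 2.0 * len(sizes)), squeeze=False,
    )
    for i, size in enumerate(sizes):
        for j, thr in enumerate(thresholds):
            ax = axes[i][j]
            cell = result.cells[(thr, size)]
            if cell.sizes:
                ax.bar(range(len(cell.sizes)), cell.sizes, color="#4477aa")
            ms = "n/a" if cell.mean_silhouette is None else f"{cell.mean_silhouette:.2f}"
            ax.set_title(
                f"t={thr:g} cap={size}\n{cell.n_communities} comms, "
                f"sil {ms}, {cell.n_unclustered} loose",
                fontsize=7,
            )
            ax.tick_params(labelsize=6)
    fig.tight_layout()

    with open(_sidecar(Path(out_path), ".csv"), "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["threshold", "max_size", "n_communities", "sizes",
                    "mean_silhouette", "n_unclustered"])
        for (thr, size), cell in sorted(result.cells.items()):
            w.writerow([thr, size, cell.n_communities,
                        "/".join(map(str, cell.sizes)),
                        "" if cell.mean_silhouette is None else repr(cell.mean_silhouette),
                        cell.n_unclustered])
    return _save(fig, out_path)
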