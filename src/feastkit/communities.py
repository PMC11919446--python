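"""Size-capped community detection, meta-communities, and diagnostics.

Communities of related terms are found by greedy (CNM) weighted modularity
maximization on the thresholded overlap network, then attenuated so that no
community exceeds a user-chosen maximum size: each oversized community's
induced subgraph is re-partitioned after raising its local edge threshold in
+0.05 steps, recursively, with a degree-ordered chunking fallback once the
local threshold reaches 1.0.  Communities are afterwards agglomerated into
meta-communities wherever weaker residual overlap remains between terms of
different communities, or where strong cross-database overlap was suppressed
because multi-database agglomeration is off.

Diagnostics: per-term silhouette widths on 1 - overlap distances, and a grid
search over (threshold, max community size) parameter pairs.
"""

from __future__ import annotations

import logging
from collections.abc import Collection, Sequence

import networkx as nx
import pandas as pd

from .models import (
    Community,
    GridCell,
    GridSearchResult,
    MetaCommunity,
    OverlapNetwork,
    SilhouetteResult,
    Term,
    TermKey,
)
from .overlap import build_term_network, pairwise_overlap_matrix

log = logging.getLogger(__name__)

_CAP_STEP = 0.05
_EPS = 1e-9


def _greedy_graph_partition(g: nx.Graph) -> list[set]:
    """Greedy weighted modularity partition; singletons for edgeless graphs."""
    if g.number_of_nodes() == 0:
        return []
    if g.number_of_edges() == 0:
        return [{n} for n in sorted(g.nodes)]
    comms = nx.community.greedy_modularity_communities(g, weight="weight", resolution=1.0)
    return sorted((set(c) for c in comms), key=lambda c: sorted(c)[0])


def greedy_modularity_partition(network: OverlapNetwork, seed: int = 0) -> list[set[TermKey]]:
    """Partition the network's nodes by greedy modularity maximization.

    Deterministic: node iteration order is lexicographic and the CNM
    agglomeration has no random tie-breaks in this implementation; ``seed``
    is accepted for interface stability only.
    """
    return _greedy_graph_partition(network.graph)


def _threshold_subgraph(g: nx.Graph, nodes: Collection[TermKey], thr: float) -> nx.Graph:
    h = nx.Graph()
    h.add_nodes_from(sorted(nodes))
    for u, v, d in g.subgraph(nodes).edges(data=True):
        if d["weight"] >= thr - _EPS:
            h.add_edge(u, v, weight=d["weight"])
    return h


def _split_part(g: nx.Graph, part: set[TermKey], max_size: int, local_thr: float) -> list[set[TermKey]]:
    if len(part) <= max_size:
        return [set(part)]
    thr = local_thr
    while thr < 1.0 - _EPS:
        thr = round(thr + _CAP_STEP, 10)
        sub = _threshold_subgraph(g, part, thr)
        parts = _greedy_graph_partition(sub)
        if len(parts) > 1:
            out: list[set[TermKey]] = []
            for p in parts:
                out.extend(_split_part(g, p, max_size, thr))
            return out
    # Fully saturated threshold and still one block: chunk by descending
    # within-part weighted degree, ties broken lexicographically.
    sub = g.subgraph(part)
    deg = dict(sub.degree(weight="weight"))
    order = sorted(part, key=lambda n: (-deg.get(n, 0.0), n))
    return [set(order[i:i + max_size]) for i in range(0, len(order), max_size)]


def cap_community_sizes(
    network: OverlapNetwork,
    partition: Sequence[set[TermKey]],
    max_size: int,
    threshold: float | None = None,
) -> list[set[TermKey]]:
    """Enforce the maximum community size on a partition.

    Oversized parts are recursively re-partitioned at progressively higher
    local edge thresholds; parts already within the cap pass through
    unchanged.
    """
    if max_size < 2:
        raise ValueError("max_size must be >= 2")
    base = network.threshold if threshold is None else threshold
    out: list[set[TermKey]] = []
    for part in partition:
        out.extend(_split_part(network.graph, set(part), max_size, base))
    return sorted(out, key=lambda p: sorted(p)[0])


def detect_communities(
    network: OverlapNetwork,
    max_size: int,
    seed: int = 0,
) -> tuple[list[Community], set[TermKey]]:
    """Full detection: greedy partition, size capping, community assembly.

    Parts with >=2 members become :class:`Community` objects; singleton
    parts are returned as unclustered terms.  Community IDs are assigned by
    descending size, then by lexicographically smallest member, so that the
    labelling is deterministic.
    """
    partition = greedy_modularity_partition(network, seed=seed)
    capped = cap_community_sizes(network, partition, max_size)
    multi = [p for p in capped if len(p) >= 2]
    unclustered = {n for p in capped if len(p) == 1 for n in p}
    multi.sort(key=lambda p: (-len(p), sorted(p)[0]))
    communities = []
    for i, part in enumerate(multi, start=1):
        goi: set[str] = set()
        for key in part:
            goi |= network.goi_set(key)
        communities.append(
            Community(community_id=f"C{i:03d}", members=frozenset(part),
                      goi_union=frozenset(goi))
        )
    return communities, unclustered


def form_meta_communities(
    communities: Collection[Community],
    overlap_matrix: pd.DataFrame,
    weak_threshold: float,
    threshold: float,
    cross_db_strong_links: dict[frozenset[TermKey], float] | None = None,
) -> list[MetaCommunity]:
    """Group communities linked by residual or cross-database overlap.

    Two communities are linked when (a) some cross-community term pair has
    overlap in ``[weak_threshold, threshold)``, or (b) some cross-community
    term pair is a recorded cross-database strong link (overlap >= threshold
    while multi-database agglomeration was off).  Meta-communities are the
    connected components of size >= 2 of this community-level graph.
    """
    if not weak_threshold < threshold:
        raise ValueError("weak_threshold must be < threshold")
    cross_db_strong_links = cross_db_strong_links or {}
    comms = sorted(communities, key=lambda c: c.community_id)
    g = nx.Graph()
    g.add_nodes_from(c.community_id for c in comms)
    for i, a in enumerate(comms):
        for b in comms[i + 1:]:
            if _communities_linked(a, b, overlap_matrix, weak_threshold,
                                   threshold, cross_db_strong_links):
                g.add_edge(a.community_id, b.community_id)
    groups = [sorted(cc) for cc in nx.connected_components(g) if len(cc) >= 2]
    groups.sort(key=lambda cc: (-len(cc), cc[0]))
    return [
        MetaCommunity(meta_id=f"M{i:03d}", member_communities=frozenset(cc))
        for i, cc in enumerate(groups, start=1)
    ]


def _communities_linked(
    a: Community,
    b: Community,
    matrix: pd.DataFrame,
    weak: float,
    strong: float,
    cross_links: dict[frozenset[TermKey], float],
) -> bool:
    pos = {key: i for i, key in enumerate(matrix.index)}
    vals = matrix.to_numpy()
    for ka in a.members:
        for kb in b.members:
            w = float(vals[pos[ka], pos[kb]])
            if weak - _EPS <= w < strong - _EPS:
                return True
            if frozenset((ka, kb)) in cross_links:
                return True
    return False


def compute_silhouettes(
    terms: Collection[Term],
    communities: Collection[Community],
    metric: str = "OC",
) -> SilhouetteResult | None:
    """Silhouette widths of clustered terms on d = 1 - overlap.

    For term i: a(i) is the mean distance to the other members of its own
    community, b(i) the smallest mean distance to any other community, and
    s(i) = (b - a) / max(a, b).  Unclustered terms are excluded.  Returns
    ``None`` (with a warning) when fewer than two communities exist, since
    b(i) is then undefined.
    """
    comms = sorted(communities, key=lambda c: c.community_id)
    if len(comms) < 2:
        log.warning("silhouette diagnostic skipped: fewer than 2 communities")
        return None
    matrix = pairwise_overlap_matrix(terms, metric)
    dist = 1.0 - matrix.to_numpy()
    pos = {key: i for i, key in enumerate(matrix.index)}
    community_of = {k: c.community_id for c in comms for k in c.members}
    members = {c.community_id: sorted(c.members) for c in comms}
    values: dict[TermKey, float] = {}
    for c in comms:
        for k in sorted(c.members):
            own = [pos[kk] for kk in members[c.community_id] if kk != k]
            a = float(dist[pos[k], own].mean())
            b = min(
                float(dist[pos[k], [pos[kk] for kk in members[other.community_id]]].mean())
                for other in comms
                if other.community_id != c.community_id
            )
            denom = max(a, b)
            values[k] = 0.0 if denom == 0 else (b - a) / denom
    community_means = {
        cid: sum(values[k] for k in ms) / len(ms) for cid, ms in members.items()
    }
    overall = sum(values.values()) / len(values)
    return SilhouetteResult(values=values, community_of=community_of,
                            community_means=community_means, overall_mean=overall)


def grid_search_communities(
    terms: Collection[Term],
    grid_thresholds: Sequence[float],
    grid_max_sizes: Sequence[int],
    metric: str = "OC",
    seed: int = 0,
    multi_db_agglomeration: bool = False,
) -> GridSearchResult:
    """Run the detection pipeline over a (threshold, max_size) grid."""
    if not grid_thresholds or not grid_max_sizes:
        raise ValueError("parameter lists must be non-empty")
    cells: dict[tuple[float, int], GridCell] = {}
    for thr in grid_thresholds:
        network = build_term_network(terms, metric=metric, threshold=thr,
                                     multi_db_agglomeration=multi_db_agglomeration)
        for size in grid_max_sizes:
            communities, unclustered = detect_communities(network, size, seed=seed)
            sil = compute_silhouettes(terms, communities, metric) if len(communities) >= 2 else None
            cells[(thr, size)] = GridCell(
                threshold=thr,
                max_size=size,
                n_communities=len(communities),
                sizes=tuple(sorted((len(c.members) for c in communities), reverse=True)),
                mean_silhouette=None if sil is None else sil.overall_mean,
                n_unclustered=len(unclustered),
            )
    return GridSearchResult(cells=cells)
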