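"""Pairwise gene-set overlap and the thresholded term network.

Two overlap metrics are supported: the overlap coefficient
``OC = |X n Y| / min(|X|, |Y|)`` and the Jaccard index
``JI = |X n Y| / |X u Y|``.  Terms become nodes of a network with an edge
between every pair whose overlap reaches a user-defined threshold
(inclusive); communities are then detected on this network.
"""

from __future__ import annotations

from collections.abc import Collection, Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .models import OverlapNetwork, Term, TermKey

METRICS = ("OC", "JI")


def overlap_coefficient(x: Iterable[str], y: Iterable[str]) -> float:
    """|X n Y| / min(|X|, |Y|).  Equals 1 iff one set contains the other."""
    xs, ys = set(x), set(y)
    if not xs or not ys:
        raise ValueError("overlap coefficient is undefined for empty sets")
    return len(xs & ys) / min(len(xs), len(ys))


def jaccard_index(x: Iterable[str], y: Iterable[str]) -> float:
    """|X n Y| / |X u Y|.  Equals 1 iff the sets are identical."""
    xs, ys = set(x), set(y)
    if not xs or not ys:
        raise ValueError("Jaccard index is undefined for empty sets")
    return len(xs & ys) / len(xs | ys)


def _metric_fn(metric: str):
    if metric == "OC":
        return overlap_coefficient
    if metric == "JI":
        return jaccard_index
    raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")


def pairwise_overlap_matrix(terms: Collection[Term], metric: str = "OC") -> pd.DataFrame:
    """Symmetric unit-diagonal overlap matrix over all term pairs.

    Rows/columns are indexed by ``(database, term_id)`` keys in sorted order.
    """
    fn = _metric_fn(metric)
    ordered = sorted(terms, key=lambda t: t.key)
    keys = [t.key for t in ordered]
    n = len(ordered)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            w = fn(ordered[i].goi_set, ordered[j].goi_set)
            mat[i, j] = mat[j, i] = w
    return pd.DataFrame(mat, index=keys, columns=keys)


def build_term_network(
    terms: Collection[Term],
    metric: str = "OC",
    threshold: float = 0.5,
    multi_db_agglomeration: bool = False,
) -> OverlapNetwork:
    """Build the thresholded overlap network of enriched terms.

    The threshold comparison is inclusive (>=).  With multi-database
    agglomeration off, pairs of terms from different source databases never
    become edges; when such a pair still reaches the threshold it is recorded
    as a cross-database strong link, later used to join the terms'
    communities into a meta-community.
    """
    if not terms:
        raise ValueError("need at least one term")
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    fn = _metric_fn(metric)
    ordered = sorted(terms, key=lambda t: t.key)
    g = nx.Graph()
    for t in ordered:
        g.add_node(t.key, goi=frozenset(t.goi_set), padj=t.padj, score=t.score,
                   description=t.description)
    cross: dict[frozenset[TermKey], float] = {}
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            w = fn(a.goi_set, b.goi_set)
            if w < threshold:
                continue
            if a.database != b.database and not multi_db_agglomeration:
                cross[frozenset((a.key, b.key))] = w
            else:
                g.add_edge(a.key, b.key, weight=w)
    return OverlapNetwork(graph=g, metric=metric, threshold=threshold,
                          cross_db_strong_links=cross)
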