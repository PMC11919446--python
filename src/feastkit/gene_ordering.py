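"""Gene orderings for the split heatmap's shared x-axis.

Three strategies:

* ``cluster`` — leaf order of an average-linkage dendrogram on the genes'
  per-experiment quantitative vectors (Euclidean distance; values missing
  because a gene is not GoI in an experiment are imputed as 0 for the
  distance computation only).
* ``annotation`` — genes sorted by descending annotation count, then by
  their binary annotation pattern, then clustered within each identical
  pattern block; this surfaces gene subsets that drive several enrichments
  at once.
* ``alphabetical`` — case-insensitive lexicographic, for easy lookup.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist


@dataclass(frozen=True)
class GeneOrdering:
    ordered_genes: tuple[str, ...]
    strategy: str


def _quant_matrix(genes: Sequence[str], quant: pd.DataFrame) -> np.ndarray:
    """Genes x experiments value matrix with missing values imputed as 0."""
    sub = quant.reindex(index=list(genes))
    return np.nan_to_num(sub.to_numpy(dtype=float), nan=0.0)


def order_by_clustering(genes: Sequence[str], quant: pd.DataFrame) -> GeneOrdering:
    """Dendrogram leaf order (average linkage, Euclidean distances).

    ``quant`` is a genes x experiments DataFrame; genes absent from an
    experiment carry NaN there.  Genes missing from ``quant`` entirely are
    treated as all-zero vectors.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("need at least one gene")
    if len(genes) == 1:
        return GeneOrdering(ordered_genes=(genes[0],), strategy="cluster")
    ordered_in = sorted(genes)  # input-order independence
    mat = _quant_matrix(ordered_in, quant)
    z = linkage(pdist(mat, metric="euclidean"), method="average")
    order = [ordered_in[i] for i in leaves_list(z)]
    return GeneOrdering(ordered_genes=tuple(order), strategy="cluster")


def order_by_annotation(annot: pd.DataFrame, quant: pd.DataFrame) -> GeneOrdering:
    """Annotation-count / annotation-pattern / local-clustering order.

    ``annot`` is a binary terms x genes matrix whose row order fixes the
    pattern encoding.  Genes are sorted by (1) descending annotation count,
    (2) the annotation pattern read as a binary string over the fixed row
    order, descending, and (3) the clustering leaf order within each block
    of identical patterns.
    """
    genes = list(annot.columns)
    counts = annot.sum(axis=0)
    patterns = {
        g: "".join("1" if annot.loc[t, g] else "0" for t in annot.index)
        for g in genes
    }
    blocks: dict[tuple[int, str], list[str]] = {}
    for g in genes:
        blocks.setdefault((int(counts[g]), patterns[g]), []).append(g)
    ordered: list[str] = []
    # count descending, then pattern descending lexicographically
    for count, pattern in sorted(blocks, key=lambda kp: (-kp[0], [1 - int(c) for c in kp[1]])):
        block = blocks[(count, pattern)]
        ordered.extend(order_by_clustering(block, quant).ordered_genes)
    return GeneOrdering(ordered_genes=tuple(ordered), strategy="annotation")


def order_alphabetical(genes: Iterable[str]) -> GeneOrdering:
    """Case-insensitive ascending; case variants tie-broken case-sensitively."""
    ordered = sorted(genes, key=lambda g: (g.casefold(), g))
    return GeneOrdering(ordered_genes=tuple(ordered), strategy="alphabetical")
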