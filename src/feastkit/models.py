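"""Core domain model.

The central objects are enriched *terms* (GO terms, KEGG pathways, gene
signatures...) restricted to the experiment's genes of interest (GoI), the
per-experiment quantitative data those genes carry (e.g. log2 fold changes),
and the communities / meta-communities of terms found by gene-set-overlap
clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx

#: Node key used everywhere a term must be addressed uniquely.
TermKey = tuple[str, str]  # (database, term_id)


class ConfigError(ValueError):
    """A configuration file or dialect map is unusable."""


class InputError(ValueError):
    """An input file violates its format contract."""


@dataclass(frozen=True)
class Term:
    """One enriched term with its gene set restricted to genes of interest.

    ``goi_set`` holds the term's annotated genes intersected with the GoI
    universe; ``padj``/``score`` carry the upstream FEA statistics when the
    input table supplied them.
    """

    term_id: str
    description: str
    database: str
    goi_set: frozenset[str]
    padj: Optional[float] = None
    score: Optional[float] = None

    @property
    def key(self) -> TermKey:
        return (self.database, self.term_id)

    @property
    def label(self) -> str:
        return f"{self.database}:{self.term_id}"


@dataclass
class ExperimentQuant:
    """Gene-level quantitative data for one experiment.

    ``membership`` is the experiment's GoI set (e.g. its DE genes); a gene
    outside membership has no value and renders grey in heatmaps.
    """

    experiment_id: str
    values: dict[str, float] = field(default_factory=dict)
    membership: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        missing = set(self.values) - self.membership
        if missing:
            raise ValueError(
                f"experiment {self.experiment_id!r}: values present for genes "
                f"outside membership: {sorted(missing)[:5]}"
            )


@dataclass
class FEAResult:
    """One study's functional enrichment analysis result."""

    fea_id: str
    terms: list[Term]
    experiments: list[ExperimentQuant]

    @property
    def goi_union(self) -> set[str]:
        out: set[str] = set()
        for exp in self.experiments:
            out |= exp.membership
        return out

    def term_keys(self) -> set[TermKey]:
        return {t.key for t in self.terms}

    def validate(self) -> None:
        goi = self.goi_union
        for t in self.terms:
            if not t.goi_set <= goi:
                raise ValueError(
                    f"term {t.label} has genes outside the GoI union: "
                    f"{sorted(t.goi_set - goi)[:5]}"
                )
        keys = [t.key for t in self.terms]
        if len(keys) != len(set(keys)):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise InputError(f"duplicate (database, term_id) pairs: {dupes}")


@dataclass(frozen=True)
class ExtraAnnotation:
    """A user-supplied a-priori gene set shown as an extra heatmap row."""

    label: str
    genes: frozenset[str]


@dataclass
class RunConfig:
    """Algorithm parameters for a summarization run.

    Defaults follow the common enrichment-map conventions: overlap
    coefficient at threshold 0.5, weak residual band starting at
    threshold/2, communities capped at 15 terms.
    """

    metric: str = "OC"  # {"OC", "JI"}
    threshold: float = 0.5
    weak_threshold: Optional[float] = None  # default: threshold / 2
    max_community_size: int = 15
    multi_db_agglomeration: bool = False
    ordering: str = "annotation"  # {"cluster", "annotation", "alphabetical"}
    search_terms: list[str] = field(default_factory=list)
    output_dir: Path = Path("feastkit_out")
    grid_thresholds: list[float] = field(default_factory=lambda: [0.3, 0.5, 0.7])
    grid_max_sizes: list[int] = field(default_factory=lambda: [10, 15])

    def __post_init__(self) -> None:
        if self.metric not in ("OC", "JI"):
            raise ConfigError(f"metric must be 'OC' or 'JI', got {self.metric!r}")
        if not 0.0 < self.threshold <= 1.0:
            raise ConfigError("threshold must lie in (0, 1]")
        if self.weak_threshold is None:
            self.weak_threshold = self.threshold / 2.0
        if not 0.0 < self.weak_threshold < self.threshold:
            raise ConfigError("weak_threshold must lie in (0, threshold)")
        if self.max_community_size < 2:
            raise ConfigError("max_community_size must be >= 2")
        if self.ordering not in ("cluster", "annotation", "alphabetical"):
            raise ConfigError(f"unknown ordering {self.ordering!r}")
        self.output_dir = Path(self.output_dir)


@dataclass
class OverlapNetwork:
    """Thresholded term-overlap network.

    Nodes are ``(database, term_id)`` keys carrying the term's GoI-restricted
    gene set; edges exist only for pairs whose overlap is >= threshold.
    When multi-database agglomeration is off, qualifying cross-database pairs
    are *not* edges but are recorded in ``cross_db_strong_links`` for
    meta-community formation.
    """

    graph: nx.Graph
    metric: str
    threshold: float
    cross_db_strong_links: dict[frozenset[TermKey], float] = field(default_factory=dict)

    @property
    def nodes(self) -> list[TermKey]:
        return sorted(self.graph.nodes)

    def goi_set(self, key: TermKey) -> frozenset[str]:
        return self.graph.nodes[key]["goi"]


@dataclass
class Community:
    """A group of >=2 terms with strong mutual gene-set overlap."""

    community_id: str
    members: frozenset[TermKey]
    goi_union: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a community needs at least 2 member terms")


@dataclass
class MetaCommunity:
    """Communities connected by weak residual or cross-database overlap."""

    meta_id: str
    member_communities: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.member_communities) < 2:
            raise ValueError("a meta-community needs at least 2 communities")


@dataclass
class SilhouetteResult:
    """Per-term silhouette widths on 1 - overlap distances."""

    values: dict[TermKey, float]
    community_of: dict[TermKey, str]
    community_means: dict[str, float]
    overall_mean: float


@dataclass(frozen=True)
class GridCell:
    threshold: float
    max_size: int
    n_communities: int
    sizes: tuple[int, ...]
    mean_silhouette: Optional[float]
    n_unclustered: int


@dataclass
class GridSearchResult:
    """Community-detection diagnostics over a parameter grid."""

    cells: dict[tuple[float, int], GridCell]
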