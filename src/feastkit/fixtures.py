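"""Synthetic FEA inputs with planted community structure.

The generator emulates the data an upstream over-representation or GSEA
pipeline would hand to the summarizer: enriched terms in blocks that share
a gene core (so terms of one block overlap strongly), a small spill-over
gene pool shared across blocks (so cross-block overlap is weak but
nonzero), and per-experiment log2-fold-change-like values drawn around a
block-consistent signed effect size.  Overlap targets are controlled in
expectation, not exactly; tests use tolerance bands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .models import ExperimentQuant, FEAResult, Term, TermKey


@dataclass(frozen=True)
class PlantedDesign:
    """Parameters of one synthetic FEA with planted term communities."""

    n_blocks: int = 4
    terms_per_block: int = 6
    genes_per_block: int = 30
    within_overlap_target: float = 0.8
    between_overlap_target: float = 0.1
    n_experiments: int = 2
    effect_size: float = 2.0  # mean |log2FC| for GoI
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.within_overlap_target <= self.between_overlap_target:
            raise ValueError("within-overlap target must exceed between-overlap target")
        for name in ("n_blocks", "terms_per_block", "genes_per_block", "n_experiments"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def _block_layout(design: PlantedDesign) -> tuple[int, int, int, int]:
    """Per-term composition: (core, spill draws, unique fill, spill pool size).

    Each term carries ``genes_per_block`` genes: a block-wide core shared by
    all the block's terms, ``m`` draws from a global spill pool (expected
    pairwise collision m^2/S gives the weak cross-block overlap), and
    term-unique filler.  The core is shrunk by the expected spill collision
    so the within-block overlap still lands on its target.
    """
    n = design.genes_per_block
    spill_pool = max(2, round(0.4 * n))
    want_cross = design.between_overlap_target * n  # expected cross intersection
    m = min(n - 1, round(math.sqrt(max(want_cross, 0.0) * spill_pool)))
    core = round(design.within_overlap_target * n - (m * m) / spill_pool)
    core = max(1, min(core, n - m))
    unique = n - core - m
    return core, m, unique, spill_pool


def generate_fea(
    design: PlantedDesign, fea_id: str = "FEA1"
) -> tuple[FEAResult, dict[TermKey, int]]:
    """Generate one synthetic FEAResult plus planted block labels.

    Deterministic given ``design.seed``.  Returns the FEAResult and a map
    from term key to its planted block index.
    """
    rng = np.random.default_rng(design.seed)
    core_n, m, unique_n, spill_n = _block_layout(design)
    spill_pool = [f"SP{j:04d}" for j in range(spill_n)]
    terms: list[Term] = []
    labels: dict[TermKey, int] = {}
    for b in range(design.n_blocks):
        core = [f"B{b:02d}C{j:04d}" for j in range(core_n)]
        for t in range(design.terms_per_block):
            unique = [f"B{b:02d}T{t:02d}U{j:04d}" for j in range(unique_n)]
            spill = list(rng.choice(spill_pool, size=m, replace=False)) if m else []
            genes = frozenset(core + unique + spill)
            term = Term(
                term_id=f"T{b:02d}{t:02d}",
                description=f"planted block {b} term {t}",
                database="GO",
                goi_set=genes,
                padj=float(10.0 ** -rng.uniform(4, 12)),
                score=float(rng.normal(0, 1)),
            )
            terms.append(term)
            labels[term.key] = b
    universe = sorted(set().union(*(t.goi_set for t in terms)))
    block_sign = {b: 1.0 if b % 2 == 0 else -1.0 for b in range(design.n_blocks)}
    gene_block = {}
    for g in universe:
        gene_block[g] = int(g[1:3]) if g.startswith("B") else None

    experiments = []
    for e in range(design.n_experiments):
        # each experiment recovers ~90% of the GoI universe, so some genes
        # render grey (not GoI) in the other experiment's heatmap row
        member_mask = rng.random(len(universe)) < 0.9
        if e == 0:
            member_mask[:] = True  # the union must cover every annotated gene
        values = {}
        for g, keep in zip(universe, member_mask):
            if not keep:
                continue
            b = gene_block[g]
            mean = block_sign[b] * design.effect_size if b is not None else 0.0
            values[g] = float(rng.normal(mean, design.noise_sd))
        experiments.append(
            ExperimentQuant(experiment_id=f"{fea_id}_E{e + 1}", values=values,
                            membership=set(values))
        )
    fea = FEAResult(fea_id=fea_id, terms=terms, experiments=experiments)
    fea.validate()
    return fea, labels


def generate_multi_fea(
    design: PlantedDesign,
    fea_ids: list[str],
    block_membership: list[list[str]] | None = None,
) -> tuple[list[FEAResult], dict[frozenset[str], set[TermKey]]]:
    """Generate several FEAs with shared and unique planted blocks.

    ``block_membership[b]`` lists the FEA ids containing block ``b``
    (default: every block in every FEA).  A block present in two or more
    FEAs emits identical terms in each, so its terms form a term-set
    intersection with exactly that signature.  Returns the FEAResults and
    the expected {signature: term keys} map (signatures of size >= 2 only).
    """
    if len(fea_ids) < 2:
        raise ValueError("need at least two FEA ids")
    if block_membership is None:
        block_membership = [list(fea_ids) for _ in range(design.n_blocks)]
    if len(block_membership) != design.n_blocks:
        raise ValueError("block_membership must name every block")

    base, labels = generate_fea(design, fea_id="BASE")
    by_block: dict[int, list[Term]] = {}
    for t in base.terms:
        by_block.setdefault(labels[t.key], []).append(t)

    results = []
    for i, fea_id in enumerate(fea_ids):
        blocks = [b for b in range(design.n_blocks) if fea_id in block_membership[b]]
        terms = [t for b in blocks for t in by_block[b]]
        sub_design = PlantedDesign(
            n_blocks=design.n_blocks, terms_per_block=design.terms_per_block,
            genes_per_block=design.genes_per_block,
            within_overlap_target=design.within_overlap_target,
            between_overlap_target=design.between_overlap_target,
            n_experiments=design.n_experiments, effect_size=design.effect_size,
            noise_sd=design.noise_sd, seed=design.seed + 1 + i,
        )
        rng = np.random.default_rng(sub_design.seed)
        universe = sorted(set().union(*(t.goi_set for t in terms))) if terms else []
        experiments = []
        for e in range(design.n_experiments):
            values = {
                g: float(rng.normal(0.0 if not g.startswith("B")
                                    else (design.effect_size if int(g[1:3]) % 2 == 0
                                          else -design.effect_size),
                                    design.noise_sd))
                for g in universe
            }
            experiments.append(
                ExperimentQuant(experiment_id=f"{fea_id}_E{e + 1}",
                                values=values, membership=set(values))
            )
        fea = FEAResult(fea_id=fea_id, terms=terms, experiments=experiments)
        fea.validate()
        results.append(fea)

    expected: dict[frozenset[str], set[TermKey]] = {}
    for b in range(design.n_blocks):
        sig = frozenset(block_membership[b])
        if len(sig) >= 2:
            expected.setdefault(sig, set()).update(t.key for t in by_block[b])
    return results, expected


def write_input_dir(
    design: PlantedDesign, out_dir: str | Path, fea_id: str = "FEA1"
) -> Path:
    """Write a ready-to-run input directory (FEA table, quant tables, config).

    Round-trips through the text formats the readers accept, so the written
    directory exercises the full parsing path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fea, _ = generate_fea(design, fea_id=fea_id)
    fea_path = out_dir / f"{fea_id}_terms.csv"
    with open(fea_path, "w", encoding="utf-8") as fh:
        fh.write("ID,Description,p.adjust,geneID\n")
        for t in sorted(fea.terms, key=lambda t: t.key):
            fh.write(f"{t.term_id},{t.description},{t.padj},{'/'.join(sorted(t.goi_set))}\n")
    quant_entries = []
    for exp in fea.experiments:
        qpath = out_dir / f"{exp.experiment_id}_quant.csv"
        with open(qpath, "w", encoding="utf-8") as fh:
            fh.write("gene,value\n")
            for g in sorted(exp.values):
                fh.write(f"{g},{exp.values[g]!r}\n")
        quant_entries.append(
            f"  - {{fea_id: {fea_id}, experiment_id: {exp.experiment_id}, "
            f"path: {qpath.name}}}"
        )
    config = out_dir / "config.yaml"
    with open(config, "w", encoding="utf-8") as fh:
        fh.write(
            "fea_tables:\n"
            f"  - {{id: {fea_id}, path: {fea_path.name}, database: GO}}\n"
            "quant_tables:\n" + "\n".join(quant_entries) + "\n"
            "metric: OC\n"
            "threshold: 0.5\n"
            "max_community_size: 15\n"
            "ordering: annotation\n"
            "output_dir: report\n"
        )
    return config
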