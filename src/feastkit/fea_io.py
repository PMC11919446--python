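"""Input parsing, CSV side-outputs, and run configuration.

Readers accept the delimited-text dialect produced by common ORA/GSEA
tooling (one row per enriched term, gene lists joined with "/"), standard
GMT gene-set files, two-column gene/value quantitative tables, and
one-gene-per-line extra-annotation lists.  A dialect map makes other column
names usable without code changes; gene identifiers are opaque,
case-sensitive strings (identifier mapping is upstream's job).
"""

from __future__ import annotations

import csv
import logging
from collections.abc import Collection, Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .models import (
    Community,
    ConfigError,
    ExperimentQuant,
    ExtraAnnotation,
    FEAResult,
    InputError,
    MetaCommunity,
    RunConfig,
    Term,
)

log = logging.getLogger(__name__)

#: Default column-name map, mirroring the common ORA/GSEA output convention.
DEFAULT_DIALECT: dict[str, str] = {
    "term_id": "ID",
    "description": "Description",
    "padj": "p.adjust",
    "genes": "geneID",
}
#: Optional dialect keys: "database" (per-row source tag), "score" (e.g. NES).

_CONFIG_DEFAULTS = {
    "metric": "OC",
    "threshold": 0.5,
    "weak_threshold": None,
    "max_community_size": 15,
    "multi_db_agglomeration": False,
    "ordering": "annotation",
    "search_terms": [],
    "output_dir": "feastkit_out",
    "grid_thresholds": [0.3, 0.5, 0.7],
    "grid_max_sizes": [10, 15],
}


def parse_fea_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    sep: str = ",",
    gene_delimiter: str = "/",
    default_database: str = "DB",
) -> list[Term]:
    """Read one FEA result table into pre-restriction Terms.

    Each row yields a Term whose ``goi_set`` holds the row's full gene list
    (split on ``gene_delimiter``, trimmed, de-duplicated); restriction to the
    GoI universe happens later in :func:`restrict_terms_to_goi`.  Rows with
    unparsable adjusted p-values keep ``padj`` unset.
    """
    path = Path(path)
    d = dict(DEFAULT_DIALECT, **(dialect or {}))
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for role in ("term_id", "description", "padj", "genes"):
        if d[role] not in df.columns:
            raise ConfigError(
                f"{path.name}: required column {d[role]!r} (role {role!r}) not found; "
                f"available: {list(df.columns)}"
            )
    terms: list[Term] = []
    for _, row in df.iterrows():
        genes = frozenset(
            g.strip() for g in str(row[d["genes"]]).split(gene_delimiter) if g.strip()
        )
        padj = _parse_float(row[d["padj"]])
        score = None
        if "score" in d and d["score"] in df.columns:
            score = _parse_float(row[d["score"]])
        database = (
            str(row[d["database"]])
            if "database" in d and d["database"] in df.columns
            else default_database
        )
        terms.append(
            Term(term_id=str(row[d["term_id"]]), description=str(row[d["description"]]),
                 database=database, goi_set=genes, padj=padj, score=score)
        )
    keys = [t.key for t in terms]
    if len(keys) != len(set(keys)):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise InputError(f"{path.name}: duplicate (database, term_id) pairs: {dupes}")
    if not terms:
        log.warning("%s: no rows after header", path.name)
    return terms


def _parse_float(raw: object) -> float | None:
    try:
        v = float(str(raw))
    except (TypeError, ValueError):
        return None
    return v


def parse_gmt(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    """Read a GMT file into {set name: (description, gene set)}."""
    path = Path(path)
    out: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"{path.name}:{lineno}: GMT line has <3 fields")
            name, desc = fields[0], fields[1]
            if name in out:
                raise InputError(f"{path.name}:{lineno}: duplicate set name {name!r}")
            out[name] = (desc, frozenset(g.strip() for g in fields[2:] if g.strip()))
    return out


def parse_quant_table(
    path: str | Path, experiment_id: str, sep: str = ","
) -> ExperimentQuant:
    """Read a two-column (gene, value) table into an ExperimentQuant."""
    path = Path(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise InputError(f"{path.name}: expected two columns (gene, value)")
    genes_col, values_col = df.columns[0], df.columns[1]
    values: dict[str, float] = {}
    for i, row in df.iterrows():
        gene = str(row[genes_col]).strip()
        if gene in values:
            raise InputError(f"{path.name}: duplicate gene {gene!r}")
        try:
            values[gene] = float(row[values_col])
        except ValueError:
            raise InputError(
                f"{path.name}: non-numeric value {row[values_col]!r} at row {i + 2}"
            ) from None
    if not values:
        log.warning("%s: empty quantitative table", path.name)
    return ExperimentQuant(experiment_id=experiment_id, values=values,
                           membership=set(values))


def parse_extra_annotation(path: str | Path, label: str) -> ExtraAnnotation:
    """Read a one-gene-per-line list into an ExtraAnnotation."""
    genes = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            g = line.strip()
            if g:
                genes.add(g)
    return ExtraAnnotation(label=label, genes=frozenset(genes))


def restrict_terms_to_goi(terms: Iterable[Term], goi_union: Collection[str]) -> list[Term]:
    """Reduce each term's gene set to the genes of interest.

    Terms whose restricted set is empty are dropped with a warning.
    Idempotent: restricting twice equals restricting once.
    """
    goi = set(goi_union)
    if not goi:
        raise ValueError("GoI universe is empty")
    out: list[Term] = []
    for t in terms:
        reduced = t.goi_set & goi
        if not reduced:
            log.warning("term %s dropped: no genes of interest", t.label)
            continue
        out.append(Term(term_id=t.term_id, description=t.description,
                        database=t.database, goi_set=frozenset(reduced),
                        padj=t.padj, score=t.score))
    return out


def apply_gmt(terms: Iterable[Term], gmt: Mapping[str, tuple[str, frozenset[str]]]) -> list[Term]:
    """Replace in-row gene lists with authoritative GMT annotations.

    When a term appears in the GMT its gene set (and empty description) is
    taken from there; in-row lists are ignored with a warning.  Terms absent
    from the GMT keep their in-row lists.
    """
    out = []
    replaced = 0
    for t in terms:
        if t.term_id in gmt:
            desc, genes = gmt[t.term_id]
            out.append(Term(term_id=t.term_id, description=t.description or desc,
                            database=t.database, goi_set=genes,
                            padj=t.padj, score=t.score))
            replaced += 1
        else:
            out.append(t)
    if replaced:
        log.warning("GMT is authoritative: replaced gene lists of %d terms", replaced)
    return out


# ---------------------------------------------------------------------------
# CSV side-outputs

TERM_COMMUNITY_CSV = "term_communities.csv"
TERM_GOI_CSV = "term_goi.csv"
EXPERIMENT_GOI_CSV = "experiment_goi.csv"


def write_csv_outputs(
    communities: Collection[Community],
    meta_communities: Collection[MetaCommunity],
    terms: Collection[Term],
    fea_results: Collection[FEAResult],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the three machine-readable CSV outputs.

    1. term-community membership (term_id, database, community_id,
       meta_community_id; empty fields when unassigned),
    2. term-GoI pairs, and
    3. experiment-GoI values.
    Rows are sorted lexicographically by all columns for determinism.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    community_of = {k: c.community_id for c in communities for k in c.members}
    meta_of = {cid: m.meta_id for m in meta_communities for cid in m.member_communities}

    membership_rows = sorted(
        (t.term_id, t.database,
         community_of.get(t.key, ""),
         meta_of.get(community_of.get(t.key, ""), ""))
        for t in terms
    )
    term_goi_rows = sorted(
        (t.term_id, t.database, g) for t in terms for g in t.goi_set
    )
    exp_rows = sorted(
        (fea.fea_id, exp.experiment_id, g, repr(v))
        for fea in fea_results
        for exp in fea.experiments
        for g, v in exp.values.items()
    )

    paths = {}
    paths["term_communities"] = _write_csv(
        out_dir / TERM_COMMUNITY_CSV,
        ["term_id", "database", "community_id", "meta_community_id"],
        membership_rows,
    )
    paths["term_goi"] = _write_csv(
        out_dir / TERM_GOI_CSV, ["term_id", "database", "gene"], term_goi_rows
    )
    paths["experiment_goi"] = _write_csv(
        out_dir / EXPERIMENT_GOI_CSV,
        ["fea_id", "experiment_id", "gene", "value"],
        exp_rows,
    )
    return paths


def _write_csv(path: Path, header: list[str], rows: Iterable[tuple]) -> Path:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        w.writerows(rows)
    return path


def read_term_community_csv(path: str | Path) -> dict[tuple[str, str], tuple[str, str]]:
    """Re-parse the membership CSV into {(db, term_id): (community, meta)}."""
    out = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out[(row["database"], row["term_id"])] = (
                row["community_id"], row["meta_community_id"]
            )
    return out


def read_term_goi_csv(path: str | Path) -> dict[tuple[str, str], set[str]]:
    out: dict[tuple[str, str], set[str]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.setdefault((row["database"], row["term_id"]), set()).add(row["gene"])
    return out


def read_experiment_goi_csv(path: str | Path) -> dict[tuple[str, str], dict[str, float]]:
    out: dict[tuple[str, str], dict[str, float]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.setdefault((row["fea_id"], row["experiment_id"]), {})[row["gene"]] = float(
                row["value"]
            )
    return out


# ---------------------------------------------------------------------------
# Configuration

@dataclass
class InputSpec:
    """Paths and dialect options naming a run's input files."""

    fea_tables: list[dict] = field(default_factory=list)  # {id, path, database?, sep?}
    quant_tables: list[dict] = field(default_factory=list)  # {fea_id, experiment_id, path, sep?}
    gmt: Path | None = None
    extra_annotations: dict[str, Path] = field(default_factory=dict)
    term_images: dict[str, Path] = field(default_factory=dict)  # term_id -> image
    dialect: dict[str, str] = field(default_factory=dict)
    gene_delimiter: str = "/"


_INPUT_KEYS = {"fea_tables", "quant_tables", "gmt", "extra_annotations",
               "term_images", "dialect", "gene_delimiter"}
_LIST_FLOAT_KEYS = {"grid_thresholds"}
_LIST_INT_KEYS = {"grid_max_sizes"}
_LIST_STR_KEYS = {"search_terms"}


def load_config(path: str | Path) -> tuple[RunConfig, InputSpec]:
    """Load a flat YAML key-value run configuration.

    Unknown keys trigger a warning; missing keys fall back to documented
    defaults.  List-valued keys accept YAML lists or comma-separated
    strings.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path.name}: config must be a key-value mapping")
    known = set(_CONFIG_DEFAULTS) | _INPUT_KEYS
    for key in raw:
        if key not in known:
            log.warning("%s: unknown config key %r ignored", path.name, key)
    cfg_kwargs = {}
    for key, default in _CONFIG_DEFAULTS.items():
        val = raw.get(key, default)
        if key in _LIST_FLOAT_KEYS:
            val = [float(v) for v in _split_list(val)]
        elif key in _LIST_INT_KEYS:
            val = [int(v) for v in _split_list(val)]
        elif key in _LIST_STR_KEYS:
            val = [str(v) for v in _split_list(val)]
        cfg_kwargs[key] = val
    config = RunConfig(**cfg_kwargs)

    base = path.parent
    spec = InputSpec()
    spec.gene_delimiter = str(raw.get("gene_delimiter", "/"))
    spec.dialect = dict(raw.get("dialect") or {})
    if raw.get("gmt"):
        spec.gmt = base / str(raw["gmt"])
    for entry in raw.get("fea_tables") or []:
        entry = dict(entry)
        entry["path"] = base / str(entry["path"])
        spec.fea_tables.append(entry)
    for entry in raw.get("quant_tables") or []:
        entry = dict(entry)
        entry["path"] = base / str(entry["path"])
        spec.quant_tables.append(entry)
    for label, p in (raw.get("extra_annotations") or {}).items():
        spec.extra_annotations[str(label)] = base / str(p)
    for term_id, p in (raw.get("term_images") or {}).items():
        spec.term_images[str(term_id)] = base / str(p)
    return config, spec


def _split_list(val: object) -> list:
    if val is None:
        return []
    if isinstance(val, str):
        return [v.strip() for v in val.split(",") if v.strip()]
    if isinstance(val, (list, tuple)):
        return list(val)
    return [val]


def load_fea_results(spec: InputSpec) -> list[FEAResult]:
    """Assemble FEAResults from an InputSpec: parse, GMT-replace, restrict."""
    gmt = parse_gmt(spec.gmt) if spec.gmt else None
    by_fea: dict[str, dict] = {}
    for entry in spec.fea_tables:
        fea_id = str(entry["id"])
        terms = parse_fea_table(
            entry["path"], dialect=spec.dialect, sep=entry.get("sep", ","),
            gene_delimiter=spec.gene_delimiter,
            default_database=str(entry.get("database", "DB")),
        )
        if gmt:
            terms = apply_gmt(terms, gmt)
        by_fea.setdefault(fea_id, {"terms": [], "experiments": []})["terms"].extend(terms)
    for entry in spec.quant_tables:
        fea_id = str(entry.get("fea_id") or next(iter(by_fea)))
        quant = parse_quant_table(entry["path"], str(entry["experiment_id"]),
                                  sep=entry.get("sep", ","))
        if fea_id not in by_fea:
            raise ConfigError(f"quant table references unknown FEA id {fea_id!r}")
        by_fea[fea_id]["experiments"].append(quant)
    results = []
    for fea_id, parts in by_fea.items():
        goi = set()
        for exp in parts["experiments"]:
            goi |= exp.membership
        terms = restrict_terms_to_goi(parts["terms"], goi)
        fea = FEAResult(fea_id=fea_id, terms=terms, experiments=parts["experiments"])
        fea.validate()
        results.append(fea)
    return results
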