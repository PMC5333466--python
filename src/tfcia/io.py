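"""Readers and writers for every table the pipeline touches.

Matrices and rankings travel as tab-delimited UTF-8 text with a header row
(genes as rows); the clinical table as CSV; run configuration as YAML or
JSON.  Readers validate and reject rather than coerce; writers round-trip
losslessly at six significant digits.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import CLINICAL_COLUMNS, ClinicalTable, ExpressionMatrix, GeneMotifTable
from .errors import IOFormatError, ValidationError

log = logging.getLogger("tfcia")

DEFAULT_THRESHOLDS = (0.70, 0.75, 0.80, 0.85)
FLOAT_FORMAT = "%.6g"


@dataclass
class RunConfig:
    """End-to-end run configuration (config-file-first, flags override)."""

    expression_path: str | None = None
    annotation_path: str | None = None
    motif_paths: dict[float, str] = field(default_factory=dict)
    clinical_path: str | None = None
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    parental_group: str = "Ag"
    resistant_groups: tuple[str, ...] = ("D8", "D12")
    adj_p_cutoff: float = 0.01
    n_axes: int = 5
    rank_product_permutations: int = 1000
    consensus_k: int = 20
    require_sign_concordance: bool = True
    seed: int = 0
    outdir: str = "tfcia_out"

    def __post_init__(self) -> None:
        if not 0 < self.adj_p_cutoff < 1:
            raise ValidationError(f"adj_p_cutoff must lie in (0,1), got {self.adj_p_cutoff}")
        if self.rank_product_permutations and self.rank_product_permutations < 100:
            raise ValidationError(
                "rank_product_permutations must be ≥ 100 when permutation "
                f"significance is requested, got {self.rank_product_permutations}"
            )
        if list(self.thresholds) != sorted(set(self.thresholds)):
            raise ValidationError("thresholds must be strictly increasing")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        try:
            raw = yaml.safe_load(path.read_text())
        except yaml.YAMLError as exc:  # pragma: no cover - passthrough
            raise IOFormatError(f"cannot parse config {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise IOFormatError(f"config {path} is not a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config field {sorted(unknown)[0]!r}")
        if "motif_paths" in raw:
            raw["motif_paths"] = {float(k): v for k, v in raw["motif_paths"].items()}
        for tup in ("thresholds", "resistant_groups"):
            if tup in raw:
                raw[tup] = tuple(raw[tup])
        return cls(**raw)


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise IOFormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_expression(path: str | Path, annotation_path: str | Path) -> ExpressionMatrix:
    """Read a gene x sample TSV plus a two-column (sample, group) annotation TSV."""
    df = _read_tsv(path)
    ann = pd.read_csv(annotation_path, sep="\t", dtype=str)
    if ann.shape[1] < 2:
        raise IOFormatError(f"annotation {annotation_path} needs (sample, group) columns")
    group_of = dict(zip(ann.iloc[:, 0], ann.iloc[:, 1]))
    return ExpressionMatrix(df.astype(float), group_of)


def write_expression(expr: ExpressionMatrix, path: str | Path, annotation_path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label="gene")
    pd.DataFrame(
        {"sample": expr.sample_ids, "group": [expr.group_of[s] for s in expr.sample_ids]}
    ).to_csv(annotation_path, sep="\t", index=False)


def read_motif_tables(
    paths_by_threshold: dict[float, str | Path], mode: str = "intersect"
) -> list[GeneMotifTable]:
    """Read the per-threshold gene x motif count tables and align their genes.

    ``mode='strict'`` demands identical gene and motif sets; ``'intersect'``
    restricts every table to the common identifiers (logged).  Tables are
    returned in increasing-threshold order with a shared lexicographic gene
    ordering.
    """
    if mode not in ("strict", "intersect"):
        raise ValidationError(f"unknown alignment mode {mode!r}")
    thresholds = sorted(paths_by_threshold)
    raw = {t: _read_tsv(paths_by_threshold[t]) for t in thresholds}
    genes = set(raw[thresholds[0]].index)
    motifs = set(raw[thresholds[0]].columns)
    for t in thresholds[1:]:
        if mode == "strict":
            if set(raw[t].index) != genes or set(raw[t].columns) != motifs:
                raise ValidationError(
                    f"motif table at threshold {t} does not share identifiers (strict mode)"
                )
        genes &= set(raw[t].index)
        motifs &= set(raw[t].columns)
    if not genes or not motifs:
        raise ValidationError("empty gene or motif intersection across motif tables")
    gene_order = sorted(genes)
    motif_order = sorted(motifs)
    dropped = {t: raw[t].shape[0] - len(gene_order) for t in thresholds}
    if any(dropped.values()):
        log.info("motif-table alignment dropped genes per threshold: %s", dropped)
    return [
        GeneMotifTable(raw[t].loc[gene_order, motif_order].astype(float), t)
        for t in thresholds
    ]


def write_motif_table(table: GeneMotifTable, path: str | Path) -> None:
    table.counts.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label="gene")


def align_to_expression(
    expr: ExpressionMatrix, motifs: GeneMotifTable
) -> tuple[ExpressionMatrix, GeneMotifTable]:
    """Restrict both tables to their common genes, in lexicographic order.

    The two coupled tables of a co-inertia analysis must be linked over the
    same gene rows in the same order; ordering is lexicographic so the result
    does not depend on input order.
    """
    common = sorted(set(expr.gene_ids) & set(motifs.gene_ids))
    if not common:
        raise ValidationError("expression and motif tables share no genes")
    n_e, n_m = len(expr.gene_ids), len(motifs.gene_ids)
    log.info(
        "gene alignment: kept %d genes (dropped %d from expression, %d from motifs)",
        len(common), n_e - len(common), n_m - len(common),
    )
    return expr.subset_genes(common), motifs.subset_genes(common)


def read_clinical(path: str | Path) -> ClinicalTable:
    path = Path(path)
    if not path.exists():
        raise IOFormatError(f"no such file: {path}")
    df = pd.read_csv(path)
    return ClinicalTable(df)


def write_clinical(table: ClinicalTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_table(df: pd.DataFrame, path: str | Path, index_label: str | None = None) -> None:
    """Write any results table as TSV at the declared precision."""
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT,
              index=index_label is not None, index_label=index_label)


def write_run_metadata(outdir: str | Path, config, extra: dict | None = None) -> Path:
    """Dump the run configuration (and optional manifest entries) as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {"config": _jsonable(config)}
    if extra:
        payload.update(extra)
    path = outdir / "run_metadata.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
    return path


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in sorted(obj)] if isinstance(obj, set) else [
            _jsonable(v) for v in obj
        ]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
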