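"""Core data containers, file formats and configuration.

Expression matrices are genes x samples TSV (first column gene ids, header
row of sample ids). Clinical tables are sample-per-row TSV with required
columns ``sample_id``, ``time``, ``status`` plus free covariate columns.
Gene sets use the standard GMT dialect. Mutations are a MAF-subset TSV with
columns ``sample_id``, ``gene``, ``variant_classification``.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("erss_pipeline")

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "GeneSetCollection",
    "MutationTable",
    "Config",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_clinical_table",
    "write_clinical_table",
    "read_gmt",
    "write_gmt",
    "read_mutation_table",
    "write_mutation_table",
    "adjust_batches",
    "VARIANT_CLASSES",
]

#: MAF-style variant classification vocabulary accepted in mutation tables.
VARIANT_CLASSES = (
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "In_Frame_Del",
    "In_Frame_Ins",
    "Splice_Site",
    "Translation_Start_Site",
    "Nonstop_Mutation",
    "Silent",
)


class ExpressionMatrix:
    """A validated genes x samples expression matrix.

    Values are assumed continuous and pre-normalized (log scale); an
    optional per-sample batch label series supports batch adjustment.
    """

    def __init__(self, values: pd.DataFrame, batch: pd.Series | None = None):
        if values.index.duplicated().any():
            dup = values.index[values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if values.columns.duplicated().any():
            dup = values.columns[values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        if values.shape[1] < 2:
            raise ValueError("expression matrix needs at least 2 samples")
        if values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        self.values = values.astype(float)
        if batch is not None:
            batch = pd.Series(batch).reindex(values.columns)
            if batch.isna().any():
                raise ValueError("batch labels missing for some samples")
        self.batch = batch

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[list(genes)], self.batch)

    def __repr__(self) -> str:  # pragma: no cover
        return f"ExpressionMatrix({self.shape[0]} genes x {self.shape[1]} samples)"


class ClinicalTable:
    """Per-sample survival time, event status and covariates.

    ``time`` is non-negative (unit declared in :class:`Config`), ``status``
    is 1 for an observed event and 0 for censoring. Any additional columns
    (age, sex, stage, group, batch, ...) ride along untouched.
    """

    REQUIRED = ("time", "status")

    def __init__(self, data: pd.DataFrame):
        if data.index.name != "sample_id":
            if "sample_id" in data.columns:
                data = data.set_index("sample_id")
            else:
                raise ValueError("clinical table needs a sample_id column or index")
        if data.index.duplicated().any():
            dup = data.index[data.index.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        for col in self.REQUIRED:
            if col not in data.columns:
                raise ValueError(f"clinical table missing required column {col!r}")
        bad = data["time"].isna() | data["status"].isna()
        if bad.any():
            logger.info("dropping %d samples with missing time/status", int(bad.sum()))
            data = data.loc[~bad]
        if (data["time"] < 0).any():
            raise ValueError("negative survival time")
        if not data["status"].isin([0, 1]).all():
            raise ValueError("status must be 0/1")
        self.data = data.copy()
        self.data["time"] = self.data["time"].astype(float)
        self.data["status"] = self.data["status"].astype(int)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time(self) -> pd.Series:
        return self.data["time"]

    @property
    def status(self) -> pd.Series:
        return self.data["status"]

    def aligned_to(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"samples absent from clinical table: {missing[:5]}")
        return ClinicalTable(self.data.loc[list(sample_ids)].reset_index())


@dataclass
class GeneSetCollection:
    """Named gene sets: mapping set name -> (description, gene list)."""

    sets: dict[str, tuple[str, list[str]]]

    def __post_init__(self):
        for name, (_, genes) in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} has duplicate genes")

    def genes(self, name: str) -> list[str]:
        return self.sets[name][1]

    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets


class MutationTable:
    """Somatic mutation events: (sample_id, gene, variant_classification)."""

    COLUMNS = ("sample_id", "gene", "variant_classification")

    def __init__(self, data: pd.DataFrame):
        if data.empty:
            data = pd.DataFrame(columns=list(self.COLUMNS))
        for col in self.COLUMNS:
            if col not in data.columns:
                raise ValueError(f"mutation table missing column {col!r}")
        unknown = set(data["variant_classification"]) - set(VARIANT_CLASSES)
        if unknown:
            raise ValueError(f"unknown variant classifications: {sorted(unknown)[:5]}")
        self.data = data[list(self.COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class Config:
    """Pipeline stage parameters; every field has a default.

    Unknown keys in a YAML config are rejected before any stage runs.
    """

    seed: int = 0
    time_unit: str = "months"
    stages: list[str] = field(default_factory=lambda: ["simulate", "de", "score", "survival"])
    # differential expression
    de_p_threshold: float = 0.05
    # ERSS / Cox screening
    screen_alpha: float = 0.05
    tie_method: str = "efron"
    score_mode: str = "refit"
    # cutpoint
    cutpoint_minprop: float = 0.1
    # immune / TMB
    ssgsea_exponent: float = 0.25
    ssgsea_normalize: bool = False
    callable_mb: float = 38.0
    tmb_counted_classes: tuple[str, ...] = tuple(c for c in VARIANT_CLASSES if c != "Silent")
    # GSEA
    gsea_permutations: int = 1000
    # WGCNA
    wgcna_min_module_size: int = 50
    wgcna_merge_height: float = 0.3
    wgcna_rsq_target: float = 0.9
    # risk model
    bootstrap_b: int = 200
    horizons: tuple[float, ...] = (12.0, 36.0, 60.0)
    # input paths (None -> stage must be fed by an upstream stage)
    expression_path: str | None = None
    clinical_path: str | None = None
    genesets_path: str | None = None
    mutations_path: str | None = None
    subjects_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "Config":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        for key in ("tmb_counted_classes", "horizons"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tmb_counted_classes"] = list(d["tmb_counted_classes"])
        d["horizons"] = list(d["horizons"])
        return d


# ---------------------------------------------------------------------------
# readers / writers


def read_expression_matrix(path: str | Path, batch_row: str | None = None) -> ExpressionMatrix:
    """Load a genes x samples TSV, dropping all-zero and incomplete rows.

    Rows that are constant zero across all samples (unexpressed genes) are
    removed and counted in the log, as are rows with any missing value.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene id: {dup!r}")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(f"non-numeric value at gene {row!r}, sample {col!r}")
    df = df.apply(pd.to_numeric)
    n_na = int(df.isna().any(axis=1).sum())
    if n_na:
        logger.info("dropping %d genes with missing values", n_na)
        df = df.dropna()
    zero = (df == 0).all(axis=1)
    if zero.any():
        logger.info("dropping %d unexpressed (all-zero) genes", int(zero.sum()))
        df = df.loc[~zero]
    batch = None
    if batch_row is not None and batch_row in df.index:
        batch = df.loc[batch_row]
        df = df.drop(index=batch_row)
    return ExpressionMatrix(df, batch)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    out = expr.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_clinical_table(path: str | Path) -> ClinicalTable:
    return ClinicalTable(pd.read_csv(path, sep="\t"))


def write_clinical_table(clin: ClinicalTable, path: str | Path) -> None:
    clin.data.reset_index().to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: ``name TAB description TAB gene TAB gene ...``."""
    sets: dict[str, tuple[str, list[str]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line {lineno}: expected >=3 tab-separated fields")
        name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
        deduped = list(dict.fromkeys(genes))
        if len(deduped) != len(genes):
            warnings.warn(f"gene set {name!r}: {len(genes) - len(deduped)} duplicate genes removed")
        sets[name] = (desc, deduped)
    return GeneSetCollection(sets)


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    lines = ["\t".join([name, desc] + genes) for name, (desc, genes) in sets.sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_mutation_table(path: str | Path) -> MutationTable:
    return MutationTable(pd.read_csv(path, sep="\t"))


def write_mutation_table(mut: MutationTable, path: str | Path) -> None:
    mut.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# batch adjustment


def adjust_batches(expr: ExpressionMatrix, batch: Sequence | None = None) -> ExpressionMatrix:
    """Per-gene, per-batch location/scale standardization.

    Each gene's values within a batch are rescaled so that the batch mean
    and standard deviation match the pooled (across-batch) mean and SD of
    that gene. This aligns first and second moments across batches; it is a
    simplification of empirical-Bayes batch correction, adequate when batch
    adjustment is only a preprocessing step. A gene with zero variance
    inside some batch is location-shifted only (with a warning).
    """
    labels = pd.Series(batch if batch is not None else expr.batch, index=expr.sample_ids)
    if labels.isna().any():
        raise ValueError("batch labels required for every sample")
    counts = labels.value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index[0]
        raise ValueError(f"batch {small!r} has fewer than 2 samples")
    if len(counts) == 1:
        return ExpressionMatrix(expr.values.copy(), labels)

    values = expr.values
    pooled_mean = values.mean(axis=1)
    pooled_sd = values.std(axis=1, ddof=1)
    out = values.copy()
    warned = False
    for b in counts.index:
        cols = labels.index[labels == b]
        sub = values[cols]
        bmean = sub.mean(axis=1)
        bsd = sub.std(axis=1, ddof=1)
        degenerate = bsd == 0
        scale = pooled_sd.where(bsd > 0, 0.0) / bsd.replace(0, np.nan)
        scale = scale.fillna(1.0)
        if degenerate.any() and not warned:
            warnings.warn(
                f"{int(degenerate.sum())} genes have zero variance within a batch; "
                "location shift only applied"
            )
            warned = True
        adj = sub.sub(bmean, axis=0).mul(scale, axis=0).add(pooled_mean, axis=0)
        out[cols] = adj
    return ExpressionMatrix(out, labels)
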