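"""Immune infiltration scores (ssGSEA, ESTIMATE-style) and mutational burden.

ssGSEA scores each sample independently: genes are ranked by expression
within the sample, and a gene set's score is the sum over the ranked list
of the difference between the rank-weighted in-set ECDF and the unweighted
out-of-set ECDF. The stromal/immune scores use exponent 0.25 and no
normalization; their sum maps to tumor purity through the published cosine
transform ``purity = cos(0.6049872018 + 0.0001467884 * score)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .pipeline_io import ClinicalTable, ExpressionMatrix, GeneSetCollection, MutationTable
from . import survstats

__all__ = [
    "SsgseaMatrix",
    "EstimateScores",
    "TmbResult",
    "ssgsea_scores",
    "ssgsea_sample_score",
    "estimate_scores",
    "compute_tmb",
    "composite_strata",
]

PURITY_INTERCEPT = 0.6049872018
PURITY_SLOPE = 0.0001467884


@dataclass
class SsgseaMatrix:
    scores: pd.DataFrame  # sets x samples
    exponent: float
    normalized: bool


@dataclass
class EstimateScores:
    table: pd.DataFrame  # per sample: stromal, immune, estimate, purity


@dataclass
class TmbResult:
    table: pd.DataFrame  # per sample: n_mutations, tmb, tmb_group
    callable_mb: float
    cutoff: float


def ssgsea_sample_score(values: np.ndarray, in_set: np.ndarray, exponent: float) -> float:
    """Single-sample enrichment score from one expression vector.

    ``values`` is the sample's expression across all genes; ``in_set``
    flags set membership. Genes are walked in decreasing expression order;
    hits advance the running sum by rank^exponent (normalized over the
    set), misses retreat by 1/(N - N_hit); the score is the sum of the
    running differences (the area variant used by single-sample GSEA).
    """
    n = len(values)
    n_hit = int(in_set.sum())
    if n_hit == 0 or n_hit >= n:
        raise ValueError("set must be a strict non-empty subset of the genes")
    ranks = rankdata(values, method="average")  # 1 = lowest expression
    order = np.argsort(-values, kind="stable")
    in_sorted = in_set[order]
    w = ranks[order] ** exponent
    hit_w = np.where(in_sorted, w, 0.0)
    p_hit = np.cumsum(hit_w) / hit_w.sum()
    p_miss = np.cumsum(~in_sorted) / (n - n_hit)
    return float((p_hit - p_miss).sum())


def ssgsea_scores(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    exponent: float = 0.25,
    normalize: bool = False,
) -> SsgseaMatrix:
    """ssGSEA enrichment of every gene set in every sample.

    Genes of a set absent from the matrix are dropped with a warning; a set
    with no present genes is an error. With ``normalize`` the whole matrix
    is rescaled by its global score range.
    """
    genes = np.array(expr.gene_ids)
    gene_pos = {g: i for i, g in enumerate(genes)}
    X = expr.values.to_numpy()
    masks = {}
    for name in sets.names():
        members = sets.genes(name)
        present = [g for g in members if g in gene_pos]
        if not present:
            raise ValueError(f"gene set {name!r} has no genes present in the matrix")
        if len(present) < len(members):
            warnings.warn(f"set {name!r}: {len(members) - len(present)} genes absent, dropped")
        mask = np.zeros(len(genes), dtype=bool)
        mask[[gene_pos[g] for g in present]] = True
        masks[name] = mask

    out = pd.DataFrame(
        index=list(masks), columns=expr.sample_ids, dtype=float
    )
    for j, sid in enumerate(expr.sample_ids):
        col = X[:, j]
        for name, mask in masks.items():
            out.loc[name, sid] = ssgsea_sample_score(col, mask, exponent)
    if normalize:
        rng = out.to_numpy().max() - out.to_numpy().min()
        if rng > 0:
            out = out / rng
    return SsgseaMatrix(out, exponent, normalize)


def estimate_scores(
    expr: ExpressionMatrix, stromal_set: list[str], immune_set: list[str]
) -> EstimateScores:
    """Stromal/immune enrichment and the cosine purity transform.

    The stromal and immune scores are unnormalized ssGSEA scores (exponent
    0.25) of the two signatures; the combined score is their sum and maps
    to tumor purity via ``cos(0.6049872018 + 0.0001467884 * combined)``.
    Purities falling outside [0, 1] are flagged, not clipped.
    """
    sets = GeneSetCollection(
        {
            "stromal": ("stromal signature", list(stromal_set)),
            "immune": ("immune signature", list(immune_set)),
        }
    )
    mat = ssgsea_scores(expr, sets, exponent=0.25, normalize=False).scores
    est = mat.loc["stromal"] + mat.loc["immune"]
    purity = np.cos(PURITY_INTERCEPT + PURITY_SLOPE * est)
    table = pd.DataFrame(
        {
            "stromal_score": mat.loc["stromal"],
            "immune_score": mat.loc["immune"],
            "estimate_score": est,
            "tumor_purity": purity,
            "purity_in_range": (purity >= 0) & (purity <= 1),
        }
    )
    if not table["purity_in_range"].all():
        warnings.warn("some purity estimates fall outside [0, 1]")
    return EstimateScores(table)


def compute_tmb(
    mut: MutationTable,
    samples,
    callable_mb: float = 38.0,
    counted_classes=None,
    cutoff: float | None = None,
) -> TmbResult:
    """Tumor mutational burden: counted mutations per callable megabase.

    Samples absent from the mutation table get TMB 0. The high/low label
    splits at ``cutoff`` (default: the cohort median).
    """
    from .pipeline_io import VARIANT_CLASSES

    if callable_mb <= 0:
        raise ValueError("callable_mb must be positive")
    if counted_classes is None:
        counted_classes = tuple(c for c in VARIANT_CLASSES if c != "Silent")
    unknown = set(counted_classes) - set(VARIANT_CLASSES)
    if unknown:
        raise ValueError(f"unknown variant classes: {sorted(unknown)}")
    data = mut.data
    counted = data[data["variant_classification"].isin(counted_classes)]
    counts = counted.groupby("sample_id").size().reindex(list(samples), fill_value=0)
    tmb = counts / callable_mb
    if cutoff is None:
        cutoff = float(tmb.median())
    table = pd.DataFrame(
        {
            "n_mutations": counts,
            "tmb": tmb,
            "tmb_group": np.where(tmb > cutoff, "high", "low"),
        }
    )
    table.index.name = "sample_id"
    return TmbResult(table, callable_mb, cutoff)


def composite_strata(
    erss_groups: pd.Series, tmb_groups: pd.Series, clin: ClinicalTable
) -> dict:
    """Four-way ERSS x TMB stratification with KM curves and log-rank test.

    Empty strata are dropped with a warning; identical groupings therefore
    reduce to two strata.
    """
    samples = [s for s in clin.sample_ids if s in erss_groups.index and s in tmb_groups.index]
    if not samples:
        raise ValueError("no overlapping samples between groupings")
    labels = pd.Series(
        [f"ERSS-{erss_groups[s]}/TMB-{tmb_groups[s]}" for s in samples], index=samples
    )
    counts = labels.value_counts()
    expected = 4
    if len(counts) < expected:
        warnings.warn(f"only {len(counts)} of 4 strata are non-empty")
    clin_sub = clin.aligned_to(samples)
    curves = survstats.km_estimate(
        clin_sub.time.to_numpy(), clin_sub.status.to_numpy(), labels.to_numpy()
    )
    if len(counts) >= 2:
        chi2, df, p = survstats.logrank_test(
            clin_sub.time.to_numpy(), clin_sub.status.to_numpy(), labels.to_numpy()
        )
    else:
        chi2 = df = p = np.nan
    return {"labels": labels, "curves": curves, "chi2": chi2, "df": df, "p": p}
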