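"""Differential expression, gene-list intersection, and enrichment tests.

The tumor/normal contrast uses the two-sided Wilcoxon rank-sum test per
gene with a log2 fold change computed as mean(tumor) - mean(normal) on the
(assumed log-scale) matrix. Over-representation uses the one-sided
hypergeometric upper tail. Preranked gene-set enrichment follows the
weighted Kolmogorov-Smirnov running-sum statistic with a gene-label
permutation null for NES, nominal p and FDR q.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .pipeline_io import ExpressionMatrix, GeneSetCollection

__all__ = [
    "DEResult",
    "differential_expression",
    "intersect_gene_list",
    "over_representation",
    "preranked_gsea",
    "enrichment_score",
]


@dataclass
class DEResult:
    """Per-gene differential expression table.

    ``table`` columns: log2fc, p, p_adj, direction, significant.
    """

    table: pd.DataFrame
    p_threshold: float

    @property
    def significant_genes(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def differential_expression(
    expr: ExpressionMatrix,
    groups,
    p_threshold: float = 0.05,
    tumor_label: str = "tumor",
    normal_label: str = "normal",
) -> DEResult:
    """Per-gene two-sided Wilcoxon rank-sum test, tumor vs normal.

    ``groups`` is a per-sample label sequence aligned to the matrix
    columns. Genes with raw p below ``p_threshold`` are flagged
    significant; Benjamini-Hochberg adjusted p-values are reported
    alongside. Direction is ``up`` iff log2FC > 0.
    """
    labels = pd.Series(np.asarray(groups), index=expr.sample_ids)
    tumor = expr.values.loc[:, labels == tumor_label].to_numpy()
    normal = expr.values.loc[:, labels == normal_label].to_numpy()
    if tumor.shape[1] < 2 or normal.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")

    res = stats.mannwhitneyu(tumor, normal, axis=1, alternative="two-sided")
    log2fc = tumor.mean(axis=1) - normal.mean(axis=1)
    p = np.asarray(res.pvalue)
    p_adj = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "p_adj": p_adj,
            "direction": np.where(log2fc > 0, "up", "down"),
            "significant": p < p_threshold,
        },
        index=expr.gene_ids,
    )
    table.index.name = "gene_id"
    return DEResult(table, p_threshold)


def intersect_gene_list(de: DEResult, gene_list) -> list[str]:
    """Significant DE genes also present in a user list, by ascending p."""
    wanted = set(gene_list)
    hits = de.table[de.table["significant"] & de.table.index.isin(wanted)]
    if hits.empty:
        warnings.warn("empty intersection between DE genes and the supplied list")
    return list(hits.sort_values("p").index)


def over_representation(
    query, universe, sets: GeneSetCollection
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    p = P(X >= overlap) with X ~ Hypergeom(|universe|, |set ∩ universe|,
    |query|); Benjamini-Hochberg adjustment across sets.
    """
    query = list(dict.fromkeys(query))
    universe_set = set(universe)
    missing = [g for g in query if g not in universe_set]
    if missing:
        raise ValueError(f"query gene absent from universe: {missing[0]!r}")
    M, N = len(universe_set), len(query)
    rows = []
    for name in sets.names():
        members = set(sets.genes(name)) & universe_set
        k = len(members & set(query))
        p = stats.hypergeom.sf(k - 1, M, len(members), N) if members else 1.0
        rows.append((name, len(members), k, p))
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"]).set_index("set")
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def enrichment_score(
    ranked_genes: np.ndarray, scores: np.ndarray, members: set, exponent: float = 1.0
) -> float:
    """Weighted KS enrichment score of one gene set on a ranked list.

    ``ranked_genes``/``scores`` must already be sorted by decreasing score.
    The running sum increments by |score|^exponent (normalized over the
    set) on hits and decrements by 1/(N - N_hit) on misses; ES is the
    deviation of maximum magnitude.
    """
    in_set = np.array([g in members for g in ranked_genes])
    n = len(ranked_genes)
    n_hit = int(in_set.sum())
    if n_hit == 0 or n_hit == n:
        raise ValueError("gene set must be a strict non-empty subset of the ranking")
    w = np.abs(scores, dtype=float) ** exponent
    hit_w = np.where(in_set, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        hit_w = in_set.astype(float)
        denom = n_hit
    running = np.cumsum(hit_w / denom - np.where(in_set, 0.0, 1.0 / (n - n_hit)))
    return float(running[np.argmax(np.abs(running))])


def preranked_gsea(
    ranking: pd.Series,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    exponent: float = 1.0,
) -> pd.DataFrame:
    """Preranked GSEA with a gene-label permutation null.

    For each set: ES from the weighted running sum; NES = ES divided by the
    mean |permuted ES| of matching sign; nominal p from the matching-sign
    permutation tail; FDR q from the pooled permutation NES distribution.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ranking = ranking.sort_values(ascending=False)
    genes = ranking.index.to_numpy()
    scores = ranking.to_numpy(dtype=float)
    n = len(genes)
    rng = np.random.default_rng(seed)

    rows = []
    perm_nes_pool: list[np.ndarray] = []
    for name in sets.names():
        members = set(sets.genes(name))
        absent = members - set(genes)
        if absent:
            raise ValueError(f"set {name!r} has genes absent from the ranking: {sorted(absent)[:3]}")
        if len(members) >= n:
            raise ValueError(f"set {name!r} is not smaller than the ranking")
        es = enrichment_score(genes, scores, members, exponent)
        k = len(members)
        perm_es = np.empty(n_perm)
        positions = np.arange(n)
        w = np.abs(scores) ** exponent
        miss_base = np.ones(n)
        for b in range(n_perm):
            idx = rng.choice(positions, size=k, replace=False)
            mask = np.zeros(n, dtype=bool)
            mask[idx] = True
            hit_w = np.where(mask, w, 0.0)
            denom = hit_w.sum()
            if denom == 0:
                hit_w = mask.astype(float)
                denom = k
            running = np.cumsum(hit_w / denom - np.where(mask, 0.0, miss_base / (n - k)) )
            perm_es[b] = running[np.argmax(np.abs(running))]
        same_sign = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
        if len(same_sign) == 0:
            nominal_p = 1.0 / n_perm
            nes = np.nan
            perm_nes = np.array([])
        else:
            nominal_p = float(np.mean(np.abs(same_sign) >= abs(es)))
            nominal_p = max(nominal_p, 1.0 / n_perm)
            denom_mean = np.mean(np.abs(same_sign))
            nes = es / denom_mean if denom_mean > 0 else np.nan
            pos = perm_es[perm_es > 0]
            neg = perm_es[perm_es < 0]
            scaled_pos = pos / pos.mean() if len(pos) else np.array([])
            scaled_neg = -(neg / np.abs(neg).mean()) if len(neg) else np.array([])
            perm_nes = np.concatenate([scaled_pos, scaled_neg])
        perm_nes_pool.append(perm_nes)
        rows.append({"set": name, "size": k, "es": es, "nes": nes, "p": nominal_p})

    out = pd.DataFrame(rows).set_index("set")
    # FDR q: ratio of the pooled-null NES tail to the observed NES tail
    all_perm = np.concatenate(perm_nes_pool) if perm_nes_pool else np.array([])
    obs = out["nes"].to_numpy()
    qs = []
    for nes in obs:
        if not np.isfinite(nes) or len(all_perm) == 0:
            qs.append(np.nan)
            continue
        if nes >= 0:
            null_tail = np.mean(all_perm >= nes) if len(all_perm) else 0.0
            obs_tail = np.mean(obs[np.isfinite(obs)] >= nes)
        else:
            null_tail = np.mean(all_perm <= nes)
            obs_tail = np.mean(obs[np.isfinite(obs)] <= nes)
        qs.append(min(1.0, null_tail / obs_tail) if obs_tail > 0 else np.nan)
    out["q"] = qs
    return out
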