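"""Weighted co-expression analysis: soft threshold, TOM, modules, hubs.

An unsigned network ``a_ij = |cor(x_i, x_j)|^beta`` is built at the
smallest soft-threshold exponent whose connectivity distribution fits a
scale-free topology (signed R^2 >= target). Topological overlap converts
adjacency into a neighborhood-sharing similarity; average-linkage
clustering with a static tree cut yields modules, small modules fall back
to grey, and modules with similar eigengenes are merged. Hub genes rank by
module membership (correlation with the module eigengene).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .pipeline_io import ExpressionMatrix

__all__ = [
    "NetworkModel",
    "ModuleAssignment",
    "pick_soft_threshold",
    "adjacency_matrix",
    "tom_similarity",
    "detect_modules",
    "module_trait_correlation",
    "hub_ranking",
]

GREY = "grey"
_MODULE_NAMES = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
]


@dataclass
class NetworkModel:
    beta: float
    fit_table: pd.DataFrame
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    connectivity: pd.Series


@dataclass
class ModuleAssignment:
    modules: pd.Series  # gene -> module label
    eigengenes: pd.DataFrame  # samples x modules
    cut_height: float

    def genes_in(self, module: str) -> list[str]:
        return list(self.modules.index[self.modules == module])


def adjacency_matrix(expr: ExpressionMatrix, beta: float) -> pd.DataFrame:
    """Unsigned adjacency |cor|^beta with zero diagonal."""
    X = expr.values.to_numpy()
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X)
    corr = np.nan_to_num(corr, nan=0.0)
    A = np.abs(corr) ** beta
    np.fill_diagonal(A, 0.0)
    return pd.DataFrame(A, index=expr.gene_ids, columns=expr.gene_ids)


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of log10(freq) on log10(mean k) over connectivity bins.

    Positive when frequency falls with connectivity (the scale-free
    direction); negative slopes of the regression are the expected case.
    """
    k = k[k > 0]
    if len(k) < n_bins:
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)  # equal-width bins
    if edges[0] == edges[-1]:
        return 0.0
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(len(edges) - 1):
        sel = which == b
        if sel.sum() == 0:
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.mean()))
    if len(xs) < 3:
        return 0.0
    slope, _, r, _, _ = stats.linregress(xs, ys)
    if not np.isfinite(r):
        return 0.0
    return float(-np.sign(slope) * r**2)


def pick_soft_threshold(
    expr: ExpressionMatrix,
    beta_grid=None,
    rsq_target: float = 0.9,
) -> tuple[float, pd.DataFrame]:
    """Choose the smallest soft threshold reaching the scale-free fit target.

    Returns the chosen beta and the fit table (signed R^2 and mean
    connectivity per candidate). Falls back with a warning to the argmax
    when no candidate reaches the target.
    """
    if beta_grid is None:
        beta_grid = list(range(1, 13)) + [14, 16, 18, 20]
    if expr.shape[0] < 30:
        warnings.warn("fewer than 30 genes; scale-free fit is unreliable")
    X = expr.values.to_numpy()
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X)
    corr = np.nan_to_num(corr, nan=0.0)
    abs_corr = np.abs(corr)
    np.fill_diagonal(abs_corr, 0.0)
    if abs_corr.max() == 0:
        raise ValueError("all gene-gene correlations are zero")
    rows = []
    for b in beta_grid:
        k = (abs_corr**b).sum(axis=1)
        rows.append({"beta": b, "signed_rsq": _scale_free_fit(k), "mean_k": float(k.mean())})
    fit = pd.DataFrame(rows).set_index("beta")
    reaching = fit.index[fit["signed_rsq"] >= rsq_target]
    if len(reaching):
        beta = float(reaching[0])
    else:
        beta = float(fit["signed_rsq"].idxmax())
        warnings.warn(
            f"no soft threshold reached signed R^2 >= {rsq_target}; using argmax beta={beta}"
        )
    return beta, fit


def tom_similarity(adjacency: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Topological overlap: TOM_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij).

    ``l_ij`` counts shared-neighbor adjacency ``sum_u a_iu a_uj``; the
    diagonal is set to 1. Input must be symmetric, in [0,1], zero diagonal.
    """
    is_df = isinstance(adjacency, pd.DataFrame)
    A = adjacency.to_numpy() if is_df else np.asarray(adjacency, dtype=float)
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if A.min() < 0 or A.max() > 1:
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = A.sum(axis=1)
    L = A @ A
    denom = np.minimum.outer(k, k) + 1.0 - A
    tom = (L + A) / denom
    np.fill_diagonal(tom, 1.0)
    if is_df:
        return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)
    return tom


def _eigengene(values: pd.DataFrame, genes: list[str]) -> pd.Series:
    """Module eigengene: orientation-fixed PC1 of the z-scored module genes."""
    sub = values.loc[genes]
    sd = sub.std(axis=1, ddof=1).replace(0, 1.0)
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    U, S, Vt = np.linalg.svd(z.to_numpy().T, full_matrices=False)
    scores = U[:, 0]
    mean_expr = z.mean(axis=0).to_numpy()
    c = np.dot(scores - scores.mean(), mean_expr - mean_expr.mean())
    if c < 0:
        scores = -scores
    return pd.Series(scores, index=values.columns)


def detect_modules(
    tom: pd.DataFrame,
    expr: ExpressionMatrix,
    min_size: int = 50,
    merge_height: float = 0.3,
    cut_height: float | None = None,
) -> ModuleAssignment:
    """Static-cut module detection on 1 - TOM with eigengene merging.

    Average-linkage clustering of the TOM dissimilarity; the tree is cut at
    ``cut_height`` (when None, the largest height on a fixed grid that
    yields >= 2 modules of at least ``min_size``, logged via warning when
    none does). Modules below ``min_size`` become grey; module pairs whose
    eigengene dissimilarity (1 - correlation) is below ``merge_height`` are
    merged iteratively.
    """
    genes = list(tom.index)
    if min_size > len(genes):
        raise ValueError("min_size exceeds the number of genes")
    dissim = 1.0 - tom.to_numpy()
    np.fill_diagonal(dissim, 0.0)
    Z = linkage(squareform(dissim, checks=False), method="average")

    def cut(height: float) -> pd.Series:
        labels = fcluster(Z, t=height, criterion="distance")
        return pd.Series(labels, index=genes)

    if cut_height is None:
        chosen = None
        for h in np.arange(0.99, 0.30, -0.02):
            labels = cut(h)
            big = (labels.value_counts() >= min_size).sum()
            if big >= 2:
                chosen = h
                break
        if chosen is None:
            chosen = 0.99
            warnings.warn("no cut height produced >= 2 modules of min_size; using 0.99")
        cut_height = float(chosen)
    labels = cut(cut_height)

    # demote small clusters to grey, name the rest by size
    counts = labels.value_counts()
    keep = [c for c in counts.index if counts[c] >= min_size]
    keep_sorted = sorted(keep, key=lambda c: -counts[c])
    name_of = {c: _MODULE_NAMES[i % len(_MODULE_NAMES)] + ("" if i < len(_MODULE_NAMES) else str(i)) for i, c in enumerate(keep_sorted)}
    modules = labels.map(lambda c: name_of.get(c, GREY))

    # iterative eigengene merging
    while True:
        names = [m for m in modules.unique() if m != GREY]
        if len(names) < 2:
            break
        eig = {m: _eigengene(expr.values, list(modules.index[modules == m])) for m in names}
        best = None
        for i, mi in enumerate(names):
            for mj in names[i + 1 :]:
                d = 1.0 - float(np.corrcoef(eig[mi], eig[mj])[0, 1])
                if d < merge_height and (best is None or d < best[0]):
                    best = (d, mi, mj)
        if best is None:
            break
        _, mi, mj = best
        modules = modules.replace(mj, mi)

    names = [m for m in modules.unique() if m != GREY]
    eigengenes = pd.DataFrame(
        {m: _eigengene(expr.values, list(modules.index[modules == m])) for m in names}
    )
    return ModuleAssignment(modules, eigengenes, cut_height)


def module_trait_correlation(assignment: ModuleAssignment, trait) -> pd.DataFrame:
    """Pearson correlation of each module eigengene with a sample trait."""
    trait = np.asarray(trait, dtype=float)
    if np.std(trait) == 0:
        raise ValueError("trait is constant")
    rows = []
    for m in assignment.eigengenes.columns:
        r, p = stats.pearsonr(assignment.eigengenes[m].to_numpy(), trait)
        rows.append({"module": m, "r": r, "p": p})
    return pd.DataFrame(rows).set_index("module")


def hub_ranking(
    assignment: ModuleAssignment, expr: ExpressionMatrix, module: str
) -> pd.DataFrame:
    """Genes of a module ranked by module membership (kME).

    kME is the correlation between a gene's expression and the module
    eigengene; ties break by intramodular connectivity (sum of |cor| to
    the other module genes).
    """
    if module == GREY:
        raise ValueError("the grey (unassigned) module has no hubs")
    genes = assignment.genes_in(module)
    if not genes:
        raise ValueError(f"module {module!r} not found")
    eig = assignment.eigengenes[module].to_numpy()
    sub = expr.values.loc[genes].to_numpy()
    kme = np.array([np.corrcoef(row, eig)[0, 1] for row in sub])
    with np.errstate(invalid="ignore"):
        corr = np.abs(np.nan_to_num(np.corrcoef(sub), nan=0.0))
    np.fill_diagonal(corr, 0.0)
    k_in = corr.sum(axis=1)
    out = pd.DataFrame({"kme": kme, "intramodular_k": k_in}, index=genes)
    return out.sort_values(["kme", "intramodular_k"], ascending=False)
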