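"""The ERSS statistic: Cox screening, sign-split clusters, PC1-difference score.

The signature score is built GGI-style: candidate genes are screened with
univariate Cox proportional-hazards fits; genes with Wald p below alpha are
split by the sign of their log-hazard coefficient into a risk cluster A
(beta > 0) and a protective cluster B (beta < 0). Each cluster's samples x
genes submatrix (gene-wise z-scored) is reduced to its first principal
component, orientation-fixed to correlate positively with the cluster's
mean expression, and the per-sample score is

    ERSS_i = PC1A_i - PC1B_i

so that high values indicate expression patterns associated with increased
hazard. A missing cluster contributes zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pipeline_io import ClinicalTable, ExpressionMatrix

__all__ = [
    "CoxScreenResult",
    "ScoreResult",
    "univariate_cox_screen",
    "compute_erss",
    "score_new_cohort",
    "cox_univariate_batch",
]


def cox_univariate_batch(
    X: np.ndarray,
    time: np.ndarray,
    status: np.ndarray,
    ties: str = "efron",
    max_iter: int = 50,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Newton-Raphson single-covariate Cox fits for many covariates at once.

    Parameters
    ----------
    X : (n_covariates, n_samples) array
        One row per covariate (gene).
    ties : {"efron", "breslow"}
        Efron's correction handles tied event times by averaging the tied
        subjects out of the risk-set denominator; Breslow leaves the full
        denominator for every tied event.

    Returns
    -------
    beta, se, converged : arrays of length n_covariates
        Non-converged or degenerate fits carry NaN coefficients.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    time = np.asarray(time, dtype=float)
    status = np.asarray(status, dtype=int)
    if status.sum() == 0:
        raise ValueError("no events observed")

    order = np.argsort(time, kind="stable")
    Xs, ts, ds = X[:, order], time[order], status[order]
    n_cov, n = Xs.shape

    uniq, starts = np.unique(ts, return_index=True)
    ends = np.append(starts[1:], n)
    # per time-group event counts and per-covariate event sums
    ev = ds.astype(float)
    d_g = np.add.reduceat(ev, starts)
    event_groups = d_g > 0
    max_d = int(d_g.max())
    xd_sum = np.add.reduceat(Xs * ev, starts, axis=1)  # (n_cov, U)

    beta = np.zeros(n_cov)
    converged = np.zeros(n_cov, dtype=bool)
    active = np.ones(n_cov, dtype=bool)
    se = np.full(n_cov, np.nan)

    def suffix_at_starts(a):
        return np.cumsum(a[:, ::-1], axis=1)[:, ::-1][:, starts]

    for _ in range(max_iter):
        idx = np.where(active & ~converged)[0]
        if len(idx) == 0:
            break
        b = beta[idx][:, None]
        xb = np.clip(b * Xs[idx], -500, 500)
        e = np.exp(xb)
        xe = Xs[idx] * e
        x2e = Xs[idx] * xe
        S0R = suffix_at_starts(e)
        S1R = suffix_at_starts(xe)
        S2R = suffix_at_starts(x2e)
        S0D = np.add.reduceat(e * ev, starts, axis=1)
        S1D = np.add.reduceat(xe * ev, starts, axis=1)
        S2D = np.add.reduceat(x2e * ev, starts, axis=1)

        grad = xd_sum[idx].sum(axis=1) * 0.0
        info = np.zeros(len(idx))
        grad += xd_sum[idx][:, event_groups].sum(axis=1)
        for l in range(max_d):
            gmask = d_g > l
            frac = (l / d_g[gmask]) if ties == "efron" else np.zeros(int(gmask.sum()))
            phi = S0R[:, gmask] - frac * S0D[:, gmask]
            m1 = (S1R[:, gmask] - frac * S1D[:, gmask]) / phi
            m2 = (S2R[:, gmask] - frac * S2D[:, gmask]) / phi
            grad -= m1.sum(axis=1)
            info += (m2 - m1**2).sum(axis=1)

        bad = ~np.isfinite(info) | (info <= 0)
        if bad.any():
            active[idx[bad]] = False
            beta[idx[bad]] = np.nan
        good = ~bad
        step = np.zeros(len(idx))
        step[good] = grad[good] / info[good]
        step = np.clip(step, -2.0, 2.0)
        beta[idx[good]] += step[good]
        done = good & (np.abs(step) < tol)
        converged[idx[done]] = True
        se[idx[done]] = 1.0 / np.sqrt(info[done])

    beta[~converged] = np.where(active[~converged], np.nan, np.nan)
    return beta, se, converged


@dataclass
class CoxScreenResult:
    """Per-gene univariate Cox screen with sign-split clusters."""

    table: pd.DataFrame
    alpha: float

    @property
    def cluster_a(self) -> list[str]:
        t = self.table
        return list(t.index[(t["p"] < self.alpha) & (t["beta"] > 0)])

    @property
    def cluster_b(self) -> list[str]:
        t = self.table
        return list(t.index[(t["p"] < self.alpha) & (t["beta"] < 0)])


def univariate_cox_screen(
    expr: ExpressionMatrix,
    clin: ClinicalTable,
    alpha: float = 0.05,
    ties: str = "efron",
) -> CoxScreenResult:
    """Screen every gene with a one-covariate proportional-hazards fit.

    Genes with Wald p < alpha are retained, partitioned by coefficient
    sign: positive coefficients (risk genes) form cluster A, negative
    (protective) cluster B. Non-converged or constant genes are excluded
    with a warning.
    """
    aligned = clin.aligned_to(expr.sample_ids)
    X = expr.values.to_numpy()
    sd = X.std(axis=1)
    usable = sd > 0
    if not usable.all():
        warnings.warn(f"{int((~usable).sum())} constant genes excluded from the Cox screen")
    beta = np.full(X.shape[0], np.nan)
    se = np.full(X.shape[0], np.nan)
    conv = np.zeros(X.shape[0], dtype=bool)
    if usable.any():
        b, s, c = cox_univariate_batch(
            X[usable], aligned.time.to_numpy(), aligned.status.to_numpy(), ties=ties
        )
        beta[usable], se[usable], conv[usable] = b, s, c
    if usable.any() and not conv[usable].all():
        warnings.warn(
            f"{int((~conv[usable]).sum())} genes did not converge and were excluded"
        )
    z = beta / se
    p = 2 * stats.norm.sf(np.abs(z))
    table = pd.DataFrame(
        {
            "beta": beta,
            "hr": np.exp(beta),
            "se": se,
            "p": p,
            "ci_low": np.exp(beta - 1.959963984540054 * se),
            "ci_high": np.exp(beta + 1.959963984540054 * se),
            "converged": conv,
        },
        index=expr.gene_ids,
    )
    table.index.name = "gene_id"
    table.loc[~conv, "p"] = np.nan
    return CoxScreenResult(table, alpha)


@dataclass
class ScoreResult:
    """Per-sample ERSS with the clusters, loadings and signs that built it."""

    cluster_a: list[str]
    cluster_b: list[str]
    erss: pd.Series
    pc1_a: pd.Series | None
    pc1_b: pd.Series | None
    loadings: dict[str, pd.Series] = field(default_factory=dict)
    signs: dict[str, float] = field(default_factory=dict)
    mode: str = "refit"
    cutpoint: float | None = None

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"erss": self.erss})
        if self.cutpoint is not None:
            out["group"] = np.where(self.erss > self.cutpoint, "high", "low")
        return out


def _zscore_genes(values: pd.DataFrame, genes: list[str]) -> pd.DataFrame:
    sub = values.loc[genes]
    sd = sub.std(axis=1, ddof=1)
    if (sd == 0).any():
        bad = sd.index[sd == 0][0]
        raise ValueError(f"cluster gene {bad!r} has zero variance")
    return sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)


def _cluster_pc1(z: pd.DataFrame) -> tuple[pd.Series, pd.Series, float]:
    """First principal component of a samples x genes z-scored block.

    Returns (scores per sample, unit-norm loading per gene, orientation
    sign). Sign is fixed so the scores correlate positively with the
    cluster's mean z-expression, eliminating the eigenvector sign
    ambiguity.
    """
    A = z.to_numpy().T  # samples x genes, columns already centered
    if A.shape[1] == 0:
        raise ValueError("empty cluster")
    total_var = float((A**2).sum())
    if total_var == 0:
        raise ValueError("cluster has zero total variance")
    U, S, Vt = np.linalg.svd(A, full_matrices=False)
    scores = U[:, 0] * S[0]
    loading = Vt[0]
    mean_expr = A.mean(axis=1)
    c = np.dot(scores - scores.mean(), mean_expr - mean_expr.mean())
    sign = 1.0 if c > 0 else (-1.0 if c < 0 else (1.0 if loading.sum() >= 0 else -1.0))
    return (
        pd.Series(sign * scores, index=z.columns, name="pc1"),
        pd.Series(sign * loading, index=z.index, name="loading"),
        sign,
    )


def compute_erss(
    expr: ExpressionMatrix, clusters: tuple[list[str], list[str]]
) -> ScoreResult:
    """PC1-difference signature score for one cohort.

    Genes are z-scored across samples; each non-empty cluster contributes
    its first-principal-component score per sample (orientation-fixed);
    ERSS_i = PC1A_i - PC1B_i.
    """
    cluster_a, cluster_b = list(clusters[0]), list(clusters[1])
    if not cluster_a and not cluster_b:
        raise ValueError("at least one cluster must be non-empty")
    missing = [g for g in cluster_a + cluster_b if g not in expr.values.index]
    if missing:
        raise KeyError(f"cluster gene absent from matrix: {missing[0]!r}")

    samples = expr.sample_ids
    pc1a = pc1b = None
    loadings: dict[str, pd.Series] = {}
    signs: dict[str, float] = {}
    erss = pd.Series(0.0, index=samples, name="erss")
    if cluster_a:
        za = _zscore_genes(expr.values, cluster_a)
        pc1a, loadings["A"], signs["A"] = _cluster_pc1(za)
        erss = erss + pc1a
    if cluster_b:
        zb = _zscore_genes(expr.values, cluster_b)
        pc1b, loadings["B"], signs["B"] = _cluster_pc1(zb)
        erss = erss - pc1b
    return ScoreResult(cluster_a, cluster_b, erss, pc1a, pc1b, loadings, signs, mode="refit")


def score_new_cohort(
    expr: ExpressionMatrix, ref: ScoreResult, mode: str = "refit"
) -> ScoreResult:
    """Score a validation cohort with a trained signature.

    ``refit`` re-derives per-cluster PC1s on the new cohort using the
    training gene clusters (the default, mirroring signature-construction
    transfer); ``project`` applies the training loading vectors to the new
    cohort's own z-scores (strict signature transfer).
    """
    if mode == "refit":
        res = compute_erss(expr, (ref.cluster_a, ref.cluster_b))
        res.mode = "refit"
        return res
    if mode != "project":
        raise ValueError("mode must be 'refit' or 'project'")

    samples = expr.sample_ids
    erss = pd.Series(0.0, index=samples, name="erss")
    pc1a = pc1b = None
    if ref.cluster_a:
        za = _zscore_genes(expr.values, ref.cluster_a)
        pc1a = pd.Series(za.to_numpy().T @ ref.loadings["A"].to_numpy(), index=samples)
        erss = erss + pc1a
    if ref.cluster_b:
        zb = _zscore_genes(expr.values, ref.cluster_b)
        pc1b = pd.Series(zb.to_numpy().T @ ref.loadings["B"].to_numpy(), index=samples)
        erss = erss - pc1b
    return ScoreResult(
        ref.cluster_a, ref.cluster_b, erss, pc1a, pc1b, dict(ref.loadings), dict(ref.signs), mode="project"
    )
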