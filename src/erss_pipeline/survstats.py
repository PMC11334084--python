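"""Survival machinery: KM curves, log-rank tests, optimal cutpoint,
multivariable Cox, time-dependent ROC, clinical association tests.

Kaplan-Meier estimation and multivariable Cox fits are delegated to
lifelines; the two-group log-rank statistic is additionally implemented in
vectorized form here because the maximally-selected-cutpoint search and the
null-calibration simulations evaluate it thousands of times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "KMCurve",
    "CoxModel",
    "CutpointResult",
    "km_estimate",
    "logrank_test",
    "logrank_z",
    "optimal_cutpoint",
    "cox_fit",
    "time_dependent_auc",
    "clinical_association",
]


@dataclass
class KMCurve:
    """Product-limit survival curve for one group."""

    label: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CoxModel:
    """Multivariable proportional-hazards fit (Efron ties, Breslow baseline)."""

    covariates: list[str]
    params: pd.Series
    summary: pd.DataFrame
    log_likelihood: float
    baseline_cumhaz: pd.DataFrame
    baseline_survival: pd.DataFrame
    means: pd.Series
    fitter: CoxPHFitter


def km_estimate(times, status, groups=None, alpha: float = 0.05) -> dict[str, KMCurve]:
    """Kaplan-Meier estimate per group with Greenwood log-log CI bands."""
    times = np.asarray(times, dtype=float)
    status = np.asarray(status, dtype=int)
    if (times < 0).any():
        raise ValueError("negative survival time")
    if groups is None:
        groups = np.array(["all"] * len(times))
    groups = np.asarray(groups)
    out = {}
    for g in pd.unique(groups):
        mask = groups == g
        kmf = KaplanMeierFitter(alpha=alpha)
        kmf.fit(times[mask], status[mask], label=str(g))
        ci = kmf.confidence_interval_survival_function_
        tl = kmf.event_table
        out[str(g)] = KMCurve(
            label=str(g),
            times=kmf.survival_function_.index.to_numpy(),
            survival=kmf.survival_function_.iloc[:, 0].to_numpy(),
            at_risk=tl["at_risk"].to_numpy(),
            ci_low=ci.iloc[:, 0].to_numpy(),
            ci_high=ci.iloc[:, 1].to_numpy(),
        )
    return out


def logrank_z(times, status, mask) -> float:
    """Standardized two-group log-rank statistic U / sqrt(V).

    ``mask`` selects group 1; the sign is positive when group 1 observes
    more events than expected (worse survival).
    """
    times = np.asarray(times, dtype=float)
    status = np.asarray(status, dtype=int)
    mask = np.asarray(mask, dtype=bool)
    order = np.argsort(times, kind="stable")
    t, s, m = times[order], status[order], mask[order]
    n = len(t)
    uniq, starts = np.unique(t, return_index=True)
    ends = np.append(starts[1:], n)

    at_risk_total = n - starts
    in1 = m.astype(float)
    at_risk_1 = in1[::-1].cumsum()[::-1][starts]
    d_total = np.add.reduceat(s.astype(float), starts)
    d1 = np.add.reduceat(s * in1, starts)

    ev = d_total > 0
    N, N1, d = at_risk_total[ev].astype(float), at_risk_1[ev], d_total[ev]
    expected = d * N1 / N
    with np.errstate(invalid="ignore", divide="ignore"):
        var = d * (N1 / N) * (1 - N1 / N) * (N - d) / np.maximum(N - 1, 1)
    U = float((d1[ev] - expected).sum())
    V = float(var.sum())
    if V <= 0:
        return 0.0
    return U / np.sqrt(V)


def logrank_test(times, status, groups) -> tuple[float, int, float]:
    """K-group log-rank test: (chi-square, df, p)."""
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    if len(levels) == 2:
        z = logrank_z(times, status, groups == levels[1])
        chi2 = z * z
        return chi2, 1, float(stats.chi2.sf(chi2, 1))
    res = multivariate_logrank_test(np.asarray(times, float), groups, np.asarray(status, int))
    df = len(levels) - 1
    return float(res.test_statistic), df, float(res.p_value)


@dataclass
class CutpointResult:
    """Maximally selected rank-statistic threshold on a continuous score."""

    threshold: float
    statistic: float  # |standardized log-rank| at the chosen split
    n_low: int
    n_high: int
    p_logrank: float  # ordinary log-rank p at the split; selection-biased


def optimal_cutpoint(score, times, status, minprop: float = 0.1) -> CutpointResult:
    """Threshold maximizing the absolute standardized log-rank statistic.

    Candidate thresholds are the observed score values; a split is eligible
    when both sides retain at least ``minprop`` of the samples. The
    reported p-value is the plain log-rank p at the chosen split and is
    biased by the selection; it is flagged as such downstream.
    """
    score = np.asarray(score, dtype=float)
    times = np.asarray(times, dtype=float)
    status = np.asarray(status, dtype=int)
    n = len(score)
    if status.sum() == 0:
        raise ValueError("no events observed")
    uniq = np.unique(score)
    if len(uniq) < 2:
        raise ValueError("all scores identical; no cutpoint exists")

    min_count = int(np.ceil(minprop * n))
    best = None
    for thr in uniq[:-1]:  # split: score <= thr vs score > thr
        high = score > thr
        n_high = int(high.sum())
        if n_high < min_count or n - n_high < min_count:
            continue
        z = logrank_z(times, status, high)
        if best is None or abs(z) > best[1]:
            best = (float(thr), abs(z), n - n_high, n_high)
    if best is None:
        raise ValueError(f"no split satisfies minprop={minprop}")
    thr, stat, n_low, n_high = best
    p = float(stats.chi2.sf(stat**2, 1))
    return CutpointResult(thr, stat, n_low, n_high, p)


def _drop_aliased(X: pd.DataFrame) -> pd.DataFrame:
    """Drop constant and linearly dependent columns, keeping the first of
    each dependent group."""
    keep: list[str] = []
    dropped: list[str] = []
    for col in X.columns:
        candidate = X[keep + [col]].to_numpy()
        if X[col].nunique() <= 1 or np.linalg.matrix_rank(
            np.column_stack([np.ones(len(X)), candidate])
        ) <= len(keep) + 1:
            dropped.append(col)
        else:
            keep.append(col)
    if dropped:
        warnings.warn(f"aliased/constant covariates dropped: {dropped}")
    return X[keep]


def cox_fit(covariates: pd.DataFrame, times, status, ties: str = "efron") -> CoxModel:
    """Multivariable Cox proportional-hazards fit.

    Aliased (constant or linearly dependent) covariate columns are dropped
    with a warning before fitting. The Breslow baseline cumulative hazard
    and baseline survival (at the covariate means) are retained for
    risk-model prediction.
    """
    X = _drop_aliased(covariates.astype(float))
    if X.shape[1] == 0:
        raise ValueError("no usable covariates after dropping aliased columns")
    df = X.copy()
    df["time"] = np.asarray(times, dtype=float)
    df["status"] = np.asarray(status, dtype=int)
    if df["status"].sum() == 0:
        raise ValueError("no events observed")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="status")
    except Exception as err:
        raise RuntimeError(f"Cox fit failed (possible separation): {err}") from err
    summary = cph.summary[["coef", "exp(coef)", "se(coef)", "exp(coef) lower 95%", "exp(coef) upper 95%", "p"]]
    summary = summary.rename(
        columns={
            "coef": "beta",
            "exp(coef)": "hr",
            "se(coef)": "se",
            "exp(coef) lower 95%": "ci_low",
            "exp(coef) upper 95%": "ci_high",
        }
    )
    return CoxModel(
        covariates=list(X.columns),
        params=cph.params_,
        summary=summary,
        log_likelihood=float(cph.log_likelihood_),
        baseline_cumhaz=cph.baseline_cumulative_hazard_,
        baseline_survival=cph.baseline_survival_,
        means=X.mean(),
        fitter=cph,
    )


def time_dependent_auc(score, times, status, horizon: float) -> float:
    """Cumulative/dynamic AUC at one horizon with IPCW weighting.

    Cases are subjects with an event by the horizon, controls those still
    at risk past it; inverse-probability-of-censoring weights come from the
    Kaplan-Meier estimate of the censoring distribution.
    """
    from sksurv.metrics import cumulative_dynamic_auc
    from sksurv.util import Surv

    times = np.asarray(times, dtype=float)
    status = np.asarray(status, dtype=int)
    score = np.asarray(score, dtype=float)
    if not ((times <= horizon) & (status == 1)).any():
        raise ValueError("no events observed by the horizon")
    if not (times > horizon).any():
        raise ValueError("no subjects at risk past the horizon")
    y = Surv.from_arrays(status.astype(bool), times)
    auc, _ = cumulative_dynamic_auc(y, y, score, [horizon])
    return float(auc[0])


def clinical_association(x, y) -> dict:
    """Association between a grouping/score and a clinical feature.

    Categorical x categorical -> chi-square, falling back to Fisher's
    exact test on 2x2 tables with any expected count at or below 5.
    Numeric score vs
    a 2-level feature -> Wilcoxon rank-sum; vs >= 3 levels ->
    Kruskal-Wallis.
    """
    x = pd.Series(x).reset_index(drop=True)
    y = pd.Series(y).reset_index(drop=True)
    ok = x.notna() & y.notna()
    x, y = x[ok], y[ok]
    if y.nunique() < 2:
        raise ValueError("clinical feature is constant or all-missing")

    x_numeric = pd.api.types.is_numeric_dtype(x) and x.nunique() > 5
    if not x_numeric:
        table = pd.crosstab(x, y)
        chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
        test = "chi-square"
        if table.shape == (2, 2) and (expected <= 5).any():
            _, p = stats.fisher_exact(table.to_numpy())
            test, chi2, dof = "fisher-exact", np.nan, np.nan
        return {"test": test, "statistic": float(chi2) if np.isfinite(chi2) else None, "df": dof, "p": float(p), "table": table}
    levels = pd.unique(y)
    samples = [x[y == lv].to_numpy() for lv in levels]
    if len(levels) == 2:
        stat, p = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
        return {"test": "wilcoxon", "statistic": float(stat), "p": float(p)}
    stat, p = stats.kruskal(*samples)
    return {"test": "kruskal-wallis", "statistic": float(stat), "p": float(p)}
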