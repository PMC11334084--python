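"""Nomogram-equivalent risk model on top of a multivariable Cox fit.

Combines the signature score with clinical covariates (age and stage by
default), predicts survival probabilities at fixed horizons from the
Breslow baseline, and evaluates the model by Harrell's C-index with a
percentile bootstrap CI, quantile-group calibration with bootstrap
optimism correction, and decision-curve net benefit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.utils import concordance_index

from . import survstats
from .survstats import CoxModel

__all__ = [
    "RiskModel",
    "fit_risk_model",
    "predict_survival",
    "concordance",
    "calibration",
    "decision_curve",
]


@dataclass
class RiskModel:
    cox: CoxModel
    train_X: pd.DataFrame
    train_times: np.ndarray
    train_status: np.ndarray
    points: pd.DataFrame  # nomogram-style 0-100 points per covariate

    @property
    def covariates(self) -> list[str]:
        return self.cox.covariates


def _points_table(cox: CoxModel, X: pd.DataFrame) -> pd.DataFrame:
    """0-100 nomogram points: the covariate with the largest |beta| x range
    spans 100 points; every covariate's points are linear in beta * x."""
    spans = {}
    for c in cox.covariates:
        rng = X[c].max() - X[c].min()
        spans[c] = abs(cox.params[c]) * rng
    top = max(spans.values()) if spans else 1.0
    rows = []
    for c in cox.covariates:
        rows.append(
            {
                "covariate": c,
                "beta": cox.params[c],
                "range": X[c].max() - X[c].min(),
                "max_points": 100.0 * spans[c] / top if top > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("covariate")


def fit_risk_model(covariates: pd.DataFrame, times, status) -> RiskModel:
    """Fit the Cox risk model and derive its points scale."""
    cox = survstats.cox_fit(covariates, times, status)
    X = covariates[cox.covariates].astype(float)
    return RiskModel(
        cox,
        X,
        np.asarray(times, dtype=float),
        np.asarray(status, dtype=int),
        _points_table(cox, X),
    )


def _baseline_survival_at(model: RiskModel, t: float) -> float:
    bs = model.cox.baseline_survival
    idx = bs.index.to_numpy()
    pos = np.searchsorted(idx, t, side="right") - 1
    return 1.0 if pos < 0 else float(bs.iloc[pos, 0])


def predict_survival(model: RiskModel, covariates: pd.DataFrame, horizon: float) -> pd.Series:
    """S(t | x) = S0(t) ^ exp(beta . (x - xbar)) with the Breslow baseline.

    Covariate values outside the training range predict with a warning.
    """
    X = covariates[model.covariates].astype(float)
    for c in model.covariates:
        lo, hi = model.train_X[c].min(), model.train_X[c].max()
        if (X[c] < lo).any() or (X[c] > hi).any():
            warnings.warn(f"covariate {c!r} outside the training range")
    lp = (X - model.cox.means).to_numpy() @ model.cox.params.to_numpy()
    s0 = _baseline_survival_at(model, horizon)
    return pd.Series(s0 ** np.exp(lp), index=X.index, name=f"S({horizon})")


def concordance(
    score, times, status, bootstrap_b: int = 200, seed: int = 0
) -> dict:
    """Harrell's C-index of a risk score with a percentile bootstrap CI.

    ``score`` is oriented as risk (higher = earlier failure). Pairs where
    the shorter time is censored are unusable and excluded.
    """
    score = np.asarray(score, dtype=float)
    times = np.asarray(times, dtype=float)
    status = np.asarray(status, dtype=int)
    c = concordance_index(times, -score, status)
    ci = (np.nan, np.nan)
    if bootstrap_b > 0:
        rng = np.random.default_rng(seed)
        n = len(times)
        boots = []
        for _ in range(bootstrap_b):
            idx = rng.integers(0, n, size=n)
            if status[idx].sum() == 0:
                continue
            try:
                boots.append(concordance_index(times[idx], -score[idx], status[idx]))
            except ZeroDivisionError:
                continue
        if boots:
            ci = tuple(np.percentile(boots, [2.5, 97.5]))
    return {"c_index": float(c), "ci_low": float(ci[0]), "ci_high": float(ci[1]), "b": bootstrap_b}


def _km_at(times, status, t: float) -> float:
    kmf = KaplanMeierFitter()
    kmf.fit(times, status)
    return float(kmf.predict(t))


def calibration(
    model: RiskModel,
    covariates: pd.DataFrame,
    times,
    status,
    horizon: float,
    n_groups: int = 4,
    bootstrap_b: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Observed (KM) vs predicted survival by quantile groups of risk.

    With ``bootstrap_b`` > 0 a bootstrap-refit optimism correction is
    subtracted from the apparent predictions: for each resample the model
    is refit and the per-group mean prediction difference between the
    resample and the original data estimates the optimism.
    """
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    times = np.asarray(times, dtype=float)
    status = np.asarray(status, dtype=int)
    pred = predict_survival(model, covariates, horizon)
    if pred.nunique() <= 1:
        groups = pd.Series(0, index=pred.index)
    else:
        try:
            groups = pd.qcut(pred, n_groups, labels=False, duplicates="drop")
        except ValueError:
            groups = pd.Series(0, index=pred.index)
    if groups.nunique() < n_groups:
        warnings.warn("ties reduced the number of calibration groups")

    rows = []
    for g in sorted(groups.unique()):
        mask = (groups == g).to_numpy()
        obs = _km_at(times[mask], status[mask], horizon)
        flagged = status[mask].sum() == 0 and not (times[mask] > horizon).any()
        rows.append(
            {
                "group": int(g),
                "n": int(mask.sum()),
                "predicted": float(pred[mask].mean()),
                "observed": obs,
                "flagged": bool(flagged),
            }
        )
    out = pd.DataFrame(rows).set_index("group")

    if bootstrap_b > 0:
        rng = np.random.default_rng(seed)
        n = len(times)
        optimism = np.zeros(len(out))
        used = 0
        for _ in range(bootstrap_b):
            idx = rng.integers(0, n, size=n)
            if status[idx].sum() < 2:
                continue
            try:
                boot_model = fit_risk_model(
                    covariates.iloc[idx].reset_index(drop=True), times[idx], status[idx]
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # resample ranges differ
                    pred_boot = predict_survival(
                        boot_model, covariates.iloc[idx].reset_index(drop=True), horizon
                    ).mean()
                    pred_orig = predict_survival(boot_model, covariates, horizon)
            except (RuntimeError, ValueError):
                continue
            for i, g in enumerate(sorted(groups.unique())):
                mask = (groups == g).to_numpy()
                optimism[i] += pred_boot - pred_orig[mask].mean()
            used += 1
        if used:
            out["predicted_corrected"] = out["predicted"] - optimism / used
    return out


def decision_curve(
    model: RiskModel,
    covariates: pd.DataFrame,
    times,
    status,
    horizon: float,
    thresholds=None,
) -> pd.DataFrame:
    """Decision-curve net benefit of treating at predicted risk >= p_t.

    Net benefit = TP/n - FP/n * p_t / (1 - p_t). Censoring before the
    horizon is handled by Kaplan-Meier accounting: within the treated
    group, the event fraction at the horizon is 1 - KM(horizon). Treat-all
    and treat-none reference curves are included.
    """
    if thresholds is None:
        thresholds = np.arange(0.05, 0.95, 0.05)
    thresholds = np.asarray(thresholds, dtype=float)
    if ((thresholds <= 0) | (thresholds >= 1)).any():
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    times = np.asarray(times, dtype=float)
    status = np.asarray(status, dtype=int)
    n = len(times)
    risk = 1.0 - predict_survival(model, covariates, horizon).to_numpy()
    event_all = 1.0 - _km_at(times, status, horizon)

    rows = []
    for pt in thresholds:
        odds = pt / (1 - pt)
        treated = risk >= pt
        if treated.any():
            ev = 1.0 - _km_at(times[treated], status[treated], horizon)
            frac = treated.mean()
            nb = ev * frac - (1 - ev) * frac * odds
        else:
            nb = 0.0
        nb_all = event_all - (1 - event_all) * odds
        rows.append(
            {"threshold": pt, "net_benefit": nb, "treat_all": nb_all, "treat_none": 0.0}
        )
    return pd.DataFrame(rows)
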