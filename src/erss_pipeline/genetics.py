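"""Case-control SNP statistics: HWE, odds ratios, logistic models,
crossover analysis, additive (RERI/AP/S) and multiplicative interaction.

Genotype effects use dominant coding by default: carriers of any minor
allele (CT + TT) against homozygous reference (CC). Odds-ratio confidence
intervals are Woolf (log-normal Wald) intervals; additive-interaction CIs
use the delta method on the fitted logistic covariance (the
Hosmer-Lemeshow formulation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "GenotypeCounts",
    "OrEstimate",
    "InteractionEstimate",
    "hwe_test",
    "odds_ratio",
    "logistic_fit",
    "crossover_analysis",
    "additive_interaction",
    "multiplicative_interaction",
    "expand_counts_to_subjects",
]

Z95 = stats.norm.ppf(0.975)


@dataclass
class GenotypeCounts:
    """Case/control genotype counts, full (CC, CT, TT) or collapsed.

    The collapsed layout is carriers (CT + TT) vs CC. A full layout
    collapses losslessly; the reverse is impossible.
    """

    case_cc: int
    case_carrier: int
    control_cc: int
    control_carrier: int
    case_ct: int | None = None
    case_tt: int | None = None
    control_ct: int | None = None
    control_tt: int | None = None

    def __post_init__(self):
        for f in ("case_cc", "case_carrier", "control_cc", "control_carrier"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")

    @classmethod
    def from_full(cls, case_cc, case_ct, case_tt, control_cc, control_ct, control_tt):
        return cls(
            case_cc=case_cc,
            case_carrier=case_ct + case_tt,
            control_cc=control_cc,
            control_carrier=control_ct + control_tt,
            case_ct=case_ct,
            case_tt=case_tt,
            control_ct=control_ct,
            control_tt=control_tt,
        )

    def table2x2(self) -> np.ndarray:
        """Rows: case, control; columns: carrier (exposed), CC (reference)."""
        return np.array(
            [[self.case_carrier, self.case_cc], [self.control_carrier, self.control_cc]]
        )


@dataclass
class OrEstimate:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    coding: str
    corrected: bool = False  # Haldane-Anscombe +0.5 applied


@dataclass
class InteractionEstimate:
    reri: float
    reri_ci: tuple[float, float]
    ap: float
    ap_ci: tuple[float, float]
    s: float | None
    s_ci: tuple[float, float] | None
    note: str = ""


def hwe_test(n_aa: int, n_ab: int, n_bb: int) -> tuple[float, int, float]:
    """Pearson chi-square test of Hardy-Weinberg proportions (1 df).

    Input is the genotype breakdown (major hom, het, minor hom) of one
    group, conventionally the controls. A monomorphic sample returns
    chi-square 0 with a warning.
    """
    n = n_aa + n_ab + n_bb
    if n <= 0:
        raise ValueError("all genotype counts are zero")
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1 - p
    if p == 0 or q == 0:
        warnings.warn("monomorphic locus; HWE test is degenerate")
        return 0.0, 1, 1.0
    expected = np.array([p * p * n, 2 * p * q * n, q * q * n])
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, 1, float(stats.chi2.sf(chi2, 1))


def odds_ratio(table: np.ndarray | GenotypeCounts, coding: str = "") -> OrEstimate:
    """OR = ad/bc with a Woolf 95% CI and two-sided Wald p.

    ``table`` rows are case/control, columns exposed/reference. Zero cells
    get the Haldane-Anscombe +0.5 correction (flagged); a fully zero row
    or column is an error.
    """
    if isinstance(table, GenotypeCounts):
        coding = coding or "CT+TT vs CC"
        table = table.table2x2()
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("a full zero row/column makes the OR undefined")
    corrected = (t == 0).any()
    if corrected:
        t = t + 0.5
    a, b = t[0]
    c, d = t[1]
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    p = 2 * stats.norm.sf(abs(log_or) / se)
    return OrEstimate(
        odds_ratio=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - Z95 * se)),
        ci_high=float(np.exp(log_or + Z95 * se)),
        p=float(p),
        coding=coding,
        corrected=bool(corrected),
    )


@dataclass
class LogisticFit:
    """ML logistic regression: coefficient table + covariance matrix."""

    table: pd.DataFrame  # per term: coef, se, or, ci_low, ci_high, p
    cov: pd.DataFrame
    n: int
    log_likelihood: float

    def or_estimate(self, term: str, coding: str = "") -> OrEstimate:
        row = self.table.loc[term]
        return OrEstimate(
            float(row["or"]), float(row["ci_low"]), float(row["ci_high"]), float(row["p"]), coding
        )


def logistic_fit(
    data: pd.DataFrame,
    outcome: str,
    terms: list[str],
    max_iter: int = 100,
    tol: float = 1e-10,
) -> LogisticFit:
    """Unconditional logistic regression by maximum likelihood (IRLS).

    ``terms`` name columns of ``data``; interaction products must be
    pre-computed columns (e.g. ``data['gxe'] = data.g * data.e``). Aliased
    columns (constant or linearly dependent with the intercept and earlier
    terms) and perfect separation are rejected with diagnostics.
    """
    y = data[outcome].astype(float).to_numpy()
    X = data[terms].astype(float)
    n = len(y)
    design = np.column_stack([np.ones(n), X.to_numpy()])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("aliased covariates: design matrix is rank-deficient")
    model = sm.Logit(y, design)
    try:
        res = model.fit(disp=False, maxiter=max_iter, tol=tol, method="newton")
    except Exception as err:
        raise RuntimeError(f"logistic fit failed (possible separation): {err}") from err
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError("logistic fit did not converge")
    if np.abs(res.params).max() > 15:
        raise RuntimeError("logistic fit suggests perfect separation (|coef| > 15)")
    names = ["intercept"] + list(terms)
    coef = pd.Series(res.params, index=names)
    se = pd.Series(res.bse, index=names)
    table = pd.DataFrame(
        {
            "coef": coef,
            "se": se,
            "or": np.exp(coef),
            "ci_low": np.exp(coef - Z95 * se),
            "ci_high": np.exp(coef + Z95 * se),
            "p": 2 * stats.norm.sf(np.abs(coef / se)),
        }
    )
    cov = pd.DataFrame(res.cov_params(), index=names, columns=names)
    return LogisticFit(table, cov, n, float(res.llf))


def crossover_analysis(
    data: pd.DataFrame,
    outcome: str = "case",
    genotype: str = "carrier",
    exposure: str = "exposure",
    protective_genotype: int = 1,
    adjust: list[str] | None = None,
) -> dict[str, OrEstimate]:
    """Joint genotype x exposure odds ratios against a single reference cell.

    The reference is the protective genotype level combined with no
    exposure; the three other cells (risk genotype only, exposure only,
    both) each get an OR from one logistic fit with category indicators.
    ``adjust`` adds covariate columns (e.g. age).
    """
    df = data.copy()
    g_risk = (df[genotype] != protective_genotype).astype(int)
    e = df[exposure].astype(int)
    if ((g_risk == 0) & (e == 0)).sum() == 0:
        raise ValueError("reference cell (protective genotype, unexposed) is empty")
    df["_g_only"] = ((g_risk == 1) & (e == 0)).astype(int)
    df["_e_only"] = ((g_risk == 0) & (e == 1)).astype(int)
    df["_both"] = ((g_risk == 1) & (e == 1)).astype(int)
    terms = ["_g_only", "_e_only", "_both"] + list(adjust or [])
    fit = logistic_fit(df, outcome, terms)
    return {
        "genotype_only": fit.or_estimate("_g_only", "risk genotype, unexposed vs reference"),
        "exposure_only": fit.or_estimate("_e_only", "protective genotype, exposed vs reference"),
        "both": fit.or_estimate("_both", "risk genotype and exposed vs reference"),
        "fit": fit,
    }


def _interaction_functions(theta: np.ndarray) -> dict[str, float]:
    bg, be, bge = theta
    or10, or01, or11 = np.exp(bg), np.exp(be), np.exp(bg + be + bge)
    out = {"reri": or11 - or10 - or01 + 1, "ap": (or11 - or10 - or01 + 1) / or11}
    denom = (or10 - 1) + (or01 - 1)
    out["lns"] = np.log((or11 - 1) / denom) if denom > 0 and or11 > 1 else np.nan
    return out


def additive_interaction(
    fit: LogisticFit, g_term: str, e_term: str, ge_term: str
) -> InteractionEstimate:
    """RERI, AP and the synergy index S with delta-method 95% CIs.

    RERI = OR11 - OR10 - OR01 + 1; AP = RERI / OR11;
    S = (OR11 - 1) / ((OR10 - 1) + (OR01 - 1)), with OR11 = exp(bg+be+bge).
    Standard errors follow the delta method on the fitted covariance of
    (bg, be, bge); the S interval is built on the log scale. S is reported
    as undefined when its denominator is non-positive.
    """
    names = [g_term, e_term, ge_term]
    theta = fit.table.loc[names, "coef"].to_numpy()
    cov = fit.cov.loc[names, names].to_numpy()

    point = _interaction_functions(theta)

    def gradient(key: str) -> np.ndarray:
        eps = 1e-6
        grad = np.zeros(3)
        for i in range(3):
            up, dn = theta.copy(), theta.copy()
            up[i] += eps
            dn[i] -= eps
            grad[i] = (_interaction_functions(up)[key] - _interaction_functions(dn)[key]) / (2 * eps)
        return grad

    def ci(key: str) -> tuple[float, float] | None:
        val = point[key]
        if not np.isfinite(val):
            return None
        g = gradient(key)
        var = float(g @ cov @ g)
        half = Z95 * np.sqrt(max(var, 0.0))
        return (val - half, val + half)

    reri_ci = ci("reri")
    ap_ci = ci("ap")
    note = ""
    if np.isfinite(point["lns"]):
        lns_ci = ci("lns")
        s = float(np.exp(point["lns"]))
        s_ci = (float(np.exp(lns_ci[0])), float(np.exp(lns_ci[1])))
    else:
        s, s_ci = None, None
        note = "S undefined: (OR10 - 1) + (OR01 - 1) <= 0 or OR11 <= 1"
    return InteractionEstimate(
        reri=float(point["reri"]),
        reri_ci=(float(reri_ci[0]), float(reri_ci[1])),
        ap=float(point["ap"]),
        ap_ci=(float(ap_ci[0]), float(ap_ci[1])),
        s=s,
        s_ci=s_ci,
        note=note,
    )


def multiplicative_interaction(fit: LogisticFit, ge_term: str) -> OrEstimate:
    """OR of the product term with its Wald CI and p from the fit."""
    if ge_term not in fit.table.index:
        raise ValueError(f"product term {ge_term!r} absent from the fit")
    return fit.or_estimate(ge_term, "multiplicative interaction (product term)")


def expand_counts_to_subjects(counts: GenotypeCounts) -> pd.DataFrame:
    """Subject-level table (carrier, case) reconstructed from 2x2 counts."""
    rows = (
        [(1, 1)] * counts.case_carrier
        + [(0, 1)] * counts.case_cc
        + [(1, 0)] * counts.control_carrier
        + [(0, 0)] * counts.control_cc
    )
    return pd.DataFrame(rows, columns=["carrier", "case"])
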