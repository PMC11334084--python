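"""Synthetic cohorts with the statistical structure the pipeline assumes.

Three generators:

* :func:`simulate_expression_cohort` — tumor/normal log-expression with
  planted differentially expressed genes, two disjoint prognostic gene
  clusters (one hazard-increasing, one hazard-decreasing) whose mean
  expression drives exponential proportional-hazards survival, and
  independent uniform censoring tuned to a target censoring rate.
* :func:`simulate_mutations` — per-sample Poisson mutation counts with
  MAF-style variant classifications.
* :func:`simulate_case_control` — a biallelic locus drawn under
  Hardy-Weinberg, a binary exposure, and case status from a logistic model
  with planted genotype, exposure and interaction odds ratios.

Every generator is a pure function of its spec (including the seed); each
returns a truth record sufficient to verify recovery downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .pipeline_io import (
    VARIANT_CLASSES,
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    MutationTable,
)

__all__ = [
    "CohortSpec",
    "CaseControlSpec",
    "simulate_expression_cohort",
    "simulate_mutations",
    "simulate_case_control",
    "make_signature_collection",
]


@dataclass
class CohortSpec:
    """Parameters of the expression + survival cohort generator.

    Defaults mirror the structure of a bulk NSCLC tumor/normal study on a
    reduced gene panel: a few hundred tumors, an order of magnitude fewer
    normals, a block of up- and down-regulated genes, and a small
    hazard-increasing (A) and hazard-decreasing (B) prognostic cluster
    planted inside the DE genes (12 risk vs 2 protective genes, matching
    the usual asymmetry of prognostic screens). Expression is on a log2
    scale; ``de_effect`` is a mean log2 shift. ``beta_A``/``beta_B`` are
    per-unit log-hazard coefficients on the cluster mean expressions.
    """

    n_tumor: int = 400
    n_normal: int = 100
    n_genes: int = 2000
    n_de_up: int = 150
    n_de_down: int = 150
    de_effect: float = 1.0
    cluster_A_size: int = 12
    cluster_B_size: int = 2
    beta_A: float = 0.8
    beta_B: float = -0.8
    baseline_hazard: float = 0.02
    censor_rate: float = 0.3
    noise_sd: float = 1.0
    cluster_factor_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_tumor, self.n_normal, self.n_genes) <= 0:
            raise ValueError("all sizes must be positive")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must be in [0, 1)")
        if self.cluster_A_size > self.n_de_up:
            raise ValueError("cluster A larger than the up-regulated DE block")
        if self.cluster_B_size > self.n_de_down:
            raise ValueError("cluster B larger than the down-regulated DE block")
        if self.n_de_up + self.n_de_down > self.n_genes:
            raise ValueError("DE gene counts exceed total genes")


@dataclass
class CaseControlSpec:
    """Parameters of the case-control genotype/exposure generator.

    Genotypes are drawn under Hardy-Weinberg with minor-allele frequency
    ``q``; the genotype effect uses dominant coding (carrier of any minor
    allele vs homozygous major). Defaults emulate a hospital case-control
    study of non-smoking women: ~50/50 case fraction, a minor allele near
    5%, a protective genotype effect, and a harmful cooking-fume exposure.
    """

    n_cases: int = 467
    n_controls: int = 395
    q: float = 0.05
    or_genotype: float = 0.6
    exposure_prev: float = 0.3
    or_exposure: float = 1.8
    or_interaction: float = 1.0
    age_mean: float = 56.5
    age_sd: float = 11.5
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.q <= 0.5):
            raise ValueError("q must be in (0, 0.5]")
        for name in ("or_genotype", "or_exposure", "or_interaction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def simulate_expression_cohort(
    spec: CohortSpec,
) -> tuple[ExpressionMatrix, ClinicalTable, dict]:
    """Draw an expression cohort with planted DE genes and survival signal.

    Normal samples follow a per-gene Gaussian baseline; tumors are shifted
    by ``+-de_effect`` on the planted DE genes. The latent per-tumor score
    ``s_i = beta_A * mean_expr(A)_i + beta_B * mean_expr(B)_i`` (centered)
    sets the hazard ``h0 * exp(s_i)`` of an exponential survival time;
    uniform censoring ``U(0, c_max)`` has ``c_max`` solved so the expected
    censored fraction matches ``censor_rate``. Normal samples carry an
    administrative-censoring placeholder so the clinical table covers the
    whole cohort; survival stages operate on the tumor group.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_tumor + spec.n_normal
    genes = _gene_ids(spec.n_genes)
    samples = [f"T{i:04d}" for i in range(spec.n_tumor)] + [
        f"N{i:04d}" for i in range(spec.n_normal)
    ]
    group = np.array(["tumor"] * spec.n_tumor + ["normal"] * spec.n_normal)

    baseline = rng.normal(6.0, 1.0, size=spec.n_genes)
    X = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n)) + baseline[:, None]

    up = np.arange(spec.n_de_up)
    down = np.arange(spec.n_de_up, spec.n_de_up + spec.n_de_down)
    tumor_cols = np.arange(spec.n_tumor)
    X[np.ix_(up, tumor_cols)] += spec.de_effect
    X[np.ix_(down, tumor_cols)] -= spec.de_effect

    # prognostic clusters are co-expressed: a shared per-sample latent
    # factor loads on every cluster gene, as in a pathway module
    idx_a = up[: spec.cluster_A_size]
    idx_b = down[: spec.cluster_B_size]
    factor_a = rng.normal(0.0, spec.cluster_factor_sd, size=n)
    factor_b = rng.normal(0.0, spec.cluster_factor_sd, size=n)
    X[idx_a, :] += factor_a[None, :]
    X[idx_b, :] += factor_b[None, :]

    cluster_a = [genes[i] for i in idx_a]
    cluster_b = [genes[i] for i in idx_b]

    expr = pd.DataFrame(X, index=genes, columns=samples)
    mean_a = expr.loc[cluster_a].iloc[:, tumor_cols].mean(axis=0).to_numpy()
    mean_b = expr.loc[cluster_b].iloc[:, tumor_cols].mean(axis=0).to_numpy()
    s = spec.beta_A * mean_a + spec.beta_B * mean_b
    s_centered = s - s.mean()

    hazard = spec.baseline_hazard * np.exp(s_centered)
    t_event = rng.exponential(1.0 / hazard)

    if spec.censor_rate > 0:
        # P(censored | T=t, c_max) = min(t, c_max) / c_max for U ~ U(0, c_max)
        def censored_fraction(c_max: float) -> float:
            return float(np.mean(np.minimum(t_event, c_max) / c_max)) - spec.censor_rate

        hi = float(t_event.max()) * 10
        c_max = brentq(censored_fraction, 1e-9, hi)
        u = rng.uniform(0, c_max, size=spec.n_tumor)
        time = np.minimum(t_event, u)
        status = (t_event <= u).astype(int)
    else:
        c_max = math.inf
        time = t_event
        status = np.ones(spec.n_tumor, dtype=int)

    follow_up = float(time.max())
    clin = pd.DataFrame(
        {
            "sample_id": samples,
            "time": np.concatenate([time, np.full(spec.n_normal, follow_up)]),
            "status": np.concatenate([status, np.zeros(spec.n_normal, dtype=int)]),
            "group": group,
            "age": np.round(rng.normal(62, 9, size=n), 1),
            "sex": rng.choice(["F", "M"], size=n),
            "stage": rng.choice(["I", "II", "III", "IV"], size=n, p=[0.4, 0.25, 0.25, 0.1]),
        }
    )

    truth = {
        "de_up": [genes[i] for i in up],
        "de_down": [genes[i] for i in down],
        "cluster_A": cluster_a,
        "cluster_B": cluster_b,
        "beta_A": spec.beta_A,
        "beta_B": spec.beta_B,
        "latent_score": dict(zip(samples[: spec.n_tumor], s_centered.tolist())),
        "c_max": c_max,
        "spec": dataclass_to_dict(spec),
    }
    return ExpressionMatrix(expr), ClinicalTable(clin), truth


def dataclass_to_dict(spec) -> dict:
    import dataclasses

    return dataclasses.asdict(spec)


def simulate_mutations(
    n_samples: int,
    mean_mutations: float,
    size_mb: float = 38.0,
    seed: int = 0,
    sample_ids: list[str] | None = None,
) -> MutationTable:
    """Per-sample Poisson(mean) mutation events with MAF-style classes.

    ``size_mb`` is recorded only through downstream TMB division; the table
    itself is event-level. Mean 0 yields an empty (valid) table.
    """
    if mean_mutations < 0:
        raise ValueError("mean_mutations must be >= 0")
    rng = np.random.default_rng(seed)
    if sample_ids is None:
        sample_ids = [f"T{i:04d}" for i in range(n_samples)]
    counts = rng.poisson(mean_mutations, size=n_samples)
    records = []
    classes = np.array(VARIANT_CLASSES)
    # nonsynonymous classes dominate; silent mutations ~20%
    probs = np.where(classes == "Silent", 0.2, 0.8 / (len(classes) - 1))
    for sid, c in zip(sample_ids, counts):
        if c == 0:
            continue
        records.append(
            pd.DataFrame(
                {
                    "sample_id": sid,
                    "gene": [f"MUT{g}" for g in rng.integers(0, 5000, size=c)],
                    "variant_classification": rng.choice(classes, size=c, p=probs),
                }
            )
        )
    if records:
        return MutationTable(pd.concat(records, ignore_index=True))
    return MutationTable(pd.DataFrame(columns=list(MutationTable.COLUMNS)))


def _solve_intercept(spec: CaseControlSpec) -> float:
    """Intercept of the case-status logistic model hitting the target case fraction."""
    q = spec.q
    p_carrier = 1 - (1 - q) ** 2  # dominant coding: CT + TT
    target = spec.n_cases / (spec.n_cases + spec.n_controls)
    bg, be, bge = (
        math.log(spec.or_genotype),
        math.log(spec.or_exposure),
        math.log(spec.or_interaction),
    )
    cells = [
        ((1 - p_carrier) * (1 - spec.exposure_prev), 0.0),
        ((1 - p_carrier) * spec.exposure_prev, be),
        (p_carrier * (1 - spec.exposure_prev), bg),
        (p_carrier * spec.exposure_prev, bg + be + bge),
    ]

    def case_fraction(b0: float) -> float:
        return sum(w / (1 + math.exp(-(b0 + lp))) for w, lp in cells) - target

    try:
        return brentq(case_fraction, -30, 30)
    except ValueError as err:  # pragma: no cover - pathological specs only
        raise ValueError("target case fraction unattainable under the spec") from err


def simulate_case_control(spec: CaseControlSpec) -> tuple[pd.DataFrame, dict]:
    """Draw subjects (genotype, exposure, age, case status) under the spec.

    Genotypes follow Hardy-Weinberg proportions ``(1-q)^2, 2q(1-q), q^2``;
    case status comes from a prospective logistic model whose intercept is
    solved so the expected case fraction equals ``n_cases / n_total``. Age
    is drawn independently of status (a pure covariate).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cases + spec.n_controls
    q = spec.q
    geno = rng.choice(
        ["CC", "CT", "TT"], size=n, p=[(1 - q) ** 2, 2 * q * (1 - q), q**2]
    )
    carrier = (geno != "CC").astype(int)
    exposure = rng.binomial(1, spec.exposure_prev, size=n)
    age = np.round(rng.normal(spec.age_mean, spec.age_sd, size=n), 1)

    b0 = _solve_intercept(spec)
    lp = (
        b0
        + math.log(spec.or_genotype) * carrier
        + math.log(spec.or_exposure) * exposure
        + math.log(spec.or_interaction) * carrier * exposure
    )
    case = rng.binomial(1, 1 / (1 + np.exp(-lp)))

    subjects = pd.DataFrame(
        {
            "subject_id": [f"S{i:05d}" for i in range(n)],
            "genotype": geno,
            "carrier": carrier,
            "exposure": exposure,
            "age": age,
            "case": case,
        }
    )
    truth = {
        "intercept": b0,
        "or_genotype": spec.or_genotype,
        "or_exposure": spec.or_exposure,
        "or_interaction": spec.or_interaction,
        "q": spec.q,
        "spec": dataclass_to_dict(spec),
    }
    return subjects, truth


def make_signature_collection(
    expr: ExpressionMatrix,
    truth: dict | None = None,
    n_sets: int = 28,
    set_size: int = 30,
    seed: int = 0,
) -> GeneSetCollection:
    """Synthetic signature gene sets drawn from a cohort's gene universe.

    Stands in for curated immune-cell / stromal signature collections in
    simulation runs: random sets of ``set_size`` genes, plus (when a truth
    record is supplied) one set enriched in the planted up-regulated genes
    so that enrichment stages have a positive control.
    """
    rng = np.random.default_rng(seed)
    genes = np.array(expr.gene_ids)
    sets: dict[str, tuple[str, list[str]]] = {}
    for i in range(n_sets):
        members = rng.choice(genes, size=min(set_size, len(genes)), replace=False)
        sets[f"signature_{i:02d}"] = ("synthetic random signature", list(members))
    if truth is not None and truth.get("de_up"):
        planted = list(rng.choice(truth["de_up"], size=min(set_size, len(truth["de_up"])), replace=False))
        sets["signature_planted_up"] = ("synthetic set enriched in planted DE genes", planted)
    return GeneSetCollection(sets)
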