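"""Stage orchestration: chain the analysis stages over shared state.

Each stage reads what it needs from the run context (filled by upstream
stages or loaded from configured input paths), writes one or more TSV
outputs into the run directory, and records itself in the JSON manifest.
Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import coexpr, diffexpr, erss, genetics, immune_tmb, riskmodel, survstats, synthdata
from .pipeline_io import (
    Config,
    read_clinical_table,
    read_expression_matrix,
    read_gmt,
    read_mutation_table,
    write_clinical_table,
    write_expression_matrix,
    write_gmt,
    write_mutation_table,
)

STAGE_ORDER = [
    "simulate",
    "de",
    "score",
    "survival",
    "immune",
    "tmb",
    "nomogram",
    "wgcna",
    "snp",
]

__all__ = ["run_pipeline", "STAGE_ORDER"]


def _require(ctx: dict, key: str, stage: str):
    if key not in ctx:
        raise RuntimeError(f"stage {stage!r} needs {key!r}; run its upstream stage or configure an input path")
    return ctx[key]


def _load_inputs(config: Config, ctx: dict) -> None:
    if config.expression_path:
        ctx["expr"] = read_expression_matrix(config.expression_path)
    if config.clinical_path:
        ctx["clin"] = read_clinical_table(config.clinical_path)
    if config.genesets_path:
        ctx["genesets"] = read_gmt(config.genesets_path)
    if config.mutations_path:
        ctx["mutations"] = read_mutation_table(config.mutations_path)
    if config.subjects_path:
        ctx["subjects"] = pd.read_csv(config.subjects_path)


def _stage_simulate(config: Config, ctx: dict, out: Path) -> list[str]:
    spec = synthdata.CohortSpec(seed=config.seed)
    expr, clin, truth = synthdata.simulate_expression_cohort(spec)
    ctx["expr"], ctx["clin"], ctx["truth"] = expr, clin, truth
    mut = synthdata.simulate_mutations(
        spec.n_tumor, mean_mutations=76.0, size_mb=config.callable_mb, seed=config.seed + 1
    )
    ctx["mutations"] = mut
    subjects, cc_truth = synthdata.simulate_case_control(synthdata.CaseControlSpec(seed=config.seed + 2))
    ctx["subjects"] = subjects
    ctx["genesets"] = synthdata.make_signature_collection(expr, truth, seed=config.seed + 3)
    write_expression_matrix(expr, out / "expression.tsv")
    write_clinical_table(clin, out / "clinical.tsv")
    write_mutation_table(mut, out / "mutations.tsv")
    subjects.to_csv(out / "subjects.tsv", sep="\t", index=False)
    write_gmt(ctx["genesets"], out / "signatures.gmt")
    (out / "truth.json").write_text(
        json.dumps({"cohort": truth, "case_control": cc_truth}, indent=1, default=str)
    )
    return ["expression.tsv", "clinical.tsv", "mutations.tsv", "subjects.tsv", "signatures.gmt", "truth.json"]


def _stage_de(config: Config, ctx: dict, out: Path) -> list[str]:
    expr = _require(ctx, "expr", "de")
    clin = _require(ctx, "clin", "de").aligned_to(expr.sample_ids)
    groups = clin.data["group"].to_numpy()
    de = diffexpr.differential_expression(expr, groups, config.de_p_threshold)
    ctx["de"] = de
    de.table.to_csv(out / "de.tsv", sep="\t")
    return ["de.tsv"]


def _stage_score(config: Config, ctx: dict, out: Path) -> list[str]:
    expr = _require(ctx, "expr", "score")
    clin = _require(ctx, "clin", "score")
    candidates = ctx["de"].significant_genes if "de" in ctx else expr.gene_ids
    tumors = [
        s for s in expr.sample_ids
        if "group" not in clin.data.columns or clin.data.loc[s, "group"] == "tumor"
    ]
    sub = expr.subset_genes(candidates)
    sub_t = type(sub)(sub.values[tumors])
    screen = erss.univariate_cox_screen(sub_t, clin.aligned_to(tumors), config.screen_alpha, config.tie_method)
    score = erss.compute_erss(sub_t, (screen.cluster_a, screen.cluster_b))
    ctx["screen"], ctx["score"], ctx["score_samples"] = screen, score, tumors
    screen.table.to_csv(out / "cox_screen.tsv", sep="\t")
    score.to_frame().to_csv(out / "erss.tsv", sep="\t", index_label="sample_id")
    signature = {
        "cluster_A": score.cluster_a,
        "cluster_B": score.cluster_b,
        "loadings": {k: v.to_dict() for k, v in score.loadings.items()},
        "signs": score.signs,
        "mode": score.mode,
    }
    (out / "signature.json").write_text(json.dumps(signature, indent=1))
    return ["cox_screen.tsv", "erss.tsv", "signature.json"]


def _stage_survival(config: Config, ctx: dict, out: Path) -> list[str]:
    score = _require(ctx, "score", "survival")
    clin = _require(ctx, "clin", "survival").aligned_to(list(score.erss.index))
    t, s = clin.time.to_numpy(), clin.status.to_numpy()
    cut = survstats.optimal_cutpoint(score.erss.to_numpy(), t, s, config.cutpoint_minprop)
    score.cutpoint = cut.threshold
    groups = np.where(score.erss.to_numpy() > cut.threshold, "high", "low")
    chi2, df, p = survstats.logrank_test(t, s, groups)
    curves = survstats.km_estimate(t, s, groups)
    ctx["erss_groups"] = pd.Series(groups, index=score.erss.index)
    rows = []
    for g, c in curves.items():
        rows.append(pd.DataFrame({"group": g, "time": c.times, "survival": c.survival}))
    pd.concat(rows, ignore_index=True).to_csv(out / "km_curves.tsv", sep="\t", index=False)
    report = pd.DataFrame(
        [
            {
                "cutpoint": cut.threshold,
                "cutpoint_statistic": cut.statistic,
                "n_low": cut.n_low,
                "n_high": cut.n_high,
                "logrank_chi2": chi2,
                "logrank_df": df,
                "logrank_p": p,
                "p_selection_biased": True,
                "time_unit": config.time_unit,
            }
        ]
    )
    report.to_csv(out / "survival_report.tsv", sep="\t", index=False)
    aucs = {}
    for h in config.horizons:
        try:
            aucs[h] = survstats.time_dependent_auc(score.erss.to_numpy(), t, s, h)
        except ValueError:
            aucs[h] = np.nan
    pd.DataFrame([{"horizon": h, "auc": a} for h, a in aucs.items()]).to_csv(
        out / "time_dependent_auc.tsv", sep="\t", index=False
    )
    return ["km_curves.tsv", "survival_report.tsv", "time_dependent_auc.tsv"]


def _stage_immune(config: Config, ctx: dict, out: Path) -> list[str]:
    expr = _require(ctx, "expr", "immune")
    sets = _require(ctx, "genesets", "immune")
    mat = immune_tmb.ssgsea_scores(expr, sets, config.ssgsea_exponent, config.ssgsea_normalize)
    ctx["ssgsea"] = mat
    mat.scores.to_csv(out / "ssgsea_scores.tsv", sep="\t", index_label="signature")
    names = sets.names()
    stromal, immune_sig = sets.genes(names[0]), sets.genes(names[1 % len(names)])
    est = immune_tmb.estimate_scores(expr, stromal, immune_sig)
    ctx["estimate"] = est
    est.table.to_csv(out / "estimate_scores.tsv", sep="\t", index_label="sample_id")
    return ["ssgsea_scores.tsv", "estimate_scores.tsv"]


def _stage_tmb(config: Config, ctx: dict, out: Path) -> list[str]:
    mut = _require(ctx, "mutations", "tmb")
    if "score" in ctx:
        samples = list(ctx["score"].erss.index)
    else:
        samples = sorted(mut.data["sample_id"].unique())
    res = immune_tmb.compute_tmb(mut, samples, config.callable_mb, config.tmb_counted_classes)
    ctx["tmb"] = res
    res.table.to_csv(out / "tmb.tsv", sep="\t")
    files = ["tmb.tsv"]
    if "erss_groups" in ctx and "clin" in ctx:
        strata = immune_tmb.composite_strata(
            ctx["erss_groups"], res.table["tmb_group"], ctx["clin"].aligned_to(samples)
        )
        pd.DataFrame(
            [{"logrank_chi2": strata["chi2"], "df": strata["df"], "p": strata["p"]}]
        ).to_csv(out / "composite_strata.tsv", sep="\t", index=False)
        files.append("composite_strata.tsv")
    return files


def _stage_nomogram(config: Config, ctx: dict, out: Path) -> list[str]:
    score = _require(ctx, "score", "nomogram")
    clin = _require(ctx, "clin", "nomogram").aligned_to(list(score.erss.index))
    stage_code = clin.data["stage"].map({"I": 1, "II": 2, "III": 3, "IV": 4}) if "stage" in clin.data.columns else None
    X = pd.DataFrame({"erss": score.erss})
    if "age" in clin.data.columns:
        X["age"] = clin.data["age"].astype(float)
    if stage_code is not None:
        X["stage"] = stage_code.astype(float)
    t, s = clin.time.to_numpy(), clin.status.to_numpy()
    model = riskmodel.fit_risk_model(X, t, s)
    ctx["riskmodel"] = model
    model.points.to_csv(out / "nomogram_points.tsv", sep="\t")
    model.cox.summary.to_csv(out / "nomogram_cox.tsv", sep="\t")
    conc = riskmodel.concordance(
        X.to_numpy() @ model.cox.params.to_numpy(), t, s, config.bootstrap_b, config.seed
    )
    preds = {}
    for h in config.horizons:
        preds[f"S({h})"] = riskmodel.predict_survival(model, X, h)
    pd.DataFrame(preds, index=X.index).to_csv(out / "nomogram_predictions.tsv", sep="\t", index_label="sample_id")
    mid = config.horizons[len(config.horizons) // 2]
    calib = riskmodel.calibration(model, X, t, s, mid, n_groups=4, bootstrap_b=min(config.bootstrap_b, 50), seed=config.seed)
    calib.to_csv(out / "calibration.tsv", sep="\t")
    dca = riskmodel.decision_curve(model, X, t, s, mid)
    dca.to_csv(out / "decision_curve.tsv", sep="\t", index=False)
    pd.DataFrame([conc]).to_csv(out / "c_index.tsv", sep="\t", index=False)
    return ["nomogram_points.tsv", "nomogram_cox.tsv", "nomogram_predictions.tsv", "calibration.tsv", "decision_curve.tsv", "c_index.tsv"]


def _stage_wgcna(config: Config, ctx: dict, out: Path) -> list[str]:
    expr = _require(ctx, "expr", "wgcna")
    clin = _require(ctx, "clin", "wgcna")
    # top-variance genes keep the network tractable
    var = expr.values.var(axis=1).sort_values(ascending=False)
    top = list(var.index[: min(500, len(var))])
    sub = expr.subset_genes(top)
    beta, fit = coexpr.pick_soft_threshold(sub, rsq_target=config.wgcna_rsq_target)
    adj = coexpr.adjacency_matrix(sub, beta)
    tom = coexpr.tom_similarity(adj)
    assignment = coexpr.detect_modules(
        tom, sub, min_size=config.wgcna_min_module_size, merge_height=config.wgcna_merge_height
    )
    trait = (clin.aligned_to(sub.sample_ids).data["group"] == "tumor").astype(float).to_numpy()
    mt = coexpr.module_trait_correlation(assignment, trait)
    fit.to_csv(out / "soft_threshold.tsv", sep="\t")
    assignment.modules.rename("module").to_csv(out / "modules.tsv", sep="\t", index_label="gene_id")
    assignment.eigengenes.to_csv(out / "eigengenes.tsv", sep="\t", index_label="sample_id")
    mt.to_csv(out / "module_trait.tsv", sep="\t")
    best = mt["r"].abs().idxmax()
    hubs = coexpr.hub_ranking(assignment, sub, best)
    hubs.to_csv(out / "hub_genes.tsv", sep="\t", index_label="gene_id")
    ctx["wgcna"] = {"beta": beta, "assignment": assignment, "module_trait": mt}
    return ["soft_threshold.tsv", "modules.tsv", "eigengenes.tsv", "module_trait.tsv", "hub_genes.tsv"]


def _stage_snp(config: Config, ctx: dict, out: Path) -> list[str]:
    subjects = _require(ctx, "subjects", "snp")
    controls = subjects[subjects["case"] == 0]
    geno = controls["genotype"].value_counts()
    chi2, df, p_hwe = genetics.hwe_test(
        int(geno.get("CC", 0)), int(geno.get("CT", 0)), int(geno.get("TT", 0))
    )
    counts = genetics.GenotypeCounts(
        case_cc=int(((subjects["case"] == 1) & (subjects["carrier"] == 0)).sum()),
        case_carrier=int(((subjects["case"] == 1) & (subjects["carrier"] == 1)).sum()),
        control_cc=int(((subjects["case"] == 0) & (subjects["carrier"] == 0)).sum()),
        control_carrier=int(((subjects["case"] == 0) & (subjects["carrier"] == 1)).sum()),
    )
    marginal = genetics.odds_ratio(counts)
    df_fit = subjects.copy()
    df_fit["gxe"] = df_fit["carrier"] * df_fit["exposure"]
    fit = genetics.logistic_fit(df_fit, "case", ["carrier", "exposure", "gxe", "age"])
    inter = genetics.additive_interaction(fit, "carrier", "exposure", "gxe")
    mult = genetics.multiplicative_interaction(fit, "gxe")
    cross = genetics.crossover_analysis(df_fit, protective_genotype=1)
    rows = [
        {"estimate": "hwe_controls_chi2", "value": chi2, "ci_low": np.nan, "ci_high": np.nan, "p": p_hwe},
        {"estimate": "or_genotype", "value": marginal.odds_ratio, "ci_low": marginal.ci_low, "ci_high": marginal.ci_high, "p": marginal.p},
        {"estimate": "or_crossover_genotype_only", "value": cross["genotype_only"].odds_ratio, "ci_low": cross["genotype_only"].ci_low, "ci_high": cross["genotype_only"].ci_high, "p": cross["genotype_only"].p},
        {"estimate": "or_crossover_exposure_only", "value": cross["exposure_only"].odds_ratio, "ci_low": cross["exposure_only"].ci_low, "ci_high": cross["exposure_only"].ci_high, "p": cross["exposure_only"].p},
        {"estimate": "or_crossover_both", "value": cross["both"].odds_ratio, "ci_low": cross["both"].ci_low, "ci_high": cross["both"].ci_high, "p": cross["both"].p},
        {"estimate": "reri", "value": inter.reri, "ci_low": inter.reri_ci[0], "ci_high": inter.reri_ci[1], "p": np.nan},
        {"estimate": "ap", "value": inter.ap, "ci_low": inter.ap_ci[0], "ci_high": inter.ap_ci[1], "p": np.nan},
        {"estimate": "synergy_index", "value": inter.s, "ci_low": inter.s_ci[0] if inter.s_ci else np.nan, "ci_high": inter.s_ci[1] if inter.s_ci else np.nan, "p": np.nan},
        {"estimate": "or_multiplicative_interaction", "value": mult.odds_ratio, "ci_low": mult.ci_low, "ci_high": mult.ci_high, "p": mult.p},
    ]
    pd.DataFrame(rows).to_csv(out / "snp_estimates.tsv", sep="\t", index=False)
    ctx["snp"] = rows
    return ["snp_estimates.tsv"]


_STAGES = {
    "simulate": _stage_simulate,
    "de": _stage_de,
    "score": _stage_score,
    "survival": _stage_survival,
    "immune": _stage_immune,
    "tmb": _stage_tmb,
    "nomogram": _stage_nomogram,
    "wgcna": _stage_wgcna,
    "snp": _stage_snp,
}


def run_pipeline(config: Config, out_dir: str | Path) -> dict:
    """Execute the configured stages in dependency order.

    Writes one or more TSVs per stage plus ``manifest.json`` recording the
    seed, parameters and produced files. Returns the run context.
    """
    unknown = set(config.stages) - set(_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ctx: dict = {}
    _load_inputs(config, ctx)
    manifest = {"seed": config.seed, "parameters": config.to_dict(), "stages": {}}
    for stage in STAGE_ORDER:
        if stage not in config.stages:
            continue
        files = _STAGES[stage](config, ctx, out)
        manifest["stages"][stage] = files
    import erss_pipeline

    manifest["version"] = getattr(erss_pipeline, "__version__", "unknown")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return ctx
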