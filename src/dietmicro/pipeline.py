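"""End-to-end pipeline: standardize -> scores -> microbiome prep -> signature
-> associations -> pathway screen, one tabular artefact per stage plus a
machine-readable run manifest."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .associations import (
    bh_fdr,
    fit_adjusted_linear,
    fit_twin_mixed,
    pathway_screen,
    percent_diff_per_sd,
    quintile_backtransform,
)
from .config import PipelineConfig
from .ffq import ENERGY_COL, ID_COL, average_repeat_records, load_serving_map, standardize_servings
from .io import TableBundle, read_tables, write_table
from .microbiome import alpha_diversity, clr_transform, depth_filter, genus_columns, prevalence_filter
from .scores import average_biomarkers_per_period, load_index_definitions, score_index
from .signature import correlate_components, fit_profile, loo_training_scores, score_samples, split_train_test

logger = logging.getLogger(__name__)

BIOMARKER_OUTCOMES = ("log_insulin", "log_glucose", "log_homa_ir", "log_crp")
ALPHA_OUTCOMES = ("log_shannon", "log_pielou")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def stage_standardize(bundle: TableBundle, config: PipelineConfig) -> pd.DataFrame:
    smap = load_serving_map(config.serving_map)
    averaged = average_repeat_records(bundle.ffq)
    intake = standardize_servings(averaged, smap)
    logger.info("standardize: %d records -> %d participants, %d subgroups",
                len(bundle.ffq), len(intake), smap.n_subgroups)
    return intake


def stage_scores(intake: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    defs = load_index_definitions(config.index_definitions)
    out = None
    for name in sorted(defs):
        scored = score_index(intake, defs[name], n_quintiles=config.quintile_count)
        out = scored if out is None else out.merge(scored, on=ID_COL)
    logger.info("scores: %d participants x %d indices", len(out), len(defs))
    return out


def stage_microbiome(genus: pd.DataFrame, config: PipelineConfig):
    qc = depth_filter(genus, config.depth_threshold)
    alpha = alpha_diversity(qc)
    prevalent = prevalence_filter(qc, config.prevalence_threshold)
    clr = clr_transform(prevalent)
    logger.info("microbiome: %d/%d samples pass depth QC; %d/%d genera prevalent",
                len(qc), len(genus), len(genus_columns(prevalent)), len(genus_columns(genus)))
    return alpha, clr


def stage_signature(clr: pd.DataFrame, dietary_scores: pd.DataFrame,
                    covariates: pd.DataFrame, config: PipelineConfig):
    """Fit one elastic-net profile per index and score every sample.

    Test-set participants are scored by the full training-set model; training
    participants get leave-one-out scores.  The pooled score column is what
    the downstream biomarker models consume.
    """
    indices = sorted(c.removesuffix("_adj") for c in dietary_scores.columns if c.endswith("_adj"))
    X = clr.set_index(ID_COL)
    ids = sorted(set(X.index) & set(dietary_scores[ID_COL]))
    X = X.loc[ids]
    pair_ids = covariates.set_index(ID_COL)["pair_id"] if config.pair_cv_folds else None
    scores_ix = dietary_scores.set_index(ID_COL)
    out = pd.DataFrame({ID_COL: ids})
    profiles = {}
    for name in indices:
        y = scores_ix.loc[ids, f"{name}_adj"]
        train_ids, test_ids = split_train_test(ids, config.train_fraction, config.seed)
        profile = fit_profile(
            X.loc[train_ids], y.loc[train_ids], index_name=name,
            n_folds=config.cv_folds, seed=config.seed,
            pair_ids=pair_ids.loc[train_ids] if pair_ids is not None else None,
        )
        test_scores = score_samples(profile, X.loc[test_ids])
        loo_scores = loo_training_scores(X.loc[train_ids], y.loc[train_ids], profile)
        pooled = pd.concat([loo_scores, test_scores])
        out[f"{name}_mb_score"] = pooled.reindex(ids).to_numpy()
        out[f"{name}_partition"] = ["train_loo" if i in set(train_ids) else "test" for i in ids]
        profiles[name] = profile
    return out, profiles


def stage_correlations(intake: pd.DataFrame, dietary_scores: pd.DataFrame, clr: pd.DataFrame,
                       mb_scores: pd.DataFrame, profiles: dict, config: PipelineConfig) -> dict:
    """Plot-ready Spearman matrices per index: profile score, dietary score,
    selected genera (CLR) and the index's food components (servings/day)."""
    from .ffq import subgroup_col
    from .scores import load_index_definitions

    defs = load_index_definitions(config.index_definitions)
    out = {}
    for name, profile in profiles.items():
        ids = mb_scores[ID_COL]
        block = pd.DataFrame(index=ids)
        block[f"{name}_mb_score"] = mb_scores.set_index(ID_COL)[f"{name}_mb_score"]
        block[f"{name}_score"] = dietary_scores.set_index(ID_COL).reindex(ids)[f"{name}_adj"].to_numpy()
        clr_ix = clr.set_index(ID_COL).reindex(ids)
        for genus in profile.selected.index:
            sign = "+" if profile.selected[genus] > 0 else "-"
            block[f"{sign}{genus}"] = clr_ix[genus].to_numpy()
        intake_ix = intake.set_index(ID_COL).reindex(ids)
        for sg, weight in defs[name].weights.items():
            sign = "+" if weight > 0 else "-"
            block[f"{subgroup_col(sg)}{sign}"] = intake_ix[subgroup_col(sg)].to_numpy()
        out[name] = correlate_components(block)
    return out


def _assemble(bundle: TableBundle, dietary_scores: pd.DataFrame, alpha: pd.DataFrame,
              mb_scores: pd.DataFrame) -> pd.DataFrame:
    """Merge the participant-level analysis frame (one period of biomarkers)."""
    bio = average_biomarkers_per_period(bundle.biomarkers)
    periods = sorted(bio["period"].unique())
    bio = bio[bio["period"] == periods[0]].drop(columns="period")
    with np.errstate(divide="ignore", invalid="ignore"):
        for col, out in (("insulin", "log_insulin"), ("glucose", "log_glucose"),
                         ("homa_ir", "log_homa_ir"), ("crp", "log_crp")):
            bio[out] = np.where(bio[col] > 0, np.log(bio[col]), np.nan)
    data = bundle.covariates.merge(bio, on=ID_COL, how="left")
    data = data.merge(dietary_scores, on=ID_COL, how="left")
    data = data.merge(alpha, on=ID_COL, how="left")
    data = data.merge(mb_scores, on=ID_COL, how="left")
    return data


def stage_associations(data: pd.DataFrame, config: PipelineConfig):
    """Biomarker and alpha-diversity association battery.

    Exposures: the energy-adjusted dietary scores and the microbiome profile
    scores, each standardized to SD units.  Models: base covariate set, base
    + BMI, and the twin-pair mixed model (random intercept per pair, zygosity
    added).  BH-FDR is applied within each exposure x model family across
    its outcomes.
    """
    indices = sorted(c.removesuffix("_adj") for c in data.columns if c.endswith("_adj"))
    exposures = [f"{n}_adj" for n in indices] + [f"{n}_mb_score" for n in indices]
    covs = list(config.covariate_list)
    rows = []
    for exposure in exposures:
        for tag, include_bmi in (("base", False), ("bmi", True)):
            family = []
            for outcome in BIOMARKER_OUTCOMES + ALPHA_OUTCOMES:
                res = fit_adjusted_linear(data, outcome, exposure, covs,
                                          include_bmi=include_bmi, standardize_exposure=True)
                family.append(res)
            fdr = bh_fdr([r.p for r in family])
            for r, q in zip(family, fdr):
                r.fdr_p = float(q)
                rows.append(r.as_row())
        for outcome in BIOMARKER_OUTCOMES + ALPHA_OUTCOMES:
            res = fit_twin_mixed(data, outcome, exposure, covs, standardize_exposure=True)
            rows.append(res.as_row())
    assoc = pd.DataFrame(rows)

    # percent difference in alpha diversity per SD, and quintile back-transform
    alpha_rows = []
    quintile_frames = []
    for name in indices:
        for outcome in ALPHA_OUTCOMES:
            for tag, include_bmi in (("base", False), ("bmi", True)):
                res = fit_adjusted_linear(data, outcome, f"{name}_adj", covs,
                                          include_bmi=include_bmi, standardize_exposure=True)
                pct, lo, hi = percent_diff_per_sd(res.beta, res.ci_low, res.ci_high)
                alpha_rows.append({"index": name, "outcome": outcome, "model": tag,
                                   "percent_diff_per_sd": pct, "ci_low": lo, "ci_high": hi,
                                   "p": res.p, "n": res.n})
                qt = quintile_backtransform(data, outcome, f"{name}_q", covs, include_bmi=include_bmi)
                qt.insert(0, "index", name)
                qt.insert(1, "outcome", outcome)
                qt.insert(2, "model", tag)
                quintile_frames.append(qt)
    return assoc, pd.DataFrame(alpha_rows), pd.concat(quintile_frames, ignore_index=True)


def stage_pathways(pathways: pd.DataFrame, data: pd.DataFrame, config: PipelineConfig):
    indices = sorted(c.removesuffix("_adj") for c in data.columns if c.endswith("_adj"))
    results = {}
    heatmaps = {}
    for name in indices:
        res, heat = pathway_screen(
            pathways, data, exposure=f"{name}_z", covariates=list(config.covariate_list),
            quintile_col=f"{name}_q", fdr_cutoff=config.fdr_cutoff,
        )
        res.insert(0, "index", name)
        results[name] = res
        heatmaps[name] = heat
    return results, heatmaps


def run_pipeline(config: PipelineConfig, workdir: str | Path = ".", outdir: str | Path = "results") -> dict:
    """Execute all stages in order, writing one artefact per stage.

    Re-running with the same config and seed reproduces every numeric output
    exactly.  Any stage failure aborts with the stage name and cause.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"package_version": __version__, "config": config.to_dict(), "stages": {}}

    def run_stage(name, fn):
        try:
            return fn()
        except Exception as err:  # noqa: BLE001 - re-raised with stage context
            raise StageError(name, err) from err

    bundle = run_stage("read_tables", lambda: read_tables(config, workdir))

    intake = run_stage("standardize", lambda: stage_standardize(bundle, config))
    write_table(intake, outdir / "intake.tsv")
    manifest["stages"]["standardize"] = {"rows_in": len(bundle.ffq), "rows_out": len(intake)}

    dietary_scores = run_stage("scores", lambda: stage_scores(intake, config))
    write_table(dietary_scores, outdir / "dietary_scores.tsv")
    manifest["stages"]["scores"] = {"rows_out": len(dietary_scores)}

    alpha, clr = run_stage("microbiome", lambda: stage_microbiome(bundle.genus, config))
    write_table(alpha, outdir / "alpha_diversity.tsv")
    write_table(clr, outdir / "clr_genus.tsv")
    manifest["stages"]["microbiome"] = {
        "samples_in": len(bundle.genus),
        "samples_qc": len(alpha),
        "samples_dropped": len(bundle.genus) - len(alpha),
        "genera_retained": len(genus_columns(clr)),
    }

    mb_scores, profiles = run_stage(
        "signature", lambda: stage_signature(clr, dietary_scores, bundle.covariates, config)
    )
    write_table(mb_scores, outdir / "microbiome_scores.tsv")
    for name, profile in profiles.items():
        profile.save(outdir / f"profile_{name}")
    manifest["stages"]["signature"] = {
        name: {"selected_genera": int((p.coef != 0).sum()), "alpha": p.alpha, "l1_ratio": p.l1_ratio}
        for name, p in profiles.items()
    }

    correlations = run_stage(
        "correlations",
        lambda: stage_correlations(intake, dietary_scores, clr, mb_scores, profiles, config),
    )
    for name, matrix in correlations.items():
        matrix.to_csv(outdir / f"component_correlations_{name}.tsv", sep="\t")
    manifest["stages"]["correlations"] = {name: len(m) for name, m in correlations.items()}

    data = _assemble(bundle, dietary_scores, alpha, mb_scores)
    assoc, alpha_assoc, quintiles = run_stage("associations", lambda: stage_associations(data, config))
    write_table(assoc, outdir / "associations.tsv")
    write_table(alpha_assoc, outdir / "alpha_percent_diff.tsv")
    write_table(quintiles, outdir / "alpha_quintiles.tsv")
    manifest["stages"]["associations"] = {"models": len(assoc)}

    pw_results, heatmaps = run_stage("pathways", lambda: stage_pathways(bundle.pathways, data, config))
    for name, res in pw_results.items():
        write_table(res, outdir / f"pathway_screen_{name}.tsv")
        heat = heatmaps[name]
        if not heat.empty:
            heat.to_csv(outdir / f"pathway_heatmap_{name}.tsv", sep="\t")
        manifest["stages"].setdefault("pathways", {})[name] = {
            "tested": int((~res["excluded"]).sum()),
            "excluded": int(res["excluded"].sum()),
            "significant": int((res["fdr_p"] < config.fdr_cutoff).sum()),
        }

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
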