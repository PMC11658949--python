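"""Synthetic twin cohort with planted diet-microbiome-biomarker structure.

The generator emulates the statistical shape of a twin-registry study: a
131-item FFQ in servings/week with total energy, 143 prevalent genera with
compositional count structure (log-normal latent abundances, multinomial
counts at a log-normal sequencing depth), biomarkers that are noisy
log-linear functions of the dietary scores, zero-inflated predicted-pathway
abundances, and monozygotic/dizygotic within-pair correlation induced by
shared latent factors.  Every cohort ships with its ground truth (planted
signal features and the true per-participant dietary scores) so parameter
recovery is testable; the truth never enters the analysis inputs.

One global seed drives independent per-stage substreams, so regenerating one
table does not perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ffq import ENERGY_COL, ID_COL, RECORD_COL, item_col, load_serving_map
from .microbiome import genus_col
from .scores import load_index_definitions

# substream keys
_STRUCTURE, _FFQ, _MICROBIOME, _BIOMARKERS, _PATHWAYS, _COVARIATES = range(6)


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stage])


@dataclass
class GeneratorParams:
    """Study conditions for the synthetic cohort.

    Effects are on the scale where they act: genus effects in CLR units per
    SD of the true dietary score, biomarker effects on the natural-log scale
    per SD, pathway effects on the log-abundance scale per SD.
    """

    n_pairs: int = 500
    mz_fraction: float = 0.5
    n_items: int = 131
    n_genera: int = 143
    n_signal_genera: int = 10          # per dietary index
    genus_effect: float = 0.5          # CLR units per SD of true score
    insulin_effect: float = 0.10       # log uIU/ml per SD of EDIH
    glucose_effect: float = 0.02       # log mmol/L per SD of EDIH
    crp_effect: float = 0.10           # log mg/L per SD of EDIP
    insulin_noise_sd: float = 0.30
    glucose_noise_sd: float = 0.10
    crp_noise_sd: float = 0.50
    within_pair_corr_mz: float = 0.5
    within_pair_corr_dz: float = 0.25
    mean_depth: float = 30_000.0
    depth_dispersion: float = 0.3      # sigma of the log-normal depth
    low_depth_fraction: float = 0.05   # samples planted below the QC threshold
    depth_threshold: int = 10_000
    n_pathways: int = 200
    n_zero_inflated: int = 20          # pathways planted with >90% zeros
    pathway_zero_rate: float = 0.2     # mean zero rate of ordinary pathways
    n_signal_pathways: int = 10        # per direction per index
    pathway_effect: float = 0.4
    item_effect: float = 0.4           # latent diet loading on log servings
    item_noise_sd: float = 0.6
    genus_noise_sd: float = 0.8
    biomarker_pair_icc: float = 0.3    # pair-shared share of biomarker noise
    repeat_record_prob: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_pairs", "n_items", "n_genera", "n_pathways"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("mz_fraction", "low_depth_fraction", "within_pair_corr_mz",
                     "within_pair_corr_dz", "biomarker_pair_icc", "repeat_record_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.within_pair_corr_mz < self.within_pair_corr_dz:
            raise ValueError("MZ within-pair correlation must be >= DZ correlation")


@dataclass
class GroundTruth:
    """Planted structure of one generated cohort."""

    scores: pd.DataFrame    # participant_id, <index>_true, <index>_true_z
    features: pd.DataFrame  # feature_type, feature, index, effect

    def true_z(self, index_name: str) -> pd.Series:
        return pd.Series(
            self.scores[f"{index_name}_true_z"].to_numpy(),
            index=self.scores[ID_COL].to_numpy(),
        )

    def signal_features(self, feature_type: str, index_name: str) -> pd.DataFrame:
        f = self.features
        return f[(f["feature_type"] == feature_type) & (f["index"] == index_name)]


def generate_twin_structure(params: GeneratorParams) -> pd.DataFrame:
    """Pairs, zygosity and sex (co-twins share sex and age)."""
    rng = _rng(params.seed, _STRUCTURE)
    n = 2 * params.n_pairs
    pids = [f"P{i:05d}" for i in range(1, n + 1)]
    pair_ids = np.repeat([f"T{i:04d}" for i in range(1, params.n_pairs + 1)], 2)
    zyg = np.repeat(np.where(rng.random(params.n_pairs) < params.mz_fraction, "MZ", "DZ"), 2)
    sex = np.repeat(np.where(rng.random(params.n_pairs) < 0.9, "F", "M"), 2)
    age = np.repeat(np.clip(rng.normal(58, 9, params.n_pairs), 25, 90), 2)
    return pd.DataFrame({ID_COL: pids, "pair_id": pair_ids, "zygosity": zyg, "sex": sex, "age": age})


def _twin_latents(rng, structure: pd.DataFrame, params: GeneratorParams, between_corr: float = 0.5):
    """Two per-participant latent diet factors with within-pair correlation.

    z = sqrt(rho) * pair-shared + sqrt(1-rho) * individual, rho by zygosity;
    the two indices' latents share ``between_corr`` at both levels.
    """
    n_pairs = params.n_pairs
    cov = np.array([[1.0, between_corr], [between_corr, 1.0]])
    chol = np.linalg.cholesky(cov)
    pair_f = rng.standard_normal((n_pairs, 2)) @ chol.T
    ind_f = rng.standard_normal((2 * n_pairs, 2)) @ chol.T
    rho = np.where(
        structure["zygosity"].to_numpy()[::2] == "MZ",
        params.within_pair_corr_mz,
        params.within_pair_corr_dz,
    )
    rho_p = np.repeat(rho, 2)[:, None]
    return np.sqrt(rho_p) * np.repeat(pair_f, 2, axis=0) + np.sqrt(1.0 - rho_p) * ind_f


def _item_loadings(params: GeneratorParams):
    """Signed item loadings implied by the packaged map and index weights.

    The planted dietary score IS the weighted subgroup sum the scoring
    pipeline computes, so the effective weight of item i for an index is
    w(subgroup(i)) * conversion(i) / 7.
    """
    smap = load_serving_map()
    defs = load_index_definitions()
    table = smap.table.set_index("item_id")
    eff = {}
    for name, defn in defs.items():
        w = np.zeros(params.n_items)
        for i in range(1, params.n_items + 1):
            if i not in table.index:
                continue
            sg = int(table.loc[i, "subgroup_id"])
            if sg in defn.weights.index:
                w[i - 1] = float(defn.weights[sg]) * float(table.loc[i, "conversion_factor"]) / 7.0
        eff[name] = w
    return eff


def generate_ffq(params: GeneratorParams, structure: pd.DataFrame | None = None):
    """FFQ records (servings/week + energy) and the true dietary scores.

    Item log-intakes load on two twin-correlated latent diet factors with the
    sign of the item's index weight; the true score of each index is the
    planted weighted combination evaluated on the participant's record-mean
    intakes, which is exactly the raw score the pipeline recomputes.
    """
    if structure is None:
        structure = generate_twin_structure(params)
    rng = _rng(params.seed, _FFQ)
    n = len(structure)
    z = _twin_latents(rng, structure, params)
    eff = _item_loadings(params)
    names = sorted(eff)
    sign = {name: np.sign(eff[name]) for name in names}

    mu = rng.normal(np.log(1.5), 0.5, params.n_items)
    load = params.item_effect * (sign[names[0]][None, :] * z[:, [0]] + sign[names[1]][None, :] * z[:, [1]])
    log_s = mu[None, :] + load + rng.normal(0, params.item_noise_sd, (n, params.n_items))
    servings = np.exp(log_s)  # weekly servings, participant-level mean intake

    n_rec = 1 + (rng.random(n) < params.repeat_record_prob).astype(int)
    rows = []
    mean_serv = np.zeros_like(servings)
    daily_total = servings.sum(axis=1) / 7.0
    energy = np.clip(600.0 + 55.0 * daily_total + rng.normal(0, 120, n), 600.0, None)
    for j in range(n):
        recs = []
        for r in range(n_rec[j]):
            jitter = np.exp(rng.normal(0, 0.1, params.n_items))
            recs.append(servings[j] * jitter)
        recs = np.array(recs)
        mean_serv[j] = recs.mean(axis=0)
        for r in range(n_rec[j]):
            rows.append((structure[ID_COL].iloc[j], r + 1, recs[r], energy[j]))

    item_mat = np.array([r[2] for r in rows])
    cols = {ID_COL: [r[0] for r in rows], RECORD_COL: [r[1] for r in rows]}
    cols.update({item_col(i + 1): item_mat[:, i] for i in range(params.n_items)})
    cols[ENERGY_COL] = [r[3] for r in rows]
    ffq = pd.DataFrame(cols)

    truth = pd.DataFrame({ID_COL: structure[ID_COL].to_numpy()})
    for name in names:
        t = mean_serv @ eff[name]
        truth[f"{name}_true"] = t
        truth[f"{name}_true_z"] = (t - t.mean()) / t.std(ddof=1)
    return ffq, truth


def generate_microbiome(params: GeneratorParams, truth: pd.DataFrame, structure: pd.DataFrame):
    """Genus count table and the planted genus signal list.

    Latent per-sample log-abundances get the configured CLR-scale effect of
    the standardized true score for each planted genus; counts are multinomial
    at a log-normal depth, with ``low_depth_fraction`` of samples planted
    below the QC threshold.
    """
    rng = _rng(params.seed, _MICROBIOME)
    n = len(truth)
    G = params.n_genera
    names = [c.removesuffix("_true_z") for c in truth.columns if c.endswith("_true_z")]
    m = rng.normal(0.0, 1.2, G)

    chosen = rng.choice(G, size=params.n_signal_genera * len(names), replace=False)
    effects = np.zeros((G, len(names)))
    feature_rows = []
    for k, name in enumerate(names):
        sel = chosen[k * params.n_signal_genera:(k + 1) * params.n_signal_genera]
        for j, g in enumerate(sel):
            e = params.genus_effect if j % 2 == 0 else -params.genus_effect
            effects[g, k] = e
            feature_rows.append({"feature_type": "genus", "feature": genus_col(g + 1),
                                 "index": name, "effect": e})

    zt = truth[[f"{nm}_true_z" for nm in names]].to_numpy()
    b = rng.normal(0.0, 0.3, G)
    u_pair = np.repeat(rng.standard_normal(params.n_pairs), 2)
    log_a = (
        m[None, :]
        + zt @ effects.T
        + u_pair[:, None] * b[None, :]
        + rng.normal(0, params.genus_noise_sd, (n, G))
    )
    p = np.exp(log_a - log_a.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)

    low = rng.random(n) < params.low_depth_fraction
    depths = np.where(
        low,
        rng.integers(3000, params.depth_threshold, n),
        np.maximum(
            np.round(np.exp(rng.normal(np.log(params.mean_depth), params.depth_dispersion, n))),
            params.depth_threshold,
        ),
    ).astype(int)

    counts = np.vstack([rng.multinomial(depths[j], p[j]) for j in range(n)])
    cols = {ID_COL: truth[ID_COL].to_numpy()}
    cols.update({genus_col(g + 1): counts[:, g] for g in range(G)})
    return pd.DataFrame(cols), pd.DataFrame(feature_rows)


def generate_biomarkers(params: GeneratorParams, truth: pd.DataFrame, structure: pd.DataFrame):
    """Fasting insulin, glucose and CRP as exp(linear predictor + noise).

    Insulin and glucose respond to the EDIH-like score, CRP to the EDIP-like
    score; noise has a pair-shared component (``biomarker_pair_icc``) and a
    per-record measurement jitter proportional to the analyte noise SD, so a
    zero noise SD makes the analyte deterministic.
    """
    rng = _rng(params.seed, _BIOMARKERS)
    n = len(truth)
    names = sorted(c.removesuffix("_true_z") for c in truth.columns if c.endswith("_true_z"))
    z1 = truth[f"{names[0]}_true_z"].to_numpy()  # EDIH-like (alphabetical first)
    z2 = truth[f"{names[1]}_true_z"].to_numpy()

    spec = {
        "insulin": (np.log(8.0), params.insulin_effect, z1, params.insulin_noise_sd),
        "glucose": (np.log(5.0), params.glucose_effect, z1, params.glucose_noise_sd),
        "crp": (np.log(1.5), params.crp_effect, z2, params.crp_noise_sd),
    }
    u_pair = np.repeat(rng.standard_normal(params.n_pairs), 2)
    icc = params.biomarker_pair_icc
    base = {}
    feature_rows = []
    for analyte, (b0, beta, z, sd) in spec.items():
        noise = sd * (np.sqrt(icc) * u_pair + np.sqrt(1 - icc) * rng.standard_normal(n))
        base[analyte] = b0 + beta * z + noise
        index_name = names[0] if z is z1 else names[1]
        feature_rows.append({"feature_type": "biomarker", "feature": analyte,
                             "index": index_name, "effect": beta})

    n_rec = 1 + (rng.random(n) < params.repeat_record_prob).astype(int)
    rows = []
    for j in range(n):
        for _ in range(n_rec[j]):
            row = {ID_COL: truth[ID_COL].iloc[j], "period": "followup3"}
            for analyte, (_, _, _, sd) in spec.items():
                jitter = rng.normal(0, 0.15 * sd) if sd > 0 else 0.0
                row[analyte] = float(np.exp(base[analyte][j] + jitter))
            rows.append(row)
    return pd.DataFrame(rows), pd.DataFrame(feature_rows)


def generate_pathways(params: GeneratorParams, truth: pd.DataFrame):
    """Zero-inflated pathway abundance table with planted score effects.

    The first ``n_zero_inflated`` pathways carry a ~97% zero rate to exercise
    the >90%-zeros exclusion rule; among the rest, ``n_signal_pathways`` per
    direction per index carry a log-scale effect of the standardized score.
    """
    rng = _rng(params.seed, _PATHWAYS)
    n = len(truth)
    P = params.n_pathways
    names = sorted(c.removesuffix("_true_z") for c in truth.columns if c.endswith("_true_z"))
    mu = rng.normal(3.0, 0.5, P)
    zero_rate = rng.uniform(0.0, 2 * params.pathway_zero_rate, P)
    zero_rate[: params.n_zero_inflated] = 0.97

    candidates = np.arange(params.n_zero_inflated, P)
    need = 2 * params.n_signal_pathways * len(names)
    chosen = rng.choice(candidates, size=min(need, len(candidates)), replace=False)
    effects = np.zeros((P, len(names)))
    feature_rows = []
    k = 0
    for ix, name in enumerate(names):
        for direction in (1.0, -1.0):
            for _ in range(params.n_signal_pathways):
                if k >= len(chosen):
                    break
                p_idx = chosen[k]
                effects[p_idx, ix] = direction * params.pathway_effect
                feature_rows.append({"feature_type": "pathway", "feature": f"pw_{p_idx + 1:03d}",
                                     "index": name, "effect": direction * params.pathway_effect})
                k += 1

    zt = truth[[f"{nm}_true_z" for nm in names]].to_numpy()
    log_ab = mu[None, :] + zt @ effects.T + rng.normal(0, 0.7, (n, P))
    nonzero = rng.random((n, P)) >= zero_rate[None, :]
    values = np.where(nonzero, np.exp(log_ab), 0.0)
    cols = {ID_COL: truth[ID_COL].to_numpy()}
    cols.update({f"pw_{p_idx + 1:03d}": values[:, p_idx] for p_idx in range(P)})
    return pd.DataFrame(cols), pd.DataFrame(feature_rows)


def generate_covariates(params: GeneratorParams, truth: pd.DataFrame, structure: pd.DataFrame,
                        energy: pd.Series) -> pd.DataFrame:
    """Demographic/lifestyle covariates; BMI is a mild function of the
    EDIH-like score so it acts as a genuine confounder downstream."""
    rng = _rng(params.seed, _COVARIATES)
    n = len(structure)
    names = sorted(c.removesuffix("_true_z") for c in truth.columns if c.endswith("_true_z"))
    z1 = truth[f"{names[0]}_true_z"].to_numpy()
    df = structure.copy()
    df["race"] = rng.choice(["White", "Black", "Asian", "Other"], size=n, p=[0.95, 0.02, 0.02, 0.01])
    df["smoking"] = rng.choice(["never", "past", "current"], size=n, p=[0.55, 0.30, 0.15])
    df["supplements"] = rng.poisson(1.0, n)
    df["occupation"] = rng.choice(
        ["unemployed", "retired", "disabled", "high_paid", "medium_paid", "low_paid"],
        size=n, p=[0.08, 0.30, 0.02, 0.15, 0.30, 0.15],
    )
    df["education"] = rng.choice(
        ["less_than_elementary", "elementary", "high_school", "college", "higher"],
        size=n, p=[0.02, 0.08, 0.35, 0.35, 0.20],
    )
    meno = np.where(df["sex"] == "M", "men",
                    np.where(df["age"] + rng.normal(0, 2, n) >= 51, "post", "pre"))
    df["menopause"] = meno
    df["hrt"] = np.where((df["sex"] == "F") & (rng.random(n) < 0.2), "yes", "no")
    df["fasted_hours"] = np.clip(rng.normal(10, 2, n), 4, 16)
    df["nsaid"] = np.where(rng.random(n) < 0.25, "yes", "no")
    df["bmi"] = np.clip(25.0 + 0.6 * z1 + rng.normal(0, 3.5, n), 16, 55)
    df[ENERGY_COL] = energy.reindex(df[ID_COL]).to_numpy()
    return df


def generate_cohort(params: GeneratorParams) -> dict:
    """Full cohort bundle: analysis inputs plus ground truth."""
    structure = generate_twin_structure(params)
    ffq, truth = generate_ffq(params, structure)
    genus, genus_truth = generate_microbiome(params, truth, structure)
    biomarkers, bio_truth = generate_biomarkers(params, truth, structure)
    pathways, pw_truth = generate_pathways(params, truth)
    energy = ffq.groupby(ID_COL)[ENERGY_COL].mean()
    covariates = generate_covariates(params, truth, structure, energy)
    features = pd.concat([genus_truth, bio_truth, pw_truth], ignore_index=True)
    return {
        "ffq": ffq,
        "genus": genus,
        "biomarkers": biomarkers,
        "pathways": pathways,
        "covariates": covariates,
        "ground_truth": GroundTruth(scores=truth, features=features),
    }
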