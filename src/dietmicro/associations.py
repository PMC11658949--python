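"""Downstream inference: adjusted linear models, alpha-diversity summaries,
twin-pair mixed models, FDR control and the functional-pathway screen.

All models are complete-case on the variables they use and report the n
actually modelled.  The covariate set follows the cohort design: total energy
intake, age, racial/ethnic group, smoking status, supplement count,
occupation, education, menopausal status (a 3-level factor that also encodes
sex: men / premenopausal / postmenopausal women), hormone replacement
therapy, fasted hours and NSAID use; BMI is added as a second model, and
zygosity enters the twin-pair sensitivity models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

# covariates of the base adjusted model, in cohort column names
DEFAULT_COVARIATES = (
    "energy_kcal",
    "age",
    "race",
    "smoking",
    "supplements",
    "occupation",
    "education",
    "menopause",
    "hrt",
    "fasted_hours",
    "nsaid",
)
CATEGORICAL = {"race", "smoking", "occupation", "education", "menopause", "hrt", "nsaid", "zygosity", "sex"}


@dataclass
class AssociationResult:
    outcome: str
    exposure: str
    model: str  # "base" | "bmi" | "mixed" | "mixed_bmi"
    beta: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    fdr_p: float | None = None
    pair_variance: float | None = None

    def as_row(self) -> dict:
        return {
            "outcome": self.outcome,
            "exposure": self.exposure,
            "model": self.model,
            "beta": self.beta,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "fdr_p": self.fdr_p,
            "n": self.n,
            "pair_variance": self.pair_variance,
        }


def _terms(covariates) -> list[str]:
    return [f"C({c})" if c in CATEGORICAL else c for c in covariates]


def _formula(outcome: str, exposure: str, covariates, include_bmi: bool) -> str:
    rhs = [exposure] + _terms(covariates)
    if include_bmi:
        rhs.append("bmi")
    return f"{outcome} ~ " + " + ".join(rhs)


def _complete_cases(data: pd.DataFrame, cols) -> pd.DataFrame:
    return data.dropna(subset=[c for c in cols if c in data.columns]).copy()


def _check_rank(model) -> None:
    exog = model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        r = np.abs(np.diag(np.linalg.qr(exog, mode="r")))
        aliased = [name for name, d in zip(model.exog_names, r) if d < 1e-8 * r.max()]
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")


def fit_adjusted_linear(
    data: pd.DataFrame,
    outcome: str,
    exposure: str,
    covariates=DEFAULT_COVARIATES,
    include_bmi: bool = False,
    standardize_exposure: bool = False,
) -> AssociationResult:
    """Multivariable-adjusted OLS of ``outcome`` on ``exposure``.

    With ``standardize_exposure`` the exposure is scaled to SD units on the
    complete-case sample, so the beta is per 1-SD increment.
    """
    used = [outcome, exposure, *covariates] + (["bmi"] if include_bmi else [])
    df = _complete_cases(data, used)
    if standardize_exposure:
        sd = df[exposure].std(ddof=1)
        if sd == 0:
            raise ValueError(f"exposure {exposure} is constant")
        df[exposure] = (df[exposure] - df[exposure].mean()) / sd
    model = smf.ols(_formula(outcome, exposure, covariates, include_bmi), data=df)
    _check_rank(model)
    fit = model.fit()
    ci = fit.conf_int().loc[exposure]
    return AssociationResult(
        outcome=outcome,
        exposure=exposure,
        model="bmi" if include_bmi else "base",
        beta=float(fit.params[exposure]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p=float(fit.pvalues[exposure]),
        n=int(fit.nobs),
    )


def percent_diff_per_sd(beta: float, ci_low: float, ci_high: float) -> tuple[float, float, float]:
    """Percent difference in a natural-log outcome per 1-SD exposure increment.

    100 * (exp(beta) - 1), with the CI transformed endpoint-wise.
    """
    f = lambda b: 100.0 * (np.exp(b) - 1.0)
    return f(beta), f(ci_low), f(ci_high)


def quintile_backtransform(
    data: pd.DataFrame,
    log_outcome: str,
    quintile_col: str,
    covariates=DEFAULT_COVARIATES,
    include_bmi: bool = False,
) -> pd.DataFrame:
    """Adjusted absolute and relative outcome values per exposure quintile.

    The natural-log outcome is regressed on quintile indicators (lowest
    quintile as reference) plus covariates.  The absolute value in quintile q
    back-transforms the adjusted linear predictor evaluated at the cohort
    means of continuous covariates and the reference levels of categorical
    ones; the relative value is exp(beta_q) with quintile 1 fixed at 1.
    """
    used = [log_outcome, quintile_col, *covariates] + (["bmi"] if include_bmi else [])
    df = _complete_cases(data, used)
    levels = sorted(df[quintile_col].unique())
    ref = levels[0]
    rhs = [f"C({quintile_col}, Treatment({ref}))"] + _terms(covariates)
    if include_bmi:
        rhs.append("bmi")
    fit = smf.ols(f"{log_outcome} ~ " + " + ".join(rhs), data=df).fit()
    cont = [c for c in covariates if c not in CATEGORICAL] + (["bmi"] if include_bmi else [])
    base_lp = float(fit.params["Intercept"]) + sum(float(fit.params[c]) * df[c].mean() for c in cont)
    rows = []
    for q in levels:
        term = f"C({quintile_col}, Treatment({ref}))[T.{q}]"
        beta = 0.0 if q == ref else float(fit.params[term])
        lo, hi = (0.0, 0.0) if q == ref else map(float, fit.conf_int().loc[term])
        rows.append(
            {
                "quintile": q,
                "absolute": float(np.exp(base_lp + beta)),
                "relative": float(np.exp(beta)),
                "rel_ci_low": float(np.exp(lo)) if q != ref else 1.0,
                "rel_ci_high": float(np.exp(hi)) if q != ref else 1.0,
                "n": int((df[quintile_col] == q).sum()),
            }
        )
    return pd.DataFrame(rows)


def fit_twin_mixed(
    data: pd.DataFrame,
    outcome: str,
    exposure: str,
    covariates=DEFAULT_COVARIATES,
    include_bmi: bool = False,
    pair_col: str = "pair_id",
    zygosity_col: str = "zygosity",
    standardize_exposure: bool = False,
) -> AssociationResult:
    """Twin-pair sensitivity model: random intercept per pair, zygosity added
    to the fixed effects.  Falls back to OLS with a warning on a singular fit.
    """
    covs = list(covariates) + [zygosity_col]
    used = [outcome, exposure, *covs, pair_col] + (["bmi"] if include_bmi else [])
    df = _complete_cases(data, used)
    if standardize_exposure:
        df[exposure] = (df[exposure] - df[exposure].mean()) / df[exposure].std(ddof=1)
    formula = _formula(outcome, exposure, covs, include_bmi)
    tag = "mixed_bmi" if include_bmi else "mixed"
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.mixedlm(formula, data=df, groups=df[pair_col]).fit(reml=True)
        if not np.isfinite(fit.bse[exposure]):
            raise np.linalg.LinAlgError("non-finite standard error")
        ci = fit.conf_int().loc[exposure]
        return AssociationResult(
            outcome=outcome,
            exposure=exposure,
            model=tag,
            beta=float(fit.params[exposure]),
            ci_low=float(ci[0]),
            ci_high=float(ci[1]),
            p=float(fit.pvalues[exposure]),
            n=int(fit.nobs),
            pair_variance=float(fit.cov_re.iloc[0, 0]),
        )
    except (np.linalg.LinAlgError, ValueError) as err:
        logger.warning("fit_twin_mixed: singular fit (%s); falling back to OLS", err)
        res = fit_adjusted_linear(df, outcome, exposure, covs, include_bmi=include_bmi)
        res.model = tag
        res.pair_variance = 0.0
        return res


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def rank_probit(values) -> np.ndarray:
    """Rank-based inverse-normal (Blom) transform.

    value -> Phi^{-1}((rank - 0.375) / (n + 0.25)), average ranks for ties.
    A constant vector maps to all zeros (flagged in the log).
    """
    x = np.asarray(values, dtype=float)
    if np.ptp(x) == 0:
        logger.warning("rank_probit: constant vector; transform is all zeros")
        return np.zeros_like(x)
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.375) / (len(x) + 0.25))


def pathway_screen(
    pathways: pd.DataFrame,
    data: pd.DataFrame,
    exposure: str,
    covariates=DEFAULT_COVARIATES,
    include_bmi: bool = False,
    quintile_col: str | None = None,
    fdr_cutoff: float = 0.10,
    zero_threshold: float = 0.90,
    top_n: int = 10,
    id_col: str = "participant_id",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen predicted functional pathways for dietary-score associations.

    Pathways with strictly more than ``zero_threshold`` zeros are excluded;
    the rest are Blom rank-probit transformed and regressed on the exposure
    with the full covariate set, with BH-FDR across the tested pathways.
    Returns (results, heatmap): results has one row per pathway with beta,
    raw and FDR p, direction and the excluded flag; heatmap is the quintile x
    pathway matrix of z-scored mean abundances for the top ``top_n``
    positively and negatively associated significant pathways.
    """
    pw_cols = [c for c in pathways.columns if c != id_col]
    merged = data.merge(pathways, on=id_col, how="inner")
    rows = []
    tested = []
    for pw in pw_cols:
        zero_frac = float((merged[pw] == 0).mean())
        if zero_frac > zero_threshold:
            rows.append({"pathway": pw, "excluded": True, "zero_fraction": zero_frac,
                         "beta": np.nan, "p": np.nan, "fdr_p": np.nan, "direction": ""})
            continue
        sub = _complete_cases(merged, [pw, exposure, *covariates] + (["bmi"] if include_bmi else []))
        sub["_probit"] = rank_probit(sub[pw].to_numpy())
        fit = smf.ols(_formula("_probit", exposure, covariates, include_bmi), data=sub).fit()
        beta = float(fit.params[exposure])
        rows.append({"pathway": pw, "excluded": False, "zero_fraction": zero_frac,
                     "beta": beta, "p": float(fit.pvalues[exposure]), "fdr_p": np.nan,
                     "direction": "+" if beta > 0 else "-"})
        tested.append(len(rows) - 1)
    results = pd.DataFrame(rows)
    if tested:
        results.loc[tested, "fdr_p"] = bh_fdr(results.loc[tested, "p"].to_numpy())
    sig = results[(~results["excluded"]) & (results["fdr_p"] < fdr_cutoff)]
    logger.info("pathway_screen[%s]: %d tested, %d significant at FDR<%.2g",
                exposure, len(tested), len(sig), fdr_cutoff)

    heatmap = pd.DataFrame()
    if quintile_col is not None and not sig.empty:
        top_pos = sig[sig["beta"] > 0].nlargest(top_n, "beta")["pathway"].tolist()
        top_neg = sig[sig["beta"] < 0].nsmallest(top_n, "beta")["pathway"].tolist()
        chosen = top_pos + top_neg
        qmeans = merged.groupby(quintile_col)[chosen].mean()  # quintile x pathway
        z = (qmeans - qmeans.mean(axis=0)) / qmeans.std(axis=0, ddof=1)
        heatmap = z
    return results, heatmap
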