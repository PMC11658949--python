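"""Dietary-index scoring: weighted sums, energy adjustment, quintiles, HOMA-IR.

A metabolic dietary index (EDIH, EDIP or a custom pattern) is a weighted sum
of standardized food-subgroup servings per day.  Scores are adjusted for
total energy intake with the residual method, standardized, and cut into
quintiles for tabulation.  Biomarker helpers compute HOMA-IR and collapse
repeated measurements per assessment period.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .ffq import ENERGY_COL, ID_COL, subgroup_col

HOMA_DENOMINATOR = 22.5


@dataclass(frozen=True)
class DietaryIndexDefinition:
    """A named dietary pattern: (subgroup id, weight) pairs.

    Positive weights mark food groups that raise the pattern score (for EDIH:
    more insulinaemic; for EDIP: more pro-inflammatory), negative weights mark
    protective groups.
    """

    name: str
    weights: pd.Series  # index: subgroup_id (int), values: weight

    def __post_init__(self) -> None:
        w = self.weights
        if not np.isfinite(w.to_numpy()).all() or (w == 0).any():
            raise ValueError(f"{self.name}: weights must be finite and nonzero")
        if w.index.duplicated().any():
            raise ValueError(f"{self.name}: duplicated subgroup in definition")


def load_index_definitions(path: str | Path | None = None) -> dict[str, DietaryIndexDefinition]:
    """Read index definitions (TSV: index, subgroup_id, weight).

    The packaged defaults are synthetic example weights with the structure of
    EDIH (18 components) and EDIP (15 components); they are NOT the published
    component weights, which are not redistributable here.
    """
    if path is None:
        with resources.files("dietmicro.data").joinpath("index_definitions_synthetic.tsv").open() as fh:
            table = pd.read_csv(fh, sep="\t")
    else:
        table = pd.read_csv(path, sep="\t")
    out = {}
    for name, grp in table.groupby("index"):
        weights = pd.Series(grp["weight"].to_numpy(), index=grp["subgroup_id"].astype(int).to_numpy())
        out[str(name)] = DietaryIndexDefinition(name=str(name), weights=weights)
    return out


def compute_raw_score(intake: pd.DataFrame, defn: DietaryIndexDefinition) -> pd.Series:
    """Weighted sum of subgroup servings/day; linear in intake."""
    cols = [subgroup_col(sg) for sg in defn.weights.index]
    missing = [c for c in cols if c not in intake.columns]
    if missing:
        raise ValueError(f"{defn.name}: definition references unknown subgroups {missing}")
    values = intake[cols].to_numpy(dtype=float) @ defn.weights.to_numpy(dtype=float)
    return pd.Series(values, index=intake[ID_COL].to_numpy(), name=f"{defn.name}_raw")


def energy_adjust_residual(raw: pd.Series, energy: pd.Series) -> pd.Series:
    """Residual-method energy adjustment.

    Regress the raw score on total energy (simple linear model with
    intercept) and return residual + cohort mean raw score, so the adjusted
    score is uncorrelated with energy but keeps an interpretable location.
    """
    if len(raw) < 3:
        raise ValueError("residual method needs at least 3 participants")
    e = energy.to_numpy(dtype=float)
    y = raw.to_numpy(dtype=float)
    if np.ptp(e) == 0:
        raise ValueError("total energy is constant; residual method undefined")
    slope, intercept = np.polyfit(e, y, 1)
    resid = y - (intercept + slope * e)
    return pd.Series(resid + y.mean(), index=raw.index, name=str(raw.name).replace("_raw", "_adj"))


def assign_quintiles(scores: pd.Series, n_groups: int = 5) -> pd.Series:
    """Rank-based split into ``n_groups`` groups of near-equal size.

    Group 1 holds the lowest scores.  Sizes differ by at most one, with the
    larger groups at the low end; ties are broken by stable participant-id
    order so the assignment is deterministic.
    """
    if len(scores) < n_groups:
        raise ValueError(f"need at least {n_groups} participants for {n_groups} groups")
    df = pd.DataFrame({"score": scores.to_numpy(), "pid": scores.index})
    order = df.sort_values(["score", "pid"], kind="mergesort").index.to_numpy()
    labels = np.empty(len(df), dtype=int)
    for q, chunk in enumerate(np.array_split(order, n_groups), start=1):
        labels[chunk] = q
    return pd.Series(labels, index=scores.index, name=str(scores.name or "score").replace("_adj", "") + "_q")


def score_index(
    intake: pd.DataFrame,
    defn: DietaryIndexDefinition,
    n_quintiles: int = 5,
) -> pd.DataFrame:
    """Raw, energy-adjusted, standardized and quintiled scores for one index.

    Quintiles are taken on the energy-adjusted score.
    """
    raw = compute_raw_score(intake, defn)
    energy = pd.Series(intake[ENERGY_COL].to_numpy(), index=raw.index)
    adj = energy_adjust_residual(raw, energy)
    z = (adj - adj.mean()) / adj.std(ddof=1)
    q = assign_quintiles(adj, n_groups=n_quintiles)
    out = pd.DataFrame(
        {
            ID_COL: raw.index,
            f"{defn.name}_raw": raw.to_numpy(),
            f"{defn.name}_adj": adj.to_numpy(),
            f"{defn.name}_z": z.to_numpy(),
            f"{defn.name}_q": q.to_numpy(),
        }
    )
    return out


def compute_homa_ir(insulin, glucose):
    """HOMA-IR = fasting insulin (uIU/ml) x fasting glucose (mmol/L) / 22.5.

    Non-positive or missing inputs yield a missing value.  Accepts scalars or
    array-likes.
    """
    ins = np.asarray(insulin, dtype=float)
    glu = np.asarray(glucose, dtype=float)
    with np.errstate(invalid="ignore"):
        value = np.where((ins > 0) & (glu > 0), ins * glu / HOMA_DENOMINATOR, np.nan)
    if value.ndim == 0:
        return float(value)
    return value


def average_biomarkers_per_period(biomarkers: pd.DataFrame) -> pd.DataFrame:
    """Mean analyte value per participant per period; HOMA-IR from the means.

    HOMA-IR is recomputed from the averaged insulin and glucose rather than
    averaged from per-visit values.
    """
    analytes = [c for c in ("insulin", "glucose", "crp") if c in biomarkers.columns]
    out = (
        biomarkers.groupby([ID_COL, "period"], sort=True)[analytes]
        .mean()
        .reset_index()
    )
    if {"insulin", "glucose"} <= set(out.columns):
        out["homa_ir"] = compute_homa_ir(out["insulin"], out["glucose"])
    return out
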