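"""Genus-table QC and transforms: depth filter, prevalence filter, CLR, alpha diversity.

Tables are wide: one row per sample (sample id equals participant id), one
column per genus, integer counts.  The processing order is: depth QC first,
alpha diversity on the full genus composition of retained samples, then
prevalence filtering and the centred log-ratio transform for modelling.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .ffq import ID_COL

logger = logging.getLogger(__name__)

GENUS_PREFIX = "g_"


def genus_col(genus_id: int) -> str:
    return f"{GENUS_PREFIX}{int(genus_id):03d}"


def genus_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.startswith(GENUS_PREFIX)]


def sample_depths(table: pd.DataFrame) -> pd.Series:
    counts = table[genus_columns(table)]
    return pd.Series(counts.sum(axis=1).to_numpy(), index=table[ID_COL].to_numpy(), name="depth")


def aggregate_genus(asv_table: pd.DataFrame, taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Sum ASV counts per assigned genus.

    ``taxonomy`` maps asv_id -> genus label; ASVs unassigned at genus level
    keep their family-level placeholder label as an opaque genus id.
    """
    asv_cols = [c for c in asv_table.columns if c != ID_COL]
    mapping = taxonomy.set_index("asv_id")["genus"]
    missing = [c for c in asv_cols if c not in mapping.index]
    if missing:
        raise ValueError(f"ASVs without taxonomy assignment: {missing[:10]}")
    out = pd.DataFrame({ID_COL: asv_table[ID_COL].to_numpy()})
    grouped: dict[str, np.ndarray] = {}
    for col in asv_cols:
        genus = str(mapping[col])
        arr = asv_table[col].to_numpy()
        grouped[genus] = grouped.get(genus, 0) + arr
    for genus in sorted(grouped):
        out[genus] = grouped[genus]
    return out


def depth_filter(table: pd.DataFrame, min_depth: int = 10_000) -> pd.DataFrame:
    """Drop samples whose sequencing depth is strictly below ``min_depth``.

    A sample at exactly the threshold is retained.
    """
    depths = table[genus_columns(table)].sum(axis=1)
    keep = depths >= min_depth
    dropped = table.loc[~keep, ID_COL].tolist()
    if dropped:
        logger.info("depth_filter: dropped %d/%d samples below %d reads", len(dropped), len(table), min_depth)
    if keep.sum() == 0:
        raise ValueError(f"all {len(table)} samples fall below depth {min_depth}")
    return table.loc[keep].reset_index(drop=True)


def prevalence_filter(table: pd.DataFrame, threshold: float = 0.90) -> pd.DataFrame:
    """Keep genera present (nonzero) in strictly more than ``threshold`` of samples."""
    cols = genus_columns(table)
    n = len(table)
    prevalence = (table[cols] > 0).sum(axis=0) / n
    keep = [c for c in cols if prevalence[c] > threshold]
    logger.info("prevalence_filter: retained %d/%d genera at >%d%% prevalence", len(keep), len(cols), round(threshold * 100))
    return table[[ID_COL] + keep].copy()


def clr_transform(table: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centred log-ratio transform after adding a pseudocount to the counts.

    Per sample: x_i = count_i + pseudocount; clr_i = ln x_i - mean_j ln x_j
    over the retained genera.  Rows sum to zero by construction.
    """
    cols = genus_columns(table)
    logs = np.log(table[cols].to_numpy(dtype=float) + pseudocount)
    clr = logs - logs.mean(axis=1, keepdims=True)
    out = pd.DataFrame(clr, columns=cols)
    out.insert(0, ID_COL, table[ID_COL].to_numpy())
    return out


def alpha_diversity(table: pd.DataFrame) -> pd.DataFrame:
    """Shannon index (nats) and Pielou evenness per sample, plus natural-log
    transforms used as regression outcomes.

    Computed on the full genus composition: p_i = count_i / depth over nonzero
    genera, H = -sum p_i ln p_i, J = H / ln S with S the observed richness.
    With a single observed genus H = 0 and J is undefined (missing); the log
    transforms are missing wherever the underlying value is not positive.
    """
    counts = table[genus_columns(table)].to_numpy(dtype=float)
    n = counts.shape[0]
    shannon = np.zeros(n)
    pielou = np.full(n, np.nan)
    for i in range(n):
        row = counts[i]
        nz = row[row > 0]
        if nz.size == 0:
            shannon[i] = np.nan
            continue
        h = float(stats.entropy(nz))  # natural log; normalizes to proportions
        shannon[i] = h
        if nz.size > 1:
            pielou[i] = h / np.log(nz.size)
        else:
            logger.info("alpha_diversity: sample %s has a single genus; evenness undefined", table[ID_COL].iloc[i])
    with np.errstate(divide="ignore", invalid="ignore"):
        log_shannon = np.where(shannon > 0, np.log(shannon), np.nan)
        log_pielou = np.where(pielou > 0, np.log(pielou), np.nan)
    return pd.DataFrame(
        {
            ID_COL: table[ID_COL].to_numpy(),
            "shannon": shannon,
            "pielou": pielou,
            "log_shannon": log_shannon,
            "log_pielou": log_pielou,
        }
    )
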