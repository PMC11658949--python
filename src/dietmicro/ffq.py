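"""FFQ harmonisation: repeated-record averaging and serving-size standardization.

Raw food-frequency questionnaires report each item in servings per week, and
a participant may have several FFQ records within one assessment period.
Standardization maps each FFQ item onto one standardized serving-size food
subgroup (168 conventional subgroups plus pizza and cream soup treated as
whole foods, 170 in all) via an item-level conversion factor, and converts
weekly frequencies to servings per day.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

ITEM_PREFIX = "item_"
SUBGROUP_PREFIX = "sg_"
ENERGY_COL = "energy_kcal"
ID_COL = "participant_id"
RECORD_COL = "record_id"


def item_col(item_id: int) -> str:
    return f"{ITEM_PREFIX}{int(item_id):03d}"


def subgroup_col(subgroup_id: int) -> str:
    return f"{SUBGROUP_PREFIX}{int(subgroup_id):03d}"


def item_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.startswith(ITEM_PREFIX)]


def subgroup_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.startswith(SUBGROUP_PREFIX)]


@dataclass(frozen=True)
class ServingSizeMap:
    """Item -> (subgroup, conversion factor) mapping with a declared universe.

    ``table`` has one row per FFQ item with columns ``item_id``,
    ``subgroup_id``, ``category_id`` and ``conversion_factor``.  The subgroup
    universe runs 1..``n_subgroups`` whether or not every subgroup receives an
    item, so the standardized output always has the full column set.
    """

    table: pd.DataFrame
    n_subgroups: int

    def __post_init__(self) -> None:
        required = {"item_id", "subgroup_id", "conversion_factor"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"serving map missing columns: {sorted(missing)}")
        if self.table["item_id"].duplicated().any():
            dupes = self.table.loc[self.table["item_id"].duplicated(), "item_id"]
            raise ValueError(f"items mapped more than once: {sorted(dupes)}")
        if (self.table["conversion_factor"] <= 0).any():
            raise ValueError("conversion factors must be positive")
        if self.table["subgroup_id"].max() > self.n_subgroups:
            raise ValueError("subgroup id outside declared universe")

    @property
    def subgroup_ids(self) -> list[int]:
        return list(range(1, self.n_subgroups + 1))


def load_serving_map(path: str | Path | None = None, n_subgroups: int | None = None) -> ServingSizeMap:
    """Load a serving-size map from TSV; default is the packaged synthetic map.

    The packaged map is a structural stand-in (131 items, 168 standardized
    subgroups in nine categories plus pizza and cream soup = 170 subgroups);
    real analyses should supply their own NDSR-derived mapping.
    """
    if path is None:
        with resources.files("dietmicro.data").joinpath("serving_map_synthetic.tsv").open() as fh:
            table = pd.read_csv(fh, sep="\t")
    else:
        table = pd.read_csv(path, sep="\t")
    if n_subgroups is None:
        n_subgroups = int(table["subgroup_id"].max())
    return ServingSizeMap(table=table, n_subgroups=n_subgroups)


def average_repeat_records(ffq: pd.DataFrame) -> pd.DataFrame:
    """Collapse multiple FFQ records per participant to their item-wise mean.

    Energy is averaged identically.  The result has one row per participant.
    """
    value_cols = item_columns(ffq) + [ENERGY_COL]
    out = ffq.groupby(ID_COL, sort=True)[value_cols].mean().reset_index()
    return out


def standardize_servings(ffq: pd.DataFrame, smap: ServingSizeMap) -> pd.DataFrame:
    """Convert weekly item servings to daily standardized-subgroup servings.

    servings/day(subgroup) = sum over mapped items of
    weekly_servings * conversion_factor / 7.  Subgroups receiving no item are
    present with value 0.  Items absent from the map are an error.
    """
    items = item_columns(ffq)
    item_ids = [int(c.removeprefix(ITEM_PREFIX)) for c in items]
    mapped = set(smap.table["item_id"])
    unmapped = sorted(set(item_ids) - mapped)
    if unmapped:
        raise ValueError(f"FFQ items not covered by the serving map: {unmapped}")

    n = len(ffq)
    values = np.zeros((n, smap.n_subgroups))
    lookup = smap.table.set_index("item_id")
    for col, iid in zip(items, item_ids):
        row = lookup.loc[iid]
        sg = int(row["subgroup_id"])
        factor = float(row["conversion_factor"])
        values[:, sg - 1] += ffq[col].to_numpy(dtype=float) * factor / 7.0
    cols = {ID_COL: ffq[ID_COL].to_numpy()}
    cols.update({subgroup_col(sg): values[:, sg - 1] for sg in smap.subgroup_ids})
    cols[ENERGY_COL] = ffq[ENERGY_COL].to_numpy(dtype=float)
    return pd.DataFrame(cols)
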