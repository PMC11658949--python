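"""Readers/writers for the tabular inputs and outputs.

All tables are delimited text with a header row; floats are written at full
round-trip precision so re-runs are byte-comparable.  Genus tables are
accepted either as wide TSV (samples x genera) or as BIOM v1 JSON
(observations x samples, dense or sparse), which is plain JSON and needs no
binary tooling.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import PipelineConfig
from .ffq import ENERGY_COL, ID_COL, RECORD_COL

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = {
    "ffq": [ID_COL, RECORD_COL, ENERGY_COL],
    "covariates": [ID_COL, "age", "sex", "race", "smoking", "supplements", "occupation",
                   "education", "menopause", "hrt", "fasted_hours", "nsaid", "bmi",
                   "zygosity", "pair_id", ENERGY_COL],
    "biomarkers": [ID_COL, "period", "insulin", "glucose", "crp"],
    "genus": [ID_COL],
    "pathways": [ID_COL],
}


@dataclass
class TableBundle:
    ffq: pd.DataFrame
    genus: pd.DataFrame
    covariates: pd.DataFrame
    biomarkers: pd.DataFrame
    pathways: pd.DataFrame

    def participant_sets(self) -> dict[str, set]:
        return {
            "ffq": set(self.ffq[ID_COL]),
            "genus": set(self.genus[ID_COL]),
            "covariates": set(self.covariates[ID_COL]),
            "biomarkers": set(self.biomarkers[ID_COL]),
            "pathways": set(self.pathways[ID_COL]),
        }


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _check_columns(df: pd.DataFrame, table_name: str) -> None:
    for col in REQUIRED_COLUMNS.get(table_name, []):
        if col not in df.columns:
            raise ValueError(f"{table_name}: missing required column '{col}'")


def _check_unique(df: pd.DataFrame, table_name: str) -> None:
    dup = df.loc[df[ID_COL].duplicated(), ID_COL].unique().tolist()
    if dup:
        raise ValueError(f"{table_name}: duplicated participant rows: {dup[:10]}")


def read_biom_json(path: str | Path) -> pd.DataFrame:
    """Read a BIOM v1 (JSON) table into a wide samples x features frame."""
    doc = json.loads(Path(path).read_text())
    obs = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    n_obs, n_samp = doc["shape"]
    import numpy as np

    mat = np.zeros((n_obs, n_samp))
    if doc.get("matrix_type") == "sparse":
        for r, c, v in doc["data"]:
            mat[int(r), int(c)] = v
    else:
        mat = np.asarray(doc["data"], dtype=float)
    out = pd.DataFrame(mat.T, columns=obs)
    out.insert(0, ID_COL, samples)
    return out


def read_genus_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix in {".biom", ".json"}:
        return read_biom_json(path)
    return read_table(path)


def read_tables(config: PipelineConfig, workdir: str | Path = ".") -> TableBundle:
    """Read and cross-validate all pipeline inputs.

    Tables must share a single participant universe; identifiers present in
    some tables but not others are reported as orphans.  Row counts are
    logged per table.
    """
    workdir = Path(workdir)

    def _path(key: str, default_name: str) -> Path:
        configured = getattr(config, key)
        return Path(configured) if configured else workdir / default_name

    ffq = read_table(_path("ffq", "ffq.tsv"))
    genus = read_genus_table(_path("genus_table", "genus.tsv"))
    covariates = read_table(_path("covariates", "covariates.tsv"))
    biomarkers = read_table(_path("biomarkers", "biomarkers.tsv"))
    pathways = read_table(_path("pathways", "pathways.tsv"))

    named = {"ffq": ffq, "genus": genus, "covariates": covariates,
             "biomarkers": biomarkers, "pathways": pathways}
    for name, df in named.items():
        _check_columns(df, name)
    for name in ("genus", "covariates", "pathways"):
        _check_unique(named[name], name)
    if ffq.duplicated([ID_COL, RECORD_COL]).any():
        dup = ffq.loc[ffq.duplicated([ID_COL, RECORD_COL]), ID_COL].unique().tolist()
        raise ValueError(f"ffq: duplicated participant/record rows: {dup[:10]}")

    bundle = TableBundle(**named)
    sets = bundle.participant_sets()
    universe = set.union(*sets.values())
    common = set.intersection(*sets.values())
    orphans = sorted(universe - common)
    if orphans:
        where = {name: sorted(universe - ids)[:5] for name, ids in sets.items() if universe - ids}
        raise ValueError(f"participant identifiers not shared by all tables: {orphans[:10]} (missing from: {where})")
    for name, df in named.items():
        logger.info("read_tables: %s -> %d rows, %d participants", name, len(df), df[ID_COL].nunique())
    return bundle
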