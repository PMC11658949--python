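import numpy as np
import pandas as pd
import pytest

import dietmicro as dm
from dietmicro.ffq import ID_COL
from dietmicro.io import TableBundle, write_table
from dietmicro.pipeline import stage_microbiome, stage_scores, stage_signature, stage_standardize


@pytest.fixture(scope="session")
def small_cohort():
    """A 120-participant synthetic twin cohort used across the suite."""
    return dm.generate_cohort(dm.GeneratorParams(n_pairs=60, seed=7))


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory, small_cohort):
    d = tmp_path_factory.mktemp("cohort")
    for name in ("ffq", "genus", "covariates", "biomarkers", "pathways"):
        write_table(small_cohort[name], d / f"{name}.tsv")
    return d


@pytest.fixture(scope="session")
def recovery():
    """Signature recovery run at study scale: 500 pairs, planted signals.

    Built once per session; used by the parameter-recovery checks.
    """
    cohort = dm.generate_cohort(dm.GeneratorParams(n_pairs=500, seed=11))
    bundle = TableBundle(
        ffq=cohort["ffq"], genus=cohort["genus"], covariates=cohort["covariates"],
        biomarkers=cohort["biomarkers"], pathways=cohort["pathways"],
    )
    cfg = dm.PipelineConfig(seed=11)
    intake = stage_standardize(bundle, cfg)
    dietary = stage_scores(intake, cfg)
    alpha, clr = stage_microbiome(bundle.genus, cfg)
    mb_scores, profiles = stage_signature(clr, dietary, bundle.covariates, cfg)
    return {
        "cohort": cohort,
        "truth": cohort["ground_truth"],
        "dietary": dietary,
        "alpha": alpha,
        "clr": clr,
        "mb_scores": mb_scores,
        "profiles": profiles,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_genus_table(counts, ids=None):
    counts = np.asarray(counts)
    ids = ids or [f"S{i}" for i in range(counts.shape[0])]
    df = pd.DataFrame(counts, columns=[f"g_{j + 1:03d}" for j in range(counts.shape[1])])
    df.insert(0, ID_COL, ids)
    return df
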