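"""Structure, determinism and planted-signal properties of the cohort generator."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import dietmicro as dm
from dietmicro.ffq import ID_COL, item_columns
from dietmicro.microbiome import clr_transform, genus_columns, prevalence_filter
from dietmicro.synthetic import (
    GeneratorParams,
    generate_biomarkers,
    generate_ffq,
    generate_microbiome,
    generate_pathways,
    generate_twin_structure,
)


class TestParams:
    def test_mz_correlation_must_dominate_dz(self):
        with pytest.raises(ValueError, match="MZ"):
            GeneratorParams(within_pair_corr_mz=0.1, within_pair_corr_dz=0.5)

    @pytest.mark.parametrize("field, value", [("n_pairs", 0), ("mz_fraction", 1.5)])
    def test_invalid_counts_and_fractions(self, field, value):
        with pytest.raises(ValueError):
            GeneratorParams(**{field: value})


class TestFfq:
    def test_shape_500_pairs(self):
        ffq, truth = generate_ffq(GeneratorParams(n_pairs=500, seed=1))
        assert truth[ID_COL].nunique() == 1000
        assert ffq[ID_COL].nunique() == 1000
        assert len(item_columns(ffq)) == 131
        assert "energy_kcal" in ffq.columns
        assert (ffq[item_columns(ffq)].to_numpy() >= 0).all()
        assert (ffq["energy_kcal"] > 0).all()

    def test_same_seed_reproduces_tables(self):
        p = GeneratorParams(n_pairs=30, seed=9)
        f1, t1 = generate_ffq(p)
        f2, t2 = generate_ffq(p)
        pd.testing.assert_frame_equal(f1, f2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_zero_within_pair_correlation(self):
        p = GeneratorParams(n_pairs=500, seed=2, within_pair_corr_mz=0.0, within_pair_corr_dz=0.0)
        _, truth = generate_ffq(p)
        z = truth["EDIH_true_z"].to_numpy()
        r = np.corrcoef(z[::2], z[1::2])[0, 1]
        assert abs(r) < 0.1

    def test_configured_within_pair_correlation_emerges(self):
        p = GeneratorParams(n_pairs=500, seed=2)
        _, truth = generate_ffq(p)
        z = truth["EDIH_true_z"].to_numpy()
        r = np.corrcoef(z[::2], z[1::2])[0, 1]
        assert r > 0.15  # positive and clearly nonzero under the MZ/DZ defaults


@pytest.fixture(scope="module")
def cohort():
    p = GeneratorParams(n_pairs=500, seed=3)
    structure = generate_twin_structure(p)
    _, truth = generate_ffq(p, structure)
    genus, features = generate_microbiome(p, truth, structure)
    return p, truth, genus, features


class TestMicrobiome:
    def test_counts_are_nonnegative_integers_summing_to_depth(self, cohort):
        _, _, genus, _ = cohort
        counts = genus[genus_columns(genus)].to_numpy()
        assert (counts >= 0).all()
        assert np.issubdtype(counts.dtype, np.integer)
        assert (counts.sum(axis=1) >= 3000).all()

    def test_planted_low_depth_fraction(self, cohort):
        p, _, genus, _ = cohort
        depths = genus[genus_columns(genus)].sum(axis=1)
        frac = (depths < p.depth_threshold).mean()
        assert frac == pytest.approx(0.05, abs=0.025)

    def test_signal_genera_are_generated_columns(self, cohort):
        _, _, genus, features = cohort
        assert set(features["feature"]) <= set(genus_columns(genus))

    def test_planted_positive_effect_gives_positive_clr_correlation(self, cohort):
        p, truth, genus, features = cohort
        clr = clr_transform(prevalence_filter(genus, 0.90))
        pos = features[(features["index"] == "EDIH") & (features["effect"] > 0)]["feature"]
        z = truth.set_index(ID_COL)["EDIH_true_z"]
        for g in pos:
            if g not in clr.columns:
                continue
            rho = spearmanr(clr[g], z.reindex(clr[ID_COL]).to_numpy()).statistic
            assert rho > 0.2

    def test_null_effects_give_centred_correlations(self):
        p = GeneratorParams(n_pairs=300, seed=4, genus_effect=0.0)
        structure = generate_twin_structure(p)
        _, truth = generate_ffq(p, structure)
        genus, _ = generate_microbiome(p, truth, structure)
        clr = clr_transform(prevalence_filter(genus, 0.90))
        z = truth.set_index(ID_COL)["EDIH_true_z"].reindex(clr[ID_COL]).to_numpy()
        rhos = [spearmanr(clr[g], z).statistic for g in genus_columns(clr)]
        assert abs(np.mean(rhos)) < 0.05
        assert np.quantile(np.abs(rhos), 0.95) < 0.15


class TestBiomarkers:
    def test_zero_effects_recover_zero_slope(self):
        p = GeneratorParams(n_pairs=1000, seed=5, insulin_effect=0.0)
        structure = generate_twin_structure(p)
        _, truth = generate_ffq(p, structure)
        bio, _ = generate_biomarkers(p, truth, structure)
        merged = bio.groupby(ID_COL)["insulin"].mean().to_frame().join(
            truth.set_index(ID_COL)["EDIH_true_z"]
        )
        slope = np.polyfit(merged["EDIH_true_z"], np.log(merged["insulin"]), 1)[0]
        assert abs(slope) < 0.03

    def test_all_values_strictly_positive(self):
        p = GeneratorParams(n_pairs=100, seed=6)
        structure = generate_twin_structure(p)
        _, truth = generate_ffq(p, structure)
        bio, _ = generate_biomarkers(p, truth, structure)
        assert (bio[["insulin", "glucose", "crp"]].to_numpy() > 0).all()

    def test_zero_noise_is_deterministic_across_records(self):
        p = GeneratorParams(n_pairs=50, seed=7, insulin_noise_sd=0.0,
                            glucose_noise_sd=0.0, crp_noise_sd=0.0)
        structure = generate_twin_structure(p)
        _, truth = generate_ffq(p, structure)
        bio, _ = generate_biomarkers(p, truth, structure)
        spread = bio.groupby(ID_COL)[["insulin", "glucose", "crp"]].agg(lambda s: s.max() - s.min())
        assert (spread.to_numpy() == 0).all()


class TestPathways:
    def test_planted_zero_inflated_block(self):
        p = GeneratorParams(n_pairs=500, seed=8)
        structure = generate_twin_structure(p)
        _, truth = generate_ffq(p, structure)
        pw, features = generate_pathways(p, truth)
        zero_frac = (pw[[c for c in pw.columns if c.startswith("pw_")]] == 0).mean()
        sparse = zero_frac[zero_frac > 0.9].index
        assert set(f"pw_{j + 1:03d}" for j in range(20)) <= set(sparse)
        assert not set(features["feature"]) & set(sparse)

    def test_same_seed_identical(self):
        p = GeneratorParams(n_pairs=20, seed=9)
        structure = generate_twin_structure(p)
        _, truth = generate_ffq(p, structure)
        pd.testing.assert_frame_equal(
            generate_pathways(p, truth)[0], generate_pathways(p, truth)[0]
        )


class TestCohortBundle:
    def test_bundle_is_internally_consistent(self, small_cohort):
        ids = set(small_cohort["covariates"][ID_COL])
        for name in ("genus", "pathways"):
            assert set(small_cohort[name][ID_COL]) == ids
        assert set(small_cohort["ffq"][ID_COL]) == ids
        truth = small_cohort["ground_truth"]
        assert set(truth.scores[ID_COL]) == ids

    def test_truth_never_leaks_into_inputs(self, small_cohort):
        for name in ("ffq", "genus", "covariates", "biomarkers", "pathways"):
            assert not [c for c in small_cohort[name].columns if "true" in c]

    def test_regenerating_one_stage_matches_bundle(self, small_cohort):
        """Per-stage substreams: tables do not depend on generation order."""
        p = GeneratorParams(n_pairs=60, seed=7)
        structure = generate_twin_structure(p)
        _, truth = generate_ffq(p, structure)
        pw, _ = generate_pathways(p, truth)
        pd.testing.assert_frame_equal(pw, small_cohort["pathways"])
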