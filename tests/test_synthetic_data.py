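"""Generator fidelity: design bookkeeping, calibrated truths, determinism."""

import io

import numpy as np
import pandas as pd
import pytest

import urchintherm as ut
from urchintherm import synthetic_data as sd
from urchintherm.model_compare import CategoricalContrastModel, counts_from_animals


class TestDesigns:
    def test_exp1_default_size(self, exp1_data):
        assert len(exp1_data) == 300
        assert exp1_data["mesocosm_id"].nunique() == 20
        by_tag = exp1_data.groupby("treatment_tag")["mesocosm_id"].nunique()
        assert by_tag["elnino"] == 4 and by_tag["lanina"] == 4
        assert by_tag["16C"] == 2

    def test_row_conservation(self):
        design = sd.ExperimentDesign("exp1", (("16C", 3, 7), ("elnino", 2, 5)))
        df = sd.simulate_experiment1(design=design, seed=1)
        assert len(df) == 3 * 7 + 2 * 5

    def test_exp2_design_cells(self):
        df = ut.simulate_experiment2(seed=4)
        # 3 treatments x 4 tanks nested with 3 locations each
        assert df.groupby(["mesocosm_id", "location"]).ngroups == 36
        assert set(df["location"]) == {"SD", "SB", "SON"}

    def test_experiment_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sd.simulate_experiment1(design=sd.ExperimentDesign.exp2_default())
        with pytest.raises(ValueError):
            sd.simulate_experiment2(design=sd.ExperimentDesign.exp1_default())

    def test_diameters_within_printed_range(self, exp1_data):
        lo, hi = sd.DIAMETER_RANGE_MM
        assert exp1_data["diameter_mm"].between(lo, hi).all()

    def test_mean_temp_matches_schedule(self, exp1_data):
        sub = exp1_data[exp1_data["treatment_tag"] == "elnino"]
        assert np.allclose(sub["mean_temp_c"], 20.0, atol=0.01)


class TestGeneratingTruth:
    def test_stage_prob_vectors_are_simplexes(self):
        for v in sd.GeneratingParams().stage_probs.values():
            assert v.min() >= 0 and abs(v.sum() - 1) < 1e-12

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            sd.GeneratingParams(stage_probs={("F", "16C"): np.array([0.5, 0.5, 0.5, 0.5])})
        with pytest.raises(ValueError):
            sd.GeneratingParams(gamma_shape=-1.0)

    def test_gonad_curve_hits_printed_values(self):
        """The generating thermal-performance curve reproduces, at 50 mm, the
        reported standardized masses and relative reductions."""
        p = sd.GeneratingParams()
        mass = lambda t, tag="": np.exp(p.log_standardized_mass(t, tag))
        assert mass(16.0) == pytest.approx(11.84, abs=1e-6)
        assert mass(20.0) == pytest.approx(7.2, abs=1e-6)
        assert 1 - mass(20.0) / mass(13.0) == pytest.approx(0.42, abs=1e-6)
        assert 1 - mass(10.0) / mass(13.0) == pytest.approx(0.22, abs=1e-6)
        assert mass(16.0, "lanina") == pytest.approx(8.69, abs=1e-6)
        assert mass(20.0, "elnino") == pytest.approx(7.03, abs=1e-6)

    def test_degenerate_stage_probs_yield_all_stage_iv(self):
        probs = {
            (sex, tag): np.array([0.0, 0.0, 0.0, 1.0])
            for sex in "FM"
            for tag in ["16C", "elnino"]
        }
        design = sd.ExperimentDesign("exp1", (("16C", 1, 20), ("elnino", 1, 20)))
        df = sd.simulate_experiment1(
            sd.GeneratingParams(stage_probs=probs), design, seed=0
        )
        assert (df["stage"] == 4).all()

    def test_cell_frequencies_converge_without_random_effects(self):
        """Law of large numbers: with tank effects off, empirical stage-IV
        share matches the generating 0.89 within 0.01 at n = 10,000."""
        params = sd.GeneratingParams(
            stage_probs={(s, "lanina"): np.array([0.03, 0.03, 0.05, 0.89]) for s in "FM"},
            sigma_meso_logit=0.0,
            sigma_meso_log=0.0,
        )
        design = sd.ExperimentDesign("exp1", (("lanina", 1, 10000),))
        df = sd.simulate_experiment1(params, design, seed=7)
        assert (df["stage"] == 4).mean() == pytest.approx(0.89, abs=0.01)

    def test_exp2_locations_share_distribution_when_sigma_zero(self):
        truth = np.array([0.1, 0.2, 0.3, 0.4])
        params = sd.GeneratingParams.exp2_default().with_overrides(
            stage_probs={(s, "10C"): truth for s in "FM"},
            sigma_location_logit=0.0, sigma_meso_logit=0.0, sigma_meso_log=0.0,
        )
        design = sd.ExperimentDesign(
            "exp2", (("10C", 1, 3400),), locations=("SD", "SB", "SON")
        )
        df = sd.simulate_experiment2(params, design, seed=11)
        freq = (
            df.groupby("location")["stage"].value_counts(normalize=True)
            .unstack(fill_value=0).reindex(columns=[1, 2, 3, 4], fill_value=0)
        )
        assert np.abs(freq.to_numpy() - truth[None]).max() < 0.02


class TestDeterminism:
    def test_identical_seed_identical_csv(self, tmp_path):
        a, b = io.StringIO(), io.StringIO()
        sd.animals_to_csv(ut.simulate_experiment1(seed=42), a)
        sd.animals_to_csv(ut.simulate_experiment1(seed=42), b)
        assert a.getvalue() == b.getvalue()

    def test_different_seed_differs(self):
        assert not ut.simulate_experiment1(seed=1).equals(ut.simulate_experiment1(seed=2))

    def test_params_json_round_trip(self, tmp_path):
        p = sd.GeneratingParams(allometry_exp=1.7)
        p.to_json(tmp_path / "params.json")
        q = sd.GeneratingParams.from_json(tmp_path / "params.json")
        assert q.allometry_exp == 1.7
        for key in p.stage_probs:
            assert np.allclose(q.stage_probs[key], p.stage_probs[key])
        assert np.allclose(q.gonad_curve_coefs, p.gonad_curve_coefs)

    def test_csv_round_trip_validates(self, tmp_path, exp1_data):
        path = tmp_path / "animals.csv"
        sd.animals_to_csv(exp1_data, path)
        back = sd.animals_from_csv(path)
        assert list(back.columns) == sd.ANIMAL_COLUMNS
        assert len(back) == len(exp1_data)
        bad = back.copy()
        bad.loc[0, "gonad_mass_g"] = -1.0
        bad_path = tmp_path / "bad.csv"
        bad.to_csv(bad_path, index=False)
        with pytest.raises(ValueError, match="rows"):
            sd.animals_from_csv(bad_path)


class TestSimulateFromFitted:
    def _design(self, n=40):
        return sd.ExperimentDesign(
            "exp1", (("10C", 1, n), ("20C", 1, n), ("elnino", 1, n))
        )

    def test_null_draw_gives_exchangeable_cells(self):
        """Under a no-treatment-effect draw the cell distributions are
        statistically indistinguishable: chi-square p-values across seeds
        behave like a uniform sample (none extreme, spread over (0,1))."""
        from scipy.stats import chi2_contingency

        design = self._design(120)
        null = CategoricalContrastModel.sex_only(design)
        pvals = []
        for seed in range(8):
            draw = null.sample_prior(seed + 100)
            df = sd.simulate_from_fitted(null, draw, design, seed=seed)
            tab = pd.crosstab(df["treatment_tag"], df["stage"])
            tab = tab.loc[:, tab.sum(axis=0) > 0]
            pvals.append(chi2_contingency(tab).pvalue)
        pvals = np.array(pvals)
        assert pvals.min() > 1e-3
        assert 0.1 < pvals.mean() < 0.95

    def test_strong_effect_draw_separates_cells(self):
        from scipy.stats import chi2_contingency

        design = self._design(120)
        full = CategoricalContrastModel.treatment_type_sex(design)
        draw = {
            (s, t): v
            for s in "FM"
            for t, v in [
                ("constant", np.array([0.05, 0.05, 0.1, 0.8])),
                ("el_nino", np.array([0.6, 0.2, 0.1, 0.1])),
            ]
        }
        df = sd.simulate_from_fitted(full, draw, design, seed=3)
        tab = pd.crosstab(df["treatment_tag"], df["stage"])
        assert chi2_contingency(tab).pvalue < 1e-6

    def test_empty_design_gives_empty_table(self):
        design = sd.ExperimentDesign("exp1", (("16C", 2, 0),))
        null = CategoricalContrastModel.intercept_only(design)
        df = sd.simulate_from_fitted(null, null.sample_prior(0), design, seed=0)
        assert len(df) == 0 and list(df.columns) == sd.ANIMAL_COLUMNS

    def test_mismatched_draw_rejected(self):
        design = self._design()
        full = CategoricalContrastModel.treatment_type_sex(design)
        with pytest.raises(ValueError, match="mismatch"):
            sd.simulate_from_fitted(full, {"wrong": np.ones(4) / 4}, design, seed=0)
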