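"""Multinomial stage model: kernel, conjugate oracle, prediction contracts."""

import numpy as np
import pandas as pd
import pytest

import urchintherm as ut
from urchintherm.mcmc import MCMCConfig
from urchintherm.model_compare import CategoricalContrastModel
from urchintherm.stage_model import (
    GP_JITTER,
    StageModelSpec,
    fit_stage_model,
    predict_stage_probs,
    sq_exp_kernel,
)


class TestKernel:
    def test_zero_distance_gives_scale_squared(self):
        assert sq_exp_kernel(0.3, 0.3, 1.0, 2.0) == pytest.approx(4.0)

    def test_long_length_scale_limit(self):
        k = sq_exp_kernel(-2.0, 2.0, 1e6, 1.5)
        assert k == pytest.approx(1.5**2, rel=1e-6)

    def test_gram_matrix_psd_at_design_temperatures(self):
        temps = np.array([10.0, 13.0, 16.0, 17.0, 18.0, 20.0])
        x = (temps - temps.mean()) / temps.std()
        for ell in (0.1, 0.5, 2.0):
            K = sq_exp_kernel(x, x, ell, 1.0)
            assert np.linalg.eigvalsh(K).min() >= -1e-8
            assert np.allclose(K, K.T)
        # jitter guarantees a Cholesky factorization exists
        K = sq_exp_kernel(x, x, 5.0, 1.0) + GP_JITTER * np.eye(6)
        np.linalg.cholesky(K)

    def test_nonpositive_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            sq_exp_kernel(0.0, 1.0, -1.0, 1.0)
        with pytest.raises(ValueError):
            sq_exp_kernel(0.0, 1.0, 1.0, 0.0)


def _single_cell_table(counts):
    rows = []
    for stage, n in zip((1, 2, 3, 4), counts):
        for _ in range(n):
            rows.append(("m1", "constant", "16C", 16.0, "F", 50.0, stage, 5.0))
    df = pd.DataFrame(
        rows,
        columns=[
            "mesocosm_id", "treatment_label", "treatment_tag", "mean_temp_c",
            "sex", "diameter_mm", "stage", "gonad_mass_g",
        ],
    )
    df.insert(0, "animal_id", [f"a{i}" for i in range(len(df))])
    df["location"] = ""
    return df


class TestConjugateOracle:
    def test_single_cell_matches_dirichlet_multinomial(self):
        """With the smoother and random effects disabled, one cell of counts
        (3,2,1,0) under a Dirichlet(1) prior has posterior mean proportions
        (n_k + 1) / (n + 4) = (4,3,2,1)/10; the sampler must agree within
        Monte-Carlo error."""
        df = _single_cell_table([3, 2, 1, 0])
        spec = StageModelSpec(
            experiment="exp2",
            use_gp=False,
            location_effects=False,
            mesocosm_effects=False,
            mcmc=MCMCConfig(n_chains=2, steps=2000, warmup=500, thin=5),
        )
        draws = fit_stage_model(df, spec, seed=0)
        probs = predict_stage_probs(draws, ("F", "16C"))
        expected = np.array([4, 3, 2, 1]) / 10
        mc_se = probs.std(axis=0) / np.sqrt(200)  # generous ESS floor
        assert np.all(np.abs(probs.mean(axis=0) - expected) < 3 * np.maximum(mc_se, 0.004))

    def test_prior_predictive_is_dirichlet_uniform(self):
        """Almost-empty data: cell proportions revert to the Dirichlet(1)
        prior mean of 1/4 per stage (one animal per stage keeps the
        likelihood proper; posterior mean is (1+1)/(4+4) = 1/4 exactly)."""
        df = _single_cell_table([1, 1, 1, 1])
        spec = StageModelSpec(
            experiment="exp2", use_gp=False, location_effects=False,
            mesocosm_effects=False,
            mcmc=MCMCConfig(n_chains=2, steps=2000, warmup=500, thin=5),
        )
        draws = fit_stage_model(df, spec, seed=1)
        probs = predict_stage_probs(draws, ("F", "16C"))
        assert np.all(np.abs(probs.mean(axis=0) - 0.25) < 0.02)


class TestFitContracts:
    def test_missing_covariate_rejected(self, exp1_data):
        with pytest.raises(ValueError, match="covariate"):
            fit_stage_model(exp1_data.drop(columns=["sex"]), StageModelSpec.exp1())
        with pytest.raises(ValueError):
            fit_stage_model(exp1_data.iloc[:0], StageModelSpec.exp1())

    def test_complete_separation_warns_but_fits(self):
        df = _single_cell_table([0, 0, 0, 12])
        spec = StageModelSpec(
            experiment="exp2", use_gp=False, location_effects=False,
            mesocosm_effects=False, mcmc=MCMCConfig.preset("smoke"),
        )
        with pytest.warns(UserWarning, match="separation"):
            fit_stage_model(df, spec, seed=0)

    def test_exp2_requires_locations(self, exp1_data):
        with pytest.raises(ValueError, match="location"):
            fit_stage_model(exp1_data, StageModelSpec.exp2())


class TestPredictions:
    def test_simplex_at_every_draw(self, stage_fit):
        probs = predict_stage_probs(stage_fit, ("F", "lanina"))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert probs.min() >= 0

    def test_deterministic_given_draws(self, stage_fit):
        a = predict_stage_probs(stage_fit, ("M", "elnino"))
        b = predict_stage_probs(stage_fit, ("M", "elnino"))
        assert np.array_equal(a, b)

    def test_recovers_monotone_temperature_decline(self, stage_fit):
        """The generating truth has female stage-IV share falling from 13 to
        20 degC; the fitted smoother must reproduce that ordering."""
        p13 = predict_stage_probs(stage_fit, ("F", "constant", 13.0))[:, 3].mean()
        p20 = predict_stage_probs(stage_fit, ("F", "constant", 20.0))[:, 3].mean()
        assert p20 < p13

    def test_off_grid_query_interpolates(self, stage_fit):
        p = predict_stage_probs(stage_fit, ("F", "constant", 14.5))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_extrapolation_warns(self, stage_fit):
        with pytest.warns(UserWarning, match="extrapolat"):
            predict_stage_probs(stage_fit, ("F", "constant", 23.0))

    def test_unknown_treatment_rejected(self, stage_fit):
        with pytest.raises(ValueError):
            predict_stage_probs(stage_fit, ("F", "heatdome"))


class TestNullCoverage:
    def test_treatment_contrasts_cover_zero_under_null(self):
        """50 replicates simulated with identical stage probabilities in all
        cells: the 95% credible interval of the La Nina minus El Nino
        female stage-IV contrast must cover 0 in at least 90% of them
        (checked on the categorical reduction of the model, whose posterior
        is exact)."""
        import urchintherm.synthetic_data as sd

        shared = np.array([0.1, 0.15, 0.25, 0.5])
        params = ut.GeneratingParams(
            stage_probs={
                (s, t): shared for s in "FM"
                for t in ["10C", "13C", "16C", "17C", "18C", "20C", "elnino", "lanina"]
            }
        )
        design = ut.ExperimentDesign.exp1_default()
        model = CategoricalContrastModel.treatment_type_sex(design)
        covered = 0
        rng = np.random.default_rng(2024)
        for _ in range(50):
            df = sd.simulate_experiment1(params, design, seed=int(rng.integers(2**31 - 1)))
            fit = model.fit(df)
            gidx_ln = model.groups.index(("F", "la_nina"))
            gidx_en = model.groups.index(("F", "el_nino"))
            post = [
                np.random.default_rng(int(rng.integers(2**31 - 1))).dirichlet(
                    1.0 + fit.group_counts[g], 4000
                )[:, 3]
                for g in (gidx_ln, gidx_en)
            ]
            diff = post[0] - post[1]
            lo, hi = np.quantile(diff, [0.025, 0.975])
            covered += lo <= 0.0 <= hi
        assert covered >= 45  # >= 90% of 50
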