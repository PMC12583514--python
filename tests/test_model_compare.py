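"""Bridge-sampling marginal likelihoods, Bayes factors, calibration."""

import numpy as np
import pandas as pd
import pytest

import urchintherm as ut
from urchintherm import model_compare as mc


def _one_cell_fit(counts=(3, 2, 1, 0)):
    tab = pd.DataFrame(
        [{"sex": "F", "treatment_tag": "16C", "location": "",
          "n1": counts[0], "n2": counts[1], "n3": counts[2], "n4": counts[3]}]
    )
    model = mc.CategoricalContrastModel("one_cell", [("F", "16C", "")], lambda s, t, l: ())
    return model.fit(tab)


class TestBridgeOracles:
    def test_dirichlet_multinomial_closed_form(self):
        """Counts (3,2,1,0), Dirichlet(1): exact log marginal is
        log[60 * B(1+n)/B(1)] = log(60/5040); bridge must land within 0.05."""
        fit = _one_cell_fit()
        exact = np.log(60.0) + np.log(6.0 * 2.0 / 362880.0 * 6.0)
        assert fit.closed_form_log_marginal() == pytest.approx(exact, abs=1e-10)
        res = mc.log_marginal_bridge(fit.sample_posterior(4000, seed=1), fit.log_joint, seed=2)
        assert res.converged
        assert res.log_marginal == pytest.approx(exact, abs=0.05)

    def test_normal_normal_closed_form(self, rng):
        """iid Normal(mu, 1) likelihood with Normal(0, 2) prior on mu: the
        bridge estimate must match the analytic marginal within 0.02."""
        y = rng.normal(0.3, 1.0, 25)
        sigma, tau = 1.0, 2.0
        exact = mc.normal_normal_log_marginal(y, sigma, 0.0, tau)
        v = 1.0 / (y.size / sigma**2 + 1.0 / tau**2)
        post = rng.normal(v * y.sum() / sigma**2, np.sqrt(v), 4000)[:, None]

        def log_joint(th):
            th = np.atleast_2d(th)
            ll = -0.5 * ((y[None, :] - th[:, [0]]) / sigma) ** 2
            ll = ll.sum(axis=1) - y.size * 0.5 * np.log(2 * np.pi * sigma**2)
            lp = -0.5 * (th[:, 0] / tau) ** 2 - 0.5 * np.log(2 * np.pi * tau**2)
            return ll + lp

        res = mc.log_marginal_bridge(post, log_joint, seed=5)
        assert res.log_marginal == pytest.approx(exact, abs=0.02)

    def test_seed_stability_within_mc_error(self):
        fit = _one_cell_fit((8, 4, 2, 6))
        r1 = mc.log_marginal_bridge(fit.sample_posterior(4000, seed=10), fit.log_joint, seed=11)
        r2 = mc.log_marginal_bridge(fit.sample_posterior(4000, seed=20), fit.log_joint, seed=21)
        tol = 3 * np.hypot(r1.mc_error, r2.mc_error) + 1e-4
        assert abs(r1.log_marginal - r2.log_marginal) < max(tol, 0.02)

    def test_nonfinite_posterior_joint_reported(self):
        draws = np.random.default_rng(0).standard_normal((200, 3))
        with pytest.raises(FloatingPointError, match="non-finite"):
            mc.log_marginal_bridge(
                draws, lambda t: np.full(np.atleast_2d(t).shape[0], np.nan), seed=0
            )


class TestBayesFactor:
    def test_self_comparison_is_unity(self, exp1_data):
        design = ut.ExperimentDesign.exp1_default()
        counts = mc.counts_from_animals(exp1_data)
        m = mc.CategoricalContrastModel.treatment_type_sex(design)
        comp = mc.bayes_factor(m.fit(counts), m.fit(counts), seed=3)
        assert abs(comp.log_bf) < 3 * comp.mc_error + 0.02

    def test_bf_identity_and_verdicts(self, exp1_data):
        design = ut.ExperimentDesign.exp1_default()
        counts = mc.counts_from_animals(exp1_data)
        full = mc.CategoricalContrastModel.treatment_type_sex(design)
        null = mc.CategoricalContrastModel.sex_only(design)
        comp = mc.bayes_factor(full.fit(counts), null.fit(counts), seed=4)
        la, lb = comp.model_labels
        assert comp.log_bf == comp.log_marginals[la] - comp.log_marginals[lb]
        assert comp.bayes_factor == pytest.approx(np.exp(comp.log_bf))
        assert "evidence" in comp.verdict or "favors" in comp.verdict

    def test_bridge_matches_conjugate_closed_form(self, exp1_data):
        """Dual route: the bridge-sampled marginals agree with the exact
        Dirichlet-multinomial marginals for both contrast models."""
        design = ut.ExperimentDesign.exp1_default()
        counts = mc.counts_from_animals(exp1_data)
        for model in (
            mc.CategoricalContrastModel.treatment_type_sex(design),
            mc.CategoricalContrastModel.sex_only(design),
        ):
            fit = model.fit(counts)
            res = mc.log_marginal_bridge(fit.sample_posterior(6000, seed=7), fit.log_joint, seed=8)
            assert res.log_marginal == pytest.approx(
                fit.closed_form_log_marginal(), abs=0.05
            )

    def test_mismatched_data_rejected(self, exp1_data):
        design = ut.ExperimentDesign.exp1_default()
        c1 = mc.counts_from_animals(exp1_data)
        c2 = mc.counts_from_animals(ut.simulate_experiment1(seed=99))
        full = mc.CategoricalContrastModel.treatment_type_sex(design)
        null = mc.CategoricalContrastModel.sex_only(design)
        with pytest.raises(ValueError, match="fingerprint"):
            mc.bayes_factor(full.fit(c1), null.fit(c2))

    def test_antisymmetry_of_log_bf(self, exp1_data):
        design = ut.ExperimentDesign.exp1_default()
        counts = mc.counts_from_animals(exp1_data)
        full = mc.CategoricalContrastModel.treatment_type_sex(design).fit(counts)
        null = mc.CategoricalContrastModel.sex_only(design).fit(counts)
        ab = full.closed_form_log_marginal() - null.closed_form_log_marginal()
        ba = null.closed_form_log_marginal() - full.closed_form_log_marginal()
        assert ab == -ba


class TestCalibration:
    def test_smoke_run_bookkeeping(self):
        design = ut.ExperimentDesign("exp1", (("10C", 1, 20), ("elnino", 1, 20)))
        full = mc.CategoricalContrastModel.treatment_type_sex(design)
        null = mc.CategoricalContrastModel.sex_only(design)
        table, summary = mc.calibrate_bf(full, null, design, n_datasets=5, seed=0)
        assert len(table) == 10
        assert np.isfinite(table["log_bf"]).all()
        assert set(table["generator"]) == {"full", "null"}
        assert summary["n_failures"] == 0

    def test_null_generated_data_favor_null(self):
        """Occam penalty: datasets simulated from the null prior favour the
        null in the clear majority of replicates."""
        design = ut.ExperimentDesign.exp1_default()
        full = mc.CategoricalContrastModel.treatment_type_sex(design)
        null = mc.CategoricalContrastModel.sex_only(design)
        table, summary = mc.calibrate_bf(
            full, null, design, n_datasets=20, seed=1, generators=("null",)
        )
        assert summary["frac_favoring_generator_null"] >= 0.75

    def test_bf_monotone_in_effect_size(self):
        """Median BF(full vs null) is non-decreasing as the simulated
        treatment effect grows from zero through moderate to the calibrated
        (reported-scale) contrast."""
        design = ut.ExperimentDesign.exp1_default()
        full = mc.CategoricalContrastModel.treatment_type_sex(design)
        null = mc.CategoricalContrastModel.sex_only(design)
        base = np.array([0.1, 0.1, 0.1, 0.7])
        suppressed = {0.0: base, 0.5: np.array([0.3, 0.15, 0.15, 0.4]),
                      1.0: np.array([0.55, 0.18, 0.12, 0.15])}
        medians = []
        for level, en in suppressed.items():
            truth = {
                (s, t): (en if t == "el_nino" else base)
                for s in "FM" for t in ("constant", "el_nino", "la_nina")
            }
            import urchintherm.synthetic_data as sd

            bfs = []
            for seed in range(10):
                df = sd.simulate_from_fitted(full, truth, design, seed=1000 + seed)
                counts = mc.counts_from_animals(df)
                bfs.append(
                    full.fit(counts).closed_form_log_marginal()
                    - null.fit(counts).closed_form_log_marginal()
                )
            medians.append(np.median(bfs))
        assert medians[0] <= medians[1] <= medians[2]
        assert medians[2] > np.log(100.0)
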