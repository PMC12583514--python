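# urchintherm

Bayesian analysis of **thermal suppression of sea-urchin reproduction** in
mesocosm heatwave experiments, built as a reusable, fully tested pipeline.

Purple urchins (*Strongylocentrotus purpuratus*) in Southern California
recruit poorly during El Niño events even though temperatures stay below
lethal limits.  One candidate mechanism is sublethal suppression of
gametogenesis: animals build gonads but fail to mature gametes.  This
package implements the statistical machinery for testing that mechanism
with mesocosm experiments that expose animals to constant temperatures
(10–20 °C) and to simulated El Niño (21→18 °C, mean 20 °C) and La Niña
(18→14 °C, mean 16 °C) seasonal trajectories:

* **Thermal schedules** — daily set-point trajectories with acclimation
  ramps, ≤ 0.5 °C/day adjustments, and event means hit exactly.
* **Synthetic data** — per-animal datasets (stage I–IV, gonad mass, sex,
  size, tank) with generating truths calibrated to the published posterior
  estimates, for both the gradient and the split-plot population design.
* **Stage model** — Bayesian multinomial logistic regression of maturity
  stage: Dirichlet(1) baseline proportions per treatment, a squared-
  exponential Gaussian-process smoother f(T̄) over mean temperature by sex,
  sex × treatment effects, and mesocosm (tank) random intercepts,

      η_k = alr_k(π_t) + male·(m_k + b_{t,k}) + f_{sex,k}(T̄) + u_tank,

  with an Exp-2 variant (categorical terms only, location random effects).
* **Gonad model** — hierarchical Gamma regression with log link: a cubic
  thermal-performance curve in T̄, allometry γ·log(diameter/50 mm), event
  offsets, and tank intercepts (integrated out by adaptive Gauss–Hermite
  quadrature); masses are reported standardized to a 50 mm animal.
* **Model comparison** — bridge-sampling marginal likelihoods, Bayes
  factors (BF > 100 decisive, 10–100 strong, < 1 favours the alternative),
  and simulation-based calibration of BF behaviour.
* **Summaries** — shortest-interval HPDs, draw-wise contrasts
  (percentage-point stage declines, relative gonad reductions), Bayesian P,
  split-Rhat convergence diagnostics (gate 1.001; 1.01 for short CI chains).

MCMC runs on differential-evolution ensemble sampling (emcee) with four
independent ensembles as chains; every model exposes its exact joint
density on the unconstrained scale, which is what the bridge estimator
consumes.  See `docs/methods.md` for the full model descriptions, priors,
and numerical choices.

## Worked example

```python
import urchintherm as ut
from urchintherm.stage_model import StageModelSpec, fit_stage_model, predict_stage_probs
from urchintherm.gonad_model import GonadModelSpec, fit_gonad_model, standardized_mass
from urchintherm import summaries as sm

# one synthetic run of the gradient experiment: 300 animals, 20 mesocosms
data = ut.simulate_experiment1(seed=1)

stage = fit_stage_model(data, StageModelSpec.exp1(mode="test"), seed=0)
p_ln = predict_stage_probs(stage, ("F", "lanina"))[:, 3]   # stage-IV share
p_en = predict_stage_probs(stage, ("F", "elnino"))[:, 3]
diff, table = sm.stage_contrast(p_ln, p_en, label="female decline")
print(f"La Nina F stage IV: {100 * p_ln.mean():.1f}%")
print(f"El Nino F stage IV: {100 * p_en.mean():.1f}%")
print(f"decline: {table.mean:.1f} pp (95% HPD {table.hpd95[0]:.1f}-{table.hpd95[1]:.1f})")

gonad = fit_gonad_model(data, GonadModelSpec(mode="test"), seed=0)
m13 = standardized_mass(gonad, ("constant", 13.0))
m20 = standardized_mass(gonad, ("constant", 20.0))
red, rt = sm.relative_reduction(m13, m20, label="20 vs 13 C")
print(f"mass at 16 C: {standardized_mass(gonad, ('constant', 16.0)).mean():.2f} g")
print(f"reduction 20 vs 13 C: {100 * rt.mean:.1f}%")
```

prints (two test-mode fits, ~2 minutes):

```
La Nina F stage IV: 89.6%
El Nino F stage IV: 16.9%
decline: 72.7 pp (95% HPD 56.5-87.3)
mass at 16 C: 12.10 g
reduction 20 vs 13 C: 46.3%
```

The generating truths behind this run are the published estimates — 89 %
and 15 % stage-IV females (a 74-point decline), 11.84 g at constant 16 °C,
and a 42 % production decrease at 20 °C versus the 13 °C peak — so the
printed numbers show the fits recovering them at the experiment's actual
replication.

The same pipeline is scriptable from the shell:

```bash
urchintherm run-all --experiment exp1 --mode test --seed 1 --out runs/exp1
urchintherm summarize --run runs/exp1
```

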