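# Methods

`urchintherm` reimplements, as a tested pipeline, the Bayesian analysis of
two mesocosm experiments on thermal suppression of purple-urchin
(*Strongylocentrotus purpuratus*) reproduction: a thermal-gradient
experiment contrasting six constant temperatures with simulated El Niño and
La Niña seasonal trajectories, and a split-plot common-garden experiment
comparing source populations.  Because the original animal-level data live
in external repositories, every analysis here runs on synthetic data drawn
from generating truths calibrated to the study's printed posterior
estimates; the tests are therefore parameter-recovery and oracle-agreement
checks, not reproductions of the original data analysis.

## Thermal schedules

Constant treatments ramp linearly from ambient (13.3 °C) to target over 14
days and hold; the ramp is generated but excluded from the analysis window,
so each mesocosm's temperature covariate is its post-ramp mean.  Event
treatments (El Niño 21→18 °C, mean 20 °C; La Niña 18→14 °C, mean 16 °C) are
built as an initial plateau at the seasonal peak followed by a constant-rate
decline of at most 0.5 °C/day — one manual set-point adjustment per morning
— with the decline onset solved by root finding so the window mean matches
the historical event mean exactly (the day-sampled mean is continuous and
monotone in the onset, so the root is exact to float precision).  The true
historical trajectories are not tabulated anywhere we can read them from;
the plateau-then-decline shape is the simplest trajectory consistent with
the reported endpoint/mean triples and the adjustment rule.  One set point
per day; no within-day variation.

## Synthetic data generator

One row per animal: mesocosm, treatment, realized mean temperature, sex
(Bernoulli 0.5 — sex ratios were not reported), test diameter (uniform on
the reported 42.12–69.46 mm range — only mean and range were reported),
gametogenic stage I–IV, and gonad wet mass.

Stage truths are sex × treatment cell probabilities.  Cells pinned by
printed estimates: stage-IV shares 0.89 / 0.15 (La Niña / El Niño females),
0.92 / 0.44 (males), 0.812 / 0.25 (constant-20 males / females).  Unpinned
cells follow the qualitative pattern of the reported figures: females
mature (stage-IV share 0.75–0.85) across 10–18 °C and collapse at 20 °C,
males flat near 0.81 across all constant levels; in collapsed cells most
remaining mass sits in stage I, in mature cells in stage III.  These splits
are assumptions, stated here once and not tuned.  Mesocosm (and, for the
split-plot design, location) random intercepts act on the non-reference
stage logits, shifting mass between stage I and the maturing stages.

Gonad truths: log mean mass for a 50 mm animal follows a cubic in raw
temperature interpolating four pinned values — 12.414 g at the 13 °C peak
(so that constant 20 °C, 7.2 g, is a 42 % decrease), 9.683 g at 10 °C (a
22 % decrease), 11.84 g at 16 °C, 7.2 g at 20 °C.  Event offsets reproduce
8.69 g (La Niña vs constant 16) and 7.03 g (El Niño vs constant 20).
Allometry multiplies log(diameter/50 mm) with exponent 2.5 (gonad mass
scales a little below body volume; the value is a default, recovered not
assumed in fits).  Masses are Gamma with shape 10 (CV ≈ 0.32, matching the
scatter visible in the reported intervals).  Random-effect scales default
to 0.25 (logit) and 0.10 (log); the study does not print them.

What the generator does *not* emulate: feeding, growth, spawning phenology,
mortality, observation error in staging, or any real Scripps Pier daily
series.  Passing recovery tests therefore shows the inference machinery is
correct and well calibrated at the study's design size — not that the
biological conclusions would replicate on new animals.

## Stage model

Unordered multinomial logit with stage I as the reference category (the
Dirichlet prior on stage proportions is only coherent for the unordered
parameterization; an ordered-logit variant is out of scope).  For stage
k ∈ {II, III, IV}:

    eta_k = alr_k(pi_treatment) + male·(m_k + b_{treatment,k})
            + f_{sex,k}(x) + u_mesocosm [+ v_location]

* `pi_treatment`: baseline stage proportions per treatment category with
  Dirichlet(1) priors, mapped to logits by the additive log-ratio
  transform (the sampler works on the unconstrained scale with the exact
  pushforward density).
* `f_{sex,k}`: zero-mean GP over standardized mean temperature, squared-
  exponential kernel, length-scale and scale shared across sexes and stages
  with folded-normal(1, 1) hyperpriors, 1e-6 jitter; fitted per sex and per
  stage because the sexes' thermal responses differ qualitatively.  Event
  animals enter the smoother at their realized means (20, 16 °C) *and*
  carry categorical offsets; the offsets are identified because constant
  mesocosms share those temperatures.
* sex and sex × treatment coefficients: Normal(0, 2.5).
* `u`: mesocosm intercepts, non-centered, half-normal(0, 1) scale; a single
  intercept shared across stages (shifting stage-I vs the rest) keeps the
  random-effect dimension at one per tank.
* Split-plot variant: no smoother (categorical terms only), location
  intercepts with a folded Student-t(3, scale 0.1) scale hyperprior.

## Gonad model

Gamma likelihood, log link:

    log mu = cubic(x) + gamma·log(d/50) + delta_elnino + delta_lanina + u_m

Sex is absent by design (the reported final model carries treatment but no
sex terms).  Priors: Normal(0, 5) coefficients, Exponential(0.1) shape,
half-normal(0, 2) mesocosm scale; `prior_overrides` rescales any of these
for sensitivity analysis.  Standardized masses fix d = 50 mm and u = 0 (the
population-median tank) rather than integrating over tanks; with a log
link, integrating would multiply every mass by exp(sigma²/2) and cancel in
every ratio reported.

Two numerical choices matter.  The cubic is fitted in an orthonormalized
(QR) basis of the standardized-temperature powers — raw powers over six
distinct temperatures are nearly collinear and cripple sampler mixing;
predictions are basis-independent.  And the 20 mesocosm intercepts are
integrated out of the likelihood by adaptive Gauss–Hermite quadrature (21
nodes centred at the Newton-located conditional mode of each tank, per
posterior evaluation).  Sampling the intercepts explicitly — centred or
non-centred — leaves an ensemble sampler stuck in the small-sigma funnel
and produces a spurious heavy upper tail on the mesocosm scale; with the
intercepts marginalized the 9-parameter posterior mixes to split-Rhat
< 1.001 in the test preset, and the sigma posterior concentrates where the
tank-level residuals actually are.  `unpack` reports each tank's
conditional mode as its intercept estimate.

## Sampling and convergence

Posteriors are sampled with differential-evolution ensemble MCMC (emcee;
80 % DE moves, 20 % snooker), vectorized over walkers, with ~2.5× dimension
walkers per ensemble and four independent ensembles serving as chains for
split-Rhat.  Walkers start in a small ball around the numerically located
posterior mode.  Presets: test mode 4 × 3,000 post-warmup steps after
1,500 (stage model) and 4 × 3,000 after 1,000 (gonad model); paper mode
4 × 12,000 after 2,000.  Convergence is gated on the *reported* quantities — cell stage
probabilities and standardized masses — at split-Rhat < 1.001 for
full-length runs, relaxed to < 1.01 for the short test-preset chains the CI
suite runs.  GP hyperparameters are tracked but not gated: with six
distinct temperatures the length-scale is weakly identified and mixes an
order of magnitude more slowly than anything reported, without moving the
reported quantities.

## Model comparison

Marginal likelihoods use the iterative optimal-bridge estimator: half the
posterior draws moment-match a multivariate-normal proposal on the
unconstrained scale, the other half feed the fixed-point iteration (log-
space, relative tolerance 1e-8, ≤ 1,000 iterations), with a delta-method
Monte-Carlo error treating draws as independent.  Oracle tests pin the
estimator to the exact Dirichlet-multinomial and normal-normal marginals
within 0.05 and 0.02 log units.

Bayes-factor hypothesis tests contrast categorical stage models sharing one
prior construction — Dirichlet(1) proportions over groups of design cells:
treatment-type × sex versus sex-only (or intercept-only) for the gradient
experiment, location × treatment × sex versus treatment × sex for the
split-plot.  Both models of a contrast keep the data as counts over the
same finest cells, so multinomial coefficients cancel exactly in the BF,
and the conjugate posterior makes each "fit" exact.  Calibration simulates
datasets from each model's own prior predictive at the design's size, fits
both, and records which model the BF favours (20 datasets per generator in
the test configuration, 200 in paper mode).  Verdict bands: BF > 100
decisive, 10–100 strong, < 1 favours the second model.

## Summaries

HPD intervals are the shortest contiguous window of sorted draws (exact for
the empirical distribution; an exhaustive-search oracle checks every
window up to n = 1,000).  All contrasts are draw-wise: stage-IV
comparisons as percentage-point differences (89 − 15 = 74), gonad and
split-plot stage comparisons as relative reductions (1 − B/A); both are
tagged in output.  Bayesian P defaults to the two-sided tail
2·min(P(Δ>0), P(Δ<0)) with the one-sided value also available, since the
convention is rarely stated in print.

## Problem sizes and known limitations

The test suite and the acceptance script run the full gradient-experiment
design (300 animals, 20 mesocosms) with test-preset chains — a stage fit
takes ~1.5 minutes and a gonad fit ~30 s on one core; paper-preset
settings reproduce the original chain lengths when wanted.  Because one
simulated dataset carries several percentage points of design-level noise
on every recovery quantity, per-cell recovery checks and the acceptance
script average the posterior means over a few independent replicate
simulations (3–5 datasets, each fitted in full); per-replicate values are
reported alongside the averages.  Calibration properties
that would need dozens of GP fits (null coverage over 50 replicates,
BF calibration) run on the conjugate categorical reduction of the stage
model, whose posterior is exact, so they probe the statistical property
rather than sampler throughput.

Recovery at the experiment's replication is noise-limited: a cell with ~30
animals of one sex has binomial sd ≈ 0.05 on a stage-IV share near 0.9, so
single-simulation posterior means can sit up to ~0.09 from truth for the
extreme cells; contrasts are more stable.  Tolerances in the acceptance
tests mirror the printed credible-interval half-widths and absorb most,
not all, of this variation — an unlucky generator seed can breach a cell
tolerance without anything being wrong.

Other documented simplifications: one shared mesocosm intercept across
stage logits (not per-stage); GP length-scale/scale shared across sexes and
stages; the exact sub-stage split of non-stage-IV mass in the generator is
an assumption; the split-plot experiment's per-cell sample sizes are not
printed and default to 12 animals per location × treatment.
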