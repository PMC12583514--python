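"""Ensemble-MCMC backbone shared by the stage and gonad models.

Posteriors are sampled with affine-invariant / differential-evolution
ensemble MCMC (emcee).  Convergence is judged across independent ensembles:
each of ``n_chains`` ensembles is started from its own seed and treated as
one chain for split-Rhat, so agreement between chains reflects genuinely
independent explorations of the posterior.

All models expose their joint density on an unconstrained parameter vector
(positive scales are log-transformed with the Jacobian included), which is
also exactly what bridge-sampling marginal-likelihood estimation needs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import emcee
import numpy as np
from scipy.optimize import minimize

from .summaries import RHAT_THRESHOLD, rhat_table

__all__ = ["MCMCConfig", "PosteriorDraws", "run_ensemble_mcmc", "find_map"]


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.

    ``steps`` counts post-warmup ensemble moves; retained draws per chain are
    ``(steps // thin) * n_walkers``.  ``mode`` presets: "test" (4 chains,
    1,500 post-warmup steps after 500 warmup) for CI-scale runs and "paper"
    (4 × 12,000 after 2,000) matching the original analysis settings.
    """

    n_chains: int = 4
    steps: int = 1500
    warmup: int = 500
    thin: int = 10
    n_walkers: int | None = None  # default: ~2.5x dimension, even, >= 64

    @classmethod
    def preset(cls, mode: str) -> "MCMCConfig":
        if mode == "test":
            return cls()
        if mode == "paper":
            return cls(steps=12000, warmup=2000, thin=40)
        if mode == "smoke":  # minutes-scale sanity runs only
            return cls(n_chains=2, steps=200, warmup=200, thin=5)
        raise ValueError(f"unknown MCMC mode {mode!r}")

    def walkers_for(self, ndim: int) -> int:
        if self.n_walkers is not None:
            n = self.n_walkers
        else:
            n = max(64, int(2.5 * ndim))
        return n + (n % 2)


@dataclass
class PosteriorDraws:
    """Labelled MCMC draws with chain structure and diagnostics.

    ``params`` maps names to arrays shaped (chain, draw, ...);
    ``unconstrained`` is (chain, draw, dim) on the sampling scale, and
    ``log_prob`` re-evaluates the unnormalized joint there (used by bridge
    sampling).  ``meta`` records seeds, spec fingerprints, and whatever a
    model needs to make predictions from its own draws.
    """

    params: dict[str, np.ndarray]
    unconstrained: np.ndarray
    rhat: dict[str, float]
    seed: int
    log_prob: Callable[[np.ndarray], float] | None = None
    acceptance_fraction: float = float("nan")
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return int(self.unconstrained.shape[0])

    @property
    def n_draws(self) -> int:
        return int(self.unconstrained.shape[0] * self.unconstrained.shape[1])

    def flat(self, name: str) -> np.ndarray:
        """Draws of one parameter with chains flattened."""
        arr = self.params[name]
        return arr.reshape((arr.shape[0] * arr.shape[1],) + arr.shape[2:])

    def flat_unconstrained(self) -> np.ndarray:
        return self.unconstrained.reshape(-1, self.unconstrained.shape[-1])

    def max_rhat(self) -> float:
        return max(self.rhat.values()) if self.rhat else float("nan")

    def reported_rhat(self) -> float:
        """Largest split-Rhat over the reported quantities (``meta['reported']``
        names, e.g. cell stage probabilities); all parameters if unset."""
        names = self.meta.get("reported")
        if not names:
            return self.max_rhat()
        vals = [v for k, v in self.rhat.items() if any(k.startswith(n) for n in names)]
        return max(vals) if vals else float("nan")

    def converged(self, threshold: float = RHAT_THRESHOLD) -> bool:
        return bool(self.reported_rhat() < threshold)


def find_map(
    log_prob: Callable[[np.ndarray], float],
    x0: np.ndarray,
    maxiter: int = 500,
) -> np.ndarray:
    """Posterior mode (numerical-gradient L-BFGS); used to centre walker
    initialization so burn-in is spent exploring, not finding, the mass."""
    res = minimize(
        lambda x: -log_prob(x), x0, method="L-BFGS-B", options={"maxiter": maxiter}
    )
    return np.asarray(res.x, dtype=float)


def run_ensemble_mcmc(
    log_prob: Callable[[np.ndarray], float],
    ndim: int,
    seed: int,
    config: MCMCConfig,
    init: np.ndarray | None = None,
    init_scatter: float = 0.05,
    param_unpack: Callable[[np.ndarray], dict[str, np.ndarray]] | None = None,
) -> PosteriorDraws:
    """Run ``config.n_chains`` independent ensembles and collect draws.

    ``param_unpack`` maps one unconstrained vector to named constrained
    parameters; it is applied to every retained draw to build the labelled
    arrays that Rhat is computed on.
    """
    rng = np.random.default_rng(seed)
    n_walkers = config.walkers_for(ndim)
    if init is None:
        init = np.zeros(ndim)
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]

    chains = []
    acc = []
    for c in range(config.n_chains):
        chain_seed = int(rng.integers(0, 2**31 - 1))
        chain_rng = np.random.default_rng(chain_seed)
        p0 = init + init_scatter * chain_rng.standard_normal((n_walkers, ndim))
        sampler = emcee.EnsembleSampler(
            n_walkers, ndim, log_prob, moves=moves, vectorize=True
        )
        sampler._random = np.random.RandomState(chain_seed)
        state = sampler.run_mcmc(p0, config.warmup, progress=False)
        sampler.reset()
        sampler.run_mcmc(state, config.steps, progress=False)
        # (steps//thin, walkers, dim) -> flatten steps-major so the chain
        # keeps temporal order for the split-halves diagnostic.
        raw = sampler.get_chain(thin=config.thin)
        chains.append(raw.reshape(-1, ndim))
        acc.append(float(np.mean(sampler.acceptance_fraction)))

    unconstrained = np.stack(chains)  # (chain, draw, dim)

    params: dict[str, np.ndarray] = {}
    if param_unpack is not None:
        probe = param_unpack(unconstrained[0, 0])
        for name, val in probe.items():
            val = np.asarray(val, dtype=float)
            params[name] = np.empty(unconstrained.shape[:2] + val.shape)
        for i in range(unconstrained.shape[0]):
            for j in range(unconstrained.shape[1]):
                for name, val in param_unpack(unconstrained[i, j]).items():
                    params[name][i, j] = val
    else:
        params["theta"] = unconstrained.copy()

    rhat = rhat_table(params)
    mean_acc = float(np.mean(acc))
    if mean_acc < 0.05:
        warnings.warn(
            f"very low ensemble acceptance fraction ({mean_acc:.3f}); "
            "draws are likely unreliable",
            RuntimeWarning,
        )
    return PosteriorDraws(
        params=params,
        unconstrained=unconstrained,
        rhat=rhat,
        seed=seed,
        log_prob=log_prob,
        acceptance_fraction=mean_acc,
        meta={"n_walkers": n_walkers, "config": config},
    )
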