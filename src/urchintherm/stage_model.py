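"""Bayesian multinomial model of gametogenic stage (I–IV).

Stage probabilities are modelled on the logit scale with stage I as the
reference category.  For each animal the stage-k logit (k = II..IV) is

    eta_k = alr_k(pi_treatment) + male * (m_k + b_{treatment,k})
            + f_{sex,k}(x) + u_mesocosm [+ v_location]

where ``pi_treatment`` are per-treatment baseline stage proportions with
vague Dirichlet(1) priors, ``f_{sex,k}`` is a zero-mean Gaussian-process
smoother over standardized mean temperature with a squared-exponential
kernel (shared length-scale and scale hyperparameters with folded-normal
(mean 1, sd 1, lower bound 0) hyperpriors), and ``u`` / ``v`` are zero-mean
mesocosm / source-location random intercepts.  Event-treatment animals
(El Niño, La Niña) contribute to the smoother through their realized mean
temperatures (20 and 16 °C) in addition to their categorical offsets.

The population-comparison variant drops the smoother (categorical terms
only) and adds location random effects whose scale carries a folded
Student-t (df 3, scale 0.1) hyperprior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, cholesky
from scipy.special import gammaln, logsumexp
from scipy.stats import t as student_t


def _folded_t_logpdf(x, df: float, scale: float):
    """Log density of a Student-t at x > 0 (fold adds log 2 at the caller)."""
    return student_t.logpdf(x, df=df, scale=scale)


def _batch_cholesky(K: np.ndarray):
    """Cholesky of a (W, G, G) batch; rows that fail factorization are
    replaced by the identity and flagged (they get -inf density)."""
    try:
        return np.linalg.cholesky(K), np.zeros(K.shape[0], dtype=bool)
    except np.linalg.LinAlgError:
        W, G, _ = K.shape
        out = np.empty_like(K)
        bad = np.zeros(W, dtype=bool)
        for i in range(W):
            try:
                out[i] = np.linalg.cholesky(K[i])
            except np.linalg.LinAlgError:
                out[i] = np.eye(G)
                bad[i] = True
        return out, bad

from .mcmc import MCMCConfig, PosteriorDraws, find_map, run_ensemble_mcmc

__all__ = [
    "StageModelSpec",
    "sq_exp_kernel",
    "fit_stage_model",
    "predict_stage_probs",
    "GP_JITTER",
]

GP_JITTER = 1e-6

TYPE_ORDER = ("constant", "el_nino", "la_nina")


def sq_exp_kernel(x1, x2, length_scale: float, scale: float) -> np.ndarray:
    """Squared-exponential covariance sigma^2 exp(-(x1-x2)^2 / (2 l^2)).

    Inputs are standardized temperatures; broadcasting gives the Gram matrix
    when ``x1`` and ``x2`` are column/row vectors.
    """
    if length_scale <= 0 or scale <= 0:
        raise ValueError("kernel hyperparameters must be positive")
    d = np.subtract.outer(np.asarray(x1, float), np.asarray(x2, float))
    return scale**2 * np.exp(-0.5 * (d / length_scale) ** 2)


@dataclass(frozen=True)
class StageModelSpec:
    """Structure and priors of one stage-model fit.

    ``mode`` selects MCMC presets ("test": 4 chains × 1,500 post-warmup
    steps after 500 warmup; "paper": 4 × 12,000 after 2,000).  ``coef_sd``
    is the normal prior sd for sex and sex-by-treatment coefficients.
    """

    experiment: str = "exp1"
    use_gp: bool = True
    location_effects: bool = False
    mesocosm_effects: bool = True
    coef_sd: float = 2.5
    dirichlet_alpha: float = 1.0
    mode: str = "test"
    mcmc: MCMCConfig | None = None

    def __post_init__(self) -> None:
        if self.dirichlet_alpha <= 0:
            raise ValueError("Dirichlet concentration must be positive")
        if self.experiment not in ("exp1", "exp2"):
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.mcmc is None:
            # the test preset runs longer than the generic one: the GP
            # hyperparameters mix slowly and shorter chains leave the
            # reported cell probabilities just above the 1.01 smoke gate
            presets = {
                "test": MCMCConfig(steps=3000, warmup=1500, thin=25),
                "paper": MCMCConfig.preset("paper"),
                "smoke": MCMCConfig.preset("smoke"),
            }
            if self.mode not in presets:
                raise ValueError(f"unknown MCMC mode {self.mode!r}")
            object.__setattr__(self, "mcmc", presets[self.mode])

    @classmethod
    def exp1(cls, mode: str = "test", **kw) -> "StageModelSpec":
        return cls(experiment="exp1", use_gp=True, mode=mode, **kw)

    @classmethod
    def exp2(cls, mode: str = "test", **kw) -> "StageModelSpec":
        """Categorical-only variant with location random effects."""
        return cls(
            experiment="exp2", use_gp=False, location_effects=True, mode=mode, **kw
        )


@dataclass
class _StageData:
    """Pre-digested design: one row per (mesocosm, [location,] sex) cell."""

    counts: np.ndarray  # (C, 4)
    treat_idx: np.ndarray  # (C,) index into treatment categories
    male: np.ndarray  # (C,) 0/1
    temp_idx: np.ndarray  # (C,) index into the temperature grid
    meso_idx: np.ndarray
    loc_idx: np.ndarray
    treatments: list[str]  # category labels (treatment type or tag)
    tag_to_treat: dict[str, int]
    tag_to_temp: dict[str, int]
    x_grid: np.ndarray  # standardized unique temperatures
    temp_mean: float
    temp_sd: float
    mesocosms: list[str]
    locations: list[str]


def _prepare(data: pd.DataFrame, spec: StageModelSpec) -> _StageData:
    required = ["mesocosm_id", "treatment_label", "treatment_tag", "mean_temp_c", "sex", "stage"]
    missing = [c for c in required if c not in data.columns or data[c].isna().any()]
    if missing:
        raise ValueError(f"missing or incomplete covariates: {missing}")
    if len(data) == 0:
        raise ValueError("empty animal table")
    if not data["stage"].isin([1, 2, 3, 4]).all():
        raise ValueError("stages must be coded 1..4")

    df = data.copy()
    # Treatment categories: type (constant/el_nino/la_nina) for the gradient
    # experiment, tag for the categorical-only design.
    cat_col = "treatment_label" if spec.experiment == "exp1" else "treatment_tag"
    treatments = [t for t in TYPE_ORDER if t in set(df[cat_col])] if (
        spec.experiment == "exp1"
    ) else sorted(set(df[cat_col]))
    t_map = {t: i for i, t in enumerate(treatments)}

    temps = np.round(df["mean_temp_c"].to_numpy(float), 6)
    grid = np.unique(temps)
    mu, sd = float(temps.mean()), float(temps.std())
    sd = sd if sd > 0 else 1.0
    x_grid = (grid - mu) / sd
    temp_map = {t: i for i, t in enumerate(grid)}

    mesocosms = sorted(set(df["mesocosm_id"]))
    m_map = {m: i for i, m in enumerate(mesocosms)}
    if spec.location_effects:
        if "location" not in df.columns or (df["location"] == "").any():
            raise ValueError("location effects requested but location is missing")
        locations = sorted(set(df["location"]))
    else:
        locations = [""]
        df["location"] = ""
    l_map = {l: i for i, l in enumerate(locations)}

    keys = ["mesocosm_id", "location", "sex"]
    cells = df.groupby(keys, sort=True)
    C = cells.ngroups
    counts = np.zeros((C, 4))
    treat_idx = np.zeros(C, int)
    male = np.zeros(C)
    temp_idx = np.zeros(C, int)
    meso_idx = np.zeros(C, int)
    loc_idx = np.zeros(C, int)
    tag_to_treat: dict[str, int] = {}
    tag_to_temp: dict[str, int] = {}
    for c, (key, grp) in enumerate(cells):
        mid, loc, sex = key
        for s, n in grp["stage"].value_counts().items():
            counts[c, int(s) - 1] = n
        treat_idx[c] = t_map[grp[cat_col].iloc[0]]
        male[c] = 1.0 if sex == "M" else 0.0
        temp_idx[c] = temp_map[round(float(grp["mean_temp_c"].iloc[0]), 6)]
        meso_idx[c] = m_map[mid]
        loc_idx[c] = l_map[loc]
        tag = grp["treatment_tag"].iloc[0]
        tag_to_treat[tag] = treat_idx[c]
        tag_to_temp[tag] = temp_idx[c]

    one_stage = (counts > 0).sum(axis=1) == 1
    if one_stage.all():
        warnings.warn(
            "complete separation: every design cell has a single observed "
            "stage; the likelihood is degenerate and only the priors bound "
            "the logits",
            UserWarning,
        )
    return _StageData(
        counts, treat_idx, male, temp_idx, meso_idx, loc_idx,
        treatments, tag_to_treat, tag_to_temp, x_grid, mu, sd, mesocosms, locations,
    )


class _StageLogProb:
    """Unnormalized log joint density on the unconstrained parameter vector.

    Layout: baseline ALR logits (T treatments x 3), male effects (3),
    male-by-treatment interactions ((T-1) x 3), then — if the smoother is on —
    GP latents z (2 sexes x 3 stages x G temps) and log length-scale /
    log scale, then log sigma_meso, mesocosm z (M), and — if location effects
    are on — log sigma_loc and location z (L).
    """

    def __init__(self, d: _StageData, spec: StageModelSpec):
        self.d = d
        self.spec = spec
        T, G = len(d.treatments), len(d.x_grid)
        self.T, self.G = T, G
        self.M, self.L = len(d.mesocosms), len(d.locations)
        sizes = [("a", T * 3), ("m", 3), ("b", (T - 1) * 3)]
        if spec.use_gp:
            sizes += [("z_gp", 2 * 3 * G), ("log_ell", 1), ("log_sgp", 1)]
        if spec.mesocosm_effects:
            sizes += [("log_sig_meso", 1), ("z_meso", self.M)]
        if spec.location_effects:
            sizes += [("log_sig_loc", 1), ("z_loc", self.L)]
        self.slices: dict[str, slice] = {}
        off = 0
        for name, size in sizes:
            self.slices[name] = slice(off, off + size)
            off += size
        self.ndim = off

    # -- parameter transforms -------------------------------------------------
    def unpack(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        s = self.slices
        out: dict[str, np.ndarray] = {}
        a = theta[s["a"]].reshape(self.T, 3)
        full = np.concatenate([np.zeros((self.T, 1)), a], axis=1)
        probs = np.exp(full - logsumexp(full, axis=1, keepdims=True))
        out["baseline_probs"] = probs
        out["m"] = theta[s["m"]]
        out["b"] = theta[s["b"]].reshape(self.T - 1, 3)
        if self.spec.mesocosm_effects:
            sig_meso = np.exp(theta[s["log_sig_meso"]][0])
            out["sigma_meso"] = sig_meso
            out["u_meso"] = sig_meso * theta[s["z_meso"]]
        if self.spec.use_gp:
            ell = np.exp(theta[s["log_ell"]][0])
            sgp = np.exp(theta[s["log_sgp"]][0])
            out["ell"], out["sgp"] = ell, sgp
            out["f"] = self._latent_f(theta, ell, sgp)
        if self.spec.location_effects:
            sig_loc = np.exp(theta[s["log_sig_loc"]][0])
            out["sigma_loc"] = sig_loc
            out["v_loc"] = sig_loc * theta[s["z_loc"]]
        out["cell_probs"] = self._report_cell_probs(out)
        return out

    def _report_cell_probs(self, p: dict) -> np.ndarray:
        """Population-median stage probabilities for every (sex, treatment
        tag) cell — the reported parameters of the fit: shape
        (2 sexes, n_tags, 4), sexes ordered (F, M), tags sorted."""
        d = self.d
        tags = sorted(d.tag_to_treat)
        base = np.log(p["baseline_probs"][:, 1:] / p["baseline_probs"][:, :1])
        b_full = np.concatenate([np.zeros((1, 3)), p["b"]], axis=0)
        out = np.empty((2, len(tags), 4))
        for si in (0, 1):
            for j, tag in enumerate(tags):
                t = d.tag_to_treat[tag]
                eta = base[t] + si * (p["m"] + b_full[t])
                if self.spec.use_gp:
                    eta = eta + p["f"][si, :, d.tag_to_temp[tag]]
                logits = np.concatenate([[0.0], eta])
                w = np.exp(logits - logits.max())
                out[si, j] = w / w.sum()
        return out

    def _latent_f(self, theta, ell, sgp) -> np.ndarray:
        z = theta[self.slices["z_gp"]].reshape(2, 3, self.G)
        K = sq_exp_kernel(self.d.x_grid, self.d.x_grid, ell, sgp)
        K[np.diag_indices_from(K)] += GP_JITTER
        Lc = cholesky(K, lower=True)
        return np.einsum("ij,skj->ski", Lc, z)

    # -- density (vectorized over walkers) ------------------------------------
    def __call__(self, theta: np.ndarray) -> float | np.ndarray:
        """Unnormalized log joint; accepts one vector or a (W, ndim) batch."""
        theta = np.asarray(theta, dtype=float)
        single = theta.ndim == 1
        th = np.atleast_2d(theta)
        # guard exp/cholesky against absurd excursions; flagged -inf below
        bad = ~np.all(np.isfinite(th), axis=1) | (np.abs(th).max(axis=1) > 30.0)
        th = np.where(bad[:, None], 0.0, th)
        W = th.shape[0]
        s, spec = self.slices, self.spec
        T, G, C = self.T, self.G, self.d.counts.shape[0]
        d = self.d
        LOG2PI = np.log(2.0 * np.pi)

        a = th[:, s["a"]].reshape(W, T, 3)
        full = np.concatenate([np.zeros((W, T, 1)), a], axis=2)
        mx = full.max(axis=2, keepdims=True)
        lse = mx[..., 0] + np.log(np.exp(full - mx).sum(axis=2))
        log_base = full - lse[..., None]  # (W, T, 4) log baseline proportions
        # Dirichlet(alpha) pushforward through ALR: prod pi^(alpha-1) x
        # Jacobian prod pi, plus the Dirichlet normalizer per treatment
        lp = spec.dirichlet_alpha * log_base.sum(axis=(1, 2))
        lp += T * float(gammaln(4 * spec.dirichlet_alpha) - 4 * gammaln(spec.dirichlet_alpha))

        m = th[:, s["m"]]
        b = th[:, s["b"]].reshape(W, T - 1, 3)
        n_coef = 3 * T  # m plus interactions
        lp += (
            -0.5 * ((m / spec.coef_sd) ** 2).sum(axis=1)
            - 0.5 * ((b / spec.coef_sd) ** 2).sum(axis=(1, 2))
            - n_coef * (np.log(spec.coef_sd) + 0.5 * LOG2PI)
        )

        base_sel = log_base[:, d.treat_idx, 1:] - log_base[:, d.treat_idx, :1]
        b_full = np.concatenate([np.zeros((W, 1, 3)), b], axis=1)
        eta = base_sel + d.male[None, :, None] * (m[:, None, :] + b_full[:, d.treat_idx])

        if spec.use_gp:
            z = th[:, s["z_gp"]].reshape(W, 2, 3, G)
            log_ell = th[:, s["log_ell"]][:, 0]
            log_sgp = th[:, s["log_sgp"]][:, 0]
            ell, sgp = np.exp(log_ell), np.exp(log_sgp)
            dx2 = np.subtract.outer(d.x_grid, d.x_grid) ** 2
            K = sgp[:, None, None] ** 2 * np.exp(
                -0.5 * dx2[None] / ell[:, None, None] ** 2
            )
            # jitter scaled with the kernel magnitude: huge length-scales
            # make K numerically rank-one and absolute jitter alone fails
            K[:, np.arange(G), np.arange(G)] += GP_JITTER * (1.0 + sgp[:, None] ** 2)
            Lc, chol_bad = _batch_cholesky(K)
            bad = bad | chol_bad
            f = np.einsum("wij,wskj->wski", Lc, z)
            lp += -0.5 * (z**2).sum(axis=(1, 2, 3)) - (6 * G) * 0.5 * LOG2PI
            for log_v, v in ((log_ell, ell), (log_sgp, sgp)):
                # folded normal(mean 1, sd 1, lb 0) + log-scale Jacobian
                lp += (
                    np.logaddexp(-0.5 * (v - 1.0) ** 2, -0.5 * (v + 1.0) ** 2)
                    - 0.5 * LOG2PI
                    + log_v
                )
            f_sel = f.transpose(0, 1, 3, 2)[:, d.male.astype(int), d.temp_idx]
            eta = eta + f_sel

        if spec.mesocosm_effects:
            log_sig = th[:, s["log_sig_meso"]][:, 0]
            sig = np.exp(log_sig)
            zu = th[:, s["z_meso"]]
            # half-normal(0,1) on sigma + Jacobian; standard normal on z
            lp += np.log(2.0) - 0.5 * LOG2PI - 0.5 * sig**2 + log_sig
            lp += -0.5 * (zu**2).sum(axis=1) - self.M * 0.5 * LOG2PI
            eta = eta + (sig[:, None] * zu)[:, d.meso_idx, None]

        if spec.location_effects:
            log_sl = th[:, s["log_sig_loc"]][:, 0]
            sl = np.exp(log_sl)
            zl = th[:, s["z_loc"]]
            lp += _folded_t_logpdf(sl, df=3.0, scale=0.1) + np.log(2.0) + log_sl
            lp += -0.5 * (zl**2).sum(axis=1) - self.L * 0.5 * LOG2PI
            eta = eta + (sl[:, None] * zl)[:, d.loc_idx, None]

        logits = np.concatenate([np.zeros((W, C, 1)), eta], axis=2)
        mx = logits.max(axis=2, keepdims=True)
        logp = logits - (mx + np.log(np.exp(logits - mx).sum(axis=2, keepdims=True)))
        lp += (d.counts[None] * logp).sum(axis=(1, 2))
        lp = np.where(bad | ~np.isfinite(lp), -np.inf, lp)
        return float(lp[0]) if single else lp

    def init_point(self) -> np.ndarray:
        """Empirical-logit start for the baselines, zeros elsewhere."""
        theta = np.zeros(self.ndim)
        a = np.zeros((self.T, 3))
        for t in range(self.T):
            n = self.d.counts[self.d.treat_idx == t].sum(axis=0) + 1.0
            pi = n / n.sum()
            a[t] = np.log(pi[1:] / pi[0])
        theta[self.slices["a"]] = a.ravel()
        return theta


def fit_stage_model(
    data: pd.DataFrame, spec: StageModelSpec | None = None, seed: int = 0
) -> PosteriorDraws:
    """Sample the stage-model posterior for one animal table.

    Returns labelled draws (baseline stage proportions per treatment, sex
    effects, smoother latents and hyperparameters, random-effect scales)
    with split-Rhat per parameter.
    """
    spec = spec or StageModelSpec()
    d = _prepare(data, spec)
    model = _StageLogProb(d, spec)
    x0 = find_map(model, model.init_point())
    draws = run_ensemble_mcmc(
        model, model.ndim, seed, spec.mcmc, init=x0, param_unpack=model.unpack
    )
    draws.meta.update(
        model=model,
        spec=spec,
        data_shape=tuple(data.shape),
        report_tags=sorted(d.tag_to_treat),
        # convergence is gated on the quantities the analysis reports (cell
        # stage probabilities); GP hyperparameters are weakly identified from
        # few distinct temperatures and are tracked but not gated
        reported=["cell_probs"],
    )
    # Simplex sanity at every draw: baseline proportions must sum to one.
    sums = draws.flat("baseline_probs").sum(axis=-1)
    assert np.allclose(sums, 1.0, atol=1e-9)
    return draws


def predict_stage_probs(
    draws: PosteriorDraws,
    at: tuple[str, str] | tuple[str, str, float],
    location: str | None = None,
) -> np.ndarray:
    """Per-draw stage I–IV probability vectors at one covariate point.

    ``at`` is ``(sex, treatment)`` or ``(sex, treatment, mean_temp_c)`` where
    treatment may be a tag ("lanina", "16C") or a type ("la_nina",
    "constant"); when the temperature is omitted it defaults to the fitted
    temperature of that treatment tag.  Mesocosm (and location, unless one is
    named) effects are set to zero — the population-median cell.  Querying a
    temperature outside the fitted range warns and extrapolates through the
    smoother's conditional mean.
    """
    model: _StageLogProb = draws.meta["model"]
    d, spec = model.d, model.spec
    sex, treatment = at[0], at[1]
    temp = at[2] if len(at) > 2 else None

    if treatment in d.tag_to_treat:
        t_idx = d.tag_to_treat[treatment]
        default_temp_idx = d.tag_to_temp[treatment]
    elif treatment in d.treatments:
        t_idx = d.treatments.index(treatment)
        default_temp_idx = None
    else:
        raise ValueError(f"unknown treatment {treatment!r}")
    s_idx = 1 if sex == "M" else 0

    base_probs = draws.flat("baseline_probs")  # (N, T, 4)
    N = base_probs.shape[0]
    base = np.log(base_probs[:, t_idx, 1:] / base_probs[:, t_idx, :1])
    m = draws.flat("m")
    b = draws.flat("b")
    b_full = np.concatenate([np.zeros((N, 1, 3)), b], axis=1)
    eta = base + s_idx * (m + b_full[:, t_idx])

    if spec.use_gp:
        f = draws.flat("f")  # (N, 2, 3, G)
        if temp is not None:
            x = (float(temp) - d.temp_mean) / d.temp_sd
            j = np.flatnonzero(np.isclose(x, d.x_grid, atol=1e-9))
            if j.size:
                eta = eta + f[:, s_idx, :, j[0]]
            else:
                if x < d.x_grid.min() or x > d.x_grid.max():
                    warnings.warn(
                        f"extrapolating the smoother beyond the fitted range "
                        f"({temp} °C)",
                        UserWarning,
                    )
                eta = eta + _krige(draws, f, s_idx, x, d)
        else:
            if default_temp_idx is None:
                raise ValueError(
                    "a mean temperature is required when querying a treatment type"
                )
            eta = eta + f[:, s_idx, :, default_temp_idx]

    if location is not None:
        if not spec.location_effects:
            raise ValueError("model was fitted without location effects")
        eta = eta + draws.flat("v_loc")[:, [d.locations.index(location)]]

    logits = np.concatenate([np.zeros((N, 1)), eta], axis=1)
    probs = np.exp(logits - logsumexp(logits, axis=1, keepdims=True))
    return probs


def _krige(draws: PosteriorDraws, f: np.ndarray, s_idx: int, x: float, d: _StageData) -> np.ndarray:
    """Conditional mean of the smoother at an off-grid point, per draw."""
    ell = draws.flat("ell")
    sgp = draws.flat("sgp")
    out = np.empty((f.shape[0], 3))
    for i in range(f.shape[0]):
        K = sq_exp_kernel(d.x_grid, d.x_grid, ell[i], sgp[i])
        K[np.diag_indices_from(K)] += GP_JITTER
        Lc = cholesky(K, lower=True)
        kstar = sq_exp_kernel(x, d.x_grid, ell[i], sgp[i])
        w = cho_solve((Lc, True), kstar.ravel())
        out[i] = f[i, s_idx] @ w
    return out
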