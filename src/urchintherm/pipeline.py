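"""End-to-end orchestration: generate → fit → compare → summarize.

A run writes, under one output directory: the thermal-schedule and animal
CSVs, per-draw reported-parameter arrays, diagnostics JSON per fit, the
model-comparison report, a summary CSV mirroring the headline quantities
(stage-IV shares and declines, standardized gonad masses and reductions),
and a manifest (config, seeds consumed, versions) sufficient to reproduce
every output byte-for-byte in test mode.

Seeds: one global seed expands to per-stage seeds by a fixed counter scheme
``stage_seed = (seed * 101 + k) mod (2^31 - 1)`` with k the stage counter
(0 simulate, 1 stage fit, 2 gonad fit, 3 comparison, 4 calibration), so any
stage can be re-run in isolation.  Every consumed seed is logged in order.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from . import model_compare as mc
from . import summaries as sm
from . import synthetic_data as sd
from . import treatments as trt
from .gonad_model import GonadModelSpec, fit_gonad_model
from .stage_model import StageModelSpec, fit_stage_model

logger = logging.getLogger("urchintherm")

_STAGE_NAMES = ("simulate", "fit_stages", "fit_gonads", "compare", "calibrate")


@dataclass
class RunConfig:
    experiment: str = "exp1"
    mode: str = "test"
    seed: int = 0
    out_dir: str = "runs/exp1"
    n_calibration_datasets: int = 0  # 0 skips calibration
    generator_overrides: dict = field(default_factory=dict)
    rhat_threshold: float = sm.RHAT_THRESHOLD_SMOKE

    def __post_init__(self) -> None:
        if self.experiment not in ("exp1", "exp2"):
            raise ValueError(f"unknown experiment id {self.experiment!r}")
        if self.mode not in ("test", "paper", "smoke"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def stage_seed(self, k: int) -> int:
        s = (self.seed * 101 + k) % (2**31 - 1)
        logger.info("seed[%s] = %d", _STAGE_NAMES[k] if k < len(_STAGE_NAMES) else k, s)
        return s


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=float) + "\n")


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def simulate_stage(config: RunConfig, out: Path) -> pd.DataFrame:
    """Write schedules and the synthetic animal table."""
    seed = config.stage_seed(0)
    if config.experiment == "exp1":
        params = sd.GeneratingParams(**config.generator_overrides)
        design = sd.ExperimentDesign.exp1_default()
        data = sd.simulate_experiment1(params, design, seed)
        schedules = trt.default_schedules_exp1()
    else:
        params = sd.GeneratingParams.exp2_default()
        if config.generator_overrides:
            params = params.with_overrides(**config.generator_overrides)
        design = sd.ExperimentDesign.exp2_default()
        data = sd.simulate_experiment2(params, design, seed)
        schedules = {
            tag: trt.default_schedules_exp1(n_days=design.n_days)[tag]
            for tag, _, _ in design.treatments
        }
    trt.schedules_to_csv(schedules, out / "schedules.csv")
    sd.animals_to_csv(data, out / "animals.csv")
    return data


def fit_stages_stage(config: RunConfig, data: pd.DataFrame, out: Path):
    seed = config.stage_seed(1)
    spec = (
        StageModelSpec.exp1(mode=config.mode)
        if config.experiment == "exp1"
        else StageModelSpec.exp2(mode=config.mode)
    )
    draws = fit_stage_model(data, spec, seed=seed)
    tags = draws.meta["report_tags"]
    cp = draws.flat("cell_probs")  # (N, 2, n_tags, 4)
    np.savez_compressed(out / "stage_draws.npz", cell_probs=cp, tags=tags)
    _dump_json(
        {
            "seed": seed,
            "mode": config.mode,
            "rhat": draws.rhat,
            "max_rhat": draws.max_rhat(),
            "reported_rhat": draws.reported_rhat(),
            "acceptance_fraction": draws.acceptance_fraction,
            "converged": draws.converged(config.rhat_threshold),
        },
        out / "stage_diagnostics.json",
    )
    return draws


def fit_gonads_stage(config: RunConfig, data: pd.DataFrame, out: Path):
    seed = config.stage_seed(2)
    draws = fit_gonad_model(data, GonadModelSpec(mode=config.mode), seed=seed)
    points = ["{}@{:g}".format(lab, t) for lab, t in draws.meta["report_points"]]
    np.savez_compressed(
        out / "gonad_draws.npz", std_mass=draws.flat("std_mass"), points=points
    )
    _dump_json(
        {
            "seed": seed,
            "mode": config.mode,
            "rhat": draws.rhat,
            "max_rhat": draws.max_rhat(),
            "reported_rhat": draws.reported_rhat(),
            "acceptance_fraction": draws.acceptance_fraction,
            "converged": draws.converged(config.rhat_threshold),
        },
        out / "gonad_diagnostics.json",
    )
    return draws


def compare_stage(config: RunConfig, data: pd.DataFrame, out: Path) -> dict:
    seed = config.stage_seed(3)
    design = (
        sd.ExperimentDesign.exp1_default()
        if config.experiment == "exp1"
        else sd.ExperimentDesign.exp2_default()
    )
    counts = mc.counts_from_animals(data)
    if config.experiment == "exp1":
        full = mc.CategoricalContrastModel.treatment_type_sex(design)
        nulls = [
            mc.CategoricalContrastModel.sex_only(design),
            mc.CategoricalContrastModel.intercept_only(design),
        ]
    else:
        full = mc.CategoricalContrastModel.location_treatment_sex(design)
        nulls = [mc.CategoricalContrastModel.treatment_sex(design, label="reduced")]
    report = {}
    for null in nulls:
        comp = mc.bayes_factor(full.fit(counts), null.fit(counts), seed=seed)
        report[f"{full.label}_vs_{null.label}"] = {
            "log_bf": comp.log_bf,
            "bayes_factor": comp.bayes_factor,
            "mc_error": comp.mc_error,
            "log_marginals": comp.log_marginals,
            "verdict": comp.verdict,
        }
    _dump_json(report, out / "comparison.json")
    if config.n_calibration_datasets > 0:
        table, summary = mc.calibrate_bf(
            full, nulls[0], design,
            n_datasets=config.n_calibration_datasets,
            seed=config.stage_seed(4),
        )
        table.to_csv(out / "calibration.csv", index=False)
        _dump_json(summary, out / "calibration_summary.json")
    return report


def summarize_stage(config: RunConfig, stage_draws, gonad_draws, out: Path) -> pd.DataFrame:
    """Report table mirroring the headline quantities of the analysis."""
    from .stage_model import predict_stage_probs
    from .gonad_model import standardized_mass

    rows = []

    def add(samples, label, definition, scale=1.0):
        t = sm.summarize_draws(np.asarray(samples) * scale, label, definition)
        rows.append(t.as_dict())

    tags = stage_draws.meta["report_tags"]
    piv = {}
    for sex in ("F", "M"):
        for tag in tags:
            p = predict_stage_probs(stage_draws, (sex, tag))[:, 3]
            piv[(sex, tag)] = p
            add(p, f"p_stageIV_{sex}_{tag}", "proportion")
    if config.experiment == "exp1":
        for sex in ("F", "M"):
            diff, t = sm.stage_contrast(
                piv[(sex, "lanina")], piv[(sex, "elnino")],
                label=f"stageIV_decline_lanina_minus_elnino_{sex}",
            )
            rows.append(t.as_dict())
        diff, t = sm.stage_contrast(
            piv[("M", "20C")], piv[("M", "elnino")],
            label="stageIV_decline_const20_minus_elnino_M",
        )
        rows.append(t.as_dict())

        masses = {
            t_: standardized_mass(gonad_draws, ("constant", float(t_)))
            for t_ in (10.0, 13.0, 16.0, 20.0)
        }
        masses["lanina"] = standardized_mass(gonad_draws, ("la_nina", 16.0))
        masses["elnino"] = standardized_mass(gonad_draws, ("el_nino", 20.0))
        for key, arr in masses.items():
            add(arr, f"std_mass_g_{key}", "g at 50 mm")
        for label, a, b in [
            ("reduction_20_vs_13", masses[13.0], masses[20.0]),
            ("reduction_10_vs_13", masses[13.0], masses[10.0]),
            ("reduction_lanina_vs_const16", masses[16.0], masses["lanina"]),
        ]:
            _, t_ = sm.relative_reduction(a, b, label=label)
            rows.append(t_.as_dict())
    table = pd.DataFrame(rows)
    table.to_csv(out / "summary.csv", index=False, float_format="%.6f")
    return table


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage; returns the run directory.

    Raises ``RuntimeError`` naming the failed stage; partial outputs are
    left in place.  The manifest records config, seeds, versions and file
    hashes.  No stage touches the network.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    fh.setLevel(logging.INFO)
    logger.addHandler(fh)
    logger.setLevel(logging.INFO)
    stage = "simulate"
    try:
        data = simulate_stage(config, out)
        stage = "fit_stages"
        stage_draws = fit_stages_stage(config, data, out)
        stage = "fit_gonads"
        gonad_draws = fit_gonads_stage(config, data, out)
        stage = "compare"
        compare_stage(config, data, out)
        stage = "summarize"
        summarize_stage(config, stage_draws, gonad_draws, out)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    finally:
        logger.removeHandler(fh)
        fh.close()

    converged = stage_draws.converged(config.rhat_threshold) and gonad_draws.converged(
        config.rhat_threshold
    )
    manifest = {
        "version": _version,
        "config": asdict(config),
        "stage_seeds": {n: (config.seed * 101 + k) % (2**31 - 1)
                        for k, n in enumerate(_STAGE_NAMES)},
        "converged": converged,
        "files": {
            p.name: _file_hash(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name not in ("manifest.json", "run.log")
        },
    }
    _dump_json(manifest, out / "manifest.json")
    return out
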