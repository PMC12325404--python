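"""Config-driven orchestration: simulate -> fit -> compare / calibrate / power.

A run configuration is a plain dict (typically loaded from JSON or YAML via
:func:`truthfx.io.read_config`) with a top-level ``seed``, an ``out_dir``,
and a ``stages`` list.  Each stage is ``{"stage": <name>, ...params}``;
results are written as JSON (plus CSV for tables) into ``out_dir`` and a
``run_log.json`` records seeds, versions, and diagnostics.  Any stage
failure aborts with a stage-tagged error.
"""

from __future__ import annotations

import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import scale_prior_means
from .comparison import compare_models
from .core import ModelVariant, truth_effect_curve
from .inference import McmcSettings, PriorSpec, fit_model, posterior_summary
from .io import read_trials, write_json, write_trials
from .peak_test import power_study
from .simulate import DesignSpec, simulate_dataset

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def _design(params: dict, seed: int) -> DesignSpec:
    fields = {k: params[k] for k in (
        "n_statements", "n_participants", "plausibility_source", "mu_p",
        "sigma_p", "sigma_u", "sigma_v",
    ) if k in params}
    return DesignSpec(seed=params.get("seed", seed), **fields)


def run_pipeline(config: dict, out_dir=None) -> dict[str, Path]:
    """Execute the configured stages; returns {stage_label: result path}."""
    if "seed" not in config:
        raise ValueError("config must carry an explicit top-level seed")
    seed = int(config["seed"])
    out = Path(out_dir or config.get("out_dir", "."))
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    log: dict = {"seed": seed, "truthfx_version": __version__,
                 "python": platform.python_version(), "stages": []}
    trials: pd.DataFrame | None = None
    fits: dict = {}

    for k, stage_cfg in enumerate(config.get("stages", [])):
        stage = stage_cfg.get("stage")
        label = stage_cfg.get("label", f"{k:02d}_{stage}")
        stage_seed = int(stage_cfg.get("seed", seed + k))
        try:
            if stage == "simulate":
                design = _design(stage_cfg, stage_seed)
                trials, params = simulate_dataset(design, stage_cfg["variant"], stage_cfg["m"])
                path = write_trials(trials, out / f"{label}.csv")
            elif stage == "load":
                trials = read_trials(stage_cfg["path"])
                path = Path(stage_cfg["path"])
            elif stage == "fit":
                if trials is None:
                    raise ValueError("no trial table simulated or loaded yet")
                variant = ModelVariant.coerce(stage_cfg["variant"])
                priors = (PriorSpec(**stage_cfg["priors"]) if "priors" in stage_cfg
                          else PriorSpec.for_variant(variant))
                settings = McmcSettings(seed=stage_seed, **stage_cfg.get("mcmc", {}))
                fit = fit_model(trials, variant, priors, settings)
                fits[variant] = fit
                summary = posterior_summary(fit)
                path = write_json({
                    "variant": variant.name,
                    "converged": fit.converged,
                    "max_rhat": fit.max_rhat,
                    "summary": {p: dict(r) for p, r in summary.to_dict("index").items()},
                }, out / f"{label}.json")
            elif stage == "compare":
                if not fits:
                    raise ValueError("no fitted models to compare")
                result = compare_models(fits, method=stage_cfg.get("method", "bridge"), rng=stage_seed)
                path = write_json(result.to_dict(), out / f"{label}.json")
            elif stage == "calibrate":
                result = scale_prior_means(
                    target_effect=stage_cfg.get("target", 0.04), rng=stage_seed,
                    analytic=stage_cfg.get("analytic", True),
                )
                path = write_json({
                    "target_effect": result.target_effect,
                    "matched_m": {v.name: m for v, m in result.matched_m.items()},
                }, out / f"{label}.json")
            elif stage == "power":
                res = power_study(
                    stage_cfg["variant"], stage_cfg["m"],
                    n_datasets=stage_cfg.get("n_datasets", 1000),
                    n_judgments=stage_cfg.get("n_judgments", 250),
                    n_bootstrap=stage_cfg.get("n_bootstrap", 5000),
                    rng=stage_seed,
                )
                path = write_json(res.__dict__ | {"variant": res.variant.name}, out / f"{label}.json")
            elif stage == "curves":
                df = truth_effect_curve(stage_cfg["variant"], stage_cfg["m"])
                path = out / f"{label}.csv"
                df.to_csv(path, index=False)
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as exc:  # noqa: BLE001 - re-raised with stage tag
            raise PipelineError(label, exc) from exc
        artifacts[label] = path
        log["stages"].append({"label": label, "stage": stage, "seed": stage_seed, "path": str(path)})

    write_json(log, out / "run_log.json")
    artifacts["run_log"] = out / "run_log.json"
    return artifacts
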