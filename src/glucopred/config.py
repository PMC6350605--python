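"""Run configuration and end-to-end pipeline wiring.

A run is described by a nested mapping (YAML on disk) with one block per
stage: model parameters, absorption constants, an optional virtual-patient
``simulate`` stage, ``train`` (identification), ``diurnal`` profiling and
``evaluate``.  Unknown keys are rejected so typos fail loudly.  A single
top-level seed fans out deterministically into per-stage child seeds, so a
whole pipeline is reproducible from the config alone.
"""

from __future__ import annotations

import copy
import dataclasses
import json
import time
from pathlib import Path

import numpy as np
import yaml

from .absorption import AbsorptionParams
from .diurnal import DiurnalProfile, train_diurnal
from .evaluation import ega_report, error_metrics, full_run, meal_wise_test
from .glycemia import PARAM_NAMES, GlycemiaParams
from .identification import ParameterSpace, TrainingConfig, train
from .lifestyle_log import MINUTES_PER_DAY, PatientLog, read_log, slice_window, write_log
from .virtual_patient import NoiseSpec, VirtualPatientSpec, generate_log

__all__ = ["DEFAULT_CONFIG", "load_config", "resolve_config", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "glucopred_out",
    "log_path": None,
    # model parameter defaults are the population-level literature values
    "model": {name: getattr(GlycemiaParams(), name) for name in PARAM_NAMES}
    | {"body_weight_kg": 70.0},
    "absorption": dataclasses.asdict(AbsorptionParams()),
    "simulate": {
        "enabled": False,
        "days": 3,
        "noise": "default",  # "default" | "none"
        "plant_multipliers": {},
        "plant_diurnal": None,  # [k0, k1, k2, k3] on K_xi
        "body_weight_kg": 80.0,
    },
    "train": {
        "enabled": True,
        "method": "ga_slow",  # brute_force | ga_fast | ga_slow
        "n_params": 6,
        "refine_nm": True,
        "bounds": [0.2, 5.0],
        "train_window_days": None,  # None = whole log
    },
    "diurnal": {"enabled": False, "parameters": ["K_xi"]},
    "evaluate": {
        "enabled": True,
        "protocol": "full_run",  # full_run | meal_wise
        "restart": True,
        "horizons": [60, 120, 240, 360],
    },
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        where = f"{path}.{key}" if path else key
        if key not in base:
            raise KeyError(f"unknown config key {where!r}")
        if isinstance(base[key], dict) and key not in ("plant_multipliers",):
            if not isinstance(value, dict):
                raise TypeError(f"config key {where!r} must be a mapping")
            out[key] = _merge(base[key], value, where)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Load a YAML config, apply overrides, and fill in defaults."""
    config = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        config = _merge(config, user)
    if overrides:
        config = _merge(config, overrides)
    return config


def resolve_config(config: dict) -> dict:
    """Build the typed objects a pipeline run needs from a config mapping."""
    model = dict(config["model"])
    body_weight = model.pop("body_weight_kg")
    params = GlycemiaParams(body_weight_kg=body_weight, **model)
    absorption = AbsorptionParams(**config["absorption"])
    lower, upper = config["train"]["bounds"]
    space = ParameterSpace.preset(
        config["train"]["n_params"], reference=params, lower=lower, upper=upper
    )
    seeds = np.random.SeedSequence(config["seed"]).spawn(3)
    stage_seed = {
        "simulate": int(seeds[0].generate_state(1)[0] % 2**31),
        "train": int(seeds[1].generate_state(1)[0] % 2**31),
        "diurnal": int(seeds[2].generate_state(1)[0] % 2**31),
    }
    method = config["train"]["method"]
    if method == "ga_fast":
        training = TrainingConfig.ga_fast(seed=stage_seed["train"])
    elif method == "ga_slow":
        training = TrainingConfig.ga_slow(seed=stage_seed["train"])
    else:
        training = TrainingConfig(method=method, seed=stage_seed["train"])
    return {
        "params": params,
        "absorption": absorption,
        "space": space,
        "training": training,
        "stage_seed": stage_seed,
    }


def run_pipeline(config: dict, echo=print) -> dict:
    """Execute the configured stages in order and write the report bundle.

    Stage outputs (trained parameters JSON, prediction CSV, evaluation
    JSON) are written into ``out_dir`` as they complete, so a failing stage
    retains the partial results.  The report embeds the fully resolved
    config for provenance.
    """
    resolved = resolve_config(config)
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": copy.deepcopy(config), "stages": {}}

    def stage(name: str):
        echo(f"[{name}] starting")
        return time.perf_counter()

    def done(name: str, t0: float, **info):
        # wall time is echoed but kept out of the report so identical
        # config + seed produce byte-identical report files
        report["stages"][name] = info
        echo(f"[{name}] done in {time.perf_counter() - t0:.2f} s")

    # --- obtain the log -------------------------------------------------------
    if config["simulate"]["enabled"]:
        t0 = stage("simulate")
        sim = config["simulate"]
        knots = sim["plant_diurnal"]
        spec = VirtualPatientSpec(
            multipliers=dict(sim["plant_multipliers"]),
            diurnal_knots=tuple(knots) if knots else None,
            body_weight_kg=sim["body_weight_kg"],
            noise=NoiseSpec.none() if sim["noise"] == "none" else NoiseSpec(),
            seed=resolved["stage_seed"]["simulate"],
        )
        log, truth = generate_log(spec, days=sim["days"])
        write_log(log, out_dir / "log.csv")
        truth.to_csv(out_dir / "truth.csv", index=False)
        resolved["params"] = dataclasses.replace(
            resolved["params"], body_weight_kg=log.body_weight_kg
        )
        resolved["space"] = dataclasses.replace(
            resolved["space"], reference=resolved["params"]
        )
        done("simulate", t0, days=sim["days"], noise=sim["noise"],
             seed=spec.seed, n_cgms=len(log.cgms()))
    elif config["log_path"]:
        log = read_log(config["log_path"])
        resolved["params"] = dataclasses.replace(
            resolved["params"], body_weight_kg=log.body_weight_kg
        )
        resolved["space"] = dataclasses.replace(
            resolved["space"], reference=resolved["params"]
        )
    else:
        raise ValueError("config must enable simulate or give log_path")

    params = resolved["params"]
    profile: DiurnalProfile | None = None

    # --- identification -------------------------------------------------------
    if config["train"]["enabled"]:
        t0 = stage("train")
        window_days = config["train"]["train_window_days"]
        train_log = (
            slice_window(log, 0.0, window_days * MINUTES_PER_DAY)
            if window_days
            else log
        )
        result = train(
            train_log,
            resolved["space"],
            resolved["training"],
            refine=config["train"]["refine_nm"],
        )
        params = result.params
        done(
            "train", t0, method=result.method, fitness=result.fitness,
            n_evaluations=result.n_evaluations, seed=resolved["training"].seed,
            multipliers=result.multipliers,
        )
        if config["diurnal"]["enabled"]:
            t0 = stage("diurnal")
            diurnal_space = ParameterSpace(
                names=tuple(config["diurnal"]["parameters"]),
                reference=params,
                lower=resolved["space"].lower,
                upper=resolved["space"].upper,
            )
            diurnal_cfg = dataclasses.replace(
                resolved["training"], seed=resolved["stage_seed"]["diurnal"]
            )
            profile, period_fits = train_diurnal(
                train_log, diurnal_space, diurnal_cfg,
                refine=config["train"]["refine_nm"],
            )
            done("diurnal", t0, knots=list(profile.knots),
                 n_evaluations=sum(r.n_evaluations for r in period_fits))
        payload = {
            "multipliers": result.multipliers,
            "params": params.as_dict(),
            "body_weight_kg": params.body_weight_kg,
            "fitness_rmse_mmol_l": result.fitness,
            "method": result.method,
            "diurnal": profile.to_dict() if profile else None,
            "seed": resolved["training"].seed,
        }
        (out_dir / "trained_params.json").write_text(json.dumps(payload, indent=1))

    # --- evaluation -----------------------------------------------------------
    if config["evaluate"]["enabled"]:
        t0 = stage("evaluate")
        ev = config["evaluate"]
        if ev["protocol"] == "full_run":
            result = full_run(log, params, profile, restart=ev["restart"],
                              absorption_params=resolved["absorption"])
            ega = ega_report(result)
            evaluation = {
                "protocol": result.protocol,
                "metrics": error_metrics(result),
                "ega": ega.fractions | {"acceptable": ega.acceptable},
            }
            import pandas as pd

            pd.DataFrame(
                {"t_min": result.times, "predicted_mmol_l": result.predicted,
                 "cgms_mmol_l": result.reference}
            ).to_csv(out_dir / "prediction.csv", index=False)
        elif ev["protocol"] == "meal_wise":
            by_horizon = meal_wise_test(
                log, params, profile, horizons=tuple(ev["horizons"]),
                absorption_params=resolved["absorption"],
            )
            evaluation = {
                "protocol": "meal_wise",
                "horizons": {
                    str(int(h)): {
                        "metrics": r["metrics"],
                        "ega": r["ega"].fractions | {"acceptable": r["ega"].acceptable},
                        "n_meals": r["n_meals"],
                    }
                    for h, r in by_horizon.items()
                },
            }
        else:
            raise ValueError(f"unknown evaluation protocol {ev['protocol']!r}")
        report["evaluation"] = evaluation
        (out_dir / "evaluation.json").write_text(json.dumps(evaluation, indent=1))
        done("evaluate", t0, protocol=ev["protocol"])

    (out_dir / "report.json").write_text(json.dumps(report, indent=1, default=float))
    return report
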