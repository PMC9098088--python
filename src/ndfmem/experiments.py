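"""Experiment protocols: single runs, learning sessions, parameter sweeps.

A structured config (nested dict, YAML on disk) fully specifies an
experiment: model parameters, trial protocol, perturbation, plasticity rule
and seed.  Shipped presets encode the standard protocols for the homogeneous
population (differential recovery, homeostatic recovery, saturating
always-on) and the ring network (differential/homeostatic/combined repair
under global, postsynaptic and presynaptic perturbations).  Identical config
plus seed reproduces outputs bit for bit; RNG streams are split per purpose
(input amplitudes, stimulus locations, Poisson decoding).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .perturbation import PerturbationSpec, apply_perturbation
from .plasticity import PlasticityConfig
from .rate import (LearningTrace, RateModelParams, TrialProtocol, run_session,
                   trials_to_criterion)
from .ring import ConnectivitySet, RingParams, run_learning_session

__all__ = [
    "PRESETS",
    "SweepSpec",
    "load_config",
    "save_config",
    "validate_config",
    "run_experiment",
    "run_sweep",
    "fit_scaling_exponent",
]


_RATE_DEFAULTS = {
    "kind": "rate",
    "model": {"W_inh": 500.0, "c": 500.0},
    "protocol": {"t_stim": 50.0, "t_delay": 300.0, "t_iti": 50.0},
    "perturbation": {"strength": 0.1},
    "plasticity": {"rule": "none"},
    "n_trials": 500,
    "n_avg": 50,
    "dt": 0.1,
    "seed": 12345,
    "criterion": 0.99,
}

_RING_DEFAULTS = {
    "kind": "ring",
    "model": {},  # RingParams defaults = the standard parameter table
    "perturbation": {"kind": "global", "strength": 0.1},
    "plasticity": {"rule": "none"},
    "n_trials": 200,
    "eval_stride": None,  # evaluate at start and end only
    "n_repeats": 20,
    "decode_scale": 0.2,
    "seed": 12345,
}

#: Shipped experiment presets.  Values follow the published protocols; any
#: deviation requires an explicit override.
PRESETS: dict[str, dict] = {
    "fig1": {  # homogeneous differential recovery from a 10% E-to-E deficit
        "kind": "rate",
        "perturbation": {"strength": 0.1},
        "plasticity": {"rule": "differential", "alpha_d": 0.01},
        "n_trials": 500,
        "n_avg": 50,
    },
    "fig3": {  # homogeneous homeostatic recovery, matched target rate
        "kind": "rate",
        "perturbation": {"strength": 0.1},
        "plasticity": {"rule": "homeostatic", "alpha_h": 4e-8, "r0": 50.0},
        "n_trials": 2000,
        "n_avg": 500,
    },
    "s10": {  # saturating always-on differential rule, short strong stimulus
        "kind": "rate",
        "model": {"W_inh": 500.0, "c": 10000.0},
        "protocol": {"t_stim": 10.0, "t_delay": 300.0, "t_iti": 50.0},
        "perturbation": {"strength": 0.1},
        "plasticity": {"rule": "saturating_differential", "alpha_d": 0.01,
                       "K": 1.0, "always_on": True},
        "n_trials": 500,
        "n_avg": 50,
    },
    "fig6": {  # ring differential repair of a 10% global perturbation
        "kind": "ring",
        "perturbation": {"kind": "global", "strength": 0.1},
        "plasticity": {"rule": "differential", "alpha_d": 1e-3},
        "n_trials": 2000,
        "eval_stride": 100,
    },
    "fig8": {  # ring homeostatic repair of a 30% global perturbation
        "kind": "ring",
        "perturbation": {"kind": "global", "strength": 0.3},
        "plasticity": {"rule": "homeostatic", "alpha_h": 1e-8, "r0": 20.0},
        "n_trials": 2000,
        "eval_stride": 100,
    },
    "fig9_homeostatic": {  # homeostatic repair of a 30% postsynaptic perturbation
        "kind": "ring",
        "perturbation": {"kind": "postsynaptic", "strength": 0.3},
        "plasticity": {"rule": "homeostatic", "alpha_h": 1e-8, "r0": 20.0},
        "n_trials": 2000,
        "eval_stride": 100,
    },
    "fig10_differential": {  # differential repair of a 30% presynaptic perturbation
        "kind": "ring",
        "perturbation": {"kind": "presynaptic", "strength": 0.3},
        "plasticity": {"rule": "differential", "alpha_d": 1e-3},
        "n_trials": 2000,
        "eval_stride": 100,
    },
    "fig11_combined": {  # combined rule under a 30% presynaptic perturbation
        "kind": "ring",
        "perturbation": {"kind": "presynaptic", "strength": 0.3},
        "plasticity": {"rule": "combined", "alpha_d": 1e-3, "alpha_h": 1e-8,
                       "r0": 20.0},
        "n_trials": 2000,
        "eval_stride": 100,
    },
}

_KNOWN_TOP_KEYS = {
    "rate": set(_RATE_DEFAULTS),
    "ring": set(_RING_DEFAULTS),
}


def _deep_update(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_update(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def resolve_config(config: dict) -> dict:
    """Merge a (possibly partial) config onto the defaults for its kind."""
    kind = config.get("kind", "rate")
    if kind == "rate":
        return _deep_update(_RATE_DEFAULTS, config)
    if kind == "ring":
        return _deep_update(_RING_DEFAULTS, config)
    raise ValueError(f"unknown experiment kind {kind!r} (config key 'kind')")


def validate_config(config: dict) -> dict:
    """Resolve defaults and reject unknown keys, reporting their paths."""
    resolved = resolve_config(config)
    kind = resolved["kind"]
    unknown = set(resolved) - _KNOWN_TOP_KEYS[kind]
    if unknown:
        raise ValueError(f"unknown config keys for kind={kind!r}: {sorted(unknown)}")
    return resolved


def preset_config(name: str) -> dict:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return validate_config(PRESETS[name])


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def set_by_path(config: dict, path: str, value) -> None:
    """Set a dotted-path key, e.g. ``plasticity.alpha_d``."""
    keys = path.split(".")
    node = config
    for key in keys[:-1]:
        node = node.setdefault(key, {})
    node[keys[-1]] = value


def _run_rate(config: dict) -> dict:
    p = config["perturbation"].get("strength", 0.0)
    model_kwargs = dict(config["model"])
    model_kwargs.setdefault("W_exc0", (1.0 - p) * model_kwargs.get("W_inh", 500.0))
    params = RateModelParams(**model_kwargs)
    proto_kwargs = dict(config["protocol"])
    if "input_range" in proto_kwargs and proto_kwargs["input_range"] is not None:
        proto_kwargs["input_range"] = tuple(proto_kwargs["input_range"])
    protocol = TrialProtocol(**proto_kwargs)
    cfg = PlasticityConfig(**config["plasticity"])
    rng = np.random.default_rng(config["seed"])
    trace = run_session(params, protocol, cfg, config["n_trials"], rng,
                        dt=config["dt"])
    n_avg = config["n_avg"]
    metrics = {
        "final_ratio_mean": float(trace.ratio[-n_avg:].mean()),
        "final_ratio_std": float(trace.ratio[-n_avg:].std()),
        "trials_to_criterion": trials_to_criterion(trace, config["criterion"]),
    }
    return {"kind": "rate", "trace": trace, "metrics": metrics, "params": params}


def _run_ring(config: dict) -> dict:
    params = RingParams(**config["model"])
    conn = ConnectivitySet.from_params(params)
    spec = PerturbationSpec(**config["perturbation"])
    conn.W_EE = apply_perturbation(conn.W_EE, spec)
    cfg = PlasticityConfig(**config["plasticity"])
    rng = np.random.default_rng(config["seed"])
    trace = run_learning_session(conn, params, cfg, config["n_trials"],
                                 config["eval_stride"], rng,
                                 decode_scale=config["decode_scale"],
                                 n_repeats=config["n_repeats"])
    metrics = {
        "initial_decoding_error": float(trace.decoding_error[0]),
        "final_decoding_error": float(trace.decoding_error[-1]),
        "final_normalized_std_F1": float(trace.normalized_std_F1[-1]),
        "final_mean_F1": float(trace.mean_F1[-1]),
    }
    return {"kind": "ring", "trace": trace, "metrics": metrics, "params": params,
            "connectivity": conn}


def run_experiment(config: dict, outdir=None) -> dict:
    """Run one experiment from a config; optionally persist its outputs.

    Outputs under ``outdir``: per-trial ``trace.csv``, ``metadata.json``
    (config snapshot, seed, package version, metrics) and, for ring runs,
    the final connectivity as ``connectivity.npz``.
    """
    config = validate_config(config)
    result = _run_rate(config) if config["kind"] == "rate" else _run_ring(config)
    result["config"] = config
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        result["trace"].to_dataframe().to_csv(outdir / "trace.csv", index=False)
        meta = {"config": config, "version": __version__,
                "metrics": result["metrics"]}
        (outdir / "metadata.json").write_text(json.dumps(meta, indent=2))
        if "connectivity" in result:
            conn = result["connectivity"]
            np.savez(outdir / "connectivity.npz", W_EE=conn.W_EE, W_EI=conn.W_EI,
                     W_IE=conn.W_IE, W_II=conn.W_II, W0_EE=conn.W0_EE)
    return result


@dataclass(frozen=True)
class SweepSpec:
    """A 1- or 2-axis parameter sweep over a base config.

    Axis parameter names are dotted config paths (``plasticity.alpha_d``,
    ``model.W_inh``, ``perturbation.strength`` ...).  One seed per cell by
    default (the base config's); ``replicate_seeds`` runs each cell once per
    seed.
    """

    base_config: dict
    axes: tuple  # ((name, values), ...) with 1 or 2 entries
    metric: str = "trials_to_criterion"
    replicate_seeds: Optional[tuple] = None

    def __post_init__(self) -> None:
        if not (1 <= len(self.axes) <= 2):
            raise ValueError("SweepSpec supports 1 or 2 axes")
        for name, values in self.axes:
            if len(values) == 0:
                raise ValueError(f"axis {name!r} has an empty grid")
        # every axis name must resolve against the resolved base config
        resolved = resolve_config(self.base_config)
        for name, _ in self.axes:
            node = resolved
            for key in name.split("."):
                if not isinstance(node, dict) or key not in node:
                    raise ValueError(f"axis parameter {name!r} does not resolve "
                                     "to a config key")
                node = node[key]


def run_sweep(sweep: SweepSpec, csv_path=None) -> pd.DataFrame:
    """Run every cell of a sweep; returns one row per (cell, seed).

    Resumable: if ``csv_path`` exists, completed cells (matched on axis
    values and seed) are skipped and their rows reused.  Per-cell failures
    are recorded (``error`` column) and the sweep continues.
    """
    done = pd.DataFrame()
    if csv_path is not None and Path(csv_path).exists():
        done = pd.read_csv(csv_path)
    seeds = sweep.replicate_seeds or (resolve_config(sweep.base_config)["seed"],)
    axis_names = [name for name, _ in sweep.axes]
    grids = [list(values) for _, values in sweep.axes]
    cells = [(a,) for a in grids[0]] if len(grids) == 1 else [
        (a, b) for a in grids[0] for b in grids[1]]

    rows = []
    for cell in cells:
        for seed in seeds:
            if len(done):
                match = np.ones(len(done), dtype=bool)
                for name, val in zip(axis_names, cell):
                    match &= np.isclose(done[name], val)
                match &= done["seed"] == seed
                if match.any():
                    rows.append(done[match].iloc[0].to_dict())
                    continue
            config = copy.deepcopy(sweep.base_config)
            for name, val in zip(axis_names, cell):
                set_by_path(config, name, float(val))
            set_by_path(config, "seed", int(seed))
            row = {name: val for name, val in zip(axis_names, cell)}
            row["seed"] = seed
            try:
                result = run_experiment(config)
                row.update(result["metrics"])
                row["error"] = ""
            except Exception as exc:  # noqa: BLE001 - per-cell failures recorded
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
    table = pd.DataFrame(rows)
    if csv_path is not None:
        table.to_csv(csv_path, index=False)
    return table


def fit_scaling_exponent(metric_grid, axis_a, axis_b) -> float:
    """Exponent k such that the metric is constant along a*b^k contours.

    Fits log(metric) = const + beta_a*log(a) + beta_b*log(b) by least squares
    over the grid and returns k = beta_b/beta_a — if the metric depends on
    the axes only through the product a*b^k, the two slopes are proportional
    with that ratio.  Intended for trials-to-criterion grids; needs >= 3
    values per axis and a non-flat, all-positive grid.
    """
    T = np.asarray(metric_grid, dtype=float)
    a = np.asarray(axis_a, dtype=float)
    b = np.asarray(axis_b, dtype=float)
    if T.shape != (a.size, b.size):
        raise ValueError("metric_grid must be (len(axis_a), len(axis_b))")
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 values per axis")
    if np.any(T <= 0):
        raise ValueError("metric grid must be positive (criterion reached everywhere)")
    if np.ptp(T) == 0:
        raise ValueError("degenerate (flat) metric grid")
    la, lb = np.meshgrid(np.log(a), np.log(b), indexing="ij")
    X = np.column_stack([np.ones(T.size), la.ravel(), lb.ravel()])
    coef, *_ = np.linalg.lstsq(X, np.log(T.ravel()), rcond=None)
    beta_a, beta_b = coef[1], coef[2]
    if abs(beta_a) < 1e-12:
        raise ValueError("metric does not vary along axis_a; exponent undefined")
    return float(beta_b / beta_a)
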