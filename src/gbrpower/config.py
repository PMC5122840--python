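"""YAML scenario-file parsing and validation.

A run file holds a master seed plus a list of scenario blocks; a grid file
declares axes that are expanded into a Cartesian product of scenarios.
Every default tracks the package-wide conventions: alpha 0.05, 1,000
iterations, 4.0-year follow-up, 37% incidence, 20 SNPs.
"""

from __future__ import annotations

import itertools
from dataclasses import fields as dc_fields
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigSchemaError
from .genetics import SNPPanel
from .power import ScenarioConfig
from .presets import get_preset

__all__ = ["load_run_config", "load_grid_config", "RunSpec"]

_SCALARS = {
    "frame_size": int,
    "n_trial": int,
    "design": str,
    "outcome": str,
    "k": int,
    "followup": float,
    "target_incidence": float,
    "treatment_main": float,
    "resid_sd": float,
    "r2_error": float,
    "alpha": float,
    "iterations": int,
    "seed": int,
    "direction": str,
}
_PAIRS = {"maf_range", "effect_range"}


class RunSpec:
    """Parsed run file: named scenarios plus their task (power | sample_size)."""

    def __init__(self, scenarios, master_seed):
        self.scenarios = scenarios  # list of (name, ScenarioConfig, task dict)
        self.master_seed = master_seed


def _build_scenario(block: dict, idx: int, master_seed: int):
    if not isinstance(block, dict):
        raise ConfigSchemaError(f"scenarios[{idx}]", "must be a mapping")
    block = dict(block)
    name = str(block.pop("name", f"scenario{idx + 1}"))
    task = {
        "task": block.pop("task", "power"),
        "target_power": float(block.pop("target_power", 0.8)),
        "iterations_per_point": block.pop("iterations_per_point", None),
        "bracket": block.pop("bracket", None),
    }
    if task["task"] not in ("power", "sample_size"):
        raise ConfigSchemaError(f"{name}.task", "must be 'power' or 'sample_size'")

    preset = block.pop("preset", None)
    panel_block = block.pop("panel", None)

    kwargs = {}
    for key, value in block.items():
        if key in _SCALARS:
            try:
                kwargs[key] = _SCALARS[key](value)
            except (TypeError, ValueError):
                raise ConfigSchemaError(f"{name}.{key}", f"cannot parse {value!r}")
        elif key in _PAIRS:
            try:
                lo, hi = value
                kwargs[key] = (float(lo), float(hi))
            except (TypeError, ValueError):
                raise ConfigSchemaError(f"{name}.{key}", "must be a [lo, hi] pair")
        else:
            raise ConfigSchemaError(f"{name}.{key}", "unknown field")
    kwargs.setdefault("seed", master_seed + idx)

    if panel_block is not None:
        try:
            kwargs["panel"] = SNPPanel(
                freqs=np.asarray(panel_block["freqs"], dtype=float),
                beta_main=np.asarray(panel_block.get(
                    "beta_main", np.zeros(len(panel_block["freqs"]))), dtype=float),
                beta_int=np.asarray(panel_block["beta_int"], dtype=float),
            )
        except (KeyError, TypeError) as exc:
            raise ConfigSchemaError(
                f"{name}.panel", f"needs 'freqs' and 'beta_int' lists ({exc})"
            )

    try:
        if preset is not None:
            cfg = get_preset(preset, **kwargs)
        else:
            required = {"frame_size", "n_trial"}
            missing = required - kwargs.keys()
            if missing:
                raise ConfigSchemaError(f"{name}.{sorted(missing)[0]}", "required")
            cfg = ScenarioConfig(**kwargs)
    except ConfigSchemaError:
        raise
    except Exception as exc:
        raise ConfigSchemaError(name, str(exc))
    return name, cfg, task


def load_run_config(path: str | Path) -> RunSpec:
    """Parse and validate a run file (seed + scenario list)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigSchemaError("<root>", "must be a mapping")
    master_seed = int(doc.get("seed", 0))
    blocks = doc.get("scenarios", [])
    if not isinstance(blocks, list):
        raise ConfigSchemaError("scenarios", "must be a list")
    scenarios = [_build_scenario(b, i, master_seed) for i, b in enumerate(blocks)]
    return RunSpec(scenarios, master_seed)


def load_grid_config(path: str | Path, cap: int = 64) -> RunSpec:
    """Expand a grid file into the Cartesian product of its axes.

    Axes: design, maf_range (list of pairs), effect_range (list of pairs),
    frame_size, n_trial -- any axis may also be a single value.  A product
    larger than ``cap`` is refused with the offending count.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigSchemaError("<root>", "must be a mapping")
    master_seed = int(doc.get("seed", 0))
    cap = int(doc.get("cap", cap))
    base = dict(doc.get("base", {}))
    axes_block = doc.get("axes", {})
    if not isinstance(axes_block, dict) or not axes_block:
        raise ConfigSchemaError("axes", "must be a non-empty mapping")

    def as_list(v, pair_axis=False):
        if pair_axis:
            if v and isinstance(v[0], (list, tuple)):
                return [tuple(map(float, p)) for p in v]
            return [tuple(map(float, v))]
        return v if isinstance(v, list) else [v]

    axis_names = list(axes_block)
    axis_values = []
    for ax in axis_names:
        axis_values.append(as_list(axes_block[ax], pair_axis=ax in _PAIRS))
    combos = list(itertools.product(*axis_values))
    if len(combos) > cap:
        raise ConfigSchemaError(
            "axes", f"grid expands to {len(combos)} scenarios, above cap {cap}"
        )
    scenarios = []
    for i, combo in enumerate(combos):
        block = dict(base)
        block.update(dict(zip(axis_names, combo)))
        parts = [f"{ax}={val}" for ax, val in zip(axis_names, combo)]
        block.setdefault("name", "grid_" + "_".join(parts).replace(" ", ""))
        scenarios.append(_build_scenario(block, i, master_seed))
    return RunSpec(scenarios, master_seed)
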