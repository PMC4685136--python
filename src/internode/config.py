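"""YAML configuration loading for the simulator.

A config file is a flat mapping of :class:`~internode.model.ModelConfig`
fields, with two optional nested sections, ``arrhenius`` (temperature
response parameters) and ``window`` (signal-window placement)::

    fil_intercept: 13.4
    fil_par_slope: 0.014
    k_elong: 0.5
    De20: 4.2
    Da20: 1.4
    temperature_sensitive: true
    arrhenius:
      deltaH_A: 69350
      T0: 305
      alpha: 3.5
      T_ref_celsius: 20
    window:
      offset_before_event: 6
      width: 4

Unknown keys are an error — silently ignoring a misspelled parameter is
worse than failing.  The pluggable f(R:FR) hook is code-only and cannot
be set from a file.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .arrhenius import ArrheniusParams
from .climate import SignalWindow
from .model import ModelConfig

__all__ = ["load_model_config", "model_config_from_dict"]

_SCALAR_FIELDS = {
    f.name
    for f in fields(ModelConfig)
    if f.name not in ("arrhenius", "window", "rfr_function")
}


def model_config_from_dict(data: dict) -> ModelConfig:
    """Build a :class:`ModelConfig` from a parsed mapping; reject unknown keys."""
    if not isinstance(data, dict):
        raise ValueError(f"config must be a mapping, got {type(data).__name__}")
    data = dict(data)
    kwargs: dict = {}

    arr = data.pop("arrhenius", None)
    if arr is not None:
        allowed = {"deltaH_A", "T0", "alpha", "T_ref_celsius"}
        unknown = set(arr) - allowed
        if unknown:
            raise ValueError(f"unknown arrhenius key(s): {sorted(unknown)}")
        kwargs["arrhenius"] = ArrheniusParams(**arr)

    win = data.pop("window", None)
    if win is not None:
        allowed = {"offset_before_event", "width"}
        unknown = set(win) - allowed
        if unknown:
            raise ValueError(f"unknown window key(s): {sorted(unknown)}")
        kwargs["window"] = SignalWindow(**win)

    unknown = set(data) - _SCALAR_FIELDS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    kwargs.update(data)
    return ModelConfig(**kwargs)


def load_model_config(path: str | Path | None) -> ModelConfig:
    """Load a model config from a YAML file; defaults when ``path`` is None."""
    if path is None:
        return ModelConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    try:
        return model_config_from_dict(data)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: {exc}") from exc
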