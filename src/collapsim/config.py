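"""Configuration loading and parameter resolution.

A config file is a flat YAML mapping whose keys mirror
:class:`~collapsim.society.ModelParams` (``n, t_max, alpha, beta, epsilon,
a, b, c, rho, p_e, seed``).  Missing keys fall back to the reference
defaults; unknown keys are rejected; explicit CLI flags override file
values.  All violations are collected and reported together.
"""

from __future__ import annotations

import dataclasses

import yaml

from .society import ModelParams, ValidationError, validate_params

__all__ = ["PARAM_KEYS", "load_config", "resolve_params"]

PARAM_KEYS = tuple(f.name for f in dataclasses.fields(ModelParams))


def load_config(path) -> dict:
    """Read a flat key:value parameter document.

    Returns the raw overrides (a subset of ``PARAM_KEYS``); an empty file
    yields the full set of defaults downstream.
    """
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ValidationError([f"config {path}: unparseable ({exc})"])
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValidationError(
            [f"config {path}: expected a flat key: value mapping"]
        )
    unknown = sorted(set(data) - set(PARAM_KEYS))
    if unknown:
        raise ValidationError(
            [
                f"config {path}: unknown key {k!r} (known keys: "
                f"{', '.join(PARAM_KEYS)})"
                for k in unknown
            ]
        )
    return data


def resolve_params(
    config: dict | None = None, overrides: dict | None = None
) -> ModelParams:
    """Merge defaults <- config file <- explicit overrides into ModelParams.

    ``overrides`` entries that are ``None`` are treated as "not given".
    Range violations from the merged set are reported all at once.
    """
    merged = {f.name: f.default for f in dataclasses.fields(ModelParams)}
    for source in (config or {}), (overrides or {}):
        for key, value in source.items():
            if key not in PARAM_KEYS:
                raise ValidationError([f"unknown parameter {key!r}"])
            if value is not None:
                merged[key] = value
    problems = validate_params(merged)
    if problems:
        raise ValidationError(problems)
    if isinstance(merged["n"], float):
        merged["n"] = int(merged["n"])
    if isinstance(merged["t_max"], float):
        merged["t_max"] = int(merged["t_max"])
    merged["seed"] = int(merged["seed"])
    return ModelParams(**merged)
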