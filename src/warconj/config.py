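"""Run configuration: strict YAML schema with packaged defaults.

A config file is a YAML mapping; every key is optional and unspecified
fields fall back to the packaged defaults (the standard parameter table
plus the simulator's integration settings), so an empty file is a valid
config equal to the defaults. Unknown keys are an error — typos never pass
silently — and out-of-range values are rejected with the offending key
named. Configs round-trip exactly: ``load(dump(cfg)) == cfg``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import yaml

from .core import STATE_FIELDS, ModelParams, ModelVariant, SystemState, default_initial_state
from .simulate import (
    DEFAULT_ATOL,
    DEFAULT_CONVERGENCE_TOL,
    DEFAULT_EXTINCTION_THRESHOLD,
    DEFAULT_RTOL,
    DEFAULT_T_MAX,
    Scenario,
)
from .sweeps import AxisSpec

__all__ = ["RunConfig", "load_config", "loads_config", "dump_config", "default_config_path"]

_TOP_LEVEL_KEYS = {
    "variant", "scenario", "params", "init", "t_max", "rtol", "atol",
    "convergence_tol", "extinction_threshold", "transfer_only_zero_gamma",
    "axes", "output", "plot",
}
_AXIS_KEYS = {"name", "values", "scale"}


class ConfigError(ValueError):
    """Raised for malformed or out-of-range configuration input."""


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved settings for a run, scenario evaluation, or sweep."""

    variant: ModelVariant = ModelVariant.DEFAULT
    scenario: Scenario = Scenario.KILLING_AND_TRANSFER
    params: ModelParams = field(default_factory=ModelParams)
    init: SystemState | None = None  # None -> the variant's standard initial state
    t_max: float = DEFAULT_T_MAX
    rtol: float = DEFAULT_RTOL
    atol: float = DEFAULT_ATOL
    convergence_tol: float = DEFAULT_CONVERGENCE_TOL
    extinction_threshold: float = DEFAULT_EXTINCTION_THRESHOLD
    transfer_only_zero_gamma: bool = False
    axes: tuple[AxisSpec, ...] = ()
    output: str | None = None
    plot: str | None = None

    def resolved_init(self) -> SystemState:
        return self.init if self.init is not None else default_initial_state(self.variant)

    def replace(self, **changes) -> "RunConfig":
        return replace(self, **changes)


def _check_keys(mapping: dict, allowed: set[str], context: str) -> None:
    unknown = sorted(set(mapping) - allowed)
    if unknown:
        raise ConfigError(
            f"unknown {context} key(s): {', '.join(repr(k) for k in unknown)}; "
            f"valid keys: {', '.join(sorted(allowed))}"
        )


def _number(mapping: dict, key: str, context: str) -> float:
    value = mapping[key]
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ConfigError(f"{context} key {key!r} must be a number, got {value!r}")
    return float(value)


def loads_config(text: str) -> RunConfig:
    """Parse and validate a YAML config document (empty text -> defaults)."""
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"config is not valid YAML: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config must be a mapping, got {type(raw).__name__}")
    _check_keys(raw, _TOP_LEVEL_KEYS, "config")

    kwargs: dict = {}
    if "variant" in raw:
        try:
            kwargs["variant"] = ModelVariant(raw["variant"])
        except ValueError:
            raise ConfigError(
                f"key 'variant': unknown variant {raw['variant']!r}; "
                f"valid: {', '.join(v.value for v in ModelVariant)}"
            ) from None
    if "scenario" in raw:
        try:
            kwargs["scenario"] = Scenario(raw["scenario"])
        except ValueError:
            raise ConfigError(
                f"key 'scenario': unknown scenario {raw['scenario']!r}; "
                f"valid: {', '.join(s.value for s in Scenario)}"
            ) from None

    if "params" in raw:
        sub = raw["params"] or {}
        if not isinstance(sub, dict):
            raise ConfigError("key 'params' must be a mapping")
        _check_keys(sub, set(ModelParams.field_names()), "params")
        overrides = {k: _number(sub, k, "params") for k in sub}
        try:
            kwargs["params"] = ModelParams(**overrides)
        except ValueError as exc:
            raise ConfigError(f"key 'params': {exc}") from exc

    if "init" in raw:
        sub = raw["init"] or {}
        if not isinstance(sub, dict):
            raise ConfigError("key 'init' must be a mapping")
        _check_keys(sub, set(STATE_FIELDS), "init")
        variant = kwargs.get("variant", ModelVariant.DEFAULT)
        base = default_initial_state(variant)
        overrides = {k: _number(sub, k, "init") for k in sub}
        try:
            kwargs["init"] = base.replace(**overrides)
        except ValueError as exc:
            raise ConfigError(f"key 'init': {exc}") from exc

    for key in ("t_max", "rtol", "atol", "convergence_tol", "extinction_threshold"):
        if key in raw:
            value = _number(raw, key, "config")
            if value <= 0:
                raise ConfigError(f"key {key!r} must be > 0, got {value!r}")
            kwargs[key] = value

    if "transfer_only_zero_gamma" in raw:
        value = raw["transfer_only_zero_gamma"]
        if not isinstance(value, bool):
            raise ConfigError(
                f"key 'transfer_only_zero_gamma' must be a boolean, got {value!r}"
            )
        kwargs["transfer_only_zero_gamma"] = value

    if "axes" in raw:
        entries = raw["axes"] or []
        if not isinstance(entries, list):
            raise ConfigError("key 'axes' must be a list of axis mappings")
        axes = []
        for i, entry in enumerate(entries):
            if not isinstance(entry, dict):
                raise ConfigError(f"axes[{i}] must be a mapping")
            _check_keys(entry, _AXIS_KEYS, f"axes[{i}]")
            if "name" not in entry or "values" not in entry:
                raise ConfigError(f"axes[{i}] requires 'name' and 'values'")
            try:
                axes.append(
                    AxisSpec(
                        str(entry["name"]),
                        tuple(entry["values"]),
                        entry.get("scale", "linear"),
                    )
                )
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"axes[{i}]: {exc}") from exc
        kwargs["axes"] = tuple(axes)

    for key in ("output", "plot"):
        if key in raw and raw[key] is not None:
            kwargs[key] = str(raw[key])

    return RunConfig(**kwargs)


def load_config(path) -> RunConfig:
    """Load and validate a config file; missing file is an error."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    except FileNotFoundError:
        raise ConfigError(f"config file not found: {path}") from None
    return loads_config(text)


def dump_config(config: RunConfig) -> str:
    """Serialize a config to YAML such that ``loads_config`` reproduces it."""
    doc: dict = {
        "variant": config.variant.value,
        "scenario": config.scenario.value,
        "params": config.params.to_dict(),
        "t_max": config.t_max,
        "rtol": config.rtol,
        "atol": config.atol,
        "convergence_tol": config.convergence_tol,
        "extinction_threshold": config.extinction_threshold,
        "transfer_only_zero_gamma": config.transfer_only_zero_gamma,
    }
    if config.init is not None:
        doc["init"] = config.init.to_dict()
    if config.axes:
        doc["axes"] = [
            {"name": a.name, "values": list(a.values), "scale": a.scale}
            for a in config.axes
        ]
    if config.output is not None:
        doc["output"] = config.output
    if config.plot is not None:
        doc["plot"] = config.plot
    return yaml.safe_dump(doc, sort_keys=True)


def default_config_path():
    """Path to the packaged defaults file (the standard parameter table)."""
    return importlib.resources.files("warconj").joinpath("data/defaults.yaml")
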