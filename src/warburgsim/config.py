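"""Run configuration: YAML loading, validation, defaults.

A run configuration selects the model variant, overrides environment values,
activity multipliers and solver options, and names a sweep or preset to run.
Unknown keys are rejected with a suggestion for the nearest valid key, and
the effective merged configuration is always echoed alongside results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .network import ModelDefinition, build_default_network, suggest_key
from .parameters import ACTIVITY_KEYS, ENV_KEYS, ParameterSet, default_parameters
from .redox import build_extended_network, extended_parameters
from .steady_state import SolverOptions

__all__ = ["RunConfig", "load_config", "ConfigError"]

MODEL_VARIANTS = ("baseline", "extended", "clamped-atp")
SOLVER_KEYS = ("abs_tol", "rel_tol", "ss_tol", "t_max", "bound_cap", "max_nfev")
TOP_KEYS = ("model_variant", "environment", "activity", "solver", "sweep",
            "preset", "output_dir")
SWEEP_KEYS = ("param", "from", "to", "points", "values", "direction",
              "continuation", "readout")


class ConfigError(ValueError):
    """A configuration problem: parse failure, unknown key or bad value."""


def _reject_unknown(mapping: dict, valid: tuple[str, ...], context: str) -> None:
    for key in mapping:
        if key not in valid:
            hint = suggest_key(str(key), list(valid))
            msg = f"unknown {context} key {key!r}"
            if hint:
                msg += f"; did you mean {hint!r}?"
            raise ConfigError(msg)


@dataclass
class RunConfig:
    """Validated run request: model variant, overrides, and what to run."""

    model_variant: str = "baseline"
    environment: dict[str, float] = field(default_factory=dict)
    activity: dict[str, float] = field(default_factory=dict)
    solver: dict[str, float] = field(default_factory=dict)
    sweep: dict | None = None
    preset: str | None = None
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.model_variant not in MODEL_VARIANTS:
            hint = suggest_key(self.model_variant, list(MODEL_VARIANTS))
            raise ConfigError(
                f"unknown model_variant {self.model_variant!r}"
                + (f"; did you mean {hint!r}?" if hint else ""))
        _reject_unknown(self.environment, ENV_KEYS, "environment")
        _reject_unknown(self.activity, ACTIVITY_KEYS, "activity")
        _reject_unknown(self.solver, SOLVER_KEYS, "solver")
        if self.sweep is not None:
            _reject_unknown(self.sweep, SWEEP_KEYS, "sweep")

    # ------------------------------------------------------------------
    def build_model(self) -> ModelDefinition:
        if self.model_variant == "extended":
            return build_extended_network()
        m = build_default_network()
        if self.model_variant == "clamped-atp":
            m = m.variant(clamp_atp=True)
        return m

    def build_parameters(self) -> ParameterSet:
        p = (extended_parameters() if self.model_variant == "extended"
             else default_parameters())
        if self.environment:
            p = p.with_env(**self.environment)
        for key, value in self.activity.items():
            if value < 0:
                raise ConfigError(f"activity.{key} must be >= 0, got {value}")
            p.activity[key] = float(value)
        return p

    def build_solver_options(self) -> SolverOptions:
        kwargs = dict(self.solver)
        if "max_nfev" in kwargs:
            kwargs["max_nfev"] = int(kwargs["max_nfev"])
        try:
            return SolverOptions(**kwargs)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"bad solver option: {exc}") from exc

    def effective(self) -> dict:
        """The fully merged configuration (defaults filled in explicitly)."""
        p = self.build_parameters()
        opts = self.build_solver_options()
        return {
            "model_variant": self.model_variant,
            "environment": {k: getattr(p, k) for k in ENV_KEYS},
            "activity": dict(p.activity),
            "solver": {k: getattr(opts, k) for k in SOLVER_KEYS},
            "sweep": self.sweep,
            "preset": self.preset,
            "output_dir": self.output_dir,
            "parameter_hash": p.param_hash(),
        }


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    An empty document yields an all-defaults configuration.  Unknown keys at
    any level are rejected with a message naming the nearest valid key.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path} must contain a mapping at top level")
    _reject_unknown(raw, TOP_KEYS, "configuration")
    cfg = RunConfig(
        model_variant=str(raw.get("model_variant", "baseline")),
        environment={k: float(v) for k, v in (raw.get("environment") or {}).items()},
        activity={k: float(v) for k, v in (raw.get("activity") or {}).items()},
        solver={k: float(v) for k, v in (raw.get("solver") or {}).items()},
        sweep=raw.get("sweep"),
        preset=raw.get("preset"),
        output_dir=str(raw.get("output_dir", ".")),
    )
    # fail early on out-of-range values
    cfg.build_parameters()
    cfg.build_solver_options()
    return cfg
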