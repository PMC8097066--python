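"""Run configuration: validated scenario constants, JSON/YAML persistence.

Two bundled scenarios mirror the worked examples: the 10-CB chain
(Gauss scission, ``dt = 100 s``, glucose-terminal ladder) and the 100-CB
chain (``dt = 10 s``, glucose-then-HMF ladder, ``T = 483 K`` vs
``T_ref = 453 K``, ``c_a = 4 %`` vs ``c_a,ref = 1 %``).  A config file may
be empty (full defaults) or override any subset of keys; unknown keys are
rejected by name.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigError
from .ladder import TerminalScheme
from .transition import (
    ArgConvention,
    ArrheniusSign,
    Distribution,
    NormalizationMode,
    ProcessConditions,
)

#: Default mean activation energy of the glycosidic-bond scissions, J/mol
#: (dilute-acid cellulose hydrolysis literature range 170-180 kJ/mol).
DEFAULT_E_AM = 170_000.0
#: Default activation energy of the glucose -> HMF step, J/mol
#: (glucose dehydration literature range ~120-140 kJ/mol).
DEFAULT_E_AG = 130_000.0


@dataclass(frozen=True)
class RunConfig:
    """One reproducible simulation scenario."""

    n_units: int = 10
    distribution: Distribution = Distribution.GAUSS
    arg_convention: ArgConvention = ArgConvention.SOURCE_CLASS
    normalization_mode: NormalizationMode = NormalizationMode.CONSERVATIVE
    terminal_scheme: TerminalScheme = TerminalScheme.GLUCOSE_TERMINAL
    dt_s: float = 100.0
    n_steps: int = 100
    c_C0_g_per_L: float = 100.0
    T_K: float = 453.0
    T_ref_K: float = 453.0
    c_a_pct: float = 1.0
    c_a_ref_pct: float = 1.0
    acid_order: float = 1.0
    E_Am_J_per_mol: float = DEFAULT_E_AM
    E_AG_J_per_mol: float = DEFAULT_E_AG
    arrhenius_sign: ArrheniusSign = ArrheniusSign.AS_PRINTED
    output_dir: str = "."

    def __post_init__(self) -> None:
        for name in (
            "dt_s",
            "c_C0_g_per_L",
            "T_K",
            "T_ref_K",
            "c_a_pct",
            "c_a_ref_pct",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_units < 1:
            raise ConfigError(f"n_units must be >= 1, got {self.n_units}")
        if self.n_steps < 0:
            raise ConfigError(f"n_steps must be >= 0, got {self.n_steps}")

    def conditions(self) -> ProcessConditions:
        return ProcessConditions(
            T=self.T_K,
            T_ref=self.T_ref_K,
            c_a=self.c_a_pct,
            c_a_ref=self.c_a_ref_pct,
            acid_order=self.acid_order,
            E_Am=self.E_Am_J_per_mol,
            E_AG=self.E_AG_J_per_mol,
            arrhenius_sign=self.arrhenius_sign,
        )

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for key, value in out.items():
            if hasattr(value, "value"):
                out[key] = value.value
        return out


#: Overrides matching the 100-CB simulation scenario.
PD200_OVERRIDES = {
    "n_units": 100,
    "terminal_scheme": "glucose_then_hmf",
    "dt_s": 10.0,
    "n_steps": 100,
    "T_K": 483.0,
    "T_ref_K": 453.0,
    "c_a_pct": 4.0,
    "c_a_ref_pct": 1.0,
}

_ENUM_FIELDS = {
    "distribution": Distribution,
    "arg_convention": ArgConvention,
    "normalization_mode": NormalizationMode,
    "terminal_scheme": TerminalScheme,
    "arrhenius_sign": ArrheniusSign,
}


def config_from_dict(raw: dict | None) -> RunConfig:
    raw = dict(raw or {})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"unknown config keys: {', '.join(unknown)}")
    # a 100-CB scenario pulls in its own defaults unless overridden
    if raw.get("n_units") == 100:
        raw = {**PD200_OVERRIDES, **raw}
    for name, enum_cls in _ENUM_FIELDS.items():
        if name in raw:
            try:
                raw[name] = enum_cls(raw[name])
            except ValueError as exc:
                raise ConfigError(f"invalid value for {name}: {raw[name]!r}") from exc
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path: str | Path) -> RunConfig:
    """Read a JSON or YAML config file; an empty file means full defaults."""
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)  # YAML is a superset of JSON
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    return config_from_dict(raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write the fully resolved config as JSON (loadable by load_config)."""
    Path(path).write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True))
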