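"""Run configuration: YAML/JSON loading, validation and the bundled case study.

Config fields are named exactly after the glossary symbols (``mu_d``,
``sigma_d``, ``mu_nd``, ``sigma_nd``, ``v``, ``u_a``, ``u_b``, ``d``,
``l0``, ``l_tn``, ``l_fn``, ``l_tp``, ``l_fp``) so transcribing a
published parameter table is mechanical.  ``d`` and the five loss
constants are optional; the losses must be given all together.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from numbers import Real
from pathlib import Path
from typing import Optional, Union

import yaml

from .analysis import TestPair
from .core import PopulationPair, TestModel
from .measures import LossSpec

__all__ = ["RunConfig", "ConfigError", "load_config", "write_config", "case_study"]

_POP_FIELDS = ("mu_d", "sigma_d", "mu_nd", "sigma_nd", "v")
_LOSS_FIELDS = ("l0", "l_tn", "l_fn", "l_tp", "l_fp")
_ALL_FIELDS = _POP_FIELDS + ("u_a", "u_b", "d") + _LOSS_FIELDS


class ConfigError(ValueError):
    """A configuration file is missing a field or violates an invariant."""


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to run the calculators on a pair of tests."""

    pop: PopulationPair
    u_a: float
    u_b: float
    d: Optional[float] = None
    loss: Optional[LossSpec] = None

    @property
    def test1(self) -> TestModel:
        return TestModel(self.pop, self.u_a)

    @property
    def test2(self) -> TestModel:
        return TestModel(self.pop, self.u_b)

    @property
    def pair(self) -> TestPair:
        return TestPair(self.test1, self.test2)

    def to_dict(self) -> dict:
        out = {
            "mu_d": self.pop.mu_d, "sigma_d": self.pop.sigma_d,
            "mu_nd": self.pop.mu_nd, "sigma_nd": self.pop.sigma_nd,
            "v": self.pop.v, "u_a": self.u_a, "u_b": self.u_b,
        }
        if self.d is not None:
            out["d"] = self.d
        if self.loss is not None:
            out.update(l0=self.loss.l0, l_tn=self.loss.l_tn, l_fn=self.loss.l_fn,
                       l_tp=self.loss.l_tp, l_fp=self.loss.l_fp)
        return out


def _from_dict(raw: dict) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping of parameter names to numbers")
    unknown = sorted(set(raw) - set(_ALL_FIELDS))
    if unknown:
        raise ConfigError(f"unknown config field(s): {', '.join(unknown)}")

    def num(name: str, required: bool):
        if name not in raw:
            if required:
                raise ConfigError(f"missing required config field: {name}")
            return None
        val = raw[name]
        if isinstance(val, bool) or not isinstance(val, Real):
            raise ConfigError(f"config field {name} must be a number, got {val!r}")
        return float(val)

    pop_kwargs = {k: num(k, required=True) for k in _POP_FIELDS}
    u_a, u_b = num("u_a", True), num("u_b", True)
    d = num("d", False)
    loss_vals = {k: num(k, False) for k in _LOSS_FIELDS}
    present = [k for k, x in loss_vals.items() if x is not None]
    if present and len(present) != len(_LOSS_FIELDS):
        missing = sorted(set(_LOSS_FIELDS) - set(present))
        raise ConfigError(f"incomplete loss specification; missing: {', '.join(missing)}")

    try:
        pop = PopulationPair(**pop_kwargs)
        loss = LossSpec(**loss_vals) if present else None
        cfg = RunConfig(pop=pop, u_a=u_a, u_b=u_b, d=d, loss=loss)
        cfg.test1, cfg.test2  # trigger u >= 0 validation
    except ValueError as exc:  # invariant messages already name the field
        raise ConfigError(str(exc)) from exc
    return cfg


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load and validate a YAML (``.yaml``/``.yml``) or JSON config file."""
    path = Path(path)
    text = path.read_text()
    try:
        raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    return _from_dict(raw)


def write_config(cfg: RunConfig, path: Union[str, Path]) -> None:
    """Write a config loadable by :func:`load_config` (format by extension)."""
    path = Path(path)
    data = cfg.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def case_study() -> RunConfig:
    """The bundled glucose/OGTT case study.

    Log-transformed two-hour post-load glucose, normalized to the
    non-diabetic SD: diseased mean 2.99 and SD 0.75, non-diseased mean 0
    and SD 1, diabetes prevalence 0.067, clinical threshold 2.26, test
    uncertainties 0.023 and 0.23, losses (l0, lTN, lFN, lTP, lFP) =
    (1, 0, 100, 0, 76).
    """
    with resources.as_file(resources.files("damu.data") / "case_study.yaml") as p:
        return load_config(p)
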