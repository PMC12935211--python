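"""Parameter and scenario file handling.

A parameter file is YAML (or JSON, a YAML subset): the physiology rate
constants as a flat map at the top level, the thermoregulation block under
``thermo:`` and the device block under ``device:``.  Unknown keys are
rejected.  The shipped defaults were fixed by the calibration procedure in
:mod:`woundtwin.calibrate` and live in ``data/defaults.yaml``.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Any

import yaml
from pydantic import ValidationError

from woundtwin.bridge import Scenario
from woundtwin.device import DeviceConfig
from woundtwin.errors import ConfigurationError
from woundtwin.physiology import PhysiologyParams
from woundtwin.thermoregulation import ThermoConfig

__all__ = ["ParamSet", "load_params", "default_params", "save_params", "load_scenario"]


class ParamSet:
    """The three configuration blocks a scenario needs."""

    def __init__(self, physiology: PhysiologyParams, thermo: ThermoConfig,
                 device: DeviceConfig):
        self.physiology = physiology
        self.thermo = thermo
        self.device = device

    def __iter__(self):
        return iter((self.physiology, self.thermo, self.device))


def _format_validation_error(kind: str, exc: ValidationError) -> str:
    parts = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        parts.append(f"{kind}.{loc}: {err['msg']}")
    return "; ".join(parts)


def _parse_mapping(text: str, source: str) -> dict[str, Any]:
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"{source}: not valid YAML/JSON: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigurationError(f"{source}: expected a mapping at the top level")
    return data


def params_from_mapping(data: dict[str, Any], source: str = "<params>") -> ParamSet:
    data = dict(data)
    thermo_raw = data.pop("thermo", None)
    device_raw = data.pop("device", None)
    try:
        phys = PhysiologyParams(**data)
    except (ValidationError, TypeError) as exc:
        if isinstance(exc, ValidationError):
            raise ConfigurationError(
                f"{source}: {_format_validation_error('physiology', exc)}") from exc
        raise ConfigurationError(f"{source}: {exc}") from exc
    if thermo_raw is None:
        thermo = ThermoConfig(Emax=phys.Emax, E50=phys.E50, gamma=phys.gamma,
                              Tbase=phys.Tbase)
    else:
        try:
            thermo = ThermoConfig(**thermo_raw)
        except ValidationError as exc:
            raise ConfigurationError(
                f"{source}: {_format_validation_error('thermo', exc)}") from exc
    if device_raw is None:
        device = DeviceConfig()
    else:
        if "anchors" in device_raw:
            device_raw = dict(device_raw)
            device_raw["anchors"] = tuple(tuple(a) for a in device_raw["anchors"])
        try:
            device = DeviceConfig(**device_raw)
        except ValidationError as exc:
            raise ConfigurationError(
                f"{source}: {_format_validation_error('device', exc)}") from exc
    return ParamSet(phys, thermo, device)


def load_params(path: str | Path) -> ParamSet:
    """Load and validate a parameter file."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"parameter file not found: {path}")
    return params_from_mapping(_parse_mapping(path.read_text(), str(path)), str(path))


def default_params() -> ParamSet:
    """The shipped calibrated defaults."""
    text = resources.files("woundtwin").joinpath("data/defaults.yaml").read_text()
    return params_from_mapping(_parse_mapping(text, "defaults.yaml"), "defaults.yaml")


def save_params(params: ParamSet, path: str | Path) -> None:
    """Write a parameter file in the canonical layout."""
    phys, thermo, device = params
    data = json.loads(phys.model_dump_json())
    data["thermo"] = json.loads(thermo.model_dump_json())
    dev = json.loads(device.model_dump_json())
    dev["anchors"] = [list(a) for a in dev["anchors"]]
    data["device"] = dev
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def load_scenario(path: str | Path) -> Scenario:
    """Load and validate a scenario file (YAML or JSON)."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"scenario file not found: {path}")
    data = _parse_mapping(path.read_text(), str(path))
    if "interventions" in data and data["interventions"] is not None:
        data = dict(data)
        data["interventions"] = tuple(data["interventions"])
    try:
        return Scenario(**data)
    except ValidationError as exc:
        raise ConfigurationError(
            f"{path}: {_format_validation_error('scenario', exc)}") from exc
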