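"""Tissue integrity to core temperature, and the fever set-point trigger.

The febrile response is a saturating Emax function of tissue-integrity
loss x = 1 - TI:

    E(x) = Emax * x / (E50**gamma + x)

E is the elevation above the afebrile baseline, so Tcore = Tbase + E and an
intact microvasculature (TI = 1) gives exactly the baseline temperature.
The trainer is commanded to start its infected presentation when the core
temperature reaches the set point (38 degC by default); the predicate here
is stateless — latching is the scenario runner's job.
"""

from __future__ import annotations

import math

from pydantic import BaseModel, ConfigDict, model_validator

from woundtwin.errors import DomainError

__all__ = ["ThermoConfig", "effect", "core_temperature", "fever_trigger"]


class ThermoConfig(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    Emax: float             # maximal febrile elevation (deg C)
    E50: float              # half-effect constant (dimensionless)
    gamma: float            # Hill exponent
    Tbase: float = 37.0     # afebrile core temperature (deg C)
    set_point: float = 38.0  # trigger threshold (deg C)

    @model_validator(mode="after")
    def _check(self) -> "ThermoConfig":
        if self.Emax <= 0:
            raise ValueError("Emax must be > 0")
        if self.E50 <= 0:
            raise ValueError("E50 must be > 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if not (self.Tbase < self.set_point < self.Tbase + self.Emax):
            raise ValueError(
                "set_point must lie strictly between Tbase and Tbase + Emax "
                "for the trigger to be reachable"
            )
        return self


def _effect_raw(TI: float, Emax: float, E50: float, gamma: float) -> float:
    x = 1.0 - TI
    return Emax * x / (E50 ** gamma + x)


def effect(TI: float, cfg: ThermoConfig) -> float:
    """Febrile temperature elevation (degC) at tissue integrity ``TI``."""
    if not math.isfinite(TI) or TI > 1.0 + 1e-12 or TI < 0.0:
        raise DomainError(f"TI={TI} outside [0, 1]")
    return _effect_raw(min(TI, 1.0), cfg.Emax, cfg.E50, cfg.gamma)


def core_temperature(TI: float, cfg: ThermoConfig) -> float:
    """Core temperature (degC): baseline plus the febrile elevation."""
    return cfg.Tbase + effect(TI, cfg)


def fever_trigger(Tcore: float, cfg: ThermoConfig) -> bool:
    """True iff the core temperature has reached the set point.

    Boundary inclusive: a reading exactly at the set point triggers.
    """
    if not math.isfinite(Tcore):
        raise DomainError("Tcore must be finite")
    return Tcore >= cfg.set_point
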