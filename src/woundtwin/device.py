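"""Digital twin of the heat-actuated moulage trainer.

The physical device is a silicone wound block with an embedded heating
coil.  Heating follows a piecewise-linear internal-temperature profile
capped by a relay; the skin surface saturates at a feverish plateau.  Three
cardinal signs are actuated by heat: focal edema (wax expansion, thermal
threshold with hysteresis), erythema (thermochromic reddening, elapsed-time
threshold) and purulence (released liquified wax — the one irreversible
sign).  Cooling reverses every sign except purulence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from woundtwin.errors import DomainError, IntegrationError

__all__ = [
    "DeviceConfig",
    "DeviceState",
    "SignEvent",
    "heating_profile",
    "inverse_heating_profile",
    "cool_step",
    "surface_from_internal",
    "update_signs",
    "device_step",
]


class DeviceConfig(BaseModel):
    """Thermal anchors, sign thresholds and cooling constants of the trainer."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    anchors: tuple[tuple[float, float], ...] = ((0.0, 37.0), (10.0, 45.0), (40.0, 70.0))
    relay_limit: float = 70.0        # hardware temperature cutoff (deg C)
    surface_plateau: float = 40.0    # feverish-skin surface cap (deg C)
    edema_on_temp: float = 45.0      # wax-expansion onset (deg C)
    edema_off_temp: float = 43.0     # hysteresis release (deg C)
    erythema_on_elapsed: float = 25.0  # minutes of heating
    purulence_delay: float = 5.0     # minutes after erythema onset
    cooling_tau: float = 15.0        # Newtonian cooling time constant (min)
    ambient: float = 22.0            # room temperature (deg C)

    @model_validator(mode="after")
    def _check(self) -> "DeviceConfig":
        times = [a[0] for a in self.anchors]
        temps = [a[1] for a in self.anchors]
        if len(self.anchors) < 2:
            raise ValueError("at least two heating anchors are required")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("anchor times must be strictly increasing")
        if any(v2 < v1 for v1, v2 in zip(temps, temps[1:])):
            raise ValueError("anchor temperatures must be non-decreasing")
        if temps[-1] > self.relay_limit:
            raise ValueError("last anchor temperature must not exceed relay_limit")
        if not self.edema_off_temp < self.edema_on_temp:
            raise ValueError("edema_off_temp must be strictly below edema_on_temp")
        if self.cooling_tau <= 0:
            raise ValueError("cooling_tau must be > 0")
        return self


@dataclass(frozen=True)
class SignEvent:
    """One transition in the device event log."""

    t_min: float          # total minutes since trigger
    sign: str             # edema | erythema | purulence | heater
    state: bool


@dataclass
class DeviceState:
    """Virtual trainer state.

    ``t_min`` is the wall clock (minutes since trigger); ``t_elapsed`` is
    the heating clock used by the anchor profile — it resumes by inverse
    interpolation when the heater restarts, because the wax does not reset.
    """

    t_min: float = 0.0
    t_elapsed: float = 0.0
    internal_temp: float = 37.0
    surface_temp: float = 37.0
    heater_on: bool = False
    edema: bool = False
    erythema: bool = False
    purulence: bool = False
    event_log: list[SignEvent] = field(default_factory=list)


def heating_profile(t_elapsed: float, cfg: DeviceConfig) -> float:
    """Internal temperature after ``t_elapsed`` minutes of continuous heating.

    Piecewise-linear through the anchors, clamped at the last anchor
    (the relay limit) beyond it.
    """
    if t_elapsed < 0:
        raise DomainError("t_elapsed must be >= 0")
    times = [a[0] for a in cfg.anchors]
    temps = [a[1] for a in cfg.anchors]
    return float(np.interp(t_elapsed, times, temps))


def inverse_heating_profile(internal: float, cfg: DeviceConfig) -> float:
    """Heating-clock time at which the profile first reaches ``internal``.

    Clamped to the anchor range; used to resume heating from the current
    temperature after a cooling interval.
    """
    times = [a[0] for a in cfg.anchors]
    temps = [a[1] for a in cfg.anchors]
    if internal <= temps[0]:
        return times[0]
    if internal >= temps[-1]:
        return times[-1]
    for (t1, v1), (t2, v2) in zip(cfg.anchors, cfg.anchors[1:]):
        if v1 <= internal <= v2:
            if v2 == v1:
                return t1
            return t1 + (internal - v1) / (v2 - v1) * (t2 - t1)
    return times[-1]


def cool_step(internal: float, dt: float, cfg: DeviceConfig) -> float:
    """Newtonian cooling toward ambient over ``dt`` minutes (closed form)."""
    if dt <= 0:
        raise DomainError("dt must be > 0")
    return cfg.ambient + (internal - cfg.ambient) * math.exp(-dt / cfg.cooling_tau)


def surface_from_internal(internal: float, cfg: DeviceConfig) -> float:
    """Skin surface temperature for a given internal temperature.

    Linear in the internal excess over ambient, scaled so the surface
    reaches its feverish plateau exactly when the internal temperature
    reaches the relay limit; clamped at the plateau.
    """
    if internal < cfg.ambient:
        raise DomainError("internal temperature below ambient")
    slope = (cfg.surface_plateau - cfg.ambient) / (cfg.relay_limit - cfg.ambient)
    return min(cfg.surface_plateau, cfg.ambient + slope * (internal - cfg.ambient))


def _log(state: DeviceState, sign: str, value: bool) -> None:
    state.event_log.append(SignEvent(t_min=state.t_min, sign=sign, state=value))


def update_signs(state: DeviceState, cfg: DeviceConfig) -> DeviceState:
    """Apply the sign rules to the current thermal state (mutates ``state``).

    edema: on at/above ``edema_on_temp``; off only once the heater is off
    and the block has cooled to ``edema_off_temp`` (hysteresis).
    erythema: on after ``erythema_on_elapsed`` minutes of heating; off with
    the heater off below the edema release temperature.
    purulence: on ``purulence_delay`` minutes after erythema onset while
    heating; latched forever.
    """
    if not state.edema and state.internal_temp >= cfg.edema_on_temp:
        state.edema = True
        _log(state, "edema", True)
    elif state.edema and not state.heater_on and state.internal_temp <= cfg.edema_off_temp:
        state.edema = False
        _log(state, "edema", False)

    if (not state.erythema and state.heater_on
            and state.t_elapsed >= cfg.erythema_on_elapsed):
        state.erythema = True
        _log(state, "erythema", True)
    elif (state.erythema and not state.heater_on
          and state.internal_temp < cfg.edema_off_temp):
        state.erythema = False
        _log(state, "erythema", False)

    if (not state.purulence and state.heater_on
            and state.t_elapsed >= cfg.erythema_on_elapsed + cfg.purulence_delay):
        state.purulence = True
        _log(state, "purulence", True)

    return state


def device_step(state: DeviceState, dt: float, heater_command: bool,
                cfg: DeviceConfig) -> DeviceState:
    """Advance the device ``dt`` minutes under the given heater command.

    Heating follows the anchor profile on the heating clock; switching the
    heater back on resumes the profile from the current temperature by
    inverse interpolation.  Cooling is Newtonian.  Mutates and returns
    ``state``.
    """
    if dt <= 0:
        raise DomainError("dt must be > 0")
    if heater_command != state.heater_on:
        state.heater_on = heater_command
        _log(state, "heater", heater_command)
        if heater_command:
            state.t_elapsed = inverse_heating_profile(state.internal_temp, cfg)
    state.t_min += dt
    if state.heater_on:
        state.t_elapsed += dt
        state.internal_temp = heating_profile(state.t_elapsed, cfg)
    else:
        state.internal_temp = cool_step(state.internal_temp, dt, cfg)
    if not math.isfinite(state.internal_temp):
        raise IntegrationError(f"device fault: non-finite internal temperature at t={state.t_min} min")
    state.surface_temp = surface_from_internal(state.internal_temp, cfg)
    update_signs(state, cfg)
    return state
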