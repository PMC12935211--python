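"""Scenario runner and the emulated serial bridge.

A physical trainer sits on a serial link: the physiology engine publishes
the patient's core temperature, a microcontroller latches the fever
trigger and drives the heater, and sign transitions are reported back.
Here the link is an in-process message log with the same sample-and-hold
semantics: physiology advances on its own fixed step (hours), the device
ticks on a faster clock (minutes) holding the latest published core
temperature, and every exchange is recorded as a timestamped message.

Reversal semantics: a correctly applied antibiotic commands the heater off
at the moment the intervention starts; the device then cools and the
reversible signs (edema, erythema) clear while purulence stays latched.
Re-triggering after a reversal is disabled.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Literal, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from woundtwin.device import DeviceConfig, DeviceState, device_step
from woundtwin.errors import ConfigurationError, UsageError
from woundtwin.physiology import (
    Intervention,
    PatientState,
    PhysiologyParams,
    Trajectory,
    classify_outcome,
    severity_to_count,
    step,
)
from woundtwin.thermoregulation import ThermoConfig, fever_trigger

__all__ = [
    "BridgeMessage",
    "Scenario",
    "ScenarioResult",
    "run_scenario",
    "detect_trigger_time",
    "write_outputs",
]

CSV_HEADER = "t_hours,P,M,IL6,NO,TI,V,Tcore"


@dataclass(frozen=True)
class BridgeMessage:
    """One timestamped record on the emulated serial link."""

    t: float                      # simulated hours
    topic: str                    # e.g. phys/core_temp, device/heater_cmd
    payload: dict[str, Any]


class Scenario(BaseModel):
    """A complete run specification."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    severity: Literal["mild", "moderate", "severe"] | None = "moderate"
    P0: float | None = None             # explicit inoculum overrides severity
    horizon: float = 36.0               # hours
    dt_phys: float = 0.01               # hours
    dt_device: float = 0.5              # minutes
    sample_interval: float = 0.1        # trajectory sampling (hours)
    interventions: tuple[Intervention, ...] = ()
    seed: int = 0                       # reserved; the core model is deterministic
    output_prefix: str | None = None

    @model_validator(mode="after")
    def _check(self) -> "Scenario":
        if self.horizon <= 0:
            raise ValueError("horizon must be > 0")
        if self.dt_phys <= 0 or self.dt_device <= 0 or self.sample_interval <= 0:
            raise ValueError("dt_phys, dt_device and sample_interval must be > 0")
        if self.P0 is None and self.severity is None:
            raise ValueError("either severity or P0 must be given")
        if self.P0 is not None and self.P0 < 0:
            raise ValueError("P0 must be >= 0")
        return self

    def initial_count(self) -> float:
        if self.P0 is not None:
            return self.P0
        return severity_to_count(self.severity)


@dataclass
class ScenarioResult:
    """Everything a run produced."""

    trajectory: Trajectory
    device_events: list                 # list[SignEvent]
    messages: list[BridgeMessage]
    outcome: str
    trigger_time: float | None
    device_state: DeviceState
    scenario: Scenario


def detect_trigger_time(traj: Trajectory, thermo: ThermoConfig) -> float | None:
    """First time the core temperature reaches the set point.

    Linear interpolation between the bracketing samples; None if the
    threshold is never reached.
    """
    if len(traj) == 0:
        raise UsageError("empty trajectory")
    tc = traj.Tcore
    above = tc >= thermo.set_point
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(traj.t[0])
    t0, t1 = traj.t[i - 1], traj.t[i]
    v0, v1 = tc[i - 1], tc[i]
    if v1 == v0:
        return float(t1)
    return float(t0 + (thermo.set_point - v0) / (v1 - v0) * (t1 - t0))


def run_scenario(scenario: Scenario, phys_params: PhysiologyParams,
                 thermo_cfg: ThermoConfig, device_cfg: DeviceConfig) -> ScenarioResult:
    """Execute a scenario: coupled physiology + device + message log.

    The device ticks every ``dt_device`` minutes on a zero-order hold of
    the last published core temperature.  The heater command is the
    latched fever trigger, cancelled permanently by the first antibiotic
    intervention (reversal).  Deterministic.
    """
    P0 = scenario.initial_count()
    state = PatientState.healthy(phys_params, P0)
    dt = scenario.dt_phys
    n_steps = int(round(scenario.horizon / dt))
    stride = max(1, int(round(scenario.sample_interval / dt)))
    dt_dev_h = scenario.dt_device / 60.0

    messages: list[BridgeMessage] = []
    samples = [state]
    # the block rests against a body-temperature base until triggered
    start_temp = max(device_cfg.anchors[0][1], device_cfg.ambient)
    device = DeviceState(internal_temp=start_temp, surface_temp=start_temp)

    triggered = False
    reversed_ = False
    antibiotic_starts = sorted(iv.t_start for iv in scenario.interventions
                               if iv.kind == "antibiotic")
    next_dev_tick = 1
    events_offset = 0

    def heater_cmd() -> bool:
        return triggered and not reversed_

    for i in range(1, n_steps + 1):
        state = step(state, dt, phys_params, scenario.interventions)
        t_now = state.t
        if not reversed_ and any(ts <= t_now for ts in antibiotic_starts):
            reversed_ = True
            messages.append(BridgeMessage(t=t_now, topic="device/heater_cmd",
                                          payload={"on": False, "reason": "antibiotic_reversal",
                                                   "celsius": state.Tcore}))
        if not triggered and fever_trigger(state.Tcore, thermo_cfg) and not reversed_:
            triggered = True
            messages.append(BridgeMessage(t=t_now, topic="device/heater_cmd",
                                          payload={"on": True, "reason": "fever_trigger",
                                                   "celsius": state.Tcore}))
        # device ticks due up to current physiology time
        while triggered and next_dev_tick * dt_dev_h <= t_now + 1e-12:
            tick_t = next_dev_tick * dt_dev_h
            messages.append(BridgeMessage(t=tick_t, topic="phys/core_temp",
                                          payload={"celsius": state.Tcore}))
            device_step(device, scenario.dt_device, heater_cmd(), device_cfg)
            next_dev_tick += 1
        if not triggered:
            # device clock starts at the trigger; keep ticks aligned to it
            next_dev_tick = int(math.floor(t_now / dt_dev_h)) + 1
        for ev in device.event_log[events_offset:]:
            messages.append(BridgeMessage(t=t_now, topic="device/event",
                                          payload={"t_min": ev.t_min, "sign": ev.sign,
                                                   "state": ev.state}))
        events_offset = len(device.event_log)
        if i % stride == 0 or i == n_steps:
            samples.append(state)

    # device ticks processed within a physiology step can carry timestamps
    # slightly before the step's own messages; a stable sort restores the
    # serial-link time order without disturbing same-time records
    messages.sort(key=lambda m: m.t)
    traj = Trajectory.from_states(samples)
    outcome = classify_outcome(traj, phys_params)
    trigger_time = detect_trigger_time(traj, thermo_cfg)
    result = ScenarioResult(trajectory=traj, device_events=list(device.event_log),
                            messages=messages, outcome=outcome,
                            trigger_time=trigger_time, device_state=device,
                            scenario=scenario)
    if scenario.output_prefix:
        write_outputs(result, scenario.output_prefix)
    return result


def _fmt(x: float) -> str:
    return format(float(x), ".10g")


def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def write_outputs(result: ScenarioResult, prefix: str | os.PathLike) -> dict[str, Path]:
    """Write trajectory CSV, event/message JSONL and a run manifest.

    Files are ``<prefix>.csv``, ``<prefix>.events.jsonl``,
    ``<prefix>.messages.jsonl`` and ``<prefix>.manifest.json``; writes are
    atomic (write-then-rename) so re-running overwrites cleanly.
    """
    prefix = Path(prefix)
    if prefix.parent and not prefix.parent.exists():
        try:
            prefix.parent.mkdir(parents=True, exist_ok=True)
        except OSError as exc:
            raise OSError(f"cannot create output directory {prefix.parent}") from exc
    traj = result.trajectory
    lines = [CSV_HEADER]
    for k in range(len(traj)):
        lines.append(",".join(_fmt(v) for v in (
            traj.t[k], traj.P[k], traj.M[k], traj.IL6[k], traj.NO[k],
            traj.TI[k], traj.V[k], traj.Tcore[k])))
    paths = {
        "trajectory": prefix.with_suffix(".csv"),
        "events": prefix.with_suffix(".events.jsonl"),
        "messages": prefix.with_suffix(".messages.jsonl"),
        "manifest": prefix.with_suffix(".manifest.json"),
    }
    _atomic_write(paths["trajectory"], "\n".join(lines) + "\n")
    _atomic_write(paths["events"], "".join(
        json.dumps({"t_min": ev.t_min, "sign": ev.sign, "state": ev.state},
                   separators=(",", ":")) + "\n"
        for ev in result.device_events))
    _atomic_write(paths["messages"], "".join(
        json.dumps({"t": m.t, "topic": m.topic, "payload": m.payload},
                   separators=(",", ":"), sort_keys=True) + "\n"
        for m in result.messages))
    manifest = {
        "scenario": json.loads(result.scenario.model_dump_json()),
        "outcome": result.outcome,
        "trigger_time_hours": result.trigger_time,
        "n_samples": len(traj),
        "device": {
            "internal_temp": result.device_state.internal_temp,
            "surface_temp": result.device_state.surface_temp,
            "edema": result.device_state.edema,
            "erythema": result.device_state.erythema,
            "purulence": result.device_state.purulence,
        },
    }
    _atomic_write(paths["manifest"], json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return paths
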