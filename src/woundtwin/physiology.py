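"""Reduced within-host infection and inflammation model.

State variables
---------------
P    pathogen load in the wound (cells)
M    macrophage activity recruited against it (dimensionless)
IL6  interleukin-6, the damage-driving cytokine (arbitrary units)
NO   nitric oxide, which tempers the damage term (arbitrary units)
TI   tissue integrity of the capillary microvasculature, in [TImin, 1]
V    relative blood volume (fraction of baseline), eroded by capillary leak

The pathogen grows logistically and is cleared by macrophages and, when an
antibiotic is present, by a saturating (Hill) kill term anchored at the MIC.
Macrophage recruitment saturates in pathogen load; IL-6 is produced by both
pathogen burden and existing tissue damage; NO tracks IL-6.  Tissue
integrity obeys a logistic self-repair term opposed by a steep (sixth-order)
IL-6 Hill switch whose effect is damped by NO.  The interplay of the fast
pathogen episode, the slow cytokine pool and the integrity switch makes the
outcome bifurcate in initial pathogen load: small inocula are cleared with a
transient fever, large ones ignite a self-sustaining inflammatory collapse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from woundtwin.errors import ConfigurationError, DomainError, IntegrationError, UsageError

__all__ = [
    "SEVERITY_PRESETS",
    "PatientState",
    "PhysiologyParams",
    "Intervention",
    "Trajectory",
    "severity_to_count",
    "pathogen_rate",
    "antibiotic_kill_rate",
    "mediator_rates",
    "tissue_integrity_rate",
    "fluid_shift_rate",
    "step",
    "integrate",
    "classify_outcome",
]

#: Fixed mapping from severity label to initial pathogen count (cells).
SEVERITY_PRESETS: dict[str, float] = {
    "mild": 1.0e7,
    "moderate": 5.0e7,
    "severe": 2.5e8,
}

OutcomeLabel = Literal["cleared", "septic_death", "ongoing"]


class PhysiologyParams(BaseModel):
    """Rate constants of the infection/inflammation model.

    Units: times in hours, pathogen counts in cells, temperatures in
    degrees Celsius; mediator concentrations are in arbitrary units so
    their half-effect constants set the scale.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    r: float          # pathogen logistic growth rate (1/h)
    K: float          # pathogen carrying capacity (cells)
    kM: float         # macrophage kill-rate coefficient (1/h per unit M)
    PH: float         # pathogen load half-saturating macrophage killing (cells)
    sM: float         # macrophage recruitment rate (1/h)
    dM: float         # macrophage decay rate (1/h)
    sIL6: float       # IL-6 production rate (1/h)
    dIL6: float       # IL-6 decay rate (1/h)
    sNO: float        # NO production rate (1/h per unit IL-6)
    dNO: float        # NO decay rate (1/h)
    kD: float         # tissue-integrity rate constant (1/h)
    xD6: float        # IL-6 half-effect constant (sixth power scale)
    xDNO: float       # NO effect constant
    TImin: float      # minimum (collapsed) tissue integrity
    Emax: float       # maximal febrile temperature elevation (deg C)
    E50: float        # half-effect constant of the temperature map
    gamma: float      # Hill exponent of the temperature map
    Tbase: float = 37.0   # afebrile core temperature (deg C)
    kfluid: float = 0.02  # capillary-leak rate coefficient (1/h)
    Ekill: float = 2.0    # maximal antibiotic kill rate (1/h)
    MIC: float = 1.0      # minimum inhibitory concentration
    hA: float = 2.0       # antibiotic Hill exponent

    @model_validator(mode="after")
    def _check(self) -> "PhysiologyParams":
        nonneg = ("r", "kM", "sM", "dM", "sIL6", "dIL6", "sNO", "dNO",
                  "kD", "xD6", "xDNO", "kfluid", "Ekill")
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 < self.TImin < 1.0):
            raise ValueError("TImin must lie in (0, 1)")
        if self.K <= 0:
            raise ValueError("K must be > 0")
        if self.PH <= 0:
            raise ValueError("PH must be > 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.MIC <= 0:
            raise ValueError("MIC must be > 0")
        return self


@dataclass
class PatientState:
    """Continuous physiological state at simulated time ``t`` (hours)."""

    t: float
    P: float
    M: float
    IL6: float
    NO: float
    TI: float
    V: float
    Tcore: float

    @classmethod
    def healthy(cls, params: PhysiologyParams, P0: float = 0.0) -> "PatientState":
        """Rest state with an optional inoculum ``P0`` planted in the wound."""
        return cls(t=0.0, P=float(P0), M=0.0, IL6=0.0, NO=0.0, TI=1.0, V=1.0,
                   Tcore=params.Tbase)


class Intervention(BaseModel):
    """A treatment window: a constant antibiotic exposure or a fluid infusion."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    t_start: float          # hours
    kind: Literal["antibiotic", "fluids"]
    concentration: float    # antibiotic conc (MIC units) or fluid rate (V/h)
    duration: float         # hours

    @model_validator(mode="after")
    def _check(self) -> "Intervention":
        if self.t_start < 0:
            raise ValueError("t_start must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        return self

    def active_at(self, t: float) -> bool:
        return self.t_start <= t < self.t_start + self.duration


def severity_to_count(label: str) -> float:
    """Initial pathogen count for a named severity preset."""
    try:
        return SEVERITY_PRESETS[label]
    except KeyError:
        valid = ", ".join(sorted(SEVERITY_PRESETS))
        raise ConfigurationError(
            f"unknown severity label {label!r}; valid labels: {valid}"
        ) from None


def pathogen_rate(P: float, M: float, A_kill: float, params: PhysiologyParams) -> float:
    """dP/dt: logistic growth minus macrophage and antibiotic clearance.

    Macrophage killing saturates in pathogen load (Holling type II with
    half-saturation ``PH``): phagocytosis is rate-limited, so a heavy
    inoculum is cleared at a far lower per-cell rate than a light one.
    The antibiotic term is first-order in P.
    """
    if P < 0 or M < 0 or A_kill < 0:
        raise DomainError("pathogen_rate requires P, M, A_kill >= 0")
    return (params.r * P * (1.0 - P / params.K)
            - params.kM * M * P / (1.0 + P / params.PH)
            - A_kill * P)


def antibiotic_kill_rate(C: float, params: PhysiologyParams) -> float:
    """Per-hour kill rate of an antibiotic at concentration ``C``.

    Saturating Hill form anchored at the MIC: half-maximal kill at C = MIC,
    approaching ``Ekill`` as C grows.
    """
    if C < 0:
        raise DomainError("antibiotic concentration must be >= 0")
    if C == 0.0:
        return 0.0
    ch = C ** params.hA
    return params.Ekill * ch / (params.MIC ** params.hA + ch)


def mediator_rates(state: PatientState, params: PhysiologyParams) -> tuple[float, float, float]:
    """(dM/dt, dIL6/dt, dNO/dt) at the given state."""
    return _mediator_rates(state.P, state.M, state.IL6, state.NO, state.TI, params)


def _mediator_rates(P: float, M: float, IL6: float, NO: float, TI: float,
                    params: PhysiologyParams) -> tuple[float, float, float]:
    dM = params.sM * P / (P + params.K / 10.0) - params.dM * M if P > 0 else -params.dM * M
    dIL6 = params.sIL6 * (P / params.K + (1.0 - TI)) - params.dIL6 * IL6
    dNO = params.sNO * IL6 - params.dNO * NO
    return dM, dIL6, dNO


def tissue_integrity_rate(TI: float, IL6: float, NO: float, params: PhysiologyParams) -> float:
    """dTI/dt: logistic self-repair opposed by an IL-6 Hill switch damped by NO.

    Both terms carry the common factor (TI - TImin), so the collapsed state
    is absorbing; the damage term uses a sixth-order Hill function of IL-6
    and the factor 1/(xDNO^2 + NO^2) through which NO tempers damage.
    """
    if not (params.TImin - 1e-12 <= TI <= 1.0 + 1e-12):
        raise DomainError(f"TI={TI} outside [{params.TImin}, 1]")
    if IL6 < 0 or NO < 0:
        raise DomainError("IL6 and NO must be >= 0")
    il6_6 = IL6 ** 6
    repair = params.kD * (1.0 - TI) * (TI - params.TImin)
    damage = (params.kD * (TI - params.TImin)
              * (il6_6 / (il6_6 + params.xD6))
              * (1.0 / (params.xDNO ** 2 + NO ** 2)))
    return repair - damage


def fluid_shift_rate(TI: float, params: PhysiologyParams, fluids_rate: float = 0.0) -> float:
    """dV/dt: capillary leak proportional to tissue damage, plus any infusion."""
    return -params.kfluid * (1.0 - TI) + fluids_rate


def _rhs(t: float, y: Sequence[float], params: PhysiologyParams,
         interventions: Sequence[Intervention]) -> tuple[float, ...]:
    P, M, IL6, NO, TI, V = y
    # Clamp to the physical domain before evaluating rates: intermediate
    # Runge-Kutta stages may step slightly outside it.
    P = max(P, 0.0)
    M = max(M, 0.0)
    IL6 = max(IL6, 0.0)
    NO = max(NO, 0.0)
    TI = min(max(TI, params.TImin), 1.0)
    a_kill = 0.0
    fluids = 0.0
    for iv in interventions:
        if iv.active_at(t):
            if iv.kind == "antibiotic":
                a_kill += antibiotic_kill_rate(iv.concentration, params)
            else:
                fluids += iv.concentration
    dP = pathogen_rate(P, M, a_kill, params)
    dM, dIL6, dNO = _mediator_rates(P, M, IL6, NO, TI, params)
    dTI = tissue_integrity_rate(TI, IL6, NO, params)
    dV = fluid_shift_rate(TI, params, fluids)
    return dP, dM, dIL6, dNO, dTI, dV


_EMPTY: tuple[Intervention, ...] = ()


def step(state: PatientState, dt: float, params: PhysiologyParams,
         active_interventions: Sequence[Intervention] = _EMPTY) -> PatientState:
    """Advance the state one fixed RK4 step of ``dt`` hours.

    After the step the state invariants are re-established: TI is clamped
    to [TImin, 1], concentrations and the pathogen count to >= 0, and the
    blood volume to (0, 1].  Deterministic: identical inputs give identical
    outputs on one platform.
    """
    if dt <= 0:
        raise DomainError("dt must be > 0")
    y0 = (state.P, state.M, state.IL6, state.NO, state.TI, state.V)
    t = state.t
    k1 = _rhs(t, y0, params, active_interventions)
    k2 = _rhs(t + dt / 2, tuple(a + dt / 2 * b for a, b in zip(y0, k1)),
              params, active_interventions)
    k3 = _rhs(t + dt / 2, tuple(a + dt / 2 * b for a, b in zip(y0, k2)),
              params, active_interventions)
    k4 = _rhs(t + dt, tuple(a + dt * b for a, b in zip(y0, k3)),
              params, active_interventions)
    y1 = [a + dt / 6.0 * (b1 + 2 * b2 + 2 * b3 + b4)
          for a, b1, b2, b3, b4 in zip(y0, k1, k2, k3, k4)]
    for name, v in zip(("P", "M", "IL6", "NO", "TI", "V"), y1):
        if not math.isfinite(v):
            raise IntegrationError(
                f"non-finite value for state component {name} at t={t + dt:.6g} h"
            )
    P, M, IL6, NO, TI, V = y1
    P = max(P, 0.0)
    M = max(M, 0.0)
    IL6 = max(IL6, 0.0)
    NO = max(NO, 0.0)
    TI = min(max(TI, params.TImin), 1.0)
    V = min(max(V, 1e-9), 1.0)
    from woundtwin.thermoregulation import _effect_raw
    tcore = params.Tbase + _effect_raw(TI, params.Emax, params.E50, params.gamma)
    return PatientState(t=t + dt, P=P, M=M, IL6=IL6, NO=NO, TI=TI, V=V, Tcore=tcore)


@dataclass
class Trajectory:
    """Sampled physiology time series (parallel numpy arrays)."""

    t: np.ndarray
    P: np.ndarray
    M: np.ndarray
    IL6: np.ndarray
    NO: np.ndarray
    TI: np.ndarray
    V: np.ndarray
    Tcore: np.ndarray

    def __len__(self) -> int:
        return len(self.t)

    @classmethod
    def from_states(cls, states: Iterable[PatientState]) -> "Trajectory":
        rows = list(states)
        if not rows:
            raise UsageError("empty trajectory")
        return cls(
            t=np.array([s.t for s in rows]),
            P=np.array([s.P for s in rows]),
            M=np.array([s.M for s in rows]),
            IL6=np.array([s.IL6 for s in rows]),
            NO=np.array([s.NO for s in rows]),
            TI=np.array([s.TI for s in rows]),
            V=np.array([s.V for s in rows]),
            Tcore=np.array([s.Tcore for s in rows]),
        )


def integrate(state: PatientState, params: PhysiologyParams, horizon: float,
              dt: float = 0.01, interventions: Sequence[Intervention] = _EMPTY,
              sample_interval: float = 0.1) -> Trajectory:
    """Integrate from ``state`` for ``horizon`` hours, sampling every
    ``sample_interval`` hours (the initial state is the first sample)."""
    if horizon <= 0:
        raise UsageError("horizon must be > 0")
    if dt <= 0 or sample_interval <= 0:
        raise DomainError("dt and sample_interval must be > 0")
    n_steps = int(round(horizon / dt))
    stride = max(1, int(round(sample_interval / dt)))
    samples = [state]
    s = state
    for i in range(1, n_steps + 1):
        s = step(s, dt, params, interventions)
        if i % stride == 0 or i == n_steps:
            samples.append(s)
    return Trajectory.from_states(samples)


def classify_outcome(traj: Trajectory, params: PhysiologyParams,
                     death_band: float = 0.01, death_hold: float = 1.0) -> OutcomeLabel:
    """Terminal outcome of a completed trajectory.

    septic_death
        tissue integrity within ``death_band`` of TImin sustained for at
        least ``death_hold`` hours (irreversible microvascular collapse);
    cleared
        pathogen extinct (P < 1 cell) at the horizon with tissue integrity
        recovering (dTI/dt >= 0);
    ongoing
        anything else.
    """
    if len(traj) == 0:
        raise UsageError("empty trajectory")
    low = traj.TI <= params.TImin + death_band
    run_start: float | None = None
    for ti, is_low in zip(traj.t, low):
        if is_low:
            if run_start is None:
                run_start = ti
            elif ti - run_start >= death_hold:
                return "septic_death"
        else:
            run_start = None
    dti_end = tissue_integrity_rate(
        float(np.clip(traj.TI[-1], params.TImin, 1.0)),
        float(traj.IL6[-1]), float(traj.NO[-1]), params)
    if traj.P[-1] < 1.0 and dti_end >= 0.0:
        return "cleared"
    return "ongoing"
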