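"""Calibration of the default physiology parameters.

None of the inflammation rate constants are observable directly; the
defaults are instead pinned down by a behavioural contract over the three
severity presets run for 36 hours:

* mild and moderate inocula are cleared (pathogen extinct, tissue
  integrity recovering);
* the severe inoculum progresses to septic death (tissue integrity pinned
  at its floor for over an hour);
* the moderate scenario first crosses the 38 degC fever set point near
  t = 14 h;
* core temperature at collapsed tissue integrity sits near the 40 degC
  feverish ceiling (fixed through Emax/E50/gamma);
* an antibiotic at 10x MIC applied at the severe scenario's fever trigger
  averts septic death with a tissue-integrity safety margin.

The contract is scored by a penalty function and minimised by multi-start
Nelder-Mead over the logarithms of the free rate constants.  The search is
deterministic (fixed restart seed).  ``calibrate_defaults`` re-derives the
shipped parameter file; expect minutes of runtime.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize

from woundtwin.config import ParamSet
from woundtwin.device import DeviceConfig
from woundtwin.physiology import PhysiologyParams, SEVERITY_PRESETS
from woundtwin.thermoregulation import ThermoConfig

__all__ = ["calibrate_defaults", "contract_report"]

FREE = ["r", "kM", "sM", "dM", "PH", "sIL6", "dIL6", "sNO", "dNO", "kD", "xD6", "xDNO"]
FIXED = dict(K=5.0e7, TImin=0.3, Emax=3.5, E50=0.3416, gamma=2.0,
             Tbase=37.0, kfluid=0.02, Ekill=10.0, MIC=1.0, hA=2.0)
BOUNDS = dict(r=(0.03, 1.5), kM=(0.01, 2), sM=(0.05, 8), dM=(0.003, 1),
              PH=(1e5, 5e7), sIL6=(0.02, 2), dIL6=(0.02, 1), sNO=(1e-3, 2),
              dNO=(0.02, 2), kD=(0.2, 6), xD6=(0.05, 5000), xDNO=(0.5, 3))

_START = dict(r=0.1, kM=0.1, sM=2.1, dM=0.005, PH=2.5e6, sIL6=0.25,
              dIL6=0.042, sNO=0.02, dNO=0.2, kD=1.2, xD6=700.0, xDNO=1.0)

_ATOL = [1e-3, 1e-8, 1e-8, 1e-8, 1e-8, 1e-8]


def _rhs(t, y, p: dict, a_kill: float):
    P, M, IL6, NO, TI, V = y
    P = max(P, 0.0); M = max(M, 0.0); IL6 = max(IL6, 0.0); NO = max(NO, 0.0)
    TI = min(max(TI, p["TImin"]), 1.0)
    dP = (p["r"] * P * (1 - P / p["K"])
          - p["kM"] * M * P / (1.0 + P / p["PH"])
          - a_kill * P)
    dM = p["sM"] * P / (P + p["K"] / 10) - p["dM"] * M
    dIL6 = p["sIL6"] * (P / p["K"] + (1 - TI)) - p["dIL6"] * IL6
    dNO = p["sNO"] * IL6 - p["dNO"] * NO
    h6 = IL6 ** 6 / (IL6 ** 6 + p["xD6"])
    g = 1.0 / (p["xDNO"] ** 2 + NO ** 2)
    dTI = p["kD"] * (1 - TI) * (TI - p["TImin"]) - p["kD"] * (TI - p["TImin"]) * h6 * g
    dV = -p["kfluid"] * (1 - TI)
    return [dP, dM, dIL6, dNO, dTI, dV]


def _sim(P0: float, p: dict, T: float = 36.0, kill_from: float | None = None,
         a_kill: float = 0.0, n: int = 721):
    y0 = [P0, 0, 0, 0, 1.0, 1.0]
    ts = np.linspace(0, T, n)
    if kill_from is None or kill_from >= T:
        s = solve_ivp(_rhs, (0, T), y0, t_eval=ts, args=(p, 0.0),
                      rtol=1e-7, atol=_ATOL)
        return s.t, s.y
    ts1 = ts[ts <= kill_from]
    ts2 = ts[ts > kill_from]
    s1 = solve_ivp(_rhs, (0, kill_from), y0, t_eval=ts1, args=(p, 0.0),
                   rtol=1e-7, atol=_ATOL)
    s2 = solve_ivp(_rhs, (kill_from, T), s1.y[:, -1], t_eval=ts2,
                   args=(p, a_kill), rtol=1e-7, atol=_ATOL)
    return np.concatenate([s1.t, s2.t]), np.concatenate([s1.y, s2.y], axis=1)


def _trigger_ti(p: dict, set_point: float = 38.0) -> float:
    rise = set_point - p["Tbase"]
    return 1.0 - rise * p["E50"] ** p["gamma"] / (p["Emax"] - rise)


def _summary(t, y, p: dict) -> dict:
    P, M, IL6, NO, TI, V = y
    TI = np.clip(TI, p["TImin"], 1.0)
    ti_star = _trigger_ti(p)
    trig = None
    idx = np.where(TI <= ti_star)[0]
    if len(idx):
        i = int(idx[0])
        if i > 0 and TI[i - 1] != TI[i]:
            f = (TI[i - 1] - ti_star) / (TI[i - 1] - TI[i])
            trig = float(t[i - 1] + f * (t[i] - t[i - 1]))
        else:
            trig = float(t[i])
    low = TI <= p["TImin"] + 0.01
    death = None
    run_start = None
    for ti_t, is_low in zip(t, low):
        if is_low:
            if run_start is None:
                run_start = ti_t
            elif ti_t - run_start >= 1.0:
                death = float(ti_t)
                break
        else:
            run_start = None
    dti_end = _rhs(t[-1], y[:, -1], p, 0.0)[4]
    return dict(trig=trig, death=death, Pend=float(P[-1]),
                minTI=float(TI.min()), dTI_end=float(dti_end))


def _loss(x: np.ndarray) -> float:
    p = dict(FIXED)
    for k, v in zip(FREE, x):
        p[k] = float(math.exp(v))
    L = 0.0
    for k in FREE:
        lo, hi = BOUNDS[k]
        if p[k] < lo:
            L += 100.0 * math.log(lo / p[k]) ** 2
        if p[k] > hi:
            L += 100.0 * math.log(p[k] / hi) ** 2
    try:
        summ = {}
        for label, P0 in SEVERITY_PRESETS.items():
            t, y = _sim(P0, p)
            summ[label] = _summary(t, y, p)
    except Exception:
        return 1e6
    for label in ("mild", "moderate"):
        v = summ[label]
        L += 12.0 * max(0.0, math.log10(max(v["Pend"], 1e-12)))
        L += 2000.0 * max(0.0, -v["dTI_end"])
        if v["death"] is not None:
            L += 80.0
    L += 60.0 * max(0.0, (p["TImin"] + 0.08) - summ["moderate"]["minTI"])
    sev = summ["severe"]
    if sev["death"] is None:
        L += 150.0 + 300.0 * max(0.0, sev["minTI"] - (p["TImin"] + 0.008))
    else:
        L += 3.0 * max(0.0, sev["death"] - 30.0)
    trig = summ["moderate"]["trig"]
    if trig is None:
        L += 200.0
    else:
        L += 8.0 * abs(trig - 14.0)
    # antibiotic rescue of the severe preset at its fever trigger
    if sev["trig"] is not None:
        a_kill = FIXED["Ekill"] * 100.0 / (1.0 + 100.0)   # C = 10x MIC, Hill 2
        try:
            t, y = _sim(SEVERITY_PRESETS["severe"], p,
                        kill_from=sev["trig"], a_kill=a_kill)
            resc = _summary(t, y, p)
        except Exception:
            return 1e6
        if resc["death"] is not None:
            L += 200.0
        L += 200.0 * max(0.0, (p["TImin"] + 0.3) - resc["minTI"])
        L += 1000.0 * max(0.0, -resc["dTI_end"])
    return L


def calibrate_defaults(maxfev: int = 2000, restarts: int = 4,
                       verbose: bool = False) -> ParamSet:
    """Re-derive the default parameter set from the calibration contract."""
    x0 = np.log([_START[k] for k in FREE])
    rng = np.random.default_rng(13)
    best, bx = None, None
    for i in range(restarts):
        x = x0 if i == 0 else x0 + rng.normal(0, 0.15, len(FREE))
        res = minimize(_loss, x, method="Nelder-Mead",
                       options=dict(maxfev=maxfev, xatol=1e-4, fatol=1e-4))
        if verbose:
            print(f"restart {i}: penalty {res.fun:.3f}")
        if best is None or res.fun < best:
            best, bx = res.fun, res.x
    res = minimize(_loss, bx, method="Nelder-Mead",
                   options=dict(maxfev=3 * maxfev, xatol=1e-6, fatol=1e-6))
    if res.fun < best:
        best, bx = res.fun, res.x
    if verbose:
        print(f"final penalty {best:.3f}")
    values = dict(FIXED)
    for k, v in zip(FREE, bx):
        values[k] = float(math.exp(v))
    phys = PhysiologyParams(**values)
    thermo = ThermoConfig(Emax=phys.Emax, E50=phys.E50, gamma=phys.gamma,
                          Tbase=phys.Tbase, set_point=38.0)
    return ParamSet(phys, thermo, DeviceConfig())


def contract_report(phys: PhysiologyParams) -> dict[str, dict]:
    """Evaluate the calibration contract for a parameter set (diagnostics)."""
    p = {k: getattr(phys, k) for k in list(FIXED) + FREE}
    out = {}
    for label, P0 in SEVERITY_PRESETS.items():
        t, y = _sim(P0, p)
        out[label] = _summary(t, y, p)
    sev = out["severe"]
    if sev["trig"] is not None:
        a_kill = phys.Ekill * 100.0 / (1.0 + 100.0)
        t, y = _sim(SEVERITY_PRESETS["severe"], p, kill_from=sev["trig"],
                    a_kill=a_kill)
        out["severe_rescued"] = _summary(t, y, p)
    return out
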