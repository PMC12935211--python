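# Methods

## Scope and intent

`woundtwin` is a self-contained software twin of a heat-actuated
infected-wound trainer driven by a patient physiology engine. It is not a
whole-body physiology simulator: there are no cardiovascular, renal or
respiratory compartments, no pharmacokinetics, and no pathogen-species
specificity. The model is reduced to the smallest state vector that can
reproduce the trainer-relevant behaviour — a severity-dependent
bifurcation between immune clearance and septic collapse, a fever signal
that triggers the device, and treatment reversal.

## The within-host model

State: pathogen load P (cells), macrophage activity M (dimensionless),
interleukin-6 IL6 and nitric oxide NO (arbitrary concentration units),
tissue integrity TI ∈ [TImin, 1] (dimensionless), relative blood volume
V ∈ (0, 1]. Time is in hours.

    dP/dt   = r·P(1 − P/K) − kM·M·P/(1 + P/PH) − A(C)·P
    dM/dt   = sM·P/(P + K/10) − dM·M
    dIL6/dt = sIL6·(P/K + (1 − TI)) − dIL6·IL6
    dNO/dt  = sNO·IL6 − dNO·NO
    dTI/dt  = kD(1 − TI)(TI − TImin)
            − kD(TI − TImin)·[IL6⁶/(IL6⁶ + xD6)]·[1/(xDNO² + NO²)]
    dV/dt   = −kfluid·(1 − TI) + fluid infusion rate

A(C) = Ekill·C^hA/(MIC^hA + C^hA) is the antibiotic kill rate at
concentration C, half-maximal at the MIC; antibiotic exposure is a
constant concentration over the intervention window (no pharmacokinetic
model — the MIC enters only as the anchor of the kill curve).

Model structure worth flagging:

* **Saturating macrophage kill.** Macrophage killing is Holling type II
  in pathogen load: per-cell clearance is kM·M/(1 + P/PH), with
  half-saturation PH ≈ K/20. Phagocytosis is rate-limited, so a heavy
  inoculum is cleared at a far lower per-cell rate than a light one.
  This term does double duty: it is the severity discriminator (large
  inocula outlast and overwhelm the response; small ones are mopped up
  quickly) and it reconciles a long inflammatory exposure with complete
  pathogen extinction inside 36 h — once P falls below PH the accumulated
  macrophage pool kills at full per-cell rate and drives P under one
  cell. A mass-action kill term (kM·M·P) cannot do both: clearing the
  moderate inoculum by 36 h then forces the high-pathogen era to end by
  ~7 h, which makes a 14-hour fever onset unreachable. We treat the
  saturating form as the model's own design choice and document the
  trade-off here.
* **Steep IL-6 switch.** The damage term is sixth-order in IL-6, so the
  cytokine acts as a near-threshold switch at IL6 ≈ xD6^(1/6). Combined
  with the damage → IL-6 feedback (the (1 − TI) production term), the
  TI–IL6 subsystem is bistable: below an ignition depth the dip in
  integrity heals when the pathogen is cleared; beyond it inflammation
  self-sustains and TI falls to its absorbing floor. Septic death is
  exactly this ignition. The shipped parameters place the ignition deep
  enough that a treated (antibiotic-reversed) severe patient stays well
  outside the basin — its minimum TI is ≈ 0.90 versus the 0.45-depth
  ignition boundary.
* **NO tempers damage.** The 1/(xDNO² + NO²) factor means nitric oxide
  reduces the damage term as written; with the shipped defaults NO is a
  weak modulator (sNO small), not a primary driver.
* **Absorbing collapse.** Both TI terms carry the factor (TI − TImin),
  so the collapsed state is a fixed point. "Septic death" is declared
  when TI stays within 0.01 of TImin for at least one continuous hour —
  microvascular collapse with no remaining repair capacity.
* **Blood volume is an output.** V integrates the capillary leak and any
  fluid infusion; nothing couples back from V. It is exposed for display
  and future use.

The healthy rest state (P=0, M=0, IL6=0, NO=0, TI=1, V=1) is an exact
equilibrium of the full system, and the integrator preserves it.

## Thermoregulation and the trigger

Core temperature is a pure Emax function of integrity loss x = 1 − TI:
E(x) = Emax·x/(E50^γ + x), Tcore = Tbase + E. The elevation is zero for
intact tissue, so the baseline (37.0 °C) is exact at rest, and E < Emax
always. The γ exponent applies to E50 only; the numerator's x is not
exponentiated. The fever trigger is the stateless predicate
Tcore ≥ set point (38.0 °C, boundary inclusive); latching is the
scenario runner's responsibility, and with the shipped parameters
Tcore(TImin) ≈ 40.0 °C — the feverish ceiling the device's skin surface
mirrors.

## Device twin

The device is a discrete-time state machine on a minutes clock.

* **Heating** follows a piecewise-linear profile through anchor points
  (0 min, 37 °C), (10 min, 45 °C), (40 min, 70 °C), clamped at the relay
  limit (70 °C). The profile runs on a heating clock: switching the
  heater off stops the clock, and switching it back on resumes from the
  current temperature by inverse interpolation — the wax does not reset.
* **Cooling** is Newtonian toward ambient (22 °C) with τ = 15 min,
  advanced by its exact closed form, so step size does not affect the
  trajectory (semigroup property holds to round-off).
* **Surface temperature** is linear in the internal excess over ambient,
  scaled to reach its 40 °C plateau exactly at the relay limit, and
  clamped there.
* **Signs.** Edema is thermal: on at 45 °C internal, off only with the
  heater off and the block cooled to 43 °C (2 °C hysteresis prevents
  chatter). Erythema is temporal: on after 25 min of heating. These two
  rules resolve an internal tension in the trainer's reported timeline
  (both printed onset marks are honoured by giving each sign its own
  trigger modality). Purulence follows erythema by 5 min of further
  heating and latches forever — the one irreversible sign. Every
  transition is appended to an event log.

## The bridge and scenario runner

Physiology advances on a fixed Runge–Kutta 4 step (default 0.01 h);
the device ticks on its own clock (default 0.5 min in coupled runs)
holding the most recently published core temperature — the same
sample-and-hold behaviour a serial link imposes. The heater command is
the latched fever trigger; the first antibiotic intervention commands
the heater off permanently (re-triggering after reversal is disabled by
default and left as a config extension point). The trigger is a binary
threshold — no proportional control on fever magnitude. All exchanges
are recorded as timestamped messages; messages are stably sorted by time
before writing. Outputs are a trajectory CSV (0.1 h sampling), two JSON
Lines logs (device events, bridge messages) and a JSON manifest; writes
are atomic and byte-reproducible run to run.

Outcome classification over the sampled trajectory: `septic_death` if TI
sits within 0.01 of TImin for ≥ 1 h; else `cleared` if P < 1 cell at the
horizon with dTI/dt ≥ 0; else `ongoing`.

## Integration and numerics

Fixed-step classical RK4, chosen for determinism and adequacy on this
smooth, non-stiff system; dt = 0.01 h by default. After each step the
state is projected back onto its domain: TI clamped to [TImin, 1],
counts and concentrations to ≥ 0, V to (0, 1]. Right-hand-side
evaluations clamp intermediate Runge–Kutta stages the same way. Halving
dt changes the moderate-scenario TI trajectory by less than 10⁻⁴ in
sup-norm; a non-finite state component aborts with an error naming the
component. Device anchor times are hit exactly by `np.interp`;
acceptance and tests step the device with binary-exact increments
(0.0625 min) so threshold crossings land on the printed minute marks
without floating-point accumulation artifacts.

## Calibration of the defaults

None of the physiological rate constants are directly observable, and
none are printed anywhere; the defaults are fixed by a behavioural
contract: (a) mild and moderate presets clear within 36 h and severe
dies; (b) the moderate scenario first crosses 38 °C near t = 14 h;
(c) core temperature at collapsed integrity sits near 40 °C; (d) an
antibiotic at 10× MIC applied at the severe scenario's fever trigger
averts death with a tissue-integrity safety margin. The thermal
parameters satisfying (c) are fixed analytically (Emax = 3.5 °C,
γ = 2, E50 = 0.3416, TImin = 0.3); the remaining twelve rate constants
are found by multi-start Nelder–Mead on their logarithms against a
penalty encoding (a), (b) and (d), with plausibility bounds on every
rate. The search is deterministic (fixed restart seed) and ships as
`woundtwin.calibrate`; `woundtwin calibrate` re-derives the parameter
file in a few minutes. The shipped `data/defaults.yaml` is its output
and reaches zero penalty: moderate trigger at 14.0 h, severe death at
23.2 h, treated-severe minimum TI ≈ 0.90.

Ekill = 10 h⁻¹ (a strongly bactericidal ceiling) and MIC = 1 in
concentration units are design values: treatment at 10× MIC must clear
the wound within ~2 h for the reversal contract to hold, because the
cytokine exposure already committed at the fever trigger is what decides
whether inflammation ignites.

## What the simulations do and do not show

All inputs are presets or user configs; there are no external datasets
and no randomness in the core model. The simulated trajectories
reproduce the *qualitative* physiology the trainer needs — severity
bifurcation, fever timing, sign onsets, reversal — under a calibrated
reduced model; they are not patient-predictive. Absolute concentrations
of IL-6 and NO are in arbitrary units; only their half-effect constants
give them scale. Parameter sets other than the shipped calibration can
move the bifurcation boundary; the calibration contract, not any single
rate constant, is the meaningful object. Hardware aspects of a physical
trainer (thermal inertia of silicone, wax phase change, electrical
limits) are reduced to the anchor profile, the relay cap and the
Newtonian cooling constant.

## Known limitations

* The pathogen is a single homogeneous population; no resistance, no
  species differences, no spatial structure.
* Antibiotic exposure is a constant concentration window; no dosing
  pharmacokinetics.
* Re-triggering of the device after an ineffective treatment is
  disabled; rebound scenarios need the config extension point.
* The severity bifurcation is a property of the calibrated defaults;
  user parameter files are validated for type and sign, not for
  preserving the bifurcation.
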