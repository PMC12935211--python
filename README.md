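# woundtwin

A software twin of a physiology-driven infected-wound trainer for medical
simulation. The package couples a reduced within-host infection and
inflammation model to a virtual moulage device — a silicone wound block
with an embedded heater — that renders the cardinal signs of a worsening
wound infection: skin warmth, focal edema, erythema and purulence.

It is intended for medical-simulation engineers and modelers who want to
develop and test trainer control logic (trigger thresholds, sign timing,
treatment reversal) without physical hardware, and as a compact, fully
reproducible example of a hybrid continuous/discrete patient simulator.

## The model

**Physiology.** Six ordinary differential equations track pathogen load
*P* (logistic growth, carrying capacity *K*, cleared by macrophage
activity *M* through a saturating Holling type-II kill and by antibiotics
through a Hill kill anchored at the MIC), macrophage activity *M*,
interleukin-6 *IL6*, nitric oxide *NO*, relative blood volume *V*, and
the tissue integrity *TI* of the capillary microvasculature:

    dTI/dt = kD (1 − TI)(TI − TImin)
           − kD (TI − TImin) · [IL6⁶/(IL6⁶ + xD6)] · [1/(xDNO² + NO²)]

Tissue integrity repairs itself logistically and is destroyed by a steep
sixth-order IL-6 switch, tempered by NO. The collapsed state TI = TImin
is absorbing: sustained collapse is septic death.

**Thermoregulation.** Core temperature follows an Emax function of
integrity loss, as a febrile elevation above baseline:

    Tcore = Tbase + Emax·(1 − TI) / (E50^γ + (1 − TI))

When Tcore reaches the 38 °C set point, the trainer is triggered.

**Device.** From the trigger, the heater follows a piecewise-linear
internal-temperature profile (37 °C → 45 °C at 10 min → 70 °C at 40 min,
capped by a relay), the skin surface saturates at a feverish 40 °C, and
the signs actuate: edema at 45 °C internal (with 2 °C hysteresis),
erythema after 25 min of heating, purulence 5 min later. Cooling
reverses everything except purulence, which latches — released wax does
not retract.

**Bridge.** An in-process emulation of the serial link between the
physiology engine and the device microcontroller: core temperature is
published on a sample-and-hold device clock, the heater command is the
latched fever trigger, and a correctly applied antibiotic commands the
heater off so the reversible signs clear.

Three severity presets set the initial bacterial count: mild 10 million,
moderate 50 million, severe 250 million. With the shipped calibrated
parameters, mild and moderate infections are cleared by the immune
response while severe progresses to septic death, and the moderate fever
crosses the set point near 14 h.

## Worked example

Run the moderate and severe presets over 36 hours:

```
$ cat scen_moderate.yaml
severity: moderate
horizon: 36.0
$ woundtwin simulate --scenario scen_moderate.yaml --out runs/mod
outcome: cleared
fever trigger: 14.00 h
device signs: edema=True erythema=True purulence=True
outputs: runs/mod.csv / .events.jsonl / .messages.jsonl / .manifest.json
```

The moderate infection fevers at 14 h (triggering the trainer — all
three signs develop while the fever lasts) but is ultimately cleared by
macrophage activity. The severe preset instead collapses:

```
$ woundtwin simulate --scenario scen_severe.yaml --out runs/sev
outcome: septic_death
fever trigger: 2.93 h
device signs: edema=True erythema=True purulence=True
```

and its device event log shows the heat-actuated timeline from trigger:

```
{"t_min":0.0,"sign":"heater","state":true}
{"t_min":10.0,"sign":"edema","state":true}
{"t_min":25.0,"sign":"erythema","state":true}
{"t_min":30.0,"sign":"purulence","state":true}
```

Adding an antibiotic at 10× MIC just after the severe trigger reverses
the course — the heater is commanded off, edema and erythema clear,
and the patient recovers:

```
$ cat scen_rescue.yaml
severity: severe
horizon: 36.0
interventions:
  - {t_start: 3.1, kind: antibiotic, concentration: 10.0, duration: 24.0}
$ woundtwin simulate --scenario scen_rescue.yaml --out runs/rescue
outcome: cleared
fever trigger: 2.93 h
device signs: edema=False erythema=False purulence=False
```

`woundtwin presets` lists the severity presets, `woundtwin validate`
lints config files, and `woundtwin calibrate` re-derives the default
parameter file from the calibration contract (see `docs/methods.md`).

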