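E50: 0.3416
Ekill: 10.0
Emax: 3.5
K: 50000000.0
MIC: 1.0
PH: 2502770.9204550004
TImin: 0.3
Tbase: 37.0
dIL6: 0.04444990786326396
dM: 0.0047505324027317716
dNO: 0.20167993512401103
device:
  ambient: 22.0
  anchors:
  - - 0.0
    - 37.0
  - - 10.0
    - 45.0
  - - 40.0
    - 70.0
  cooling_tau: 15.0
  edema_off_temp: 43.0
  edema_on_temp: 45.0
  erythema_on_elapsed: 25.0
  purulence_delay: 5.0
  relay_limit: 70.0
  surface_plateau: 40.0
gamma: 2.0
hA: 2.0
kD: 1.1995858221993987
kM: 0.10020439123143836
kfluid: 0.02
r: 0.09859146727562565
sIL6: 0.24111645434735465
sM: 2.119915213259092
sNO: 0.01914779895916145
thermo:
  E50: 0.3416
  Emax: 3.5
  Tbase: 37.0
  gamma: 2.0
  set_point: 38.0
xD6: 803.0997355306705
xDNO: 0.9999910333063331
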