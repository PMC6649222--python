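# Healthy reference: normal lungs under standard intraoperative ventilation,
# no extracorporeal support.  The native lung supplies the whole VO2.
name: healthy_no_ecmo
patient:
  cardiac_output: 5.0        # L/min
  hb: 14.0                   # g/dL
  vo2: 250.0                 # mL/min
  vco2: 200.0                # mL/min
  shunt_fraction: 0.03
  hco3: 24.0                 # mEq/L
  ideal_body_weight: 70.0    # kg
vent:
  mode: VCV
  peep: 5.0                  # cmH2O
  driving_pressure: 10.0     # cmH2O -> Vt 500 mL at Cst 50
  cst: 50.0                  # mL/cmH2O
  rr: 12.0                   # breaths/min
  t_insp: 1.5                # s
  raw: 8.0                   # cmH2O/L/s
  fio2: 0.4
  dead_space: 154.0          # mL, anatomic (2.2 mL/kg IBW)
ecmo:
  blood_flow: 0.0
  sweep_flow: 0.0
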