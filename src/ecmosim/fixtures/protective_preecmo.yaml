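# Severe ARDS on protective ventilation, before ECMO: 36-year-old patient,
# refractory hypoxemia (influenza pneumonia).  Vt 6 mL/kg IBW = 360 mL,
# Pplat 38 -> driving pressure 20 at Cst 18.  Shunt 0.75 and a large
# physiological dead space (~0.7 Vt, typical of severe ARDS) depict the
# refractory hypoxemia with hypercapnic acidosis.
name: protective_preecmo
patient:
  cardiac_output: 10.0       # L/min, hyperdynamic
  hb: 10.0                   # g/dL, slightly anemic
  vo2: 200.0                 # mL/min
  vco2: 160.0                # mL/min
  shunt_fraction: 0.75
  hco3: 24.0                 # mEq/L
  ideal_body_weight: 60.0    # kg
vent:
  mode: VCV
  peep: 18.0                 # cmH2O
  tidal_volume_ml: 360.0     # -> driving_pressure 20 cmH2O
  cst: 18.0                  # mL/cmH2O
  rr: 35.0                   # breaths/min
  t_insp: 0.6                # s (I:E ~ 1:1.9 at RR 35)
  raw: 10.0                  # cmH2O/L/s
  fio2: 1.0
  dead_space: 250.0          # mL, physiological (ARDS)
ecmo:
  blood_flow: 0.0
  sweep_flow: 0.0
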