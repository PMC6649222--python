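# The same severe-ARDS patient after VV-ECMO initiation: ultraprotective
# pressure-controlled ventilation (PEEP 14, DP 10, Cst 14 -> Vt 140 mL,
# RR 10, FiO2 0.3) with ECMO blood flow 4.9 L/min and sweep gas 3 L/min
# (FiO2 1.0).  Native lung near-total shunt (0.95, "white-out").
# membrane_co2_efficiency is the device calibration parameter; 0.85
# reproduces the reference arterial blood gas (PaCO2 35 mmHg) for this
# circuit and sweep flow.
name: ultraprotective_on_ecmo
patient:
  cardiac_output: 10.0       # L/min
  hb: 10.0                   # g/dL
  vo2: 200.0                 # mL/min
  vco2: 160.0                # mL/min
  shunt_fraction: 0.95
  hco3: 24.0                 # mEq/L
  ideal_body_weight: 60.0    # kg
vent:
  mode: PCV
  peep: 14.0                 # cmH2O
  driving_pressure: 10.0     # cmH2O -> Vt 140 mL at Cst 14
  cst: 14.0                  # mL/cmH2O
  rr: 10.0                   # breaths/min
  t_insp: 1.0                # s
  raw: 10.0                  # cmH2O/L/s
  fio2: 0.3
  dead_space: 132.0          # mL, anatomic (2.2 mL/kg IBW)
ecmo:
  blood_flow: 4.9            # L/min
  sweep_flow: 3.0            # L/min
  sweep_fio2: 1.0
  membrane_o2_efficiency: 1.0
  membrane_co2_efficiency: 0.85
  recirculation_fraction: 0.0
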