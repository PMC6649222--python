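"""Solve the prototypical severe-ARDS patient on VV-ECMO end to end.

Loads the packaged on-ECMO scenario (ECMO 4.9 L/min, sweep 3 L/min,
ultraprotective ventilation, pulmonary shunt 95%) and prints the converged
steady state: how the ventilator energy load, gas tensions and the
ECMO-vs-lung transfer split come out.
"""

from ecmosim import load_fixture, run_scenario

report = run_scenario(load_fixture("ultraprotective_on_ecmo"))
r = report.result

print(f"scenario: {report.scenario.name}")
print(f"mechanical power     {report.mechanical_power:6.1f} J/min   "
      "(energy the ventilator still delivers to the injured lungs)")
print(f"arterial blood gas   PO2 {r.arterial.po2:5.1f}  PCO2 {r.arterial.pco2:5.1f}  "
      f"sat {100 * r.arterial.sat:5.1f}%  pH {r.arterial.ph:5.2f}")
print(f"mixed venous         PO2 {r.mixed_venous.po2:5.1f}  PCO2 {r.mixed_venous.pco2:5.1f}  "
      f"sat {100 * r.mixed_venous.sat:5.1f}%")
print(f"O2 uptake            ECMO {r.ecmo_o2_transfer:5.1f} + lung {r.lung_o2_transfer:4.1f} "
      f"= {r.ecmo_o2_transfer + r.lung_o2_transfer:5.1f} mL/min  (equals VO2: Fick balance)")
print(f"CO2 removal          ECMO {r.ecmo_vco2:5.1f} + lung {r.lung_vco2:4.1f} "
      f"= {r.ecmo_vco2 + r.lung_vco2:5.1f} mL/min  (equals VCO2)")
print(f"HPV stimulus PO2     {report.p_stimulus_o2:6.1f} mmHg  "
      "(effective O2 tension relaxing pulmonary vasoconstriction)")
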