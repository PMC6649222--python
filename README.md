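# ecmosim

A deterministic steady-state simulator of cardiopulmonary gas exchange during
venous-venous extracorporeal membrane oxygenation (VV-ECMO), written for
intensivists, perfusionists and physiology educators who want to reason
quantitatively about severe ARDS support: how much energy the ventilator
still delivers to injured lungs, how arterial oxygenation responds to circuit
blood flow, how sweep gas flow sets the PaCO2, and what happens to the oxygen
stimulus of hypoxic pulmonary vasoconstriction.

## The model

Four coupled pieces, solved to a common steady state:

**Ventilator energy load.** Mechanical power, the energy per minute
transferred to the respiratory system, is computed from the elastic/PEEP
work per breath:

    MP [J/min] = 0.098 · RR · Vt · (PEEP + ΔP/2),        Vt = ΔP · Cst

with Vt in litres, pressures in cmH2O and 0.098 J per L·cmH2O.  An optional
constant-flow resistive term `0.098 · RR · Vt · Raw · (Vt/Tinsp)` can be
added.

**Blood gas chemistry.**  Oxyhemoglobin saturation follows the Severinghaus
curve `S = 1/(1 + 23400/(P³ + 150P))` on a Bohr-shifted virtual PO2
(pH and PCO2 corrections, 37 °C); O2 content is `1.34·Hb·S + 0.0031·PO2`
(mL/dL); CO2 content uses the Douglas whole-blood formula (plasma
Henderson–Hasselbalch content times a hemoglobin/saturation Haldane
correction); pH closes through a fixed bicarbonate pool.

**Membrane oxygenator.**  Single-pass lumped device model: blood PO2
equilibrates a fraction (the membrane O2 efficiency) of the way to the
sweep-gas oxygen tension; CO2 removal is the smaller of the gas-side limit
`sweep_flow · 1000 · η · PvCO2/(Pb − PH2O)` and what the blood side carries.
The efficiencies are the device's calibration parameters.

**Circulation.**  A single venous pool splits into the ECMO drain and the
flow bypassing the circuit; the oxygenator return mixes with bypassing
venous blood into the pulmonary artery; the native lung is a shunt
compartment plus a ventilated compartment equilibrated to alveolar gas
(alveolar PO2 from the alveolar gas equation, alveolar PCO2 from the
ventilation/perfusion CO2 balance); tissues exchange O2 and CO2 by the Fick
principle.  The solver iterates on the mixed-venous gas contents
(damped substitution with Newton-type acceleration) until the update falls
below 1e-4 mL/dL; at convergence ECMO + lung O2 transfer equals VO2 and
likewise for CO2, exactly.

The hypoxic pulmonary vasoconstriction (HPV) stimulus is reported as the
classical weighted geometric mean `PsO2 = PAO2^0.62 · PvO2^0.38`.

Everything is deterministic — identical inputs give bit-identical outputs.

## Worked example

```
$ python examples/prototypical_case.py
scenario: ultraprotective_on_ecmo
mechanical power        2.6 J/min   (energy the ventilator still delivers to the injured lungs)
arterial blood gas   PO2 112.5  PCO2  35.3  sat  98.6%  pH  7.45
mixed venous         PO2  52.7  PCO2  43.7  sat  85.1%
O2 uptake            ECMO 198.3 + lung  1.7 = 200.0 mL/min  (equals VO2: Fick balance)
CO2 removal          ECMO 156.4 + lung  3.6 = 160.0 mL/min  (equals VCO2)
HPV stimulus PO2      146.3 mmHg  (effective O2 tension relaxing pulmonary vasoconstriction)
```

This is the packaged severe-ARDS case on ECMO: circuit blood flow 4.9 L/min
and sweep gas 3 L/min at a 95% pulmonary shunt.  Ultraprotective ventilation
(PEEP 14, ΔP 10, RR 10) delivers only 2.6 J/min to the lungs — versus
34.6 J/min for the protective pre-ECMO settings (PEEP 18, Vt 360 mL, RR 35) —
while the membrane lung takes essentially the whole gas-exchange burden:
198 of 200 mL/min of oxygen uptake and 156 of 160 mL/min of CO2 removal,
holding PaCO2 at 35 mmHg.

Other examples: `mechanical_power.py` (energy-load comparison),
`oxygenation_vs_ecmo_flow.py` (SatO2 vs circuit flow, with the infeasible
low-flow points flagged), `co2_removal_vs_sweep.py` (PaCO2 vs sweep gas
flow), `hpv_stimulus_curves.py` (stimulus curves at pre-/on-ECMO venous PO2).

## Command line

```
ecmosim run ultraprotective_on_ecmo --out result.csv
ecmosim sweep ultraprotective_on_ecmo --param ecmo.blood_flow \
        --values 1,2,3,4,4.9,5.5 --out sweep.csv
ecmosim fixtures list
```

`run` and `sweep` accept either a packaged fixture name or a path to a
YAML/JSON scenario file (see `src/ecmosim/fixtures/` for the schema).
Exit codes: 0 success, 2 validation error, 3 infeasible/non-converged.

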