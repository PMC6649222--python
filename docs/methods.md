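# Methods

This note documents the physiological model behind `ecmosim`, the numerical
choices, the calibration of the packaged scenarios, and the limits of what
the simulator can claim about real patients.

## Scope and state

The simulator computes the *steady state* of whole-body gas exchange for a
patient on venous-venous ECMO.  The state of any blood stream is
(PO2, PCO2, pH, SatO2, Hb) together with the derived O2 and CO2 contents
(mL of gas per dL of blood).  Flows are in L/min; the 10 dL/L factor is
applied only where flows multiply contents.  There are no time-resolved
dynamics, no pulsatility, and no feedback of blood gases on cardiac output
or shunt: cardiac output, VO2, VCO2 and shunt fraction are inputs.

## Blood gas chemistry

**Dissociation curve.**  Saturation uses the Severinghaus form
`S(P) = 1/(1 + 23400/(P³ + 150P))`, which puts the P50 at 26.86 mmHg, on a
virtual PO2 shifted for the Bohr effect:
`P_virt = PO2 · 10^(0.40(pH − 7.40) + 0.06(log10 40 − log10 PCO2))`,
temperature fixed at 37 °C.  This combination was chosen because it is the
standard simple *invertible* formulation; the inverse (PO2 from saturation)
is a bracketed root find with round-trip error below 0.01 mmHg.

**Contents.**  O2 content is Hüfner binding (1.34 mL/g) plus dissolved O2
(0.0031 mL/dL/mmHg).  CO2 content is the Douglas whole-blood formula: plasma
content `2.226 · 0.0307 · PCO2 · (1 + 10^(pH−6.1))` mL/dL corrected to whole
blood by `1 − 0.0289·Hb/((3.352 − 0.456·SatO2)(8.142 − pH))`.  The
correction encodes the Haldane effect (deoxygenated blood carries more CO2)
and restricts the usable pH domain to (6.5, 8.0).

**Acid-base closure.**  pH is recomputed from PCO2 by Henderson–Hasselbalch
at a *fixed* patient bicarbonate (default 24 mEq/L); there is no metabolic
compensation and no bicarbonate generation with CO2 loading.  Consequence:
along the self-consistent (PCO2, pH) path the CO2 content changes only
~0.16 mL/dL per mmHg, so arteriovenous PCO2 differences are larger than in
blood with dynamic buffering.  This is the main reason the membrane CO2
efficiency needs calibration (below).

**State reconstruction.**  Mixing and the solver work on contents (the
conserved quantities) and invert back to tensions: PCO2 and pH are solved
jointly on the bicarbonate-consistent path (unique root, since content is
strictly increasing in PCO2 along it), then PO2 from the O2 content at that
pH/PCO2; saturation (Haldane) and pH (Bohr) couple weakly, so alternating
the two one-dimensional inversions converges in a few passes.  PO2 is capped
at 2000 mmHg — far above the 713 mmHg sweep-gas ceiling — and contents
outside the invertible range raise a diagnostic error.  A note on mixing:
because streams with different PCO2/pH shift each other's dissociation
curve, the mixed PO2 can fall marginally outside the interval of the stream
PO2s; only contents are conserved.

## Ventilator mechanics

Tidal volume is `ΔP · Cst`.  Mechanical power is elastic-only by default,
`0.098 · RR · Vt · (PEEP + ΔP/2)` J/min, which makes the power exactly
linear in RR and PEEP and quadratic in ΔP (through Vt).  A constant-flow
resistive term `0.098 · RR · Vt · Raw·(Vt/Tinsp)` is available but off by
default; I:E affects power only through that term.  For the packaged
protective scenario (PEEP 18, Vt 360 mL, RR 35) elastic-only power is
34.6 J/min; including the resistive term at Raw 10 would give 42 J/min,
so the elastic-only default is the better-behaved convention and the one
the package reports.

Note on the printed source settings: ultraprotective ΔP 10 at Cst 14
implies Vt 140 mL (a printed "14 mL" is treated as a typographical slip —
140 mL is also what the 2.6 J/min energy load requires).

Alveolar PO2 uses the alveolar gas equation
`FiO2·(Pb − PH2O) − PaCO2/RQ`, floored at 1 mmHg.  Alveolar ventilation is
`RR · max(0, Vt − Vd)`; the default dead space is anatomic,
2.2 mL/kg ideal body weight.

## Membrane oxygenator

A lumped single-pass model with two efficiency parameters:

* O2: outlet PO2 moves a fraction `η_O2` of the way from inlet PO2 to the
  sweep-gas oxygen tension `sweep_FiO2 · (Pb − PH2O)`.  Default `η_O2 = 1`
  (fresh membrane, full equilibration).
* CO2: removal is `min(sweep_flow · 1000 · η_CO2 · PvCO2/(Pb − PH2O),
  blood_flow · 10 · C_CO2,in)` mL/min — the sweep gas leaves equilibrated to
  inlet blood PCO2, scaled by `η_CO2`, never more than the blood carries.
  Because the fixed-bicarbonate chemistry cannot represent blood drained
  below pH 8.0, the blood-side limit is additionally capped at the content
  of the pH-domain edge; the cap is computed at exactly the same edge the
  content inversion enforces so that removal is a *continuous* function of
  the inlet state (a discontinuity here leaves the steady-state map without
  a fixed point at extreme sweep/blood-flow ratios).

Outlet PCO2/pH re-solve from the outlet content at the inlet's implied
bicarbonate; mass balance per pass is exact to inversion tolerance.
Pressure drops, clot burden, hemolysis and heat exchange are out of scope.

**Calibration.**  The efficiencies are the device model's only free
parameters.  The packaged on-ECMO scenario sets `η_CO2 = 0.85`, the value at
which the solved steady state reproduces the scenario's reference arterial
blood gas (PaCO2 35 mmHg at blood flow 4.9 L/min, sweep 3 L/min); with
`η_CO2 = 1` the same scenario gives PaCO2 30.6 mmHg.  Class defaults remain
1.0.

## Circulation and the steady-state solver

Topology: one venous pool; the circuit drains
`min(Q_ECMO·(1 − recirculation), Q_CO)` before the right atrium; oxygenator
return mixes with the bypassing venous flow into pulmonary-artery blood; the
native lung splits into a shunt fraction (passes through unchanged) and a
ventilated fraction equilibrated to alveolar gas; tissues apply the Fick
principle (`ΔC_O2 = VO2/(10·Q_CO)` and the CO2 analogue).  Alveolar PCO2 is
the root of gas export = blood-side unloading,
`VA·1000·PACO2/(Pb − PH2O) = (1−shunt)·Q_CO·10·(C_pa − C_cap(PACO2))`;
the left side rises and the right falls in PACO2, so the root is unique.
(The Haldane offset between pulmonary-artery and end-capillary blood can
push the balance point slightly *above* the pulmonary-artery PCO2 at very
low alveolar ventilation; the bracket extends upward to cover this.)

Recirculation is an explicit user parameter (default 0) that shrinks the
effective circuit flow; no flow-dependent functional form is imposed.  Under
this topology with zero recirculation the prototypical on-ECMO scenario
yields an arterial saturation near 99%, noticeably above the reference
scenario's reported 84% — reproducing that value would require a nonzero
effective recirculation (roughly a third of pump flow not reaching fresh
venous blood), which users can set explicitly.  No claim is made on absolute
saturation for that case.

**Solver.**  Fixed-point iteration on the two mixed-venous contents
(O2, CO2): venous → partition → membrane pass → mixing → lung → arterial →
tissue → new venous.  Phase 1 is damped successive substitution
(damping 0.5, up to 200 iterations) — robust but linearly convergent, and
near operating points where the CO2 removal sits on its cap the contraction
rate degrades towards 1.  Phase 2 therefore applies a Newton-type
root finder (Powell hybrid) to the two-component residual from the damped
iterate, with infeasible excursions penalized; phase 3 falls back to damped
grinding up to 10,000 iterations if the acceleration fails.  Convergence
tolerance is 1e-4 mL/dL on the undamped update; everything is deterministic.
At the fixed point the transfer decomposition
`ECMO + lung = VO2` (and VCO2) holds exactly by construction — the tests
assert it to 0.5 mL/min across a 100-scenario grid.

If arterial oxygen content cannot supply VO2 (e.g. total shunt without
ECMO flow, or circuit flow too low), the solver raises a diagnostic
`OxygenSupplyError`; sweeps flag such points and continue.

## HPV stimulus

`PsO2 = PAO2^0.62 · PvO2^0.38` (classical Marshall weighting; exponents are
parameters).  The stimulus is bounded by its two inputs, strictly increasing
in each, and homogeneous of degree 1.  Shunt affects the stimulus only
through the circulation-computed PAO2 and PvO2, not through the formula.
The formulation is not calibrated to any absolute vascular-tone threshold
(a healthy-reference stimulus of ~19 mmHg quoted in some sources is not
reproduced by this weighting); within this package the stimulus supports
trend and dominance comparisons only.

## Packaged scenarios

* `protective_preecmo` — severe ARDS before ECMO: PEEP 18, Vt 360 mL
  (ΔP 20 at Cst 18), RR 35, FiO2 1.0.  Shunt 0.75 and a physiological dead
  space of 250 mL (~0.7·Vt, typical of severe ARDS) were chosen once to
  depict refractory hypoxemia with hypercapnic acidosis; the model then
  gives PaO2 43, SatO2 70%, PaCO2 57, pH 7.23.  The depiction is
  qualitative: the fixed-bicarbonate closure cannot reproduce a specific
  printed ABG exactly.
* `ultraprotective_on_ecmo` — the same patient on ECMO 4.9 L/min / sweep
  3 L/min, ultraprotective ventilation, shunt 0.95, `η_CO2 = 0.85`
  (calibration above).
* `healthy_no_ecmo` — normal lungs, no circuit; the native lung supplies
  the whole VO2 (solved lung transfer 250 of 250 mL/min).

## What the tests do and do not show

The test suite verifies internal consistency (round-trip inversions below
0.01 mmHg, exact per-pass and whole-body mass balance, bit-identical
determinism), the closed-form reference values of each primitive, and the
directional physiology: saturation rising with circuit flow, PaCO2 falling
with sweep flow, higher hemoglobin giving higher saturation, power linear in
RR/PEEP.  Passing these says the model is a faithful implementation of the
stated formulas — not that the formulas capture any individual patient:
real patients have dynamic bicarbonate buffering, temperature and 2,3-DPG
effects, flow-dependent recirculation, membrane aging and cardiac-output
responses, none of which are modelled.

## Numerical summary

| Quantity | Value |
| --- | --- |
| Content-update tolerance | 1e-4 mL/dL |
| Damping (phase 1/3) | 0.5 |
| Max iterations | 10,000 |
| Inversion tolerances | 1e-9–1e-10 (brentq xtol) |
| PO2 inversion ceiling | 2000 mmHg |
| CO2 chemistry pH domain | (6.5, 8.0) |
| Acceptance sweep grid | Q_ECMO 0.5–5.5 L/min, step 0.5 |
| Property grid | 100 scenarios (flow × sweep × shunt) |
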