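"""Membrane-oxygenator device model: single-pass O2 loading and CO2 removal.

Oxygenation is modelled as fractional equilibration of blood PO2 toward the
sweep-gas oxygen tension with a single membrane efficiency parameter
(1.0 = a fresh membrane reaching full equilibration).  CO2 removal is a
lumped single-pass model: the sweep gas leaves equilibrated to inlet blood
PCO2 scaled by a CO2 efficiency, capped by what the blood side can give up.
Efficiencies are the device's calibration parameters; pressure drops, clot
burden and heat exchange are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

from .blood_gas import (
    DEFAULT_CONSTANTS,
    BloodGasError,
    BloodState,
    GasConstants,
    o2_content,
    pco2_ph_from_co2_content,
    sat_from_po2,
)

__all__ = ["EcmoSettings", "EcmoError", "oxygenate", "o2_transfer_rate", "co2_removal"]


class EcmoError(ValueError):
    """Invalid ECMO circuit configuration."""


@dataclass(frozen=True)
class EcmoSettings:
    """ECMO circuit configuration.

    ``blood_flow`` (Q_ECMO) and ``sweep_flow`` in L/min; ``sweep_fio2`` is the
    oxygen fraction of the sweep gas; membrane efficiencies in (0, 1];
    ``recirculation_fraction`` is the fraction of returned blood immediately
    re-drained by the circuit (handled by the circulation topology, not here).
    """

    blood_flow: float = 0.0
    sweep_flow: float = 0.0
    sweep_fio2: float = 1.0
    membrane_o2_efficiency: float = 1.0
    membrane_co2_efficiency: float = 1.0
    recirculation_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.blood_flow < 0:
            raise EcmoError(f"blood_flow must be >= 0, got {self.blood_flow}")
        if self.sweep_flow < 0:
            raise EcmoError(f"sweep_flow must be >= 0, got {self.sweep_flow}")
        if not 0.21 <= self.sweep_fio2 <= 1.0:
            raise EcmoError(f"sweep_fio2={self.sweep_fio2} outside [0.21, 1.0]")
        for name in ("membrane_o2_efficiency", "membrane_co2_efficiency"):
            val = getattr(self, name)
            if not 0.0 < val <= 1.0:
                raise EcmoError(f"{name}={val} outside (0, 1]")
        if not 0.0 <= self.recirculation_fraction < 1.0:
            raise EcmoError(
                f"recirculation_fraction={self.recirculation_fraction} outside [0, 1)"
            )


def co2_removal(
    inlet: BloodState,
    e: EcmoSettings,
    constants: GasConstants = DEFAULT_CONSTANTS,
) -> tuple[float, float]:
    """Sweep-gas CO2 removal for one membrane pass.

    Returns ``(vco2_removed mL/min, outlet_pco2 mmHg)``.  The gas-side limit
    is the sweep flow carrying away gas equilibrated to inlet PCO2 (scaled by
    membrane efficiency); the blood-side limit is the CO2 the blood actually
    carries.  Outlet PCO2/pH are re-solved from the outlet CO2 content at the
    inlet's implied bicarbonate.
    """
    if e.sweep_flow == 0:
        return 0.0, inlet.pco2
    if e.blood_flow <= 0:
        raise EcmoError("co2_removal requires positive blood flow")
    gas_side = (
        e.sweep_flow * 1000.0 * e.membrane_co2_efficiency
        * inlet.pco2 / constants.dry_pressure
    )
    blood_side = e.blood_flow * 10.0 * inlet.co2_content
    removed = min(gas_side, blood_side)
    outlet_content = inlet.co2_content - removed / (e.blood_flow * 10.0)
    hco3 = inlet.hco3
    try:
        pco2, _ph = pco2_ph_from_co2_content(
            outlet_content, inlet.hb, inlet.sat, hco3, constants
        )
    except BloodGasError:
        # blood-side limit would push pH past the chemistry model's domain;
        # cap removal at the lowest invertible content (only reachable at
        # absurd sweep/blood-flow ratios)
        from .blood_gas import _pco2_bounds_for_hco3, co2_content as _co2c, ph_from_pco2

        lo, _hi = _pco2_bounds_for_hco3(hco3, constants)
        # cap at the same domain edge the inversion enforces, keeping the
        # removal a continuous function of the inlet state
        floor_content = _co2c(
            lo, ph_from_pco2(lo, hco3, constants), inlet.hb, inlet.sat, constants
        ) + 1e-9
        removed = max(0.0, e.blood_flow * 10.0 * (inlet.co2_content - floor_content))
        outlet_content = inlet.co2_content - removed / (e.blood_flow * 10.0)
        pco2, _ph = pco2_ph_from_co2_content(
            outlet_content, inlet.hb, inlet.sat, hco3, constants
        )
    return removed, pco2


def oxygenate(
    inlet: BloodState,
    e: EcmoSettings,
    constants: GasConstants = DEFAULT_CONSTANTS,
) -> BloodState:
    """Single membrane pass: returns the post-oxygenator blood state.

    Outlet PO2 moves a fraction ``membrane_o2_efficiency`` of the way from
    inlet PO2 to the sweep-gas oxygen tension; CO2 is removed per
    :func:`co2_removal`; hemoglobin is unchanged.  Saturation, pH and both
    contents are re-derived self-consistently at the inlet's implied
    bicarbonate.
    """
    if e.blood_flow == 0:
        return inlet
    sweep_po2 = e.sweep_fio2 * constants.dry_pressure
    outlet_po2 = inlet.po2 + e.membrane_o2_efficiency * (sweep_po2 - inlet.po2)
    removed, _ = co2_removal(inlet, e, constants)
    outlet_content = inlet.co2_content - removed / (e.blood_flow * 10.0)
    hco3 = inlet.hco3

    # saturation (Haldane) and pH (Bohr) couple weakly; a few alternations
    sat = inlet.sat
    pco2, ph = inlet.pco2, inlet.ph
    for _ in range(60):
        pco2, ph = pco2_ph_from_co2_content(
            outlet_content, inlet.hb, sat, hco3, constants
        )
        new_sat = sat_from_po2(outlet_po2, ph, pco2, constants)
        if abs(new_sat - sat) < 1e-12:
            sat = new_sat
            break
        sat = new_sat
    return BloodState(
        po2=outlet_po2, pco2=pco2, ph=ph, sat=sat, hb=inlet.hb, constants=constants
    )


def o2_transfer_rate(
    inlet: BloodState, outlet: BloodState, blood_flow: float
) -> float:
    """O2 transfer across the membrane (mL O2/min) at a given blood flow."""
    if abs(inlet.hb - outlet.hb) > 1e-9:
        raise EcmoError("inlet and outlet hemoglobin must match")
    return blood_flow * 10.0 * (outlet.o2_content - inlet.o2_content)
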