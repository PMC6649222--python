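"""Ventilator settings model: tidal volume, mechanical power, alveolar gas.

Mechanical power is the energy per minute the ventilator transfers to the
respiratory system.  The default formulation counts the elastic/PEEP work
only,

    MP [J/min] = 0.098 * RR * Vt * (PEEP + DP/2),

with Vt in litres and pressures in cmH2O; 0.098 converts L*cmH2O to joules.
An optional resistive term ``0.098 * RR * Vt * Raw * (Vt / Tinsp)`` can be
added for constant-flow volume-controlled breaths.
"""

from __future__ import annotations

from dataclasses import dataclass

from .blood_gas import DEFAULT_CONSTANTS, GasConstants

__all__ = [
    "VentSettings",
    "VentError",
    "JOULES_PER_L_CMH2O",
    "tidal_volume",
    "static_compliance",
    "mechanical_power",
    "alveolar_po2",
    "alveolar_ventilation",
]

JOULES_PER_L_CMH2O = 0.098


class VentError(ValueError):
    """Invalid ventilator configuration."""


@dataclass(frozen=True)
class VentSettings:
    """Ventilator configuration.

    Pressures in cmH2O, times in seconds, compliance in mL/cmH2O, airway
    resistance in cmH2O/L/s, dead space in mL.  ``mode`` is ``"PCV"`` or
    ``"VCV"``; the distinction only matters for the optional resistive power
    term (constant inspiratory flow is assumed for VCV).
    """

    mode: str = "PCV"
    peep: float = 5.0
    driving_pressure: float = 10.0
    rr: float = 12.0
    t_insp: float = 1.0
    raw: float = 10.0
    cst: float = 50.0
    fio2: float = 0.21
    dead_space: float = 150.0

    def __post_init__(self) -> None:
        if self.mode not in ("VCV", "PCV"):
            raise VentError(f"mode must be 'VCV' or 'PCV', got {self.mode!r}")
        if self.peep < 0:
            raise VentError(f"peep must be >= 0, got {self.peep}")
        if self.driving_pressure <= 0:
            raise VentError(f"driving_pressure must be > 0, got {self.driving_pressure}")
        if self.rr < 0:
            raise VentError(f"rr must be >= 0, got {self.rr}")
        if self.t_insp <= 0:
            raise VentError(f"t_insp must be > 0, got {self.t_insp}")
        if self.rr > 0 and self.t_insp >= 60.0 / self.rr:
            raise VentError(
                f"t_insp={self.t_insp}s leaves no expiratory time at rr={self.rr}"
            )
        if self.cst <= 0:
            raise VentError(f"cst must be > 0, got {self.cst}")
        if not 0.21 <= self.fio2 <= 1.0:
            raise VentError(f"fio2={self.fio2} outside [0.21, 1.0]")
        if self.dead_space < 0:
            raise VentError(f"dead_space must be >= 0, got {self.dead_space}")
        if self.raw < 0:
            raise VentError(f"raw must be >= 0, got {self.raw}")

    @classmethod
    def from_tidal_volume(cls, tidal_volume_ml: float, **kwargs) -> "VentSettings":
        """Build settings from a prescribed tidal volume (mL).

        The driving pressure is back-computed as Vt/Cst, the volume-controlled
        idiom where Vt is the set quantity.
        """
        cst = kwargs.get("cst", 50.0)
        if tidal_volume_ml <= 0:
            raise VentError(f"tidal volume must be > 0, got {tidal_volume_ml}")
        kwargs["driving_pressure"] = tidal_volume_ml / cst
        return cls(**kwargs)

    @property
    def ie_ratio(self) -> float:
        """Inspiratory:expiratory time ratio (I when E is normalised to 1)."""
        if self.rr == 0:
            return 0.0
        t_exp = 60.0 / self.rr - self.t_insp
        return self.t_insp / t_exp


def tidal_volume(v: VentSettings) -> float:
    """Tidal volume in litres: driving pressure times static compliance."""
    return v.driving_pressure * v.cst / 1000.0


def static_compliance(tidal_volume_ml: float, pplat: float, peep: float) -> float:
    """Static respiratory compliance (mL/cmH2O) = Vt / (Pplat - PEEP)."""
    dp = pplat - peep
    if dp <= 0:
        raise VentError(f"pplat ({pplat}) must exceed peep ({peep})")
    return tidal_volume_ml / dp


def mechanical_power(v: VentSettings, include_resistive: bool = False) -> float:
    """Energy per minute transferred to the lungs (J/min).

    Elastic-only by default; with ``include_resistive`` a constant-flow
    resistive term ``Raw * Vt / Tinsp`` is added to the per-breath pressure.
    Returns 0 when the respiratory rate is 0.
    """
    if v.rr == 0:
        return 0.0
    vt = tidal_volume(v)
    pressure = v.peep + v.driving_pressure / 2.0
    if include_resistive:
        pressure += v.raw * (vt / v.t_insp)
    return JOULES_PER_L_CMH2O * v.rr * vt * pressure


def alveolar_po2(
    fio2: float,
    paco2: float,
    constants: GasConstants = DEFAULT_CONSTANTS,
) -> float:
    """Alveolar gas equation: PAO2 = FiO2 (Pb - PH2O) - PaCO2/RQ, >= 1 mmHg."""
    if not 0.21 <= fio2 <= 1.0:
        raise VentError(f"fio2={fio2} outside [0.21, 1.0]")
    if paco2 <= 0:
        raise VentError(f"paco2 must be > 0, got {paco2}")
    pao2 = fio2 * constants.dry_pressure - paco2 / constants.respiratory_quotient
    return max(pao2, 1.0)


def alveolar_ventilation(v: VentSettings) -> float:
    """Alveolar minute ventilation (L/min): RR * max(0, Vt - Vd)."""
    vt_ml = tidal_volume(v) * 1000.0
    return v.rr * max(0.0, vt_ml - v.dead_space) / 1000.0
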