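"""Blood gas chemistry: oxyhemoglobin dissociation, gas contents, acid-base.

The module provides the closed-form relations between partial pressures,
saturation and gas contents that the rest of the simulator composes, together
with the numerical inverses (pressure from saturation, pressure from content)
that stream-mixing and the steady-state solver need.

Model choices
-------------
* Oxyhemoglobin dissociation: the Severinghaus curve
  ``S = 1 / (1 + 23400 / (p^3 + 150 p))`` evaluated at a "virtual" PO2 shifted
  for the Bohr effect (pH and PCO2 at 37 degC, Kelman-type factors).
* O2 content: Hufner binding (1.34 mL O2 per g Hb) plus physically dissolved
  O2 (0.0031 mL/dL/mmHg).
* CO2 content: Douglas whole-blood formula — plasma CO2 from
  Henderson-Hasselbalch times a hemoglobin/saturation (Haldane) correction.
* Acid-base closure: pH from PCO2 at a fixed bicarbonate concentration
  (Henderson-Hasselbalch); no metabolic compensation dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.optimize import brentq

__all__ = [
    "GasConstants",
    "BloodState",
    "DEFAULT_CONSTANTS",
    "BloodGasError",
    "sat_from_po2",
    "po2_from_sat",
    "o2_content",
    "co2_content",
    "pco2_from_co2_content",
    "ph_from_pco2",
    "implied_bicarbonate",
    "blood_state_from_contents",
]

# mmol/L -> mL (STPD) /dL for CO2
_MMOL_PER_L_TO_ML_PER_DL = 2.226

# Douglas whole-blood correction coefficients
_DG_HB = 0.0289
_DG_SAT_A = 3.352
_DG_SAT_B = 0.456
_DG_PH = 8.142

_PH_LO, _PH_HI = 6.5, 8.0


class BloodGasError(ValueError):
    """Domain or inversion failure in the blood-gas relations."""


@dataclass(frozen=True)
class GasConstants:
    """Physical constants shared by every gas-exchange computation.

    Units: pressures mmHg, solubilities per mmHg, Hufner mL O2 per g Hb.
    """

    barometric_pressure: float = 760.0
    water_vapor_pressure: float = 47.0
    respiratory_quotient: float = 0.8
    hufner: float = 1.34
    o2_solubility: float = 0.0031      # mL O2 / dL / mmHg
    co2_solubility: float = 0.0307     # mmol / L / mmHg
    pk_prime: float = 6.1

    def __post_init__(self) -> None:
        for name in (
            "barometric_pressure",
            "water_vapor_pressure",
            "respiratory_quotient",
            "hufner",
            "o2_solubility",
            "co2_solubility",
            "pk_prime",
        ):
            if getattr(self, name) <= 0:
                raise BloodGasError(f"GasConstants.{name} must be positive")
        if self.water_vapor_pressure >= self.barometric_pressure:
            raise BloodGasError("water vapor pressure must be below barometric")

    @property
    def dry_pressure(self) -> float:
        """Barometric minus water-vapor pressure (mmHg), the wet-gas divisor."""
        return self.barometric_pressure - self.water_vapor_pressure


DEFAULT_CONSTANTS = GasConstants()


def sat_from_po2(
    po2: float,
    ph: float = 7.40,
    pco2: float = 40.0,
    constants: GasConstants = DEFAULT_CONSTANTS,
) -> float:
    """Hemoglobin O2 saturation (fraction) at a given PO2, pH and PCO2.

    Severinghaus base curve on a Bohr-shifted virtual PO2:
    ``p_virtual = po2 * 10^(0.40 (pH - 7.40) + 0.06 (log10 40 - log10 pco2))``.
    Strictly increasing in ``po2``; approaches 1 asymptotically.
    """
    if po2 <= 0:
        raise BloodGasError(f"po2 must be positive, got {po2}")
    if pco2 <= 0:
        raise BloodGasError(f"pco2 must be positive, got {pco2}")
    shift = 0.40 * (ph - 7.40) + 0.06 * (math.log10(40.0) - math.log10(pco2))
    p = po2 * 10.0 ** shift
    return 1.0 / (1.0 + 23400.0 / (p ** 3 + 150.0 * p))


def po2_from_sat(
    sat: float,
    ph: float = 7.40,
    pco2: float = 40.0,
    constants: GasConstants = DEFAULT_CONSTANTS,
) -> float:
    """Invert the dissociation curve: PO2 (mmHg) at a given saturation.

    Root-finds on (0.1, 800] mmHg, extending the upper bracket when the
    requested saturation sits on the flat top of the curve.
    """
    if not 0.0 < sat < 1.0:
        raise BloodGasError(f"sat must lie strictly in (0, 1), got {sat}")
    lo, hi = 1e-3, 800.0
    while sat_from_po2(hi, ph, pco2, constants) < sat:
        hi *= 2.0
        if hi > 1e6:
            raise BloodGasError(
                f"cannot bracket po2 for sat={sat} (curve saturates below target)"
            )
    return float(
        brentq(lambda p: sat_from_po2(p, ph, pco2, constants) - sat, lo, hi, xtol=1e-9)
    )


def o2_content(
    hb: float,
    sat: float,
    po2: float,
    constants: GasConstants = DEFAULT_CONSTANTS,
) -> float:
    """Blood O2 content (mL O2/dL): hemoglobin-bound plus dissolved."""
    if hb < 0 or po2 < 0 or not 0.0 <= sat <= 1.0:
        raise BloodGasError(
            f"invalid o2_content inputs hb={hb}, sat={sat}, po2={po2}"
        )
    return constants.hufner * hb * sat + constants.o2_solubility * po2


def co2_content(
    pco2: float,
    ph: float,
    hb: float,
    sat: float,
    constants: GasConstants = DEFAULT_CONSTANTS,
) -> float:
    """Whole-blood CO2 content (mL CO2/dL), Douglas formula.

    Plasma CO2 (dissolved + bicarbonate via Henderson-Hasselbalch) corrected
    to whole blood with a hemoglobin/saturation factor; deoxygenated blood
    carries more CO2 at equal PCO2 (Haldane effect).
    """
    if pco2 <= 0:
        raise BloodGasError(f"pco2 must be positive, got {pco2}")
    if not _PH_LO < ph < _PH_HI:
        raise BloodGasError(f"ph={ph} outside supported range ({_PH_LO}, {_PH_HI})")
    if hb < 0 or not 0.0 <= sat <= 1.0:
        raise BloodGasError(f"invalid hb={hb} or sat={sat}")
    plasma_mmol = constants.co2_solubility * pco2 * (
        1.0 + 10.0 ** (ph - constants.pk_prime)
    )
    haldane = 1.0 - (_DG_HB * hb) / (
        (_DG_SAT_A - _DG_SAT_B * sat) * (_DG_PH - ph)
    )
    return _MMOL_PER_L_TO_ML_PER_DL * plasma_mmol * haldane


def pco2_from_co2_content(
    content: float,
    ph: float,
    hb: float,
    sat: float,
    constants: GasConstants = DEFAULT_CONSTANTS,
) -> float:
    """Invert ``co2_content`` at fixed pH: PCO2 (mmHg) for a target content."""
    if content <= 0:
        raise BloodGasError(f"co2 content must be positive, got {content}")
    lo, hi = 1e-3, 500.0
    while co2_content(hi, ph, hb, sat, constants) < content:
        hi *= 2.0
        if hi > 1e5:
            raise BloodGasError(f"cannot bracket pco2 for content={content}")
    return float(
        brentq(
            lambda p: co2_content(p, ph, hb, sat, constants) - content,
            lo,
            hi,
            xtol=1e-9,
        )
    )


def ph_from_pco2(
    pco2: float,
    hco3: float,
    constants: GasConstants = DEFAULT_CONSTANTS,
) -> float:
    """Henderson-Hasselbalch pH at a given PCO2 and bicarbonate (mEq/L)."""
    if pco2 <= 0 or hco3 <= 0:
        raise BloodGasError(f"pco2={pco2} and hco3={hco3} must be positive")
    return constants.pk_prime + math.log10(
        hco3 / (constants.co2_solubility * pco2)
    )


def implied_bicarbonate(
    pco2: float, ph: float, constants: GasConstants = DEFAULT_CONSTANTS
) -> float:
    """Bicarbonate (mEq/L) consistent with a (PCO2, pH) pair."""
    return constants.co2_solubility * pco2 * 10.0 ** (ph - constants.pk_prime)


def _pco2_bounds_for_hco3(
    hco3: float, constants: GasConstants = DEFAULT_CONSTANTS
) -> tuple[float, float]:
    # PCO2 interval on which ph_from_pco2 stays inside the Douglas pH domain
    lo = hco3 / (constants.co2_solubility * 10.0 ** (_PH_HI - constants.pk_prime))
    hi = hco3 / (constants.co2_solubility * 10.0 ** (_PH_LO - constants.pk_prime))
    return lo * (1.0 + 1e-9), hi * (1.0 - 1e-9)


def pco2_ph_from_co2_content(
    content: float,
    hb: float,
    sat: float,
    hco3: float,
    constants: GasConstants = DEFAULT_CONSTANTS,
) -> tuple[float, float]:
    """Self-consistent (PCO2, pH) for a CO2 content at fixed bicarbonate.

    Solves ``co2_content(p, ph_from_pco2(p, hco3), hb, sat) = content``; the
    constrained content is strictly increasing in PCO2, so the root is unique.
    """
    lo, hi = _pco2_bounds_for_hco3(hco3, constants)

    def f(p: float) -> float:
        return co2_content(p, ph_from_pco2(p, hco3, constants), hb, sat, constants) - content

    f_lo, f_hi = f(lo), f(hi)
    if f_lo > 0 or f_hi < 0:
        raise BloodGasError(
            f"CO2 content {content:.2f} mL/dL not invertible at hco3={hco3} "
            f"(reachable range {content + f_lo:.2f}-{content + f_hi:.2f} mL/dL)"
        )
    pco2 = float(brentq(f, lo, hi, xtol=1e-10))
    return pco2, ph_from_pco2(pco2, hco3, constants)


@dataclass(frozen=True)
class BloodState:
    """One blood stream's gas state with derived contents.

    ``o2_content``/``co2_content`` are derived from the other fields at
    construction and must not be passed in.
    """

    po2: float                     # mmHg
    pco2: float                    # mmHg
    ph: float                      # pH units
    sat: float                     # fraction [0, 1]
    hb: float                      # g/dL
    constants: GasConstants = DEFAULT_CONSTANTS
    o2_content: float = field(init=False)
    co2_content: float = field(init=False)

    def __post_init__(self) -> None:
        if self.po2 <= 0 or self.pco2 <= 0:
            raise BloodGasError(
                f"partial pressures must be positive (po2={self.po2}, pco2={self.pco2})"
            )
        if not 0.0 <= self.sat <= 1.0:
            raise BloodGasError(f"sat={self.sat} outside [0, 1]")
        if not 2.0 <= self.hb <= 25.0:
            raise BloodGasError(f"hb={self.hb} g/dL outside plausible range [2, 25]")
        object.__setattr__(
            self, "o2_content", o2_content(self.hb, self.sat, self.po2, self.constants)
        )
        object.__setattr__(
            self,
            "co2_content",
            co2_content(self.pco2, self.ph, self.hb, self.sat, self.constants),
        )

    @classmethod
    def from_gases(
        cls,
        po2: float,
        pco2: float,
        ph: float,
        hb: float,
        constants: GasConstants = DEFAULT_CONSTANTS,
    ) -> "BloodState":
        """Build a state with saturation taken from the dissociation curve."""
        sat = sat_from_po2(po2, ph, pco2, constants)
        return cls(po2=po2, pco2=pco2, ph=ph, sat=sat, hb=hb, constants=constants)

    @property
    def hco3(self) -> float:
        """Bicarbonate (mEq/L) implied by this state's PCO2/pH pair."""
        return implied_bicarbonate(self.pco2, self.ph, self.constants)


def blood_state_from_contents(
    o2c: float,
    co2c: float,
    hb: float,
    hco3: float,
    constants: GasConstants = DEFAULT_CONSTANTS,
    max_iter: int = 80,
    tol: float = 1e-10,
) -> BloodState:
    """Recover a full :class:`BloodState` from O2 and CO2 contents.

    The coupling is mild — saturation enters CO2 content only through the
    Haldane factor, and pH enters the O2 curve only through the Bohr shift —
    so alternating the two one-dimensional inversions converges in a handful
    of passes.
    """
    if o2c <= 0:
        raise BloodGasError(f"O2 content must be positive, got {o2c}")
    sat = min(0.999, max(1e-6, o2c / (constants.hufner * hb)))
    prev_sat = None
    pco2 = ph = po2 = None
    for _ in range(max_iter):
        pco2, ph = pco2_ph_from_co2_content(co2c, hb, sat, hco3, constants)

        def g(p: float) -> float:
            return (
                o2_content(hb, sat_from_po2(p, ph, pco2, constants), p, constants)
                - o2c
            )

        # 2000 mmHg is far above any oxygen tension the model can produce
        hi = 800.0
        while g(hi) < 0:
            hi *= 2.0
            if hi > 2000.0:
                raise BloodGasError(
                    f"O2 content {o2c:.2f} mL/dL exceeds carrying capacity at hb={hb}"
                )
        po2 = float(brentq(g, 1e-6, hi, xtol=1e-9))
        new_sat = sat_from_po2(po2, ph, pco2, constants)
        if prev_sat is not None and abs(new_sat - sat) < tol:
            sat = new_sat
            break
        prev_sat, sat = sat, new_sat
    return BloodState(po2=po2, pco2=pco2, ph=ph, sat=sat, hb=hb, constants=constants)
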