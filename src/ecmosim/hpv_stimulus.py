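"""Hypoxic pulmonary vasoconstriction (HPV) oxygen stimulus.

Pulmonary vascular tone responds to an effective oxygen tension sensed at
the alveolo-capillary level, classically modelled as a weighted geometric
mean of alveolar and mixed-venous PO2:

    PsO2 = PAO2^wA * PvO2^wV,    wA + wV = 1.

The default weights (0.62 alveolar / 0.38 venous) follow the classical
Marshall stimulus weighting and are exposed as parameters.  The module makes
no attempt to predict vascular resistance or pressure — it reports the
stimulus tension only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .blood_gas import DEFAULT_CONSTANTS, GasConstants
from .vent_mechanics import alveolar_po2

__all__ = ["HpvInputs", "HpvError", "p_stimulus_o2", "stimulus_curve"]


class HpvError(ValueError):
    """Invalid HPV stimulus inputs."""


@dataclass(frozen=True)
class HpvInputs:
    """Alveolar and mixed-venous oxygen tensions with stimulus weights."""

    pao2_alveolar: float            # mmHg
    pvo2: float                     # mmHg, post-ECMO-mixing mixed venous
    alveolar_weight: float = 0.62
    venous_weight: float = 0.38

    def __post_init__(self) -> None:
        if self.pao2_alveolar <= 0 or self.pvo2 <= 0:
            raise HpvError(
                f"pressures must be positive (PAO2={self.pao2_alveolar}, PvO2={self.pvo2})"
            )
        if self.alveolar_weight <= 0 or self.venous_weight <= 0:
            raise HpvError("stimulus weights must be positive")
        if abs(self.alveolar_weight + self.venous_weight - 1.0) > 1e-9:
            raise HpvError("stimulus weights must sum to 1")


def p_stimulus_o2(h: HpvInputs) -> float:
    """Effective HPV oxygen stimulus (mmHg), geometric weighted mean.

    Lies between the two input tensions, is strictly increasing in each, and
    scales linearly when both inputs are scaled together.
    """
    return math.exp(
        h.alveolar_weight * math.log(h.pao2_alveolar)
        + h.venous_weight * math.log(h.pvo2)
    )


def stimulus_curve(
    fio2_grid: Sequence[float],
    shunt: float,
    pvo2: float,
    paco2: float,
    alveolar_weight: float = 0.62,
    venous_weight: float = 0.38,
    constants: GasConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Stimulus PO2 across an FiO2 grid at fixed shunt, PvO2 and PaCO2.

    For each FiO2 the alveolar PO2 is computed from the alveolar gas equation
    and combined with the given mixed-venous PO2.  ``shunt`` is carried as a
    scenario label; it shapes PvO2 through the circulation, not the stimulus
    formula itself.  Returns a DataFrame with columns
    ``fio2, shunt, pvo2, pao2_alveolar, p_stimulus_o2``, monotone
    non-decreasing in FiO2.
    """
    rows = []
    for fio2 in fio2_grid:
        pao2 = alveolar_po2(fio2, paco2, constants)
        ps = p_stimulus_o2(
            HpvInputs(
                pao2_alveolar=pao2,
                pvo2=pvo2,
                alveolar_weight=alveolar_weight,
                venous_weight=venous_weight,
            )
        )
        rows.append(
            {
                "fio2": fio2,
                "shunt": shunt,
                "pvo2": pvo2,
                "pao2_alveolar": pao2,
                "p_stimulus_o2": ps,
            }
        )
    return pd.DataFrame(rows)
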