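"""Whole-body coupling and the steady-state gas-exchange solver.

Flow topology (single venous pool):

    tissues -> mixed venous blood -> [ECMO drain | bypassing venous return]
    -> membrane oxygenator / straight through -> mixed pulmonary-artery blood
    -> native lung (shunt + ventilated compartment) -> arterial blood
    -> tissues (Fick exchange) -> mixed venous blood ...

The solver iterates on the pair of mixed-venous gas contents
(O2, CO2 in mL/dL) with damped successive substitution until the update
falls below tolerance.  At the fixed point, conservation holds exactly by
construction: ECMO plus native-lung O2 transfer equals VO2, and likewise
for CO2.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from scipy.optimize import brentq

from .blood_gas import (
    DEFAULT_CONSTANTS,
    BloodGasError,
    BloodState,
    GasConstants,
    blood_state_from_contents,
    co2_content,
    implied_bicarbonate,
    o2_content,
    ph_from_pco2,
    sat_from_po2,
)
from .oxygenator import EcmoSettings, oxygenate
from .vent_mechanics import VentSettings, alveolar_po2, alveolar_ventilation

__all__ = [
    "PatientParams",
    "SteadyStateResult",
    "CirculationError",
    "OxygenSupplyError",
    "ConvergenceError",
    "partition_flows",
    "mix_streams",
    "lung_exchange",
    "tissue_exchange",
    "solve_steady_state",
]


class CirculationError(ValueError):
    """Invalid circulation inputs."""


class OxygenSupplyError(RuntimeError):
    """Oxygen demand cannot be met: venous O2 content would go negative."""


class ConvergenceError(RuntimeError):
    """The fixed-point iteration failed to converge."""


@dataclass(frozen=True)
class PatientParams:
    """Whole-body physiological parameters.

    ``cardiac_output`` in L/min, ``hb`` g/dL, ``vo2``/``vco2`` mL/min (STPD),
    ``shunt_fraction`` the fraction of pulmonary blood flow bypassing
    ventilated alveoli, ``hco3`` mEq/L, ``ideal_body_weight`` kg.
    """

    cardiac_output: float = 5.0
    hb: float = 14.0
    vo2: float = 250.0
    vco2: float = 200.0
    shunt_fraction: float = 0.05
    hco3: float = 24.0
    ideal_body_weight: float = 60.0

    def __post_init__(self) -> None:
        if self.cardiac_output <= 0:
            raise CirculationError(f"cardiac_output must be > 0, got {self.cardiac_output}")
        if self.vo2 <= 0 or self.vco2 <= 0:
            raise CirculationError(
                f"vo2={self.vo2} and vco2={self.vco2} must be > 0"
            )
        if not 0.0 <= self.shunt_fraction <= 1.0:
            raise CirculationError(f"shunt_fraction={self.shunt_fraction} outside [0, 1]")
        if self.hco3 <= 0:
            raise CirculationError(f"hco3 must be > 0, got {self.hco3}")
        if not 2.0 <= self.hb <= 25.0:
            raise CirculationError(f"hb={self.hb} outside [2, 25] g/dL")


@dataclass(frozen=True)
class SteadyStateResult:
    """Converged (or diagnosed) steady state of the coupled system."""

    arterial: BloodState
    mixed_venous: BloodState
    post_oxygenator: BloodState
    pulmonary_artery: BloodState
    ecmo_o2_transfer: float      # mL O2/min across the membrane
    lung_o2_transfer: float      # mL O2/min via the native lung
    ecmo_vco2: float             # mL CO2/min removed by the sweep gas
    lung_vco2: float             # mL CO2/min exhaled by the native lung
    alveolar_pco2: float         # mmHg in the ventilated compartment
    alveolar_po2: float          # mmHg in the ventilated compartment
    iterations: int
    converged: bool
    residual: float              # mL/dL, last undamped content update


def partition_flows(p: PatientParams, e: EcmoSettings) -> tuple[float, float]:
    """Split venous return into ECMO-drained and bypassing flow (L/min).

    Recirculation shrinks the *effective* circuit flow — the fraction of pump
    flow that actually carries fresh venous blood — and the drain can never
    exceed cardiac output.
    """
    effective = e.blood_flow * (1.0 - e.recirculation_fraction)
    drained = min(effective, p.cardiac_output)
    return drained, p.cardiac_output - drained


def mix_streams(
    streams: Sequence[tuple[float, BloodState]],
    constants: GasConstants = DEFAULT_CONSTANTS,
) -> BloodState:
    """Flow-weighted mixing of blood streams, conserving gas contents exactly.

    Contents mix as flow-weighted means; partial pressures, pH and saturation
    are recovered by inverting the content formulas at the flow-weighted
    bicarbonate.  All streams must share the same hemoglobin.
    """
    streams = [(f, b) for f, b in streams if f > 0]
    if not streams:
        raise CirculationError("mix_streams needs at least one stream with flow > 0")
    total = sum(f for f, _ in streams)
    hb = streams[0][1].hb
    if any(abs(b.hb - hb) > 1e-9 for _, b in streams):
        raise CirculationError("all mixed streams must share the same hemoglobin")
    if len(streams) == 1:
        return streams[0][1]
    o2c = sum(f * b.o2_content for f, b in streams) / total
    co2c = sum(f * b.co2_content for f, b in streams) / total
    hco3 = sum(f * b.hco3 for f, b in streams) / total
    return blood_state_from_contents(o2c, co2c, hb, hco3, constants)


def _capillary_state(
    paco2_alv: float,
    v: VentSettings,
    p: PatientParams,
    constants: GasConstants,
) -> BloodState:
    """End-capillary blood equilibrated to the alveolar gas."""
    pao2 = alveolar_po2(v.fio2, paco2_alv, constants)
    ph = ph_from_pco2(paco2_alv, p.hco3, constants)
    sat = sat_from_po2(pao2, ph, paco2_alv, constants)
    return BloodState(
        po2=pao2, pco2=paco2_alv, ph=ph, sat=sat, hb=p.hb, constants=constants
    )


def _solve_alveolar_pco2(
    pa_blood: BloodState,
    v: VentSettings,
    p: PatientParams,
    constants: GasConstants,
) -> float:
    """Alveolar PCO2 balancing gas-side export against blood-side unloading.

    Root of  VA * 1000 * PACO2 / (Pb - PH2O)
             = (1 - shunt) * Qco * 10 * (C_pa - C_cap(PACO2)).
    The left side rises and the right side falls with PACO2, so the root is
    unique; with VA = 0 the capillary blood simply equilibrates to the
    pulmonary-artery PCO2 (no gas export).
    """
    va = alveolar_ventilation(v)
    q_cap = (1.0 - p.shunt_fraction) * p.cardiac_output
    if va <= 0 or q_cap <= 0:
        return pa_blood.pco2

    def g(pa: float) -> float:
        gas = va * 1000.0 * pa / constants.dry_pressure
        cap = _capillary_state(pa, v, p, constants)
        blood = q_cap * 10.0 * (pa_blood.co2_content - cap.co2_content)
        return gas - blood

    from .blood_gas import _pco2_bounds_for_hco3

    hco3_lo, _ = _pco2_bounds_for_hco3(p.hco3, constants)
    lo = max(0.5, hco3_lo * 1.001)
    hi = max(pa_blood.pco2, lo * 1.01)
    # Haldane offset can leave g(pa.pco2) < 0: alveolar CO2 then accumulates
    # above the pulmonary-artery PCO2 until the balance closes
    while g(hi) < 0:
        hi *= 1.5
        if hi > 400.0:
            raise ConvergenceError("alveolar PCO2 balance failed to bracket")
    if g(lo) > 0:
        return lo
    return float(brentq(g, lo, hi, xtol=1e-8))


def lung_exchange(
    pa_blood: BloodState,
    v: VentSettings,
    p: PatientParams,
    constants: GasConstants = DEFAULT_CONSTANTS,
) -> BloodState:
    """Native-lung pass: shunt admixture of pulmonary-artery blood with
    end-capillary blood equilibrated to the alveolar gas.

    With ``shunt_fraction = 1`` the lung is a pass-through.
    """
    arterial, _, _ = _lung_exchange_detail(pa_blood, v, p, constants)
    return arterial


def _lung_exchange_detail(
    pa_blood: BloodState,
    v: VentSettings,
    p: PatientParams,
    constants: GasConstants,
) -> tuple[BloodState, float, float]:
    shunt = p.shunt_fraction
    if shunt >= 1.0:
        pao2 = alveolar_po2(v.fio2, pa_blood.pco2, constants)
        return pa_blood, pa_blood.pco2, pao2
    paco2_alv = _solve_alveolar_pco2(pa_blood, v, p, constants)
    cap = _capillary_state(paco2_alv, v, p, constants)
    if shunt <= 0.0:
        return cap, paco2_alv, cap.po2
    o2c = shunt * pa_blood.o2_content + (1.0 - shunt) * cap.o2_content
    co2c = shunt * pa_blood.co2_content + (1.0 - shunt) * cap.co2_content
    hco3 = shunt * pa_blood.hco3 + (1.0 - shunt) * cap.hco3
    arterial = blood_state_from_contents(o2c, co2c, p.hb, hco3, constants)
    return arterial, paco2_alv, cap.po2


def tissue_exchange(
    arterial: BloodState,
    p: PatientParams,
    constants: GasConstants = DEFAULT_CONSTANTS,
) -> BloodState:
    """Fick tissue exchange: subtract VO2 from, add VCO2 to, the blood stream."""
    dv = p.cardiac_output * 10.0
    venous_o2c = arterial.o2_content - p.vo2 / dv
    venous_co2c = arterial.co2_content + p.vco2 / dv
    if venous_o2c <= 1e-3:
        raise OxygenSupplyError(
            f"oxygen demand infeasible: arterial content {arterial.o2_content:.2f} "
            f"mL/dL cannot supply VO2={p.vo2} mL/min at Qco={p.cardiac_output} L/min"
        )
    return blood_state_from_contents(
        venous_o2c, venous_co2c, arterial.hb, arterial.hco3, constants
    )


def solve_steady_state(
    p: PatientParams,
    v: VentSettings,
    e: EcmoSettings,
    constants: GasConstants = DEFAULT_CONSTANTS,
    damping: float = 0.5,
    tol: float = 1e-4,
    max_iter: int = 10_000,
) -> SteadyStateResult:
    """Damped successive substitution on the mixed-venous gas contents.

    One sweep: venous state -> flow partition -> membrane pass -> stream
    mixing -> native-lung pass -> arterial state -> Fick tissue exchange ->
    new venous contents.  Converged when the undamped content update is below
    ``tol`` (mL/dL) for both gases.

    Raises :class:`OxygenSupplyError` when the configuration cannot supply
    VO2 (e.g. total shunt with no ECMO flow).
    """
    hb, hco3 = p.hb, p.hco3
    # mid-range venous starting point
    ph0 = ph_from_pco2(45.0, hco3, constants)
    cv_o2 = o2_content(hb, 0.70, 38.0, constants)
    cv_co2 = co2_content(45.0, ph0, hb, 0.70, constants)

    drained, bypassing = partition_flows(p, e)
    e_eff = replace(e, blood_flow=drained) if drained > 0 else e

    state: dict = {}

    def sweep_once(o2c: float, co2c: float) -> tuple[float, float]:
        venous = blood_state_from_contents(o2c, co2c, hb, hco3, constants)
        if drained > 0:
            post = oxygenate(venous, e_eff, constants)
            ecmo_o2 = drained * 10.0 * (post.o2_content - venous.o2_content)
            ecmo_co2 = drained * 10.0 * (venous.co2_content - post.co2_content)
            pa = mix_streams([(drained, post), (bypassing, venous)], constants)
        else:
            post = venous
            ecmo_o2 = ecmo_co2 = 0.0
            pa = venous
        arterial, paco2_alv, pao2_alv = _lung_exchange_detail(pa, v, p, constants)
        lung_o2 = p.cardiac_output * 10.0 * (arterial.o2_content - pa.o2_content)
        lung_co2 = p.cardiac_output * 10.0 * (pa.co2_content - arterial.co2_content)
        new_venous = tissue_exchange(arterial, p, constants)
        state.update(
            venous=venous,
            post=post,
            pa=pa,
            arterial=arterial,
            ecmo_o2=ecmo_o2,
            ecmo_co2=ecmo_co2,
            lung_o2=lung_o2,
            lung_co2=lung_co2,
            paco2_alv=paco2_alv,
            pao2_alv=pao2_alv,
            new_venous=new_venous,
        )
        return new_venous.o2_content, new_venous.co2_content

    iterations = 0
    residual = float("inf")
    converged = False

    # phase 1: damped successive substitution (robust, globally convergent
    # for this map, but the linear rate degrades when the content-PCO2
    # coupling is stiff)
    damped_budget = min(200, max_iter)
    for iterations in range(1, damped_budget + 1):
        n_o2, n_co2 = sweep_once(cv_o2, cv_co2)
        residual = max(abs(n_o2 - cv_o2), abs(n_co2 - cv_co2))
        if residual < tol:
            converged = True
            break
        cv_o2 += damping * (n_o2 - cv_o2)
        cv_co2 += damping * (n_co2 - cv_co2)

    # phase 2: Newton-type acceleration on the two-component residual,
    # started from the damped iterate (deterministic; the damped phase has
    # already located the feasible basin)
    if not converged:
        from scipy.optimize import root as _root

        def fun(x):
            try:
                n_o2, n_co2 = sweep_once(x[0], x[1])
            except (OxygenSupplyError, BloodGasError):
                # push the solver back toward the feasible region
                return [1e3, 1e3]
            return [n_o2 - x[0], n_co2 - x[1]]

        sol = _root(fun, [cv_o2, cv_co2], method="hybr", options={"xtol": 1e-12})
        iterations += int(sol.nfev)
        cand_o2, cand_co2 = float(sol.x[0]), float(sol.x[1])
        try:
            n_o2, n_co2 = sweep_once(cand_o2, cand_co2)
            residual = max(abs(n_o2 - cand_o2), abs(n_co2 - cand_co2))
            if residual < tol:
                converged = True
                cv_o2, cv_co2 = cand_o2, cand_co2
        except (OxygenSupplyError, BloodGasError):
            pass

    # phase 3: if acceleration failed (kinked regime boundary), grind on with
    # the damped iteration up to the full budget
    if not converged:
        n_o2, n_co2 = sweep_once(cv_o2, cv_co2)
        while iterations < max_iter:
            iterations += 1
            residual = max(abs(n_o2 - cv_o2), abs(n_co2 - cv_co2))
            if residual < tol:
                converged = True
                break
            cv_o2 += damping * (n_o2 - cv_o2)
            cv_co2 += damping * (n_co2 - cv_co2)
            n_o2, n_co2 = sweep_once(cv_o2, cv_co2)

    return SteadyStateResult(
        arterial=state["arterial"],
        mixed_venous=state["new_venous"],
        post_oxygenator=state["post"],
        pulmonary_artery=state["pa"],
        ecmo_o2_transfer=state["ecmo_o2"],
        lung_o2_transfer=state["lung_o2"],
        ecmo_vco2=state["ecmo_co2"],
        lung_vco2=state["lung_co2"],
        alveolar_pco2=state["paco2_alv"],
        alveolar_po2=state["pao2_alv"],
        iterations=iterations,
        converged=converged,
        residual=residual,
    )
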