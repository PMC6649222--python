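"""Scenario configuration, packaged cases, and the parameter-sweep engine.

A scenario bundles patient parameters, ventilator settings, ECMO settings and
gas constants under a name.  Scenarios load from YAML or JSON files (keys
snake_case, units fixed as in the dataclasses, no unit parsing); packaged
fixtures cover a severe-ARDS case before ECMO, the same patient on ECMO with
ultraprotective ventilation, and a healthy reference.

``run_scenario`` solves the steady state and attaches the ventilator energy
load and the HPV oxygen stimulus; ``run_sweep`` repeats that along one dotted
parameter path, tolerating infeasible points, and renders rows suitable for
CSV output.  Everything is deterministic: re-running a scenario or sweep
produces byte-identical CSV.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .blood_gas import DEFAULT_CONSTANTS, GasConstants
from .circulation import (
    ConvergenceError,
    OxygenSupplyError,
    PatientParams,
    SteadyStateResult,
    solve_steady_state,
)
from .hpv_stimulus import HpvInputs, p_stimulus_o2
from .oxygenator import EcmoSettings
from .vent_mechanics import VentSettings, mechanical_power, tidal_volume

__all__ = [
    "Scenario",
    "SweepSpec",
    "ScenarioReport",
    "ScenarioError",
    "load_scenario",
    "scenario_from_dict",
    "run_scenario",
    "run_sweep",
    "list_fixtures",
    "load_fixture",
    "report_to_row",
    "write_csv",
]

logger = logging.getLogger("ecmosim")

_SECTION_TYPES = {
    "patient": PatientParams,
    "vent": VentSettings,
    "ecmo": EcmoSettings,
    "constants": GasConstants,
}


class ScenarioError(ValueError):
    """Scenario validation failure; the message names the offending field."""


@dataclass(frozen=True)
class Scenario:
    """A named, fully validated simulation configuration."""

    name: str
    patient: PatientParams
    vent: VentSettings
    ecmo: EcmoSettings
    constants: GasConstants = DEFAULT_CONSTANTS

    def __post_init__(self) -> None:
        if not self.name:
            raise ScenarioError("scenario name must be non-empty")

    def replace_path(self, dotted: str, value: float) -> "Scenario":
        """Return a copy with one dotted-path field replaced
        (e.g. ``"ecmo.blood_flow"``)."""
        parts = dotted.split(".")
        if len(parts) != 2 or parts[0] not in _SECTION_TYPES:
            raise ScenarioError(
                f"parameter path {dotted!r} must be '<section>.<field>' with "
                f"section in {sorted(_SECTION_TYPES)}"
            )
        section, fieldname = parts
        obj = getattr(self, section)
        if fieldname not in {f.name for f in dataclasses.fields(obj)}:
            raise ScenarioError(f"unknown field {fieldname!r} in section {section!r}")
        try:
            new_obj = dataclasses.replace(obj, **{fieldname: value})
        except ValueError as exc:
            raise ScenarioError(f"{dotted}={value}: {exc}") from exc
        return dataclasses.replace(self, **{section: new_obj})


@dataclass(frozen=True)
class SweepSpec:
    """One-parameter sweep: dotted path, ordered values, output columns."""

    parameter_path: str
    values: tuple
    outputs: tuple = ()

    def __post_init__(self) -> None:
        if not self.values:
            raise ScenarioError("sweep values must be non-empty")
        vals = tuple(float(x) for x in self.values)
        for x in vals:
            if x != x or x in (float("inf"), float("-inf")):
                raise ScenarioError(f"sweep value {x} is not finite")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "outputs", tuple(self.outputs))


@dataclass(frozen=True)
class ScenarioReport:
    """One scenario's full solution bundle."""

    scenario: Scenario
    result: SteadyStateResult
    mechanical_power: float       # J/min
    tidal_volume: float           # L
    p_stimulus_o2: float          # mmHg


def _build_section(name: str, data: dict, cls) -> Any:
    unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
    if unknown:
        raise ScenarioError(
            f"section {name!r}: unknown key(s) {sorted(unknown)}"
        )
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ScenarioError(f"section {name!r}: {exc}") from exc


def scenario_from_dict(raw: dict) -> Scenario:
    """Validate a plain dict (parsed YAML/JSON) into a :class:`Scenario`."""
    if not isinstance(raw, dict):
        raise ScenarioError("scenario document must be a mapping")
    name = raw.get("name")
    if not name or not isinstance(name, str):
        raise ScenarioError("missing required key 'name'")
    sections: dict[str, Any] = {}
    for key, cls in _SECTION_TYPES.items():
        data = raw.get(key)
        if data is None:
            if key == "constants":
                sections[key] = DEFAULT_CONSTANTS
                continue
            raise ScenarioError(f"missing required section {key!r}")
        if not isinstance(data, dict):
            raise ScenarioError(f"section {key!r} must be a mapping")
        data = dict(data)
        if key == "vent" and "tidal_volume_ml" in data:
            vt = data.pop("tidal_volume_ml")
            cst = data.get("cst")
            if cst is None:
                raise ScenarioError(
                    "section 'vent': tidal_volume_ml requires cst to back-compute "
                    "driving_pressure"
                )
            if "driving_pressure" in data:
                raise ScenarioError(
                    "section 'vent': give either driving_pressure or tidal_volume_ml, "
                    "not both"
                )
            data["driving_pressure"] = vt / cst
        sections[key] = _build_section(key, data, cls)
    scenario = Scenario(name=name, **sections)
    for key in _SECTION_TYPES:
        logger.info("scenario %s: %s = %s", name, key, getattr(scenario, key))
    return scenario


def load_scenario(path: str | Path) -> Scenario:
    """Load and validate a scenario from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        try:
            raw = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ScenarioError(f"cannot parse {path}: {exc}") from exc
    return scenario_from_dict(raw)


def list_fixtures() -> list[str]:
    """Names of the packaged scenario fixtures."""
    pkg = resources.files("ecmosim") / "fixtures"
    return sorted(p.name.removesuffix(".yaml") for p in pkg.iterdir() if p.name.endswith(".yaml"))


def load_fixture(name: str) -> Scenario:
    """Load a packaged scenario fixture by name."""
    pkg = resources.files("ecmosim") / "fixtures" / f"{name}.yaml"
    try:
        text = pkg.read_text()
    except FileNotFoundError as exc:
        raise ScenarioError(
            f"no packaged fixture {name!r}; available: {list_fixtures()}"
        ) from exc
    return scenario_from_dict(yaml.safe_load(text))


def run_scenario(s: Scenario) -> ScenarioReport:
    """Solve the scenario's steady state and attach power and HPV stimulus.

    Raises :class:`ecmosim.circulation.OxygenSupplyError` (annotated with the
    scenario name) when oxygen demand is infeasible, and
    :class:`ecmosim.circulation.ConvergenceError` when the solver does not
    converge.
    """
    try:
        result = solve_steady_state(s.patient, s.vent, s.ecmo, s.constants)
    except OxygenSupplyError as exc:
        raise OxygenSupplyError(f"scenario {s.name!r}: {exc}") from exc
    if not result.converged:
        raise ConvergenceError(
            f"scenario {s.name!r}: steady state not reached "
            f"(residual {result.residual:.3g} mL/dL after {result.iterations} iterations)"
        )
    mp = mechanical_power(s.vent)
    ps = p_stimulus_o2(
        HpvInputs(
            pao2_alveolar=result.alveolar_po2,
            pvo2=result.pulmonary_artery.po2,
        )
    )
    return ScenarioReport(
        scenario=s,
        result=result,
        mechanical_power=mp,
        tidal_volume=tidal_volume(s.vent),
        p_stimulus_o2=ps,
    )


_INPUT_COLS = (
    ("cardiac_output", lambda s: s.patient.cardiac_output),
    ("hb", lambda s: s.patient.hb),
    ("vo2", lambda s: s.patient.vo2),
    ("vco2", lambda s: s.patient.vco2),
    ("shunt_fraction", lambda s: s.patient.shunt_fraction),
    ("hco3", lambda s: s.patient.hco3),
    ("peep", lambda s: s.vent.peep),
    ("driving_pressure", lambda s: s.vent.driving_pressure),
    ("rr", lambda s: s.vent.rr),
    ("cst", lambda s: s.vent.cst),
    ("fio2", lambda s: s.vent.fio2),
    ("ecmo_blood_flow", lambda s: s.ecmo.blood_flow),
    ("sweep_flow", lambda s: s.ecmo.sweep_flow),
    ("sweep_fio2", lambda s: s.ecmo.sweep_fio2),
    ("recirculation_fraction", lambda s: s.ecmo.recirculation_fraction),
)


def report_to_row(report: ScenarioReport) -> dict:
    """Flatten a report into a CSV row (inputs first, then outputs)."""
    s = report.scenario
    r = report.result
    row = {"scenario": s.name}
    for col, getter in _INPUT_COLS:
        row[col] = getter(s)
    row.update(
        tidal_volume_ml=report.tidal_volume * 1000.0,
        mechanical_power=report.mechanical_power,
        arterial_po2=r.arterial.po2,
        arterial_pco2=r.arterial.pco2,
        arterial_sat=r.arterial.sat,
        arterial_ph=r.arterial.ph,
        venous_po2=r.mixed_venous.po2,
        venous_pco2=r.mixed_venous.pco2,
        venous_sat=r.mixed_venous.sat,
        ecmo_o2_transfer=r.ecmo_o2_transfer,
        lung_o2_transfer=r.lung_o2_transfer,
        ecmo_vco2=r.ecmo_vco2,
        lung_vco2=r.lung_vco2,
        p_stimulus_o2=report.p_stimulus_o2,
        iterations=r.iterations,
        converged=r.converged,
    )
    return row


_FAIL_OUTPUT_COLS = [
    "tidal_volume_ml", "mechanical_power", "arterial_po2", "arterial_pco2",
    "arterial_sat", "arterial_ph", "venous_po2", "venous_pco2", "venous_sat",
    "ecmo_o2_transfer", "lung_o2_transfer", "ecmo_vco2", "lung_vco2",
    "p_stimulus_o2", "iterations",
]


def run_sweep(s: Scenario, spec: SweepSpec) -> pd.DataFrame:
    """Run the scenario once per sweep value, in order.

    Infeasible or non-converging points are flagged (``converged=False``,
    ``error`` column) and the sweep continues.  The parameter path is
    validated before any run.
    """
    s.replace_path(spec.parameter_path, float(spec.values[0]))  # path check
    rows = []
    for value in spec.values:
        point = s.replace_path(spec.parameter_path, float(value))
        row: dict[str, Any] = {spec.parameter_path: float(value)}
        try:
            report = run_scenario(point)
            row.update(report_to_row(report))
            row["error"] = ""
        except (OxygenSupplyError, ConvergenceError) as exc:
            logger.warning("sweep point %s=%s failed: %s", spec.parameter_path, value, exc)
            row["scenario"] = s.name
            for col, getter in _INPUT_COLS:
                row[col] = getter(point)
            for col in _FAIL_OUTPUT_COLS:
                row[col] = float("nan")
            row["converged"] = False
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    df = pd.DataFrame(rows)
    if spec.outputs:
        keep = [spec.parameter_path, *spec.outputs, "converged", "error"]
        df = df[[c for c in keep if c in df.columns]]
    return df


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as locale-independent CSV ('.' decimals)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6g", lineterminator="\n")
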