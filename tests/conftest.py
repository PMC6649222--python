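import pytest
from hypothesis import settings

from ecmosim import EcmoSettings, PatientParams, VentSettings

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture
def ards_patient():
    """Hyperdynamic, slightly anemic severe-ARDS patient on ECMO support."""
    return PatientParams(
        cardiac_output=10.0,
        hb=10.0,
        vo2=200.0,
        vco2=160.0,
        shunt_fraction=0.95,
        hco3=24.0,
        ideal_body_weight=60.0,
    )


@pytest.fixture
def ultraprotective_vent():
    """Ultraprotective PCV: PEEP 14, DP 10, Cst 14 (Vt 140 mL), RR 10."""
    return VentSettings(
        mode="PCV",
        peep=14.0,
        driving_pressure=10.0,
        rr=10.0,
        t_insp=1.0,
        raw=10.0,
        cst=14.0,
        fio2=0.3,
        dead_space=132.0,
    )


@pytest.fixture
def protective_vent():
    """Protective VCV: PEEP 18, Vt 360 mL (DP 20 at Cst 18), RR 35."""
    return VentSettings(
        mode="VCV",
        peep=18.0,
        driving_pressure=20.0,
        rr=35.0,
        t_insp=0.6,
        raw=10.0,
        cst=18.0,
        fio2=1.0,
        dead_space=250.0,
    )


@pytest.fixture
def ecmo_49():
    """Prototypical circuit: blood flow 4.9 L/min, sweep 3 L/min, FiO2 1."""
    return EcmoSettings(
        blood_flow=4.9,
        sweep_flow=3.0,
        sweep_fio2=1.0,
        membrane_co2_efficiency=0.85,
    )
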