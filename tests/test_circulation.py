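"""Circulation coupling: flow partition, mixing, lung/tissue exchange, solver."""

import dataclasses

import pytest

from ecmosim.blood_gas import BloodState, blood_state_from_contents, ph_from_pco2
from ecmosim.circulation import (
    CirculationError,
    OxygenSupplyError,
    PatientParams,
    lung_exchange,
    mix_streams,
    partition_flows,
    solve_steady_state,
    tissue_exchange,
)
from ecmosim.oxygenator import EcmoSettings
from ecmosim.vent_mechanics import VentSettings


class TestPartition:
    @pytest.mark.parametrize(
        "qco, qecmo, recirc, expected",
        [
            (10.0, 4.9, 0.0, (4.9, 5.1)),
            (10.0, 0.0, 0.0, (0.0, 10.0)),
            (10.0, 12.0, 0.0, (10.0, 0.0)),     # drain clamped to cardiac output
            (10.0, 4.9, 0.3, (3.43, 6.57)),     # recirculation shrinks effective flow
        ],
    )
    def test_flow_split(self, qco, qecmo, recirc, expected):
        p = PatientParams(cardiac_output=qco, hb=10, vo2=200, vco2=160, shunt_fraction=0.95)
        e = EcmoSettings(blood_flow=qecmo, sweep_flow=3.0, recirculation_fraction=recirc)
        drained, bypassing = partition_flows(p, e)
        assert (drained, bypassing) == pytest.approx(expected)
        assert drained + bypassing == pytest.approx(qco)


class TestMixing:
    def test_idempotent_for_identical_streams(self):
        b = BloodState.from_gases(po2=60.0, pco2=44.0, ph=ph_from_pco2(44.0, 24.0), hb=10.0)
        mixed = mix_streams([(2.0, b), (3.0, b)])
        assert mixed.o2_content == pytest.approx(b.o2_content, abs=1e-9)
        assert mixed.po2 == pytest.approx(b.po2, abs=1e-3)

    def test_flow_weighted_contents(self):
        rich = blood_state_from_contents(14.95, 42.0, 10.0, 24.0)
        poor = blood_state_from_contents(9.0, 50.0, 10.0, 24.0)
        mixed = mix_streams([(4.9, rich), (5.1, poor)])
        assert mixed.o2_content == pytest.approx(
            (4.9 * 14.95 + 5.1 * 9.0) / 10.0, abs=1e-9
        )  # 11.915
        assert mixed.co2_content == pytest.approx(
            (4.9 * 42.0 + 5.1 * 50.0) / 10.0, abs=1e-9
        )

    def test_order_invariance(self):
        a = blood_state_from_contents(13.0, 45.0, 10.0, 24.0)
        b = blood_state_from_contents(10.0, 52.0, 10.0, 24.0)
        m1 = mix_streams([(2.0, a), (8.0, b)])
        m2 = mix_streams([(8.0, b), (2.0, a)])
        assert m1.po2 == pytest.approx(m2.po2, abs=1e-9)
        assert m1.pco2 == pytest.approx(m2.pco2, abs=1e-9)

    def test_rejects_empty_and_mismatched_hb(self):
        a = BloodState.from_gases(po2=60, pco2=44, ph=7.37, hb=10)
        b = BloodState.from_gases(po2=60, pco2=44, ph=7.37, hb=12)
        with pytest.raises(CirculationError):
            mix_streams([])
        with pytest.raises(CirculationError):
            mix_streams([(0.0, a)])
        with pytest.raises(CirculationError):
            mix_streams([(1.0, a), (1.0, b)])


class TestLungExchange:
    def test_total_shunt_is_passthrough(self, ards_patient, ultraprotective_vent):
        p = dataclasses.replace(ards_patient, shunt_fraction=1.0)
        pa = BloodState.from_gases(po2=45.0, pco2=48.0, ph=ph_from_pco2(48.0, 24.0), hb=10.0)
        assert lung_exchange(pa, ultraprotective_vent, p) is pa

    def test_no_shunt_equilibrates_to_alveolar_gas(self, ards_patient):
        # healthy-lung ventilation at FiO2 1.0: arterial PO2 tracks alveolar PO2
        p = dataclasses.replace(ards_patient, shunt_fraction=0.0)
        v = VentSettings(mode="VCV", peep=5, driving_pressure=10, rr=12, t_insp=1.5,
                         raw=8, cst=50, fio2=1.0, dead_space=150)
        pa = BloodState.from_gases(po2=45.0, pco2=48.0, ph=ph_from_pco2(48.0, 24.0), hb=10.0)
        art = lung_exchange(pa, v, p)
        assert art.po2 == pytest.approx(1.0 * 713 - art.pco2 / 0.8, abs=0.5)
        assert art.po2 > 600

    def test_partial_shunt_mixes_contents(self, ards_patient, ultraprotective_vent):
        pa = BloodState.from_gases(po2=45.0, pco2=48.0, ph=ph_from_pco2(48.0, 24.0), hb=10.0)
        art = lung_exchange(pa, ultraprotective_vent, ards_patient)
        # arterial content lies between pulmonary-artery and end-capillary blood
        assert art.o2_content > pa.o2_content
        assert art.co2_content < pa.co2_content


class TestTissueExchange:
    @pytest.mark.parametrize("qco, vo2, expected_diff", [(10.0, 200.0, 2.0), (5.5, 200.0, 3.64)])
    def test_fick_o2_difference(self, qco, vo2, expected_diff):
        p = PatientParams(cardiac_output=qco, hb=10, vo2=vo2, vco2=160, shunt_fraction=0.95)
        art = BloodState.from_gases(po2=90.0, pco2=40.0, ph=ph_from_pco2(40.0, 24.0), hb=10.0)
        ven = tissue_exchange(art, p)
        assert art.o2_content - ven.o2_content == pytest.approx(expected_diff, abs=0.005)
        assert ven.co2_content - art.co2_content == pytest.approx(p.vco2 / (qco * 10), abs=1e-9)

    def test_negligible_vo2_preserves_content(self):
        p = PatientParams(cardiac_output=10, hb=10, vo2=1e-6, vco2=1e-6, shunt_fraction=0.95)
        art = BloodState.from_gases(po2=90.0, pco2=40.0, ph=ph_from_pco2(40.0, 24.0), hb=10.0)
        ven = tissue_exchange(art, p)
        assert ven.o2_content == pytest.approx(art.o2_content, abs=1e-6)

    def test_demand_beyond_delivery_flagged(self):
        p = PatientParams(cardiac_output=2.0, hb=10, vo2=500, vco2=160, shunt_fraction=0.95)
        art = BloodState.from_gases(po2=40.0, pco2=40.0, ph=ph_from_pco2(40.0, 24.0), hb=10.0)
        with pytest.raises(OxygenSupplyError):
            tissue_exchange(art, p)


class TestSteadyState:
    def test_prototypical_case_conserves_gases(self, ards_patient, ultraprotective_vent, ecmo_49):
        r = solve_steady_state(ards_patient, ultraprotective_vent, ecmo_49)
        assert r.converged
        assert r.ecmo_o2_transfer + r.lung_o2_transfer == pytest.approx(200.0, abs=0.5)
        assert r.ecmo_vco2 + r.lung_vco2 == pytest.approx(160.0, abs=0.5)
        # Fick consistency across the systemic circulation
        av_o2 = r.arterial.o2_content - r.mixed_venous.o2_content
        assert 10 * 10 * av_o2 == pytest.approx(200.0, abs=0.5)

    def test_healthy_lung_supplies_all_oxygen(self):
        p = PatientParams(cardiac_output=5, hb=14, vo2=250, vco2=200, shunt_fraction=0.03)
        v = VentSettings(mode="VCV", peep=5, driving_pressure=10, rr=12, t_insp=1.5,
                         raw=8, cst=50, fio2=0.4, dead_space=154)
        r = solve_steady_state(p, v, EcmoSettings())
        assert r.converged
        assert r.arterial.sat > 0.97
        assert r.ecmo_o2_transfer == 0.0
        assert r.lung_o2_transfer == pytest.approx(250.0, abs=0.5)

    def test_total_shunt_without_ecmo_is_infeasible(self, ultraprotective_vent):
        p = PatientParams(cardiac_output=10, hb=10, vo2=200, vco2=160, shunt_fraction=1.0)
        with pytest.raises(OxygenSupplyError):
            solve_steady_state(p, ultraprotective_vent, EcmoSettings())

    def test_bitwise_determinism(self, ards_patient, ultraprotective_vent, ecmo_49):
        r1 = solve_steady_state(ards_patient, ultraprotective_vent, ecmo_49)
        r2 = solve_steady_state(ards_patient, ultraprotective_vent, ecmo_49)
        assert r1.arterial.po2 == r2.arterial.po2
        assert r1.mixed_venous.co2_content == r2.mixed_venous.co2_content
        assert r1.iterations == r2.iterations

    def test_saturation_rises_with_ecmo_flow(self, ards_patient, ultraprotective_vent):
        sats = []
        for q in (2.0, 3.5, 5.0):
            e = EcmoSettings(blood_flow=q, sweep_flow=3.0, membrane_co2_efficiency=0.85)
            sats.append(solve_steady_state(ards_patient, ultraprotective_vent, e).arterial.sat)
        assert sats[0] < sats[1] < sats[2]

    def test_paco2_falls_with_sweep_flow(self, ards_patient, ultraprotective_vent):
        pco2s = []
        for sf in (1.5, 3.0, 6.0):
            e = EcmoSettings(blood_flow=4.9, sweep_flow=sf, membrane_co2_efficiency=0.85)
            pco2s.append(solve_steady_state(ards_patient, ultraprotective_vent, e).arterial.pco2)
        assert pco2s[0] > pco2s[1] > pco2s[2]

    def test_higher_hemoglobin_improves_saturation(self, ards_patient, ultraprotective_vent):
        e = EcmoSettings(blood_flow=3.0, sweep_flow=3.0, membrane_co2_efficiency=0.85)
        sat_low = solve_steady_state(
            dataclasses.replace(ards_patient, hb=7.0), ultraprotective_vent, e
        ).arterial.sat
        sat_high = solve_steady_state(
            dataclasses.replace(ards_patient, hb=10.0), ultraprotective_vent, e
        ).arterial.sat
        assert sat_high >= sat_low

    def test_invalid_patient_rejected(self):
        with pytest.raises(CirculationError):
            PatientParams(cardiac_output=0)
        with pytest.raises(CirculationError):
            PatientParams(shunt_fraction=1.2)
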