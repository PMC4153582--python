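import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm

from mph_pbpk import scenarios, simulate
from mph_pbpk.model import (
    ExposureSchedule,
    gut_submodel_rates,
    hepatic_hydrolysis_rate,
    hepatic_oxidation_rate,
)
from mph_pbpk.parameters import (
    EnantiomerKinetics,
    PartitionSet,
    PhysiologicalParams,
    PopulationModel,
)


def _custom_population(partition=None, kin_kwargs=None, QCC=15.87, BW=70.0,
                       route="iv"):
    """Adult-human-shaped population with overridable pieces, for oracle
    configurations that registry populations cannot express."""
    ph = PhysiologicalParams.with_closure(
        BW=BW, QCC=QCC, QFC=0.053, QLC=0.24, QBC=0.11, QHC=0.038,
        QGC=0.00054, VPC=0.0435, VFC=0.213, VLC=0.026, VBC=0.02,
        VHC=0.0045, VGC=0.0007)
    kw = dict(Kmliver=27_600, VmaxliverC=38_000, KmetC=0.7, VbodyC=0.6,
              Ku_RAC=0.305, Kmliver_inhibitor=10_172)
    kw.update(kin_kwargs or {})
    kin = EnantiomerKinetics(**kw)
    return PopulationModel(
        species="human", age_class="adult", route=route, physio=ph,
        partition=partition or PartitionSet(),
        kinetics_d=kin, kinetics_l=kin)


class TestHepaticHydrolysis:
    def test_reduces_to_michaelis_menten_without_inhibitor(self):
        v = hepatic_hydrolysis_rate(50.0, 0.0, 100.0, 20.0, 10.0)
        assert v == pytest.approx(100.0 * 50.0 / (20.0 + 50.0))

    def test_zero_substrate_gives_zero(self):
        assert hepatic_hydrolysis_rate(0.0, 10.0, 100.0, 20.0, 10.0) == 0.0

    def test_competitive_inhibition_arithmetic(self):
        # Km doubled by the inhibitor term: 100*20 / (20*(1+10/10) + 20)
        v = hepatic_hydrolysis_rate(20.0, 10.0, 100.0, 20.0, 10.0)
        assert v == pytest.approx(100.0 * 20.0 / 60.0)

    def test_negative_concentration_clamped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            assert hepatic_hydrolysis_rate(-1.0, 0.0, 100.0, 20.0, 10.0) == 0.0

    def test_nonpositive_km_rejected(self):
        with pytest.raises(ValueError):
            hepatic_hydrolysis_rate(1.0, 0.0, 100.0, 0.0, 10.0)

    @settings(deadline=None, derandomize=True)
    @given(c=st.floats(0.0, 1e6), c_inh=st.floats(0.0, 1e6))
    def test_rate_bounded_by_vmax_and_monotone_in_inhibitor(self, c, c_inh):
        v = hepatic_hydrolysis_rate(c, c_inh, 100.0, 20.0, 10.0)
        assert 0.0 <= v < 100.0 + 1e-9
        v_more_inh = hepatic_hydrolysis_rate(c, c_inh + 1.0, 100.0, 20.0, 10.0)
        assert v_more_inh <= v + 1e-12


class TestGutSubmodel:
    def test_oxidation_is_linear(self):
        assert hepatic_oxidation_rate(10.0, 0.5) == 5.0
        assert hepatic_oxidation_rate(10.0, 0.0) == 0.0

    def test_rate_partition(self):
        r = gut_submodel_rates(10.0, 5.0, ge=2.0, k3=1.0, k5=3.0, f=0.8)
        assert r["stomach_outflow"] == 20.0
        assert r["uptake_to_liver"] == 5.0
        assert r["ra_formation"] == pytest.approx(0.8 * 15.0)
        assert r["gut_oxidation"] == pytest.approx(0.2 * 15.0)

    def test_symmetric_competition_splits_evenly(self):
        r = gut_submodel_rates(0.0, 8.0, ge=1.0, k3=2.0, k5=2.0, f=1.0)
        assert r["uptake_to_liver"] == r["ra_formation"]

    def test_invalid_hydrolysis_fraction_rejected(self):
        with pytest.raises(ValueError):
            gut_submodel_rates(1.0, 1.0, 1.0, 1.0, 1.0, f=1.5)


class TestExposureSchedule:
    def test_weekday_pattern_yields_ten_events_per_week(self):
        s = ExposureSchedule(times_of_day=(0.0, 4.0), days="weekdays",
                             duration_days=7)
        t = s.event_times()
        assert len(t) == 10
        assert np.all(np.diff(t) > 0)
        assert t[0] == 0.0 and t[-1] == 4.0 + 24.0 * 4

    def test_mg_per_kg_resolution(self):
        s = ExposureSchedule(dose=2.5, dose_unit="mg/kg")
        assert s.dose_ug(4.0) == pytest.approx(10_000.0)

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValueError):
            ExposureSchedule(times_of_day=(4.0, 0.0))


class TestSimulation:
    def test_zero_dose_gives_zero_trajectory(self, juvenile_monkey_oral):
        s = ExposureSchedule(dose=0.0)
        traj = simulate(juvenile_monkey_oral, s, 24.0)
        assert np.all(traj.y == 0.0)

    @pytest.mark.parametrize("pop_builder,sched", [
        (lambda: scenarios.adult_human("oral"), scenarios.daily_bid_schedule(0.3)),
        (lambda: scenarios.adult_human("iv"), scenarios.single_iv_dose(10.0)),
        (lambda: scenarios.juvenile_monkey("oral"),
         scenarios.monkey_toxicity_schedule(2.5)),
        (lambda: scenarios.child(6), scenarios.daily_bid_schedule(0.3)),
    ])
    def test_mass_balance(self, pop_builder, sched):
        """Drug accounted in body + metabolite + urine + oxidized sinks
        equals drug administered, at every output time."""
        traj = simulate(pop_builder(), sched, 48.0)
        assert traj.mass_balance_error() < 1e-3

    def test_state_non_negativity(self, jm_tox_week):
        dose = jm_tox_week.dose_administered_ug
        assert jm_tox_week.y.min() > -1e-9 * dose

    def test_total_is_sum_of_enantiomers(self, adult_human_bid_week):
        tr = adult_human_bid_week
        np.testing.assert_allclose(
            tr.conc_plasma("total"),
            tr.conc_plasma("d") + tr.conc_plasma("l"), rtol=1e-12)

    def test_enantiomer_asymmetry_oral_adult(self, adult_human_bid_week):
        """l-MPH clears faster, so plasma d-MPH dominates after uptake."""
        tr = adult_human_bid_week
        mask = tr.t > 0.5
        assert np.all(tr.conc_plasma("d")[mask] >=
                      tr.conc_plasma("l")[mask] - 1e-12)

    def test_iv_bolus_peak_at_event(self):
        pop = scenarios.adult_human("iv")
        tr = simulate(pop, scenarios.single_iv_dose(10.0), 12.0)
        assert np.argmax(tr.conc_plasma("total")) == 0

    def test_single_exit_limit_recovers_dose_in_urine(self):
        """With oxidation and gut metabolism off, hydrolysis->RA->urine is
        the only exit, so cumulative urine RA approaches the dose."""
        pop = _custom_population(
            kin_kwargs={"KmetC": 0.0, "GEC": 3.5, "K3C": 1.293, "K5C": 0.0},
            route="oral")
        sched = ExposureSchedule(route="oral", dose=10.0, dose_unit="mg",
                                 times_of_day=(0.0,), duration_days=1)
        tr = simulate(pop, sched, 600.0, points_per_hour=10)
        assert tr.urine_ra("total")[-1] / tr.dose_administered_ug > 0.995

    def test_solver_tolerance_convergence(self, juvenile_monkey_oral):
        sched = scenarios.single_oral_dose(2.5)
        c1 = simulate(juvenile_monkey_oral, sched, 24.0,
                      rtol=1e-8, atol=1e-10).conc_plasma("total").max()
        c2 = simulate(juvenile_monkey_oral, sched, 24.0,
                      rtol=5e-9, atol=5e-11).conc_plasma("total").max()
        assert abs(c1 - c2) / c1 < 1e-3

    def test_dose_linearity_below_saturation(self, juvenile_monkey_oral):
        """At doses far below Km the model is linear: doubling the dose
        doubles Cmax to within 1%."""
        lo = simulate(juvenile_monkey_oral, scenarios.single_oral_dose(0.025),
                      24.0).conc_plasma("total").max()
        hi = simulate(juvenile_monkey_oral, scenarios.single_oral_dose(0.05),
                      24.0).conc_plasma("total").max()
        assert hi / lo == pytest.approx(2.0, rel=0.01)


class TestOracles:
    def test_matches_matrix_exponential_solution(self):
        """With saturable hydrolysis switched off the single-enantiomer iv
        system is linear; the integrator must match the matrix-exponential
        solution of the independently assembled rate matrix."""
        pop = _custom_population(kin_kwargs={"VmaxliverC": 0.0})
        ph, pt = pop.physio, pop.partition
        qc = ph.cardiac_output
        names = ["plasma", "fat", "brain", "rich", "slow", "gonads",
                 "heart", "liver"]
        q = np.array([np.nan, ph.QFC, ph.QBC, ph.QRC, ph.QSC, ph.QGC,
                      ph.QHC, ph.QLC]) * qc
        v = np.array([ph.VPC, ph.VFC, ph.VBC, ph.VRC, ph.VSC, ph.VGC,
                      ph.VHC, ph.VLC]) * ph.BW
        p = np.array([1.0, pt.Pfat, pt.Pbrain, pt.Prich, pt.Pslow,
                      pt.Pgonads, pt.Pheart, pt.Pliver])
        A = np.zeros((8, 8))
        for i in range(1, 8):
            A[i, 0] = q[i] / v[0]
            A[i, i] = -q[i] / (v[i] * p[i])
            A[0, i] = q[i] / (v[i] * p[i])
        A[0, 0] = -np.nansum(q[1:]) / v[0]
        A[7, 7] -= 0.7 * ph.BW ** 0.75 / (v[7] * p[7])  # hepatic oxidation

        dose_each = 5000.0  # µg per enantiomer
        sched = ExposureSchedule(route="iv", dose=10.0, dose_unit="mg",
                                 times_of_day=(0.0,), duration_days=1)
        tr = simulate(pop, sched, 24.0)
        y0 = np.zeros(8)
        y0[0] = dose_each
        for t_chk in (0.5, 2.0, 8.0, 24.0):
            ref = (expm(A * t_chk) @ y0)[0] / v[0]
            got = np.interp(t_chk, tr.t, tr.conc_plasma("d"))
            assert got == pytest.approx(ref, rel=1e-6)

    def test_one_compartment_closed_form(self):
        """All partitions 1, a single small clearance and near-instant
        distribution reduce the model to one compartment: C(t) =
        (D/V) exp(-CL t / V)."""
        cl = 1.0  # L/h at BW = 1 kg
        pop = _custom_population(
            partition=PartitionSet(1, 1, 1, 1, 1, 1, 1),
            kin_kwargs={"VmaxliverC": 0.0, "KmetC": cl},
            QCC=1e5, BW=1.0)
        sched = ExposureSchedule(route="iv", dose=1.0, dose_unit="mg",
                                 times_of_day=(0.0,), duration_days=1)
        tr = simulate(pop, sched, 2.0, points_per_hour=200)
        v_total = 0.93  # sum of all fractional volumes at BW 1
        mask = tr.t >= 0.05  # past the (near-instant) distribution phase
        expected = (1000.0 / v_total) * np.exp(-cl * tr.t[mask] / v_total)
        got = tr.conc_plasma("total")[mask]
        assert np.max(np.abs(got - expected) / expected) < 1e-3
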