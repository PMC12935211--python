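"""Infection/inflammation model: rate laws, integrator, outcome classifier."""

import math

import numpy as np
import pytest

from woundtwin.errors import ConfigurationError, DomainError, UsageError
from woundtwin.physiology import (
    PatientState,
    PhysiologyParams,
    SEVERITY_PRESETS,
    Trajectory,
    antibiotic_kill_rate,
    classify_outcome,
    fluid_shift_rate,
    integrate,
    mediator_rates,
    pathogen_rate,
    severity_to_count,
    step,
    tissue_integrity_rate,
)


def make_params(**over):
    base = dict(r=0.4, K=1e9, PH=1e8, kM=0.2, sM=0.5, dM=0.1, sIL6=0.3, dIL6=0.1,
                sNO=0.05, dNO=0.2, kD=1.0, xD6=1.0, xDNO=1.0, TImin=0.2,
                Emax=3.5, E50=0.5, gamma=2.0)
    base.update(over)
    return PhysiologyParams(**base)


class TestSeverityPresets:
    @pytest.mark.parametrize("label,count", [
        ("mild", 1.0e7),
        ("moderate", 5.0e7),
        ("severe", 2.5e8),
    ])
    def test_fixed_mapping(self, label, count):
        assert severity_to_count(label) == count

    def test_mapping_is_total(self):
        assert set(SEVERITY_PRESETS) == {"mild", "moderate", "severe"}

    def test_unknown_label_names_valid_ones(self):
        with pytest.raises(ConfigurationError, match="mild.*moderate.*severe"):
            severity_to_count("catastrophic")


class TestPathogenRate:
    def test_extinction_absorbing(self):
        p = make_params()
        assert pathogen_rate(0.0, 3.0, 1.0, p) == 0.0

    def test_logistic_equilibrium(self):
        p = make_params()
        assert pathogen_rate(p.K, 0.0, 0.0, p) == 0.0

    def test_half_capacity_growth(self):
        p = make_params(r=0.4)
        assert pathogen_rate(p.K / 2, 0.0, 0.0, p) == pytest.approx(0.1 * p.K, rel=1e-12)

    def test_negative_inputs_rejected(self):
        p = make_params()
        with pytest.raises(DomainError):
            pathogen_rate(-1.0, 0.0, 0.0, p)


class TestAntibioticKill:
    def test_no_drug_no_kill(self):
        assert antibiotic_kill_rate(0.0, make_params()) == 0.0

    def test_half_max_at_mic(self):
        p = make_params()
        assert antibiotic_kill_rate(p.MIC, p) == pytest.approx(p.Ekill / 2, rel=1e-12)

    def test_saturates_at_ekill(self):
        p = make_params()
        assert antibiotic_kill_rate(1e9 * p.MIC, p) == pytest.approx(p.Ekill, rel=1e-6)

    def test_monotone_in_concentration(self):
        p = make_params()
        cs = np.linspace(0, 20, 400)
        ks = [antibiotic_kill_rate(float(c), p) for c in cs]
        assert all(b >= a for a, b in zip(ks, ks[1:]))
        assert all(0.0 <= k <= p.Ekill for k in ks)

    def test_negative_concentration_rejected(self):
        with pytest.raises(DomainError):
            antibiotic_kill_rate(-0.5, make_params())


class TestMediatorRates:
    def test_healthy_rest_state_is_equilibrium(self):
        p = make_params()
        s = PatientState(t=0, P=0, M=0, IL6=0, NO=0, TI=1.0, V=1.0, Tcore=37.0)
        assert mediator_rates(s, p) == (0.0, 0.0, 0.0)

    def test_pure_decay_without_drive(self):
        p = make_params()
        c = 0.73
        s = PatientState(t=0, P=0, M=0, IL6=c, NO=0, TI=1.0, V=1.0, Tcore=37.0)
        dM, dIL6, dNO = mediator_rates(s, p)
        assert dIL6 == pytest.approx(-p.dIL6 * c, rel=1e-12)
        assert dNO == pytest.approx(p.sNO * c, rel=1e-12)

    def test_matches_independent_evaluation(self):
        # hand-coded oracle for the stated functional forms
        p = make_params()
        rng = np.random.default_rng(42)
        for _ in range(200):
            P = float(rng.uniform(0, p.K))
            M = float(rng.uniform(0, 5))
            IL6 = float(rng.uniform(0, 4))
            NO = float(rng.uniform(0, 4))
            TI = float(rng.uniform(p.TImin, 1.0))
            s = PatientState(t=0, P=P, M=M, IL6=IL6, NO=NO, TI=TI, V=1.0, Tcore=37.0)
            dM, dIL6, dNO = mediator_rates(s, p)
            assert dM == pytest.approx(p.sM * P / (P + p.K / 10) - p.dM * M, rel=1e-12)
            assert dIL6 == pytest.approx(p.sIL6 * (P / p.K + (1 - TI)) - p.dIL6 * IL6, rel=1e-12)
            assert dNO == pytest.approx(p.sNO * IL6 - p.dNO * NO, rel=1e-12)


def oracle_ti_rate(TI, IL6, NO, kD, TImin, xD6, xDNO):
    """Independent evaluation of the tissue-integrity expression."""
    return (kD * (1 - TI) * (TI - TImin)
            - kD * (TI - TImin) * (IL6**6 / (IL6**6 + xD6)) * (1 / (xDNO**2 + NO**2)))


class TestTissueIntegrityRate:
    def test_zero_at_floor_for_any_mediators(self):
        p = make_params()
        for il6, no in [(0, 0), (5, 0), (0, 5), (3, 3)]:
            assert tissue_integrity_rate(p.TImin, il6, no, p) == 0.0

    def test_zero_at_intact_tissue_without_il6(self):
        p = make_params()
        assert tissue_integrity_rate(1.0, 0.0, 0.0, p) == 0.0

    def test_printed_equation_arithmetic(self):
        # kD=1, TImin=0.2, TI=0.6, IL6^6=xD6, NO=0, xDNO=1:
        # 0.4*0.4 - 0.4*0.5*1 = -0.04
        p = make_params(kD=1.0, TImin=0.2, xD6=1.0, xDNO=1.0)
        il6 = 1.0  # IL6**6 == xD6
        assert tissue_integrity_rate(0.6, il6, 0.0, p) == pytest.approx(-0.04, rel=1e-12)

    def test_oracle_equivalence_on_random_tuples(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            timin = float(rng.uniform(0.05, 0.6))
            p = make_params(kD=float(rng.uniform(0.1, 5)), TImin=timin,
                            xD6=float(rng.uniform(0.1, 100)),
                            xDNO=float(rng.uniform(0.3, 3)))
            ti = float(rng.uniform(timin, 1.0))
            il6 = float(rng.uniform(0, 10))
            no = float(rng.uniform(0, 10))
            got = tissue_integrity_rate(ti, il6, no, p)
            want = oracle_ti_rate(ti, il6, no, p.kD, p.TImin, p.xD6, p.xDNO)
            assert got == pytest.approx(want, rel=1e-12, abs=1e-300)

    def test_monotone_in_il6_and_no(self):
        # more IL-6 never helps; more NO never hurts (as the damage term is written)
        p = make_params()
        ti = 0.7
        il6s = np.linspace(0, 5, 200)
        vals = [tissue_integrity_rate(ti, float(x), 0.5, p) for x in il6s]
        assert all(b <= a + 1e-15 for a, b in zip(vals, vals[1:]))
        nos = np.linspace(0, 5, 200)
        vals = [tissue_integrity_rate(ti, 2.0, float(x), p) for x in nos]
        assert all(b >= a - 1e-15 for a, b in zip(vals, vals[1:]))

    def test_out_of_domain_rejected(self):
        p = make_params()
        with pytest.raises(DomainError):
            tissue_integrity_rate(p.TImin - 0.05, 1.0, 1.0, p)
        with pytest.raises(DomainError):
            tissue_integrity_rate(1.05, 1.0, 1.0, p)


class TestFluidShift:
    def test_no_leak_with_intact_tissue(self):
        assert fluid_shift_rate(1.0, make_params()) == 0.0

    def test_maximal_leak_at_floor(self):
        p = make_params(kfluid=0.02)
        assert fluid_shift_rate(p.TImin, p) == pytest.approx(-0.02 * (1 - p.TImin))

    def test_infusion_adds(self):
        assert fluid_shift_rate(1.0, make_params(), fluids_rate=0.05) == 0.05


class TestStep:
    def test_healthy_equilibrium_preserved(self):
        p = make_params()
        s = PatientState.healthy(p)
        for _ in range(100):
            s = step(s, 1.0, p)
        assert (s.P, s.M, s.IL6, s.NO) == (0.0, 0.0, 0.0, 0.0)
        assert s.TI == 1.0 and s.V == 1.0
        assert s.Tcore == p.Tbase

    def test_rk4_order_via_richardson(self):
        # one step at dt vs two at dt/2: local error ratio ~ 2^4 as dt shrinks
        p = make_params()
        s0 = PatientState(t=0, P=1e6, M=0.5, IL6=0.8, NO=0.3, TI=0.9, V=0.99,
                          Tcore=37.5)
        errs = []
        for dt in (0.2, 0.1):
            one = step(s0, dt, p)
            half = step(step(s0, dt / 2, p), dt / 2, p)
            errs.append(abs(one.TI - half.TI))
        assert errs[1] < errs[0] / 8  # >= 3rd-order decay, RK4 gives ~16x

    def test_step_halving_on_moderate_preset(self, phys):
        s = PatientState.healthy(phys, severity_to_count("moderate"))
        t1 = integrate(s, phys, horizon=12.0, dt=0.02)
        t2 = integrate(s, phys, horizon=12.0, dt=0.01)
        assert np.max(np.abs(t1.TI - t2.TI)) < 1e-4

    def test_invalid_dt(self):
        p = make_params()
        with pytest.raises(DomainError):
            step(PatientState.healthy(p), 0.0, p)


class TestClassifyOutcome:
    def test_flat_healthy_trajectory_cleared(self):
        p = make_params()
        states = [PatientState(t=float(t), P=0, M=0, IL6=0, NO=0, TI=1.0, V=1.0,
                               Tcore=37.0) for t in range(10)]
        assert classify_outcome(Trajectory.from_states(states), p) == "cleared"

    def test_ti_pinned_at_floor_is_death(self):
        p = make_params()
        states = [PatientState(t=float(t) * 0.5, P=1e5, M=1, IL6=2, NO=0,
                               TI=p.TImin, V=0.9, Tcore=40.0) for t in range(10)]
        assert classify_outcome(Trajectory.from_states(states), p) == "septic_death"

    def test_brief_dip_is_not_death(self):
        p = make_params()
        tis = [1.0, 0.9, p.TImin, 0.9, 1.0]
        states = [PatientState(t=float(i) * 0.4, P=2e5, M=1, IL6=1, NO=0,
                               TI=ti, V=1.0, Tcore=38.0) for i, ti in enumerate(tis)]
        assert classify_outcome(Trajectory.from_states(states), p) == "ongoing"

    def test_empty_trajectory_rejected(self):
        with pytest.raises(UsageError):
            Trajectory.from_states([])


class TestParamValidation:
    def test_timin_bounds(self):
        with pytest.raises(ValueError):
            make_params(TImin=0.0)
        with pytest.raises(ValueError):
            make_params(TImin=1.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            make_params(r=-0.1)

    def test_unknown_field_rejected(self):
        with pytest.raises(Exception):
            make_params(bogus=1.0)
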