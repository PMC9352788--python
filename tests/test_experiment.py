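"""Schedules, dilution-corrected concentrations, peak integration, IO."""

import numpy as np
import pytest

import mvitc as mv
from mvitc.experiment import KCAL_PER_UCAL_PER_UMOL


class TestTotalConcentrations:
    def test_bivalent_first_injection_matches_closed_form(self, bivalent_conc):
        # frozen from exact rational evaluation of the dilution formulas
        assert bivalent_conc.l[0] == pytest.approx(4.8526857250582390e-4, rel=1e-12)
        assert bivalent_conc.m[0] == pytest.approx(7.0950779896013865e-2, rel=1e-12)
        assert len(bivalent_conc) == 14

    def test_trivalent_first_injection_matches_closed_form(self, trivalent_conc):
        assert trivalent_conc.l[0] == pytest.approx(6.7798951987242253e-4, rel=1e-12)

    def test_vanishing_injection_recovers_undiluted_cell(self):
        sched = mv.TitrationSchedule(V0=1.0, injection_volumes=[1e-12], c_L=1.0, c_M=0.5)
        conc = mv.total_concentrations(sched)
        assert conc.l[0] == pytest.approx(0.0, abs=1e-11)
        assert conc.m[0] == pytest.approx(0.5, rel=1e-10)

    def test_monotonicity(self, bivalent_conc, trivalent_conc):
        for conc in (bivalent_conc, trivalent_conc):
            assert np.all(np.diff(conc.l) > 0)
            assert np.all(np.diff(conc.m) < 0)

    def test_scale_consistency(self, bivalent_schedule):
        base = mv.total_concentrations(bivalent_schedule)
        doubled = mv.total_concentrations(mv.TitrationSchedule(
            V0=bivalent_schedule.V0,
            injection_volumes=bivalent_schedule.injection_volumes,
            c_L=2 * bivalent_schedule.c_L, c_M=2 * bivalent_schedule.c_M))
        np.testing.assert_allclose(doubled.l, 2 * base.l, rtol=1e-14)
        np.testing.assert_allclose(doubled.m, 2 * base.m, rtol=1e-14)

    def test_final_molar_ratio_passes_weighting_centre(self, bivalent_conc,
                                                       trivalent_conc):
        assert bivalent_conc.molar_ratio[-1] > 0.3
        assert trivalent_conc.molar_ratio[-1] > 0.3

    def test_overfull_schedule_rejected(self):
        with pytest.raises(ValueError, match="2\\*V0"):
            mv.TitrationSchedule(V0=0.05, injection_volumes=[0.06, 0.06],
                                 c_L=1.0, c_M=0.1)


def _flat_trace(T=3, window=100.0, samples=120, value=0.0):
    t = np.linspace(0.0, T * window, T * samples, endpoint=False)
    return mv.PowerTrace(time=t, power=np.full_like(t, value),
                         injection_times=np.arange(T) * window)


def _schedule(T=3, c_L=1.0, V=0.01):
    return mv.TitrationSchedule(V0=1.4, injection_volumes=[V] * T, c_L=c_L, c_M=0.1)


class TestIntegratePeaks:
    def test_zero_trace_gives_zero_heats(self):
        heats = mv.integrate_peaks(_flat_trace(), _schedule())
        np.testing.assert_allclose(heats.q, 0.0, atol=1e-12)

    def test_rectangular_pulse_closed_form(self):
        # pulse of height h, width w inside window 1 -> q_1 = h*w / (c_L*V) * 1e-3
        sched = _schedule()
        trace = _flat_trace()
        t = trace.time
        h, w = 5.0, 20.0
        box = (t >= 130.0) & (t < 130.0 + w)
        power = np.zeros_like(t)
        power[box] = h
        trace = mv.PowerTrace(time=t, power=power, injection_times=trace.injection_times)
        heats = mv.integrate_peaks(trace, sched, baseline="none")
        expected = h * w / (sched.c_L * 0.01) * KCAL_PER_UCAL_PER_UMOL
        # spline integration of a discontinuous box is exact only up to
        # the sample spacing at the edges
        assert heats.q[1] == pytest.approx(expected, rel=2e-2)
        assert heats.q[0] == pytest.approx(0.0, abs=1e-10)
        assert heats.q[2] == pytest.approx(0.0, abs=1e-10)

    def test_exponential_peaks_closed_form(self):
        # A*exp(-(t-t_i)/tau) per window -> integral A*tau*(1-exp(-D/tau))
        T, window, samples = 3, 100.0, 2000
        sched = _schedule(T=T)
        t = np.linspace(0.0, T * window, T * samples, endpoint=False)
        tau, A = 8.0, (3.0, -1.5, 0.25)
        power = np.zeros_like(t)
        for i in range(T):
            sel = (t >= i * window) & (t < (i + 1) * window)
            power[sel] = A[i] * np.exp(-(t[sel] - i * window) / tau)
        trace = mv.PowerTrace(time=t, power=power,
                              injection_times=np.arange(T) * window)
        heats = mv.integrate_peaks(trace, sched, baseline="none")
        for i in range(T):
            exact = A[i] * tau * (1 - np.exp(-window / tau))
            expected = exact / (sched.c_L * 0.01) * KCAL_PER_UCAL_PER_UMOL
            # window end falls one sample short of the analytic upper limit
            assert heats.q[i] == pytest.approx(expected, rel=1e-3)

    def test_additivity(self):
        rng = np.random.default_rng(0)
        sched = _schedule()
        base = _flat_trace()
        p1 = rng.normal(size=base.time.size)
        p2 = rng.normal(size=base.time.size)
        q1 = mv.integrate_peaks(mv.PowerTrace(base.time, p1, base.injection_times),
                                sched, baseline="none").q
        q2 = mv.integrate_peaks(mv.PowerTrace(base.time, p2, base.injection_times),
                                sched, baseline="none").q
        q12 = mv.integrate_peaks(mv.PowerTrace(base.time, p1 + p2, base.injection_times),
                                 sched, baseline="none").q
        np.testing.assert_allclose(q12, q1 + q2, rtol=1e-8, atol=1e-10)

    def test_linear_baseline_removes_drift(self):
        # a purely linear drift integrates to zero after baseline removal
        sched = _schedule()
        base = _flat_trace()
        drift = 0.02 * base.time - 1.0
        heats = mv.integrate_peaks(
            mv.PowerTrace(base.time, drift, base.injection_times), sched)
        np.testing.assert_allclose(heats.q, 0.0, atol=1e-8)

    def test_too_few_samples_rejected(self):
        t = np.array([0.0, 1.0, 2.0, 50.0, 60.0, 70.0, 80.0, 90.0, 95.0, 99.0])
        trace = mv.PowerTrace(time=t, power=np.zeros_like(t),
                              injection_times=np.array([0.0, 50.0]))
        sched = mv.TitrationSchedule(V0=1.4, injection_volumes=[0.01, 0.01],
                                     c_L=1.0, c_M=0.1)
        with pytest.raises(ValueError, match="degree-5 spline"):
            mv.integrate_peaks(trace, sched)


class TestIO:
    def test_heats_round_trip(self, tmp_path, bivalent_schedule, bivalent_qc_heats):
        cfg, csv = tmp_path / "cfg.json", tmp_path / "heats.csv"
        mv.write_experiment(cfg, csv, bivalent_schedule, bivalent_qc_heats)
        sched, heats = mv.read_experiment(cfg, csv)
        assert sched.T_inj == bivalent_schedule.T_inj
        assert sched.valency == 2
        np.testing.assert_array_equal(heats.q, bivalent_qc_heats.q)

    def test_power_trace_round_trip(self, tmp_path):
        sched = _schedule()
        trace = _flat_trace(value=1.5)
        cfg, csv = tmp_path / "cfg.json", tmp_path / "trace.csv"
        mv.write_experiment(cfg, csv, sched, trace)
        _, back = mv.read_experiment(cfg, csv)
        np.testing.assert_array_equal(back.time, trace.time)
        np.testing.assert_array_equal(back.power, trace.power)
        np.testing.assert_array_equal(back.injection_times, trace.injection_times)

    def test_negative_injection_volume_rejected(self, tmp_path):
        cfg = tmp_path / "cfg.json"
        cfg.write_text('{"V0_ml": 1.4, "c_L_mmol_per_l": 1.0, '
                       '"c_M_mmol_per_l": 0.1, "injection_volumes_ml": [0.01, -0.01]}')
        heats = tmp_path / "heats.csv"
        heats.write_text("injection,q_kcal_per_mol\n1,-1.0\n2,-0.5\n")
        with pytest.raises(ValueError, match="not positive"):
            mv.read_experiment(cfg, heats)

    def test_missing_field_reported_by_name(self, tmp_path):
        cfg = tmp_path / "cfg.json"
        cfg.write_text('{"V0_ml": 1.4}')
        with pytest.raises(ValueError, match="c_L_mmol_per_l"):
            mv.read_experiment(cfg, cfg)

    def test_heat_count_must_match_schedule(self, tmp_path):
        cfg = tmp_path / "cfg.json"
        cfg.write_text('{"V0_ml": 1.4, "c_L_mmol_per_l": 1.0, '
                       '"c_M_mmol_per_l": 0.1, "injection_volumes_ml": [0.01, 0.01]}')
        heats = tmp_path / "heats.csv"
        heats.write_text("injection,q_kcal_per_mol\n1,-1.0\n")
        with pytest.raises(ValueError, match="injection 2"):
            mv.read_experiment(cfg, heats)
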