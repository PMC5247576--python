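"""Reporter circuit: synthesis saturation, ssrA decay, deconvolution."""

import math

import numpy as np
import pytest

from electrogenetics import circuit as cm
from electrogenetics import electrochem as ec


@pytest.fixture
def params():
    return cm.CircuitParams()


class TestSynthesisRate:
    def test_no_pyocyanin_no_synthesis(self, params):
        p = cm.CircuitParams(pyo=0.0)
        for f in (0.0, 0.5, 1.0):
            assert cm.synthesis_rate(f, p) == 0.0

    def test_reduced_pool_gives_basal_only(self):
        p = cm.CircuitParams(pyo=1e6)  # saturating inducer
        assert cm.synthesis_rate(0.0, p) == pytest.approx(p.s0, rel=1e-5)

    def test_half_saturation(self):
        p = cm.CircuitParams(pyo=1e6, K_fcn=0.5)
        assert cm.synthesis_rate(0.5, p) == pytest.approx(p.s0 + p.s_max / 2,
                                                          rel=1e-5)

    def test_out_of_range_fraction_rejected(self, params):
        with pytest.raises(ValueError):
            cm.synthesis_rate(1.5, params)


class TestSimulateExpression:
    def test_no_degradation_monotone_growth(self):
        p = cm.CircuitParams(k_deg=0.0)
        sched = ec.SignalSchedule([(0.5, 3600.0)])
        res = cm.simulate_expression(sched, p)
        P = res.trace.fluorescence
        assert np.all(np.diff(P) > 0)
        # asymptotically linear: late slope matches the saturated rate
        late = (P[-1] - P[-601]) / 600.0
        assert late == pytest.approx(cm.synthesis_rate(res.frac_ox[-1], p),
                                     rel=0.01)

    def test_steady_state_closed_form(self, params):
        k = params.k_deg
        sched = ec.SignalSchedule([(0.5, 6.0 / k)])
        res = cm.simulate_expression(sched, params)
        s_inf = cm.synthesis_rate(res.frac_ox[-1], params)
        assert res.trace.fluorescence[-1] == pytest.approx(s_inf / k, rel=0.01)

    def test_halving_k_deg_doubles_plateau(self, params):
        sched = ec.SignalSchedule([(0.5, 8.0 / params.k_deg)])
        p_half = cm.CircuitParams(k_deg=params.k_deg / 2)
        hi = cm.simulate_expression(sched, p_half).trace.fluorescence[-1]
        lo = cm.simulate_expression(sched, params).trace.fluorescence[-1]
        assert hi / lo == pytest.approx(2.0, rel=0.02)

    def test_repeated_cycles_reproducible_peaks(self, params):
        # hour-long ON/OFF cycling: cells fluoresce similarly after each ON
        segs = [(0.5, 3600.0), (-0.3, 3600.0)] * 4
        res = cm.simulate_expression(ec.SignalSchedule(segs), params)
        t = res.trace.times
        P = res.trace.fluorescence
        peaks = []
        for c in range(1, 4):  # skip the start-up cycle
            sel = (t >= 7200.0 * c) & (t <= 7200.0 * c + 3600.0)
            peaks.append(P[sel].max())
        assert np.ptp(peaks) / np.mean(peaks) < 0.10

    def test_nonnegative_fluorescence(self, params):
        segs = [(0.5, 600.0), (-0.3, 2400.0), (0.5, 300.0)]
        res = cm.simulate_expression(ec.SignalSchedule(segs), params)
        assert np.all(res.trace.fluorescence >= 0)


class TestIntegratedSynthesis:
    def test_zero_degradation_identity(self):
        t = np.linspace(0, 1000, 201)
        P = 3.0 + 0.01 * t
        trace = cm.ExpressionTrace(times=t, fluorescence=P)
        S = cm.integrated_synthesis(trace, k_deg=0.0)
        assert np.allclose(S, P - P[0])

    def test_constant_synthesis_recovery(self):
        # P(t) = s/k (1 - e^{-kt}) closed form; recovered S should be s*t
        s, k = 0.4, math.log(2) / 1500
        t = np.linspace(0, 7200, 7201)
        P = s / k * (1 - np.exp(-k * t))
        S = cm.integrated_synthesis(cm.ExpressionTrace(times=t, fluorescence=P), k)
        assert np.max(np.abs(S[1:] - s * t[1:]) / (s * t[-1])) < 0.01

    def test_roundtrip_against_simulator_truth(self, params):
        segs = [(0.5, 1200.0), (-0.3, 1800.0), (0.4, 900.0), (None, 1800.0)]
        res = cm.simulate_expression(ec.SignalSchedule(segs), params)
        S = cm.integrated_synthesis(res.trace, params.k_deg)
        err = np.max(np.abs(S - res.true_synthesis)) / res.true_synthesis.max()
        assert err < 0.01

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            cm.integrated_synthesis(
                cm.ExpressionTrace(times=np.array([0.0]),
                                   fluorescence=np.array([1.0])), 1e-3)


class TestChargeSynthesisRelation:
    CHARGES = [-0.05, -0.1, -0.18, -0.27, -0.38, -0.5]

    def test_zero_charge_gives_basal_synthesis(self, params):
        res = cm.charge_synthesis_relation([0.0, -0.1, -0.2], params,
                                           horizon=7200.0)
        basal = cm.synthesis_rate(0.0, params) * 7200.0
        assert res.synthesis[0] == pytest.approx(basal, rel=0.01)

    def test_linear_with_high_r_squared(self, params):
        res = cm.charge_synthesis_relation(self.CHARGES, params)
        assert res.slope > 0
        assert res.r_squared > 0.99

    def test_duration_and_potential_sweeps_agree(self, params):
        # equal charges delivered either way induce the same synthesis:
        # the charge, not the voltage or its duration, is what matters
        rd = cm.charge_synthesis_relation(self.CHARGES, params, mode="duration")
        rp = cm.charge_synthesis_relation(self.CHARGES, params, mode="potential")
        assert np.all(np.abs(rd.synthesis - rp.synthesis) / rd.synthesis < 0.05)

    def test_unreachable_charge_rejected(self, params):
        with pytest.raises(ValueError):
            cm.charge_synthesis_relation([-0.5, -1.0, -2.0], params)

    def test_fewer_than_three_charges_rejected(self, params):
        with pytest.raises(ValueError):
            cm.charge_synthesis_relation([-0.1, -0.2], params)


class TestCycleExperiment:
    CYCLES = [1800.0, 3600.0, 5400.0, 7200.0, 10800.0]

    def test_half_cycle_fluorescence_monotone(self, params):
        res = cm.cycle_experiment(self.CYCLES, params)
        half = [r.half_cycle_fluor for r in res]
        assert np.all(np.diff(half) >= 0)

    def test_no_degradation_no_end_drop(self):
        p = cm.CircuitParams(k_deg=0.0)
        for r in cm.cycle_experiment(self.CYCLES, p):
            assert r.end_cycle_fluor >= r.half_cycle_fluor * (1 - 1e-9)

    def test_longer_cycles_decay_more(self, params):
        # short cycles leave cells exposed to the oxidized mediator most of
        # the time; long OFF phases let ssrA degradation dominate
        res = cm.cycle_experiment([1800.0, 10800.0], params)
        decays = [(r.half_cycle_fluor - r.end_cycle_fluor) / r.half_cycle_fluor
                  for r in res]
        assert decays[1] > decays[0]


class TestFitDegradationRate:
    def test_exact_recovery_noiseless(self):
        k = 5e-4
        t = np.arange(0, 3000.0, 60.0)
        P = 800.0 * np.exp(-k * t)
        fit = cm.fit_degradation_rate(cm.ExpressionTrace(times=t, fluorescence=P),
                                      off_start=0.0)
        assert fit.k_deg == pytest.approx(k, rel=1e-6)
        assert fit.stderr < 1e-9

    def test_constant_trace_gives_zero(self):
        t = np.arange(0, 600.0, 60.0)
        fit = cm.fit_degradation_rate(
            cm.ExpressionTrace(times=t, fluorescence=np.full(10, 500.0)), 0.0)
        assert fit.k_deg == pytest.approx(0.0, abs=1e-12)
        assert fit.stderr == pytest.approx(0.0, abs=1e-12)

    def test_noisy_recovery_within_ten_percent(self):
        k = math.log(2) / 1500
        t = np.arange(0.0, 3000.0, 100.0)
        rng = np.random.default_rng(7)
        errs = []
        for _ in range(100):
            P = 800.0 * np.exp(-k * t) * (1 + 0.05 * rng.standard_normal(t.size))
            fit = cm.fit_degradation_rate(
                cm.ExpressionTrace(times=t, fluorescence=np.clip(P, 1e-9, None)),
                off_start=0.0)
            errs.append(abs(fit.k_deg - k) / k)
        assert np.median(errs) < 0.10

    def test_nonpositive_values_rejected(self):
        t = np.arange(0, 600.0, 60.0)
        P = np.full(10, 1.0)
        P[4] = 0.0
        with pytest.raises(ValueError):
            cm.fit_degradation_rate(cm.ExpressionTrace(times=t, fluorescence=P), 0.0)

    def test_too_few_samples_rejected(self):
        t = np.array([0.0, 60.0, 120.0])
        with pytest.raises(ValueError):
            cm.fit_degradation_rate(
                cm.ExpressionTrace(times=t, fluorescence=np.ones(3)), 0.0)
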