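import numpy as np
import pytest

import helipol as hp
from helipol.binding import hill_curve
from helipol.fluorescence import FluorescenceError, multi_exp_curve
from helipol.simulate import emit_two_exp_trace, make_split_timebase


def _trace(signal, time=None, segment=None):
    if time is None:
        time, segment = make_split_timebase()
    return hp.FluorTrace(time=time, signal=signal, segment=segment)


class TestAverageTraces:
    def test_averaging_identical_traces_is_identity(self):
        tr = emit_two_exp_trace(-0.3, 0.5, -0.2, 2e-3, 1.5, noise_sd=0.0, seed=0)
        avg = hp.average_traces([tr, tr])
        np.testing.assert_allclose(avg.signal, tr.signal)

    def test_symmetric_deviations_cancel(self):
        t, seg = make_split_timebase()
        m = np.full(t.size, 2.0)
        dev = np.sin(t)
        avg = hp.average_traces([_trace(m + dev), _trace(m - dev)])
        np.testing.assert_allclose(avg.signal, m, atol=1e-12)

    def test_variance_shrinks_as_replicate_count(self):
        """Averaging 7 noisy replicates cuts the residual sd ~ sqrt(7)-fold."""
        t, seg = make_split_timebase()
        truth = multi_exp_curve(t, [-0.3, -0.2], [0.5, 2e-3], 1.5)
        rng = np.random.default_rng(42)
        traces = [_trace(truth + rng.normal(0, 0.01, t.size)) for _ in range(7)]
        avg = hp.average_traces(traces)
        sd_single = np.std(traces[0].signal - truth)
        sd_avg = np.std(avg.signal - truth)
        assert sd_avg == pytest.approx(sd_single / np.sqrt(7), rel=0.25)

    def test_grid_mismatch_rejected(self):
        t1, s1 = make_split_timebase(((10.0, 100), (300.0, 50)))
        t2, s2 = make_split_timebase(((10.0, 100), (200.0, 50)))
        with pytest.raises(FluorescenceError, match="grid"):
            hp.average_traces([
                hp.FluorTrace(time=t1, signal=np.ones(150), segment=s1),
                hp.FluorTrace(time=t2, signal=np.ones(150), segment=s2),
            ])


class TestMultiExponentialFit:
    def test_noiseless_two_phase_exact_recovery(self):
        tr = emit_two_exp_trace(-0.5, 0.5, -0.2, 1.5e-3, 1.7, noise_sd=0.0, seed=0)
        fit = hp.fit_multi_exponential(tr, 2)
        assert fit.fast_phase.rate == pytest.approx(0.5, rel=1e-6)
        assert fit.slow_phase.rate == pytest.approx(1.5e-3, rel=1e-6)
        assert fit.fast_phase.amplitude == pytest.approx(-0.5, rel=1e-6)
        assert fit.slow_phase.amplitude == pytest.approx(-0.2, rel=1e-6)

    def test_phases_ordered_fast_to_slow(self):
        tr = emit_two_exp_trace(-0.5, 0.5, 0.2, 1.5e-3, 1.5, noise_sd=0.005, seed=1)
        fit = hp.fit_multi_exponential(tr, 2)
        assert fit.phases[0].rate > fit.phases[-1].rate

    def test_nested_model_null_second_phase(self):
        """Fitting 2 exponentials to 1-phase data leaves an insignificant phase."""
        t, seg = make_split_timebase(((10.0, 400), (2000.0, 400)))
        rng = np.random.default_rng(3)
        v = 1.0 - 0.4 * np.exp(-0.01 * t) + rng.normal(0, 0.01, t.size)
        fit = hp.fit_multi_exponential(_trace(v, t, seg), 2)
        t_ratios = [abs(p.amplitude) / p.amplitude_se for p in fit.phases]
        assert fit.degenerate or min(t_ratios) <= 2.0

    def test_direction_convention_negative_amplitude_rises(self):
        tr = emit_two_exp_trace(-0.3, 0.5, 0.2, 1.5e-3, 1.5, noise_sd=0.0, seed=0)
        fit = hp.fit_multi_exponential(tr, 2)
        assert fit.fast_phase.direction is hp.PhaseDirection.INCREASE
        assert fit.slow_phase.direction is hp.PhaseDirection.DECREASE

    def test_uniform_density_weights_match_single_segment(self):
        """Split-segment fitting equals one-segment fitting at uniform sampling."""
        n = 400
        t = np.linspace(0.05, 20.0, n)
        rng = np.random.default_rng(8)
        v = 1.0 - 0.5 * np.exp(-0.4 * t) + rng.normal(0, 0.005, n)
        seg_one = np.zeros(n, dtype=int)
        seg_two = np.where(t < 10.0, 0, 1)
        fit1 = hp.fit_multi_exponential(hp.FluorTrace(time=t, signal=v, segment=seg_one), 1)
        fit2 = hp.fit_multi_exponential(hp.FluorTrace(time=t, signal=v, segment=seg_two), 1)
        assert fit2.fast_phase.rate == pytest.approx(fit1.fast_phase.rate, rel=1e-3)
        assert fit2.fast_phase.amplitude == pytest.approx(fit1.fast_phase.amplitude, rel=1e-3)

    def test_phase_direction_self_consistency(self):
        """simulate -> fit recovers the simulated slow-phase sign (20 seeded runs)."""
        cond_rise = hp.ConditionDescriptor(
            label_site="N_terminus", block=True, substrate_class="fork_3long"
        )
        cond_fall = hp.ConditionDescriptor(
            label_site="C682", block=True, substrate_class="fork_3long"
        )
        correct = 0
        for seed in range(10):
            for cond, expected in ((cond_rise, hp.PhaseDirection.INCREASE),
                                   (cond_fall, hp.PhaseDirection.DECREASE)):
                tr, _ = hp.simulate_fret_trace(
                    cond, "N_first", fast=(0.2, 0.26), slow_rate=1.5e-3,
                    timebase=((10.0, 400), (3000.0, 400)), seed=100 + seed,
                )
                fit = hp.fit_multi_exponential(tr, 2)
                correct += fit.slow_phase.direction is expected
        assert correct >= 19

    def test_rate_recovery_in_separated_regime(self):
        """k1/k2 >= 100: both rates within 20% in >= 90% of seeded runs."""
        cond = hp.ConditionDescriptor(
            label_site="N_terminus", block=True, substrate_class="fork_3long"
        )
        ok = 0
        for seed in range(20):
            tr, _ = hp.simulate_fret_trace(
                cond, "N_first", fast=(0.2, 0.3), slow_rate=2e-3,
                timebase=((10.0, 400), (2000.0, 400)), seed=300 + seed,
            )
            fit = hp.fit_multi_exponential(tr, 2)
            ok += (
                abs(fit.fast_phase.rate - 0.3) / 0.3 < 0.2
                and abs(fit.slow_phase.rate - 2e-3) / 2e-3 < 0.2
            )
        assert ok >= 18


class TestOrderSelection:
    def test_single_phase_truth_selects_order_one(self):
        t, seg = make_split_timebase()
        chosen = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            v = 1.0 - 0.5 * np.exp(-0.3 * t) + rng.normal(0, 0.01, t.size)
            order, _ = hp.select_exponential_order(_trace(v, t, seg))
            chosen.append(order)
        assert np.mean(np.asarray(chosen) == 1) >= 0.95

    def test_two_phase_truth_selects_order_two(self):
        tr = emit_two_exp_trace(
            -0.3, 0.5, -0.4, 2e-3, 1.7,
            timebase=((10.0, 400), (2000.0, 400)), noise_sd=0.01, seed=21,
        )
        order, fits = hp.select_exponential_order(tr)
        assert order == 2
        assert 1 in fits and 2 in fits

    def test_flat_trace_falls_back_to_order_one(self):
        t, seg = make_split_timebase()
        rng = np.random.default_rng(2)
        v = 1.0 + rng.normal(0, 0.01, t.size)
        order, fits = hp.select_exponential_order(_trace(v, t, seg))
        assert order == 1
        assert abs(fits[1].fast_phase.amplitude) < 0.05


class TestNormalizeQuench:
    def test_pure_background_gives_zero_quench(self):
        c = np.linspace(0, 500, 6)
        s = 100.0 - 0.02 * c
        np.testing.assert_allclose(hp.normalize_quench(c, s, s), 0.0, atol=1e-12)

    def test_definition_without_background_drift(self):
        c = np.array([0.0, 100.0, 200.0])
        q_true = np.array([0.0, 0.2, 0.35])
        s_lab = 50.0 * (1 - q_true)
        s_unlab = np.full(3, 80.0)
        np.testing.assert_allclose(hp.normalize_quench(c, s_lab, s_unlab), q_true)

    def test_c_label_quench_deeper_when_c_at_duplex_dominates(self):
        """With a C@duplex-rich population the C-terminal dye sits nearer the
        reporter, so its quench curve lies above the N-terminal one at every
        concentration."""
        c = np.linspace(0, 1000, 9)
        occupancy = hill_curve(c, 1.0, 150.0, 2.0)
        f_c_at_duplex = 0.77
        depth = {"C": 0.5 * f_c_at_duplex + 0.1 * (1 - f_c_at_duplex),
                 "N": 0.1 * f_c_at_duplex + 0.5 * (1 - f_c_at_duplex)}
        s_unlab = 90.0 - 0.002 * c
        curves = {}
        for label in ("C", "N"):
            s_lab = 70.0 * (1 - depth[label] * occupancy) + (s_unlab - s_unlab[0])
            curves[label] = hp.normalize_quench(c, s_lab, s_unlab)
        assert np.all(curves["C"][1:] > curves["N"][1:])
        assert curves["C"][0] == curves["N"][0] == 0.0

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(FluorescenceError, match="positive"):
            hp.normalize_quench([0, 1], [0.0, 1.0], [1.0, 1.0])
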