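import numpy as np
import pytest

import helipol as hp
from helipol.simulate import (
    Arm,
    Direction,
    Orientation,
    SimulationError,
    emit_two_exp_trace,
    make_split_timebase,
    slow_phase_direction,
)


class TestBindingPopulation:
    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(SimulationError, match="sum to 1"):
            hp.BindingPopulation(
                probabilities={(Arm.ARM3, Orientation.N_AT_DUPLEX): 0.4}, unbound=0.0
            )

    def test_productive_fraction_follows_rule(self):
        pop = hp.BindingPopulation(
            probabilities={
                (Arm.ARM3, Orientation.N_AT_DUPLEX): 0.3,
                (Arm.ARM3, Orientation.C_AT_DUPLEX): 0.5,
                (Arm.ARM5, Orientation.N_AT_DUPLEX): 0.2,
            }
        )
        # only 3'-arm-loaded hexamers lead into the duplex
        assert pop.productive_fraction(Direction.N_FIRST) == pytest.approx(0.3)
        assert pop.productive_fraction(Direction.C_FIRST) == pytest.approx(0.5)


class TestCleavageProfiles:
    def test_single_configuration_mass_confined_to_n_region(
        self, equal_arm, equal_arm_regions
    ):
        pop = hp.orientation_population(1.0)  # all N@duplex on the 3'-arm
        lanes, ctrl, _ = hp.simulate_cleavage_profiles(
            equal_arm, equal_arm_regions, pop, noise_cv=0.0, n_replicates=1, seed=0
        )
        corrected = hp.background_subtract(lanes[0], ctrl)
        inside = corrected.intensities[equal_arm_regions.region_slice("N")].sum()
        assert inside / corrected.intensities.sum() > 0.99

    def test_all_unbound_population_matches_control(self, equal_arm, equal_arm_regions):
        pop = hp.BindingPopulation(probabilities={}, unbound=1.0)
        lanes, ctrl, _ = hp.simulate_cleavage_profiles(
            equal_arm, equal_arm_regions, pop, noise_cv=0.0, n_replicates=1, seed=0
        )
        corrected = hp.background_subtract(lanes[0], ctrl)
        assert corrected.intensities.sum() == pytest.approx(0.0)

    def test_mixture_linearity_in_n_region(self, equal_arm, equal_arm_regions):
        """Noise-free region mass is affine in the N@duplex probability."""
        masses = []
        for p in (0.0, 0.5, 1.0):
            pop = hp.orientation_population(p)
            lanes, ctrl, _ = hp.simulate_cleavage_profiles(
                equal_arm, equal_arm_regions, pop, noise_cv=0.0, n_replicates=1, seed=0
            )
            corrected = hp.background_subtract(lanes[0], ctrl)
            masses.append(corrected.intensities[equal_arm_regions.region_slice("N")].sum())
        assert masses[1] == pytest.approx((masses[0] + masses[2]) / 2, rel=1e-9)

    def test_footprint_stage_recovers_equal_arm_population(
        self, equal_arm, equal_arm_regions
    ):
        """Generated lanes at aggregate P(N@duplex)=0.23 recover F_N within 2 SE."""
        pop = hp.orientation_population(0.23)
        lanes, ctrl, _ = hp.simulate_cleavage_profiles(
            equal_arm, equal_arm_regions, pop, n_replicates=5, noise_cv=0.10, seed=1
        )
        res = hp.analyze_replicates(lanes, ctrl, equal_arm_regions)
        assert abs(res.mean_f_n - 0.23) < 2 * res.se_f_n

    def test_seed_determinism(self, equal_arm, equal_arm_regions):
        pop = hp.orientation_population(0.4)
        a = hp.simulate_cleavage_profiles(equal_arm, equal_arm_regions, pop, seed=9)
        b = hp.simulate_cleavage_profiles(equal_arm, equal_arm_regions, pop, seed=9)
        for lane_a, lane_b in zip(a[0] + [a[1]], b[0] + [b[1]]):
            np.testing.assert_array_equal(lane_a.intensities, lane_b.intensities)


class TestUnwindingTimecourse:
    def test_zero_productive_fraction_gives_flat_series(self):
        pop = hp.orientation_population(0.0)  # no N@duplex => nothing productive
        tc, _ = hp.simulate_unwinding_timecourse(pop, "N_first", k=0.1, noise_sd=0.0, seed=0)
        _, f = hp.fraction_unwound(tc)
        np.testing.assert_allclose(f, 0.0, atol=1e-12)

    def test_closed_form_fraction_at_one_lifetime(self):
        pop = hp.orientation_population(1.0)
        tc, _ = hp.simulate_unwinding_timecourse(
            pop, "N_first", k=0.1, times=[0.0, 5.0, 10.0, 20.0], noise_sd=0.0, seed=0
        )
        t, f = hp.fraction_unwound(tc)
        assert f[2] == pytest.approx(1.0 - np.exp(-1.0), rel=1e-9)

    def test_band_conservation_without_noise(self):
        pop = hp.orientation_population(0.6)
        tc, _ = hp.simulate_unwinding_timecourse(pop, "N_first", k=0.05, noise_sd=0.0, seed=0)
        totals = tc.i_ss + tc.i_ds
        np.testing.assert_allclose(totals, totals[0])

    def test_nonincreasing_times_rejected(self):
        pop = hp.orientation_population(0.5)
        with pytest.raises(SimulationError, match="strictly increasing"):
            hp.simulate_unwinding_timecourse(pop, "N_first", k=0.1, times=[0, 5, 5], seed=0)

    def test_seed_determinism(self):
        pop = hp.orientation_population(0.5)
        a, _ = hp.simulate_unwinding_timecourse(pop, "N_first", k=0.07, seed=11)
        b, _ = hp.simulate_unwinding_timecourse(pop, "N_first", k=0.07, seed=11)
        np.testing.assert_array_equal(a.i_ss, b.i_ss)
        np.testing.assert_array_equal(a.i_ds, b.i_ds)


class TestAnisotropySeries:
    def test_half_saturation_identity(self):
        for n in (0.5, 1.0, 2.0, 4.0):
            ser = hp.simulate_anisotropy_series(
                0.2, 150.0, n, [10.0, 150.0, 1000.0], noise_sd=0.0, seed=0
            )
            assert ser.anisotropy[1] == pytest.approx(0.1, rel=1e-12)

    def test_zero_concentration_gives_zero(self):
        ser = hp.simulate_anisotropy_series(0.2, 150.0, 2.0, [0.0, 150.0], noise_sd=0.0, seed=0)
        assert ser.anisotropy[0] == 0.0

    def test_empty_concentrations_rejected(self):
        with pytest.raises(SimulationError, match="empty"):
            hp.simulate_anisotropy_series(0.2, 150.0, 2.0, [], seed=0)


class TestFretTrace:
    @pytest.mark.parametrize(
        "label,truth,expected_sign",
        [
            ("N_terminus", "N_first", 1),   # labelled face leads: slow rise
            ("C682", "N_first", -1),        # trailing face label: slow fall
            ("C682", "C_first", 1),
            ("N_terminus", "C_first", -1),
        ],
    )
    def test_blocked_slow_phase_direction_table(self, label, truth, expected_sign):
        cond = hp.ConditionDescriptor(
            label_site=label, block=True, substrate_class="fork_3long"
        )
        assert slow_phase_direction(cond, Direction(truth)) == expected_sign

    def test_unblocked_always_falls(self):
        for label in ("N_terminus", "C682"):
            cond = hp.ConditionDescriptor(
                label_site=label, block=False, substrate_class="fork_3long"
            )
            assert slow_phase_direction(cond, Direction.N_FIRST) == -1

    def test_no_atp_has_no_slow_phase(self):
        cond = hp.ConditionDescriptor(
            label_site="N_terminus", block=True, substrate_class="fork_3long", atp=False
        )
        trace, truth = hp.simulate_fret_trace(
            cond, "N_first", fast=(0.3, 0.5), slow_rate=1.5e-3, seed=4
        )
        assert truth.kinetics["slow_sign"] == 0
        fit = hp.fit_multi_exponential(trace, 2)
        # the second phase is statistically null
        t_ratios = [abs(p.amplitude) / p.amplitude_se for p in fit.phases]
        assert min(t_ratios) <= 2.0 or fit.degenerate

    def test_split_timebase_segments_contiguous(self):
        t, seg = make_split_timebase(((10.0, 100), (300.0, 50)))
        assert t.size == 150
        assert np.all(np.diff(t) > 0)
        assert set(np.unique(seg)) == {0, 1}

    def test_seed_determinism(self):
        a = emit_two_exp_trace(-0.3, 0.5, -0.2, 1e-3, 1.5, seed=2)
        b = emit_two_exp_trace(-0.3, 0.5, -0.2, 1e-3, 1.5, seed=2)
        np.testing.assert_array_equal(a.signal, b.signal)
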