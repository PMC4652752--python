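import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import replichore as rp
from replichore.synthetic_data import UnreachableRegionError


def single_origin(length=10_000, pos=0, **kw):
    return rp.ChromosomeConfig(length_bp=length, origins=[rp.Origin("o", pos)], **kw)


PARAMS = dict(fork_speed_bp_per_s=1000.0, bin_width_bp=1000)


class TestReplicationTiming:
    def test_symmetric_single_origin(self):
        t = rp.simulate_replication_timing(single_origin(), rp.SimulationParams(**PARAMS))
        assert np.array_equal(t.t_rep, [0, 1, 2, 3, 4, 5, 4, 3, 2, 1])
        assert t.termination_positions == [5000.0]
        fusion = [e for e in t.events if e["event"] == "fusion"][0]
        assert fusion["time_s"] == 5.0

    def test_polar_trap_reroutes_fork(self):
        cfg = single_origin(ter_sites=[rp.TerSite("t", 3000, "blocks_clockwise")])
        t = rp.simulate_replication_timing(cfg, rp.SimulationParams(**PARAMS))
        # t_rep(x) = x up to the trap, 10 - x beyond (counterclockwise fork)
        assert np.array_equal(t.t_rep, [0, 1, 2, 3, 6, 5, 4, 3, 2, 1])
        assert t.termination_positions == [3000.0]
        fusion = [e for e in t.events if e["event"] == "fusion"][0]
        assert fusion["time_s"] == 7.0

    def test_trap_transparent_without_tus(self):
        cfg = single_origin(ter_sites=[rp.TerSite("t", 3000, "blocks_clockwise")])
        t = rp.simulate_replication_timing(cfg, rp.SimulationParams(tus_active=False, **PARAMS))
        assert np.array_equal(t.t_rep, [0, 1, 2, 3, 4, 5, 4, 3, 2, 1])

    def test_two_simultaneous_origins(self):
        cfg = rp.ChromosomeConfig(
            length_bp=10_000, origins=[rp.Origin("a", 0), rp.Origin("b", 5000)]
        )
        t = rp.simulate_replication_timing(cfg, rp.SimulationParams(**PARAMS))
        assert sorted(t.termination_positions) == [2500.0, 7500.0]
        assert np.array_equal(t.t_rep, [0, 1, 2, 2, 1, 0, 1, 2, 2, 1])
        assert max(e["time_s"] for e in t.events if e["event"] == "fusion") == 2.5

    def test_no_trap_timing_equals_distance_over_speed(self):
        """Oracle equivalence: t_rep = circular_distance(origin, x) / v."""
        cfg = single_origin(length=100_000, pos=37_000)
        t = rp.simulate_replication_timing(cfg, rp.SimulationParams(**PARAMS))
        expect = [
            rp.circular_distance(37_000, x, 100_000) / 1000.0
            for x in range(0, 100_000, 1000)
        ]
        np.testing.assert_allclose(t.t_rep, expect)

    def test_blocked_fork_arrival_closed_form(self):
        """Beyond a clockwise trap, arrival is the counterclockwise fork's time."""
        cfg = single_origin(length=100_000, pos=0,
                            ter_sites=[rp.TerSite("t", 20_000, "blocks_clockwise")])
        t = rp.simulate_replication_timing(cfg, rp.SimulationParams(**PARAMS))
        for i in range(21, 100):
            assert t.t_rep[i] == pytest.approx((100_000 - i * 1000) / 1000.0)

    def test_head_on_zone_scales_local_slope(self):
        """Inside a head-on zone with factor f the timing slope is 1/f."""
        zone = rp.SlowZone("z", 30_000, 40_000, "counterclockwise", head_on_factor=0.5)
        cfg = single_origin(length=100_000, pos=0, slow_zones=[zone])
        t = rp.simulate_replication_timing(cfg, rp.SimulationParams(**PARAMS))
        slopes = np.diff(t.t_rep[:50])
        np.testing.assert_allclose(slopes[31:39], 2.0)  # 1/f
        np.testing.assert_allclose(slopes[:30], 1.0)

    def test_step_discontinuity_at_trap(self, oriz_copy_number):
        """The single-oriZ profile steps at the terC trap (1.609 Mbp bin)."""
        i = 1_609_000 // 1000  # last bin replicated by the blocked clockwise fork
        jump = abs(oriz_copy_number[i + 1] - oriz_copy_number[i])
        baseline = abs(oriz_copy_number[i] - oriz_copy_number[i - 1])
        assert jump > 50 * baseline

    def test_opposing_traps_unreachable(self):
        cfg = single_origin(ter_sites=[
            rp.TerSite("cw", 3000, "blocks_clockwise"),
            rp.TerSite("ccw", 8000, "blocks_counterclockwise"),
        ])
        with pytest.raises(UnreachableRegionError):
            rp.simulate_replication_timing(cfg, rp.SimulationParams(**PARAMS))

    def test_barrier_pause_delays_downstream(self):
        cfg = single_origin(length=100_000, pos=0,
                            barriers=[rp.Barrier("tetO", 10_000, pause_s=5.0)])
        t = rp.simulate_replication_timing(cfg, rp.SimulationParams(**PARAMS))
        assert t.t_rep[9] == pytest.approx(9.0)
        assert t.t_rep[11] == pytest.approx(16.0)  # 11 s travel + 5 s pause

    def test_rpo_star_relieves_slow_zones(self):
        zone = rp.SlowZone("z", 30_000, 40_000, "counterclockwise", head_on_factor=0.5)
        cfg = single_origin(length=100_000, pos=0, slow_zones=[zone])
        t = rp.simulate_replication_timing(
            cfg, rp.SimulationParams(rpo_star=True, rpo_star_relief=0.5, **PARAMS))
        slopes = np.diff(t.t_rep[:50])
        np.testing.assert_allclose(slopes[31:39], 1 / 0.75)  # deficit halved


class TestCopyNumber:
    def test_zero_time_gives_one(self):
        t = rp.simulate_replication_timing(single_origin(), rp.SimulationParams(**PARAMS))
        m = rp.timing_to_copy_number(t, 1e9)
        np.testing.assert_allclose(m, 1.0, atol=1e-6)

    def test_halving_at_one_doubling_time(self):
        timing = rp.ReplicationTiming(np.array([0.0, 60.0]), 1000, 2000, [])
        m = rp.timing_to_copy_number(timing, 1.0)
        assert m[1] == pytest.approx(0.5)

    def test_trap_fusion_copy_number_closed_form(self):
        """Fusion at t = 7 s with tau_d = 10 s gives 2^-0.7 at the fusion."""
        cfg = single_origin(ter_sites=[rp.TerSite("t", 3000, "blocks_clockwise")])
        t = rp.simulate_replication_timing(cfg, rp.SimulationParams(**PARAMS))
        fusion_t = [e for e in t.events if e["event"] == "fusion"][0]["time_s"]
        assert 2 ** (-fusion_t / 10.0) == pytest.approx(0.6155722066, abs=1e-9)
        m = rp.timing_to_copy_number(t, 10.0 / 60.0)
        np.testing.assert_allclose(m, 2.0 ** (-t.t_rep / 10.0))

    def test_origin_terminus_ratio(self, oriz_timing, oriz_copy_number):
        ratio = oriz_copy_number.max() / oriz_copy_number.min()
        assert ratio == pytest.approx(2 ** (oriz_timing.t_max / (39.8 * 60)))

    def test_nonpositive_doubling_time(self, oriz_timing):
        with pytest.raises(ValueError):
            rp.timing_to_copy_number(oriz_timing, 0)


class TestCountPair:
    def test_deterministic_under_seed(self):
        m = np.linspace(0.5, 1.0, 50)
        p = rp.SimulationParams(seed=11, bias_sd_log=0.2, mean_depth_per_bin=50)
        a1, b1 = rp.sample_count_pair(m, p)
        a2, b2 = rp.sample_count_pair(m, p)
        assert np.array_equal(a1.counts, a2.counts)
        assert np.array_equal(b1.counts, b2.counts)

    def test_means_proportional_to_copy_number(self):
        m = np.concatenate([np.full(500, 0.5), np.full(500, 1.0)])
        p = rp.SimulationParams(seed=1, bias_sd_log=0.0, mean_depth_per_bin=2000)
        exp, stat = rp.sample_count_pair(m, p)
        ratio = exp.counts[:500].mean() / exp.counts[500:].mean()
        assert ratio == pytest.approx(0.5, rel=0.02)
        assert stat.counts.mean() == pytest.approx(2000, rel=0.02)

    def test_enrichment_dispersion_delta_method(self):
        """Flat copy number at depth 100: enrichment sd ~ sqrt(2/100)."""
        m = np.ones(4640)
        p = rp.SimulationParams(seed=5, mean_depth_per_bin=100)
        exp, stat = rp.sample_count_pair(m, p)
        e = rp.marker_frequency(exp, stat).enrichment
        assert e.mean() == pytest.approx(1.0, abs=0.01)
        assert e.std() == pytest.approx(np.sqrt(2 / 100), rel=0.1)

    def test_negative_binomial_overdisperses(self):
        m = np.ones(4000)
        base = dict(seed=3, mean_depth_per_bin=100)
        po, _ = rp.sample_count_pair(m, rp.SimulationParams(**base))
        nb, _ = rp.sample_count_pair(
            m, rp.SimulationParams(noise_model="negative_binomial", nb_dispersion=5, **base))
        assert nb.counts.var() > 2 * po.counts.var()


class TestInversionTrack:
    def test_linear_ramp_by_hand(self):
        out = rp.apply_inversion(np.arange(10), 2000, 6000, 1000)
        assert list(out) == [0, 1, 5, 4, 3, 2, 6, 7, 8, 9]

    def test_single_bin_segment_unchanged(self):
        x = np.arange(10)
        assert np.array_equal(rp.apply_inversion(x, 3000, 4000, 1000), x)

    def test_snapping_warns_and_strict_raises(self):
        with pytest.warns(UserWarning):
            rp.apply_inversion(np.arange(10), 2500, 6000, 1000)
        with pytest.raises(ValueError):
            rp.apply_inversion(np.arange(10), 2500, 6000, 1000, strict=True)

    @given(
        i1=st.integers(0, 59), seg=st.integers(1, 59), data=st.integers(0, 2**31 - 1)
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_involution(self, i1, seg, data):
        rng = np.random.default_rng(data)
        x = rng.normal(size=60)
        b1, b2 = i1 * 1000, ((i1 + seg) % 60) * 1000
        twice = rp.apply_inversion(rp.apply_inversion(x, b1, b2, 1000), b1, b2, 1000)
        np.testing.assert_array_equal(twice, x)

    def test_wraps_through_origin_of_coordinates(self):
        out = rp.apply_inversion(np.arange(10), 8000, 2000, 1000)
        assert list(out) == [9, 8, 2, 3, 4, 5, 6, 7, 1, 0]


class TestGrowthCurves:
    def test_single_population_doubles(self):
        c = rp.simulate_growth_curve([(1.0, 20.0)], n0_cfu_per_ml=1e6, t_max_min=120)
        np.testing.assert_allclose(c.cfu_per_ml, 1e6 * 2 ** (c.times_min / 20.0))
        assert np.array_equal(c.times_min, np.arange(0, 121, 30))

    def test_biphasic_mixture_is_convex_in_log(self):
        c = rp.simulate_growth_curve([(0.99, 40.0), (0.01, 20.0)], t_max_min=600)
        log_n = np.log2(c.cfu_per_ml)
        second = np.diff(log_n, 2)
        assert np.all(second > -1e-12)
        assert second[-1] > 1e-4  # late acceleration from the fast subpopulation

    def test_noise_free_deterministic(self):
        a = rp.simulate_growth_curve([(1.0, 25.0)], seed=1)
        b = rp.simulate_growth_curve([(1.0, 25.0)], seed=2)
        np.testing.assert_array_equal(a.cfu_per_ml, b.cfu_per_ml)

    def test_noisy_reproducible_under_seed(self):
        a = rp.simulate_growth_curve([(1.0, 25.0)], noise_sd_log=0.1, seed=4)
        b = rp.simulate_growth_curve([(1.0, 25.0)], noise_sd_log=0.1, seed=4)
        np.testing.assert_array_equal(a.cfu_per_ml, b.cfu_per_ml)
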