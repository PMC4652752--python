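import numpy as np
import pytest

import replichore as rp
from replichore.replichore_analysis import FlatArmError, TerminationMinimum
from replichore.smoothing import SmoothedProfile, SmoothingParams


def smoothed(values, bin_width=1000):
    values = np.asarray(values, dtype=float)
    return SmoothedProfile(values, np.ones(len(values), bool), SmoothingParams(),
                           bin_width, len(values) * bin_width)


class TestFindMinima:
    def test_v_shape_unique_minimum(self):
        n = 100
        v = np.abs(np.arange(n) - 63).astype(float) + 1
        cfg = rp.ChromosomeConfig(length_bp=n * 1000, origins=[rp.Origin("o", 0)])
        (m,) = rp.find_termination_minima(smoothed(v), cfg)
        assert m.position_bp == 63_000
        assert not m.suspect

    def test_tie_broken_toward_smaller_coordinate(self):
        v = np.full(50, 1.0)
        v[20] = v[30] = 0.5
        cfg = rp.ChromosomeConfig(length_bp=50_000, origins=[rp.Origin("o", 0)])
        (m,) = rp.find_termination_minima(smoothed(v), cfg)
        assert m.position_bp == 20_000

    def test_origin_bin_never_a_terminus(self):
        v = np.full(50, 1.0)
        v[10] = 0.1  # artificial dip at the origin bin itself
        cfg = rp.ChromosomeConfig(length_bp=50_000, origins=[rp.Origin("o", 10_000)])
        (m,) = rp.find_termination_minima(smoothed(v), cfg)
        assert m.position_bp != 10_000

    def test_simulated_single_origin_minimum_at_trap(self, oriz_model, oriz_smoothed):
        """Noise-free single-oriZ profile: minimum past the terC fork trap."""
        (m,) = rp.find_termination_minima(oriz_smoothed, oriz_model)
        # LOESS smoothing across the trap step displaces the fitted minimum
        # beyond the fusion point, as in real profiles; it must stay within
        # half a smoothing window clockwise of the trap.
        assert 1_609_000 <= m.position_bp <= 1_609_000 + 232_000
        assert m.arc_from == m.arc_to == "oriZ"

    def test_symmetric_simulation_minimum_at_fusion(self):
        cfg = rp.ChromosomeConfig(length_bp=4_640_000,
                                  origins=[rp.Origin("ori", 344_000)])
        t = rp.simulate_replication_timing(cfg, rp.SimulationParams())
        s = rp.remove_outliers_and_refit(
            rp.noise_free_profile(rp.timing_to_copy_number(t, 19.9)))
        (m,) = rp.find_termination_minima(s, cfg)
        assert abs(m.position_bp - t.termination_positions[0]) <= 1000

    def test_two_origin_minima_near_fusions(self, model):
        t = rp.simulate_replication_timing(model, rp.SimulationParams(tus_active=False))
        s = rp.remove_outliers_and_refit(
            rp.noise_free_profile(rp.timing_to_copy_number(t, 20.6)))
        minima = rp.find_termination_minima(s, model)
        got = sorted(m.position_bp for m in minima)
        want = sorted(t.termination_positions)
        for g, w in zip(got, want):
            assert abs(g - w) <= 16_000  # rrn slow zones skew the trap-free fusions

    def test_trap_removal_moves_minima_toward_midpoints(self, model):
        """Mirrors the tus-deletion comparison: minima approach the midpoints."""
        mids = {(m.arc_from, m.arc_to): m.position_bp for m in model.midpoints()}
        L = model.length_bp

        def shifts(tus):
            t = rp.simulate_replication_timing(
                model, rp.SimulationParams(doubling_time_min=20.6, tus_active=tus))
            s = rp.remove_outliers_and_refit(
                rp.noise_free_profile(rp.timing_to_copy_number(t, 20.6)))
            return {
                (m.arc_from, m.arc_to): abs(
                    rp.signed_arc_offset(mids[(m.arc_from, m.arc_to)] % L,
                                         m.position_bp, L))
                for m in rp.find_termination_minima(s, model)
            }

        with_trap = shifts(True)
        without = shifts(False)
        for arc in with_trap:
            assert without[arc] <= with_trap[arc]

    def test_noisy_minima_recovery(self, oriz_model, oriz_copy_number, oriz_smoothed):
        """Depth 100/bin: recovered minima within 20 kb of the noise-free one."""
        ref = rp.find_termination_minima(oriz_smoothed, oriz_model)[0].position_bp
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            p = rp.SimulationParams(doubling_time_min=39.8, mean_depth_per_bin=100,
                                    bias_sd_log=0.1, seed=seed)
            exp, stat = rp.sample_count_pair(oriz_copy_number, p)
            s = rp.remove_outliers_and_refit(rp.marker_frequency(exp, stat))
            m = rp.find_termination_minima(s, oriz_model)[0].position_bp
            hits += abs(m - ref) <= 20_000
        assert hits >= 0.9 * n_seeds


class TestReplichoreReport:
    def test_asymmetric_replichores_from_printed_minimum(self, oriz_model):
        """Origin 0.344, minimum 1.709: arms of 1.365 and 3.275 Mbp (~1.3/3.3)."""
        minima = [TerminationMinimum("oriZ", "oriZ", 1_709_000, 0.5)]
        rep = rp.replichore_report(minima, oriz_model)
        arms = rep.replichore_lengths_mbp["oriZ"]
        assert arms["clockwise"] == 1.365
        assert arms["counterclockwise"] == 3.275
        assert rp.format_mbp(3_275_000, 1) == 3.3
        assert rp.format_mbp(1_365_000, 1) == 1.4

    def test_zero_shift_when_minimum_at_midpoint(self, oriz_model):
        minima = [TerminationMinimum("oriZ", "oriZ", 2_664_000, 0.5)]
        rep = rp.replichore_report(minima, oriz_model)
        assert rep.shifts_kb == [0.0]

    def test_two_origin_shifts_from_printed_inputs(self, model):
        """Printed minima 1.699/4.459 vs midpoints 2.1335/4.4535."""
        minima = [
            TerminationMinimum("oriZ", "oriC", 1_699_000, 0.5),
            TerminationMinimum("oriC", "oriZ", 4_459_000, 0.6),
        ]
        rep = rp.replichore_report(minima, model)
        shifts = dict(zip([(m.arc_from, m.arc_to) for m in minima], rep.shifts_kb))
        assert shifts[("oriZ", "oriC")] == pytest.approx(-434.5)
        assert shifts[("oriC", "oriZ")] == pytest.approx(5.5)

    def test_round_trip_dict(self, oriz_model):
        minima = [TerminationMinimum("oriZ", "oriZ", 1_709_000, 0.5)]
        rep = rp.replichore_report(minima, oriz_model, {"rrnH": 2.0})
        d = rep.to_dict()
        assert d["minima"][0]["position_mbp"] == 1.709
        assert d["midpoints"][0]["position_mbp"] == 2.664
        assert d["deviation_scores"] == {"rrnH": 2.0}


class TestDeviationScores:
    def make(self, head_on_factor=None, direction="counterclockwise"):
        zones = []
        if head_on_factor is not None:
            zones = [rp.SlowZone("Z", 1_000_000, 1_050_000, direction,
                                 head_on_factor=head_on_factor)]
        cfg = rp.ChromosomeConfig(length_bp=4_640_000,
                                  origins=[rp.Origin("ori", 0)], slow_zones=zones)
        t = rp.simulate_replication_timing(cfg, rp.SimulationParams())
        m = rp.timing_to_copy_number(t, 19.9)
        s = smoothed(m / m.mean())
        minima = rp.find_termination_minima(s, cfg)
        return cfg, s, minima

    def test_uniform_gradient_scores_one(self):
        cfg, s, minima = self.make()
        region = rp.SlowZone("R", 900_000, 950_000, "clockwise")
        scores = rp.gradient_deviation_scores(s, [region], cfg, minima)
        assert scores["R"] == pytest.approx(1.0, abs=0.01)

    def test_head_on_zone_scores_near_two(self):
        """Head-on factor 0.5 doubles |dt/dx| inside the zone."""
        cfg, s, minima = self.make(head_on_factor=0.5)
        scores = rp.gradient_deviation_scores(s, list(cfg.slow_zones), cfg, minima)
        assert scores["Z"] == pytest.approx(2.0, abs=0.05)

    def test_scale_invariance(self):
        cfg, s, minima = self.make(head_on_factor=0.5)
        s2 = smoothed(s.fitted * 37.0)
        a = rp.gradient_deviation_scores(s, list(cfg.slow_zones), cfg, minima)
        b = rp.gradient_deviation_scores(s2, list(cfg.slow_zones), cfg, minima)
        assert a["Z"] == pytest.approx(b["Z"], rel=1e-9)

    def test_flat_arm_signalled(self):
        v = np.full(100, 1.0)
        v[50:] = np.linspace(1.0, 0.5, 50)  # one informative arm, one flat
        cfg = rp.ChromosomeConfig(length_bp=100_000, origins=[rp.Origin("o", 50_000)])
        s = smoothed(v)
        minima = [TerminationMinimum("o", "o", 10_000, 1.0)]
        region = rp.SlowZone("flat", 20_000, 30_000, "clockwise")
        with pytest.raises(FlatArmError):
            rp.gradient_deviation_scores(s, [region], cfg, minima)
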