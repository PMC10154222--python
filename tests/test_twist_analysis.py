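"""Magnetic-tweezers analysis: hat curves, pause detection, rates."""

import numpy as np
import pytest
from scipy.signal import savgol_coeffs

from topomech import synthetic_data as sd
from topomech import twist_analysis as ta


def _staircase(segments, dt=0.1):
    """Build (time, turns) from (duration_s, rate_turns_per_s) segments."""
    xs = [np.array([0.0])]
    for dur, rate in segments:
        n = int(dur / dt)
        xs.append(xs[-1][-1] + rate * dt * np.arange(1, n + 1))
    x = np.concatenate(xs)
    return np.arange(len(x)) * dt, x


class TestHatCurve:
    def test_parameters_recovered(self, rng):
        hat = sd.TwistScenario().hat()
        turns = np.linspace(-40, 40, 400)
        ext = hat.extension_at(turns) + rng.normal(0, 30.0, 400)
        fit = ta.fit_hat_curve(turns, ext)
        assert fit.plateau_extension == pytest.approx(hat.plateau_extension, rel=0.05)
        assert fit.slope_left == pytest.approx(hat.slope_left, rel=0.05)
        assert fit.slope_right == pytest.approx(hat.slope_right, rel=0.05)
        assert fit.center_turn == pytest.approx(0.0, abs=1.0)

    def test_mirror_symmetry(self, rng):
        hat = sd.TwistScenario().hat()
        turns = np.linspace(-40, 40, 400)
        ext = hat.extension_at(turns) + rng.normal(0, 20.0, 400)
        fit = ta.fit_hat_curve(turns, ext)
        assert abs(fit.slope_left) == pytest.approx(abs(fit.slope_right), rel=0.1)

    def test_flankless_data_rejected(self):
        turns = np.linspace(-40, 40, 100)
        with pytest.raises(ValueError):
            ta.fit_hat_curve(turns, np.full(100, 3600.0))

    def test_buckling_points_bracket_center(self):
        hat = sd.TwistScenario().hat()
        assert hat.buckling_left < hat.center_turn < hat.buckling_right


class TestTurnsFromExtension:
    def test_round_trip_on_flank(self):
        hat = sd.TwistScenario().hat()
        turns = np.linspace(-40, -3, 200)
        ext = hat.extension_at(turns)
        back, clipped = hat.turns_at(ext, "minus")
        assert not clipped.any()
        assert np.sqrt(np.mean((back - turns) ** 2)) < 0.05

    def test_plateau_extension_reads_full_relaxation(self):
        sc = sd.TwistScenario()
        hat = sc.hat()
        trace = ta.TwistTrace(np.arange(10) * 0.1,
                              np.full(10, hat.plateau_extension),
                              np.full(10, -40.0))
        relaxed, _ = ta.turns_from_extension(trace, hat, "minus")
        assert np.allclose(relaxed, 40.0, atol=1e-9)

    def test_above_plateau_clipped_and_flagged(self):
        hat = sd.TwistScenario().hat()
        trace = ta.TwistTrace(np.arange(3) * 0.1,
                              np.array([3000.0, 3700.0, 3500.0]),
                              np.full(3, -40.0))
        relaxed, clipped = ta.turns_from_extension(trace, hat, "minus")
        assert clipped[1] and not clipped[0]

    def test_staircase_reproduced(self):
        sc = sd.TwistScenario(noise_sd=0.0, pause_probability=0.0, seed=3)
        trace, truth = sd.gen_twist_trace(sc)
        relaxed, _ = ta.turns_from_extension(trace, sc.hat(), "minus")
        # reconstruct the true staircase from the event log
        true = np.zeros(len(trace.time))
        for t_ev in truth["event_times"]:
            true[trace.time >= t_ev] += 2.0
        m = relaxed < 39.0  # below the rounded cap the flank mapping is exact
        assert np.sqrt(np.mean((relaxed[m] - true[m]) ** 2)) < 0.2


class TestSgSmooth:
    def test_quadratic_reproduced(self):
        t = np.arange(1000) * 0.1
        y = 3.0 + 0.5 * t - 0.02 * t ** 2
        out = ta.sg_smooth(y, 30.0, 10.0)
        assert np.allclose(out[200:-200], y[200:-200], atol=1e-8)

    def test_constant_unchanged(self):
        out = ta.sg_smooth(np.full(500, 7.0), 30.0, 10.0)
        assert np.allclose(out, 7.0)

    def test_noise_reduction_matches_filter_gain(self, rng):
        # white-noise sd shrinks by sqrt(sum of squared SG coefficients)
        noise = rng.normal(0, 1.0, 200_000)
        out = ta.sg_smooth(noise, 30.0, 10.0)
        coeffs = savgol_coeffs(301, 2)
        expected = np.sqrt(np.sum(coeffs ** 2))
        assert np.std(out[500:-500]) == pytest.approx(expected, rel=0.1)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            ta.sg_smooth(np.zeros(100), 30.0, 10.0)


class TestDetectPauses:
    def test_constant_rate_no_pauses(self):
        t, x = _staircase([(40.0, 1.0)])
        assert ta.detect_pauses(ta.sg_smooth(x, 30.0, 10.0), t) == []

    def test_injected_pauses_recovered(self):
        t, x = _staircase([(10.0, 1.0), (30.0, 0.0), (10.0, 1.0),
                           (30.0, 0.0), (12.0, 1.0)])
        pauses = ta.detect_pauses(ta.sg_smooth(x, 30.0, 10.0), t)
        assert len(pauses) == 2
        assert pauses[0].turn_level == pytest.approx(10.0, abs=0.4)
        assert pauses[1].turn_level == pytest.approx(20.0, abs=0.4)
        for p in pauses:
            assert p.duration == pytest.approx(30.0, rel=0.2)

    def test_levels_on_two_turn_steps(self):
        # pausing levels on catalytic-step traces concentrate at the
        # injected even-turn levels
        hits, total = 0, 0
        for seed in range(6):
            sc = sd.TwistScenario(pause_probability=0.2, seed=seed)
            trace, truth = sd.gen_twist_trace(sc)
            relaxed, _ = ta.turns_from_extension(trace, sc.hat(), "minus")
            sm = ta.sg_smooth(relaxed, 30.0, 10.0)
            end = ta.relaxation_window(sm)
            pauses = ta.detect_pauses(sm[:end], trace.time[:end])
            inj = [p["level"] for p in truth["pauses"]]
            for p in pauses:
                total += 1
                hits += any(abs(p.turn_level - l) <= 0.4 for l in inj)
        assert total > 0
        assert hits / total >= 0.75

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            ta.detect_pauses(np.zeros(1), np.zeros(1))


class TestPauseFreeRate:
    def test_noiseless_ramp(self):
        t, x = _staircase([(33.0, 1.2)])
        trace = ta.TwistTrace(t, np.zeros_like(t), np.full(len(t), -40.0))
        assert ta.pause_free_rate(trace, x, []) == pytest.approx(1.2, abs=0.05)

    def test_invariant_to_pauses_after_first_burst(self):
        t, x = _staircase([(20.0, 1.2), (60.0, 0.0), (10.0, 1.2)])
        trace = ta.TwistTrace(t, np.zeros_like(t), np.full(len(t), -40.0))
        pauses = ta.detect_pauses(ta.sg_smooth(x, 30.0, 10.0), t)
        r = ta.pause_free_rate(trace, x, pauses)
        assert r == pytest.approx(1.2, abs=0.1)

    def test_noise_robustness(self):
        # doubling extension noise moves the estimate by < 10%
        rates = {}
        for sdev in (30.0, 60.0):
            vals = []
            for seed in range(8):
                sc = sd.TwistScenario(pause_probability=0.0, noise_sd=sdev,
                                      seed=seed)
                trace, _ = sd.gen_twist_trace(sc)
                relaxed, _ = ta.turns_from_extension(trace, sc.hat(), "minus")
                vals.append(ta.pause_free_rate(trace, relaxed, []))
            rates[sdev] = np.median(vals)
        assert rates[60.0] == pytest.approx(rates[30.0], rel=0.1)


class TestPauseFrequency:
    def test_geometric_draw_recovery(self, rng):
        draws = 2.0 * rng.geometric(0.2, size=200)  # mean 10 turns
        freq, flagged = ta.pause_frequency(draws, np.zeros(200, bool),
                                           censor_turns=1e9)
        assert not flagged
        assert freq == pytest.approx(0.1, rel=0.15)

    def test_all_censored_bounded_and_flagged(self):
        freq, flagged = ta.pause_frequency(np.full(20, 30.0),
                                           np.ones(20, bool))
        assert flagged
        assert freq <= 1.0 / 30.0 + 1e-9

    def test_frequency_tracks_pause_probability(self, rng):
        # doubling the per-cycle pause probability doubles the frequency
        d1 = 2.0 * rng.geometric(0.1, size=400)
        d2 = 2.0 * rng.geometric(0.2, size=400)
        f1, _ = ta.pause_frequency(d1, np.zeros(400, bool), censor_turns=1e9)
        f2, _ = ta.pause_frequency(d2, np.zeros(400, bool), censor_turns=1e9)
        assert f2 / f1 == pytest.approx(2.0, rel=0.25)

    def test_too_few_traces_rejected(self):
        with pytest.raises(ValueError):
            ta.pause_frequency([5.0] * 5)


class TestMeanRelaxationRate:
    def test_no_pause_equals_pause_free(self):
        t, x = _staircase([(33.3, 1.2)])
        trace = ta.TwistTrace(t, np.zeros_like(t), np.full(len(t), -40.0))
        mean_rate, done = ta.mean_relaxation_rate(trace, x)
        assert done
        assert mean_rate == pytest.approx(ta.pause_free_rate(trace, x, []),
                                          rel=0.05)

    def test_half_time_paused_halves_rate(self):
        t, x = _staircase([(16.65, 1.2), (33.3, 0.0), (16.65, 1.2)])
        trace = ta.TwistTrace(t, np.zeros_like(t), np.full(len(t), -40.0))
        mean_rate, done = ta.mean_relaxation_rate(trace, x)
        assert done
        assert mean_rate == pytest.approx(0.6, rel=0.1)

    def test_never_relaxing_flagged(self):
        t = np.arange(100) * 0.1
        trace = ta.TwistTrace(t, np.zeros_like(t), np.full(len(t), -40.0))
        mean_rate, done = ta.mean_relaxation_rate(trace, np.zeros(100))
        assert not done
        assert mean_rate == pytest.approx(0.0, abs=1e-9)


class TestTrappedLoopSize:
    def test_identical_hats_zero(self):
        hat = sd.TwistScenario().hat()
        bp, ok = ta.trapped_loop_size(hat, hat)
        assert bp == pytest.approx(0.0, abs=1e-9) and ok

    def test_thousand_bp_reduction(self, elasticity):
        from topomech.polymer_mechanics import ds_extension

        hat1 = sd.TwistScenario().hat()
        d_ext = ds_extension(0.22, 1000, elasticity)
        hat2 = sd.TwistScenario(hat_plateau=hat1.plateau_extension - d_ext).hat()
        bp, ok = ta.trapped_loop_size(hat1, hat2)
        assert ok
        assert bp == pytest.approx(1000, rel=0.10)

    def test_common_vertical_shift_invariance(self):
        h1 = sd.TwistScenario(hat_plateau=3600.0).hat()
        h2 = sd.TwistScenario(hat_plateau=3400.0).hat()
        h1s = sd.TwistScenario(hat_plateau=3700.0).hat()
        h2s = sd.TwistScenario(hat_plateau=3500.0).hat()
        assert ta.trapped_loop_size(h1, h2)[0] == pytest.approx(
            ta.trapped_loop_size(h1s, h2s)[0], rel=1e-9)

    def test_growing_hat_flagged_inconsistent(self):
        h1 = sd.TwistScenario(hat_plateau=3400.0).hat()
        h2 = sd.TwistScenario(hat_plateau=3600.0).hat()
        _, ok = ta.trapped_loop_size(h1, h2)
        assert not ok
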