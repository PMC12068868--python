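"""Scaling math, truncation, growth summaries and replicate envelopes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleopop.psmc_io import PsmcRound
from paleopop.trajectory_stats import (
    DegenerateTrajectoryError,
    DemographicTrajectory,
    ScalingParams,
    replicate_envelope,
    scale_round,
    summarize,
    truncate_recent,
)


def traj(ts, nes, taxon="t"):
    return DemographicTrajectory(np.asarray(ts, float), np.asarray(nes, float), taxon)


class TestScaleRound:
    def test_worked_example(self):
        # theta0 = 0.0023 with mu = 2.3e-9/yr, g = 2.5, s = 100:
        # mu_gen = 5.75e-9, N0 = 0.0023 / (4 * 5.75e-9 * 100) = 1000
        r = PsmcRound(0, 0.0023, 4e-4, 15.0, [(0.0, 1.0), (0.05, 3.0)])
        out = scale_round(r, ScalingParams())
        assert out.ne[0] == pytest.approx(1000.0)
        # t_years = 2 * N0 * t_k * g = 2 * 1000 * 0.05 * 2.5 = 250
        assert out.t_years[1] == pytest.approx(250.0)
        assert out.ne[1] == pytest.approx(3000.0)

    def test_constant_lambda_gives_constant_n0(self):
        r = PsmcRound(0, 0.0023, 4e-4, 15.0, [(0.0, 1.0), (0.1, 1.0), (0.7, 1.0)])
        out = scale_round(r)
        assert np.allclose(out.ne, 1000.0)

    def test_scaling_params_must_be_positive(self):
        with pytest.raises(ValueError):
            ScalingParams(mu_per_site_year=0.0)


class TestTruncateRecent:
    def test_drops_steps_more_recent_than_cutoff(self):
        t = traj([10e3, 60e3, 200e3], [1e4, 2e4, 3e4])
        out = truncate_recent(t, 50e3)
        assert list(out.t_years) == [60e3, 200e3]
        assert len(t) == 3  # input untouched

    def test_zero_cutoff_is_identity(self):
        t = traj([0.0, 60e3, 200e3], [1e4, 2e4, 3e4])
        out = truncate_recent(t, 0.0)
        assert np.array_equal(out.t_years, t.t_years)

    def test_cutoff_beyond_oldest_step_is_degenerate(self):
        t = traj([10e3, 60e3], [1e4, 2e4])
        with pytest.raises(DegenerateTrajectoryError, match="survive"):
            truncate_recent(t, 1e6)


class TestSummarize:
    def test_two_step_growth(self):
        # growth from 1e4 at 3 Myr (trough/origin) to 5e4 at 1 Myr (peak)
        s = summarize(traj([1.0e6, 3.0e6], [5.0e4, 1.0e4]))
        assert s.degree == pytest.approx(0.8)
        assert s.deltaT == pytest.approx(2.0e6)
        assert s.rate == pytest.approx(4.0e-7)
        assert (s.N_trough, s.t_trough) == (1.0e4, 3.0e6)

    def test_initial_decline_gives_negative_degree(self):
        # origin 7e4 at 0.9 Myr falling to 4e4 at 0.15 Myr then recovering
        t = traj([0.05e6, 0.15e6, 0.5e6, 0.9e6], [6.0e4, 4.0e4, 5.0e4, 7.0e4])
        for mode in ("first_turning", "global"):
            s = summarize(t, peak_mode=mode)
            assert s.degree == pytest.approx(1 - 7.0 / 4.0)  # -0.75
            assert s.t_peak == pytest.approx(0.15e6)
            assert s.rate < 0

    def test_constant_trajectory(self):
        s = summarize(traj([1e5, 2e5, 4e5], [3e4, 3e4, 3e4]))
        assert s.degree == 0.0
        assert s.cv == 0.0

    def test_global_mode_matches_bruteforce_argmax(self, rng):
        for _ in range(50):
            n = 50
            t = np.sort(rng.uniform(5e4, 5e6, size=n))
            ne = np.exp(rng.normal(11, 1, size=n))
            s = summarize(traj(t, ne), peak_mode="global")
            old_to_recent = ne[::-1]
            imax = int(np.argmax(old_to_recent))
            expect = int(np.argmin(old_to_recent)) if imax == 0 else imax
            assert s.N_peak == old_to_recent[expect]
            assert s.t_peak == t[::-1][expect]

    def test_first_turning_epsilon_filters_wiggles(self):
        # 2% wiggle below epsilon=0.05 must not stop the scan
        t = traj([1e5, 2e5, 3e5, 4e5, 5e5],
                 [5.0e4, 3.0e4, 1.02e4, 1.0e4, 1.02e4])
        s = summarize(t, peak_mode="first_turning", epsilon=0.05)
        assert s.t_peak == pytest.approx(1e5)
        # with a permissive epsilon the small dip becomes the peak
        s2 = summarize(t, peak_mode="first_turning", epsilon=0.001)
        assert s2.t_peak == pytest.approx(4e5)

    def test_zero_deltaT_flags_rate(self):
        # monotone decline from the origin, global mode: peak = minimum =
        # most recent; first_turning: same
        t = traj([1e5, 2e5], [5e4, 5e4])
        s = summarize(t, peak_mode="global")
        assert s.deltaT == 0.0
        assert s.rate is None

    def test_time_reversal_flips_sign_of_monotone_growth(self):
        ts = np.array([1e5, 2e5, 4e5, 8e5])
        grow = traj(ts, [1e4, 2e4, 4e4, 8e4][::-1])  # oldest small -> growth
        s = summarize(grow)
        assert s.degree > 0
        rev = traj(ts, [1e4, 2e4, 4e4, 8e4])  # oldest large -> decline
        assert summarize(rev).degree < 0

    def test_weighted_and_sample_sd_options(self):
        t = traj([1e5, 2e5, 6e5], [1e4, 3e4, 5e4])
        s_pop = summarize(t)
        assert s_pop.sd_Ne == pytest.approx(np.std([1e4, 3e4, 5e4]))
        s_samp = summarize(t, sd_ddof=1)
        assert s_samp.sd_Ne == pytest.approx(np.std([1e4, 3e4, 5e4], ddof=1))
        s_w = summarize(t, time_weighted=True)
        # widths 1e5 and 4e5 on the two youngest steps; oldest excluded
        assert s_w.mean_Ne == pytest.approx(np.average([1e4, 3e4], weights=[1e5, 4e5]))

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=30, deadline=None)
    def test_cv_and_deltaT_invariant_under_ne_rescaling(self, scale):
        t = traj([1e5, 3e5, 9e5, 2e6], [2e4, 7e4, 4e4, 1e4])
        s1 = summarize(t)
        s2 = summarize(traj(t.t_years, t.ne * scale))
        assert s2.cv == pytest.approx(s1.cv)
        assert s2.deltaT == pytest.approx(s1.deltaT)

    def test_degree_bounds_and_sign_coupling(self, rng):
        for _ in range(30):
            n = 20
            t = np.sort(rng.uniform(5e4, 5e6, size=n))
            ne = np.exp(rng.normal(11, 1, size=n))
            for mode in ("first_turning", "global"):
                s = summarize(traj(t, ne), peak_mode=mode)
                assert s.degree < 1
                assert s.deltaT >= 0
                assert (s.degree > 0) == (s.N_peak > s.N_trough)
                if s.rate is not None and s.degree != 0:
                    assert np.sign(s.rate) == np.sign(s.degree)


class TestReplicateEnvelope:
    def test_single_trajectory_collapses(self):
        t = traj([1e5, 2e5, 4e5], [1e4, 2e4, 3e4])
        env = replicate_envelope([t], [1.5e5, 3e5])
        assert np.array_equal(env["min"], env["max"])
        assert np.array_equal(env["median"], t.at([1.5e5, 3e5]))

    def test_even_count_median_is_mean_of_middle(self):
        a = traj([1e5, 2e5], [1e4, 1e4])
        b = traj([1e5, 2e5], [3e4, 3e4])
        env = replicate_envelope([a, b], [1.5e5])
        assert env["median"][0] == pytest.approx(2e4)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            replicate_envelope([], [1e5])

    def test_envelope_contains_noise_free_source(self):
        from paleopop.synthetic_data import emit_psmc, make_trajectory, migrant_archetype
        from paleopop.psmc_io import parse_psmc
        from paleopop.trajectory_stats import scale_round

        src = make_trajectory(migrant_archetype())
        reps = []
        for i in range(100):
            text = emit_psmc(src, noise_sigma=0.1, seed=1000 + i)
            reps.append(scale_round(parse_psmc(text, "r").last_round()))
        grid = np.geomspace(5e4, src.t_years[-1], 60)
        env = replicate_envelope(reps, grid)
        inside = (env["min"] <= src.at(grid)) & (src.at(grid) <= env["max"])
        assert inside.mean() >= 0.95
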