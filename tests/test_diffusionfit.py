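"""SPT analysis: linking, per-track D, mixture fit, bound-fraction decay."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.integrate import quad

from stressburst.containers import RateSeries, Track
from stressburst.diffusionfit import (
    bound_fraction_timecourse,
    diffusion_coefficients,
    estimate_half_life,
    fit_diffusion_mixture,
    link_tracks,
    mixture_density,
    saxton_density,
    track_diffusion_coefficient,
)

DT = 0.01548  # s
PX = 0.096    # μm


def _locs(rows):
    return pd.DataFrame(rows, columns=["frame", "x_px", "y_px"])


class TestLinking:
    def test_within_window_consecutive_frames_linked(self):
        tracks = link_tracks(_locs([(0, 0.0, 0.0), (1, 5.0, 0.0)]),
                             max_disp=8.0)
        assert len(tracks) == 1
        assert tracks[0].frames.tolist() == [0, 1]

    def test_beyond_window_not_linked(self):
        tracks = link_tracks(_locs([(0, 0.0, 0.0), (1, 9.0, 0.0)]),
                             max_disp=8.0)
        assert len(tracks) == 0  # two singletons, both dropped

    def test_memory_bridges_one_missed_frame(self):
        tracks = link_tracks(_locs([(1, 0.0, 0.0), (3, 4.0, 0.0)]), memory=1)
        assert len(tracks) == 1
        assert tracks[0].frames.tolist() == [1, 3]

    def test_gap_of_two_frames_not_bridged(self):
        tracks = link_tracks(_locs([(1, 0.0, 0.0), (4, 1.0, 0.0)]), memory=1)
        assert len(tracks) == 0

    def test_conflicts_resolved_by_total_displacement(self):
        # two molecules crossing paths: optimal assignment keeps each
        # track's step minimal rather than swapping
        rows = [(0, 0.0, 0.0), (0, 6.0, 0.0), (1, 1.0, 0.0), (1, 5.0, 0.0)]
        tracks = link_tracks(_locs(rows), max_disp=8.0)
        steps = sorted(abs(t.positions[1, 0] - t.positions[0, 0]) / PX
                       for t in tracks)
        assert np.allclose(steps, [1.0, 1.0])

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            link_tracks(_locs([(0, 0, 0)]), max_disp=-1.0)

    def test_well_separated_molecules_recovered_exactly(self):
        # molecules on a grid spaced far beyond 2 * max_disp
        rng = np.random.default_rng(3)
        rows = []
        truth = {}
        for m in range(40):
            x0, y0 = (m % 8) * 50.0, (m // 8) * 50.0
            n = rng.integers(5, 9)
            xs = x0 + np.cumsum(rng.normal(0, 1.5, n))
            ys = y0 + np.cumsum(rng.normal(0, 1.5, n))
            truth[m] = n
            for k in range(n):
                rows.append((k, xs[k], ys[k]))
        tracks = link_tracks(_locs(rows), max_disp=8.0)
        assert len(tracks) == 40
        assert sorted(t.frames.size for t in tracks) == sorted(truth.values())


class TestTrackD:
    def _track(self, frames, xy_um):
        return Track(track_id=0, frames=np.asarray(frames),
                     positions=np.asarray(xy_um))

    def test_stationary_track_zero(self):
        tr = self._track(range(5), [[1.0, 1.0]] * 5)
        assert track_diffusion_coefficient(tr, DT) == 0.0

    def test_constant_step_gives_printed_value(self):
        # 0.1 μm per frame along x: MSD = 0.01 μm², D = 0.01/(4*0.01548)
        xs = [[0.1 * k, 0.0] for k in range(6)]
        tr = self._track(range(6), xs)
        d = track_diffusion_coefficient(tr, DT)
        assert d == pytest.approx(0.01 / (4 * DT), rel=1e-12)
        assert d == pytest.approx(0.1615, abs=2e-4)

    def test_short_track_discarded_not_error(self):
        tr = self._track(range(4), [[0.01 * k, 0.0] for k in range(4)])
        assert track_diffusion_coefficient(tr, DT) is None

    def test_track_with_internal_gap_discarded(self):
        tr = self._track([0, 1, 3, 4, 5], [[0.01 * k, 0.0] for k in range(5)])
        assert track_diffusion_coefficient(tr, DT) is None

    def test_long_track_truncated_to_first_five(self):
        rng = np.random.default_rng(1)
        pos = np.cumsum(rng.normal(0, 0.05, (20, 2)), axis=0)
        full = self._track(range(20), pos)
        head = self._track(range(5), pos[:5])
        assert (track_diffusion_coefficient(full, DT)
                == track_diffusion_coefficient(head, DT))

    def test_estimator_unbiased_for_brownian_motion(self):
        rng = np.random.default_rng(2)
        D = 0.5
        steps = rng.normal(0, np.sqrt(2 * D * DT), (4000, 5, 2))
        vals = []
        for s in steps:
            pos = np.cumsum(s, axis=0)
            vals.append(track_diffusion_coefficient(
                Track(0, np.arange(5), pos), DT))
        vals = np.array(vals)
        sem = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean() - D) < 2 * sem


class TestSaxtonDensity:
    @pytest.mark.parametrize("D", [0.17, 0.8, 2.5])
    def test_normalizes_to_one(self, D):
        val, _ = quad(lambda x: saxton_density(np.array([x]), D)[0], 0, 50 * D)
        assert val == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("D", [0.17, 0.8])
    def test_mode_and_mean(self, D):
        x = np.linspace(1e-4, 6 * D, 20000)
        f = saxton_density(x, D)
        assert x[np.argmax(f)] == pytest.approx(3 * D / 4, rel=1e-3)
        mean = np.trapezoid(x * f, x)
        assert mean == pytest.approx(D, rel=1e-4)

    def test_printed_value_at_unity(self):
        assert saxton_density(np.array([1.0]), 1.0)[0] == pytest.approx(
            256 * np.exp(-4) / 6, rel=1e-12
        )

    def test_nonpositive_d_rejected(self):
        with pytest.raises(ValueError):
            saxton_density(np.array([1.0]), 0.0)


def _sample_mixture(rng, n, d1, d2, a1):
    n1 = rng.binomial(n, a1)
    return np.concatenate([rng.gamma(4.0, d1 / 4.0, n1),
                           rng.gamma(4.0, d2 / 4.0, n - n1)])


class TestMixtureFit:
    def test_single_species_fixed_d1_drives_a1_to_zero(self):
        rng = np.random.default_rng(5)
        x = rng.gamma(4.0, 0.8 / 4.0, 8000)
        fit = fit_diffusion_mixture(x, fix_d1=0.17)
        assert fit.a1 < 0.02

    def test_half_half_mixture_recovered(self):
        rng = np.random.default_rng(6)
        x = _sample_mixture(rng, 10000, 0.17, 0.8, 0.5)
        fit = fit_diffusion_mixture(x, fix_d1=0.17)
        assert fit.a1 == pytest.approx(0.5, abs=0.02)
        assert fit.d2 == pytest.approx(0.8, rel=0.05)

    def test_free_fit_recovers_both_species(self):
        rng = np.random.default_rng(7)
        x = _sample_mixture(rng, 20000, 0.17, 0.8, 0.3)
        fit = fit_diffusion_mixture(x)
        assert fit.d1 == pytest.approx(0.17, rel=0.1)
        assert fit.d2 == pytest.approx(0.8, rel=0.1)
        assert fit.a1 == pytest.approx(0.3, abs=0.03)
        assert fit.a1 + fit.a2 == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("a1", [0.1, 0.3, 0.5, 0.7])
    @pytest.mark.parametrize("d2", [0.5, 0.8])
    def test_bias_grid(self, a1, d2):
        rng = np.random.default_rng(int(1000 * a1 + 10 * d2))
        x = _sample_mixture(rng, 10000, 0.17, d2, a1)
        fit = fit_diffusion_mixture(x, fix_d1=0.17)
        assert abs(fit.a1 - a1) < 0.03

    def test_fixed_equals_free_when_consistent(self):
        rng = np.random.default_rng(8)
        x = _sample_mixture(rng, 20000, 0.17, 0.8, 0.4)
        free = fit_diffusion_mixture(x)
        fixed = fit_diffusion_mixture(x, fix_d1=free.d1)
        assert fixed.a1 == pytest.approx(free.a1, abs=1e-3)
        assert fixed.d2 == pytest.approx(free.d2, rel=1e-3)

    def test_histogram_mode_agrees_with_mle(self):
        rng = np.random.default_rng(9)
        x = _sample_mixture(rng, 20000, 0.17, 0.8, 0.4)
        mle = fit_diffusion_mixture(x, fix_d1=0.17)
        hist = fit_diffusion_mixture(x, fix_d1=0.17, method="histogram")
        assert hist.a1 == pytest.approx(mle.a1, abs=0.03)

    def test_close_species_flagged_unidentifiable(self):
        rng = np.random.default_rng(10)
        x = rng.gamma(4.0, 0.5 / 4.0, 5000)
        fit = fit_diffusion_mixture(x)
        assert fit.unidentifiable or abs(fit.d1 - fit.d2) >= 0.05

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            fit_diffusion_mixture(np.array([0.5, -0.1, 0.2]))

    def test_mixture_density_is_convex_combination(self):
        x = np.linspace(0.01, 3, 50)
        f = mixture_density(x, 0.17, 0.8, 0.3)
        ref = 0.3 * saxton_density(x, 0.17) + 0.7 * saxton_density(x, 0.8)
        np.testing.assert_allclose(f, ref)

    def test_simulated_d_from_tracks_fits_to_truth(self, oxyr_cfg):
        from stressburst.pipeline import _tracks_from_truth
        from stressburst.simkit import simulate_spt

        locs, truth = simulate_spt(oxyr_cfg, 6000, 5.0, seed=11)
        tracks = _tracks_from_truth(locs, oxyr_cfg.pixel_size)
        d, _ = diffusion_coefficients(tracks, oxyr_cfg.frame_interval_spt)
        fit = fit_diffusion_mixture(d, fix_d1=0.17)
        p_true = float(oxyr_cfg.spt.bound_prob_curve(np.array([5.0]))[0])
        assert fit.a1 == pytest.approx(p_true, abs=0.04)


class TestTimecourse:
    def _fit(self, a1, se=0.01, unident=False):
        from stressburst.containers import DiffusionFitResult

        return DiffusionFitResult(d1=0.17, d2=0.8, a1=a1, n_tracks=1000,
                                  d1_fixed=True, log_likelihood=0.0,
                                  se_a1=se, unidentifiable=unident)

    def test_constant_scenario_flat_series(self):
        fits = [(t, self._fit(0.25)) for t in (0, 5, 10, 15)]
        rs = bound_fraction_timecourse(fits)
        np.testing.assert_allclose(rs.values, 25.0)

    def test_unidentifiable_point_missing(self):
        fits = [(0, self._fit(0.2)), (5, self._fit(0.4, unident=True)),
                (10, self._fit(0.3))]
        rs = bound_fraction_timecourse(fits)
        assert np.isnan(rs.values[1])
        assert rs.values[0] == pytest.approx(20.0)

    def test_exact_exponential_half_life(self):
        t = np.array([5.0, 10, 15, 20, 30, 45])
        y = 10.0 + 25.0 * np.exp(-np.log(2) / 15.0 * (t - 5.0))
        rs = RateSeries(t, y, np.ones(t.size), np.full(t.size, np.nan))
        assert estimate_half_life(rs, basal=10.0) == pytest.approx(15.0,
                                                                   rel=1e-6)

    def test_flat_series_has_no_decay(self):
        t = np.arange(6) * 5.0
        rs = RateSeries(t, np.full(6, 20.0), np.ones(6), np.ones(6))
        with pytest.raises(ValueError):
            estimate_half_life(rs, basal=10.0)

    def test_too_few_post_peak_points_rejected(self):
        t = np.array([0.0, 5.0, 10.0])
        rs = RateSeries(t, np.array([1.0, 3.0, 2.0]), np.ones(3), np.ones(3))
        with pytest.raises(ValueError):
            estimate_half_life(rs, basal=0.5)
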