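"""Trace analysis: divisions, fates, survival, rates, deconvolution."""

import numpy as np
import pandas as pd
import pytest

from stressburst.containers import CellTrace, RateSeries
from stressburst.simkit import simulate_lineage
from stressburst.trenchtrace import (
    align_and_average,
    classify_fate_and_truncate,
    deconvolve_maturation,
    detect_divisions,
    elongation_rate_series,
    mismatch_rate_series,
    promoter_activity,
    survival_curve,
)


def _trace(lengths, dt=3.0, cell_id=0, **kw):
    lengths = np.asarray(lengths, dtype=float)
    return CellTrace(cell_id=cell_id, times=np.arange(lengths.size) * dt,
                     lengths=lengths, **kw)


class TestDivisions:
    def test_fifty_percent_drop_is_one_division(self):
        tr = _trace([2.0, 2.5, 3.0, 3.8, 1.9, 2.4])
        div, gen = detect_divisions(tr)
        assert div.size == 1
        assert div[0] == pytest.approx(4 * 3.0)  # at the 5th point
        assert gen.size == 0

    def test_monotone_trace_has_no_divisions(self):
        tr = _trace(np.linspace(2.0, 4.0, 20))
        div, gen = detect_divisions(tr)
        assert div.size == 0 and gen.size == 0

    def test_generation_times_are_intervals_between_divisions(self):
        L = [2.0, 3.0, 4.0, 2.0, 3.0, 4.0, 2.0]
        div, gen = detect_divisions(_trace(L))
        assert div.size == 2
        np.testing.assert_allclose(gen, [9.0])

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_divisions(_trace([2.0]))

    def test_recovers_ground_truth_divisions(self, wt_cfg):
        cfg = wt_cfg
        sim = simulate_lineage(cfg, 400, 120, seed=21)
        n_true = n_match = 0
        for tr in sim.traces:
            true_div = sim.truth.division_times[tr.cell_id]
            det, _ = detect_divisions(tr)
            n_true += true_div.size
            for t in true_div:
                if det.size and np.min(np.abs(det - t)) <= 3.0:
                    n_match += 1
        assert n_true > 500
        assert n_match / n_true >= 0.99


class TestElongation:
    def test_constant_length_rate_zero(self):
        rs = elongation_rate_series([_trace(np.full(10, 3.0))])
        np.testing.assert_allclose(rs.values, 0.0, atol=1e-12)

    def test_exponential_trace_rate_grows_with_length(self):
        t = np.arange(20) * 3.0
        tr = _trace(2.0 * np.exp(0.02 * t))
        rs = elongation_rate_series([tr])
        # derivative of the exponential: increasing, approx r*L at midpoint
        assert np.all(np.diff(rs.values[~np.isnan(rs.values)]) > 0)
        mid_L = 2.0 * np.exp(0.02 * (t[5:7].mean()))
        assert rs.values[5] == pytest.approx(0.02 * mid_L, rel=0.01)

    def test_division_intervals_excluded(self):
        rs = elongation_rate_series([_trace([2.0, 3.0, 4.0, 2.0, 3.0])])
        assert rs.n_cells_per_frame[2] == 0  # the division interval
        assert np.isnan(rs.values[2])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            elongation_rate_series([])


class TestFates:
    def test_flat_tail_is_arrest_at_tail_start(self):
        L = np.concatenate([2.0 * np.exp(0.03 * np.arange(10) * 3.0)[:10],
                            np.full(8, 2.0 * np.exp(0.03 * 27.0))])
        tr = classify_fate_and_truncate(_trace(L), trench_length_um=50.0)
        assert tr.fate == "arrest"
        assert tr.truncation_time == pytest.approx(10 * 3.0, abs=3.0)

    def test_crossing_trench_length_is_filamentation(self):
        L = 2.0 * np.exp(0.03 * np.arange(30) * 3.0)
        tr = classify_fate_and_truncate(_trace(L), trench_length_um=7.68)
        assert tr.fate == "filamentation"
        assert L[int(tr.truncation_time / 3.0)] >= 7.68

    def test_vanishing_mask_is_lysis(self):
        L = np.array([2.0, 2.2, 2.4, np.nan, np.nan, np.nan])
        tr = classify_fate_and_truncate(_trace(L), trench_length_um=50.0)
        assert tr.fate == "lysis"
        assert tr.truncation_time == pytest.approx(2 * 3.0)

    def test_growing_dividing_cell_is_alive(self):
        L = [2.0, 2.6, 3.4, 4.3, 2.2, 2.8, 3.6, 4.4, 2.3, 2.9]
        tr = classify_fate_and_truncate(_trace(L), trench_length_um=50.0)
        assert tr.fate == "alive"
        assert tr.truncation_time is None

    def test_simulated_fate_accuracy(self, wt_cfg):
        sim = simulate_lineage(wt_cfg, 2000, 180, seed=22)
        trench_um = wt_cfg.optics.trench_length_px * wt_cfg.pixel_size
        truth = sim.truth.fates.set_index("cell_id")["fate"]
        correct = 0
        for tr in sim.traces:
            classify_fate_and_truncate(tr, trench_um)
            correct += tr.fate == truth.loc[tr.cell_id]
        assert correct / len(sim.traces) >= 0.95


class TestSurvival:
    def test_fraction_untruncated(self):
        traces = [_trace(np.full(10, 3.0), cell_id=i) for i in range(10)]
        for tr in traces[:2]:
            tr.truncation_time = 9.0
        rs = survival_curve(traces, t_treatment=0.0)
        assert rs.values[0] == pytest.approx(1.0)
        assert rs.values[-1] == pytest.approx(0.8)

    def test_zero_hazard_curve_is_one(self):
        traces = [_trace(np.full(10, 3.0), cell_id=i) for i in range(5)]
        rs = survival_curve(traces, t_treatment=6.0)
        np.testing.assert_allclose(rs.values, 1.0)

    def test_monotone_nonincreasing_and_bounded(self, wt_cfg, wt_sim):
        trench_um = wt_cfg.optics.trench_length_px * wt_cfg.pixel_size
        for tr in wt_sim.traces:
            classify_fate_and_truncate(tr, trench_um)
        rs = survival_curve(wt_sim.traces, wt_cfg.t_treatment)
        assert np.all(np.diff(rs.values) <= 1e-12)
        assert np.all((rs.values >= 0) & (rs.values <= 1))

    def test_no_cells_alive_is_error(self):
        tr = _trace(np.full(10, 3.0))
        tr.truncation_time = 0.0
        with pytest.raises(ValueError):
            survival_curve([tr], t_treatment=3.0)


class TestMismatchRate:
    def test_rate_formula(self):
        traces = [_trace(np.full(6, 3.0), cell_id=i) for i in range(500)]
        events = pd.DataFrame({"cell_id": np.arange(10), "first_frame": 2,
                               "x_px": 5.0, "y_px": 5.0, "frames_spanned": 1})
        rs = mismatch_rate_series(events, traces, frame_interval=3.0)
        # 10 events / 500 cells / 3 min
        assert rs.values[2] == pytest.approx(10 / 500 / 3)

    def test_no_events_gives_zero(self):
        traces = [_trace(np.full(6, 3.0), cell_id=i) for i in range(10)]
        rs = mismatch_rate_series(pd.DataFrame(columns=["first_frame"]),
                                  traces, 3.0)
        np.testing.assert_allclose(rs.values, 0.0)

    def test_zero_observed_cells_is_missing_not_zero(self):
        tr = _trace(np.array([3.0, 3.1, np.nan, np.nan]))
        rs = mismatch_rate_series(pd.DataFrame(columns=["first_frame"]),
                                  [tr], 3.0)
        assert np.isnan(rs.values[2]) and np.isnan(rs.values[3])

    def test_unbiased_estimator_over_seeds(self, null_cfg):
        # grand mean over 100 simulations at constant rate within 2 SEM
        from stressburst.focidetect import deduplicate_events

        m = null_cfg.mismatch_rate_curve.baseline
        means = []
        for s in range(100):
            sim = simulate_lineage(null_cfg, 100, 90, seed=s)
            ev = deduplicate_events(sim.foci_detections)
            rs = mismatch_rate_series(ev, sim.traces, 3.0,
                                      null_cfg.t_treatment)
            means.append(np.nanmean(rs.values[1:]))
        grand = np.mean(means)
        sem = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(grand - m) < 2 * sem


class TestDeconvolution:
    def test_constant_signal_recovered(self):
        F = np.full(20, 7.5)
        s = deconvolve_maturation(F, tau=6.4, dt=3.0)
        np.testing.assert_allclose(s, 7.5)

    def test_step_response_inverts_to_unit_step(self):
        tau, dt = 6.4, 3.0
        k = np.arange(30)
        alpha = np.exp(-dt / tau)
        F = 1.0 - alpha**k  # response to a unit step at t=0
        s = deconvolve_maturation(F, tau, dt)
        np.testing.assert_allclose(s[1:], 1.0, atol=1e-12)

    def test_derivative_mode_round_trip_fine_sampling(self):
        # smooth signal, 0.1-min sampling: max error < 1e-3 * max(s).
        # Oracle: the continuous convolution with (1/tau) exp(-u/tau) has a
        # closed form for s = A + B sin(w t) + C t (steady state):
        #   F = A + C (t - tau) + B/(1+(w tau)^2) (sin wt - w tau cos wt)
        tau, dt = 6.4, 0.1
        w = 2 * np.pi / 40.0
        t = np.arange(0, 120, dt)
        s = 3.0 + 2.0 * np.sin(w * t) + 0.02 * t
        F = (3.0 + 0.02 * (t - tau)
             + 2.0 / (1 + (w * tau) ** 2) * (np.sin(w * t)
                                             - w * tau * np.cos(w * t)))
        rec = deconvolve_maturation(F, tau, dt, method="derivative")
        err = np.max(np.abs(rec[2:-2] - s[2:-2]))
        assert err < 1e-3 * np.max(np.abs(s))

    def test_exact_mode_round_trip_machine_precision(self):
        rng = np.random.default_rng(0)
        s = np.cumsum(rng.uniform(0, 1, 50))
        tau, dt = 6.4, 3.0
        alpha = np.exp(-dt / tau)
        F = np.empty_like(s)
        F[0] = s[0]
        for i in range(1, s.size):
            F[i] = alpha * F[i - 1] + (1 - alpha) * s[i]
        rec = deconvolve_maturation(F, tau, dt)
        np.testing.assert_allclose(rec, s, atol=1e-9)

    @pytest.mark.parametrize("bad_tau", [0.0, -1.0])
    def test_nonpositive_tau_rejected(self, bad_tau):
        with pytest.raises(ValueError):
            deconvolve_maturation(np.ones(10), bad_tau, 3.0)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            deconvolve_maturation(np.ones(2), 6.4, 3.0)


class TestPromoterActivity:
    def test_linear_intensity_constant_activity(self):
        tr = _trace(np.full(20, 3.0))
        tr.total_intensity = 5.0 * np.arange(20) * 3.0  # slope 5 au/min
        tr.area = np.full(20, 10.0)
        rs = promoter_activity(tr, tau=6.4, dt=3.0)
        # constant-slope input: deconvolution of a ramp adds a constant
        # offset, the derivative is slope/area everywhere in the interior
        np.testing.assert_allclose(rs.values[2:], 5.0 / 10.0, rtol=1e-9)

    def test_constant_intensity_zero_activity(self):
        tr = _trace(np.full(20, 3.0))
        tr.total_intensity = np.full(20, 42.0)
        tr.area = np.full(20, 10.0)
        rs = promoter_activity(tr, tau=6.4, dt=3.0)
        np.testing.assert_allclose(rs.values, 0.0, atol=1e-12)

    def test_zero_area_rejected(self):
        tr = _trace(np.full(20, 3.0))
        tr.total_intensity = np.arange(20.0)
        tr.area = np.zeros(20)
        with pytest.raises(ValueError):
            promoter_activity(tr, tau=6.4, dt=3.0)

    def test_step_induction_activity_precedes_intensity_half_max(self, wt_cfg):
        from stressburst.simkit import simulate_reporter_trace

        sim = simulate_lineage(wt_cfg, 1, 180, seed=23)
        tr = sim.traces[0]
        tr.lengths = np.full_like(tr.lengths, 3.0)  # constant area
        tr = simulate_reporter_trace(wt_cfg, tr, noise_sd=0.0)
        rs = promoter_activity(tr, wt_cfg.maturation_tau, 3.0,
                               wt_cfg.t_treatment)
        t_act_peak = rs.times[np.nanargmax(rs.values)]
        F = tr.total_intensity
        rel = tr.times - wt_cfg.t_treatment
        half = (F[0] + F[-1]) / 2
        t_half = rel[np.argmax(F >= half)]
        assert t_act_peak < t_half


class TestAlignAndAverage:
    def _series(self, shift=0.0, scale=1.0):
        t = np.arange(-10, 11) * 3.0 + shift
        v = scale * np.exp(-((t - shift - 6.0) ** 2) / 40.0)
        return RateSeries(t, v, np.full(t.size, 100), np.full(t.size, 0.01))

    def test_two_identical_replicates_average_to_one(self):
        a, b = self._series(), self._series()
        avg = align_and_average([a, b])
        np.testing.assert_allclose(avg.values, a.values)

    def test_single_replicate_passthrough_with_shift(self):
        a = self._series(shift=60.0)
        avg = align_and_average([a], t_treatments=[60.0])
        np.testing.assert_allclose(avg.times, a.times - 60.0)
        np.testing.assert_allclose(avg.values, a.values)

    def test_peaks_coincide_after_alignment(self):
        a = self._series(shift=60.0)
        b = self._series(shift=90.0)
        avg = align_and_average([a, b], t_treatments=[60.0, 90.0])
        assert avg.times[np.argmax(avg.values)] == pytest.approx(6.0)

    def test_incompatible_cadence_rejected(self):
        a = self._series()
        t = np.arange(-10, 11) * 2.0
        b = RateSeries(t, np.ones(t.size), np.ones(t.size), np.ones(t.size))
        with pytest.raises(ValueError):
            align_and_average([a, b])

    def test_missing_values_carry_no_weight(self):
        a = self._series()
        b = self._series(scale=3.0)
        b.values[5] = np.nan
        avg = align_and_average([a, b])
        assert avg.values[5] == pytest.approx(a.values[5])
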