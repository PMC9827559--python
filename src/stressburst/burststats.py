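"""Summary statistics for burst time courses and mutant-frequency assays."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from stressburst.containers import BurstMetrics, RateSeries

__all__ = ["burst_metrics", "fold_change", "mutant_frequency",
           "MutantFrequencyResult"]


def _smooth3(y: np.ndarray) -> np.ndarray:
    """3-point moving average, NaN-aware, endpoints shortened."""
    out = np.full_like(y, np.nan)
    for i in range(y.size):
        w = y[max(i - 1, 0):i + 2]
        w = w[~np.isnan(w)]
        if w.size:
            out[i] = w.mean()
    return out


def _crossings(t: np.ndarray, y: np.ndarray, level: float) -> np.ndarray:
    """Times where the piecewise-linear series crosses ``level``."""
    out = []
    for i in range(y.size - 1):
        y0, y1 = y[i], y[i + 1]
        if np.isnan(y0) or np.isnan(y1):
            continue
        if (y0 - level) * (y1 - level) < 0:
            frac = (level - y0) / (y1 - y0)
            out.append(t[i] + frac * (t[i + 1] - t[i]))
    return np.array(out)


def _log_quadratic_peak(ts: np.ndarray, ys: np.ndarray, baseline: float,
                        ipk: int) -> tuple[float, float] | None:
    """Refined (peak_value, peak_time) from a weighted parabola fit to
    log(y − baseline) over the contiguous high-signal bins around ``ipk``.

    Returns None when fewer than 4 usable bins exist or the fitted
    parabola is not concave with its vertex inside the fitted span — the
    caller then keeps the single-bin estimate.
    """
    resid = ys - baseline
    if np.isnan(resid[ipk]) or resid[ipk] <= 0:
        return None
    level = 0.3 * resid[ipk]
    lo = ipk
    while lo - 1 >= 0 and not np.isnan(resid[lo - 1]) and resid[lo - 1] > level:
        lo -= 1
    hi = ipk
    while (hi + 1 < resid.size and not np.isnan(resid[hi + 1])
           and resid[hi + 1] > level):
        hi += 1
    sel = np.arange(lo, hi + 1)
    if sel.size < 4:
        return None
    tt, rr = ts[sel], resid[sel]
    w = rr**2  # down-weights low-SNR tail bins of the log transform
    coef = np.polyfit(tt, np.log(rr), 2, w=np.sqrt(w))
    if coef[0] >= 0:
        return None
    t_vertex = -coef[1] / (2 * coef[0])
    if not tt[0] <= t_vertex <= tt[-1]:
        return None
    amp = float(np.exp(np.polyval(coef, t_vertex)))
    return baseline + amp, float(t_vertex)


def burst_metrics(series: RateSeries, baseline_window: float = 60.0
                  ) -> BurstMetrics:
    """Burst summary of a treatment-relative rate time course.

    * baseline — mean over the ``baseline_window`` minutes before time 0;
    * peak — located on a 3-point moving average (robust to single-frame
      noise), with the peak *value* read from the raw series at that
      location so the coarse-cadence smoothing does not bias the amplitude;
    * duration — full width of the region above baseline + (peak −
      baseline)/2, by linear interpolation between samples;
    * fold change — peak / baseline.

    A peak below baseline + 2·SEM is flagged ``no_burst`` (peak statistics
    are then reported against the baseline, duration 0).
    """
    t = series.times
    y = series.values
    pre = (t >= -baseline_window) & (t < 0) & ~np.isnan(y)
    if not np.any(pre):
        raise ValueError("series does not cover the baseline window")
    baseline = float(np.mean(y[pre]))

    post = t >= 0
    ts, ys = t[post], y[post]
    if ts.size < 3:
        raise ValueError("series does not cover the burst region")
    # smooth over the full series so the first post-treatment point is not
    # an endpoint-shortened (upward-biased) window
    ys_smooth = _smooth3(y)[post]
    ipk = int(np.nanargmax(ys_smooth))
    peak_time = float(ts[ipk])
    peak_value = float(ys[ipk]) if not np.isnan(ys[ipk]) else float(ys_smooth[ipk])
    # refine peak amplitude/time by a weighted log-quadratic fit over the
    # burst-region samples (a Gaussian bump is a parabola in log space);
    # a single-bin read is noisy at coarse cadence and biased low whenever
    # noise shifts the smoothed argmax one bin off the true peak
    refined = _log_quadratic_peak(ts, ys, baseline, ipk)
    if refined is not None:
        peak_value, peak_time = refined

    sem_pk = series.sem[post][ipk] if series.sem is not None else np.nan
    no_burst = bool(
        not np.isnan(sem_pk) and peak_value < baseline + 2.0 * sem_pk
    ) or peak_value <= baseline
    if no_burst:
        return BurstMetrics(baseline=baseline, peak_value=peak_value,
                            peak_time=peak_time, duration_fwhm=0.0,
                            fold_change=peak_value / baseline if baseline > 0
                            else np.nan, no_burst=True)

    # half-maximum crossings on the full series: the rising edge of a burst
    # peaking shortly after treatment can cross half-max before time 0
    half = baseline + (peak_value - baseline) / 2.0
    crossings = _crossings(t, y, half)
    left = crossings[crossings <= peak_time]
    right = crossings[crossings >= peak_time]
    t_left = left[-1] if left.size else t[0]
    t_right = right[0] if right.size else t[-1]
    duration = float(t_right - t_left)

    return BurstMetrics(
        baseline=baseline,
        peak_value=peak_value,
        peak_time=peak_time,
        duration_fwhm=duration,
        fold_change=peak_value / baseline if baseline > 0 else np.nan,
        no_burst=False,
    )


def fold_change(series: RateSeries, t: float,
                baseline_window: float = 60.0) -> float:
    """Value at time ``t`` (interpolated) divided by the pre-treatment mean."""
    times, y = series.times, series.values
    pre = (times >= -baseline_window) & (times < 0) & ~np.isnan(y)
    if not np.any(pre):
        raise ValueError("series does not cover the baseline window")
    baseline = float(np.mean(y[pre]))
    if baseline == 0:
        raise ValueError("baseline is zero; fold change undefined")
    ok = ~np.isnan(y)
    value = float(np.interp(t, times[ok], y[ok]))
    return value / baseline


@dataclass
class MutantFrequencyResult:
    """Per-culture mutant frequencies with group statistics."""

    frequencies: np.ndarray
    mean: float
    sem: float
    t_statistic: float = np.nan
    p_value: float = np.nan


def mutant_frequency(rif_counts, lb_counts, lb_dilution: float,
                     other: MutantFrequencyResult | None = None
                     ) -> MutantFrequencyResult:
    """Rifampicin-resistance mutant frequency per culture.

    frequency = rif colonies / (LB colonies / dilution); e.g. LB plated at
    a 10⁻⁷ dilution means ``lb_dilution = 1e-7``. When ``other`` is given,
    a Welch (unequal-variance) two-sample t-test between the two groups is
    reported on the result.
    """
    rif = np.asarray(rif_counts, dtype=float)
    lb = np.asarray(lb_counts, dtype=float)
    if np.any(lb <= 0):
        raise ValueError("LB colony counts must be positive")
    if np.any(rif < 0):
        raise ValueError("rifampicin colony counts must be nonnegative")
    freq = rif / (lb / lb_dilution)
    mean = float(np.mean(freq))
    sem = float(np.std(freq, ddof=1) / np.sqrt(freq.size)) if freq.size > 1 else np.nan
    res = MutantFrequencyResult(frequencies=freq, mean=mean, sem=sem)
    if other is not None:
        t_stat, p = stats.ttest_ind(freq, other.frequencies, equal_var=False)
        res.t_statistic = float(t_stat)
        res.p_value = float(p)
    return res
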