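"""Single-particle-tracking analysis.

Nearest-neighbour track linking with a one-frame memory, per-track apparent
diffusion coefficients from the mean squared displacement over four steps
(D = MSD/(4·Δt)), and the two-species mixture fit of the resulting
diffusion-coefficient distribution.

The per-track estimate is the mean of four independent lag-1 squared
displacements; for 2-D Brownian motion each squared displacement is
exponential with mean 4·D·Δt, so D_est follows a gamma distribution with
shape 4 and rate 4/D:

    f(x; D) = (4/D)^4 · x^3 · e^(−4x/D) / 6

The measured distribution is fitted as A1·f(x; D1) + A2·f(x; D2) with
A1 + A2 = 1; A1 is interpreted as the DNA-bound (immobile) fraction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, linear_sum_assignment, minimize

from stressburst.containers import DiffusionFitResult, RateSeries, Track

__all__ = ["link_tracks", "track_diffusion_coefficient",
           "diffusion_coefficients", "saxton_density", "mixture_density",
           "fit_diffusion_mixture", "bound_fraction_timecourse",
           "estimate_half_life"]

#: number of averaged lag-1 steps in the per-track estimate
N_STEPS = 4
#: |D1 − D2| below which the two-species fit is flagged unidentifiable, μm²/s
RESOLUTION_LIMIT = 0.05
#: deterministic multi-start points (D1, D2, A1) for the mixture fit
FIT_STARTS = ((0.1, 0.5, 0.3), (0.17, 0.8, 0.3), (0.2, 1.0, 0.5))


# ---------------------------------------------------------------------------
# linking

def link_tracks(localizations: pd.DataFrame, max_disp: float = 8.0,
                memory: int = 1, pixel_size: float = 0.096) -> list[Track]:
    """Link frame-to-frame localizations into tracks.

    Localizations within ``max_disp`` pixels in consecutive frames are
    linked; a track may skip up to ``memory`` frames (blinking or missed
    detection). Conflicts within a frame pair are resolved by minimizing
    the total displacement (optimal assignment); ties fall to the lowest
    localization index. Positions are converted to μm with ``pixel_size``.
    """
    if max_disp < 0:
        raise ValueError("max_disp must be nonnegative")
    cols = ["frame", "x_px", "y_px"]
    df = localizations[cols].sort_values("frame", kind="stable")
    frames = df["frame"].to_numpy(int)
    xy = df[["x_px", "y_px"]].to_numpy(float)

    finished: list[dict] = []
    active: list[dict] = []
    for f in np.unique(frames):
        pts = xy[frames == f]
        # retire tracks whose last frame is beyond memory reach
        keep = []
        for tr in active:
            if f - tr["frames"][-1] > memory + 1:
                finished.append(tr)
            else:
                keep.append(tr)
        active = keep

        assigned = np.full(len(pts), False)
        if active and len(pts):
            last = np.array([tr["pos"][-1] for tr in active])
            dist = np.linalg.norm(last[:, None, :] - pts[None, :, :], axis=2)
            big = 1e6
            cost = np.where(dist <= max_disp, dist, big)
            ti, pi = linear_sum_assignment(cost)
            for a, b in zip(ti, pi):
                if cost[a, b] < big:
                    active[a]["frames"].append(int(f))
                    active[a]["pos"].append(pts[b])
                    assigned[b] = True
        for i in np.flatnonzero(~assigned):
            active.append({"frames": [int(f)], "pos": [pts[i]]})
    finished.extend(active)

    tracks = []
    tid = 0
    for tr in finished:
        if len(tr["frames"]) < 2:
            continue
        tracks.append(
            Track(
                track_id=tid,
                frames=np.array(tr["frames"]),
                positions=np.array(tr["pos"]) * pixel_size,
            )
        )
        tid += 1
    return tracks


# ---------------------------------------------------------------------------
# per-track D

def track_diffusion_coefficient(track: Track, dt: float,
                                n_steps: int = N_STEPS) -> float | None:
    """Apparent diffusion coefficient of one track, or None if discarded.

    The track is truncated to its first ``n_steps + 1`` localizations; the
    MSD is the mean of the ``n_steps`` lag-1 squared displacements. Steps
    across a memory gap contribute no displacement; a track with fewer
    than ``n_steps`` usable lag-1 steps is discarded (returns None).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if track.frames.size < n_steps + 1:
        return None
    frames = track.frames[:n_steps + 1]
    pos = track.positions[:n_steps + 1]
    lag1 = np.diff(frames) == 1
    if lag1.sum() < n_steps:
        return None
    disp = np.diff(pos, axis=0)[lag1]
    msd = float(np.mean(np.sum(disp**2, axis=1)))
    return msd / (4.0 * dt)


def diffusion_coefficients(tracks: list[Track], dt: float,
                           n_steps: int = N_STEPS
                           ) -> tuple[np.ndarray, int]:
    """Per-track D for an ensemble; returns (values, number discarded)."""
    vals = []
    discarded = 0
    for tr in tracks:
        d = track_diffusion_coefficient(tr, dt, n_steps)
        if d is None:
            discarded += 1
        else:
            tr.d_est = d
            vals.append(d)
    return np.array(vals), discarded


# ---------------------------------------------------------------------------
# two-species mixture

def saxton_density(x, D: float) -> np.ndarray:
    """Single-species density of the 4-step D estimate: gamma(4, 4/D).

    Mean D, mode 3D/4; integrates to 1 for any D > 0.
    """
    if D <= 0:
        raise ValueError("D must be positive")
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    r = 4.0 / D
    out[pos] = r**4 * x[pos] ** 3 * np.exp(-r * x[pos]) / 6.0
    return out


def mixture_density(x, d1: float, d2: float, a1: float) -> np.ndarray:
    return a1 * saxton_density(x, d1) + (1.0 - a1) * saxton_density(x, d2)


def _nll(x: np.ndarray, d1: float, d2: float, a1: float) -> float:
    dens = mixture_density(x, d1, d2, a1)
    return float(-np.sum(np.log(np.clip(dens, 1e-300, None))))


def _hessian_se(fun, theta: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Standard errors from the observed information (numerical Hessian)."""
    k = theta.size
    h = np.maximum(np.abs(theta), 1e-3) * rel_step
    H = np.zeros((k, k))
    f0 = fun(theta)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                H[i, i] = (fun(theta + ei) - 2 * f0 + fun(theta - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    fun(theta + ei + ej) - fun(theta + ei - ej)
                    - fun(theta - ei + ej) + fun(theta - ei - ej)
                ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    return se


def fit_diffusion_mixture(d_ests: np.ndarray, fix_d1: float | None = None,
                          method: str = "mle",
                          n_bins: int = 60) -> DiffusionFitResult:
    """Fit the two-species mixture to per-track diffusion coefficients.

    Maximum likelihood on the raw values by default (no binning); the
    constraint A1 + A2 = 1 is structural. With ``fix_d1`` only D2 and A1
    are free — the convention for per-time-point fits after pooling fixes
    the immobile species' D. ``method="histogram"`` fits the binned
    empirical density by least squares instead, as a cross-check.
    """
    x = np.asarray(d_ests, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 diffusion-coefficient values")
    if np.any(x <= 0):
        raise ValueError("diffusion-coefficient values must be positive")

    if method == "histogram":
        hi = np.quantile(x, 0.999)
        counts, edges = np.histogram(x, bins=n_bins, range=(0, hi), density=True)
        centers = (edges[:-1] + edges[1:]) / 2.0

        if fix_d1 is None:
            def model(c, d1, d2, a1):
                return mixture_density(c, d1, d2, a1)
            p0 = (0.17, 0.8, 0.3)
            bounds = ([1e-4, 1e-4, 0.0], [10.0, 10.0, 1.0])
        else:
            def model(c, d2, a1):
                return mixture_density(c, fix_d1, d2, a1)
            p0 = (0.8, 0.3)
            bounds = ([1e-4, 0.0], [10.0, 1.0])
        popt, _ = curve_fit(model, centers, counts, p0=p0, bounds=bounds,
                            maxfev=20000)
        if fix_d1 is None:
            d1, d2, a1 = popt
        else:
            d1, (d2, a1) = fix_d1, popt
        if d1 > d2:
            d1, d2, a1 = d2, d1, 1.0 - a1
        return DiffusionFitResult(
            d1=float(d1), d2=float(d2), a1=float(a1), n_tracks=x.size,
            d1_fixed=fix_d1 is not None, log_likelihood=-_nll(x, d1, d2, a1),
            unidentifiable=bool(abs(d2 - d1) < RESOLUTION_LIMIT),
        )

    if method != "mle":
        raise ValueError(f"unknown method {method!r}")

    # MLE in transformed coordinates: log D, logit A1
    def unpack(theta):
        if fix_d1 is None:
            d1, d2 = np.exp(theta[0]), np.exp(theta[1])
            a1 = 1.0 / (1.0 + np.exp(-theta[2]))
        else:
            d1 = fix_d1
            d2 = np.exp(theta[0])
            a1 = 1.0 / (1.0 + np.exp(-theta[1]))
        return d1, d2, a1

    def objective(theta):
        return _nll(x, *unpack(theta))

    best = None
    diagnostics = []
    for s_d1, s_d2, s_a1 in FIT_STARTS:
        if fix_d1 is None:
            theta0 = [np.log(s_d1), np.log(s_d2),
                      np.log(s_a1 / (1.0 - s_a1))]
        else:
            theta0 = [np.log(s_d2), np.log(s_a1 / (1.0 - s_a1))]
        res = minimize(objective, theta0, method="L-BFGS-B")
        diagnostics.append((theta0, res.success, res.fun))
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(
            f"mixture fit failed to converge from all starts: {diagnostics}"
        )

    d1, d2, a1 = unpack(best.x)
    if d1 > d2 and fix_d1 is None:
        d1, d2, a1 = d2, d1, 1.0 - a1

    # observed-information standard errors in natural coordinates
    if fix_d1 is None:
        def nat_nll(p):
            return _nll(x, p[0], p[1], np.clip(p[2], 1e-9, 1 - 1e-9))
        se = _hessian_se(nat_nll, np.array([d1, d2, a1]))
        se_d1, se_d2, se_a1 = se
    else:
        def nat_nll(p):
            return _nll(x, d1, p[0], np.clip(p[1], 1e-9, 1 - 1e-9))
        se = _hessian_se(nat_nll, np.array([d2, a1]))
        se_d1, (se_d2, se_a1) = 0.0, se

    return DiffusionFitResult(
        d1=float(d1), d2=float(d2), a1=float(a1), n_tracks=int(x.size),
        d1_fixed=fix_d1 is not None, log_likelihood=float(-best.fun),
        se_d1=float(se_d1), se_d2=float(se_d2), se_a1=float(se_a1),
        unidentifiable=bool(abs(d2 - d1) < RESOLUTION_LIMIT),
    )


# ---------------------------------------------------------------------------
# time courses

def bound_fraction_timecourse(fits: list[tuple[float, DiffusionFitResult]]
                              ) -> RateSeries:
    """Bound fraction A1 (in %) vs time from per-time-point fits.

    Unidentifiable fits are emitted as missing (NaN).
    """
    times = np.array([t for t, _ in fits], dtype=float)
    order = np.argsort(times)
    vals, sems, ns = [], [], []
    for i in order:
        _, fit = fits[i]
        if fit.unidentifiable:
            vals.append(np.nan)
            sems.append(np.nan)
            ns.append(0)
        else:
            vals.append(fit.a1 * 100.0)
            sems.append(fit.se_a1 * 100.0)
            ns.append(fit.n_tracks)
    return RateSeries(times[order], np.array(vals), np.array(ns),
                      np.array(sems))


def estimate_half_life(series: RateSeries, basal: float) -> float:
    """Half-life (minutes) of the post-peak exponential decay toward basal.

    Fits y(t) − basal = (y_peak − basal)·exp(−k·(t − t_peak)) by least
    squares on the points from the peak onward; ``basal`` must be in the
    same units as the series values. Raises on a flat or rising tail.
    """
    t = series.times
    y = series.values
    ok = ~np.isnan(y)
    t, y = t[ok], y[ok]
    if t.size < 4:
        raise ValueError("need a peak followed by at least 3 points")
    ipk = int(np.argmax(y))
    tp, yp = t[ipk:], y[ipk:]
    if tp.size < 4:
        raise ValueError("need at least 3 points after the peak")
    resid = yp - basal
    if np.any(resid <= 0):
        # keep only the strictly-above-basal head for the log-linear seed
        cut = np.argmax(resid <= 0)
        if cut < 3:
            raise ValueError("series does not decay above basal")
        seed_t, seed_r = tp[:cut], resid[:cut]
    else:
        seed_t, seed_r = tp, resid
    slope, _ = np.polyfit(seed_t - seed_t[0], np.log(seed_r), 1)
    k0 = -slope
    if k0 <= 0:
        raise ValueError("series does not decay after its maximum")

    amp0 = resid[0]

    def model(tt, amp, k):
        return amp * np.exp(-k * (tt - tp[0]))

    popt, _ = curve_fit(model, tp, resid, p0=(amp0, k0), maxfev=10000)
    k = popt[1]
    if k <= 0:
        raise ValueError("fitted decay rate is not positive")
    return float(np.log(2.0) / k)
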