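"""Synthetic mother-machine and single-particle-tracking experiments.

Everything here generates data with the statistical structure the analysis
modules assume, together with a :class:`~stressburst.containers.GroundTruth`
registry so recovery can be measured exactly:

* :func:`simulate_lineage` — mother-cell length traces with exponential
  elongation, near-half divisions, an inhomogeneous death hazard expressed
  as arrest / lysis / filamentation, and mismatch-focus events drawn from an
  inhomogeneous Poisson process (each visible for a configurable number of
  consecutive frames, so first-frame deduplication matters).
* :func:`simulate_reporter_trace` — forward model of a maturation-filtered
  fluorescent reporter (exponential kernel).
* :func:`simulate_spt` — two-state (bound/free) Brownian trajectories in a
  reflecting rectangular cell footprint at the SPT frame interval.

All randomness flows through a ``numpy.random.Generator`` seeded per call;
identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from stressburst.config import ScenarioConfig
from stressburst.containers import CellTrace, GroundTruth

__all__ = ["LineageResult", "simulate_lineage", "simulate_reporter_trace",
           "simulate_spt"]


@dataclass
class LineageResult:
    """Traces plus the raw (pre-deduplication) focus detections and truth."""

    traces: list[CellTrace]
    #: columns: cell_id, frame, x_px, y_px, intensity — one row per frame a
    #: focus is visible in (events persist, so consecutive-frame duplicates
    #: are present by construction)
    foci_detections: pd.DataFrame
    truth: GroundTruth


def _truncated_normal(rng: np.random.Generator, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _sample_death_times(cfg: ScenarioConfig, rel_times: np.ndarray,
                        rng: np.random.Generator, n_cells: int) -> np.ndarray:
    """Inverse-CDF sampling of death times from the inhomogeneous hazard.

    Returns death time on the relative clock; +inf for cells that outlive
    the movie. The cumulative hazard is piecewise exact on the frame grid.
    """
    hazard = cfg.death_hazard_curve
    cum = np.zeros(rel_times.size)
    for i in range(1, rel_times.size):
        cum[i] = cum[i - 1] + hazard.integral(rel_times[i - 1], rel_times[i])
    target = -np.log(rng.uniform(size=n_cells))
    death = np.full(n_cells, np.inf)
    doomed = target < cum[-1]
    if np.any(doomed):
        # linear interpolation of the cumulative hazard between frames
        death[doomed] = np.interp(target[doomed], cum, rel_times)
    return death


def simulate_lineage(cfg: ScenarioConfig, n_cells: int, duration: float,
                     seed: int, express_fates: bool = True) -> LineageResult:
    """Simulate ``n_cells`` mother cells over ``duration`` minutes.

    Parameters
    ----------
    cfg
        Scenario; all curves are evaluated on the treatment-relative clock.
    n_cells, duration
        Number of mother cells and movie length in minutes.
    seed
        Seed for this simulation's private random generator.
    express_fates
        When False, death only truncates the ground-truth clock but the
        length traces remain unperturbed — used to check survival against
        exp(−∫h) without fate-classification effects.
    """
    if n_cells <= 0 or duration <= 0:
        raise ValueError("n_cells and duration must be positive")
    rng = np.random.default_rng(seed)
    dt = cfg.frame_interval_trace
    n_frames = int(np.floor(duration / dt)) + 1
    times = np.arange(n_frames) * dt
    rel = times - cfg.t_treatment

    lam = cfg.elongation_rate_curve
    rate_mid = lam(rel[:-1] + dt / 2.0)  # specific rate per inter-frame interval

    # desynchronized initial lengths, uniform in log-phase of the cycle
    L = cfg.birth_length_um * np.exp(
        rng.uniform(size=n_cells) * np.log(cfg.division_length_um / cfg.birth_length_um)
    )
    lengths = np.empty((n_cells, n_frames))
    lengths[:, 0] = L

    death_rel = _sample_death_times(cfg, rel, rng, n_cells)
    death_abs = death_rel + cfg.t_treatment
    fate_names = list(cfg.fate_mix.keys())
    fate_probs = np.array([cfg.fate_mix[k] for k in fate_names])
    fates = np.array(fate_names)[rng.choice(len(fate_names), size=n_cells, p=fate_probs)]
    fates = np.where(np.isinf(death_rel), "alive", fates)

    division_times: dict[int, list[float]] = {i: [] for i in range(n_cells)}
    trench_um = cfg.optics.trench_length_px * cfg.pixel_size

    for k in range(n_frames - 1):
        t_next = times[k + 1]
        growing = np.ones(n_cells, dtype=bool)
        if express_fates:
            # arrested cells stop growing at death; filamentous keep growing
            growing &= ~((fates == "arrest") & (t_next > death_abs))
        grown = np.where(growing, L * np.exp(rate_mid[k] * dt), L)
        may_divide = grown > cfg.division_length_um
        if express_fates:
            may_divide &= ~((fates != "alive") & (t_next > death_abs))
        idx = np.flatnonzero(may_divide)
        if idx.size:
            q = _truncated_normal(rng, 0.5, 0.05, 0.35, 0.65, idx.size)
            grown[idx] *= q
            for i in idx:
                division_times[int(i)].append(float(t_next))
        L = grown
        lengths[:, k + 1] = L

    # multiplicative length measurement noise
    if cfg.length_noise_cv > 0:
        lengths *= np.exp(rng.normal(0.0, cfg.length_noise_cv, size=lengths.shape))

    # express lysis (mask vanishes) after death
    if express_fates:
        for i in np.flatnonzero(fates == "lysis"):
            lengths[i, times > death_abs[i]] = np.nan

    # ------------------------------------------------------------------
    # mismatch-focus events: inhomogeneous Poisson per cell per interval
    m = cfg.mismatch_rate_curve
    interval_lambda = np.array(
        [m.integral(rel[k], rel[k + 1]) for k in range(n_frames - 1)]
    )
    persist = cfg.foci_persistence_frames
    det_rows = []
    ev_rows = []
    counts = rng.poisson(np.broadcast_to(interval_lambda, (n_cells, n_frames - 1)))
    cell_w_px = 6.0
    x_margin = (cfg.optics.trench_width_px - cell_w_px) / 2.0
    for i, k in zip(*np.nonzero(counts)):
        for _ in range(counts[i, k]):
            t_ev = rng.uniform(times[k], times[k + 1])
            if t_ev >= death_abs[i]:  # no replication after death
                continue
            first_frame = k + 1
            L_px = lengths[i, first_frame] / cfg.pixel_size
            if np.isnan(L_px):
                continue
            # foci sit on the nucleoid: inset 1 px from the footprint edge
            y = rng.uniform(1.0, max(L_px - 1.0, 2.0))
            x = x_margin + 1.0 + rng.uniform(0.0, cell_w_px - 2.0)
            ev_rows.append((int(i), t_ev, first_frame, x, y))
            for j in range(persist):
                f = first_frame + j
                if f >= n_frames or times[f] > death_abs[i]:
                    break
                jitter = rng.normal(0.0, 0.3, size=2)
                det_rows.append(
                    (int(i), f, x + jitter[0], y + jitter[1],
                     cfg.optics.focus_amplitude)
                )

    detections = pd.DataFrame(
        det_rows, columns=["cell_id", "frame", "x_px", "y_px", "intensity"]
    ).sort_values(["frame", "cell_id"], kind="stable").reset_index(drop=True)
    truth_events = pd.DataFrame(
        ev_rows, columns=["cell_id", "time_min", "first_frame", "x_px", "y_px"]
    )

    traces = []
    for i in range(n_cells):
        traces.append(
            CellTrace(
                cell_id=i,
                times=times.copy(),
                lengths=lengths[i],
                fate="alive",  # labels are the analysis side's job
            )
        )

    truth = GroundTruth(
        division_times={i: np.array(v) for i, v in division_times.items()},
        foci_events=truth_events,
        fates=pd.DataFrame(
            {
                "cell_id": np.arange(n_cells),
                "fate": fates,
                "death_time_min": death_abs,
            }
        ),
    )
    _ = trench_um  # geometry checked by the renderer
    return LineageResult(traces=traces, foci_detections=detections, truth=truth)


def simulate_reporter_trace(cfg: ScenarioConfig, trace: CellTrace,
                            seed: int | None = None,
                            noise_sd: float = 0.0) -> CellTrace:
    """Attach a maturation-filtered reporter signal to a trace.

    The true (instant-maturation) total-intensity signal accumulates at the
    promoter activity (au·min⁻¹·px⁻²) times the cell area; the observed
    signal is its convolution with the exponential maturation kernel
    k(u) = (1/τ)·exp(−u/τ), discretized as a zero-order-hold filter, plus
    optional additive Gaussian noise. Both signals are stored (the true one
    in ``trace.reporter_true``).
    """
    tau = cfg.maturation_tau
    if tau <= 0:
        raise ValueError("maturation_tau must be positive")
    rng = np.random.default_rng(seed)
    rel = trace.times - cfg.t_treatment
    activity = cfg.promoter_activity_curve(rel)  # au/min/px²
    L_px = trace.lengths / cfg.pixel_size
    area = np.nan_to_num(L_px * 6.0)  # px², 6-px cell width

    production = activity * area  # au/min
    dt = np.diff(trace.times)
    s = np.concatenate(([0.0], np.cumsum(0.5 * (production[1:] + production[:-1]) * dt)))

    alpha = np.exp(-cfg.frame_interval_trace / tau)
    F = np.empty_like(s)
    F[0] = s[0]
    for k in range(1, s.size):
        F[k] = alpha * F[k - 1] + (1.0 - alpha) * s[k]
    if noise_sd > 0:
        F = F + rng.normal(0.0, noise_sd, size=F.size)

    trace.total_intensity = F
    with np.errstate(divide="ignore", invalid="ignore"):
        trace.reporter_intensity = np.where(area > 0, F / area, np.nan)
    trace.area = area
    trace.reporter_true = s  # noqa: attached for recovery tests
    return trace


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold coordinates back into [lo, hi] by reflection."""
    width = hi - lo
    y = np.mod(x - lo, 2.0 * width)
    y = np.where(y > width, 2.0 * width - y, y)
    return y + lo


def simulate_spt(cfg: ScenarioConfig, n_molecules: int, t_sample: float,
                 seed: int) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one SPT acquisition at ``t_sample`` minutes post-treatment.

    Each molecule is bound with probability ``bound_prob_curve(t_sample)``
    and performs 2-D Brownian motion (per-axis step variance 2·D·Δt) inside
    a reflecting rectangle; optional bound↔free switching at ``k_switch``
    preserves the stationary bound probability. Track lengths are geometric
    with the configured mean; start frames are staggered to the configured
    molecule density. Localizations are returned in pixels.
    """
    if n_molecules <= 0:
        raise ValueError("n_molecules must be positive")
    spt = cfg.spt
    if spt.d_bound < 0 or spt.d_free < 0:
        raise ValueError("diffusion coefficients must be >= 0")
    rng = np.random.default_rng(seed)
    dt = cfg.frame_interval_spt
    p_bound = float(spt.bound_prob_curve(np.array([t_sample]))[0])

    lengths = rng.geometric(1.0 / spt.track_length_mean, size=n_molecules)
    lengths = np.maximum(lengths, 2)
    total_frames = max(int(np.ceil(lengths.sum() / spt.density)), int(lengths.max()) + 1)
    starts = rng.integers(0, total_frames, size=n_molecules)
    bound = rng.uniform(size=n_molecules) < p_bound

    d_bound_eff = 0.0 if spt.explicit_error else spt.d_bound
    Lc, Wc = spt.cell_length_um, spt.cell_width_um

    # flat row layout: one row per (molecule, frame)
    total = int(lengths.sum())
    mol = np.repeat(np.arange(n_molecules), lengths)
    first_row = np.concatenate(([0], np.cumsum(lengths)[:-1]))
    is_first = np.zeros(total, dtype=bool)
    is_first[first_row] = True
    within = np.arange(total) - np.repeat(first_row, lengths)
    frames = starts[mol] + within

    # per-row bound state
    if spt.k_switch > 0 and 0 < p_bound < 1:
        p_unbind = 1.0 - np.exp(-spt.k_switch * dt)
        p_bind = 1.0 - np.exp(-spt.k_switch * dt * p_bound / (1.0 - p_bound))
        state = np.empty(total, dtype=bool)
        u = rng.uniform(size=total)
        for r in range(total):  # rarely used path; switching defaults off
            if is_first[r]:
                state[r] = bound[mol[r]]
            elif state[r - 1]:
                state[r] = not (u[r] < p_unbind)
            else:
                state[r] = u[r] < p_bind
    else:
        state = bound[mol]

    D_row = np.where(state, d_bound_eff, spt.d_free)
    steps = rng.normal(size=(total, 2)) * np.sqrt(2.0 * D_row[:, None] * dt)
    steps[is_first] = 0.0
    cs = np.cumsum(steps, axis=0)
    seg_cum = cs - np.repeat(cs[first_row], lengths, axis=0)  # 0 at track start

    x0 = np.column_stack([rng.uniform(0, Lc, n_molecules),
                          rng.uniform(0, Wc, n_molecules)])
    free = x0[mol] + seg_cum
    # folding the free path into the box is reflected Brownian motion in law
    pos = np.column_stack([_reflect(free[:, 0], 0.0, Lc),
                           _reflect(free[:, 1], 0.0, Wc)])
    obs = pos
    if spt.loc_error_sigma > 0:
        obs = pos + rng.normal(0.0, spt.loc_error_sigma, size=pos.shape)

    locs = pd.DataFrame(
        {
            "track_id": mol,
            "frame": frames,
            "x_px": obs[:, 0] / cfg.pixel_size,
            "y_px": obs[:, 1] / cfg.pixel_size,
            "intensity": 1000.0,
            "bound": state,
        }
    )
    true_positions = {
        int(m): pos[first_row[m]:first_row[m] + lengths[m]]
        for m in range(n_molecules)
    }
    truth = GroundTruth(
        states=pd.DataFrame({"track_id": np.arange(n_molecules), "bound": bound}),
        true_positions=true_positions,
    )
    return locs, truth
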