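"""End-to-end pipelines tying the stages together, with run manifests.

Two pipelines mirror the two experimental arms:

* :func:`run_trace_pipeline` — simulate a mother-machine experiment,
  deduplicate foci, classify fates, and produce elongation / survival /
  mismatch-rate series plus burst metrics.
* :func:`run_spt_pipeline` — simulate SPT acquisitions over a series of
  time points, link tracks, compute per-track D, pool-fit the two-species
  mixture (both D free), re-fit each time point with D1 fixed at the
  pooled value, and estimate the bound-fraction half-life.

All randomness flows from a single root seed split per stage with
``numpy.random.SeedSequence(root).spawn``; the same seed reproduces every
output bit for bit.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from stressburst import __version__
from stressburst.burststats import burst_metrics
from stressburst.config import ScenarioConfig
from stressburst.containers import RateSeries
from stressburst.diffusionfit import (
    bound_fraction_timecourse,
    diffusion_coefficients,
    estimate_half_life,
    fit_diffusion_mixture,
    link_tracks,
)
from stressburst.focidetect import deduplicate_events
from stressburst.io import write_traces_csv
from stressburst.simkit import simulate_lineage, simulate_spt
from stressburst.trenchtrace import (
    classify_fate_and_truncate,
    elongation_rate_series,
    mismatch_rate_series,
    survival_curve,
)

__all__ = ["RunManifest", "run_trace_pipeline", "run_spt_pipeline"]


@dataclass
class RunManifest:
    """What a pipeline run did: scenario, seed, stages and output files."""

    scenario: str
    seed: int
    version: str = __version__
    stages: list[dict] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    started: str = ""
    finished: str = ""

    def add_stage(self, name: str, **info) -> None:
        self.stages.append({"name": name, **info})

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def _stage_seeds(root: int, n: int) -> list[int]:
    children = np.random.SeedSequence(root).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def _write_series(series: RateSeries, path: Path) -> None:
    series.to_frame().to_csv(path, index=False)


def run_trace_pipeline(cfg: ScenarioConfig, out_dir: str | Path, seed: int,
                       n_cells: int = 2000, duration: float = 180.0
                       ) -> RunManifest:
    """Simulate and analyze one mother-machine experiment."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(scenario=cfg.name, seed=seed,
                           started=time.strftime("%Y-%m-%dT%H:%M:%S"))
    (sim_seed,) = _stage_seeds(seed, 1)

    sim = simulate_lineage(cfg, n_cells, duration, seed=sim_seed)
    manifest.add_stage("simulate", n_cells=n_cells, duration_min=duration,
                       seed=sim_seed)

    events = deduplicate_events(sim.foci_detections)
    manifest.add_stage("deduplicate", n_detections=len(sim.foci_detections),
                       n_events=len(events))

    trench_um = cfg.optics.trench_length_px * cfg.pixel_size
    for tr in sim.traces:
        classify_fate_and_truncate(tr, trench_um)
    manifest.add_stage("classify_fates",
                       n_dead=sum(t.fate != "alive" for t in sim.traces))

    dt = cfg.frame_interval_trace
    elong = elongation_rate_series(sim.traces, cfg.t_treatment)
    surv = survival_curve(sim.traces, cfg.t_treatment)
    rate = mismatch_rate_series(events, sim.traces, dt, cfg.t_treatment)
    metrics = burst_metrics(rate, baseline_window=min(60.0, cfg.t_treatment)
                            if cfg.t_treatment > 0 else 60.0)
    manifest.add_stage("burst_metrics", **metrics.to_dict())

    write_traces_csv(sim.traces, out / "traces.csv")
    events.to_csv(out / "events.csv", index=False)
    _write_series(elong, out / "elongation_rate.csv")
    _write_series(surv, out / "survival.csv")
    _write_series(rate, out / "mismatch_rate.csv")
    with open(out / "burst_metrics.json", "w") as fh:
        json.dump(metrics.to_dict(), fh, indent=2)
    manifest.outputs = sorted(p.name for p in out.iterdir() if p.is_file()
                              and p.name != "manifest.json")
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.to_json(out / "manifest.json")
    manifest.outputs.append("manifest.json")
    return manifest


def run_spt_pipeline(cfg: ScenarioConfig, out_dir: str | Path, seed: int,
                     timepoints: tuple[float, ...] = (0, 5, 10, 15, 20, 30, 45),
                     n_molecules: int = 2000,
                     use_linking: bool = True) -> RunManifest:
    """Simulate and analyze the SPT time-course experiment.

    ``use_linking=False`` bypasses the linker and groups localizations by
    their ground-truth track id (useful when only the downstream fit is of
    interest).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(scenario=cfg.name, seed=seed,
                           started=time.strftime("%Y-%m-%dT%H:%M:%S"))
    seeds = _stage_seeds(seed, len(timepoints))
    dt = cfg.frame_interval_spt

    per_tp_d = []
    for t_sample, s in zip(timepoints, seeds):
        locs, _ = simulate_spt(cfg, n_molecules, t_sample, seed=s)
        if use_linking:
            tracks = link_tracks(locs, max_disp=8.0, memory=1,
                                 pixel_size=cfg.pixel_size)
        else:
            tracks = _tracks_from_truth(locs, cfg.pixel_size)
        d_vals, discarded = diffusion_coefficients(tracks, dt)
        per_tp_d.append(d_vals)
        manifest.add_stage("simulate_spt", t_min=float(t_sample), seed=s,
                           n_molecules=n_molecules, n_tracks=len(tracks),
                           n_discarded=discarded)

    pooled = np.concatenate(per_tp_d)
    pooled_fit = fit_diffusion_mixture(pooled, fix_d1=None)
    manifest.add_stage("pooled_fit", **pooled_fit.to_dict())

    fits = []
    for t_sample, d_vals in zip(timepoints, per_tp_d):
        fit = fit_diffusion_mixture(d_vals, fix_d1=pooled_fit.d1)
        fits.append((float(t_sample), fit))
        manifest.add_stage("timepoint_fit", t_min=float(t_sample),
                           **fit.to_dict())

    series = bound_fraction_timecourse(fits)
    _write_series(series, out / "bound_fraction.csv")

    result = {"pooled": pooled_fit.to_dict(),
              "timepoints": [{"t_min": t, **f.to_dict()} for t, f in fits]}
    if len(timepoints) >= 4:
        basal = series.values[series.times <= 0]
        basal = float(basal[0]) if basal.size else float(np.nanmin(series.values))
        half_life = estimate_half_life(series, basal)
        result["half_life_min"] = half_life
        manifest.add_stage("half_life", basal_percent=basal,
                           half_life_min=half_life)
    else:
        result["half_life_min"] = None
        manifest.add_stage("half_life", skipped="need >= 4 time points")

    with open(out / "diffusion_fits.json", "w") as fh:
        json.dump(result, fh, indent=2)
    manifest.outputs = sorted(p.name for p in out.iterdir() if p.is_file()
                              and p.name != "manifest.json")
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.to_json(out / "manifest.json")
    manifest.outputs.append("manifest.json")
    return manifest


def _tracks_from_truth(locs, pixel_size: float):
    """Group a localization table by its track_id column into Track objects."""
    from stressburst.containers import Track

    tid = locs["track_id"].to_numpy()
    frames = locs["frame"].to_numpy(int)
    xy = locs[["x_px", "y_px"]].to_numpy(float) * pixel_size
    order = np.lexsort((frames, tid))
    tid, frames, xy = tid[order], frames[order], xy[order]
    bounds = np.concatenate(
        ([0], np.flatnonzero(np.diff(tid)) + 1, [tid.size])
    )
    tracks = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a < 2:
            continue
        tracks.append(
            Track(track_id=int(tid[a]), frames=frames[a:b], positions=xy[a:b])
        )
    return tracks
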