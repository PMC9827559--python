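# stressburst

Quantitative analysis of stress-induced mutagenesis bursts and DNA-binding
dynamics in single bacteria, with a synthetic-experiment generator that makes
every stage testable by parameter recovery.

The package targets two kinds of live-cell microscopy data from *E. coli*
under sudden oxidative stress (H₂O₂ step in a mother-machine microfluidic
device, and single-molecule tracking on agarose pads):

1. **Mother-machine time-lapse traces** — per-cell length and fluorescence at
   a 3-min cadence. The package detects divisions as sharp length drops,
   measures absolute elongation rates, classifies death fates (growth arrest,
   lysis, filamentation) and truncates traces accordingly, computes survival
   curves, converts fluorescent mismatch-repair foci (MutL fusions marking
   DNA replication errors) into a per-frame mismatch rate
   (events·cell⁻¹·min⁻¹, counted at first appearance only), deconvolves
   fluorophore maturation (exponential kernel, τ = 6.4 min) and derives
   promoter activities, and aligns replicates on the treatment time.
2. **Single-particle tracking (SPT)** — localizations at Δt = 15.48 ms.
   Localizations are linked into tracks (8-px window, 1-frame memory), each
   track yields an apparent diffusion coefficient from the mean squared
   displacement over four steps, D = MSD/(4·Δt), and the distribution of
   per-track D is fitted with a two-species analytic model to quantify the
   DNA-bound (immobile) fraction of a transcription factor such as OxyR.

## The core statistic

For 2-D Brownian motion each lag-1 squared displacement is exponential with
mean 4DΔt, so the per-track estimate (mean of n = 4 squared displacements,
divided by 4Δt) follows a gamma distribution with shape 4 and rate 4/D:

    f(x; D) = (4/D)⁴ x³ e^(−4x/D) / 6

A population with a bound fraction A₁ follows the mixture
A₁·f(x; D₁) + (1 − A₁)·f(x; D₂) with A₁ + A₂ = 1. The package fits this by
maximum likelihood on the raw per-track values (multi-start, with standard
errors from the observed information); pooling all time points with both D
free pins the immobile species' apparent D₁, which is then held fixed for
per-time-point fits so that A₁(t) is comparable across time. An exponential
fit to the post-peak decay of A₁(t) toward its untreated level yields the
deactivation half-life.

The burst statistic on the trace side is the mismatch-rate time course:
baseline level, peak rate, peak time and duration (full width at half
maximum above baseline), measured by `burststats.burst_metrics`.

## Worked example

Three scenario fixtures ship with the package (`WT_100uM`, `OxyR_100uM`,
`null_untreated`); each fully parameterizes one synthetic experiment.

```python
import numpy as np
import stressburst as sb
from stressburst.simkit import simulate_lineage
from stressburst.focidetect import deduplicate_events
from stressburst.trenchtrace import mismatch_rate_series
from stressburst.burststats import burst_metrics

cfg = sb.packaged_scenario("WT_100uM")
sim = simulate_lineage(cfg, n_cells=6000, duration=180.0, seed=1)
events = deduplicate_events(sim.foci_detections)
rate = mismatch_rate_series(events, sim.traces,
                            cfg.frame_interval_trace, cfg.t_treatment)
m = burst_metrics(rate, baseline_window=60.0)
print(f"peak {m.peak_value:.4f} /cell/min at {m.peak_time:.1f} min, "
      f"FWHM {m.duration_fwhm:.1f} min")
```

prints

```
peak 0.0205 /cell/min at 4.6 min, FWHM 12.7 min
```

i.e. the analysis recovers the burst this scenario encodes — a sharp
mutagenesis burst peaking at about 0.021 mismatches·cell⁻¹·min⁻¹ roughly
4.5 min after the H₂O₂ step, lasting about 12 min, on a baseline of
0.0029 — from simulated foci detections that still contain consecutive-frame
duplicates and death-truncated traces.

The same runs from the shell:

```bash
stressburst pipeline --scenario WT_100uM --arm trace --out out/ --seed 1
stressburst pipeline --scenario OxyR_100uM --arm spt --out out_spt/ --seed 1
```

Each pipeline writes its intermediates (CSV), a metrics/fits JSON and a
`manifest.json` recording the scenario, seed and stage order; identical
seeds give bit-identical outputs.

## Layout

| module | contents |
| --- | --- |
| `stressburst.config` | scenario schema, YAML loading, packaged fixtures |
| `stressburst.simkit` | lineage, reporter and SPT generators with ground truth |
| `stressburst.render` | synthetic two-channel trench image stacks |
| `stressburst.focidetect` | band-pass filter, phasor localization, spot detection, segmentation, event deduplication |
| `stressburst.trenchtrace` | divisions, elongation, fates, survival, mismatch rate, deconvolution, promoter activity, replicate alignment |
| `stressburst.diffusionfit` | track linking, per-track D, two-species mixture fit, bound-fraction time course, half-life |
| `stressburst.burststats` | burst metrics, fold changes, rifampicin mutant frequency |
| `stressburst.pipeline` / `cli` | end-to-end pipelines, manifests, `stressburst` command |

See `docs/methods.md` for the models, conventions and known limitations.
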