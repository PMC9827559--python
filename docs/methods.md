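# Methods

This note documents the models behind `stressburst`, the conventions and
numerical choices that matter for interpreting its output, and what the
synthetic-data generator does and does not emulate.

## Time conventions

All rate curves in a scenario are functions of minutes relative to treatment
onset; `t_treatment` places them on the experiment clock. Analysis outputs
(`RateSeries`) use the treatment-relative axis.

A quantity measured over a frame interval — an event count, a length
difference — is attributed to the **mid-point of that interval**. An event
first visible at frame *f* occurred somewhere in the preceding 3 minutes;
plotting its rate contribution at *t_f − Δt/2* is the unbiased time
attribution for binned rates, and it is what makes the recovered burst peak
time land on the generator's peak time rather than half a frame late.

## Mother-machine arm

**Growth and division.** Mother cells elongate exponentially at the
scenario's specific rate λ(t) (min⁻¹); at 3-min cadence the per-interval
rate is evaluated at the interval mid-point. A cell divides when its length
exceeds `division_length_um` (default 4.4 μm); the retained fraction is a
truncated normal 0.5 ± 0.05 (clipped to [0.35, 0.65]), so the observed drop
is near one half — comfortably past the 30% relative-drop division detector.
The detector threshold (default `drop_fraction` 0.3) separates division
drops from the 1% multiplicative length-measurement noise; both are
configurable.

**Elongation rate** is the absolute length change per interval (μm/min),
not the specific rate: longer cells legitimately report larger values, and
the population drop after an H₂O₂ step is then the ratio of specific rates.
Division intervals are excluded.

**Fates and truncation.** The generator draws death times from the
scenario's inhomogeneous hazard (exact piecewise cumulative hazard,
inverse-CDF sampling) and expresses a drawn fate: arrest freezes the length,
lysis ends the trace (NaN tail), filamentation suppresses division and lets
the cell grow until it escapes the trench. The classifier mirrors this:
lysis = vanished mask; filamentation = length crossing the trench length
without division; arrest = a division-free flat tail (relative elongation
< 2% from the tail start over at least 5 frames). The arrest window and
tolerance are not physical constants; they were calibrated once against the
generator (≥ 95% label accuracy on the packaged scenarios; in practice
≈ 99.9% at the fixture noise level). Survival is the fraction of traces not
yet truncated, with the denominator frozen at treatment onset.

**Mismatch rate.** Focus events are an inhomogeneous Poisson process per
cell with intensity `mismatch_rate_curve` — a baseline plus Gaussian burst
b + (p − b)·exp(−(t − t_peak)²/2σ²), σ = FWHM/2.355. The Gaussian is *not*
truncated at t = 0, so a burst peaking at +4.5 min with a 12-min FWHM bleeds
slightly into the pre-treatment window; the measured baseline over the last
hour before treatment is therefore a few tens of percent above the true
baseline in burst scenarios (the untreated scenario is flat and unaffected).
Each event stays detectable for `foci_persistence_frames` (default 2)
consecutive frames, which is what makes first-frame deduplication
consequential. The rate estimator — first-frame event count divided by
observed cells and by the 3-min interval — is unbiased (checked over 100
seeded simulations); frames with no observed cells yield missing values,
never zeros.

**Burst metrics.** Baseline = pre-treatment mean. The burst is located on a
3-point moving average of the series (computed over the full series so the
first post-treatment point is not an endpoint-shortened window). The peak
value and time are then refined by a weighted log-quadratic fit (Caruana's
method, weights (y − baseline)²) over the contiguous bins above 30% of the
peak residual: a Gaussian bump is a parabola in log space, and the
refinement both removes the downward bias incurred when noise shifts the
smoothed argmax one 3-min bin off the peak and roughly halves the variance
of a single-bin read. With fewer than 4 usable bins the single-bin estimate
is kept. Duration is the full width at half maximum above baseline by
linear interpolation, with crossings searched on the full series because
the rising edge of an early burst can cross half-maximum before t = 0. A
peak below baseline + 2·SEM is flagged "no burst".

**Maturation deconvolution.** Fluorophore maturation low-pass filters the
true synthesis signal with kernel k(u) = (1/τ)e^(−u/τ), τ = 6.4 min by
default. The generator applies the zero-order-hold discretization
F_i = αF_{i−1} + (1 − α)s_i, α = e^(−Δt/τ); the default deconvolution is
its exact algebraic inverse, which round-trips to machine precision at any
cadence. The continuous-time inverse s = F + τ·dF/dt with centered
differences (optional 3-point pre-smoothing) is available as
`method="derivative"`; on finely sampled data (0.1 min) it agrees to
< 10⁻³ relative. Promoter activity is the per-interval derivative of the
deconvolved total intensity divided by cell area; a flag switches to
differentiate-then-deconvolve (the operations commute for a linear filter
up to endpoints).

## Imaging arm

Synthetic trench stacks carry two channels, as in a two-colour experiment:
a bright constitutive cytoplasmic channel used for Otsu-threshold
segmentation (mother cell = component nearest the closed end), and a foci
channel in which the diffuse reporter inside the cell is faint
(`foci_cell_signal`, default 4 counts over a 100-count background) relative
to a focus (250 counts). Cell bodies are blurred by the Gaussian PSF
(σ = 1 px); noise is Poisson plus Gaussian read noise.

Detection band-passes the foci channel with a difference of Gaussians
(σ 1 and 3 px — the conventional reading of a "3-pixel Gaussian band-pass"),
thresholds local maxima at 5 robust background SDs (median absolute
deviation of the *unclipped* response; the clipped response has a
degenerate MAD), and localizes each peak by the phasor method — the phase
of the first Fourier coefficient of a 7×7 window along each axis. Phasor
bias is < 10⁻³ px across sub-pixel shifts at zero noise. The 1-px image
border is excluded from peak finding: boundary-reflected filtering inflates
the noise variance there, and foci sit on the nucleoid, away from the
membrane (the generator insets them 1 px accordingly). With the default
optics the rendered-fixture operating point is ≥ 95% event recall at ≤ 5%
false events.

Deduplication links detections of the same cell within 3 px in consecutive
frames (configurable gap tolerance, default 0) by greedy closest-pair
matching and counts each chain once, at its first frame. Two genuinely
distinct events that overlap in space and time are merged at a rate well
under 1% at the packaged event densities.

## SPT arm

**Generator.** Each molecule is bound with probability given by the
scenario's bound-probability curve (basal level, linear rise to a peak at
the first post-treatment observation, exponential relaxation with the
configured half-life), and performs 2-D Brownian motion with per-axis step
variance 2DΔt inside a reflecting rectangle (default 3.0 × 0.9 μm; the
reflected path is generated by folding the free path, which has the correct
law). Track lengths are geometric (mean 8 frames); start frames are
staggered to the configured molecule density. `D_bound` (0.17 μm²/s) is the
*apparent* diffusion coefficient of the bound species — localization error
is folded in, so the scenario default adds none; an explicit-error mode
(D = 0 plus per-frame Gaussian localization error) exists. Optional
bound↔free switching at `k_switch` preserves the stationary bound
probability; it defaults off, since at 15.48-ms frames and minutes-scale
binding the state is effectively constant within a 5-frame track.

**Linking** is greedy nearest-neighbour with per-frame-pair optimal
assignment (minimal total displacement), an 8-px window and a 1-frame
memory. On well-separated molecules it reproduces ground-truth tracks
exactly; at the default density (2 concurrent molecules per cell) occasional
end-to-end bridging of distinct tracks biases the mean per-track D up by
~3%, which the mixture fit absorbs into the freely fitted mobile D.

**Per-track D** is the mean of the four lag-1 squared displacements of the
first five localizations, divided by 4Δt. This reading makes the estimator
unbiased and gives exactly the gamma(4, 4/D) sampling density used by the
fit — the analytic model and the simulator validate each other (KS test at
α = 0.01, n = 5000). Tracks shorter than five localizations, or with a
memory gap among their first five, are discarded (counted, not erred).

**Mixture fit.** Maximum likelihood on raw values, parameterized as log D
and logit A₁, L-BFGS from three fixed starts ((0.1, 0.5, 0.3),
(0.17, 0.8, 0.3), (0.2, 1.0, 0.5)); standard errors from the numerically
inverted observed information; a histogram least-squares mode serves as a
cross-check. Fits with |D₁ − D₂| < 0.05 μm²/s are flagged unidentifiable
and emitted as missing points in time courses. Recovery bias |Â₁ − A₁| is
below 0.03 at n = 10⁴ across A₁ ∈ [0.1, 0.7], D₂ ∈ {0.5, 0.8}.

Confinement makes the measured distributions slightly heavier at low D than
the ideal gamma mixture; at the packaged geometry this depresses the pooled
free-fit D₁ by ~4% (0.163–0.168 recovered for a true 0.17) and is the
dominant systematic in the bound-fraction time course. The half-life of the
A₁ decay is fitted as amp·e^(−k(t − t_peak)) on post-peak points with the
untreated A₁ as the basal level; recovery is unbiased to within ~2% over
50 replicate simulations.

## Problem sizes and determinism

Acceptance-scale runs use 2,000 cells × 200 min (untreated baseline),
6,000 cells × 180 min (burst recovery), and 4,000 molecules per time point
× 7 time points × 50 replicate seeds (bound-fraction half-life) — chosen to
match the single-experiment statistics the analysis is designed for while
keeping a full recovery run under a minute. All randomness flows from one
root seed via `numpy.random.SeedSequence.spawn`; identical seeds give
bit-identical tables, images and fits.

## What the generator does not emulate

No real point-spread function beyond a Gaussian, no stage drift, no
photobleaching kinetics beyond geometric track lengths, no daughter-cell
lineages beyond the mother row, no cell-shape detail (rectangular
footprints), and no H₂O₂ chemistry — curves are imposed, not emergent.
Passing recovery tests therefore demonstrates that the estimators invert
the assumed measurement process at realistic noise and sample sizes, not
that they are robust to every artefact of real microscopy (drift,
segmentation errors on irregular cells, heterogeneous illumination).

## Known limitations

* The two-species model cannot represent transiently switching molecules
  within a track; an HMM-style segmentation is out of scope.
* Localization error is not subtracted from per-track D; apparent D values
  are reported as measured.
* The burst-duration FWHM is only meaningful for unimodal bursts; multiple
  bursts would be summarized by their widest half-maximum region around the
  global peak.
* `align_and_average` requires replicates at a common cadence; no
  resampling is performed.
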