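# Single-particle-tracking scenario for the redox sensor: a two-species
# diffusion mixture whose bound fraction peaks at the earliest post-treatment
# time point (5 min) and relaxes with a 15-min half-life. The basal and peak
# bound fractions are package choices (the source data report them only
# graphically). D_bound is the apparent diffusion coefficient of the
# promoter-bound species with localization error folded in.
name: OxyR_100uM
t_treatment: 60.0
frame_interval_trace: 3.0
frame_interval_spt: 0.01548
pixel_size: 0.096
maturation_tau: 6.4

elongation_rate_curve:
  knots:
    - [-1000.0, 0.030]
    - [-0.001, 0.030]
    - [0.0, 0.015]
    - [30.0, 0.015]
    - [70.0, 0.030]
    - [1000.0, 0.030]

death_hazard_curve: 0.0

fate_mix:
  arrest: 0.5
  lysis: 0.3
  filamentation: 0.2

mismatch_rate_curve:
  baseline: 0.0029
  peak: 0.021
  t_peak: 4.5
  fwhm: 12.0

promoter_activity_curve:
  knots:
    - [-1000.0, 1.0]
    - [0.0, 1.0]
    - [5.0, 6.0]
    - [20.0, 6.0]
    - [40.0, 1.5]
    - [1000.0, 1.5]

spt:
  D_bound: 0.17
  D_free: 0.8
  bound_prob_curve: {basal: 0.10, peak: 0.35, t_peak: 5.0, t_half: 15.0}
  k_switch: 0.0
  loc_error_sigma: 0.0
  track_length_mean: 8.0
  density: 2.0
  cell_length_um: 3.0
  cell_width_um: 0.9

seed: 0
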