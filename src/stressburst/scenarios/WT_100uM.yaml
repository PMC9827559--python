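# Wild-type cells under a sudden, continuously replenished 100 uM H2O2 step.
# Curves are minutes relative to treatment onset.
name: WT_100uM
t_treatment: 60.0
frame_interval_trace: 3.0
frame_interval_spt: 0.01548
pixel_size: 0.096
maturation_tau: 6.4

# Specific elongation rate (min^-1): steady exponential growth, an immediate
# two-fold drop at treatment onset, recovery to the pretreatment rate after
# an adaptation lag.
elongation_rate_curve:
  knots:
    - [-1000.0, 0.030]
    - [-0.001, 0.030]
    - [0.0, 0.015]
    - [30.0, 0.015]
    - [70.0, 0.030]
    - [1000.0, 0.030]

# Transient mortality during the adaptation lag (min^-1); integrated hazard
# over the first 100 min is ~0.058, i.e. ~94% survival.
death_hazard_curve:
  knots:
    - [-1000.0, 0.0]
    - [0.0, 0.0]
    - [8.0, 0.00075]
    - [14.0, 0.00225]
    - [20.0, 0.003]
    - [26.0, 0.00225]
    - [32.0, 0.00075]
    - [40.0, 0.00015]
    - [60.0, 0.0]
    - [1000.0, 0.0]

fate_mix:
  arrest: 0.5
  lysis: 0.3
  filamentation: 0.2

# Mismatch-focus rate (events cell^-1 min^-1): steady baseline with a sharp
# Gaussian burst right after treatment onset.
mismatch_rate_curve:
  baseline: 0.0029
  peak: 0.021
  t_peak: 4.5
  fwhm: 12.0

# Stress-regulon promoter activity (au min^-1 px^-2): basal expression with a
# transient induction pulse following treatment.
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

optics:
  trench_length_px: 80
  trench_width_px: 12
  background_offset: 100.0
  cell_signal: 120.0
  foci_cell_signal: 4.0
  focus_amplitude: 250.0
  psf_sigma_px: 1.0
  read_noise_sd: 2.0

seed: 0
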