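# Steady-state control: no treatment effects, constant baseline mismatch rate,
# zero death hazard. t_treatment only anchors the relative time axis.
name: null_untreated
t_treatment: 60.0
frame_interval_trace: 3.0
pixel_size: 0.096
maturation_tau: 6.4

elongation_rate_curve:
  knots:
    - [-1000.0, 0.030]
    - [1000.0, 0.030]

death_hazard_curve: 0.0

fate_mix:
  arrest: 0.5
  lysis: 0.3
  filamentation: 0.2

# flat: peak == baseline, no burst
mismatch_rate_curve:
  baseline: 0.0029
  peak: 0.0029
  t_peak: 0.0
  fwhm: 0.0

promoter_activity_curve: 1.0

seed: 0
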