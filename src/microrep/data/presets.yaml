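# Disease-stage presets for the synthetic RP field model.
# Base values define the cohort mean; "jitter" gives the between-patient
# Gaussian sd of each parameter.  The "mid" preset is calibrated so a
# default cohort has roughly a third of loci non-seen, with the pointwise
# distribution mode at -1.0 dB; "late" produces fields dominated by the
# ring scotoma, where mean sensitivity floors at 0.0 dB despite residual
# seen loci.  "flat" is a uniform field far from floor and ceiling, used
# for noise parameter-recovery studies.
early:
  s_center_db: 28.0
  ring_radius_deg: 6.5
  ring_width_deg: 1.8
  ring_depth_db: 20.0
  peripheral_slope_db_per_deg: 1.0
  progression_db_per_year: 0.8
  jitter: &jitter
    s_center_db: 3.0
    ring_radius_deg: 0.8
    ring_width_deg: 0.3
    ring_depth_db: 3.0
    peripheral_slope_db_per_deg: 0.3
mid:
  s_center_db: 22.0
  ring_radius_deg: 5.0
  ring_width_deg: 2.4
  ring_depth_db: 27.0
  peripheral_slope_db_per_deg: 1.6
  progression_db_per_year: 0.8
  jitter: *jitter
late:
  s_center_db: 9.0
  ring_radius_deg: 3.5
  ring_width_deg: 2.0
  ring_depth_db: 20.0
  peripheral_slope_db_per_deg: 2.0
  progression_db_per_year: 0.8
  jitter: *jitter
flat:
  s_center_db: 18.0
  ring_radius_deg: 5.0
  ring_width_deg: 2.0
  ring_depth_db: 0.0
  peripheral_slope_db_per_deg: 0.0
  progression_db_per_year: 0.0
  jitter:
    s_center_db: 0.0
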