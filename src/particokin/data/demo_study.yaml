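# Demo synthetic study: a biopersistent (Au-like, one-phase) and a biosoluble
# (Ag-like, two-phase) analyte under single and combined exposure, with the
# study's group structure (4 animals at E-1, 5 per post-exposure day).
# Kinetic truths follow the published half-times; deposits are per exposure
# day, ng.  The Ag-like rapid_initial_loss reflects within-day removal of
# soluble species and is illustrative.
outdir: particokin-demo-out
seed: 20210121
ratio_mode: ratio_of_means
simulate:
  schedule: {hours_per_day: 6, days_per_week: 5, weeks: 4}
  noise: {burden_cv: 0.25, lung_weight_mean: 1.4, lung_weight_cv: 0.08}
  cells:
    - {analyte: Au, group: AuNP, daily_deposit: 466.0, fast_fraction: 0.0,
       half_time_fast: 81.5, half_time_slow: 81.5}
    - {analyte: Au, group: AuNP+AgNP, daily_deposit: 313.0, fast_fraction: 0.0,
       half_time_fast: 54.2, half_time_slow: 54.2}
    - {analyte: Ag, group: AgNP, daily_deposit: 47.0, fast_fraction: 0.3333,
       half_time_fast: 3.1, half_time_slow: 48.5, rapid_initial_loss: 0.85}
    - {analyte: Ag, group: AuNP+AgNP, daily_deposit: 23.0, fast_fraction: 0.5,
       half_time_fast: 2.2, half_time_slow: 28.4, rapid_initial_loss: 0.85}
fits:
  - {analyte: Au, group: AuNP, model: one-phase, exposure_mode: single}
  - {analyte: Au, group: AuNP+AgNP, model: one-phase, exposure_mode: co}
  - {analyte: Ag, group: AgNP, model: two-phase, exposure_mode: single,
     fast_fraction: 0.3333}
  - {analyte: Ag, group: AuNP+AgNP, model: two-phase, exposure_mode: co,
     fast_fraction: 0.5}
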