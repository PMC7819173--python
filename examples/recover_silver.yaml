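# Parameter-recovery experiment for a silver-like two-phase truth:
#   particokin recover --config examples/recover_silver.yaml --replicates 200
truth:
  daily_deposit: 47.0
  fast_fraction: 0.33333
  half_time_fast: 3.1
  half_time_slow: 48.5
noise:
  burden_cv: 0.25
model: two-phase
mode: bolus
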