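# 16-electrode MEA wells, 10-minute recordings. Condition rates follow
# the D42 observation: ~10 Hz control (WT2) vs ~3 Hz mutant (HT3), with
# early compound treatment lowering the mutant to ~2 Hz. Correlation is
# induced by mother-process thinning (pairwise count correlation = rho).
mea_sim:
  n_electrodes: 16
  duration_s: 600
  jitter_ms: 2.0
conditions:
  WT2:
    rate_hz: 10.0
    rho: 0.30
  HT3:
    rate_hz: 3.0
    rho: 0.15
  HT3_benproperine_early:
    rate_hz: 2.0
    rho: 0.15
  WT2_bursting:                 # rate-matched bursting variant
    burst:
      tonic_rate_hz: 2.0
      burst_rate_hz: 0.4
      intra_rate_hz: 100.0
      length_s: 0.2
    rho: 0.0
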