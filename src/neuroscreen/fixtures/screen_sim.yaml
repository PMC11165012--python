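# Full-scale duplicate screen: 7,120 compounds at 1 uM on 384-well plates.
# Baseline ratios match the DMSO condition (22% Ki67, 25% HuC/D); the
# positive-control separations put the mean Z' near 0.56 (Ki67) and 0.47
# (HuC/D); the same-sign latent compound-effect distribution sets the
# replicate concordance near r = 0.85 / 0.79. 42 planted actives sit in
# the (Ki67 up, HuC/D down) hit quadrant; 30 toxic compounds share that
# quadrant but die (nuclei ~1200), so the <2000 live-count filter must
# remove them.
seed_stage: screen
screen_sim:
  n_compounds: 7120
  n_replicates: 2
  plate:
    rows: 16
    cols: 24
    n_dmso: 24
    n_positive: 8
  baseline:
    ki67_ratio: 0.22
    hucd_ratio: 0.25
    nuclei_mean: 4000
    nuclei_sd: 250
  well_noise_sd: 0.015          # ratio units, both metrics
  plate_jitter_sd: 0.010        # additive per-plate offset on both ratios
  latent:                       # per-compound effects, in well-SD units
    shared_sd: 2.3              # same-sign component on both metrics
    hucd_scale: 0.8
    independent_sd: 0.3
  actives:
    n: 42
    effect_min_sd: 6.0          # Ki67 up, HuC/D down
    effect_max_sd: 9.0
  toxics:
    n: 30
    nuclei_mean: 1200
    nuclei_sd: 150
    effect_min_sd: 6.0          # quadrant effects, removed by toxicity
    effect_max_sd: 9.0
  positive_control:             # GSK-25-like separation, in well-SD units
    ki67_shift_sd: 13.64        # 6 / (1 - 0.56) -> Z' ~ 0.56
    hucd_shift_sd: -11.32       # 6 / (1 - 0.47) -> Z' ~ 0.47
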