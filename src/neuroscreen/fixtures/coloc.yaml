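# Two-channel ARPC2 / ß-actin colocalization fields. The condition's
# coloc_fraction is the target fraction of ARPC2-positive area placed on
# actin structures: 20% in the untreated mutant, 32% in the control, 30%
# in the compound-rescued mutant.
image_sim:
  field_shape: [512, 512]
  pixel_size_um: 0.65
  background: 100
  noise_sd: 8
  illumination_gradient: 0.10
  coloc:
    n_actin_blobs: 60
    n_arpc2_blobs: 80
    actin_radius_px: [5, 8]
    amplitude: 500
conditions:
  HT3_DMSO:
    coloc_fraction: 0.20
  WT2_DMSO:
    coloc_fraction: 0.32
  HT3_benproperine:
    coloc_fraction: 0.30
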