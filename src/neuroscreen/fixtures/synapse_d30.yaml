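# D30 synaptic-phenotype fields (60X-like geometry): MAP2 neurite trees
# with Synapsin1/SHANK3 puncta. The mutant (HT3-like) condition carries
# twice the control's synapse density and reduced SHANK3 punctum
# amplitude (less SHANK3 per synapse).
image_sim:
  field_shape: [512, 512]
  pixel_size_um: 0.108
  background: 100
  noise_sd: 8
  illumination_gradient: 0.10
  neurites:
    n_trees: 10
    segment_mean_um: 12
    levels: 3
    sigma_px: 1.5
    amplitude: 1200
  puncta:
    sigma_px: 1.8
    amplitude: 500
    amplitude_sd: 80
conditions:
  WT2_DMSO:
    synapses_per_100um: 4.0
    extra_synapsin_per_100um: 1.5
    extra_shank3_per_100um: 1.2
    off_skeleton_per_field: 10
    shank3_amp_scale: 1.0
  HT3_DMSO:
    synapses_per_100um: 8.0     # ~two-fold increased synapse density
    extra_synapsin_per_100um: 1.5
    extra_shank3_per_100um: 1.2
    off_skeleton_per_field: 10
    shank3_amp_scale: 0.6       # reduced synaptic SHANK3 content
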