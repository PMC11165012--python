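# D6 differentiation fields (20X-like geometry): Hoechst nuclei with
# dead/debris subpopulations and Ki67 / HuC/D marker painting. The DMSO
# condition carries the screen's baseline positivity: 22% Ki67, 25% HuC/D.
image_sim:
  field_shape: [512, 512]
  pixel_size_um: 0.65
  background: 100
  noise_sd: 8
  illumination_gradient: 0.15
  nuclei:
    per_field: 110
    radius_px: [7, 10]
    intensity_mean: 600
    intensity_sd: 60
    dead_fraction: 0.05
    dead_size_mult: 0.65
    dead_intensity_mult: 2.2
    debris_fraction: 0.06
    debris_radius_px: [2, 4]
    debris_intensity_mult: 0.6
conditions:
  DMSO:
    ki67_fraction: 0.22
    hucd_fraction: 0.25
    marker_snr: 40
    marker_coverage: 1.0
  HT3_DMSO:                     # hyperdifferentiated mutant baseline
    ki67_fraction: 0.12
    hucd_fraction: 0.45
    marker_snr: 40
    marker_coverage: 1.0
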