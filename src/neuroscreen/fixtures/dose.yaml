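# 42-compound dose-response set over seven 3-fold dilutions from 10 uM
# down to 0.014 uM, measured in the mutant (HT3) and isogenic control
# (WT2) lines. 11 compounds carry a mutant-only proliferation increase
# (3 of them also a mutant-only differentiation decrease), 21 respond in
# both lines, 10 are flat; 4 of the both-line actives are toxic at the
# top dose.
dose_sim:
  doses_um: [10.0, 3.333, 1.111, 0.370, 0.123, 0.041, 0.014]
  n_replicates: 3
  noise_sd: 0.008
  hill: 1.2
  ec50_um: 0.4
  amplitude:
    ki67: 0.10
    hucd: -0.15
  mutant_line: HT3
  control_line: WT2
  baseline:                     # HT3: hyperdifferentiated
    ki67: 0.12
    hucd: 0.45
  control_baseline:             # WT2
    ki67: 0.22
    hucd: 0.25
  nuclei_mean: 4000
  nuclei_sd: 250
  compounds:
    n_total: 42
    n_prolif_specific: 11
    n_both_specific: 3
    n_active_both_lines: 21
    n_flat: 10
    n_toxic_top_dose: 4
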