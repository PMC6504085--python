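# Minimal end-to-end run: one cell type, one pathway, microarray output.
seed: 7
model:
  initial_num: 10
  hours: 24
  density: 0.05
  cell_types:
    - name: tumor
      cycle_mean: 12.0
      cycle_sd: 2.0
      proportion: 1.0
pathways:
  - name: mitosis
    genes: [MKI67, CCNB1, CDK1, PLK1, AURKA, BUB1, TOP2A, BIRC5]
    activity:
      rule: phase_transition
      phase: M
      window: 1.0
    calibration:
      lambda: 20.0
      stddev: 2.0
  - name: s_phase
    genes: [PCNA, MCM2, MCM3, RRM1, RRM2, POLA1]
    activity:
      rule: phase_transition
      phase: S
      window: 1.0
    calibration:
      lambda: 20.0
      stddev: 2.0
expression:
  sample_freq: 4.0
  n_cells: 10
output:
  directory: cellsim_out
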