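# 103-cell close-packed spheroid (~100 um), border-seeded, alpha = 10.4.
tissue:
  kind: spheroid
  n_cells: 103
  spheroid_diameter: 100.0
  cell_diameter: 21.0
  spacing_factor: 0.85
  seed_cells: [102]
rule:
  kind: contact
  contact_slack: 0.01
protocol: {T0: 272.15, B: 100.0, T_end: 258.15}
mc:
  alpha: 10.4
  replicates: 100
  rng_seed: 0
  method: gillespie
stages: [propagation]
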