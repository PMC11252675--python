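# 22-cell hexagonally packed hepatocyte disc monolayer, corner-seeded,
# fast cooling, with the mechanics stage (ice expansion + detachment).
tissue:
  kind: disc
  n_cells: 22
  cell_diameter: 21.0
  spacing_factor: 0.85
  packing: hex
  seed_cells: [21]
rule:
  kind: contact
  contact_slack: 0.01
protocol: {T0: 272.15, B: 400.0, T_end: 258.15}
mc:
  alpha: 10.4
  replicates: 100
  rng_seed: 0
  method: gillespie
mech:
  c_adh: 30.0
  c_rep: 750.0
  adh_reach: 1.25
  dt_mech: 0.001
stages: [propagation, mechanics]
snapshot_every: 200
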