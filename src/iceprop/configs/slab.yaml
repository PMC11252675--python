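# 31x11x7 lattice slab (2387 cells, 651x231x147 um), corner-seeded.
# Face-contact neighbourhood (max degree 6).
tissue:
  kind: slab
  nx: 31
  ny: 11
  nz: 7
  cell_diameter: 21.0
  seed_cells: [0]
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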