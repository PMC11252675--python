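# 2x2 validation construct: all four cells mutually neighbouring
# (radius rule spanning the square diagonal), alpha = 10.4.
tissue:
  kind: slab
  nx: 2
  ny: 2
  nz: 1
  cell_diameter: 21.0
rule:
  kind: radius
  R: 31.0
protocol: {T0: 272.15, B: 400.0, T_end: 258.15}
mc:
  alpha: 10.4
  epsilon: 0.05
  tau_max: 1.0
  replicates: 1000
  rng_seed: 0
  method: fixed_step
stages: [propagation]
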