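# Demo pipeline: synthesize a monolayer, measure its roughness, and test a
# roughness contrast.  Run with:
#   nucleodrop run --config examples/demo.yaml --out results/demo --seed 11
seed: 11
stages:
  - name: mono
    kind: synth.monolayer
    params:
      field: [40.0, 40.0]
      tall_cell_fraction: 0.2
  - name: rough
    kind: measure.roughness
    params:
      stack_stage: mono
      crop_margin: 2.0
      downsample: 4
  - name: contrast
    kind: stats.permutation
    params:
      group_a: [1.9, 2.1, 1.7, 2.2]
      group_b: [1.1, 0.9, 1.3, 1.2]
      n_perm: 9999
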