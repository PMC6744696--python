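# Desk-scale end-to-end experiment: synthetic corpus -> train -> evaluate.
# Usage: micronet run --config examples/desk.yaml --seed 1 --out results/desk
seed: 1
profile: desk
network:
  base_width: 8
encoding:
  alpha: 3.0
  d: 15.0
  scale: 5.0
loss:
  lam: 5.0
  gamma: 1.0
height: 64
width: 64
n_per_style: 40
target_style: styleA
# pool the other two organ styles as auxiliary data (gamma balances them):
# auxiliary_styles: [styleB, styleC]
# aux_fraction: 0.5
xi_grid: [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
radius: 16.0
min_distance: 6
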