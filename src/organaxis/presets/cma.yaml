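# Thymic cortico-medullary axis preset.
# Composite axis: 0.2 * H(edge->cortex) + 0.8 * H(cortex->medulla);
# negative at the capsule, positive in the deep medulla.
pairs:
  - [edge, cortex]
  - [cortex, medulla]
weights: [0.2, 0.8]
beta: 1.0
scale_C: auto
auto_percentile: 95.0
k_dist: 10
level: broad
bins:
  names:
    - capsular
    - subcapsular
    - cortical_1
    - cortical_2
    - cortical_3
    - cortical_cmj
    - medullary_cmj
    - medullary_1
    - medullary_2
    - medullary_3
  cutoffs: [-0.95, -0.8, -0.575, -0.35, -0.125, 0.1, 0.325, 0.55, 0.775]
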