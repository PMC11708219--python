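# As scenario3a but the improved phenotyping is nearly free: it adds only
# 10 EUR per phenotyped test daughter (cost per daughter 4,000 + 10 * x4).
name: scenario3b
objective_weight: 50.0
variables:
  - name: x1
    kind: continuous
    domain: [1, 2500]
    cost_bearing: true
  - name: x2
    kind: continuous
    domain: [1, 3333]
    init_bounds: [100, 700]
    cost_bearing: true
  - name: x3
    kind: continuous
    domain: [1, 500]
    init_bounds: [3, 30]
  - name: x4
    kind: class
    categories: [0, 1]
    init_probs: [0.5, 0.5]
cost_model:
  budget: 10000000
  coefficients:
    x1: {base: 4000, depends_on: x4, by_value: {0: 0, 1: 10}}
    x2: 3000
simulator:
  kind: breeding
  roles: {daughters: x1, bulls: x2, sires: x3}
  h2: 0.30
  h2_overrides:
    - {variable: x4, value: 1, h2: 0.32}
  burn_in_cycles: 5
  future_cycles: 10
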