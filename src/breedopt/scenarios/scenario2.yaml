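# Same breeding program and costs as scenario1, but the initial search space
# deliberately excludes the known optimal region (x2 in [300, 500],
# x3 in [15, 25]); the optimizer must escape the initialization box.
name: scenario2
objective_weight: 50.0
variables:
  - name: x1
    kind: continuous
    domain: [1, 2500]
    cost_bearing: true
  - name: x2
    kind: continuous
    domain: [1, 3333]
    init_bounds: [300, 500]
    cost_bearing: true
  - name: x3
    kind: continuous
    domain: [1, 500]
    init_bounds: [15, 25]
cost_model:
  budget: 10000000
  coefficients:
    x1: 4000
    x2: 3000
simulator:
  kind: breeding
  roles: {daughters: x1, bulls: x2, sires: x3}
  h2: 0.30
  burn_in_cycles: 5
  future_cycles: 10
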