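# Traditional progeny-testing dairy cattle scheme, single trait (h2 = 0.30).
# Annual budget of 10M EUR with 4,000 EUR housing cost per phenotyped test
# daughter and 3,000 EUR per test bull; x2 and x3 bounds apply at
# initialization only.
name: scenario1
objective_weight: 50.0
variables:
  - name: x1            # number of test daughters
    kind: continuous
    domain: [1, 2500]
    cost_bearing: true
  - name: x2            # number of test bulls
    kind: continuous
    domain: [1, 3333]
    init_bounds: [100, 700]
    cost_bearing: true
  - name: x3            # number of selected sires
    kind: continuous
    domain: [1, 500]
    init_bounds: [3, 30]
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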