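"""Cost accounting and budget scaling for a dairy progeny-testing scheme.

A design with 1,025 test daughters (4,000 EUR each) and 300 test bulls
(3,000 EUR each) costs half the 10M EUR annual budget; because unspent
budget is never rewarded, the optimizer scales every design up to the
budget line (floor, then greedy single-unit top-up).
"""

import breedopt as bo

problem = bo.load_scenario("scenario1")

setting = (1025, 300, 20)  # daughters, bulls, selected sires
cost = bo.compute_cost(setting, problem)
print(f"design {setting} costs {cost:,.0f} EUR of {problem.cost_model.budget:,.0f}")

scaled = bo.scale_to_budget(setting, problem)
print(f"budget-scaled to {scaled}, cost {bo.compute_cost(scaled, problem):,.0f} EUR")

# a non-integer scaling factor leaves a rounding gap that the top-up closes
setting = (1000, 300, 20)
scaled = bo.scale_to_budget(setting, problem)
print(f"design {setting} scales to {scaled}, cost {bo.compute_cost(scaled, problem):,.0f} EUR")
print("the number of selected sires bears no cost and is never rescaled")
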