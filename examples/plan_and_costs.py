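"""Evaluation budget and compute cost of a full 40-iteration campaign.

600 initial designs plus 300 generated per iteration (100+200 in the first
band) give 2,400 evaluations by iteration 7 and 12,300 by iteration 40; at
0.55 cent per simulation a complete campaign costs about 68 EUR of compute.
"""

from breedopt import IterationSchedule
from breedopt.run import estimate_campaign_cost, iteration_plan

schedule = IterationSchedule.default()
plan = iteration_plan(schedule, 40)
for it in (1, 2, 7, 10, 20, 40):
    print(f"through iteration {it:2d}: {plan[it - 1]:6,d} evaluations")
print(f"compute cost of the full campaign at 0.55 cent/simulation: "
      f"{estimate_campaign_cost(plan[-1], 0.0055):.2f} EUR")
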