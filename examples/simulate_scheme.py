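"""Evaluate one breeding-program design with the built-in simulator.

The miniature progeny-testing scheme (here at 1/10 economic scale to stay
quick) reports the genetic gain g over ten future cycles in genetic
standard deviations, the mean pedigree inbreeding F of the final daughter
cohort, and the combined objective m = g - 50 f.  Replicates differ only
through their seeds.
"""

import numpy as np

import breedopt as bo

problem = bo.scale_problem(bo.load_scenario("scenario1"), 0.1)
simulator = bo.BreedingSimulator(problem)

design = bo.scale_to_budget((237, 18, 6), problem)  # daughters, test bulls, sires
outcomes = [simulator.evaluate(design, seed) for seed in range(10)]
g = np.array([o.g for o in outcomes])
f = np.array([o.f for o in outcomes])
m = np.array([o.m for o in outcomes])

print(f"design {design}, cost {outcomes[0].cost:,.0f} of {problem.cost_model.budget:,.0f} EUR")
print(f"genetic gain  g: mean {g.mean():6.3f} sd {g.std(ddof=1):5.3f}  (sigma_a units)")
print(f"inbreeding    f: mean {f.mean():6.4f} sd {f.std(ddof=1):6.4f}")
print(f"objective     m: mean {m.mean():6.3f} sd {m.std(ddof=1):5.3f}  (m = g - 50 f)")
print("the spread across seeds is the evaluation noise the optimizer must average away")
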