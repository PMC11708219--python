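"""A short optimization campaign on the built-in dairy scheme.

The full problem (10M EUR budget, thousands of animals) is shrunk by a
factor of 10 and run with a reduced evaluation schedule so the example
finishes in under a minute.  The campaign checkpoints after every
iteration; an interrupted run resumes onto the identical trajectory.
"""

import numpy as np

import breedopt as bo

problem = bo.scale_problem(bo.load_scenario("scenario1"), 0.1)
simulator = bo.BreedingSimulator(problem)

config = bo.RunConfig(
    problem=problem,
    evaluator=simulator,
    schedule=bo.IterationSchedule.default().scaled(0.2),
    master_seed=1,
    max_iterations=10,
    final_replicates=30,
)
result = bo.run_optimization(config)
report = result.report

x1, x2, x3 = report.setting
print(f"suggested optimum: {x1} test daughters, {x2} test bulls, {x3} selected sires")
print(f"cost {bo.compute_cost(report.setting, problem):,.0f} of {problem.cost_model.budget:,.0f} EUR")
a = report.assessment
print(f"30-replicate assessment: g = {a['g']['mean']:.3f} sigma_a, "
      f"f = {a['f']['mean']:.4f}, m = {a['m']['mean']:.3f}")
print(f"evaluations used: {len(result.archive)}")
print("per-iteration optima (KR-expected m):")
for it in result.archive.iterations:
    rec = result.archive.optima[it]
    print(f"  iteration {it:2d}: {rec.setting}  m = {rec.kr_value:.3f}")
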