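# Methods

## The optimization problem

A breeding-program design is a vector of decision variables: integer counts
on closed intervals (number of phenotyped test daughters `x1`, test bulls
`x2`, selected sires `x3`) and, optionally, class variables with finitely
many realizations (e.g. a binary "improved phenotyping" switch `x4`).
Designs are evaluated by stochastic simulation, which returns the expected
genetic gain `g` (in genetic standard deviations, sigma_a) and the
inbreeding level `f` of the final cohort; the scalar objective is

    m(x) = g(x) - w * f(x),       w = 50 by default,

so gain is traded off against loss of diversity.  Costs are linear
(`4,000 EUR` per daughter, `3,000 EUR` per bull in the packaged baseline
scenario; the per-daughter cost may depend on a class variable, e.g.
`4,000 + 1,000*x4`) under an annual budget of `10,000,000 EUR`.  Because an
unspent budget is never rewarded, any optimum uses the full budget; every
candidate design is therefore *budget-scaled*: all cost-bearing variables
are multiplied by `budget/cost`, floored to integers, and the remaining
budget is spent greedily one unit at a time (most expensive unit first,
ties by declaration order) until no single unit of any cost-bearing
variable fits.  The result is maximal — adding one unit of even the
cheapest cost-bearing variable would exceed the budget — and the operation
is idempotent.

Bounds like `100 <= x2 <= 700` and `3 <= x3 <= 30` restrict only the
*initialization*; the evolutionary search may leave them later.  They are
enforced after budget scaling by rejection sampling, which is the only
reading under which pinned bounds (e.g. `x2 = 300`, `x3 = 20`) force the
unique full-budget design `x1 = 2,275`.  Interdependent variables sharing a
resource (stable-capacity style) are handled during sampling by clipping
each later variable's range by the capacity remaining after the earlier
draws.

## The evolutionary loop

Iteration 1 evaluates 600 initial designs (continuous variables uniform
over their init bounds, class variables generalized-Bernoulli).  Each later
iteration selects parents from the last evaluated population and generates
a fixed number of new designs; counts follow a banded schedule:

| iterations | selected (3.1/3.2/3.3) | generated (4.1/4.2/4.3) |
|-----------:|------------------------|--------------------------|
| 2–3        | 70 / 30 / 0            | 100 / 200 / 0            |
| 4–10       | 30 / 15 / 5            | 50 / 170 / 80            |
| 11–40      | 20 / 7 / 3             | 30 / 180 / 90            |

Selection strategies: (3.1) largest realized objective `m`; (3.2) largest
*kernel-regression expected* objective, which smooths evaluation noise and,
because every candidate receives exactly one estimate, carries no bias
toward densely sampled regions; (3.3) the best designs of the
second-to-last iteration — unless a previously suggested optimum (any
iteration) has a higher kernel-regression expected value than everything in
the current population, in which case those optima take the slots.  A
greedy diversity filter then drops near-duplicate selections (identical
class values and all continuous coordinates within 0.1 current bandwidths)
and backfills from the next-best pool, so a cluster of clones cannot
monopolize the parent set.

Generation: (4.1) every parent is re-queued with a fresh seed — replicates
accumulate across iterations without a separate replication mechanism;
(4.2) offspring recombine two random parents, `z_i = w x_i + (1-w) y_i`
with a single `w ~ U(0,1)` per offspring applied to all continuous
dimensions, class values inherited from either parent with probability
1/2, followed by mutation: each continuous dimension is perturbed with
probability `p_activ = 0.2` by `t ~ U(-2 s_i, 2 s_i)` where `s_i` is the
current population SD of that parameter; each class variable is resampled
uniformly among its other categories at the decayed class rate; (4.3)
"refinements" re-mutate designs generated this iteration with
`p_activ = 0.3`, redrawing until at least one mutation fires.  All
offspring are rounded half-up, clipped to their domains and budget-scaled.

Two probabilities decay with iteration, in percentage points of their
initial value: the probability of pairing parents with *different* class
values (multiplier 1.0, then 0.8 at iteration 2, minus 0.10 per iteration,
floor 0.2) and the class-mutation rate (1.0, then 0.9, minus 0.05 per
iteration, floor 0.6); both floors are reached at iteration 8.  The pairing
multiplier is implemented so that the realized share of mixed-class pairs
equals the multiplier times the unrestricted share (a rejected mixed pair
is redrawn among same-class pairs).  Additionally, when one category of a
class variable holds more than 80% of the selected parents for five
consecutive iterations, that variable's mutation rate is halved until the
dominance breaks (decay first, then halving).

## Kernel machinery

All estimators use the product Gaussian kernel
`K(y_1..y_p) = prod_j exp(-y_j^2/2)/sqrt(2 pi)` over the continuous
variables with per-dimension adaptive bandwidths `h_j` = the empirical SD
(n-1 denominator) of the settings in a window: the current iteration for
selection (3.2), the last five iterations for optimum derivation.
Bandwidths are floored at `1e-8` of the domain width so fully converged
populations do not divide by zero.  Class variables carry no distance and
enter by exact-match stratification; an empty stratum falls back to all
rows with a logged warning.  The Nadaraya–Watson estimate is computed with
a per-query log-shift so far-away queries cannot underflow to 0/0.  The
density estimate is `f(y) = (1/(n h_1...h_p)) sum_i prod_j K((y_j-x_ij)/h_j)`
— with the categorical part acting as an indicator kernel and `n` the total
row count, which keeps the mixed estimator a proper density.

## Optimum derivation, termination, final assessment

Per iteration the suggested optimum is derived in two stages: all settings
of the last five iterations are density-gated — those at or below the 20%
KDE quantile are discarded, because sparsely sampled regions produce lucky
outliers — and the kernel regression, supported on *all* simulations so
far, is maximized over the survivors.  Ties break toward the earlier
evaluation.  The per-iteration optima are registered (feeding strategy 3.3)
and logged.

A termination criterion (off by default; campaigns run to the configured
iteration cap) stops the run when, over a 10-iteration window, the best
KR-expected optimum value improves on the window start by less than a
user-set threshold.  The final optimum is re-simulated with 100 independent
replicates (kernel regression is downward-biased exactly in an extremum),
and two candidate optima can be compared with a Welch two-sample t-test on
replicate `m` values (zero-variance conventions: equal means give p = 1,
shifted give p = 0, flagged degenerate).

## Reproducibility and execution

Every per-evaluation seed is a pure function of (master seed, iteration,
slot index), and all operator randomness derives from (master seed,
iteration) streams.  Consequences, all tested: identical master seeds give
byte-identical archive CSVs; serial and parallel execution (joblib) are
indistinguishable; an interrupted campaign resumed from its iteration-level
checkpoint (archive CSV, per-iteration optima CSV, run-state JSON)
reproduces the uninterrupted trajectory exactly.  A corrupted or mismatched
checkpoint refuses to resume with a diagnostic.

## The built-in breeding simulator

The packaged evaluator is a deliberately compact progeny-testing dairy
scheme under the infinitesimal model — a stand-in for a full genomic
simulation with SNP-level genomes and BLUP evaluations, which is out of
scope.  Per cycle: `x2` young test bulls are bred from the current sires
and the best cows (preselected on parent-average EBV from twice as many
candidates); each bull is mated to produce a balanced share of `x1`
phenotyped test daughters; the bull's EBV is the daughter-mean phenotype
deviation shrunk by the half-sib reliability `r^2 = n t / (1 + (n-1) t)`,
`t = h^2/4`, times 2; the top `x3` bulls become the next sires.  The cow
herd holds the two youngest daughter cohorts (herd factor 2 by default);
cows are ranked on own-phenotype EBV (`h^2` times the phenotype deviation).
True breeding values follow parent mean plus Mendelian sampling
`N(0, (sigma_a^2/2)(1 - (F_s + F_d)/2))`; inbreeding is exact pedigree
inbreeding, propagated as a kinship matrix over the active animals (the
recursion only ever needs kinships among current parents, so the full
pedigree never has to be stored; a stand-alone recursive-kinship routine is
provided for explicit pedigrees and is tested against the tabular
relationship-matrix method).  Baseline heritability is 0.30 (sigma_a^2 = 1,
so the trait is in genetic-SD units), rising to 0.32 when the
improved-phenotyping class variable is active; 5 burn-in plus 10 future
cycles; `g` is the change in mean true breeding value between the end of
burn-in and the final daughter cohort, `f` the mean inbreeding coefficient
of that final cohort.  With `h^2 = 0` all EBVs vanish and the expected gain
is zero (tested by Monte Carlo).  Structurally impossible designs never
crash a campaign: `x3 > x2` is clipped with a warning; `x2 > x1` returns a
heavily penalized objective (default -100, configurable).

What this simulator does *not* emulate: genomic selection, overlapping age
structures, non-additive genetic effects, and the absolute outcome scale of
a full dairy-cattle simulation.  Passing tests therefore demonstrate the
*optimizer's* behaviour (recovery of known optima, stability across seeds,
budget exhaustion, gain/inbreeding trade-offs with the expected signs), not
calibrated predictions for a real breeding program.

## Problem sizes used in tests and the acceptance script

Full-size campaigns (600 + 300/iteration, thousands of animals per cycle)
are desk-runnable but slow; the shipped checks therefore use two reductions,
chosen once as the package's working configuration:

* a `scale` factor (0.1) that shrinks the budget and the ranges of the
  cost-bearing variables, leaving `x3`'s range and all rates untouched, so
  the miniature scheme keeps comparable selection intensities;
* a proportionally reduced schedule (`IterationSchedule.scaled(0.1)`: 60
  initial designs, 30 per iteration) for the synthetic-objective studies.

At reduced scale the population is small, so inbreeding per cycle is much
higher than at full scale and the objective surface is shallower along the
`x2`/`x3` trade-off; miniature optima are internally consistent but not
numerically comparable to full-scale results.

## Known limitations

* The diversity filter and the per-variable rate adaptation are documented
  approximations with simple thresholds (0.1 bandwidths; share 0.8 over 5
  iterations, rate halved).
* The dam pathway (herd of two daughter cohorts, phenotype-ranked) is a
  concrete choice where schemes in practice differ widely.
* Kernel regression near domain boundaries is biased inward; the final
  replicate assessment exists precisely to remove that bias from reported
  optima.
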