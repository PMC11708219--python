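"""Evolutionary-algorithm core: archive, schedules, selection and variation.

Each iteration the engine selects parents from the last evaluated
population with three complementary strategies — raw objective value,
kernel-regression expected value (which smooths evaluation noise without a
density bias), and a carry-over of strong settings from the second-to-last
iteration or previously registered optima — then generates a fixed number
of new settings: straight re-evaluations with fresh seeds, recombinations
of random parent pairs, and refinements (guaranteed mutations) of settings
produced this iteration.  Per-iteration counts follow a banded schedule and
the mixing/mutation probabilities decay on a fixed percentage-point
schedule with floors.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np

from .problem import CLASS, ProblemDefinition, Setting, scale_to_budget
from .simulator import SimulationOutcome
from .surrogate import nadaraya_watson

__all__ = [
    "ORIGIN_INIT",
    "ORIGIN_REEVAL",
    "ORIGIN_RECOMBINATION",
    "ORIGIN_REFINEMENT",
    "EvaluatedSetting",
    "SimulationArchive",
    "ScheduleBand",
    "IterationSchedule",
    "RateSchedule",
    "EffectiveRates",
    "schedule_rates",
    "AdaptiveClassRates",
    "select_top_by_objective",
    "select_top_by_kernel_regression",
    "carry_over_previous",
    "enforce_diversity",
    "recombine",
    "mutate",
    "refine",
    "draw_parent_pair",
    "generate_offspring",
]

logger = logging.getLogger(__name__)

ORIGIN_INIT = "init"
ORIGIN_REEVAL = "reeval"
ORIGIN_RECOMBINATION = "recombination"
ORIGIN_REFINEMENT = "refinement"


@dataclass(frozen=True)
class EvaluatedSetting:
    """One archive row: a setting plus one stochastic evaluation."""

    setting: Setting
    outcome: SimulationOutcome
    iteration: int
    origin: str

    def __post_init__(self) -> None:
        if self.iteration < 1:
            raise ValueError("iteration indices start at 1")

    @property
    def m(self) -> float:
        return self.outcome.m

    @property
    def g(self) -> float:
        return self.outcome.g

    @property
    def f(self) -> float:
        return self.outcome.f


class SimulationArchive:
    """Append-only store of every evaluation, indexed by iteration.

    The archive is the regression/density substrate for the surrogate
    machinery and additionally keeps a registry of the optimum suggested at
    each iteration (consumed by the carry-over selection strategy).
    """

    def __init__(self) -> None:
        self._rows: list[EvaluatedSetting] = []
        self._by_iteration: dict[int, list[EvaluatedSetting]] = {}
        self.optima: dict[int, Any] = {}

    def __len__(self) -> int:
        return len(self._rows)

    @property
    def rows(self) -> tuple[EvaluatedSetting, ...]:
        return tuple(self._rows)

    @property
    def iterations(self) -> list[int]:
        return sorted(self._by_iteration)

    @property
    def max_iteration(self) -> int:
        return max(self._by_iteration, default=0)

    def add(self, rows: Iterable[EvaluatedSetting]) -> None:
        rows = list(rows)
        for row in rows:
            expected = self.max_iteration
            if row.iteration not in self._by_iteration and row.iteration != expected + 1:
                raise ValueError(
                    f"iteration indices must be contiguous; got {row.iteration} after {expected}"
                )
            self._rows.append(row)
            self._by_iteration.setdefault(row.iteration, []).append(row)

    def rows_for(self, iteration: int) -> list[EvaluatedSetting]:
        return list(self._by_iteration.get(iteration, []))

    def window_rows(self, iteration: int, k: int = 5) -> list[EvaluatedSetting]:
        """Rows of the last ``k`` iterations up to and including ``iteration``."""
        lo = max(1, iteration - k + 1)
        out: list[EvaluatedSetting] = []
        for it in range(lo, iteration + 1):
            out.extend(self._by_iteration.get(it, []))
        return out

    def register_optimum(self, record: Any) -> None:
        """Register the per-iteration suggested optimum (needs .iteration/.setting/.kr_value)."""
        self.optima[record.iteration] = record

    # -- CSV round-trip ------------------------------------------------------
    # Hand-rolled formatting so that two runs with identical results produce
    # byte-identical files (a checkpoint/resume invariant).

    @staticmethod
    def _fmt(value: Any) -> str:
        if isinstance(value, float):
            return repr(value)
        return str(value)

    def to_csv_text(self, problem: ProblemDefinition) -> str:
        buf = io.StringIO()
        header = ["iteration", "origin", "seed", *problem.names, "g", "f", "m", "cost"]
        buf.write(",".join(header) + "\n")
        for row in self._rows:
            o = row.outcome
            fields = [str(row.iteration), row.origin, str(o.seed)]
            fields += [self._fmt(v) for v in row.setting]
            fields += [self._fmt(o.g), self._fmt(o.f), self._fmt(o.m), self._fmt(o.cost)]
            buf.write(",".join(fields) + "\n")
        return buf.getvalue()

    def write_csv(self, path, problem: ProblemDefinition) -> None:
        Path(path).write_text(self.to_csv_text(problem))

    @classmethod
    def read_csv(cls, path, problem: ProblemDefinition) -> "SimulationArchive":
        archive = cls()
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            expected = {"iteration", "origin", "seed", "g", "f", "m", "cost", *problem.names}
            if set(reader.fieldnames or []) != expected:
                raise ValueError(f"unexpected archive columns {reader.fieldnames}")
            rows = []
            for rec in reader:
                setting = tuple(
                    _parse_value(rec[var.name], var) for var in problem.variables
                )
                outcome = SimulationOutcome(
                    g=float(rec["g"]), f=float(rec["f"]), m=float(rec["m"]),
                    cost=float(rec["cost"]), seed=int(rec["seed"]),
                )
                rows.append(
                    EvaluatedSetting(
                        setting=setting, outcome=outcome,
                        iteration=int(rec["iteration"]), origin=rec["origin"],
                    )
                )
        archive.add(rows)
        return archive


def _parse_value(text: str, var) -> Any:
    if var.kind == CLASS:
        for cat in var.categories:
            if str(cat) == text:
                return cat
        raise ValueError(f"unknown category {text!r} for {var.name}")
    return int(text) if var.integral else float(text)


# -- iteration schedule ------------------------------------------------------


@dataclass(frozen=True)
class ScheduleBand:
    """Counts for a contiguous iteration range (``last=None`` = open-ended).

    ``select`` holds the parent counts for the three selection strategies
    (objective / kernel regression / carry-over) and ``generate`` the
    offspring counts (re-evaluation / recombination / refinement).  The
    re-evaluation count always equals the number of selected parents.
    """

    first: int
    last: int | None
    select: tuple[int, int, int]
    generate: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.generate[0] != sum(self.select):
            raise ValueError(
                f"band {self.first}-{self.last}: re-evaluation count {self.generate[0]} "
                f"must equal total selected {sum(self.select)}"
            )
        if min(self.select) < 0 or min(self.generate) < 0:
            raise ValueError("schedule counts must be non-negative")

    def covers(self, iteration: int) -> bool:
        return self.first <= iteration and (self.last is None or iteration <= self.last)

    @property
    def total_generated(self) -> int:
        return sum(self.generate)


@dataclass(frozen=True)
class IterationSchedule:
    """Initial population size plus per-band selection/generation counts."""

    initial_size: int
    bands: tuple[ScheduleBand, ...]

    def __post_init__(self) -> None:
        if self.initial_size < 1:
            raise ValueError("initial_size must be >= 1")

    @classmethod
    def default(cls) -> "IterationSchedule":
        return cls(
            initial_size=600,
            bands=(
                ScheduleBand(2, 3, (70, 30, 0), (100, 200, 0)),
                ScheduleBand(4, 10, (30, 15, 5), (50, 170, 80)),
                ScheduleBand(11, None, (20, 7, 3), (30, 180, 90)),
            ),
        )

    def band(self, iteration: int) -> ScheduleBand:
        for band in self.bands:
            if band.covers(iteration):
                return band
        raise ValueError(f"no schedule band covers iteration {iteration}")

    def scaled(self, factor: float) -> "IterationSchedule":
        """A proportionally smaller schedule for quick runs.

        Selection counts round to at least 1 when nonzero in the template;
        the refinement count scales likewise and the recombination count
        absorbs the remainder so each band's generation total scales too.
        """

        def shrink(x: int) -> int:
            return max(1, round(x * factor)) if x > 0 else 0

        bands = []
        for b in self.bands:
            select = tuple(shrink(x) for x in b.select)
            total = max(sum(select) + 1, round(b.total_generated * factor))
            n43 = shrink(b.generate[2])
            n41 = sum(select)
            n42 = max(0, total - n41 - n43)
            bands.append(ScheduleBand(b.first, b.last, select, (n41, n42, n43)))
        return IterationSchedule(initial_size=max(2, round(self.initial_size * factor)), bands=tuple(bands))


# -- mutation / pairing rate schedules ---------------------------------------


@dataclass(frozen=True)
class RateSchedule:
    """Base variation probabilities and their iteration decays.

    ``p_activ`` is the per-parameter continuous-mutation activation
    probability (0.2; raised to ``p_refine`` = 0.3 during refinement).  The
    probability of pairing parents with *different* class values and the
    class-mutation rate are damped as iterations progress: both start at
    multiplier 1.0, drop to 0.8 / 0.9 at iteration 2, then lose 0.10 / 0.05
    per iteration until the floors 0.2 / 0.6 (both reached at iteration 8).
    """

    p_activ: float = 0.2
    p_refine: float = 0.3
    pair_step: float = 0.10
    pair_floor: float = 0.2
    class_step: float = 0.05
    class_floor: float = 0.6

    def __post_init__(self) -> None:
        for p in (self.p_activ, self.p_refine, self.pair_floor, self.class_floor):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class EffectiveRates:
    """Iteration-resolved rates used by the variation operators."""

    p_activ: float
    p_refine: float
    pair_multiplier: float
    class_multiplier: float
    class_overrides: Mapping[str, float] = field(default_factory=dict)

    def class_rate(self, name: str, base: float | None = None) -> float:
        """Effective mutation rate for one class variable (decay, then adaptation)."""
        p = (self.p_activ if base is None else base) * self.class_multiplier
        return p * float(self.class_overrides.get(name, 1.0))


def schedule_rates(
    iteration: int,
    base: RateSchedule,
    class_overrides: Mapping[str, float] | None = None,
) -> EffectiveRates:
    """Resolve the decayed multipliers for ``iteration`` (1-based)."""
    if iteration < 1:
        raise ValueError("iteration must be >= 1")
    if iteration == 1:
        pair, cls = 1.0, 1.0
    else:
        pair = max(base.pair_floor, 0.8 - base.pair_step * (iteration - 2))
        cls = max(base.class_floor, 0.9 - base.class_step * (iteration - 2))
    return EffectiveRates(
        p_activ=base.p_activ,
        p_refine=base.p_refine,
        pair_multiplier=pair,
        class_multiplier=cls,
        class_overrides=dict(class_overrides or {}),
    )


class AdaptiveClassRates:
    """Per-variable mutation-rate adaptation from parent class shares.

    When one category of a class variable dominates the selected parents
    (share above ``threshold``) for ``window`` consecutive iterations, that
    variable's class-mutation rate is halved; the halving is lifted as soon
    as the share drops back below the threshold.
    """

    def __init__(self, problem: ProblemDefinition, threshold: float = 0.8, window: int = 5):
        self.problem = problem
        self.threshold = threshold
        self.window = window
        self.streak: dict[str, int] = {problem.variables[i].name: 0 for i in problem.class_indices}
        self.halved: set[str] = set()

    def update(self, parent_settings: Sequence[Setting], iteration: int) -> None:
        if not parent_settings:
            return
        for i in self.problem.class_indices:
            name = self.problem.variables[i].name
            values = [s[i] for s in parent_settings]
            top_share = max(values.count(c) for c in set(values)) / len(values)
            if top_share > self.threshold:
                self.streak[name] += 1
            else:
                self.streak[name] = 0
                self.halved.discard(name)
            if self.streak[name] >= self.window:
                if name not in self.halved:
                    logger.info(
                        "iteration %d: halving class-mutation rate of %s "
                        "(dominant category share > %.0f%% for %d iterations)",
                        iteration, name, 100 * self.threshold, self.window,
                    )
                self.halved.add(name)

    def overrides(self) -> dict[str, float]:
        return {name: 0.5 for name in self.halved}

    def state_dict(self) -> dict:
        return {"streak": dict(self.streak), "halved": sorted(self.halved)}

    def load_state(self, state: Mapping) -> None:
        self.streak.update({k: int(v) for k, v in state.get("streak", {}).items()})
        self.halved = set(state.get("halved", []))


# -- selection ---------------------------------------------------------------


def _rank_rows(rows: Sequence[EvaluatedSetting], key) -> list[EvaluatedSetting]:
    """Stable best-first ordering: larger key first, earlier evaluation wins ties."""
    order = sorted(enumerate(rows), key=lambda pair: (-key(pair[1]), pair[0]))
    return [row for _, row in order]


def select_top_by_objective(rows: Sequence[EvaluatedSetting], n: int) -> list[EvaluatedSetting]:
    """The ``n`` rows with the largest realized objective ``m``."""
    if n > len(rows):
        raise ValueError(f"cannot select {n} from {len(rows)} rows")
    return _rank_rows(rows, lambda r: r.m)[:n]


def select_top_by_kernel_regression(
    rows: Sequence[EvaluatedSetting],
    archive: SimulationArchive,
    n: int,
    bandwidths: np.ndarray,
    problem: ProblemDefinition,
) -> list[EvaluatedSetting]:
    """The ``n`` rows with the highest kernel-regression expected objective.

    Estimates are Nadaraya-Watson over the full archive (not just the
    current iteration), which averages replicate noise away; because every
    candidate gets exactly one estimate, dense regions gain no advantage.
    """
    if n > len(rows):
        raise ValueError(f"cannot select {n} from {len(rows)} rows")
    if n == 0:
        return []
    est = kernel_regression_values(rows, archive, bandwidths, problem)
    order = sorted(range(len(rows)), key=lambda i: (-est[i], i))
    return [rows[i] for i in order[:n]]


def kernel_regression_values(
    rows_or_settings: Sequence,
    archive: SimulationArchive,
    bandwidths: np.ndarray,
    problem: ProblemDefinition,
) -> np.ndarray:
    """KR-expected objective for each row/setting, supported on the full archive."""
    settings = [
        r.setting if isinstance(r, EvaluatedSetting) else r for r in rows_or_settings
    ]
    support_rows = archive.rows
    X = problem.continuous_matrix([r.setting for r in support_rows])
    y = np.asarray([r.m for r in support_rows])
    Q = problem.continuous_matrix(settings)
    qc = problem.class_tuples(settings) if problem.class_indices else None
    sc = problem.class_tuples([r.setting for r in support_rows]) if problem.class_indices else None
    return nadaraya_watson(Q, X, y, bandwidths, query_class=qc, support_class=sc, on_empty="widen")


def carry_over_previous(
    archive: SimulationArchive,
    iteration: int,
    n: int,
    bandwidths: np.ndarray,
    problem: ProblemDefinition,
) -> list[Setting]:
    """Carry-over parents for ``iteration``: strong earlier settings.

    Default: the top-``n`` settings by objective from iteration
    ``iteration - 2``.  Substitution rule: previously registered optima (any
    iteration) whose kernel-regression expected value beats every objective
    value of the last evaluated iteration take those slots, best first.
    Returns an empty list when no second-to-last iteration exists yet.
    """
    if n == 0:
        return []
    prev2 = archive.rows_for(iteration - 2)
    defaults = [r.setting for r in _rank_rows(prev2, lambda r: r.m)[:n]] if prev2 else []
    current_rows = archive.rows_for(iteration - 1)
    if not current_rows or not archive.optima:
        return defaults
    current_max = max(r.m for r in current_rows)
    optima = [rec for rec in archive.optima.values()]
    if not optima:
        return defaults
    kr = kernel_regression_values([rec.setting for rec in optima], archive, bandwidths, problem)
    better = sorted(
        [(v, i) for i, v in enumerate(kr) if v > current_max], key=lambda t: (-t[0], t[1])
    )
    substituted = [optima[i].setting for _, i in better[:n]]
    return (substituted + defaults)[:n]


def enforce_diversity(
    candidates: Sequence[Setting],
    pool: Sequence[Setting],
    bandwidths: np.ndarray,
    problem: ProblemDefinition,
    n: int | None = None,
    delta: float = 0.1,
) -> list[Setting]:
    """Greedily drop near-duplicate selections, backfilling from ``pool``.

    A candidate (best-first order) is kept only if, against every kept
    setting, it differs in at least one class value or some continuous
    dimension by at least ``delta`` current bandwidths.  Rejected slots are
    refilled from the next-best pool entries under the same rule so the
    selection count still matches the schedule; if the pool runs dry a
    shorter list is returned with a warning.
    """
    n = len(candidates) if n is None else n
    cont_idx = problem.continuous_indices
    class_idx = problem.class_indices
    h = np.asarray(bandwidths, dtype=float)

    kept: list[Setting] = []

    def distinct(s: Setting) -> bool:
        for k in kept:
            class_diff = any(s[i] != k[i] for i in class_idx)
            cont_diff = any(
                abs(float(s[i]) - float(k[i])) >= delta * h[j]
                for j, i in enumerate(cont_idx)
            )
            if not (class_diff or cont_diff):
                return False
        return True

    for s in candidates:
        if len(kept) >= n:
            break
        if distinct(s):
            kept.append(s)
    if len(kept) < n:
        for s in pool:
            if len(kept) >= n:
                break
            if distinct(s):
                kept.append(s)
    if len(kept) < n:
        logger.warning("diversity filter exhausted the pool: %d of %d slots filled", len(kept), n)
    return kept


# -- variation operators -----------------------------------------------------


def recombine(
    x: Setting,
    y: Setting,
    problem: ProblemDefinition,
    rng: np.random.Generator,
    w: float | None = None,
    scale: bool = True,
) -> Setting:
    """Intermediate recombination ``z_i = w x_i + (1 - w) y_i``.

    A single weight ``w ~ U(0, 1)`` is drawn per offspring and applied to
    every continuous dimension; each class value is inherited from either
    parent with probability 1/2.  The result is rounded half-up, clipped to
    the domain and budget-scaled (unless ``scale`` is false).
    """
    if w is None:
        w = float(rng.uniform())
    z = list(x)
    for i in problem.continuous_indices:
        z[i] = w * float(x[i]) + (1.0 - w) * float(y[i])
    for i in problem.class_indices:
        z[i] = x[i] if rng.random() < 0.5 else y[i]
    out = problem.clip_continuous(tuple(z))
    if scale and problem.cost_model is not None:
        out = scale_to_budget(out, problem)
    return out


def continuous_mutation_deltas(
    sigmas: np.ndarray, p_activ: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-dimension activation flags and perturbations ``t ~ U(-2s, 2s)``.

    Draws are made for every dimension (and masked by the activations) so
    the stream of random numbers consumed is independent of the outcome.
    """
    sigmas = np.asarray(sigmas, dtype=float)
    active = rng.random(sigmas.shape[0]) < p_activ
    t = rng.uniform(-2.0 * sigmas, 2.0 * sigmas) if sigmas.size else np.empty(0)
    return active, np.where(active, t, 0.0)


def mutate(
    z: Setting,
    sigmas: np.ndarray,
    rates: EffectiveRates,
    problem: ProblemDefinition,
    rng: np.random.Generator,
    p_activ: float | None = None,
    scale: bool = True,
) -> tuple[Setting, bool]:
    """Mutate a setting; returns ``(setting, fired)``.

    Continuous dimensions are independently perturbed by ``t ~ U(-2s, 2s)``
    with activation probability ``p_activ`` (``sigmas`` are the empirical
    SDs of the current iteration's settings); class dimensions are resampled
    uniformly among the *other* categories with the decayed (and possibly
    adaptively halved) class rate.  The result is rounded, clipped and
    budget-scaled.
    """
    p = rates.p_activ if p_activ is None else p_activ
    out = list(z)
    cont_idx = problem.continuous_indices
    active, t = continuous_mutation_deltas(np.asarray(sigmas, dtype=float), p, rng)
    fired = bool(active.any() and np.any(t[active] != 0.0))
    for j, i in enumerate(cont_idx):
        out[i] = float(out[i]) + t[j]
    for i in problem.class_indices:
        var = problem.variables[i]
        rate = rates.class_rate(var.name, base=p)
        if rng.random() < rate:
            others = [c for c in var.categories if c != out[i]]
            out[i] = others[int(rng.integers(0, len(others)))]
            fired = True
    setting = problem.clip_continuous(tuple(out))
    if scale and problem.cost_model is not None:
        setting = scale_to_budget(setting, problem)
    return setting, fired


def refine(
    setting: Setting,
    sigmas: np.ndarray,
    rates: EffectiveRates,
    problem: ProblemDefinition,
    rng: np.random.Generator,
    max_retries: int = 1000,
    scale: bool = True,
) -> Setting:
    """Guaranteed small modification: mutate at the refinement rate (0.3).

    The draw is repeated until at least one mutation fires, so (before
    rounding and budget scaling) the output differs from the input whenever
    any dimension can move; after ``max_retries`` fruitless draws (all
    sigmas zero and class rates zero) the input is returned with a warning.
    """
    for _ in range(max_retries):
        mutated, fired = mutate(
            setting, sigmas, rates, problem, rng, p_activ=rates.p_refine, scale=scale
        )
        if fired:
            return mutated
    logger.warning("refine: no mutation fired in %d attempts; returning the input", max_retries)
    return setting


def draw_parent_pair(
    parents: Sequence[Setting],
    problem: ProblemDefinition,
    pair_multiplier: float,
    rng: np.random.Generator,
    max_redraws: int = 100,
) -> tuple[Setting, Setting]:
    """Draw a random parent pair, damping pairs with differing class values.

    A drawn mixed-class pair is kept with probability ``pair_multiplier``;
    otherwise the draw is repeated accepting only same-class pairs (bounded,
    after which the last draw is accepted).  The realized share of
    mixed-class pairs is therefore the multiplier times the unrestricted
    share.
    """
    if len(parents) == 1:
        return parents[0], parents[0]
    class_idx = problem.class_indices

    def draw() -> tuple[Setting, Setting, bool]:
        i, j = rng.choice(len(parents), size=2, replace=False)
        a, b = parents[int(i)], parents[int(j)]
        return a, b, any(a[k] != b[k] for k in class_idx)

    a, b, mixed = draw()
    if not mixed or rng.random() < pair_multiplier:
        return a, b
    for _ in range(max_redraws):
        a, b, mixed = draw()
        if not mixed:
            return a, b
    return a, b  # no same-class pair found in the redraw budget


def generate_offspring(
    parents: Sequence[Setting],
    archive: SimulationArchive,
    iteration: int,
    schedule: IterationSchedule,
    rates: EffectiveRates,
    sigmas: np.ndarray,
    problem: ProblemDefinition,
    rng: np.random.Generator,
    max_pair_redraws: int = 100,
) -> list[tuple[Setting, str]]:
    """Emit the band's offspring: re-evaluations, recombinations, refinements.

    Re-evaluations queue every parent again (fresh seeds are assigned by the
    runner).  Recombination draws random parent pairs, down-weighting pairs
    with differing class values by the decayed pairing multiplier (rejected
    pairs are redrawn, boundedly), then mutates each offspring.  Refinement
    applies guaranteed mutations to settings generated this iteration.
    """
    if not parents:
        raise ValueError("generate_offspring needs at least one parent")
    band = schedule.band(iteration)
    n41, n42, n43 = band.generate
    out: list[tuple[Setting, str]] = [(p, ORIGIN_REEVAL) for p in list(parents)[:n41]]

    if len(parents) == 1:
        logger.warning("single parent: recombination degenerates to mutation only")

    fresh: list[Setting] = []
    for _ in range(n42):
        a, b = draw_parent_pair(parents, problem, rates.pair_multiplier, rng, max_pair_redraws)
        z = recombine(a, b, problem, rng)
        z, _ = mutate(z, sigmas, rates, problem, rng)
        fresh.append(z)
        out.append((z, ORIGIN_RECOMBINATION))

    refine_pool = [s for s, _ in out]
    if n43 > 0:
        take = min(n43, len(refine_pool))
        picked = rng.choice(len(refine_pool), size=take, replace=False)
        for idx in sorted(int(i) for i in picked):
            refined = refine(refine_pool[idx], sigmas, rates, problem, rng)
            out.append((refined, ORIGIN_REFINEMENT))
    return out
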