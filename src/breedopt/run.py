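"""Orchestration: the optimization loop, optimum derivation and final assessment.

The loop evaluates an initial population (uniform/generalized-Bernoulli
sampling plus budget scaling), then iterates select -> generate -> evaluate
-> derive optimum.  The optimum of an iteration is derived in two stages:
a kernel-density gate first discards all settings of the last five
iterations whose estimated density falls at or below the 20% quantile
(sparsely sampled regions produce lucky outliers), then the
kernel-regression expected objective — supported on *all* simulations — is
maximized over the survivors.

Every per-evaluation seed is a pure function of (master seed, iteration,
slot), so serial and parallel execution produce identical archives and an
interrupted run resumes onto the exact same trajectory from its
iteration-level checkpoint (archive CSV + run-state JSON).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
from scipy import stats

from .engine import (
    ORIGIN_INIT,
    AdaptiveClassRates,
    EvaluatedSetting,
    IterationSchedule,
    RateSchedule,
    SimulationArchive,
    carry_over_previous,
    enforce_diversity,
    generate_offspring,
    kernel_regression_values,
    schedule_rates,
    select_top_by_kernel_regression,
    select_top_by_objective,
)
from .problem import ProblemDefinition, Setting, sample_initial_population
from .simulator import SimulationOutcome
from .surrogate import adaptive_bandwidths, kernel_density

__all__ = [
    "RunConfig",
    "OptimumReport",
    "RunResult",
    "TerminationDecision",
    "WelchResult",
    "CheckpointError",
    "SerialExecutor",
    "JoblibExecutor",
    "evaluation_seed",
    "derive_optimum",
    "assess_termination",
    "final_assessment",
    "compare_optima",
    "iteration_plan",
    "estimate_campaign_cost",
    "run_optimization",
    "resume_optimization",
]

logger = logging.getLogger(__name__)

_INIT_STREAM = 101
_GEN_STREAM = 202
_ASSESS_STREAM = 303


class CheckpointError(RuntimeError):
    """Raised when a checkpoint directory is missing, inconsistent or corrupted."""


@dataclass
class RunConfig:
    """Everything needed to reproduce an optimization campaign."""

    problem: ProblemDefinition
    evaluator: Any  # must expose evaluate(setting, seed) -> SimulationOutcome
    schedule: IterationSchedule = field(default_factory=IterationSchedule.default)
    rates: RateSchedule = field(default_factory=RateSchedule)
    master_seed: int = 0
    max_iterations: int = 40
    termination_window: int = 10
    termination_threshold: float | None = None
    kde_quantile: float = 0.2
    kr_window: int = 5
    diversity_delta: float = 0.1
    adapt_threshold: float = 0.8
    adapt_window: int = 5
    final_replicates: int = 100
    n_jobs: int = 1
    outdir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.master_seed is None:
            raise ValueError("a master seed is required for reproducibility")


@dataclass(frozen=True)
class OptimumReport:
    """The suggested optimum of one iteration with its gating diagnostics."""

    setting: Setting
    kr_value: float
    iteration: int
    density: float
    gated_out: int
    n_candidates: int
    assessment: Mapping[str, Any] | None = None


@dataclass(frozen=True)
class RunResult:
    report: OptimumReport
    archive: SimulationArchive


@dataclass(frozen=True)
class TerminationDecision:
    stop: bool
    improvement: float | None = None


@dataclass(frozen=True)
class WelchResult:
    statistic: float
    pvalue: float
    df: float
    degenerate: bool = False


# -- seeds and executors -----------------------------------------------------


def evaluation_seed(master_seed: int, iteration: int, slot: int) -> int:
    """Deterministic per-evaluation seed: a pure function of its coordinates."""
    ss = np.random.SeedSequence([int(master_seed), int(iteration), int(slot)])
    return int(ss.generate_state(1)[0] % (2**31))


class SerialExecutor:
    """Evaluate settings one by one (reference behaviour)."""

    def run(self, evaluator, settings: Sequence[Setting], seeds: Sequence[int]):
        return [evaluator.evaluate(s, seed) for s, seed in zip(settings, seeds)]


class JoblibExecutor:
    """Parallel evaluation; results are identical to serial execution because
    each evaluation's seed is fixed up front."""

    def __init__(self, n_jobs: int, prefer: str = "processes"):
        self.n_jobs = n_jobs
        self.prefer = prefer

    def run(self, evaluator, settings: Sequence[Setting], seeds: Sequence[int]):
        from joblib import Parallel, delayed

        return Parallel(n_jobs=self.n_jobs, prefer=self.prefer)(
            delayed(evaluator.evaluate)(s, seed) for s, seed in zip(settings, seeds)
        )


def _make_executor(config: RunConfig, executor=None):
    if executor is not None:
        return executor
    if config.n_jobs and config.n_jobs != 1:
        return JoblibExecutor(config.n_jobs)
    return SerialExecutor()


# -- optimum derivation ------------------------------------------------------


def derive_optimum(
    archive: SimulationArchive,
    iteration: int,
    problem: ProblemDefinition,
    kde_quantile: float = 0.2,
    window: int = 5,
) -> OptimumReport:
    """Density-gated kernel-regression argmax over the recent populations.

    (1) collect all settings of the last ``window`` iterations; (2) estimate
    their kernel density with bandwidths from the same window's empirical
    SDs; (3) drop settings at or below the ``kde_quantile`` density quantile;
    (4) estimate the expected objective of the survivors by kernel
    regression over the *entire* archive; (5) return the argmax.
    """
    rows = archive.window_rows(iteration, window)
    if not rows:
        raise ValueError("archive holds no rows for the requested window")
    settings = [r.setting for r in rows]
    X = problem.continuous_matrix(settings)
    classes = problem.class_tuples(settings) if problem.class_indices else None
    h = adaptive_bandwidths(X, problem.bandwidth_floor())

    distinct = {tuple(s) for s in settings}
    if len(distinct) == 1:
        only = settings[0]
        kr = float(np.mean([r.m for r in rows]))
        return OptimumReport(
            setting=only, kr_value=kr, iteration=iteration,
            density=float("nan"), gated_out=0, n_candidates=len(rows),
        )

    dens = kernel_density(X, X, h, query_class=classes, points_class=classes)
    cutoff = float(np.quantile(dens, kde_quantile))
    keep = dens > cutoff
    if not keep.any():
        keep = np.ones(len(rows), dtype=bool)
    survivors = [settings[i] for i in np.flatnonzero(keep)]
    kr_vals = kernel_regression_values(survivors, archive, h, problem)
    best_local = int(np.argmax(kr_vals))
    best_global = int(np.flatnonzero(keep)[best_local])
    return OptimumReport(
        setting=settings[best_global],
        kr_value=float(kr_vals[best_local]),
        iteration=iteration,
        density=float(dens[best_global]),
        gated_out=int((~keep).sum()),
        n_candidates=len(rows),
    )


def assess_termination(
    optima_values: Sequence[float],
    window: int = 10,
    threshold: float | None = None,
) -> TerminationDecision:
    """Stop when the best KR-expected objective stalls over a window.

    With a threshold set, the run stops once at least ``window`` iterations
    exist and the best value within the last ``window`` iterations improves
    on the window's first value by less than the threshold.  Unset threshold
    (the default) disables the criterion entirely.
    """
    if threshold is None or len(optima_values) < window:
        return TerminationDecision(stop=False)
    recent = list(optima_values)[-window:]
    improvement = max(recent) - recent[0]
    return TerminationDecision(stop=improvement < threshold, improvement=improvement)


# -- assessment --------------------------------------------------------------


def final_assessment(
    optimum: Setting,
    evaluator,
    n_replicates: int = 100,
    seed: int = 0,
    weight: float | None = None,
) -> dict[str, Any]:
    """Unbiased re-evaluation of the suggested optimum with fresh seeds.

    The kernel regression is downward-biased exactly in an extremum, so the
    final optimum is re-simulated ``n_replicates`` times; the report holds
    per-quantity means, SDs and quantiles plus the replicate values.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    seeds = [evaluation_seed(seed, 0, _ASSESS_STREAM + i) for i in range(n_replicates)]
    rows: list[SimulationOutcome] = []
    failures = 0
    for s in seeds:
        try:
            rows.append(evaluator.evaluate(optimum, s))
        except Exception:  # noqa: BLE001 - a failed replicate must not sink the report
            failures += 1
            logger.warning("replicate with seed %d failed; excluded", s, exc_info=True)
    out: dict[str, Any] = {"n": len(rows), "failures": failures, "replicates": {}}
    for key in ("g", "f", "m"):
        vals = np.asarray([getattr(r, key) for r in rows])
        out[key] = {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            "min": float(vals.min()),
            "q25": float(np.quantile(vals, 0.25)),
            "median": float(np.quantile(vals, 0.5)),
            "q75": float(np.quantile(vals, 0.75)),
            "max": float(vals.max()),
        }
        out["replicates"][key] = [float(v) for v in vals]
    return out


def compare_optima(m_a: Sequence[float], m_b: Sequence[float]) -> WelchResult:
    """Welch two-sample t-test on replicate objective values."""
    a = np.asarray(m_a, dtype=float)
    b = np.asarray(m_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicates per group")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return WelchResult(statistic=0.0, pvalue=1.0, df=float(len(a) + len(b) - 2), degenerate=True)
        sign = 1.0 if a.mean() > b.mean() else -1.0
        return WelchResult(statistic=sign * math.inf, pvalue=0.0, df=float(len(a) + len(b) - 2), degenerate=True)
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(statistic=float(res.statistic), pvalue=float(res.pvalue), df=float(res.df))


def iteration_plan(schedule: IterationSchedule, max_iterations: int) -> list[int]:
    """Cumulative number of evaluations after each iteration."""
    out = [schedule.initial_size]
    for it in range(2, max_iterations + 1):
        out.append(out[-1] + schedule.band(it).total_generated)
    return out


def estimate_campaign_cost(n_simulations: int, cost_per_simulation: float) -> float:
    """Total compute cost of a campaign, rounded to cents."""
    if n_simulations < 0 or cost_per_simulation < 0:
        raise ValueError("inputs must be >= 0")
    return round(n_simulations * cost_per_simulation + 1e-12, 2)


# -- the loop ----------------------------------------------------------------


def _problem_fingerprint(problem: ProblemDefinition) -> str:
    payload = {
        "variables": [
            {
                "name": v.name,
                "kind": v.kind,
                "domain": v.domain,
                "integral": v.integral,
                "categories": list(map(str, v.categories)) if v.categories else None,
                "init_bounds": v.init_bounds,
                "cost_bearing": v.cost_bearing,
            }
            for v in problem.variables
        ],
        "budget": problem.cost_model.budget if problem.cost_model else None,
        "weight": problem.objective_weight,
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def _select_parents(
    config: RunConfig, archive: SimulationArchive, iteration: int
) -> tuple[list[Setting], np.ndarray]:
    problem = config.problem
    band = config.schedule.band(iteration)
    n1, n2, n3 = band.select
    rows_prev = archive.rows_for(iteration - 1)
    X_prev = problem.continuous_matrix([r.setting for r in rows_prev])
    h = adaptive_bandwidths(X_prev, problem.bandwidth_floor())

    sel1 = select_top_by_objective(rows_prev, min(n1, len(rows_prev)))
    chosen = set(id(r) for r in sel1)
    remaining = [r for r in rows_prev if id(r) not in chosen]
    sel2 = select_top_by_kernel_regression(
        remaining, archive, min(n2, len(remaining)), h, problem
    )
    chosen.update(id(r) for r in sel2)
    sel3 = carry_over_previous(archive, iteration, n3, h, problem)

    candidates = [r.setting for r in sel1] + [r.setting for r in sel2] + list(sel3)
    pool = [
        r.setting
        for r in _sorted_by_m(rows_prev)
        if id(r) not in chosen
    ]
    parents = enforce_diversity(
        candidates, pool, h, problem, n=n1 + n2 + n3, delta=config.diversity_delta
    )
    return parents, h


def _sorted_by_m(rows):
    return [row for _, row in sorted(enumerate(rows), key=lambda p: (-p[1].m, p[0]))]


def _evaluate_iteration(
    config: RunConfig,
    executor,
    iteration: int,
    tagged_settings: Sequence[tuple[Setting, str]],
) -> list[EvaluatedSetting]:
    settings = [s for s, _ in tagged_settings]
    seeds = [evaluation_seed(config.master_seed, iteration, slot) for slot in range(len(settings))]
    outcomes = executor.run(config.evaluator, settings, seeds)
    return [
        EvaluatedSetting(setting=s, outcome=o, iteration=iteration, origin=tag)
        for (s, tag), o in zip(tagged_settings, outcomes)
    ]


def _checkpoint(config: RunConfig, archive: SimulationArchive, adaptive: AdaptiveClassRates,
                completed: int) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    archive.write_csv(outdir / "archive.csv", config.problem)
    _write_optima_csv(outdir / "optima.csv", archive, config.problem)
    state = {
        "format": 1,
        "master_seed": config.master_seed,
        "completed_iteration": completed,
        "n_rows": len(archive),
        "problem_fingerprint": _problem_fingerprint(config.problem),
        "adaptive": adaptive.state_dict(),
    }
    (outdir / "run_state.json").write_text(json.dumps(state, indent=2, sort_keys=True))


def _write_optima_csv(path, archive: SimulationArchive, problem: ProblemDefinition) -> None:
    lines = [",".join(["iteration", *problem.names, "kr_value", "density", "gated_out", "n_candidates"])]
    for it in sorted(archive.optima):
        rec = archive.optima[it]
        fields = [str(it)]
        fields += [repr(v) if isinstance(v, float) else str(v) for v in rec.setting]
        fields += [repr(float(rec.kr_value)), repr(float(rec.density)),
                   str(rec.gated_out), str(rec.n_candidates)]
        lines.append(",".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def _read_optima_csv(path, problem: ProblemDefinition) -> list[OptimumReport]:
    import csv as _csv

    out = []
    with open(path, newline="") as fh:
        for rec in _csv.DictReader(fh):
            setting = tuple(_parse_optima_value(rec[v.name], v) for v in problem.variables)
            out.append(
                OptimumReport(
                    setting=setting,
                    kr_value=float(rec["kr_value"]),
                    iteration=int(rec["iteration"]),
                    density=float(rec["density"]),
                    gated_out=int(rec["gated_out"]),
                    n_candidates=int(rec["n_candidates"]),
                )
            )
    return out


def _parse_optima_value(text: str, var) -> Any:
    if var.kind == "class":
        for cat in var.categories:
            if str(cat) == text:
                return cat
        raise ValueError(f"unknown category {text!r} for {var.name}")
    return int(text) if var.integral else float(text)


def _load_checkpoint(config: RunConfig) -> tuple[SimulationArchive, AdaptiveClassRates, int]:
    outdir = Path(config.outdir)
    try:
        state = json.loads((outdir / "run_state.json").read_text())
        archive = SimulationArchive.read_csv(outdir / "archive.csv", config.problem)
    except FileNotFoundError as exc:
        raise CheckpointError(f"no checkpoint found in {outdir}") from exc
    except (ValueError, KeyError) as exc:
        raise CheckpointError(f"corrupted checkpoint in {outdir}: {exc}") from exc
    if state.get("problem_fingerprint") != _problem_fingerprint(config.problem):
        raise CheckpointError("checkpoint was written for a different problem definition")
    if state.get("master_seed") != config.master_seed:
        raise CheckpointError("checkpoint was written under a different master seed")
    if state.get("n_rows") != len(archive):
        raise CheckpointError("archive row count disagrees with run state; refusing to resume")
    completed = int(state["completed_iteration"])
    if archive.max_iteration != completed:
        raise CheckpointError("archive iterations disagree with run state; refusing to resume")
    adaptive = AdaptiveClassRates(config.problem, config.adapt_threshold, config.adapt_window)
    adaptive.load_state(state.get("adaptive", {}))
    # reload the per-iteration optima registry exactly as recorded: recomputing
    # against the fuller archive would alter earlier optima and the trajectory
    try:
        for rec in _read_optima_csv(outdir / "optima.csv", config.problem):
            archive.register_optimum(rec)
    except (OSError, ValueError, KeyError) as exc:
        raise CheckpointError(f"corrupted optima registry in {outdir}: {exc}") from exc
    if sorted(archive.optima) != archive.iterations:
        raise CheckpointError("optima registry incomplete; refusing to resume")
    return archive, adaptive, completed


def _run_loop(
    config: RunConfig,
    executor,
    archive: SimulationArchive,
    adaptive: AdaptiveClassRates,
    start_iteration: int,
) -> RunResult:
    problem = config.problem
    for iteration in range(start_iteration, config.max_iterations + 1):
        if iteration == 1:
            rng = np.random.default_rng(
                np.random.SeedSequence([config.master_seed, 1, _INIT_STREAM])
            )
            settings = sample_initial_population(problem, config.schedule.initial_size, rng)
            tagged = [(s, ORIGIN_INIT) for s in settings]
        else:
            parents, h = _select_parents(config, archive, iteration)
            adaptive.update(parents, iteration)
            rates = schedule_rates(iteration, config.rates, adaptive.overrides())
            rows_prev = archive.rows_for(iteration - 1)
            sigmas = np.std(
                problem.continuous_matrix([r.setting for r in rows_prev]), axis=0, ddof=1
            ) if len(rows_prev) > 1 else np.zeros(len(problem.continuous_indices))
            rng = np.random.default_rng(
                np.random.SeedSequence([config.master_seed, iteration, _GEN_STREAM])
            )
            tagged = generate_offspring(
                parents, archive, iteration, config.schedule, rates, sigmas, problem, rng
            )
        rows = _evaluate_iteration(config, executor, iteration, tagged)
        archive.add(rows)
        report = derive_optimum(archive, iteration, problem, config.kde_quantile, config.kr_window)
        archive.register_optimum(report)
        logger.info(
            "iteration %d: %d evaluations, optimum %s (KR-expected m = %.4f)",
            iteration, len(rows), report.setting, report.kr_value,
        )
        if config.outdir is not None:
            _checkpoint(config, archive, adaptive, iteration)
        values = [archive.optima[i].kr_value for i in sorted(archive.optima)]
        decision = assess_termination(values, config.termination_window, config.termination_threshold)
        if decision.stop:
            logger.info(
                "termination criterion met at iteration %d (improvement %.3g below threshold)",
                iteration, decision.improvement,
            )
            break

    final = archive.optima[archive.max_iteration]
    assessment = None
    if config.final_replicates >= 2:
        assessment = final_assessment(
            final.setting, config.evaluator, config.final_replicates,
            seed=evaluation_seed(config.master_seed, 0, _ASSESS_STREAM),
        )
    report = dataclasses.replace(final, assessment=assessment)
    if config.outdir is not None:
        payload = dataclasses.asdict(report)
        payload["setting"] = dict(zip(problem.names, report.setting))
        (Path(config.outdir) / "optimum.json").write_text(json.dumps(payload, indent=2, default=str))
    return RunResult(report=report, archive=archive)


def run_optimization(config: RunConfig, executor=None) -> RunResult:
    """Run a full optimization campaign from scratch."""
    executor = _make_executor(config, executor)
    archive = SimulationArchive()
    adaptive = AdaptiveClassRates(config.problem, config.adapt_threshold, config.adapt_window)
    return _run_loop(config, executor, archive, adaptive, start_iteration=1)


def resume_optimization(config: RunConfig, executor=None) -> RunResult:
    """Resume an interrupted campaign from its checkpoint directory.

    The remaining trajectory is identical to the uninterrupted run because
    all randomness is re-derived from (master seed, iteration) coordinates.
    """
    if config.outdir is None:
        raise CheckpointError("resume requires outdir")
    executor = _make_executor(config, executor)
    archive, adaptive, completed = _load_checkpoint(config)
    return _run_loop(config, executor, archive, adaptive, start_iteration=completed + 1)
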