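"""Optimization-problem definition for breeding-program design search.

A breeding-program design is encoded as an ordered vector of decision
variables: *continuous* variables (typically integer counts such as the
number of test daughters, test bulls or selected sires) and *class*
variables (categorical choices with a small number of realizations, e.g.
whether an improved-phenotyping strategy is used).  Designs are constrained
by a linear annual cost model under a fixed budget; because spending less
money is never rewarded by the objective, every candidate design is rescaled
so that it consumes the full budget (up to integer rounding).

The scalar objective combines the simulated genetic gain ``g`` and the
inbreeding level ``f`` as ``m = g - weight * f`` (default weight 50).

This module owns:

* :class:`DecisionVariable`, :class:`CostModel`, :class:`ProblemDefinition`
  and the ``Setting`` convention (a plain tuple, one value per variable),
* cost evaluation and the floor-then-top-up budget scaling rule,
* initial-population sampling (uniform / generalized-Bernoulli with
  capacity-style dependency clipping and init-only bounds),
* YAML problem configs, including the four packaged example scenarios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "Setting",
    "ProblemConfigError",
    "DomainError",
    "DecisionVariable",
    "CostCoefficient",
    "CostModel",
    "LinearConstraint",
    "CapacityRule",
    "ProblemDefinition",
    "compute_cost",
    "scale_to_budget",
    "objective_combine",
    "sample_initial_population",
    "scale_problem",
    "load_problem",
    "load_scenario",
    "list_scenarios",
]

#: A candidate design ("parameter setting"): ordered values, one per variable.
Setting = tuple

CONTINUOUS = "continuous"
CLASS = "class"


class ProblemConfigError(ValueError):
    """Raised for an inconsistent or incomplete problem configuration."""


class DomainError(ValueError):
    """Raised when a setting value lies outside its variable's domain."""


@dataclass(frozen=True)
class DecisionVariable:
    """One optimizable design parameter.

    Parameters
    ----------
    name:
        Unique identifier, referenced by cost model and constraints.
    kind:
        ``"continuous"`` (interval domain, usually integral counts) or
        ``"class"`` (finite category list).
    domain:
        Closed ``(lower, upper)`` interval for continuous variables.
    integral:
        If true (default) the variable only takes integer values; all
        operators round before use.
    categories:
        Category labels for class variables (at least two).
    init_bounds:
        Optional narrower interval used *only* during initialization; the
        optimizer may leave it in later iterations.
    class_init_probs:
        Optional category probabilities for the initialization sampler
        (generalized Bernoulli); uniform if omitted.
    cost_bearing:
        Marks variables that are rescaled jointly to exhaust the budget.
    """

    name: str
    kind: str = CONTINUOUS
    domain: tuple[float, float] | None = None
    integral: bool = True
    categories: tuple[Any, ...] | None = None
    init_bounds: tuple[float, float] | None = None
    class_init_probs: tuple[float, ...] | None = None
    cost_bearing: bool = False

    def __post_init__(self) -> None:
        if self.kind not in (CONTINUOUS, CLASS):
            raise ProblemConfigError(f"unknown variable kind {self.kind!r}")
        if self.kind == CONTINUOUS:
            if self.domain is None:
                raise ProblemConfigError(f"{self.name}: continuous variable needs a domain")
            lo, hi = self.domain
            if not (math.isfinite(lo) and math.isfinite(hi) and lo <= hi):
                raise ProblemConfigError(f"{self.name}: invalid domain {self.domain}")
            if self.init_bounds is not None:
                ilo, ihi = self.init_bounds
                if ilo > ihi or ilo < lo or ihi > hi:
                    raise ProblemConfigError(
                        f"{self.name}: init_bounds {self.init_bounds} outside domain {self.domain}"
                    )
            if self.categories is not None:
                raise ProblemConfigError(f"{self.name}: continuous variable cannot have categories")
        else:
            if self.categories is None or len(self.categories) < 2:
                raise ProblemConfigError(f"{self.name}: class variable needs >= 2 categories")
            if len(set(self.categories)) != len(self.categories):
                raise ProblemConfigError(f"{self.name}: duplicate categories")
            if self.class_init_probs is not None:
                if len(self.class_init_probs) != len(self.categories):
                    raise ProblemConfigError(f"{self.name}: class_init_probs length mismatch")
                if abs(sum(self.class_init_probs) - 1.0) > 1e-9 or min(self.class_init_probs) < 0:
                    raise ProblemConfigError(f"{self.name}: class_init_probs must sum to 1")
            if self.cost_bearing:
                raise ProblemConfigError(f"{self.name}: class variables cannot be cost bearing")

    def contains(self, value: Any) -> bool:
        """True if ``value`` lies in this variable's domain."""
        if self.kind == CLASS:
            return value in self.categories
        lo, hi = self.domain
        if not (lo - 1e-9 <= value <= hi + 1e-9):
            return False
        if self.integral and abs(value - round(value)) > 1e-9:
            return False
        return True

    def sampling_bounds(self) -> tuple[float, float]:
        return self.init_bounds if self.init_bounds is not None else self.domain


@dataclass(frozen=True)
class CostCoefficient:
    """Per-unit cost of one variable, optionally conditional on a class variable.

    The effective coefficient is ``base + by_value[setting[depends_on]]``, so
    e.g. a per-cow housing cost of 4,000 that rises by 1,000 when improved
    phenotyping is active is ``CostCoefficient(4000, "x4", {0: 0, 1: 1000})``.
    """

    base: float = 0.0
    depends_on: str | None = None
    by_value: Mapping[Any, float] | None = None

    def __post_init__(self) -> None:
        if (self.depends_on is None) != (self.by_value is None):
            raise ProblemConfigError("depends_on and by_value must be given together")

    def resolve(self, values: Mapping[str, Any]) -> float:
        if self.depends_on is None:
            return float(self.base)
        try:
            ctx = values[self.depends_on]
        except KeyError as exc:
            raise ProblemConfigError(f"cost coefficient depends on unknown variable {self.depends_on!r}") from exc
        try:
            return float(self.base) + float(self.by_value[ctx])
        except KeyError as exc:
            raise ProblemConfigError(
                f"no cost coefficient for {self.depends_on}={ctx!r}"
            ) from exc


@dataclass(frozen=True)
class CostModel:
    """Linear annual cost model with a hard budget.

    ``cost(x) = sum_i coefficient_i(class context) * x_i`` over the variables
    listed in ``coefficients``; the all-zero setting always costs 0.
    """

    budget: float
    coefficients: Mapping[str, float | CostCoefficient]

    def __post_init__(self) -> None:
        if not self.budget > 0:
            raise ProblemConfigError("budget must be positive")
        for name, coeff in self.coefficients.items():
            if isinstance(coeff, CostCoefficient):
                vals = [coeff.base + v for v in coeff.by_value.values()] if coeff.by_value else [coeff.base]
            else:
                vals = [coeff]
            if any(v < 0 for v in vals):
                raise ProblemConfigError(f"negative cost coefficient for {name}")

    def unit_cost(self, name: str, values: Mapping[str, Any]) -> float:
        coeff = self.coefficients[name]
        if isinstance(coeff, CostCoefficient):
            return coeff.resolve(values)
        return float(coeff)


@dataclass(frozen=True)
class LinearConstraint:
    """Linear inequality ``lower <= sum_i c_i x_i <= upper`` with a scope.

    ``scope="init_only"`` constraints are checked during initialization only;
    settings produced later by the optimizer may violate them freely.
    """

    coefficients: Mapping[str, float]
    lower: float | None = None
    upper: float | None = None
    scope: str = "always"

    def __post_init__(self) -> None:
        if self.scope not in ("always", "init_only"):
            raise ProblemConfigError(f"unknown constraint scope {self.scope!r}")
        if self.lower is None and self.upper is None:
            raise ProblemConfigError("constraint needs a lower or upper bound")

    def satisfied(self, values: Mapping[str, Any], tol: float = 1e-9) -> bool:
        total = sum(c * float(values[name]) for name, c in self.coefficients.items())
        if self.lower is not None and total < self.lower - tol:
            return False
        if self.upper is not None and total > self.upper + tol:
            return False
        return True


@dataclass(frozen=True)
class CapacityRule:
    """Joint-capacity dependency: the variables listed share a resource pool.

    During sampling the variables are drawn in declaration order and the
    remaining capacity clips the admissible range of each later variable
    (e.g. a stable housing at most 3,000 animals across males and females).
    """

    variables: tuple[str, ...]
    capacity: float


@dataclass(frozen=True)
class ProblemDefinition:
    """A complete optimization problem: variables, costs, objective, constraints."""

    variables: tuple[DecisionVariable, ...]
    cost_model: CostModel | None = None
    objective_weight: float = 50.0
    constraints: tuple[LinearConstraint, ...] = ()
    dependencies: tuple[CapacityRule, ...] = ()
    name: str = "problem"
    simulator_config: Mapping[str, Any] | None = None

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ProblemConfigError("variable names must be unique")
        if self.objective_weight < 0:
            raise ProblemConfigError("objective_weight must be >= 0")
        index = {name: i for i, name in enumerate(names)}
        object.__setattr__(self, "_index", index)
        if self.cost_model is not None:
            for cname, coeff in self.cost_model.coefficients.items():
                if cname not in index:
                    raise ProblemConfigError(f"cost model references unknown variable {cname!r}")
                if self.variables[index[cname]].kind != CONTINUOUS:
                    raise ProblemConfigError(f"cost coefficient on non-continuous variable {cname!r}")
                if isinstance(coeff, CostCoefficient) and coeff.depends_on is not None:
                    if coeff.depends_on not in index:
                        raise ProblemConfigError(
                            f"cost coefficient depends on unknown variable {coeff.depends_on!r}"
                        )
            if not any(v.cost_bearing for v in self.variables):
                raise ProblemConfigError("a budget requires at least one cost_bearing variable")
        for con in self.constraints:
            for cname in con.coefficients:
                if cname not in index:
                    raise ProblemConfigError(f"constraint references unknown variable {cname!r}")
        for rule in self.dependencies:
            for cname in rule.variables:
                if cname not in index:
                    raise ProblemConfigError(f"dependency references unknown variable {cname!r}")

    # -- structural helpers -------------------------------------------------

    def index(self, name: str) -> int:
        return self._index[name]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    @property
    def continuous_indices(self) -> tuple[int, ...]:
        return tuple(i for i, v in enumerate(self.variables) if v.kind == CONTINUOUS)

    @property
    def class_indices(self) -> tuple[int, ...]:
        return tuple(i for i, v in enumerate(self.variables) if v.kind == CLASS)

    @property
    def cost_bearing_indices(self) -> tuple[int, ...]:
        return tuple(i for i, v in enumerate(self.variables) if v.cost_bearing)

    def as_dict(self, setting: Setting) -> dict[str, Any]:
        if len(setting) != len(self.variables):
            raise DomainError(f"setting has {len(setting)} values, expected {len(self.variables)}")
        return {v.name: setting[i] for i, v in enumerate(self.variables)}

    def continuous_matrix(self, settings: Sequence[Setting]) -> np.ndarray:
        """Stack the continuous components of ``settings`` into an (n, p) array."""
        idx = self.continuous_indices
        return np.asarray([[float(s[i]) for i in idx] for s in settings], dtype=float).reshape(
            len(settings), len(idx)
        )

    def class_tuples(self, settings: Sequence[Setting]) -> list[tuple]:
        idx = self.class_indices
        return [tuple(s[i] for i in idx) for s in settings]

    def domain_widths(self) -> np.ndarray:
        return np.asarray(
            [self.variables[i].domain[1] - self.variables[i].domain[0] for i in self.continuous_indices],
            dtype=float,
        )

    def bandwidth_floor(self, rel: float = 1e-8) -> np.ndarray:
        """Per-continuous-dimension bandwidth floor (a tiny fraction of the domain width)."""
        widths = self.domain_widths()
        return np.maximum(rel * widths, 1e-300)

    # -- feasibility --------------------------------------------------------

    def validate_setting(self, setting: Setting, scope: str = "always") -> None:
        """Raise :class:`DomainError` if ``setting`` is infeasible.

        ``scope="init"`` additionally enforces init-only bounds and
        constraints; ``scope="always"`` checks only the permanent ones, so
        optimizer-generated settings may leave the initialization box
        without error.
        """
        values = self.as_dict(setting)
        for i, var in enumerate(self.variables):
            if not var.contains(setting[i]):
                raise DomainError(f"{var.name}={setting[i]!r} outside domain")
            if scope == "init" and var.kind == CONTINUOUS and var.init_bounds is not None:
                lo, hi = var.init_bounds
                if not (lo - 1e-9 <= setting[i] <= hi + 1e-9):
                    raise DomainError(f"{var.name}={setting[i]!r} outside init bounds {var.init_bounds}")
        for con in self.constraints:
            if con.scope == "init_only" and scope != "init":
                continue
            if not con.satisfied(values):
                raise DomainError(f"constraint violated: {con}")
        if self.cost_model is not None:
            cost = compute_cost(setting, self)
            if cost > self.cost_model.budget + 1e-6:
                raise DomainError(f"cost {cost} exceeds budget {self.cost_model.budget}")

    def setting_is_feasible(self, setting: Setting, scope: str = "always") -> bool:
        try:
            self.validate_setting(setting, scope=scope)
        except DomainError:
            return False
        return True

    def clip_continuous(self, setting: Setting) -> Setting:
        """Round integral variables half-up and clip continuous values to their domain."""
        out = list(setting)
        for i in self.continuous_indices:
            var = self.variables[i]
            v = float(out[i])
            if var.integral:
                v = math.floor(v + 0.5)
            lo, hi = var.domain
            v = min(max(v, lo), hi)
            out[i] = int(v) if var.integral else v
        return tuple(out)


# -- operations --------------------------------------------------------------


def compute_cost(setting: Setting, problem: ProblemDefinition) -> float:
    """Annual cost of a design under the problem's linear cost model."""
    cm = problem.cost_model
    if cm is None:
        raise ProblemConfigError("problem has no cost model")
    values = problem.as_dict(setting)
    total = 0.0
    for name in cm.coefficients:
        total += cm.unit_cost(name, values) * float(values[name])
    return total


def objective_combine(g: float, f: float, weight: float = 50.0) -> float:
    """Scalar objective ``m = g - weight * f`` (gain penalized by inbreeding)."""
    if weight < 0:
        raise ValueError("weight must be >= 0")
    return g - weight * f


def scale_to_budget(setting: Setting, problem: ProblemDefinition) -> Setting:
    """Rescale the cost-bearing variables so the design exhausts the budget.

    All cost-bearing variables are multiplied by the common factor
    ``budget / cost`` and floored to integers; remaining budget is then
    spent greedily one unit at a time, trying variables in decreasing
    per-unit cost (ties by declaration order), until no single unit of any
    cost-bearing variable fits.  Non-cost-bearing variables are unchanged.
    The result therefore satisfies ``cost <= budget`` and is maximal: one
    more unit of even the cheapest cost-bearing variable would exceed the
    budget.
    """
    cm = problem.cost_model
    if cm is None:
        return tuple(setting)
    cb = problem.cost_bearing_indices
    for i in cb:
        if setting[i] < 0:
            raise DomainError(f"negative value for cost-bearing variable {problem.variables[i].name}")
    cost = compute_cost(setting, problem)
    if cost <= 0:
        raise DomainError("cannot scale a zero-cost setting to the budget")
    factor = cm.budget / cost
    new = list(setting)
    all_integral = all(problem.variables[i].integral for i in cb)
    for i in cb:
        v = float(setting[i]) * factor
        new[i] = math.floor(v + 1e-9) if problem.variables[i].integral else v
    if not all_integral:
        return tuple(new)

    values = problem.as_dict(tuple(new))
    units = {i: cm.unit_cost(problem.variables[i].name, values) for i in cb}
    order = sorted(cb, key=lambda i: (-units[i], i))
    cost = compute_cost(tuple(new), problem)
    tol = 1e-9 * max(1.0, cm.budget)
    progress = True
    while progress:
        progress = False
        for i in order:
            u = units[i]
            if u <= 0:
                continue
            hi = problem.variables[i].domain[1]
            while cost + u <= cm.budget + tol and new[i] + 1 <= hi + 1e-9:
                new[i] += 1
                cost += u
                progress = True
    return tuple(int(new[i]) if i in set(cb) and problem.variables[i].integral else new[i] for i in range(len(new)))


def sample_initial_population(
    problem: ProblemDefinition,
    n: int,
    rng: np.random.Generator | int | None = None,
    max_attempts: int = 2000,
) -> list[Setting]:
    """Draw ``n`` budget-feasible initial designs.

    Continuous variables are sampled uniformly over their init bounds (or
    domain), class variables from their init probabilities (generalized
    Bernoulli).  Capacity dependencies clip ranges sequentially in variable
    order.  Each draw is budget-scaled and accepted only if it satisfies all
    init-scope constraints *after* scaling; infeasible draws are retried.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    out: list[Setting] = []
    for _ in range(n):
        for _attempt in range(max_attempts):
            setting = _sample_one(problem, gen)
            if setting is None:
                continue
            if problem.cost_model is not None:
                try:
                    setting = scale_to_budget(setting, problem)
                except DomainError:
                    continue
            if problem.setting_is_feasible(setting, scope="init"):
                out.append(setting)
                break
        else:
            raise ProblemConfigError(
                f"could not sample a feasible initial setting in {max_attempts} attempts; "
                "init bounds and budget may be incompatible"
            )
    return out


def _sample_one(problem: ProblemDefinition, rng: np.random.Generator) -> Setting | None:
    remaining = {rule: rule.capacity for rule in problem.dependencies}
    vals: list[Any] = []
    for var in problem.variables:
        if var.kind == CLASS:
            probs = var.class_init_probs
            k = len(var.categories)
            idx = int(rng.choice(k, p=probs)) if probs is not None else int(rng.integers(0, k))
            vals.append(var.categories[idx])
            continue
        lo, hi = var.sampling_bounds()
        for rule in problem.dependencies:
            if var.name in rule.variables:
                hi = min(hi, remaining[rule])
        if hi < lo:
            return None
        if var.integral:
            v: float = int(rng.integers(int(math.ceil(lo)), int(math.floor(hi)) + 1))
        else:
            v = float(rng.uniform(lo, hi))
        vals.append(v)
        for rule in problem.dependencies:
            if var.name in rule.variables:
                remaining[rule] -= v
    return tuple(vals)


def scale_problem(problem: ProblemDefinition, factor: float) -> ProblemDefinition:
    """Shrink a problem for quick runs: budget and cost-bearing variable ranges scale by ``factor``.

    Non-cost-bearing variables (e.g. the number of selected sires) keep their
    bounds, so selection intensities remain comparable to the full-size
    problem.
    """
    if not 0 < factor:
        raise ValueError("factor must be positive")
    if problem.cost_model is None:
        raise ProblemConfigError("scale_problem requires a cost model")

    def _scale_iv(bounds, lo_floor=1.0):
        lo, hi = bounds
        return (max(lo_floor, round(lo * factor)) if lo > 1 else lo, max(lo_floor, round(hi * factor)))

    new_vars = []
    for var in problem.variables:
        if var.cost_bearing:
            new_vars.append(
                replace(
                    var,
                    domain=_scale_iv(var.domain),
                    init_bounds=None if var.init_bounds is None else _scale_iv(var.init_bounds),
                )
            )
        else:
            new_vars.append(var)
    cm = replace(problem.cost_model, budget=problem.cost_model.budget * factor)
    return replace(
        problem,
        variables=tuple(new_vars),
        cost_model=cm,
        name=f"{problem.name}_scale{factor:g}",
    )


# -- configuration files -----------------------------------------------------


def _parse_coefficient(raw: Any) -> float | CostCoefficient:
    if isinstance(raw, Mapping):
        return CostCoefficient(
            base=float(raw.get("base", 0.0)),
            depends_on=raw.get("depends_on"),
            by_value=dict(raw["by_value"]) if "by_value" in raw else None,
        )
    return float(raw)


def _parse_variable(raw: Mapping[str, Any]) -> DecisionVariable:
    kind = raw.get("kind", CONTINUOUS)
    return DecisionVariable(
        name=raw["name"],
        kind=kind,
        domain=tuple(raw["domain"]) if "domain" in raw else None,
        integral=bool(raw.get("integral", True)),
        categories=tuple(raw["categories"]) if "categories" in raw else None,
        init_bounds=tuple(raw["init_bounds"]) if "init_bounds" in raw else None,
        class_init_probs=tuple(raw["init_probs"]) if "init_probs" in raw else None,
        cost_bearing=bool(raw.get("cost_bearing", False)),
    )


def load_problem(source: str | Path | Mapping[str, Any]) -> ProblemDefinition:
    """Build a :class:`ProblemDefinition` from a YAML file or mapping."""
    if isinstance(source, Mapping):
        data = source
    else:
        with open(source, "r") as fh:
            data = yaml.safe_load(fh)
    variables = tuple(_parse_variable(v) for v in data["variables"])
    cost_model = None
    if "cost_model" in data and data["cost_model"]:
        cmraw = data["cost_model"]
        cost_model = CostModel(
            budget=float(cmraw["budget"]),
            coefficients={k: _parse_coefficient(v) for k, v in cmraw.get("coefficients", {}).items()},
        )
    constraints = tuple(
        LinearConstraint(
            coefficients=dict(c["coefficients"]),
            lower=c.get("lower"),
            upper=c.get("upper"),
            scope=c.get("scope", "always"),
        )
        for c in data.get("constraints", []) or []
    )
    dependencies = tuple(
        CapacityRule(variables=tuple(d["variables"]), capacity=float(d["capacity"]))
        for d in data.get("dependencies", []) or []
    )
    return ProblemDefinition(
        variables=variables,
        cost_model=cost_model,
        objective_weight=float(data.get("objective_weight", 50.0)),
        constraints=constraints,
        dependencies=dependencies,
        name=str(data.get("name", "problem")),
        simulator_config=data.get("simulator"),
    )


def list_scenarios() -> list[str]:
    """Names of the packaged example scenarios."""
    pkg = resources.files("breedopt") / "scenarios"
    return sorted(p.name[: -len(".yaml")] for p in pkg.iterdir() if p.name.endswith(".yaml"))


def load_scenario(name: str) -> ProblemDefinition:
    """Load a packaged scenario config (``scenario1``, ``scenario2``, ``scenario3a``, ``scenario3b``)."""
    pkg = resources.files("breedopt") / "scenarios" / f"{name}.yaml"
    if not pkg.is_file():
        raise ProblemConfigError(f"unknown scenario {name!r}; available: {list_scenarios()}")
    data = yaml.safe_load(pkg.read_text())
    return load_problem(data)
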