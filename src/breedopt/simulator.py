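"""Stochastic evaluation of breeding-program designs.

Two evaluators are provided, both honouring the plug-in contract
``evaluate(setting, seed) -> SimulationOutcome``:

* :class:`BreedingSimulator` — a deliberately compact progeny-testing dairy
  scheme under the infinitesimal model.  Each cycle, ``x2`` young test bulls
  are bred from the current sires and the best cows, mated to produce ``x1``
  phenotyped test daughters (about ``x1/x2`` per bull); every bull receives a
  progeny-test EBV from the shrunken daughter-mean deviation and the top
  ``x3`` bulls become the next sires, while the cow herd turns over to the
  youngest daughter cohorts.  True breeding values follow parent mean plus
  Mendelian sampling ``N(0, sigma_a^2/2 * (1 - (F_sire + F_dam)/2))`` and
  inbreeding is tracked exactly by pedigree (kinship-matrix recursion).
  The reported outcome is the genetic gain ``g`` over the future cycles (in
  genetic standard deviations), the mean pedigree inbreeding coefficient
  ``f`` of the final daughter cohort, and ``m = g - weight * f``.

* :func:`make_test_objective` — noisy concave quadratics with a known
  optimum and optional class-variable bonuses, used to test the optimizer
  against an analytically known answer.

The module also provides stand-alone pedigree utilities (recursive kinship /
inbreeding coefficients, plain-text pedigree I/O).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

import numpy as np

from .problem import (
    ProblemConfigError,
    ProblemDefinition,
    Setting,
    compute_cost,
    objective_combine,
)

__all__ = [
    "SimulationOutcome",
    "BreedingSchemeConfig",
    "BreedingSimulator",
    "simulate_breeding_program",
    "PedigreeRecord",
    "pedigree_inbreeding",
    "write_pedigree",
    "read_pedigree",
    "SyntheticObjective",
    "make_test_objective",
    "build_evaluator",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationOutcome:
    """One stochastic evaluation of a design.

    ``g``: genetic gain over the future cycles in units of the genetic
    standard deviation; ``f``: mean pedigree inbreeding coefficient of the
    final daughter cohort; ``m``: combined objective ``g - weight * f``;
    ``cost``: realized annual cost; ``seed``: the seed that produced it.
    """

    g: float
    f: float
    m: float
    cost: float
    seed: int


@dataclass(frozen=True)
class BreedingSchemeConfig:
    """Tunable parameters of the built-in progeny-testing scheme.

    ``h2`` is the baseline narrow-sense heritability (0.30); ``h2_overrides``
    lists ``(variable, value, h2)`` triples raising it when a class variable
    is active (0.32 under improved phenotyping).  ``genetic_variance`` sets
    the additive variance, so the trait is expressed in genetic-standard-
    deviation units by default.  The cow herd holds ``herd_factor`` times the
    annual daughter crop (two overlapping daughter cohorts by default) and
    ``bull_candidate_factor * x2`` bull calves are preselected on
    parent-average EBV each cycle.  ``penalty_objective`` is returned as the
    objective for structurally invalid designs (more test bulls than
    daughters) so an optimization run never crashes mid-flight.
    """

    h2: float = 0.30
    genetic_variance: float = 1.0
    burn_in_cycles: int = 5
    future_cycles: int = 10
    herd_factor: float = 2.0
    bull_candidate_factor: float = 2.0
    h2_overrides: tuple[tuple[str, Any, float], ...] = ()
    penalty_objective: float = -100.0
    roles: Mapping[str, str] = field(
        default_factory=lambda: {"daughters": "x1", "bulls": "x2", "sires": "x3"}
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ProblemConfigError("h2 must lie in [0, 1]")
        if self.burn_in_cycles < 0 or self.future_cycles < 1:
            raise ProblemConfigError("need burn_in_cycles >= 0 and future_cycles >= 1")
        if self.genetic_variance <= 0:
            raise ProblemConfigError("genetic_variance must be positive")

    @classmethod
    def from_config(cls, raw: Mapping[str, Any] | None) -> "BreedingSchemeConfig":
        raw = dict(raw or {})
        overrides = tuple(
            (o["variable"], o["value"], float(o["h2"])) for o in raw.get("h2_overrides", [])
        )
        kwargs = {}
        for key in (
            "h2",
            "genetic_variance",
            "burn_in_cycles",
            "future_cycles",
            "herd_factor",
            "bull_candidate_factor",
            "penalty_objective",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "roles" in raw:
            kwargs["roles"] = dict(raw["roles"])
        return cls(h2_overrides=overrides, **kwargs)


def _extend_kinship(K: np.ndarray, sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Append offspring of parents (rows/cols of ``K``) to a kinship matrix.

    Standard recursion: phi(o, a) = (phi(s, a) + phi(d, a)) / 2 for any older
    animal a, phi(o_i, o_j) averages the four parent kinships, and the
    self-kinship is (1 + phi(s, d)) / 2.
    """
    m = K.shape[0]
    k = len(sire)
    Ks, Kd = K[sire], K[dam]
    cross = 0.5 * (Ks + Kd)
    quad = 0.25 * (Ks[:, sire] + Ks[:, dam] + Kd[:, sire] + Kd[:, dam])
    quad[np.diag_indices(k)] = 0.5 * (1.0 + K[sire, dam])
    out = np.empty((m + k, m + k), dtype=K.dtype)
    out[:m, :m] = K
    out[m:, :m] = cross
    out[:m, m:] = cross.T
    out[m:, m:] = quad
    return out


class BreedingSimulator:
    """Evaluate designs with the built-in progeny-testing breeding scheme."""

    def __init__(self, problem: ProblemDefinition, scheme: BreedingSchemeConfig | None = None):
        self.problem = problem
        if scheme is None:
            scheme = BreedingSchemeConfig.from_config(problem.simulator_config)
        self.scheme = scheme
        idx = {}
        for role in ("daughters", "bulls", "sires"):
            name = scheme.roles.get(role)
            if name is None or name not in problem.names:
                raise ProblemConfigError(f"scheme role {role!r} maps to unknown variable {name!r}")
            idx[role] = problem.index(name)
        self._role_idx = idx

    def heritability(self, setting: Setting) -> float:
        """Effective h2 for a design, honouring class-variable overrides."""
        h2 = self.scheme.h2
        values = self.problem.as_dict(setting)
        for var, val, h2_new in self.scheme.h2_overrides:
            if values.get(var) == val:
                h2 = h2_new
        return h2

    def evaluate(self, setting: Setting, seed: int) -> SimulationOutcome:
        return self.simulate(setting, seed)

    def simulate(self, setting: Setting, seed: int, trace: list | None = None) -> SimulationOutcome:
        s = self.scheme
        x1 = int(round(float(setting[self._role_idx["daughters"]])))
        x2 = int(round(float(setting[self._role_idx["bulls"]])))
        x3 = int(round(float(setting[self._role_idx["sires"]])))
        cost = compute_cost(setting, self.problem) if self.problem.cost_model is not None else 0.0
        weight = self.problem.objective_weight
        if x1 < 1 or x2 < 1 or x3 < 1 or x2 > x1:
            logger.warning(
                "invalid design x1=%d x2=%d x3=%d: returning penalized objective", x1, x2, x3
            )
            g = s.penalty_objective
            return SimulationOutcome(g=g, f=0.0, m=objective_combine(g, 0.0, weight), cost=cost, seed=seed)
        if x3 > x2:
            logger.warning("x3=%d exceeds x2=%d; clipping the number of sires to x2", x3, x2)
            x3 = x2
        h2 = self.heritability(setting)
        rng = np.random.default_rng(seed)
        g, f = self._run(x1, x2, x3, h2, rng, trace)
        return SimulationOutcome(g=g, f=f, m=objective_combine(g, f, weight), cost=cost, seed=seed)

    def _run(
        self, x1: int, x2: int, x3: int, h2: float, rng: np.random.Generator, trace: list | None
    ) -> tuple[float, float]:
        s = self.scheme
        sa2 = s.genetic_variance
        sa = math.sqrt(sa2)
        # residual SD from h2 = sa2 / (sa2 + se2); at h2 = 0 the phenotype is
        # pure noise on an arbitrary unit scale (all EBVs vanish anyway).
        resid_sd = sa * math.sqrt((1.0 - h2) / h2) if h2 > 0 else 1.0
        cohort = max(1, int(round(s.herd_factor * x1 / 2.0)))

        # founders: x3 proven sires and two unrelated dam cohorts
        n0 = x3 + 2 * cohort
        tbv = rng.normal(0.0, sa, n0)
        phen = tbv + rng.normal(0.0, 1.0, n0) * (resid_sd if h2 > 0 else 1.0)
        ebv = np.concatenate([np.zeros(x3), h2 * (phen[x3:] - phen[x3:].mean())])
        K = 0.5 * np.eye(n0)
        sire_idx = np.arange(x3)
        young_idx = np.arange(x3, x3 + cohort)
        old_idx = np.arange(x3 + cohort, n0)

        base_mean = 0.0 if s.burn_in_cycles == 0 else None
        final_mean = 0.0
        final_f = 0.0
        n_cycles = s.burn_in_cycles + s.future_cycles
        for cycle in range(1, n_cycles + 1):
            herd = np.concatenate([young_idx, old_idx])
            # -- test bull production: sires x best cows, preselected on
            #    parent-average EBV
            ncand = max(x2, int(math.ceil(s.bull_candidate_factor * x2)))
            cs = sire_idx[rng.integers(0, len(sire_idx), ncand)]
            pool = herd[np.argsort(-ebv[herd], kind="stable")[: max(ncand, 1)]]
            if len(pool) >= ncand:
                cd = rng.permutation(pool)[:ncand]
            else:
                cd = pool[rng.integers(0, len(pool), ncand)]
            keep = np.argsort(-(0.5 * (ebv[cs] + ebv[cd])), kind="stable")[:x2]
            bs, bd = cs[keep], cd[keep]
            K = _extend_kinship(K, bs, bd)
            bull_pos = np.arange(K.shape[0] - x2, K.shape[0])
            Fs = 2.0 * K[bs, bs] - 1.0
            Fd = 2.0 * K[bd, bd] - 1.0
            msd = np.sqrt(0.5 * sa2 * (1.0 - 0.5 * (Fs + Fd)))
            bull_tbv = 0.5 * (tbv[bs] + tbv[bd]) + rng.normal(0.0, 1.0, x2) * msd
            bull_ext = np.concatenate([tbv, bull_tbv])

            # -- progeny test: balanced daughter groups of about x1/x2
            db = np.arange(x1) % x2
            if len(herd) >= x1:
                dd = rng.permutation(herd)[:x1]
            else:
                dd = herd[rng.integers(0, len(herd), x1)]
            dsire = bull_pos[db]
            Fsb = 2.0 * K[dsire, dsire] - 1.0
            Fdd = 2.0 * K[dd, dd] - 1.0
            msd_d = np.sqrt(0.5 * sa2 * (1.0 - 0.5 * (Fsb + Fdd)))
            dau_tbv = 0.5 * (bull_ext[dsire] + tbv[dd]) + rng.normal(0.0, 1.0, x1) * msd_d
            dau_F = K[dsire, dd]
            dau_phen = dau_tbv + rng.normal(0.0, 1.0, x1) * resid_sd if h2 > 0 else rng.normal(
                0.0, 1.0, x1
            )

            # -- progeny-test EBV: shrunken daughter-mean deviation
            dev = dau_phen - dau_phen.mean()
            nb = np.bincount(db, minlength=x2).astype(float)
            mean_dev = np.bincount(db, weights=dev, minlength=x2) / np.maximum(nb, 1.0)
            t = h2 / 4.0
            r2 = nb * t / (1.0 + np.maximum(nb - 1.0, 0.0) * t) if t > 0 else np.zeros(x2)
            bull_ebv = 2.0 * r2 * mean_dev
            sel = np.argsort(-bull_ebv, kind="stable")[:x3]
            dau_ebv = h2 * dev

            # -- pedigree bookkeeping for the next generation of parents:
            # assemble kinship only among animals that stay active (selected
            # sires, the retained daughter cohort and the previous cohort)
            n_keep = min(cohort, x1)
            keep_dau = np.argsort(-dau_ebv, kind="stable")[:n_keep] if n_keep < x1 else np.arange(x1)
            keep_old = np.concatenate([bull_pos[sel], young_idx])
            ds, dk = dsire[keep_dau], dd[keep_dau]
            n_old, n_new = len(keep_old), len(keep_dau)
            Kn = np.empty((n_old + n_new, n_old + n_new))
            Kn[:n_old, :n_old] = K[keep_old][:, keep_old]
            Kds, Kdk = K[ds], K[dk]
            cross = 0.5 * (Kds[:, keep_old] + Kdk[:, keep_old])
            Kn[n_old:, :n_old] = cross
            Kn[:n_old, n_old:] = cross.T
            quad = 0.25 * (Kds[:, ds] + Kds[:, dk] + Kdk[:, ds] + Kdk[:, dk])
            quad[np.diag_indices(n_new)] = 0.5 * (1.0 + K[ds, dk])
            Kn[n_old:, n_old:] = quad
            K = Kn
            nsel = len(sel)
            tbv = np.concatenate([bull_tbv[sel], tbv[young_idx], dau_tbv[keep_dau]])
            ebv = np.concatenate([bull_ebv[sel], ebv[young_idx], dau_ebv[keep_dau]])
            sire_idx = np.arange(nsel)
            old_idx = np.arange(nsel, nsel + len(young_idx))
            young_idx = np.arange(nsel + len(young_idx), len(tbv))

            cohort_mean = float(dau_tbv.mean())
            cohort_f = float(dau_F.mean())
            if trace is not None:
                trace.append({"cycle": cycle, "mean_tbv": cohort_mean, "mean_f": cohort_f})
            if cycle == s.burn_in_cycles:
                base_mean = cohort_mean
            final_mean, final_f = cohort_mean, cohort_f

        assert base_mean is not None
        g = (final_mean - base_mean) / sa
        return g, final_f


def simulate_breeding_program(
    setting: Setting,
    problem: ProblemDefinition,
    scheme: BreedingSchemeConfig | None = None,
    seed: int = 0,
) -> SimulationOutcome:
    """One-shot convenience wrapper around :class:`BreedingSimulator`."""
    return BreedingSimulator(problem, scheme).simulate(setting, seed)


# -- explicit pedigrees ------------------------------------------------------


@dataclass(frozen=True)
class PedigreeRecord:
    """One animal in an explicit pedigree; unknown parents are ``None``."""

    animal: Any
    sire: Any = None
    dam: Any = None
    birth_cycle: int = 0
    sex: str | None = None
    tbv: float | None = None
    phenotype: float | None = None


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, unknown ordering)."""


def _as_records(pedigree: Iterable) -> list[PedigreeRecord]:
    out = []
    for entry in pedigree:
        if isinstance(entry, PedigreeRecord):
            out.append(entry)
        else:
            animal, sire, dam = entry[:3]
            out.append(PedigreeRecord(animal=animal, sire=sire, dam=dam))
    return out


def pedigree_inbreeding(pedigree: Iterable) -> dict[Any, float]:
    """Inbreeding coefficients for a topologically ordered pedigree.

    ``pedigree`` is an iterable of :class:`PedigreeRecord` or
    ``(animal, sire, dam)`` triples, parents before offspring; unknown
    parents are ``None`` (or ``0``/``"0"``).  F(offspring) equals the kinship
    of its parents, computed by the classic recursion; founders get 0.
    """
    records = _as_records(pedigree)
    unknown = {None, 0, "0", ""}
    parents: dict[Any, tuple[Any, Any]] = {}
    order: dict[Any, int] = {}
    for rec in records:
        if rec.animal in parents:
            raise PedigreeError(f"duplicate animal id {rec.animal!r}")
        # 0/"0"/"" mean "unknown" only when no animal carries that id
        sire = None if (rec.sire in unknown and rec.sire not in parents) else rec.sire
        dam = None if (rec.dam in unknown and rec.dam not in parents) else rec.dam
        for p in (sire, dam):
            if p is not None and p not in parents:
                raise PedigreeError(
                    f"animal {rec.animal!r} lists parent {p!r} that does not precede it "
                    "(pedigree must be topologically ordered and acyclic)"
                )
        parents[rec.animal] = (sire, dam)
        order[rec.animal] = len(order)

    memo: dict[tuple[Any, Any], float] = {}

    def kinship(a: Any, b: Any) -> float:
        if a is None or b is None:
            return 0.0
        key = (a, b) if order[a] <= order[b] else (b, a)
        hit = memo.get(key)
        if hit is not None:
            return hit
        if a == b:
            sa_, da_ = parents[a]
            val = 0.5 * (1.0 + kinship(sa_, da_))
        else:
            # recurse on the younger animal
            if order[a] < order[b]:
                a, b = b, a
            sa_, da_ = parents[a]
            val = 0.5 * (kinship(sa_, b) + kinship(da_, b))
        memo[key] = val
        return val

    return {animal: kinship(*parents[animal]) for animal in parents}


def write_pedigree(pedigree: Iterable, path) -> None:
    """Write a 3-column plain-text pedigree (animal, sire, dam; 0 = unknown)."""
    records = _as_records(pedigree)
    with open(path, "w") as fh:
        fh.write("animal\tsire\tdam\n")
        for rec in records:
            sire = 0 if rec.sire is None else rec.sire
            dam = 0 if rec.dam is None else rec.dam
            fh.write(f"{rec.animal}\t{sire}\t{dam}\n")


def read_pedigree(path) -> list[PedigreeRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            animal, sire, dam = line.split()
            records.append(PedigreeRecord(animal=animal, sire=None if sire == "0" else sire,
                                          dam=None if dam == "0" else dam))
    return records


# -- synthetic test objectives ----------------------------------------------


class SyntheticObjective:
    """Noisy concave quadratic with a known optimum.

    ``value = peak - sum_i curvature_i * (x_i - opt_i)^2 + class bonus +
    N(0, noise_sd^2)`` over the continuous variables; class variables add a
    per-category bonus.  The evaluator is deterministic given the seed and
    reports the value as both ``g`` and ``m`` (``f = 0``).
    """

    def __init__(
        self,
        problem: ProblemDefinition,
        optimum: Mapping[str, float],
        curvature: Mapping[str, float] | float,
        peak: float = 100.0,
        noise_sd: float = 0.0,
        class_effects: Mapping[str, Mapping[Any, float]] | None = None,
    ):
        self.problem = problem
        self.peak = float(peak)
        self.noise_sd = float(noise_sd)
        self.class_effects = {k: dict(v) for k, v in (class_effects or {}).items()}
        cont = [problem.variables[i].name for i in problem.continuous_indices]
        self.optimum = {name: float(optimum[name]) for name in cont if name in optimum}
        if isinstance(curvature, Mapping):
            self.curvature = {name: float(curvature[name]) for name in self.optimum}
        else:
            self.curvature = {name: float(curvature) for name in self.optimum}
        if any(c <= 0 for c in self.curvature.values()):
            raise ValueError("curvature must be positive")

    def noiseless(self, setting: Setting) -> float:
        values = self.problem.as_dict(setting)
        total = self.peak
        for name, opt in self.optimum.items():
            total -= self.curvature[name] * (float(values[name]) - opt) ** 2
        for name, table in self.class_effects.items():
            total += float(table.get(values[name], 0.0))
        return total

    def evaluate(self, setting: Setting, seed: int) -> SimulationOutcome:
        value = self.noiseless(setting)
        if self.noise_sd > 0:
            value += float(np.random.default_rng(seed).normal(0.0, self.noise_sd))
        cost = compute_cost(setting, self.problem) if self.problem.cost_model is not None else 0.0
        return SimulationOutcome(g=value, f=0.0, m=value, cost=cost, seed=seed)


def make_test_objective(
    problem: ProblemDefinition,
    optimum: Mapping[str, float],
    curvature: Mapping[str, float] | float,
    peak: float = 100.0,
    noise_sd: float = 0.0,
    class_effects: Mapping[str, Mapping[Any, float]] | None = None,
) -> SyntheticObjective:
    """Build a noisy-quadratic evaluation contract with a known optimum."""
    return SyntheticObjective(problem, optimum, curvature, peak, noise_sd, class_effects)


def build_evaluator(problem: ProblemDefinition):
    """Instantiate the evaluator named by the problem's ``simulator:`` config block."""
    cfg = dict(problem.simulator_config or {})
    kind = cfg.get("kind", "breeding")
    if kind == "breeding":
        return BreedingSimulator(problem)
    raise ProblemConfigError(f"unknown simulator kind {kind!r}")
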