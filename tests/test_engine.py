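import numpy as np
import pytest
from scipy import stats

import breedopt as bo
from breedopt.engine import (
    AdaptiveClassRates,
    EvaluatedSetting,
    IterationSchedule,
    RateSchedule,
    ScheduleBand,
    SimulationArchive,
    carry_over_previous,
    continuous_mutation_deltas,
    draw_parent_pair,
    enforce_diversity,
    generate_offspring,
    mutate,
    recombine,
    refine,
    schedule_rates,
    select_top_by_kernel_regression,
    select_top_by_objective,
)
from breedopt.run import OptimumReport
from conftest import make_row


def rates(p_activ=0.2, pair=1.0, cls=1.0, overrides=None):
    from breedopt.engine import EffectiveRates

    return EffectiveRates(
        p_activ=p_activ, p_refine=0.3, pair_multiplier=pair, class_multiplier=cls,
        class_overrides=overrides or {},
    )


# -- archive -----------------------------------------------------------------


def test_archive_indexes_and_windows(quad_problem):
    archive = SimulationArchive()
    archive.add([make_row((i, 0, 0), m=float(i), iteration=1) for i in range(3)])
    archive.add([make_row((i, 1, 0), m=float(i), iteration=2) for i in range(2)])
    assert len(archive) == 5
    assert archive.iterations == [1, 2]
    assert len(archive.window_rows(2, 5)) == 5
    assert len(archive.window_rows(2, 1)) == 2
    with pytest.raises(ValueError):
        archive.add([make_row((0, 0, 0), m=0.0, iteration=9)])


def test_archive_csv_round_trip_is_byte_identical(tmp_path, scenario3a):
    archive = SimulationArchive()
    rng = np.random.default_rng(0)
    rows = []
    for it in (1, 2):
        for k in range(5):
            s = (int(rng.integers(1, 2000)), int(rng.integers(1, 700)), int(rng.integers(3, 30)),
                 int(rng.integers(0, 2)))
            rows.append(
                EvaluatedSetting(
                    setting=s,
                    outcome=bo.SimulationOutcome(
                        g=float(rng.normal()), f=float(rng.uniform(0, 0.2)),
                        m=float(rng.normal()), cost=float(rng.integers(10**6, 10**7)),
                        seed=int(rng.integers(0, 2**31)),
                    ),
                    iteration=it, origin="init",
                )
            )
    archive.add(rows)
    p1 = tmp_path / "a.csv"
    archive.write_csv(p1, scenario3a)
    back = SimulationArchive.read_csv(p1, scenario3a)
    p2 = tmp_path / "b.csv"
    back.write_csv(p2, scenario3a)
    assert p1.read_bytes() == p2.read_bytes()
    assert back.rows[0].setting == rows[0].setting


# -- schedules ---------------------------------------------------------------


def test_default_schedule_matches_banded_counts():
    sched = IterationSchedule.default()
    assert sched.initial_size == 600
    assert sched.band(2).select == (70, 30, 0) and sched.band(2).generate == (100, 200, 0)
    assert sched.band(7).select == (30, 15, 5) and sched.band(7).generate == (50, 170, 80)
    assert sched.band(40).select == (20, 7, 3) and sched.band(40).generate == (30, 180, 90)
    for it in range(2, 41):
        band = sched.band(it)
        assert band.generate[0] == sum(band.select)


def test_band_rejects_inconsistent_counts():
    with pytest.raises(ValueError):
        ScheduleBand(2, 3, (70, 30, 0), (99, 200, 0))


def test_scaled_schedule_keeps_consistency():
    sched = IterationSchedule.default().scaled(0.1)
    for it in (2, 5, 12):
        band = sched.band(it)
        assert band.generate[0] == sum(band.select)
        assert band.total_generated >= sum(band.select) + 1


def test_rate_schedule_decay_path():
    base = RateSchedule()
    r1 = schedule_rates(1, base)
    assert (r1.pair_multiplier, r1.class_multiplier, r1.p_activ) == (1.0, 1.0, 0.2)
    r2 = schedule_rates(2, base)
    assert (r2.pair_multiplier, r2.class_multiplier) == (0.8, 0.9)
    r5 = schedule_rates(5, base)
    assert (r5.pair_multiplier, r5.class_multiplier) == (pytest.approx(0.5), pytest.approx(0.75))
    for it in (8, 9, 20, 40):
        r = schedule_rates(it, base)
        assert (r.pair_multiplier, r.class_multiplier) == (pytest.approx(0.2), pytest.approx(0.6))


# -- selection ---------------------------------------------------------------


def test_select_top_by_objective_examples():
    rows = [make_row((i,), m=m) for i, m in enumerate([5.0, 3.0, 9.0])]
    top = select_top_by_objective(rows, 2)
    assert [r.m for r in top] == [9.0, 5.0]
    assert select_top_by_objective(rows, 3) == sorted(rows, key=lambda r: -r.m)
    with pytest.raises(ValueError):
        select_top_by_objective(rows, 4)


def test_select_top_matches_sort_oracle():
    rng = np.random.default_rng(1)
    rows = [make_row((i,), m=float(v)) for i, v in enumerate(rng.normal(size=50))]
    top = select_top_by_objective(rows, 10)
    oracle = sorted(rows, key=lambda r: -r.m)[:10]
    assert [r.setting for r in top] == [r.setting for r in oracle]


def test_kr_selection_degenerates_to_objective_for_isolated_points(quad_problem):
    # far-apart settings, each evaluated once, bandwidth << spacing:
    # every KR estimate collapses to the row's own value
    rng = np.random.default_rng(2)
    rows = [
        make_row((float(x), 0.0, 0.0), m=float(rng.normal()))
        for x in range(0, 100, 10)
    ]
    archive = SimulationArchive()
    archive.add(rows)
    h = np.array([0.01, 0.01, 0.01])
    kr = select_top_by_kernel_regression(rows, archive, 4, h, quad_problem)
    obj = select_top_by_objective(rows, 4)
    assert [r.setting for r in kr] == [r.setting for r in obj]


def test_kr_selection_estimate_equals_replicate_mean(quad_problem):
    vals = [1.0, 2.0, 3.0, 4.0, 10.0]
    rows = [make_row((50.0, 50.0, 50.0), m=v) for v in vals]
    far = make_row((0.0, 0.0, 0.0), m=0.0)
    archive = SimulationArchive()
    archive.add(rows + [far])
    from breedopt.engine import kernel_regression_values

    est = kernel_regression_values([rows[0]], archive, np.array([0.5, 0.5, 0.5]), quad_problem)
    assert est[0] == pytest.approx(np.mean(vals), abs=1e-9)


def test_kr_selection_matches_brute_force(quad_problem):
    rng = np.random.default_rng(3)
    rows = [
        make_row(tuple(float(v) for v in rng.uniform(0, 100, 3)), m=float(rng.normal()))
        for _ in range(30)
    ]
    archive = SimulationArchive()
    archive.add(rows)
    h = np.array([5.0, 8.0, 12.0])
    picked = select_top_by_kernel_regression(rows, archive, 7, h, quad_problem)

    def brute(q):
        w = [
            np.exp(-0.5 * sum(((q[j] - r.setting[j]) / h[j]) ** 2 for j in range(3)))
            for r in rows
        ]
        return sum(wi * r.m for wi, r in zip(w, rows)) / sum(w)

    est = [brute(r.setting) for r in rows]
    oracle = [rows[i] for i in sorted(range(30), key=lambda i: (-est[i], i))[:7]]
    assert [r.setting for r in picked] == [r.setting for r in oracle]


def _archive_with_iterations(n_per_iter, iterations, rng):
    archive = SimulationArchive()
    for it in range(1, iterations + 1):
        archive.add(
            [
                make_row(
                    tuple(float(v) for v in rng.uniform(0, 100, 3)),
                    m=float(rng.normal()), iteration=it,
                )
                for _ in range(n_per_iter)
            ]
        )
    return archive


def test_carry_over_empty_before_iteration_three(quad_problem):
    rng = np.random.default_rng(4)
    archive = _archive_with_iterations(10, 1, rng)
    h = np.ones(3)
    assert carry_over_previous(archive, 2, 3, h, quad_problem) == []


def test_carry_over_defaults_to_second_to_last_iteration(quad_problem):
    rng = np.random.default_rng(5)
    archive = _archive_with_iterations(10, 11, rng)
    h = np.ones(3)
    got = carry_over_previous(archive, 12, 3, h, quad_problem)
    oracle = [
        r.setting for r in sorted(archive.rows_for(10), key=lambda r: -r.m)[:3]
    ]
    assert got == oracle


def test_carry_over_substitutes_dominant_registered_optimum(quad_problem):
    rng = np.random.default_rng(6)
    archive = _archive_with_iterations(10, 5, rng)
    # an optimum registered at iteration 3, backed by a huge archive value,
    # beats everything the current (5th) iteration produced
    star = (50.0, 50.0, 50.0)
    archive.add([make_row(star, m=1000.0, iteration=3)])
    archive.register_optimum(
        OptimumReport(setting=star, kr_value=1000.0, iteration=3, density=1.0,
                      gated_out=0, n_candidates=1)
    )
    got = carry_over_previous(archive, 6, 2, np.full(3, 0.5), quad_problem)
    assert got[0] == star


def test_enforce_diversity_drops_duplicates_and_backfills(quad_problem):
    h = np.array([10.0, 10.0, 10.0])
    best = (50.0, 50.0, 50.0)
    dup = (50.0, 50.0, 50.0)
    near = (50.1, 50.2, 50.0)  # within 0.1 * h in every dimension
    far = (80.0, 10.0, 30.0)
    pool = [(10.0, 90.0, 50.0), (20.0, 20.0, 20.0)]
    kept = enforce_diversity([best, dup, near, far], pool, h, quad_problem, n=4)
    assert kept == [best, far, pool[0], pool[1]]


def test_enforce_diversity_identity_for_distant_candidates(quad_problem):
    h = np.ones(3)
    cands = [(0.0, 0.0, 0.0), (10.0, 0.0, 0.0), (0.0, 10.0, 0.0)]
    assert enforce_diversity(cands, [], h, quad_problem) == cands


def test_enforce_diversity_cluster_collapses_to_one(quad_problem):
    rng = np.random.default_rng(7)
    h = np.full(3, 10.0)
    cluster = [(50.0 + 0.01 * i, 50.0, 50.0) for i in range(5)]
    scattered = [tuple(float(v) for v in rng.uniform(0, 100, 3)) for _ in range(30)]
    kept = enforce_diversity(cluster + scattered, [], h, quad_problem, n=10)
    in_cluster = [s for s in kept if abs(s[0] - 50.0) < 1 and s[1] == 50.0 and s[2] == 50.0]
    assert len(in_cluster) <= 1
    assert len(kept) == 10


def test_class_difference_counts_as_diverse(class_problem):
    h = np.array([10.0])
    kept = enforce_diversity([(50, 0), (50, 1)], [], h, class_problem)
    assert kept == [(50, 0), (50, 1)]


# -- variation operators -----------------------------------------------------


def test_recombine_boundary_weights(quad_problem):
    rng = np.random.default_rng(8)
    x, y = (10, 40, 10), (90, 80, 90)
    assert recombine(x, y, quad_problem, rng, w=1.0)[:3] == x
    assert recombine(x, y, quad_problem, rng, w=0.0)[:3] == y
    z = recombine(x, y, quad_problem, rng, w=0.25)
    assert z[0] == 70  # 0.25*10 + 0.75*90
    # offspring stay inside the parental interval per dimension
    for _ in range(200):
        z = recombine(x, y, quad_problem, rng)
        assert all(min(a, b) <= v <= max(a, b) for v, a, b in zip(z, x, y))


def test_recombine_class_inheritance_is_balanced(class_problem):
    rng = np.random.default_rng(9)
    x, y = (10, 0), (90, 1)
    counts = [0, 0]
    for _ in range(10_000):
        counts[recombine(x, y, class_problem, rng)[1]] += 1
    assert stats.chisquare(counts).pvalue > 1e-3


def test_recombined_offspring_respect_budget(scenario1):
    rng = np.random.default_rng(10)
    pop = bo.sample_initial_population(scenario1, 20, rng=11)
    for _ in range(100):
        i, j = rng.choice(len(pop), 2, replace=False)
        z = recombine(pop[i], pop[j], scenario1, rng)
        assert bo.compute_cost(z, scenario1) <= scenario1.cost_model.budget


def test_mutation_deltas_bounded_and_uniform():
    rng = np.random.default_rng(12)
    sig = np.array([10.0])
    deltas = []
    for _ in range(10_000):
        active, t = continuous_mutation_deltas(sig, 1.0, rng)
        deltas.append(t[0])
    deltas = np.array(deltas)
    assert np.all(np.abs(deltas) <= 20.0)
    assert stats.kstest(deltas, stats.uniform(loc=-20, scale=40).cdf).pvalue > 1e-3


def test_mutate_degenerate_cases(quad_problem):
    rng = np.random.default_rng(13)
    z = (50, 60, 70)
    out, fired = mutate(z, np.zeros(3), rates(p_activ=0.0), quad_problem, rng)
    assert out == z and not fired
    out, _ = mutate(z, np.zeros(3), rates(p_activ=1.0), quad_problem, rng)
    assert out == z  # zero sigma cannot move continuous values


def test_mutate_class_rate_uses_decay_and_override(class_problem):
    rng = np.random.default_rng(14)
    r = rates(p_activ=1.0, cls=0.6, overrides={"u": 0.5})
    flips = sum(
        mutate((50, 0), np.zeros(1), r, class_problem, rng)[0][1] == 1 for _ in range(10_000)
    )
    # effective rate = 1.0 * 0.6 * 0.5 = 0.3
    assert stats.binomtest(flips, 10_000, 0.3).pvalue > 1e-3


def test_refine_always_changes_something(real_problem):
    rng = np.random.default_rng(15)
    s = (50.0, 60.0)
    for _ in range(200):
        out = refine(s, np.array([5.0, 5.0]), rates(), real_problem, rng)
        assert out != s


def test_refine_activation_matches_truncated_bernoulli(real_problem):
    rng = np.random.default_rng(16)
    s = (50.0, 60.0)
    p, d = 0.3, 2
    changed = np.zeros(d)
    n = 10_000
    for _ in range(n):
        out = refine(s, np.array([5.0, 5.0]), rates(), real_problem, rng)
        changed += [out[j] != s[j] for j in range(d)]
    expected = p / (1.0 - (1.0 - p) ** d)  # per-dim marginal given >= 1 fired
    for j in range(d):
        assert stats.binomtest(int(changed[j]), n, expected).pvalue > 1e-4


def test_refine_class_only_when_sigma_zero(class_problem):
    rng = np.random.default_rng(17)
    out = refine((50, 0), np.zeros(1), rates(), class_problem, rng)
    assert out[0] == 50 and out[1] == 1


def test_adaptive_class_rates(class_problem):
    adapt = AdaptiveClassRates(class_problem, threshold=0.8, window=5)
    balanced = [(1, 0)] * 5 + [(1, 1)] * 5
    dominated = [(1, 0)] * 10
    for it in range(1, 6):
        adapt.update(balanced, it)
    assert adapt.overrides() == {}
    for it in range(6, 11):
        adapt.update(dominated, it)
    assert adapt.overrides() == {"u": 0.5}
    # a balanced iteration restores the rate (consecutiveness required)
    adapt.update(balanced, 11)
    assert adapt.overrides() == {}
    adapt2 = AdaptiveClassRates(class_problem, threshold=0.8, window=5)
    for it in range(1, 5):
        adapt2.update([(1, 0)] * 10, it)  # share 1.0 but only 4 times
    adapt2.update(balanced, 5)
    assert adapt2.overrides() == {}


def test_mixed_class_pairing_frequency_at_floor(class_problem):
    rng = np.random.default_rng(18)
    parents = [(10, 0), (20, 0), (30, 1), (40, 1)]
    # unrestricted mixed share among unordered pairs is 4/6
    n, mixed = 20_000, 0
    for _ in range(n):
        a, b = draw_parent_pair(parents, class_problem, 0.2, rng)
        mixed += a[1] != b[1]
    assert stats.binomtest(mixed, n, (4 / 6) * 0.2).pvalue > 1e-3


def test_generate_offspring_counts_and_feasibility(scenario1):
    rng = np.random.default_rng(19)
    sched = IterationSchedule.default()
    parents = bo.sample_initial_population(scenario1, 30, rng=20)
    sigmas = np.std(scenario1.continuous_matrix(parents), axis=0, ddof=1)
    archive = SimulationArchive()
    out = generate_offspring(
        parents, archive, 12, sched, schedule_rates(12, RateSchedule()), sigmas, scenario1, rng
    )
    tags = [t for _, t in out]
    assert (tags.count("reeval"), tags.count("recombination"), tags.count("refinement")) == (30, 180, 90)
    assert len(out) == 300
    for s, _ in out:
        assert bo.compute_cost(s, scenario1) <= scenario1.cost_model.budget + 1e-6


def test_generate_offspring_band2_counts(scenario1):
    rng = np.random.default_rng(21)
    sched = IterationSchedule.default()
    parents = bo.sample_initial_population(scenario1, 100, rng=22)
    sigmas = np.std(scenario1.continuous_matrix(parents), axis=0, ddof=1)
    out = generate_offspring(
        parents, SimulationArchive(), 2, sched, schedule_rates(2, RateSchedule()), sigmas,
        scenario1, rng,
    )
    tags = [t for _, t in out]
    assert (tags.count("reeval"), tags.count("recombination"), tags.count("refinement")) == (100, 200, 0)
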