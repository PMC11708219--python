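import json
import math

import numpy as np
import pytest
from scipy import stats

import breedopt as bo
from breedopt.engine import IterationSchedule, SimulationArchive
from breedopt.run import (
    CheckpointError,
    JoblibExecutor,
    assess_termination,
    compare_optima,
    derive_optimum,
    estimate_campaign_cost,
    evaluation_seed,
    final_assessment,
    iteration_plan,
)
from conftest import make_row


@pytest.fixture
def quad_config(quad_problem, tmp_path):
    obj = bo.make_test_objective(
        quad_problem, {"a": 30, "b": 62, "c": 45}, 0.02, peak=100.0, noise_sd=10.0
    )
    return bo.RunConfig(
        problem=quad_problem,
        evaluator=obj,
        schedule=IterationSchedule.default().scaled(0.1),
        master_seed=5,
        max_iterations=10,
        final_replicates=0,
    )


# -- derive_optimum ----------------------------------------------------------


def test_derive_optimum_single_setting(quad_problem):
    archive = SimulationArchive()
    archive.add([make_row((5, 5, 5), m=float(v)) for v in (1.0, 2.0, 3.0)])
    report = derive_optimum(archive, 1, quad_problem)
    assert report.setting == (5, 5, 5)
    assert report.kr_value == pytest.approx(2.0)


def test_density_gate_removes_sparse_outlier(quad_problem):
    rng = np.random.default_rng(0)
    archive = SimulationArchive()
    cluster = [
        make_row(tuple(float(v) for v in rng.normal(50, 1.5, 3)), m=float(5 + rng.normal(0, 0.1)))
        for _ in range(40)
    ]
    outlier = make_row((95.0, 5.0, 95.0), m=50.0)  # lucky draw, far from everything
    archive.add(cluster + [outlier])
    report = derive_optimum(archive, 1, quad_problem)
    assert report.setting != outlier.setting
    assert report.gated_out >= 1
    assert np.all(np.abs(np.array(report.setting) - 50.0) < 10.0)


def test_derive_optimum_matches_brute_force(quad_problem):
    rng = np.random.default_rng(1)
    archive = SimulationArchive()
    for it in range(1, 8):  # more than the 5-iteration window
        archive.add(
            [
                make_row(tuple(float(v) for v in rng.uniform(0, 100, 3)),
                         m=float(rng.normal()), iteration=it)
                for _ in range(30)
            ]
        )
    report = derive_optimum(archive, 7, quad_problem, kde_quantile=0.2, window=5)

    # independent brute-force implementation of the whole pipeline
    rows5 = [r for r in archive.rows if r.iteration >= 3]
    X = np.array([r.setting for r in rows5], dtype=float)
    h = np.maximum(X.std(axis=0, ddof=1), 1e-8 * 100.0)
    dens = []
    for q in X:
        total = sum(
            math.prod(
                math.exp(-0.5 * ((q[j] - x[j]) / h[j]) ** 2) / math.sqrt(2 * math.pi)
                for j in range(3)
            )
            for x in X
        )
        dens.append(total / (len(X) * math.prod(h)))
    dens = np.array(dens)
    keep = dens > np.quantile(dens, 0.2)
    Xa = np.array([r.setting for r in archive.rows], dtype=float)
    ya = np.array([r.m for r in archive.rows])
    best_val, best_idx = -np.inf, None
    for i in np.flatnonzero(keep):
        w = np.exp(-0.5 * (((X[i] - Xa) / h) ** 2).sum(axis=1))
        est = (w @ ya) / w.sum()
        if est > best_val:
            best_val, best_idx = est, i
    assert report.setting == tuple(X[best_idx])
    assert report.kr_value == pytest.approx(best_val, abs=1e-9)
    assert report.gated_out == int((~keep).sum())


# -- termination, assessment, comparisons ------------------------------------


def test_assess_termination_paths():
    assert not assess_termination([1, 2, 3], window=10, threshold=1e-6).stop
    rising = list(range(15))
    assert not assess_termination(rising, window=10, threshold=0.5).stop
    flat = [5.0] * 12
    decision = assess_termination(flat, window=10, threshold=1e-6)
    assert decision.stop and decision.improvement == 0.0
    # disabled without a threshold
    assert not assess_termination(flat, window=10, threshold=None).stop


def test_final_assessment_statistics(quad_problem):
    noiseless = bo.make_test_objective(quad_problem, {"a": 30, "b": 62, "c": 45}, 0.02)
    out = final_assessment((30, 62, 45), noiseless, n_replicates=100, seed=1)
    assert out["n"] == 100
    assert out["m"]["sd"] == 0.0
    assert out["m"]["mean"] == pytest.approx(100.0)
    noisy = bo.make_test_objective(quad_problem, {"a": 30}, 0.02, noise_sd=2.0)
    out = final_assessment((30, 62, 45), noisy, n_replicates=50, seed=2)
    vals = out["replicates"]["m"]
    assert out["m"]["mean"] == pytest.approx(np.mean(vals), abs=1e-12)
    assert len(vals) == 50


def test_compare_optima_conventions_and_oracle():
    a = [1.0, 2.0, 3.0, 4.0]
    same = compare_optima(a, a)
    assert same.statistic == pytest.approx(0.0) and same.pvalue == pytest.approx(1.0)
    shifted = compare_optima([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
    assert shifted.degenerate and shifted.pvalue == 0.0
    rng = np.random.default_rng(3)
    x, y = rng.normal(0, 1, 30), rng.normal(0.5, 2, 20)
    res = compare_optima(x, y)
    # textbook Welch formulas
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    t = (x.mean() - y.mean()) / math.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
    p = 2 * stats.t.sf(abs(t), df)
    assert res.statistic == pytest.approx(t, abs=1e-10)
    assert res.df == pytest.approx(df, abs=1e-8)
    assert res.pvalue == pytest.approx(p, abs=1e-10)


def test_iteration_plan_matches_banded_schedule():
    plan = iteration_plan(IterationSchedule.default(), 40)
    assert plan[0] == 600
    assert plan[1] == 900
    assert plan[6] == 2400
    assert plan[39] == 12300


def test_estimate_campaign_cost():
    assert estimate_campaign_cost(12_300, 0.0055) == 67.65
    assert estimate_campaign_cost(0, 0.0055) == 0.0
    assert estimate_campaign_cost(1000, 0.01) == 10.00


# -- the loop ----------------------------------------------------------------


def test_evaluation_seed_is_pure_and_bounded():
    assert evaluation_seed(1, 2, 3) == evaluation_seed(1, 2, 3)
    assert evaluation_seed(1, 2, 3) != evaluation_seed(1, 2, 4)
    assert 0 <= evaluation_seed(123, 40, 599) < 2**31


def test_run_is_deterministic_and_registers_every_iteration(quad_config, quad_problem):
    res1 = bo.run_optimization(quad_config)
    res2 = bo.run_optimization(quad_config)
    assert res1.archive.to_csv_text(quad_problem) == res2.archive.to_csv_text(quad_problem)
    assert sorted(res1.archive.optima) == list(range(1, 11))
    assert res1.report.setting == res2.report.setting


def test_parallel_execution_matches_serial(quad_config, quad_problem):
    serial = bo.run_optimization(quad_config)
    parallel = bo.run_optimization(quad_config, executor=JoblibExecutor(2, prefer="threads"))
    assert serial.archive.to_csv_text(quad_problem) == parallel.archive.to_csv_text(quad_problem)


def test_resume_reproduces_uninterrupted_run(quad_config, quad_problem, tmp_path):
    import dataclasses

    full = dataclasses.replace(quad_config, outdir=tmp_path / "full")
    res_full = bo.run_optimization(full)

    part = dataclasses.replace(quad_config, outdir=tmp_path / "part", max_iterations=4)
    bo.run_optimization(part)
    resumed_cfg = dataclasses.replace(quad_config, outdir=tmp_path / "part", max_iterations=10)
    res_resumed = bo.resume_optimization(resumed_cfg)

    a = (tmp_path / "full" / "archive.csv").read_bytes()
    b = (tmp_path / "part" / "archive.csv").read_bytes()
    assert a == b
    assert res_full.report.setting == res_resumed.report.setting


def test_corrupted_checkpoint_refuses_resume(quad_config, tmp_path):
    import dataclasses

    cfg = dataclasses.replace(quad_config, outdir=tmp_path / "run", max_iterations=3)
    bo.run_optimization(cfg)
    (tmp_path / "run" / "run_state.json").write_text("{ not json")
    with pytest.raises(CheckpointError):
        bo.resume_optimization(dataclasses.replace(cfg, max_iterations=5))
    with pytest.raises(CheckpointError):
        bo.resume_optimization(dataclasses.replace(cfg, outdir=tmp_path / "missing"))


def test_termination_stops_early(quad_problem):
    # zero noise: the optimum stabilizes almost immediately
    obj = bo.make_test_objective(quad_problem, {"a": 30, "b": 62, "c": 45}, 0.02)
    cfg = bo.RunConfig(
        problem=quad_problem,
        evaluator=obj,
        schedule=IterationSchedule.default().scaled(0.1),
        master_seed=6,
        max_iterations=40,
        termination_window=10,
        termination_threshold=1e-3,
        final_replicates=0,
    )
    res = bo.run_optimization(cfg)
    assert res.archive.max_iteration < 40


def test_run_writes_outputs(quad_config, quad_problem, tmp_path):
    import dataclasses

    cfg = dataclasses.replace(
        quad_config, outdir=tmp_path / "out", max_iterations=3, final_replicates=10
    )
    res = bo.run_optimization(cfg)
    outdir = tmp_path / "out"
    assert (outdir / "archive.csv").exists()
    assert (outdir / "optima.csv").exists()
    report = json.loads((outdir / "optimum.json").read_text())
    assert report["iteration"] == 3
    assert res.report.assessment["n"] == 10
    back = SimulationArchive.read_csv(outdir / "archive.csv", quad_problem)
    assert len(back) == len(res.archive)
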