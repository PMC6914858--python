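"""Sequential forward selection, the RII stopping rule, and the GA wrapper."""

import numpy as np
import pytest

from fmg_chansel import GAConfig, ga_repeat, ga_select, rii_threshold, sfs_run
from fmg_chansel.classification import fit_count, loocv_error, reset_fit_counter
from conftest import make_gesture_coded_dataset
from oracles import exhaustive_best_subsets, sfs_bruteforce

FAST_GA = GAConfig(population_size=30, stall_generations=15, max_generations=60,
                   function_tolerance=1e-6, n_restarts=10, seed=0)


def test_rii_threshold_worked_values():
    # old_crit = 0: sqrt(eps) * tol = sqrt(2.2204e-16) * 1e-6
    assert rii_threshold(0.0) == pytest.approx(1.49011e-14, rel=1e-4)
    assert rii_threshold(0.2) == pytest.approx(2.0000e-7, rel=1e-3)
    # alternative quadratic reading is exposed but off by default
    assert rii_threshold(0.2, quadratic=True) == pytest.approx(0.2 * 2.0000e-7, rel=1e-3)


def test_rii_threshold_rejects_nonfinite():
    with pytest.raises(ValueError):
        rii_threshold(float("nan"))


def test_sfs_starts_with_perfectly_separating_channel(separable_toy):
    trace = sfs_run(separable_toy, reps=[1, 2, 3, 4], stop="rii")
    assert trace.order[0] == 2
    # once error is ~0 no further addition can clear the RII threshold
    assert len(trace.order) <= 2


def test_sfs_full_ranking_orders_all_channels(tiny_synth):
    ds, _ = tiny_synth
    trace = sfs_run(ds, reps=[1, 2, 3], stop="full_ranking")
    assert len(trace.order) == ds.n_channels
    assert sorted(trace.order) == list(range(ds.n_channels))
    assert trace.stopped_at is None


def test_sfs_trace_matches_bruteforce_oracle(tiny_synth):
    ds, _ = tiny_synth
    reps = [1, 2, 3, 4]
    trace = sfs_run(ds, reps=reps, stop="full_ranking")
    order, path = sfs_bruteforce(ds, reps)
    assert list(trace.order) == order
    np.testing.assert_allclose(trace.criterion_path, path, atol=1e-12)


def test_sfs_rii_path_strictly_improving(small_synth):
    ds, _ = small_synth
    trace = sfs_run(ds, reps=[1, 2, 3, 4], stop="rii")
    path = np.array(trace.criterion_path)
    assert np.all(np.diff(path) < 0)  # each accepted addition improved
    assert trace.stopped_at == len(trace.order)


def test_sfs_fit_count_formula(tiny_synth):
    """Full ranking costs folds * n(n+1)/2 classifier fits."""
    ds, _ = tiny_synth
    reps = [1, 2, 3]
    reset_fit_counter()
    sfs_run(ds, reps=reps, stop="full_ranking")
    n = ds.n_channels
    assert fit_count() == len(reps) * n * (n + 1) // 2


def test_ga_deterministic_under_seed(tiny_synth):
    ds, _ = tiny_synth
    cfg = GAConfig(population_size=12, stall_generations=5, max_generations=15, seed=3)
    s1, h1 = ga_select(ds, [1, 2, 3], cfg)
    s2, h2 = ga_select(ds, [1, 2, 3], cfg)
    assert s1.indices == s2.indices
    assert h1 == h2


def test_ga_best_fitness_non_increasing(tiny_synth):
    ds, _ = tiny_synth
    cfg = GAConfig(population_size=15, stall_generations=8, max_generations=30, seed=1)
    _, history = ga_select(ds, [1, 2, 3, 4], cfg)
    assert all(b <= a + 1e-12 for a, b in zip(history, history[1:]))


def test_ga_finds_exhaustive_optimum_on_8_channels():
    """255-subset exhaustive oracle; GA reaches the optimum in >= 8/10 seeds."""
    ds = make_gesture_coded_dataset(
        8, {1: 2.0, 5: 1.2}, noise=0.6, samples_per_gesture=15, seed=6
    )
    reps = [1, 2, 3, 4]
    best_err, _ = exhaustive_best_subsets(ds, reps)
    hits = 0
    for i in range(10):
        cfg = GAConfig(population_size=30, stall_generations=15, max_generations=60,
                       seed=100 + i)
        subset, history = ga_select(ds, reps, cfg)
        if history[-1] <= best_err + 1e-12:
            hits += 1
    assert hits >= 8


def test_ga_recovers_planted_channels_among_noise():
    # jointly (not individually) separating pair: one channel codes the
    # gesture index mod 3, the other its integer third
    ds = make_gesture_coded_dataset(
        20, {4: lambda gi: 3.0 * (gi % 3), 13: lambda gi: 3.0 * (gi // 3)},
        noise=0.4, samples_per_gesture=12, seed=8,
    )
    found = 0
    for i in range(10):
        cfg = GAConfig(population_size=30, stall_generations=10, max_generations=40,
                       seed=200 + i)
        subset, _ = ga_select(ds, [1, 2, 3, 4], cfg)
        if {4, 13} <= set(subset.indices):
            found += 1
    assert found >= 8


def test_ga_repeat_aggregates_restarts(tiny_synth):
    ds, _ = tiny_synth
    cfg = GAConfig(population_size=10, stall_generations=4, max_generations=10,
                   n_restarts=4, seed=5)
    summary = ga_repeat(ds, [1, 2, 3], cfg)
    assert len(summary.sizes) == 4
    assert summary.format_size() == f"{summary.mean_size:.1f} ± {summary.sd_size:.1f}"
    if len(set(summary.sizes)) == 1:
        assert summary.sd_size == 0.0


def test_ga_config_validation():
    with pytest.raises(ValueError):
        GAConfig(elite_count=50, population_size=50)
    with pytest.raises(ValueError):
        GAConfig(function_tolerance=0.0)
    with pytest.raises(ValueError):
        GAConfig(mutation_rate=1.5)
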