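"""Genetic feature selection: operators, fitness arithmetic, invariants."""

import numpy as np
import pandas as pd
import pytest

import harkit as hk
from harkit.gfsfan import (
    GAConfig,
    Individual,
    WrapperFitness,
    adaptive_probability,
    cofan,
    fitness_from_fm,
    init_individual,
    mofan,
    selection_probabilities,
)


# ---------------------------------------------------------------------------
# selection probabilities and initialization


def test_selection_probabilities_arithmetic_sequence():
    np.testing.assert_allclose(selection_probabilities(3), [0.8, 0.6, 0.4])
    np.testing.assert_allclose(selection_probabilities(2), [0.8, 0.4])
    np.testing.assert_allclose(selection_probabilities(1), [0.8])
    sp = selection_probabilities(100)
    assert np.all(np.diff(sp) < 0)
    assert np.all((sp >= 0.4) & (sp <= 0.8))


def test_init_all_bits_when_ninit_equals_m():
    rng = np.random.default_rng(0)
    ind = init_individual(np.full(6, 0.5), 6, rng)
    assert ind.popcount == 6


def test_init_equal_sp_uniform_over_subsets():
    """With equal SPs the weighted draw reduces to uniform subsets."""
    from itertools import combinations
    from scipy.stats import chisquare

    rng = np.random.default_rng(1)
    m, ninit, draws = 5, 2, 10_000
    subsets = {c: 0 for c in combinations(range(m), ninit)}
    for _ in range(draws):
        ind = init_individual(np.full(m, 0.6), ninit, rng)
        subsets[tuple(ind.active())] += 1
    _, p = chisquare(list(subsets.values()))
    assert p > 0.01


def test_init_prefers_high_sp_feature():
    """SP 0.8 vs 0.4, pick 1 of 2: P(u1^(1/0.8) > u2^(1/0.4)) by Monte Carlo."""
    rng = np.random.default_rng(2)
    n = 50_000
    u = rng.random((n, 2))
    expected = np.mean(u[:, 0] ** 1.25 > u[:, 1] ** 2.5)
    rng2 = np.random.default_rng(3)
    hits = sum(
        init_individual(np.array([0.8, 0.4]), 1, rng2).mask[0] for _ in range(n)
    )
    assert abs(hits / n - expected) < 0.01
    assert 0.6 < hits / n < 0.72  # around 2/3


# ---------------------------------------------------------------------------
# fitness arithmetic


def test_fitness_formula_values():
    np.testing.assert_allclose(fitness_from_fm(1.0, 1.0), 1.1 * np.e)
    np.testing.assert_allclose(
        fitness_from_fm(0.9, 0.8), np.exp(0.9) + 0.1 * np.exp(0.8)
    )


def test_wrapper_fitness_perfect_separation():
    rng = np.random.default_rng(4)
    X = np.vstack([rng.normal(0, 0.1, (30, 2)), rng.normal(10, 0.1, (30, 2))])
    table = hk.FeatureTable(
        X=pd.DataFrame(X, columns=["a", "b"]),
        labels=np.array(["u"] * 30 + ["v"] * 30),
    )
    ev = WrapperFitness([table], seed=0)
    f, fm_all, fm_min = ev(np.array([True, True]))
    assert fm_all == fm_min == 1.0
    np.testing.assert_allclose(f, 1.1 * np.e)


def test_adaptive_probability_branches():
    crange = (0.4, 0.8)
    assert adaptive_probability(0.5, 1.0, 2.0, crange) == 0.8  # below mean
    assert adaptive_probability(2.0, 1.0, 2.0, crange) == 0.4  # at max
    assert adaptive_probability(1.0, 1.0, 2.0, crange) == 0.8  # at mean
    assert adaptive_probability(1.0, 1.0, 1.0, crange) == 0.4  # degenerate


# ---------------------------------------------------------------------------
# operators


def _ind(active, m=8):
    mask = np.zeros(m, dtype=bool)
    mask[list(active)] = True
    return Individual(mask=mask)


def test_cofan_keeps_shared_and_stays_in_union():
    rng = np.random.default_rng(5)
    for _ in range(200):
        c1, c2 = cofan(_ind({1, 2, 3}), _ind({2, 3, 4}), rng)
        for c in (c1, c2):
            active = set(c.active())
            assert {2, 3} <= active <= {1, 2, 3, 4}
            assert c.popcount == 3


def test_cofan_identical_parents_identity():
    rng = np.random.default_rng(6)
    p = _ind({0, 3, 5})
    c1, c2 = cofan(p, p, rng)
    np.testing.assert_array_equal(c1.mask, p.mask)
    np.testing.assert_array_equal(c2.mask, p.mask)


def test_cofan_disjoint_parents_mix_within_union():
    rng = np.random.default_rng(7)
    p1, p2 = _ind({0, 1, 2}), _ind({5, 6, 7})
    for _ in range(100):
        c1, c2 = cofan(p1, p2, rng)
        union = {0, 1, 2, 5, 6, 7}
        assert set(c1.active()) <= union and set(c2.active()) <= union
        assert c1.popcount == c2.popcount == 3


def test_mofan_zero_probability_identity():
    rng = np.random.default_rng(8)
    p = _ind({1, 4, 6})
    child = mofan(p, 0.0, rng)
    np.testing.assert_array_equal(child.mask, p.mask)


def test_mofan_full_probability_migrates_all_bits():
    rng = np.random.default_rng(9)
    p = _ind({0, 1, 2}, m=8)  # m >= 2 * ninit
    child = mofan(p, 1.0, rng)
    assert child.popcount == 3
    assert not (set(child.active()) & {0, 1, 2})


def test_operator_popcount_invariant_sweep():
    """popcount == ninit after thousands of random operator applications."""
    rng = np.random.default_rng(10)
    m, ninit = 40, 7
    sp = selection_probabilities(m)
    for _ in range(2000):
        p1 = init_individual(sp, ninit, rng)
        p2 = init_individual(sp, ninit, rng)
        c1, c2 = cofan(p1, p2, rng)
        c1 = mofan(c1, 0.4, rng)
        c2 = mofan(c2, 0.4, rng)
        assert c1.popcount == ninit and c2.popcount == ninit
        # no invented bits: every active child bit came from a parent or
        # was explicitly migrated in by mutation (which may pick any bit),
        # so check the pre-mutation children only
        pre1, pre2 = cofan(p1, p2, rng)
        union = set(p1.active()) | set(p2.active())
        assert set(pre1.active()) <= union and set(pre2.active()) <= union


# ---------------------------------------------------------------------------
# full run


def _small_table(seed=0):
    spec = hk.SyntheticFeatureSpec(
        n_features=12, n_informative=2, n_classes=2, gap=4.0,
        samples_per_class=(30, 30), seed=seed,
    )
    table, truth = hk.generate_feature_table(spec)
    return table, truth


def test_ninit_equals_m_returns_all_features():
    table, _ = _small_table()
    cfg = GAConfig(ninit=12, population=10, max_iterations=3, seed=0)
    res = hk.run_gfsfan(table, cfg)
    assert res.selected == table.feature_names
    assert len(res.history_best) == 1


def test_best_fitness_monotone_under_elitism():
    table, _ = _small_table(1)
    cfg = GAConfig(ninit=3, population=12, max_iterations=8, seed=1)
    res = hk.run_gfsfan(table, cfg)
    assert np.all(np.diff(res.history_best) >= -1e-12)


def test_run_deterministic_under_seed():
    table, _ = _small_table(2)
    cfg = GAConfig(ninit=3, population=10, max_iterations=5, seed=42)
    r1 = hk.run_gfsfan(table, cfg)
    r2 = hk.run_gfsfan(table, cfg)
    assert r1.selected == r2.selected
    assert r1.history_best == r2.history_best


def test_ninit_larger_than_m_rejected():
    table, _ = _small_table()
    with pytest.raises(ValueError, match="ninit"):
        hk.run_gfsfan(table, GAConfig(ninit=13, population=4, max_iterations=1))


def test_selected_subset_beats_random_subsets_on_fi():
    """The chosen subset's summed Fisher Index should exceed nearly all
    random subsets of the same size."""
    table, truth = _small_table(3)
    cfg = GAConfig(ninit=3, population=16, max_iterations=10, seed=3)
    res = hk.run_gfsfan(table, cfg)
    rep = hk.fisher_index(table)
    chosen_sfi = hk.sfi(rep, res.selected)
    rng = np.random.default_rng(4)
    names = table.feature_names
    draws = [
        hk.sfi(rep, [names[j] for j in rng.choice(len(names), 3, replace=False)])
        for _ in range(1000)
    ]
    assert chosen_sfi >= np.quantile(draws, 0.99)
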