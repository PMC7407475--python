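import itertools

import numpy as np
import pytest

from oracles import fscore_oracle, merit_of, mvt_oracle, scoping_oracle, vanraden_oracle
from scopesim import (
    Couple,
    fscore,
    mvt_criterion,
    mvt_select,
    pm_select,
    population_merit,
    random_mating,
    scoping_select,
    truncation_select,
    vanraden_G,
)


# ---------------------------------------------------------------------------
# Truncation + random mating
# ---------------------------------------------------------------------------


def test_truncation_examples_and_oracle(rng):
    assert list(truncation_select(np.array([3.0, 1.0, 2.0]), 2)) == [0, 2]
    assert set(truncation_select(np.array([3.0, 1.0, 2.0]), 3)) == {0, 1, 2}
    g = rng.normal(size=1000)
    sel = truncation_select(g, 100)
    assert set(sel) == set(np.argsort(g)[-100:])
    with pytest.raises(ValueError):
        truncation_select(g, 1001)


def test_random_mating_covers_all_parents(rng):
    couples = random_mating(np.arange(100), rng)
    used = [p for c in couples for p in (c.p1, c.p2)]
    assert len(couples) == 50
    assert sorted(used) == list(range(100))
    with pytest.raises(ValueError):
        random_mating(np.arange(5), rng)


def test_random_mating_uniform_over_matchings(rng):
    counts = {}
    for _ in range(10_000):
        cs = random_mating(np.arange(4), rng)
        key = frozenset(frozenset((c.p1, c.p2)) for c in cs)
        counts[key] = counts.get(key, 0) + 1
    assert len(counts) == 3
    for v in counts.values():
        se = np.sqrt((1 / 3) * (2 / 3) / 10_000)
        assert abs(v / 10_000 - 1 / 3) < 4 * se


# ---------------------------------------------------------------------------
# fscore / scoping
# ---------------------------------------------------------------------------


def test_fscore_hand_cases():
    assert fscore(np.array([[1.0], [-1.0]]), np.array([1.0])) == pytest.approx(2.0)
    assert fscore(np.array([[1.0, 0, 1], [1.0, 0, 1]]), np.ones(3)) == 0.0
    Z = np.array([[1.0, 0.0, 1.0], [-1.0, 0.0, 1.0]])
    assert fscore(Z, np.array([1.0, 1.0, 0.0])) == pytest.approx(2.0)
    assert fscore(np.array([[1.0, 2.0]]), np.ones(2)) == 0.0  # single row


@pytest.mark.parametrize("seed", range(5))
def test_fscore_matches_oracle(seed):
    rng = np.random.default_rng(seed)
    Z = rng.choice([-1.0, 0.0, 1.0], size=(6, 9))
    p = rng.integers(0, 2, 9).astype(float)
    assert fscore(Z, p) == pytest.approx(fscore_oracle(Z, p), abs=1e-10)


def test_scoping_boundary_equals_truncation(rng):
    n, k = 20, 8
    g = rng.normal(size=n)
    Z = rng.choice([-1.0, 1.0], size=(n, k))
    couples = scoping_select(g, Z, SR=0.2, n_couples=2)  # ceil(0.2*20)=4=2*2
    used = {p for c in couples for p in (c.p1, c.p2)}
    assert used == set(truncation_select(g, 4))


@pytest.mark.parametrize("seed", range(8))
def test_scoping_matches_stepwise_oracle(seed):
    rng = np.random.default_rng(100 + seed)
    n, k = 6, 4
    g = rng.normal(size=n)
    Z = rng.choice([-1.0, 0.0, 1.0], size=(n, k))
    got = [(c.p1, c.p2) for c in scoping_select(g, Z, SR=1.0, n_couples=2)]
    assert got == scoping_oracle(g, Z, 1.0, 2)


def test_scoping_identical_candidates_fall_back_to_gebv(rng):
    n, k = 8, 5
    g = np.arange(n, 0, -1.0)
    Z = np.tile(np.array([1.0, -1.0, 1.0, -1.0, 1.0]), (n, 1))
    couples = scoping_select(g, Z, SR=1.0, n_couples=2)
    # clones have zero variance everywhere; P2 falls back to highest GEBV
    assert [(c.p1, c.p2) for c in couples] == [(0, 1), (2, 3)]


def test_scoping_rejects_bad_rates(rng):
    g = rng.normal(size=20)
    Z = rng.choice([-1.0, 1.0], size=(20, 4))
    with pytest.raises(ValueError):
        scoping_select(g, Z, SR=0.05, n_couples=2)
    with pytest.raises(ValueError):
        scoping_select(g, Z, SR=0.1, n_couples=1000)


# ---------------------------------------------------------------------------
# VanRaden G
# ---------------------------------------------------------------------------


def test_vanraden_hand_cases():
    Z = np.array([[1.0, 1.0], [-1.0, -1.0]])  # opposite inbreds, P = (0.5, 0.5)
    G = vanraden_G(Z).G
    assert np.allclose(G, [[2.0, -2.0], [-2.0, 2.0]])
    assert G[0, 0] - 1 == pytest.approx(1.0)  # inbreeding coefficient of an inbred
    with pytest.raises(ValueError, match="monomorphic"):
        vanraden_G(np.ones((3, 4)))


@pytest.mark.parametrize("seed", range(5))
def test_vanraden_matches_oracle(seed):
    rng = np.random.default_rng(200 + seed)
    Z = rng.choice([-1.0, 0.0, 1.0], size=(7, 11))
    src = rng.choice([-1.0, 0.0, 1.0], size=(9, 11))
    got = vanraden_G(Z, src).G
    assert np.allclose(got, vanraden_oracle(Z, src), atol=1e-10)


# ---------------------------------------------------------------------------
# Population merit
# ---------------------------------------------------------------------------


def test_population_merit_arithmetic():
    assert population_merit(1.0, 20.0, 0.02) == pytest.approx(0.6)
    assert population_merit(0.7, 0.0, 0.5) == 0.7
    assert population_merit(0.7, 50.0, 0.0) == 0.7


def test_pm_select_c0_is_truncation(rng):
    n = 30
    g = rng.normal(size=n)
    Z = rng.choice([-1.0, 1.0], size=(n, 10))
    couples = pm_select(g, Z, rng, c=0.0, n=10)
    used = {p for c in couples for p in (c.p1, c.p2)}
    assert used == set(truncation_select(g, 10))


@pytest.mark.parametrize("seed", range(6))
def test_pm_select_is_single_swap_optimal(seed):
    rng = np.random.default_rng(300 + seed)
    n_pop, n, c = 8, 4, 5.0
    g = rng.normal(size=n_pop)
    Z = rng.choice([-1.0, 1.0], size=(n_pop, 12))
    G = vanraden_G(Z).G
    couples = pm_select(g, Z, rng, c=c, n=n)
    sel = {p for cp in couples for p in (cp.p1, cp.p2)}
    B = merit_of(sel, g, G, c)
    for p in sel:
        for q in set(range(n_pop)) - sel:
            neighbor = (sel - {p}) | {q}
            assert merit_of(neighbor, g, G, c) <= B + 1e-9


def test_pm_select_large_penalty_avoids_clones(rng):
    # two identical top lines; huge c must forbid co-selecting the clone pair
    base = rng.choice([-1.0, 1.0], size=(10, 20))
    base[1] = base[0]
    g = np.concatenate([[10.0, 9.9], rng.normal(size=8)])
    couples = pm_select(g, base, rng, c=1e4, n=4)
    sel = {p for cp in couples for p in (cp.p1, cp.p2)}
    assert not {0, 1} <= sel


# ---------------------------------------------------------------------------
# MVT
# ---------------------------------------------------------------------------


def test_mvt_criterion_hand_cases():
    assert mvt_criterion(np.array([[2.0, -2.0], [-2.0, 2.0]])) == pytest.approx(6.0)
    assert mvt_criterion(np.array([[2.0, 2.0], [2.0, 2.0]])) == pytest.approx(-2.0)
    with pytest.raises(ValueError):
        mvt_criterion(np.array([[2.0]]))


@pytest.mark.parametrize("seed", range(5))
def test_mvt_criterion_matches_oracle(seed):
    rng = np.random.default_rng(400 + seed)
    Z = rng.choice([-1.0, 1.0], size=(6, 15))
    G = vanraden_G(Z).G
    idx = rng.choice(6, 4, replace=False)
    sub = G[np.ix_(idx, idx)]
    assert mvt_criterion(sub) == pytest.approx(mvt_oracle(sub), abs=1e-10)


def test_mvt_pre_n_equals_n_is_truncation(rng):
    n_pop, n = 20, 4
    g = rng.normal(size=n_pop)
    Z = rng.choice([-1.0, 1.0], size=(n_pop, 8))
    couples = mvt_select(g, Z, rng, pre_n=n, n=n)
    used = {p for c in couples for p in (c.p1, c.p2)}
    assert used == set(truncation_select(g, n))
    # P1 half is the GEBV top half
    p1s = {c.p1 for c in couples}
    assert p1s == set(truncation_select(g, n // 2))


@pytest.mark.parametrize("seed", range(6))
def test_mvt_select_is_single_replacement_optimal(seed):
    rng = np.random.default_rng(500 + seed)
    n_pop, pre_n, n = 12, 8, 4
    g = rng.normal(size=n_pop)
    Z = rng.choice([-1.0, 1.0], size=(n_pop, 14))
    G = vanraden_G(Z).G
    couples = mvt_select(g, Z, rng, pre_n=pre_n, n=n)
    p1 = [c.p1 for c in couples]
    p2 = [c.p2 for c in couples]
    assert set(p1) == set(truncation_select(g, n // 2))  # P1 fixed by GEBV
    pre = set(truncation_select(g, pre_n))
    pool = pre - set(p1) - set(p2)
    sel = np.array(p1 + p2)
    crit = mvt_criterion(G[np.ix_(sel, sel)])
    for i, pc in enumerate(p2):
        for q in pool:
            alt = np.array(p1 + p2[:i] + [q] + p2[i + 1 :])
            assert mvt_criterion(G[np.ix_(alt, alt)]) <= crit + 1e-9


def test_mvt_avoids_cloning_p1(rng):
    # pool contains an exact clone of a P1 parent among unrelated lines
    Z = rng.choice([-1.0, 1.0], size=(8, 30))
    Z[4] = Z[0]  # clone of the future top-GEBV parent
    g = np.array([10.0, 9.0, 8.0, 7.0, 1.0, 0.9, 0.8, 0.7])
    couples = mvt_select(g, Z, rng, pre_n=8, n=4)
    p2 = {c.p2 for c in couples}
    assert 4 not in p2  # the clone never enters while alternatives improve


# ---------------------------------------------------------------------------
# Cross-strategy invariants
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("seed", range(3))
def test_all_strategies_return_distinct_parent_couples(seed):
    rng = np.random.default_rng(600 + seed)
    n_pop, n_couples = 60, 10
    g = rng.normal(size=n_pop)
    Z = rng.choice([-1.0, 0.0, 1.0], size=(n_pop, 25))
    blocks = {
        "baseline": random_mating(truncation_select(g, 2 * n_couples), rng),
        "scoping": scoping_select(g, Z, SR=0.5, n_couples=n_couples),
        "pm": pm_select(g, Z, rng, c=2.0, n=2 * n_couples),
        "mvt": mvt_select(g, Z, rng, pre_n=40, n=2 * n_couples),
    }
    for name, couples in blocks.items():
        used = [p for c in couples for p in (c.p1, c.p2)]
        assert len(couples) == n_couples, name
        assert len(set(used)) == 2 * n_couples, name


def test_couple_rejects_selfing():
    with pytest.raises(ValueError):
        Couple(3, 3)
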