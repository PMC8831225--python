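"""Exact contingency tests, Markov-chain agreement, p-value combination."""

import numpy as np
import pytest
from scipy import stats

from colonykin.datatypes import Individual
from colonykin.differentiation import (combine_fisher, combine_stouffer,
                                       count_tables, exact_table_test,
                                       genotypic_exact_test,
                                       satellite_merge_test)
from colonykin.datatypes import ColonyMeta, GenotypeDataset, MarkerPanel
from colonykin.simulate import SimConfig, simulate_dataset
from conftest import make_dataset
from oracles import exact_prob_test_2x2


def test_balanced_identical_distributions_give_p_one():
    tab = np.array([[5, 5], [5, 5]])
    res = exact_table_test(tab)
    assert res.p > 0.99
    assert res.method == "enumeration"


def test_disjoint_2x2_matches_enumeration_oracle():
    tab = np.array([[5, 0], [0, 5]])
    res = exact_table_test(tab)
    assert res.p == pytest.approx(2 / 252)
    assert res.p == pytest.approx(stats.fisher_exact(tab)[1])


@pytest.mark.parametrize("seed", range(8))
def test_enumeration_matches_independent_2x2_oracle(seed):
    rng = np.random.default_rng(seed)
    tab = rng.integers(0, 8, size=(2, 2))
    if tab.sum(axis=0).min() == 0 or tab.sum(axis=1).min() == 0:
        tab = tab + 1
    ours = exact_table_test(tab).p
    assert ours == pytest.approx(exact_prob_test_2x2(tab), abs=1e-12)
    assert ours == pytest.approx(stats.fisher_exact(tab)[1], abs=1e-9)


def test_mcmc_agrees_with_enumeration_on_small_tables():
    """Chain p within 3 Monte-Carlo SEs of the exhaustive value."""
    rng = np.random.default_rng(14)
    done = 0
    while done < 6:
        shape = (int(rng.integers(2, 4)), int(rng.integers(2, 4)))
        tab = rng.integers(0, 7, size=shape)
        if tab.sum(axis=0).min() == 0 or tab.sum(axis=1).min() == 0:
            continue
        if count_tables(tab.sum(axis=1), tab.sum(axis=0), cap=10 ** 4) > 10 ** 4:
            continue
        enum = exact_table_test(tab)
        mc = exact_table_test(tab, seed=done, enumeration_limit=1,
                              dememorization=5_000, batches=40, batch_size=2_000)
        assert mc.method == "mcmc" and mc.mc_se >= 0
        assert abs(mc.p - enum.p) < 3 * mc.mc_se + 1e-9
        done += 1


def test_fisher_combination_closed_forms():
    res = combine_fisher([0.5, 0.5])
    assert res.statistic == pytest.approx(2.773, abs=1e-3)
    assert res.df == 4
    assert res.p == pytest.approx(0.597, abs=1e-3)

    res = combine_fisher([1.0, 1.0, 1.0])
    assert res.statistic == 0.0 and res.p == pytest.approx(1.0)

    assert combine_fisher([0.5] * 10).df == 20  # df = 2 x loci

    with pytest.warns(UserWarning, match="clamped"):
        res = combine_fisher([0.0, 0.5])
    assert np.isfinite(res.statistic)


def test_stouffer_closed_forms():
    res = combine_stouffer([0.5, 0.5, 0.5])
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(0.5)

    res = combine_stouffer([0.05, 0.5])
    assert res.statistic == pytest.approx(1.1631, abs=1e-4)
    assert res.p == pytest.approx(0.1224, abs=1e-4)

    for bad in ([0.0, 0.5], [0.5, 1.0]):
        with pytest.raises(ValueError):
            combine_stouffer(bad)


def test_combinations_monotone():
    """Decreasing any input p never increases the combined p."""
    rng = np.random.default_rng(15)
    for _ in range(20):
        p = rng.uniform(0.01, 0.99, size=5)
        q = p.copy()
        q[rng.integers(5)] *= rng.uniform(0.1, 0.99)
        assert combine_fisher(q).p <= combine_fisher(p).p + 1e-12
        assert combine_stouffer(q).p <= combine_stouffer(p).p + 1e-12


def test_genotypic_exact_test_on_dataset():
    inds = [Individual(f"g{k}", "C", "gyne", "perennial", {"L": (1, 2)}) for k in range(5)]
    inds += [Individual(f"w{k}", "C", "worker", "perennial", {"L": (3, 3)}) for k in range(5)]
    ds = make_dataset(inds)
    res = genotypic_exact_test(ds, "L", lambda i: i.caste)
    assert res.p == pytest.approx(2 / 252)

    mono = [Individual(f"x{k}", "C", "gyne" if k < 3 else "worker", "perennial",
                       {"L": (1, 1)}) for k in range(6)]
    res = genotypic_exact_test(make_dataset(mono), "L", lambda i: i.caste)
    assert res.p == 1.0 and res.method == "degenerate"


def _with_satellite(sim, parent="P01", n_move=15):
    """Re-home some of the parent's workers into a satellite nest record."""
    ds = sim.dataset
    moved = 0
    inds = []
    for ind in ds.individuals:
        if ind.colony == parent and ind.caste == "worker" and moved < n_move:
            inds.append(Individual(ind.id, "SAT", ind.caste, ind.form,
                                   dict(ind.genotype)))
            moved += 1
        else:
            inds.append(ind)
    colonies = list(ds.colonies) + [ColonyMeta("SAT", "perennial",
                                               satellite_of=parent)]
    return GenotypeDataset(ds.panel, inds, colonies)


def test_satellite_merge_recommended_for_true_bud():
    sim = simulate_dataset(SimConfig(n_annual=0, n_perennial=3, queens=2, mates=2,
                                     workers_perennial=40, gynes_perennial=0,
                                     males_perennial=0, mtdna_samples_perennial=0,
                                     seed=31))
    ds = _with_satellite(sim)
    out = satellite_merge_test(ds, "P01", "SAT", seed=1,
                               dememorization=2000, batches=20, batch_size=500)
    assert out["merge"] is True
    assert out["per_caste"]["worker"] > 0.05
    assert "gyne" in out["skipped"] and "male" in out["skipped"]


def test_satellite_from_foreign_colony_rejected():
    sim = simulate_dataset(SimConfig(n_annual=0, n_perennial=3, queens=1, mates=1,
                                     workers_perennial=40, gynes_perennial=0,
                                     males_perennial=0, mtdna_samples_perennial=0,
                                     seed=32))
    ds = sim.dataset
    # satellite populated from an unrelated colony's workers
    inds = []
    for ind in ds.individuals:
        if ind.colony == "P02" and ind.caste == "worker":
            inds.append(Individual(ind.id, "SAT", ind.caste, ind.form,
                                   dict(ind.genotype)))
        else:
            inds.append(ind)
    colonies = [c for c in ds.colonies if c.colony_id != "P02"]
    colonies.append(ColonyMeta("SAT", "perennial", satellite_of="P01"))
    ds2 = GenotypeDataset(ds.panel, [i for i in inds if i.colony != "P02"], colonies)
    out = satellite_merge_test(ds2, "P01", "SAT", seed=1,
                               dememorization=2000, batches=20, batch_size=500)
    assert out["merge"] is False
    assert out["per_caste"]["worker"] < 0.01
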