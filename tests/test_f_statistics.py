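"""Variance components and theta against independent oracles and null sims."""

import numpy as np
import pytest

from colonykin.datatypes import Individual
from colonykin.f_statistics import (EstimationError, hierarchical_theta,
                                    multilocus_theta, pairwise_fst,
                                    variance_components)
from conftest import hw_individuals, make_dataset
from oracles import haploid_oneway_components, wc84_components


def test_fixed_difference_gives_theta_one():
    inds = [Individual(f"a{k}", "A", "worker", "annual", {"L": (1, 1)}) for k in range(5)]
    inds += [Individual(f"b{k}", "B", "worker", "annual", {"L": (2, 2)}) for k in range(5)]
    vc = variance_components(make_dataset(inds), "L")
    assert vc.theta == pytest.approx(1.0)


def test_monomorphic_locus_flagged():
    inds = [Individual(f"{c}{k}", c, "worker", "annual", {"L": (1, 1)})
            for c in "AB" for k in range(3)]
    vc = variance_components(make_dataset(inds), "L")
    assert not vc.informative
    assert (vc.a, vc.b, vc.c) == (0.0, 0.0, 0.0)


def test_single_group_errors(toy_two_colony):
    inds = [i for i in toy_two_colony.individuals if i.colony == "A"]
    with pytest.raises(EstimationError, match="single group"):
        variance_components(toy_two_colony, "L1", subset=inds)


def test_components_match_wc84_oracle():
    """Random small diploid datasets agree with the closed-form oracle to 1e-10."""
    rng = np.random.default_rng(5)
    checked = 0
    while checked < 200:
        r = int(rng.integers(2, 5))
        groups, inds = [], []
        for gi in range(r):
            m = int(rng.integers(2, 6))
            genos = [tuple(sorted(rng.integers(1, 5, size=2))) for _ in range(m)]
            groups.append(genos)
            inds += [Individual(f"g{gi}i{k}", f"C{gi}", "worker", "annual", {"L": g})
                     for k, g in enumerate(genos)]
        if sum(len(g) for g in groups) * 2 > 30:
            continue
        if len({a for g in groups for geno in g for a in geno}) < 2:
            continue
        vc = variance_components(make_dataset(inds), "L")
        a, b, c = wc84_components(groups)
        assert abs(vc.a - a) < 1e-10
        assert abs(vc.b - b) < 1e-10
        assert abs(vc.c - c) < 1e-10
        checked += 1


def test_haploid_components_match_oneway_oracle():
    rng = np.random.default_rng(6)
    for _ in range(50):
        groups, inds = [], []
        for gi in range(int(rng.integers(2, 5))):
            alleles = rng.integers(1, 4, size=int(rng.integers(2, 7))).tolist()
            groups.append(alleles)
            inds += [Individual(f"g{gi}m{k}", f"C{gi}", "male", "annual", {"L": (a,)})
                     for k, a in enumerate(alleles)]
        if len({a for g in groups for a in g}) < 2:
            continue
        vc = variance_components(make_dataset(inds), "L")
        a, w = haploid_oneway_components(groups)
        assert vc.a == pytest.approx(a, abs=1e-10)
        assert vc.b == 0.0
        assert vc.c == pytest.approx(w, abs=1e-10)


def test_null_split_theta_near_zero():
    """One panmictic sample split into two arbitrary 'colonies' has theta ~ 0."""
    rng = np.random.default_rng(8)
    freqs = {f"L{j}": (np.arange(1, 11), np.full(10, 0.1)) for j in range(10)}
    inds = (hw_individuals(rng, "A", 100, freqs) + hw_individuals(rng, "B", 100, freqs))
    res = multilocus_theta(make_dataset(inds), "colony")
    assert abs(res.theta) < 0.01
    assert abs(res.theta) < 4 * res.se_jackknife + 0.005


def test_multilocus_is_ratio_of_sums(toy_two_colony):
    res = multilocus_theta(toy_two_colony, "colony")
    tab = res.per_locus
    assert res.theta == pytest.approx(tab["a"].sum() / (tab[["a", "b", "c"]].sum().sum()))
    # identical data at every locus: multilocus equals per-locus, SE = 0
    inds = [Individual(i.id, i.colony, i.caste, i.form,
                       {"L1": i.genotype["L1"], "L2": i.genotype["L1"]})
            for i in toy_two_colony.individuals]
    dup = multilocus_theta(make_dataset(inds), "colony")
    assert dup.theta == pytest.approx(dup.per_locus["theta"].iloc[0])
    assert dup.se_jackknife == pytest.approx(0.0, abs=1e-12)


def test_pairwise_fst_consistency_and_relabeling():
    rng = np.random.default_rng(9)
    freqs = {f"L{j}": (np.arange(1, 6), np.full(5, 0.2)) for j in range(4)}
    inds = []
    for c in ("A", "B", "C"):
        # distinct families: shift the frequency mass per colony
        p = rng.dirichlet(np.ones(5))
        f = {k: (v[0], p) for k, v in freqs.items()}
        inds += hw_individuals(rng, c, 15, f)
    ds = make_dataset(inds)
    mat = pairwise_fst(ds)
    assert np.allclose(mat.to_numpy(), mat.to_numpy().T)
    assert np.allclose(np.diag(mat.to_numpy()), 0.0)
    # each entry equals the two-colony multilocus run on the restriction
    sub = [i for i in inds if i.colony in ("A", "C")]
    assert mat.loc["A", "C"] == pytest.approx(
        multilocus_theta(ds, "colony", subset=sub).theta)
    # duplicated colony: near-zero differentiation
    dup = [Individual(i.id + "_d", "D", i.caste, i.form, dict(i.genotype))
           for i in inds if i.colony == "A"]
    mat2 = pairwise_fst(make_dataset(inds + dup))
    # unbiased estimator on truly identical colonies: small, non-positive
    assert -0.1 < mat2.loc["A", "D"] <= 1e-12


def test_hierarchical_null_and_signal():
    rng = np.random.default_rng(10)
    freqs = {f"L{j}": (np.arange(1, 11), np.full(10, 0.1)) for j in range(10)}
    # null: forms assigned arbitrarily to colonies from one population
    inds = []
    for ci in range(8):
        form = "annual" if ci % 2 else "perennial"
        inds += hw_individuals(rng, f"C{ci}", 20, freqs, form=form)
    h = hierarchical_theta(make_dataset(inds), n_boot=500, seed=1)
    assert h.ci95_S[0] <= 0.0 <= h.ci95_S[1]

    # signal: colonies are distinct families -> theta_C > 0, CI excludes 0
    inds = []
    for ci in range(8):
        form = "annual" if ci % 2 else "perennial"
        p = rng.dirichlet(np.ones(10) * 0.3)
        f = {k: (v[0], p) for k, v in freqs.items()}
        inds += hw_individuals(rng, f"C{ci}", 20, f, form=form)
    h = hierarchical_theta(make_dataset(inds), n_boot=500, seed=1)
    assert h.theta_C > 0.05
    assert h.ci95_C[0] > 0.0


def test_hierarchical_clonal_degenerate():
    """Colonies of clones: nearly all variance lies among colonies within forms."""
    rng = np.random.default_rng(11)
    inds = []
    for ci in range(6):
        # homozygous clones: every gene copy in a colony is identical, so all
        # within-form variance sits at the colony level
        geno = {f"L{j}": (int(a := rng.integers(1, 20)), int(a)) for j in range(6)}
        form = "annual" if ci % 2 else "perennial"
        inds += [Individual(f"C{ci}_{k}", f"C{ci}", "worker", form, dict(geno))
                 for k in range(10)]
    h = hierarchical_theta(make_dataset(inds), n_boot=200, seed=2)
    assert h.theta_C > 0.95


def test_hierarchical_requires_both_forms(toy_two_colony):
    with pytest.raises(EstimationError, match="both social forms"):
        hierarchical_theta(toy_two_colony, n_boot=100)
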