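"""Haplotype calling, diversity and matriline summaries."""

import numpy as np
import pytest

from colonykin.datatypes import SequenceAlignment
from colonykin.mtdna import (call_haplotypes, haplotype_diversity,
                             haplotype_form_test, matriline_summary,
                             trim_alignment)
from colonykin.simulate import SimConfig, simulate_dataset
from oracles import exact_prob_test_2x2


def _aln(seqs, prefix="s"):
    return SequenceAlignment(tuple((f"{prefix}{i}", s) for i, s in enumerate(seqs)))


def test_trim_defaults_and_errors():
    rng = np.random.default_rng(1)
    full = "".join(rng.choice(list("ACGT"), size=458))
    aln = _aln([full] * 3)
    trimmed = trim_alignment(aln)
    assert trimmed.length == 338
    assert trimmed.records[0][1] == full[120:458]

    # explicit full window is the identity
    same = trim_alignment(aln, (0, 458))
    assert same.records == aln.records

    with pytest.raises(ValueError, match="window"):
        trim_alignment(aln, (100, 500))


def test_call_haplotypes_monomorphic_and_patterns():
    hs = call_haplotypes(_aln(["ACGTACGT"] * 4))
    assert len(hs.haplotypes) == 1
    assert hs.segregating_sites == ()

    # three sequences, two variable columns, three patterns
    hs = call_haplotypes(_aln(["AAAAA", "AAGAA", "TAGAA"]))
    assert len(hs.segregating_sites) == 2
    assert len(hs.haplotypes) == 3
    assert hs.segregating_sites_1based == (1, 3)


def test_ambiguity_policy():
    seqs = ["AAAA", "AATA", "AANA"]
    flagged = call_haplotypes(_aln(seqs), ambiguity_policy="flag")
    assert flagged.assignment["s2"] is None
    dropped = call_haplotypes(_aln(seqs), ambiguity_policy="drop")
    assert "s2" not in dropped.assignment


def test_call_then_trim_idempotent():
    rng = np.random.default_rng(2)
    base = rng.choice(list("ACGT"), size=338)
    other = base.copy()
    other[100] = "A" if base[100] != "A" else "G"
    aln = _aln(["".join(base), "".join(other)])
    once = trim_alignment(aln)
    assert once.records == aln.records  # already at analysis length
    h1 = call_haplotypes(once)
    h2 = call_haplotypes(trim_alignment(once))
    assert h1.haplotypes == h2.haplotypes and h1.assignment == h2.assignment


@pytest.mark.parametrize("counts, expected", [
    ((5, 5), 10 / 9 * 0.5),
    ((2, 2), 4 / 3 * 0.5),
])
def test_diversity_closed_forms(counts, expected):
    res = haplotype_diversity(counts)
    assert res.h == pytest.approx(expected)


def test_diversity_edge_cases():
    assert haplotype_diversity([7]).h == 0.0
    with pytest.raises(ValueError):
        haplotype_diversity([1])
    # relabel invariance and singleton growth
    assert haplotype_diversity([3, 2, 1]).h == pytest.approx(
        haplotype_diversity([1, 2, 3]).h)
    assert haplotype_diversity([9, 1]).h > haplotype_diversity([10]).h


def test_matriline_summary_on_simulated_colonies():
    cfg = SimConfig(n_annual=2, n_perennial=3, queens=4, mates=2,
                    workers_perennial=12, gynes_perennial=0, males_perennial=0,
                    workers_annual=8, mtdna_samples_perennial=8,
                    mtdna_samples_annual=4, seed=61)
    sim = simulate_dataset(cfg)
    cmap = {i.id: i.colony for i in sim.dataset.individuals}
    hs = call_haplotypes(trim_alignment(sim.alignment), cmap)
    summary = matriline_summary(hs)
    # natal recruitment: every colony is a single matriline
    assert not summary["multiple_matrilines"].any()

    planted = simulate_dataset(SimConfig(**{**cfg.__dict__, "planted_foreign_worker": True}))
    cmap = {i.id: i.colony for i in planted.dataset.individuals}
    hs = call_haplotypes(trim_alignment(planted.alignment), cmap)
    summary = matriline_summary(hs).set_index("colony")
    target = planted.truth["planted_foreign_worker"]
    colony = cmap[target]
    assert summary.loc[colony, "multiple_matrilines"]
    assert target in summary.loc[colony, "minority_records"].split(",")


def test_haplotype_form_test_toy_tables():
    # identical per-form haplotype frequencies: p = 1
    seq_a, seq_b = "AAAA", "AATA"
    records, cmap, fmap = [], {}, {}
    k = 0
    for form in ("annual", "perennial"):
        for hap, seq in (("x", seq_a), ("y", seq_b)):
            for _ in range(2):
                rid = f"r{k}"
                records.append((rid, seq))
                cmap[rid] = f"c{k}"
                fmap[f"c{k}"] = form
                k += 1
    hs = call_haplotypes(SequenceAlignment(tuple(records)), cmap)
    res = haplotype_form_test(hs, fmap)
    assert res.p > 0.99

    # disjoint haplotype sets, 3 colonies per form: enumeration on the 2x2
    records, cmap, fmap = [], {}, {}
    for i in range(3):
        records.append((f"a{i}", seq_a)); cmap[f"a{i}"] = f"A{i}"; fmap[f"A{i}"] = "annual"
        records.append((f"p{i}", seq_b)); cmap[f"p{i}"] = f"P{i}"; fmap[f"P{i}"] = "perennial"
    hs = call_haplotypes(SequenceAlignment(tuple(records)), cmap)
    res = haplotype_form_test(hs, fmap)
    assert res.p == pytest.approx(exact_prob_test_2x2([[3, 0], [0, 3]]))
    assert res.p == pytest.approx(0.10)
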