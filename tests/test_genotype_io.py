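"""Sample-table / GENEPOP / FASTA round trips and error handling."""

import textwrap

import pytest

from colonykin.datatypes import DatasetError
from colonykin.genotype_io import (ParseError, read_fasta, read_genepop,
                                   read_sample_table, write_fasta,
                                   write_genepop, write_sample_table)
from colonykin.simulate import SimConfig, simulate_dataset


def test_genepop_structural_parse(tmp_path):
    """A 2-POP, 2-locus toy file with 3-digit alleles parses into 2 colonies."""
    text = textwrap.dedent("""\
        toy file
        LocA
        LocB
        POP
        i1, 145162 101101
        i2, 000000 145162
        POP
        i3, 162162 102103
        """)
    path = tmp_path / "toy.gen"
    path.write_text(text)
    ds = read_genepop(path)
    assert len(ds.colonies) == 2
    assert ds.panel.locus_names == ("LocA", "LocB")
    by_id = {i.id: i for i in ds.individuals}
    # all-zero field decodes as missing; the rest as allele pairs
    assert by_id["i2"].genotype["LocA"] is None
    assert by_id["i2"].genotype["LocB"] == (145, 162)
    assert by_id["i1"].genotype["LocA"] == (145, 162)


@pytest.mark.parametrize("bad, match", [
    ("toy\nLocA\nPOP\ni1, 145162 101101\n", "genotype fields"),
    ("toy\nLocA\nPOP\ni1, 1451 \n", "chars wide"),
    ("toy\nLocA\nPOP\ni1, 145162\ni1, 145162\n", "duplicate sample id"),
])
def test_genepop_malformed(tmp_path, bad, match):
    path = tmp_path / "bad.gen"
    path.write_text(bad)
    with pytest.raises(ParseError, match=match):
        read_genepop(path)


def test_genepop_round_trip_identity(tmp_path):
    """write_genepop -> read_genepop preserves genotypes, ploidy and metadata."""
    sim = simulate_dataset(SimConfig(n_annual=2, n_perennial=2, queens=3, mates=2,
                                     workers_perennial=6, gynes_perennial=2,
                                     males_perennial=3, workers_annual=4,
                                     mtdna_samples_annual=0,
                                     mtdna_samples_perennial=0, seed=3))
    ds = sim.dataset
    path = tmp_path / "sim.gen"
    write_genepop(ds, path)
    back = read_genepop(path)
    assert back.panel.locus_names == ds.panel.locus_names
    orig = {i.id: i for i in ds.individuals}
    assert set(orig) == {i.id for i in back.individuals}
    for ind in back.individuals:
        o = orig[ind.id]
        assert (ind.colony, ind.caste, ind.form) == (o.colony, o.caste, o.form)
        for locus in ds.panel.locus_names:
            assert ind.genotype[locus] == o.genotype[locus]
    assert {c.colony_id: (c.form, c.latitude, c.longitude) for c in back.colonies} == \
           {c.colony_id: (c.form, c.latitude, c.longitude) for c in ds.colonies}


def test_genepop_deterministic_output(tmp_path):
    sim = simulate_dataset(SimConfig(n_annual=1, n_perennial=1, workers_perennial=5,
                                     workers_annual=5, gynes_perennial=0,
                                     males_perennial=0, mtdna_samples_annual=0,
                                     mtdna_samples_perennial=0, seed=1))
    p1, p2 = tmp_path / "a.gen", tmp_path / "b.gen"
    write_genepop(sim.dataset, p1)
    write_genepop(sim.dataset, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_genepop_caste_partition(tmp_path):
    sim = simulate_dataset(SimConfig(n_annual=0, n_perennial=1, workers_perennial=4,
                                     gynes_perennial=3, males_perennial=0,
                                     mtdna_samples_perennial=0, seed=2))
    path = tmp_path / "c.gen"
    write_genepop(sim.dataset, path, partition_by="caste-within-colony")
    pops = [l for l in path.read_text().splitlines() if l.strip() == "POP"]
    assert len(pops) == 2  # workers and gynes of the single colony


def test_sample_table_ploidy_and_missing(tmp_path):
    csv = textwrap.dedent("""\
        id,colony,caste,form,lat,long,L1.1,L1.2,L2.1,L2.2
        m1,HA,male,perennial,33.1175,-86.1227,101,,102,
        w1,HA,worker,perennial,33.1175,-86.1227,101,102,,
        w2,HA,worker,perennial,33.1175,-86.1227,103,103,101,104
        w3,KL,worker,perennial,32.1253,-85.9370,101,101,102,102
        """)
    path = tmp_path / "t.csv"
    path.write_text(csv)
    ds = read_sample_table(path)
    by_id = {i.id: i for i in ds.individuals}
    assert by_id["m1"].genotype["L1"] == (101,)       # haploid male
    assert by_id["w1"].genotype["L2"] is None         # empty cells -> missing
    assert by_id["w2"].genotype["L2"] == (101, 104)
    cmap = ds.colony_map
    assert cmap["HA"].latitude == pytest.approx(33.1175)
    assert cmap["HA"].longitude == pytest.approx(-86.1227)
    assert cmap["KL"].latitude == pytest.approx(32.1253)


def test_sample_table_errors(tmp_path):
    bad_male = "id,colony,caste,form,L1.1,L1.2\nm1,HA,male,perennial,101,102\n"
    path = tmp_path / "bad.csv"
    path.write_text(bad_male)
    with pytest.raises(ParseError, match="two distinct alleles"):
        read_sample_table(path)
    path.write_text("id,colony,caste,form,L1.1,L1.2\nw1,HA,soldier,perennial,101,102\n")
    with pytest.raises(ParseError, match="caste"):
        read_sample_table(path)


def test_sample_table_round_trip(tmp_path):
    sim = simulate_dataset(SimConfig(n_annual=1, n_perennial=2, queens=2,
                                     workers_perennial=5, gynes_perennial=2,
                                     males_perennial=2, workers_annual=4,
                                     mtdna_samples_annual=0,
                                     mtdna_samples_perennial=0, seed=9))
    path = tmp_path / "rt.csv"
    write_sample_table(sim.dataset, path)
    back = read_sample_table(path)
    orig = {i.id: i for i in sim.dataset.individuals}
    for ind in back.individuals:
        assert ind.genotype == orig[ind.id].genotype
        assert (ind.colony, ind.caste, ind.form) == \
               (orig[ind.id].colony, orig[ind.id].caste, orig[ind.id].form)


def test_fasta_roundtrip_and_validation(tmp_path):
    p = tmp_path / "a.fasta"
    p.write_text(">r1\n" + "acgt" * 3 + "\n>r2\n" + "ACGT" * 3 + "\n")
    aln = read_fasta(p)
    assert aln.length == 12
    assert aln.sequence("r1") == "ACGT" * 3  # uppercased
    out = tmp_path / "b.fasta"
    write_fasta(aln, out)
    assert read_fasta(out).records == aln.records

    p.write_text(">r1\nACGT\n>r2\nACG\n")
    with pytest.raises(DatasetError, match="r2"):
        read_fasta(p)


def test_fasta_equal_length_amplicon(tmp_path):
    seq = "A" * 338
    p = tmp_path / "cytb.fasta"
    p.write_text("".join(f">s{i}\n{seq}\n" for i in range(3)))
    assert read_fasta(p).length == 338
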