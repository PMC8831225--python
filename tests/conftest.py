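"""Shared fixtures: hand-built toy datasets and cached simulations."""

from __future__ import annotations

import numpy as np
import pytest

from colonykin.datatypes import (ColonyMeta, GenotypeDataset, Individual,
                                 MarkerPanel)
from colonykin.simulate import SimConfig, simulate_dataset


def make_dataset(individuals, colony_forms=None, coords=None):
    """Build a GenotypeDataset from Individual objects, inferring everything."""
    loci = sorted({l for ind in individuals for l in ind.genotype})
    seen = {}
    for ind in individuals:
        seen.setdefault(ind.colony, ind.form)
    colonies = []
    for cid, form in seen.items():
        lat, lon = (coords or {}).get(cid, (None, None))
        colonies.append(ColonyMeta(cid, form, lat, lon))
    panel = MarkerPanel.from_genotypes(loci, individuals)
    return GenotypeDataset(panel, list(individuals), colonies)


def hw_individuals(rng, colony, n, freqs, loci=None, form="annual", caste="worker",
                   prefix=None):
    """Diploid individuals drawn from Hardy-Weinberg at the given frequencies.

    ``freqs`` is a dict locus -> (labels, probabilities).
    """
    loci = loci or list(freqs)
    out = []
    for k in range(n):
        geno = {}
        for locus in loci:
            labels, p = freqs[locus]
            geno[locus] = tuple(sorted(int(a) for a in rng.choice(labels, size=2, p=p)))
        out.append(Individual(f"{prefix or colony}_{k:03d}", colony, caste, form, geno))
    return out


@pytest.fixture(scope="session")
def monogyne_sim():
    """50 single-queen singly-mated colonies, 20 workers + 20 sons each."""
    cfg = SimConfig(n_annual=0, n_perennial=50, queens=1, mates=1,
                    allele_counts=[10] * 10, freq_law="equifrequent",
                    workers_perennial=20, gynes_perennial=0, males_perennial=20,
                    mtdna_samples_perennial=0, seed=11)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def toy_two_colony():
    """2 colonies x 3 diploids, 2 loci — small enough for hand oracles."""
    inds = [
        Individual("a1", "A", "worker", "annual", {"L1": (1, 1), "L2": (1, 2)}),
        Individual("a2", "A", "worker", "annual", {"L1": (1, 2), "L2": (2, 2)}),
        Individual("a3", "A", "worker", "annual", {"L1": (2, 2), "L2": (1, 1)}),
        Individual("b1", "B", "worker", "annual", {"L1": (1, 1), "L2": (3, 3)}),
        Individual("b2", "B", "worker", "annual", {"L1": (1, 3), "L2": (2, 3)}),
        Individual("b3", "B", "worker", "annual", {"L1": (3, 3), "L2": (2, 2)}),
    ]
    return make_dataset(inds)
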