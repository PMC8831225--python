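"""Core containers for colony-structured genotype and sequence data.

The central object is :class:`GenotypeDataset`: multilocus genotypes of
individually sampled wasps (diploid females, haploid males) annotated with
colony membership, caste (worker / gyne / male), social form (annual /
perennial) and colony coordinates.  All downstream statistics — allele
frequencies, variance-component F-statistics, relatedness, exact tests,
queen-number inference — operate on this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

CASTES = ("worker", "gyne", "male")
FORMS = ("annual", "perennial")

#: A genotype at one locus: ``(a,)`` for a haploid male, ``(a, b)`` for a
#: diploid female, ``None`` when the locus failed to amplify.
Genotype = Optional[tuple]


class DatasetError(ValueError):
    """Raised on structurally invalid genotype data."""


@dataclass(frozen=True)
class MarkerPanel:
    """The set of scored microsatellite loci and their allele labels.

    Allele labels are positive integers (PCR fragment sizes in bp).  The
    ``missing_code`` (default 0, the GENEPOP convention) is reserved and may
    never appear as a real allele.
    """

    locus_names: tuple[str, ...]
    alleles: Mapping[str, frozenset]
    missing_code: int = 0

    def __post_init__(self):
        if len(set(self.locus_names)) != len(self.locus_names):
            raise DatasetError("locus names must be unique")
        for locus in self.locus_names:
            for a in self.alleles.get(locus, ()):
                if not (isinstance(a, (int, np.integer)) and a > 0):
                    raise DatasetError(f"allele labels must be positive integers, got {a!r} at {locus}")
                if a == self.missing_code:
                    raise DatasetError(f"missing code {a} used as allele at {locus}")

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    @staticmethod
    def from_genotypes(locus_names: Sequence[str], individuals: Iterable["Individual"],
                       missing_code: int = 0) -> "MarkerPanel":
        """Infer the panel from observed genotypes."""
        alleles: dict[str, set] = {l: set() for l in locus_names}
        for ind in individuals:
            for locus, g in ind.genotype.items():
                if g is not None:
                    alleles[locus].update(int(a) for a in g)
        return MarkerPanel(tuple(locus_names),
                           {l: frozenset(s) for l, s in alleles.items()},
                           missing_code)


@dataclass(frozen=True)
class Individual:
    """One genotyped wasp.

    Males develop from unfertilized eggs and are haploid: exactly one allele
    per non-missing locus.  Workers and gynes are diploid females.
    """

    id: str
    colony: str
    caste: str
    form: str
    genotype: Mapping[str, Genotype]
    mtdna_haplotype: Optional[str] = None

    def __post_init__(self):
        if self.caste not in CASTES:
            raise DatasetError(f"unknown caste {self.caste!r} for {self.id} (expected one of {CASTES})")
        if self.form not in FORMS:
            raise DatasetError(f"unknown form {self.form!r} for {self.id} (expected one of {FORMS})")
        want = 1 if self.caste == "male" else 2
        for locus, g in self.genotype.items():
            if g is None:
                continue
            if len(g) != want:
                raise DatasetError(
                    f"{self.id} ({self.caste}) carries {len(g)} allele(s) at {locus}, expected {want}")

    @property
    def ploidy(self) -> int:
        return 1 if self.caste == "male" else 2


@dataclass(frozen=True)
class ColonyMeta:
    """Colony-level metadata: social form, location, satellite linkage."""

    colony_id: str
    form: str
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    satellite_of: Optional[str] = None

    def __post_init__(self):
        if self.form not in FORMS:
            raise DatasetError(f"unknown form {self.form!r} for colony {self.colony_id}")
        if self.latitude is not None and abs(self.latitude) > 90:
            raise DatasetError(f"latitude out of range for colony {self.colony_id}")
        if self.longitude is not None and abs(self.longitude) > 180:
            raise DatasetError(f"longitude out of range for colony {self.colony_id}")


@dataclass
class GenotypeDataset:
    """Multilocus genotypes plus sample and colony metadata."""

    panel: MarkerPanel
    individuals: list
    colonies: list

    def __post_init__(self):
        ids = [ind.id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise DatasetError(f"duplicate individual ids: {dup[:5]}")
        known = {c.colony_id for c in self.colonies}
        for ind in self.individuals:
            if ind.colony not in known:
                raise DatasetError(f"individual {ind.id} references unknown colony {ind.colony}")
        for c in self.colonies:
            if c.satellite_of is not None and c.satellite_of not in known:
                raise DatasetError(f"satellite link {c.colony_id} -> {c.satellite_of} dangles")

    # -- convenience accessors -------------------------------------------

    @property
    def colony_map(self) -> dict:
        return {c.colony_id: c for c in self.colonies}

    def subset(self, colonies: Optional[Sequence[str]] = None, caste: Optional[str] = None,
               form: Optional[str] = None, loci: Optional[Sequence[str]] = None,
               ids: Optional[Sequence[str]] = None) -> "GenotypeDataset":
        """Restrict to matching individuals (and optionally loci).

        Colony metadata is kept for every retained colony; the panel is
        restricted but allele registries are preserved as observed.
        """
        keep = self.individuals
        if colonies is not None:
            cset = set(colonies)
            keep = [i for i in keep if i.colony in cset]
        if caste is not None:
            keep = [i for i in keep if i.caste == caste]
        if form is not None:
            keep = [i for i in keep if i.form == form]
        if ids is not None:
            idset = set(ids)
            keep = [i for i in keep if i.id in idset]
        locus_names = tuple(loci) if loci is not None else self.panel.locus_names
        if loci is not None:
            keep = [replace(i, genotype={l: i.genotype.get(l) for l in locus_names}) for i in keep]
        kept_colonies = sorted({i.colony for i in keep})
        metas = [self.colony_map[c] for c in kept_colonies]
        panel = MarkerPanel(locus_names,
                            {l: self.panel.alleles.get(l, frozenset()) for l in locus_names},
                            self.panel.missing_code)
        return GenotypeDataset(panel, keep, metas)

    def merge_satellites(self) -> "GenotypeDataset":
        """Fold satellite nests into their parent colonies."""
        parent = {c.colony_id: (c.satellite_of or c.colony_id) for c in self.colonies}
        inds = [replace(i, colony=parent[i.colony]) if parent[i.colony] != i.colony else i
                for i in self.individuals]
        metas = [c for c in self.colonies if c.satellite_of is None]
        return GenotypeDataset(self.panel, inds, metas)

    def gene_copies(self, locus: str, individuals: Optional[Sequence[Individual]] = None):
        """Flatten genotypes at ``locus`` into parallel per-gene-copy arrays.

        Returns ``(alleles, colony_labels, individual_labels, diploid_mask)``
        where each gene copy of a diploid contributes one row.  Missing
        genotypes are dropped (locus-wise deletion only).
        """
        inds = self.individuals if individuals is None else individuals
        alleles, col, iid, dip = [], [], [], []
        for ind in inds:
            g = ind.genotype.get(locus)
            if g is None:
                continue
            for a in g:
                alleles.append(int(a))
                col.append(ind.colony)
                iid.append(ind.id)
                dip.append(len(g) == 2)
        return (np.asarray(alleles, dtype=int), np.asarray(col, dtype=object),
                np.asarray(iid, dtype=object), np.asarray(dip, dtype=bool))

    def __len__(self) -> int:
        return len(self.individuals)


@dataclass(frozen=True)
class SequenceAlignment:
    """Aligned nucleotide sequences of equal length (ids unique)."""

    records: tuple  # of (id, sequence) pairs

    def __post_init__(self):
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            raise DatasetError("duplicate sequence ids in alignment")
        lengths = {len(r[1]) for r in self.records}
        if len(lengths) > 1:
            bad = [r[0] for r in self.records if len(r[1]) != len(self.records[0][1])]
            raise DatasetError(f"ragged alignment; offending ids: {bad}")

    @property
    def length(self) -> int:
        return len(self.records[0][1]) if self.records else 0

    @property
    def ids(self) -> tuple:
        return tuple(r[0] for r in self.records)

    def sequence(self, rec_id: str) -> str:
        for rid, seq in self.records:
            if rid == rec_id:
                return seq
        raise KeyError(rec_id)
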