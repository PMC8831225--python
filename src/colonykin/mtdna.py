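"""Mitochondrial haplotype calling, diversity and matriline analysis.

Haplotypes are strings over the segregating sites of a trimmed alignment;
because mtDNA is maternally inherited, per-colony haplotype composition
identifies matrilines.  Haplotype diversity uses the gene-copy corrected
estimator ``h = n/(n-1) * (1 - sum p_i^2)``.

Window coordinates are 0-based half-open internally; reported positions are
1-based in human-readable output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import SequenceAlignment
from .differentiation import ExactTestResult, exact_table_test

UNAMBIGUOUS = set("ACGT")
DEFAULT_TRIM_START = 120   # 458-bp amplicon -> 338-bp analysis window
DEFAULT_TRIM_LENGTH = 338


@dataclass(frozen=True)
class HaplotypeSet:
    trimmed_length: int
    segregating_sites: tuple         # 0-based column indices
    haplotypes: Mapping[str, str]    # id -> site pattern
    assignment: Mapping[str, Optional[str]]  # record id -> haplotype id (None = ambiguous)
    per_colony_counts: Optional[pd.DataFrame]  # colonies x haplotypes
    colony_map: Optional[Mapping[str, str]] = None

    @property
    def segregating_sites_1based(self) -> tuple:
        return tuple(s + 1 for s in self.segregating_sites)


@dataclass(frozen=True)
class DiversityResult:
    h: float
    n: int
    k: int

    def __post_init__(self):
        assert 0.0 <= self.h <= 1.0 + 1e-12
        assert (self.k == 1) == (self.h == 0.0)


def trim_alignment(alignment: SequenceAlignment,
                   window: Optional[tuple] = None) -> SequenceAlignment:
    """Cut every record to the same 0-based half-open window.

    Without an explicit window, a full-length amplicon (458 bp) is trimmed
    to the default 338-bp analysis window; already-trimmed input is returned
    unchanged.
    """
    if window is None:
        if alignment.length == DEFAULT_TRIM_LENGTH:
            return alignment
        window = (DEFAULT_TRIM_START, DEFAULT_TRIM_START + DEFAULT_TRIM_LENGTH)
    start, stop = window
    if not (0 <= start < stop <= alignment.length):
        raise ValueError(f"window {window} outside alignment of length {alignment.length}")
    return SequenceAlignment(tuple((rid, seq[start:stop]) for rid, seq in alignment.records))


def call_haplotypes(alignment: SequenceAlignment,
                    colony_map: Optional[Mapping[str, str]] = None,
                    ambiguity_policy: str = "flag") -> HaplotypeSet:
    """Identify haplotypes from the segregating sites of an alignment.

    Segregating sites are columns with at least two distinct unambiguous
    bases; gap-only and ambiguity-only columns are ignored.  Records with an
    ambiguous character at a segregating site are dropped or flagged
    (assigned ``None``) per ``ambiguity_policy``.  Haplotype ids ``H1, H2...``
    are ordered by decreasing frequency, ties by pattern.
    """
    if not alignment.records:
        raise ValueError("empty alignment")
    if ambiguity_policy not in ("drop", "flag"):
        raise ValueError("ambiguity_policy must be 'drop' or 'flag'")
    arr = np.array([list(seq) for _, seq in alignment.records])
    seg = [j for j in range(arr.shape[1])
           if len({b for b in arr[:, j] if b in UNAMBIGUOUS}) >= 2]

    patterns = {}
    assignment: dict = {}
    for i, (rid, _) in enumerate(alignment.records):
        pat = "".join(arr[i, j] for j in seg)
        if any(b not in UNAMBIGUOUS for b in pat):
            assignment[rid] = None
            continue
        patterns.setdefault(pat, []).append(rid)
        assignment[rid] = pat
    if ambiguity_policy == "drop":
        assignment = {rid: p for rid, p in assignment.items() if p is not None}

    order = sorted(patterns, key=lambda p: (-len(patterns[p]), p))
    hap_id = {pat: f"H{i + 1}" for i, pat in enumerate(order)}
    haplotypes = {hap_id[p]: p for p in order}
    assignment = {rid: (hap_id[p] if p is not None else None)
                  for rid, p in assignment.items()}

    per_colony = None
    if colony_map is not None:
        rows = [{"colony": colony_map[rid], "haplotype": h}
                for rid, h in assignment.items() if h is not None and rid in colony_map]
        if rows:
            per_colony = (pd.DataFrame(rows).value_counts().unstack(fill_value=0)
                          .sort_index())
            per_colony = per_colony[sorted(per_colony.columns, key=lambda h: int(h[1:]))]
    return HaplotypeSet(alignment.length, tuple(seg), haplotypes, assignment, per_colony,
                        dict(colony_map) if colony_map is not None else None)


def haplotype_diversity(counts: Sequence[int]) -> DiversityResult:
    """Gene-copy corrected haplotype diversity from haplotype counts."""
    counts = np.asarray([c for c in counts if c > 0], dtype=float)
    n = counts.sum()
    if n < 2:
        raise ValueError("need at least 2 sequences")
    p = counts / n
    h = n / (n - 1) * (1.0 - float((p ** 2).sum()))
    return DiversityResult(float(h), int(n), int(counts.size))


def matriline_summary(hapset: HaplotypeSet) -> pd.DataFrame:
    """Per-colony haplotype counts with multi-matriline flags.

    Colonies with more than one haplotype are flagged and their
    minority-haplotype records listed (the foreign-matriline suspects).
    """
    if hapset.per_colony_counts is None:
        raise ValueError("haplotype set carries no colony map")
    counts = hapset.per_colony_counts
    cmap = hapset.colony_map or {}
    rows_out = []
    for colony, row in counts.iterrows():
        present = row[row > 0]
        multiple = len(present) > 1
        minority_ids = []
        if multiple:
            modal = present.idxmax()
            minority_haps = {h for h in present.index if h != modal}
            minority_ids = [rid for rid, h in hapset.assignment.items()
                            if h in minority_haps and cmap.get(rid) == colony]
        rows_out.append({"colony": colony, "n_haplotypes": int(len(present)),
                         "multiple_matrilines": multiple,
                         "minority_records": ",".join(sorted(minority_ids))})
    return pd.DataFrame(rows_out)


def haplotype_form_test(hapset: HaplotypeSet, form_map: Mapping[str, str],
                        one_per_colony: bool = True, seed: int = 0,
                        **mc_kwargs) -> ExactTestResult:
    """Exact (genic) test of haplotype frequency differences between forms.

    ``form_map`` maps colony id to social form.  With ``one_per_colony`` the
    dataset is first collapsed to each colony's modal haplotype (an error
    names any colony whose modal haplotype is ambiguous), removing the
    pseudo-replication of sampling many wasps per matriline.
    """
    if hapset.per_colony_counts is None:
        raise ValueError("haplotype set carries no colony map")
    counts = hapset.per_colony_counts
    forms = sorted({form_map[c] for c in counts.index})
    if len(forms) < 2:
        raise ValueError("need at least two social forms")
    haps = list(counts.columns)
    if one_per_colony:
        table = pd.DataFrame(0, index=haps, columns=forms)
        for colony, row in counts.iterrows():
            present = row[row > 0]
            top = present[present == present.max()]
            if len(top) > 1:
                raise ValueError(f"colony {colony} has an ambiguous modal haplotype")
            table.loc[top.index[0], form_map[colony]] += 1
    else:
        table = pd.DataFrame(0, index=haps, columns=forms)
        for colony, row in counts.iterrows():
            for h, c in row.items():
                table.loc[h, form_map[colony]] += int(c)
    res = exact_table_test(table.to_numpy(), seed=seed, **mc_kwargs)
    return ExactTestResult("haplotype~form", res.p, res.mc_se, res.table_dims, res.method)
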