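"""Per-locus marker variability statistics and between-form comparisons.

Statistics follow the SPAGEDi conventions: expected heterozygosity (gene
diversity) uses the sample-size corrected estimator
``H_e = n/(n-1) * (1 - sum p_i^2)`` over ``n`` gene copies; the effective
number of alleles is ``A_e = 1 / sum p_i^2``.  Haploid males contribute
single gene copies to allele frequencies, allele counts and ``A_e``, but not
to observed heterozygosity, which is defined for diploids only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeDataset


class NoDataError(ValueError):
    """No usable gene copies for the requested statistic."""


@dataclass(frozen=True)
class LocusSummary:
    locus: str
    A_n: int
    A_e: float
    H_e: float
    H_o: Optional[float]  # None when the subset holds no diploids
    n_gene_copies: int


def allele_frequencies(dataset: GenotypeDataset, locus: str,
                       subset: Optional[Sequence] = None) -> pd.Series:
    """Allele frequencies over gene copies (2 per diploid, 1 per haploid male).

    ``subset`` is an optional list of :class:`Individual` to restrict to.
    Raises :class:`NoDataError` when no non-missing gene copy exists.
    """
    alleles, _, _, _ = dataset.gene_copies(locus, subset)
    if alleles.size == 0:
        raise NoDataError(f"no non-missing gene copies at locus {locus}")
    counts = pd.Series(alleles).value_counts().sort_index()
    return counts / counts.sum()


def summarize_locus(dataset: GenotypeDataset, locus: str,
                    subset: Optional[Sequence] = None) -> LocusSummary:
    """Observed/effective allele numbers and heterozygosities at one locus."""
    freqs = allele_frequencies(dataset, locus, subset)
    alleles, _, _, dip = dataset.gene_copies(locus, subset)
    n = alleles.size
    if n < 2:
        raise NoDataError(f"need >=2 gene copies at {locus}, have {n}")
    p2 = float((freqs ** 2).sum())
    A_n = int(freqs.size)
    A_e = 1.0 / p2
    H_e = n / (n - 1) * (1.0 - p2)

    inds = dataset.individuals if subset is None else list(subset)
    dip_genos = [ind.genotype.get(locus) for ind in inds
                 if ind.ploidy == 2 and ind.genotype.get(locus) is not None]
    if dip_genos:
        H_o = float(np.mean([g[0] != g[1] for g in dip_genos]))
    else:
        H_o = None  # haploid-only subset: observed heterozygosity undefined
    return LocusSummary(locus, A_n, A_e, H_e, H_o, n)


def locus_table(dataset: GenotypeDataset, subset: Optional[Sequence] = None) -> pd.DataFrame:
    """Variability summary for every locus in the panel (one row per locus)."""
    rows = []
    for locus in dataset.panel.locus_names:
        try:
            s = summarize_locus(dataset, locus, subset)
        except NoDataError:
            continue
        rows.append({"locus": s.locus, "A_n": s.A_n, "A_e": s.A_e, "H_e": s.H_e,
                     "H_o": s.H_o, "n_gene_copies": s.n_gene_copies})
    return pd.DataFrame(rows)


def alleles_segregating_per_form(dataset: GenotypeDataset,
                                 loci: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Observed allele counts per locus within each social form.

    ``loci`` restricts the comparison to a shared marker subset (e.g. the
    loci genotyped in both study arms).  Requires both forms to be present.
    """
    forms = {i.form for i in dataset.individuals}
    if forms != {"annual", "perennial"}:
        missing = {"annual", "perennial"} - forms
        raise NoDataError(f"both social forms required; missing {sorted(missing)}")
    loci = list(loci) if loci is not None else list(dataset.panel.locus_names)
    rows = []
    for locus in loci:
        row = {"locus": locus}
        for form in ("annual", "perennial"):
            inds = [i for i in dataset.individuals if i.form == form]
            try:
                row[f"A_n_{form}"] = int(allele_frequencies(dataset, locus, inds).size)
            except NoDataError:
                row[f"A_n_{form}"] = 0
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PairedComparison:
    t_statistic: float
    t_p: float
    wilcoxon_statistic: float
    wilcoxon_p: float
    n_pairs: int


def compare_forms_paired(values_a: Sequence[float], values_b: Sequence[float]) -> PairedComparison:
    """Paired t-test and Wilcoxon signed-rank test on per-locus value pairs.

    Two-sided p-values.  The Wilcoxon test is exact for up to 15 pairs and
    uses the normal approximation above that, mirroring common statistical
    package behaviour.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.allclose(a, b):
        # degenerate: no signal at all
        return PairedComparison(0.0, 1.0, 0.0, 1.0, a.size)
    t_stat, t_p = stats.ttest_rel(a, b)
    method = "exact" if a.size <= 15 else "approx"
    w_stat, w_p = stats.wilcoxon(a, b, alternative="two-sided", method=method)
    return PairedComparison(float(t_stat), float(t_p), float(w_stat), float(w_p), a.size)


def compare_forms_ranksum(values_a: Sequence[float], values_b: Sequence[float]):
    """Wilcoxon rank-sum (Mann-Whitney) alternative for unpaired readings."""
    res = stats.mannwhitneyu(values_a, values_b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
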