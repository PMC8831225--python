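"""Weir-Cockerham-style F-statistics: global, pairwise and hierarchical theta.

Per locus, variance components are estimated on allele indicators with a
nested random-effects ANOVA (see :mod:`colonykin.anova`): ``a`` among
groups, ``b`` among individuals within groups, ``c`` within individuals.
Multilocus estimates are ratios of summed components (never means of
per-locus ratios), with jackknife-over-loci standard errors and
bootstrap-over-loci confidence intervals.  Negative estimates are retained —
truncating at zero would bias downstream relatedness.

Haploid males enter as individuals carrying a single gene copy: they
contribute to the among-group frequency component but have no
within-individual term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .anova import nested_variance_components
from .datatypes import GenotypeDataset


class EstimationError(ValueError):
    pass


@dataclass(frozen=True)
class VarianceComponents:
    """Per-locus nested ANOVA components for one grouping."""
    locus: str
    a: float            # among groups
    b: float            # among individuals within groups
    c: float            # within individuals (gene copies)
    n_groups: int
    n_individuals: int
    n_gene_copies: int
    informative: bool   # False for monomorphic / degenerate loci

    @property
    def theta(self) -> float:
        tot = self.a + self.b + self.c
        return self.a / tot if tot != 0 else float("nan")


@dataclass(frozen=True)
class FstResult:
    grouping: str
    theta: float
    F_IT: float
    F_IS: float
    per_locus: pd.DataFrame      # columns locus, a, b, c, theta
    se_jackknife: float

    def __post_init__(self):
        for v in (self.theta, self.F_IT, self.F_IS):
            if np.isfinite(v) and not -1.0001 <= v <= 1.0001:
                raise EstimationError(f"F-statistic out of [-1, 1]: {v}")


@dataclass(frozen=True)
class HierarchicalFst:
    theta_S: float                     # between social forms
    theta_C: float                     # colonies within forms
    ci95_S: tuple
    ci95_C: tuple
    per_locus: pd.DataFrame
    n_boot: int
    seed: int


def _group_labels(dataset: GenotypeDataset, grouping) -> Callable:
    if callable(grouping):
        return grouping
    if grouping == "colony":
        return lambda ind: ind.colony
    if grouping == "form":
        return lambda ind: ind.form
    raise ValueError(f"unknown grouping {grouping!r}")


def variance_components(dataset: GenotypeDataset, locus: str, grouping="colony",
                        subset: Optional[Sequence] = None) -> VarianceComponents:
    """Single-locus nested components ``(a, b, c)`` for the given grouping.

    Requires at least two groups with data; monomorphic loci return zero
    components flagged uninformative.  All-haploid subsets collapse the
    individual level (``b = 0``).
    """
    labeler = _group_labels(dataset, grouping)
    inds = dataset.individuals if subset is None else list(subset)
    alleles, _, iid, dip = dataset.gene_copies(locus, inds)
    groups = np.array([labeler(ind) for ind in inds for _ in (ind.genotype.get(locus) or ())],
                      dtype=object)
    if alleles.size == 0:
        raise EstimationError(f"no data at locus {locus}")
    uniq_groups = np.unique(groups.astype(str))
    n_ind = np.unique(iid.astype(str)).size
    if uniq_groups.size < 2:
        raise EstimationError(f"grouping yields a single group at locus {locus}")
    if np.unique(alleles).size < 2:
        return VarianceComponents(locus, 0.0, 0.0, 0.0, uniq_groups.size, n_ind,
                                  alleles.size, informative=False)
    if dip.any():
        comps = nested_variance_components([groups, iid], alleles)
        a, b, c = comps
    else:
        a, c = nested_variance_components([groups], alleles)
        b = 0.0
    return VarianceComponents(locus, float(a), float(b), float(c),
                              uniq_groups.size, n_ind, alleles.size, informative=True)


def components_table(dataset: GenotypeDataset, grouping="colony",
                     subset: Optional[Sequence] = None,
                     loci: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Per-locus (a, b, c) components; uninformative loci carry zeros."""
    rows = []
    for locus in (loci or dataset.panel.locus_names):
        try:
            vc = variance_components(dataset, locus, grouping, subset)
        except EstimationError:
            continue
        rows.append({"locus": vc.locus, "a": vc.a, "b": vc.b, "c": vc.c,
                     "informative": vc.informative})
    return pd.DataFrame(rows)


def _ratio(tab: pd.DataFrame):
    sa, sb, sc = tab["a"].sum(), tab["b"].sum(), tab["c"].sum()
    tot = sa + sb + sc
    if tot == 0:
        return np.nan, np.nan, np.nan
    theta = sa / tot
    f_it = (sa + sb) / tot
    f_is = sb / (sb + sc) if (sb + sc) != 0 else np.nan
    return theta, f_it, f_is


def multilocus_theta(dataset: GenotypeDataset, grouping="colony",
                     subset: Optional[Sequence] = None,
                     loci: Optional[Sequence[str]] = None) -> FstResult:
    """Multilocus theta / F_IT / F_IS as ratios of summed components."""
    tab = components_table(dataset, grouping, subset, loci)
    info = tab[tab["informative"]] if len(tab) else tab
    if len(info) == 0:
        raise EstimationError("all loci uninformative for this grouping")
    theta, f_it, f_is = _ratio(info)
    per_locus = info.assign(theta=lambda d: d["a"] / (d["a"] + d["b"] + d["c"]))
    L = len(info)
    if L > 1:
        pseudo = np.array([_ratio(info.drop(index=i))[0] for i in info.index])
        se = float(np.sqrt((L - 1) / L * np.sum((pseudo - pseudo.mean()) ** 2)))
    else:
        se = float("nan")
    label = grouping if isinstance(grouping, str) else "custom"
    return FstResult(label, float(theta), float(f_it), float(f_is), per_locus, se)


def pairwise_fst(dataset: GenotypeDataset, caste: Optional[str] = None) -> pd.DataFrame:
    """Symmetric matrix of pairwise multilocus theta between colonies.

    Colonies without genotyped individuals are excluded; a pair sharing no
    informative locus gets NaN.  Pools all castes unless ``caste`` filters.
    """
    inds = dataset.individuals if caste is None else [i for i in dataset.individuals
                                                      if i.caste == caste]
    by_colony: dict[str, list] = {}
    for ind in inds:
        by_colony.setdefault(ind.colony, []).append(ind)
    colonies = sorted(c for c, v in by_colony.items() if v)
    mat = pd.DataFrame(0.0, index=colonies, columns=colonies)
    for i, ci in enumerate(colonies):
        for cj in colonies[i + 1:]:
            pair_inds = by_colony[ci] + by_colony[cj]
            try:
                res = multilocus_theta(dataset, "colony", subset=pair_inds)
                val = res.theta
            except EstimationError:
                val = np.nan
            mat.loc[ci, cj] = mat.loc[cj, ci] = val
    return mat


def hierarchical_theta(dataset: GenotypeDataset, n_boot: int = 1000,
                       seed: int = 0) -> HierarchicalFst:
    """Two-level nested analysis: social form over colony over individual.

    theta_S is the share of total allelic variance among social forms;
    theta_C measures colony differentiation within forms
    (``sigma2_C / (sigma2_C + sigma2_I + sigma2_G)``).  95% CIs come from a
    seeded bootstrap over loci on the ratio of summed components.
    """
    forms = {i.form for i in dataset.individuals}
    if len(forms) < 2:
        raise EstimationError("both social forms required for the hierarchical analysis")
    for form in forms:
        if len({i.colony for i in dataset.individuals if i.form == form}) < 2:
            raise EstimationError(f"form {form!r} has fewer than 2 colonies")
    rows = []
    inds = dataset.individuals
    for locus in dataset.panel.locus_names:
        alleles, col, iid, dip = dataset.gene_copies(locus)
        if alleles.size == 0 or np.unique(alleles).size < 2:
            continue
        frm = np.array([ind.form for ind in inds for _ in (ind.genotype.get(locus) or ())],
                       dtype=object)
        # a locus only informs the form level when both forms carry data at it
        if np.unique(frm.astype(str)).size < 2:
            continue
        try:
            if dip.any():
                s, c, i_, g = nested_variance_components([frm, col, iid], alleles)
            else:
                s, c, g = nested_variance_components([frm, col], alleles)
                i_ = 0.0
        except np.linalg.LinAlgError:
            continue
        rows.append({"locus": locus, "s": s, "c": c, "i": i_, "g": g})
    tab = pd.DataFrame(rows)
    if tab.empty:
        raise EstimationError("no informative loci")

    def ratios(t):
        tot = t[["s", "c", "i", "g"]].to_numpy().sum()
        within = t[["c", "i", "g"]].to_numpy().sum()
        th_s = t["s"].sum() / tot if tot != 0 else np.nan
        th_c = t["c"].sum() / within if within != 0 else np.nan
        return th_s, th_c

    theta_s, theta_c = ratios(tab)
    rng = np.random.default_rng(seed)
    L = len(tab)
    boots = np.empty((n_boot, 2))
    arr = tab[["s", "c", "i", "g"]].to_numpy()
    for bi in range(n_boot):
        pick = arr[rng.integers(0, L, size=L)].sum(axis=0)
        tot = pick.sum()
        within = pick[1:].sum()
        boots[bi, 0] = pick[0] / tot if tot != 0 else np.nan
        boots[bi, 1] = pick[1] / within if within != 0 else np.nan
    lo_s, hi_s = np.nanpercentile(boots[:, 0], [2.5, 97.5])
    lo_c, hi_c = np.nanpercentile(boots[:, 1], [2.5, 97.5])
    # intervals are widened to contain the point estimate in pathological
    # bootstrap distributions (tiny locus counts)
    ci_s = (min(lo_s, theta_s), max(hi_s, theta_s))
    ci_c = (min(lo_c, theta_c), max(hi_c, theta_c))
    return HierarchicalFst(float(theta_s), float(theta_c), ci_s, ci_c, tab, n_boot, seed)
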