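"""Group (nestmate) relatedness from F-statistics, after Pamilo.

For diploid nestmates the regression relatedness is ``r = 2*F_ST / (1 + F_IT)``
with colonies as groups.  For haploid males that transformation would give
2/3 for brothers; the correct haploid group relatedness is the allele
intraclass correlation theta itself, which equals the 0.5 pedigree
expectation for single-queen broods.  Per-locus estimates give the standard
error of the mean; significance between groups is judged by whether the
``r +/- 1.96*SEM`` intervals overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import GenotypeDataset
from .f_statistics import EstimationError, components_table, multilocus_theta
from .anova import nested_variance_components


@dataclass(frozen=True)
class RelatednessEstimate:
    group_label: str
    r: float
    per_locus_r: np.ndarray
    sem: float
    ci95: tuple
    n_individuals: int
    n_colonies: int

    def __post_init__(self):
        if np.isfinite(self.sem):
            lo, hi = self.ci95
            assert abs(lo - (self.r - 1.96 * self.sem)) < 1e-9
            assert abs(hi - (self.r + 1.96 * self.sem)) < 1e-9


def pamilo_relatedness(dataset: GenotypeDataset, caste: str,
                       form: Optional[str] = None,
                       ploidy_mode: str = "auto") -> RelatednessEstimate:
    """Within-colony relatedness of nestmates of one caste (optionally one form).

    Colonies are the grouping level; only colonies holding at least two
    individuals of the focal caste are used.  ``ploidy_mode`` is ``auto``
    (males -> haploid estimator), ``diploid`` or ``haploid``.
    """
    inds = [i for i in dataset.individuals
            if i.caste == caste and (form is None or i.form == form)]
    if not inds:
        raise EstimationError(f"no individuals of caste {caste!r}"
                              + (f" and form {form!r}" if form else ""))
    sizes = pd.Series([i.colony for i in inds]).value_counts()
    keep = set(sizes[sizes >= 2].index)
    inds = [i for i in inds if i.colony in keep]
    if len(keep) < 2:
        raise EstimationError("need >=2 colonies with >=2 individuals of the focal caste")

    if ploidy_mode == "auto":
        ploidy_mode = "haploid" if caste == "male" else "diploid"

    if ploidy_mode == "diploid":
        tab = components_table(dataset, "colony", subset=inds)
        info = tab[tab["informative"]]
        if info.empty:
            raise EstimationError("no informative loci")
        denom = 2 * info["a"] + 2 * info["b"] + info["c"]
        per_locus = (2 * info["a"] / denom).to_numpy()
        r = float(2 * info["a"].sum() / denom.sum())
    elif ploidy_mode == "haploid":
        per, num, den = [], 0.0, 0.0
        for locus in dataset.panel.locus_names:
            alleles, col, _, _ = dataset.gene_copies(locus, inds)
            if alleles.size == 0 or np.unique(alleles).size < 2:
                continue
            if np.unique(col.astype(str)).size < 2:
                continue
            a, w = nested_variance_components([col], alleles)
            if a + w == 0:
                continue
            per.append(a / (a + w))
            num += a
            den += a + w
        if not per:
            raise EstimationError("no informative loci")
        per_locus = np.asarray(per)
        r = float(num / den)
    else:
        raise ValueError(f"unknown ploidy_mode {ploidy_mode!r}")

    L = per_locus.size
    sem = float(np.std(per_locus, ddof=1) / np.sqrt(L)) if L > 1 else float("nan")
    ci = (r - 1.96 * sem, r + 1.96 * sem) if np.isfinite(sem) else (float("nan"),) * 2
    label = f"{caste}" + (f"/{form}" if form else "")
    return RelatednessEstimate(label, r, per_locus, sem, ci,
                               n_individuals=len(inds), n_colonies=len(keep))


def ci_overlap_significant(est_a: RelatednessEstimate, est_b: RelatednessEstimate):
    """Significant difference iff the 95% CIs (r +/- 1.96*SEM) are disjoint."""
    for est in (est_a, est_b):
        if not np.isfinite(est.sem):
            raise ValueError(f"estimate {est.group_label} has no SEM")
    lo_a, hi_a = est_a.ci95
    lo_b, hi_b = est_b.ci95
    disjoint = hi_a < lo_b or hi_b < lo_a
    report = {"a": {"label": est_a.group_label, "ci95": est_a.ci95},
              "b": {"label": est_b.group_label, "ci95": est_b.ci95},
              "significant": bool(disjoint)}
    return bool(disjoint), report


def expected_relatedness(queens: int, effective_paternity: float,
                         queen_relatedness: float = 0.0) -> dict:
    """Pedigree expectations for nestmate relatedness under haplodiploidy.

    With ``Q`` equally contributing queens of mutual relatedness ``g``, each
    with effective paternity ``m_e`` (mates unrelated to each other and to
    the queens):

    * sister-sister (workers or gynes): within a matriline
      ``0.25 + 0.5/m_e``; across matrilines ``g/4``.
    * brother-brother: within a matriline ``0.5``; across ``g/2``.

    A random nestmate pair is within-matriline with probability ``1/Q``.
    """
    Q, m_e, g = queens, effective_paternity, queen_relatedness
    if Q < 1 or m_e < 1 or not 0 <= g <= 1:
        raise ValueError("require Q >= 1, m_e >= 1, 0 <= g <= 1")
    within_f = 0.25 + 0.5 / m_e
    r_female = within_f / Q + (1 - 1 / Q) * (g / 4)
    r_male = 0.5 / Q + (1 - 1 / Q) * (g / 2)
    return {"worker": r_female, "gyne": r_female, "male": r_male}
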