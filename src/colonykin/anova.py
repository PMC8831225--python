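"""Method-of-moments variance components for nested random effects.

The estimator works on allele indicator variables: each gene copy is an
observation, nested inside individuals, colonies, and (optionally) social
forms.  For each allele we form the "uncorrected sums of squares of cell
means"

    T_g = sum over cells c of grouping g of  (cell total)^2 / n_c

and use the classical expectation (Henderson's method I for fully nested
classifications)

    E[T_g] = N mu^2 + sum_v sigma^2_v * k(g, v),
    k(g, v) = sum_{c in g} sum_{d in cells(v)} n_{c AND d}^2 / n_c ,

where v ranges over the nested random levels plus the gene-copy residual.
Subtracting the one-cell "grand" grouping removes the mu^2 term; solving the
resulting linear system gives the per-level components.  For an all-diploid
two-level design (colonies / individuals / copies) this reproduces the
Weir & Cockerham (1984) theta components exactly, including their unbalanced
sample-size corrections; haploid males simply enter as individuals carrying
a single gene copy.
"""

from __future__ import annotations

import numpy as np


def _cell_index(label_rows: list) -> np.ndarray:
    """Factorize a nested cell id from stacked label arrays (coarse first)."""
    keys = list(zip(*[list(map(str, arr)) for arr in label_rows]))
    _, inv = np.unique(np.array(["\x1f".join(k) for k in keys]), return_inverse=True)
    return inv


def nested_variance_components(level_labels: list, alleles: np.ndarray) -> np.ndarray:
    """Estimate variance components of a fully nested design on allele indicators.

    Parameters
    ----------
    level_labels:
        List of 1-D label arrays, coarsest first (e.g. ``[colony, individual]``
        or ``[form, colony, individual]``), one entry per gene copy.  Finer
        levels are interpreted nested within all coarser ones.
    alleles:
        Integer allele codes per gene copy.

    Returns
    -------
    ndarray of length ``len(level_labels) + 1``: one component per level plus
    the within-finest-level (gene-copy) residual, each summed over alleles.
    """
    alleles = np.asarray(alleles)
    N = alleles.size
    if N == 0:
        raise ValueError("no gene copies")
    uniq, acode = np.unique(alleles, return_inverse=True)
    A = uniq.size
    L = len(level_labels)

    # cell index per grouping: grand, level 0..L-1, observations
    groupings = [np.zeros(N, dtype=int)]
    for d in range(L):
        groupings.append(_cell_index(level_labels[: d + 1]))
    groupings.append(np.arange(N))  # finest: individual gene copies

    # per-grouping cell sizes and per-allele totals
    def cell_stats(inv):
        n_cells = inv.max() + 1
        sizes = np.bincount(inv, minlength=n_cells).astype(float)
        totals = np.zeros((n_cells, A))
        np.add.at(totals, (inv, acode), 1.0)
        return sizes, totals

    stats = [cell_stats(inv) for inv in groupings]

    def T(gi):
        sizes, totals = stats[gi]
        return (totals ** 2 / sizes[:, None]).sum(axis=0)  # per allele

    def k(gi, vi):
        """sum_c sum_d n_{cd}^2 / n_c for grouping gi vs level vi."""
        inv_g, inv_v = groupings[gi], groupings[vi]
        sizes_g = stats[gi][0]
        n_v = inv_v.max() + 1
        pair = inv_g.astype(np.int64) * n_v + inv_v
        n_cd = np.bincount(pair, minlength=(inv_g.max() + 1) * n_v).astype(float)
        # map each pair bin back to its g cell
        gi_of_pair = np.arange(n_cd.size) // n_v
        return float(np.sum(n_cd ** 2 / sizes_g[gi_of_pair]))

    # variance levels: level 0..L-1 and residual (the observation level)
    var_levels = list(range(1, L + 1)) + [L + 1]
    eq_groupings = list(range(1, L + 2))  # everything except grand

    K = np.empty((len(eq_groupings), len(var_levels)))
    D = np.empty((len(eq_groupings), A))
    T_grand = T(0)
    k_grand = [k(0, v) for v in var_levels]
    for r, g in enumerate(eq_groupings):
        D[r] = T(g) - T_grand
        for cidx, v in enumerate(var_levels):
            K[r, cidx] = k(g, v) - k_grand[cidx]

    if np.linalg.matrix_rank(K) < K.shape[0]:
        raise np.linalg.LinAlgError(
            "degenerate nested design (a level is confounded with another); "
            "drop the redundant level, e.g. the individual level for all-haploid data")
    comps = np.linalg.solve(K, D)  # (levels+residual) x alleles
    return comps.sum(axis=1)
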