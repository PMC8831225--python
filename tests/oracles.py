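"""Independent oracles for cross-checking the estimators.

Everything here is written from first principles (textbook closed forms,
exhaustive enumeration) and deliberately shares no code with the package
implementations it checks.
"""

from __future__ import annotations

import math
from itertools import permutations

import numpy as np


def wc84_components(groups):
    """Weir-Cockerham (1984) closed-form (a, b, c), summed over alleles.

    ``groups`` is a list of groups, each a list of diploid genotype tuples.
    Uses the published frequency/heterozygosity parameterisation, a
    different algebraic route than the package's sums-of-squares ANOVA.
    """
    r = len(groups)
    alleles = sorted({a for g in groups for geno in g for a in geno})
    n = np.array([len(g) for g in groups], dtype=float)
    nbar = n.mean()
    nc = (r * nbar - (n ** 2).sum() / (r * nbar)) / (r - 1)
    A = B = C = 0.0
    for al in alleles:
        p = np.array([np.mean([geno.count(al) / 2 for geno in g]) for g in groups])
        h = np.array([np.mean([al in geno and geno[0] != geno[1] for geno in g])
                      for g in groups])
        pbar = (n * p).sum() / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n * h).sum() / (r * nbar)
        a = (nbar / nc) * (s2 - (1 / (nbar - 1)) *
                           (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2
                                   - ((2 * nbar - 1) / (4 * nbar)) * hbar)
        c = hbar / 2
        A += a
        B += b
        C += c
    return A, B, C


def haploid_oneway_components(groups):
    """One-level ANOVA components (among, within) for haploid gene copies.

    ``groups`` is a list of lists of single allele values.  Classic
    mean-square moment estimator: a = (MSP - MSW) / n_c.
    """
    r = len(groups)
    n = np.array([len(g) for g in groups], dtype=float)
    N = n.sum()
    nc = (N - (n ** 2).sum() / N) / (r - 1)
    alleles = sorted({a for g in groups for a in g})
    A = W = 0.0
    for al in alleles:
        p = np.array([np.mean([x == al for x in g]) for g in groups])
        pbar = (n * p).sum() / N
        msp = (n * (p - pbar) ** 2).sum() / (r - 1)
        msw = (n * p * (1 - p)).sum() / (N - r)
        A += (msp - msw) / nc
        W += msw
    return A, W


def exact_prob_test_2x2(table):
    """Two-sided probability-ordering exact p for a 2x2 table by enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def logp(x):
        y, z, w = r1 - x, c1 - x, r2 - (c1 - x)
        if min(y, z, w) < 0:
            return None
        return (math.lgamma(r1 + 1) + math.lgamma(r2 + 1) + math.lgamma(c1 + 1)
                + math.lgamma(n - c1 + 1) - math.lgamma(n + 1)
                - math.lgamma(x + 1) - math.lgamma(y + 1)
                - math.lgamma(z + 1) - math.lgamma(w + 1))

    obs = logp(a)
    total = 0.0
    for x in range(min(r1, c1) + 1):
        lp = logp(x)
        if lp is not None and lp <= obs + 1e-9:
            total += math.exp(lp)
    return min(total, 1.0)


def mantel_exhaustive_p(G, D):
    """Exact one-sided Mantel p over all n! simultaneous relabelings."""
    G = np.asarray(G, float)
    D = np.asarray(D, float)
    n = G.shape[0]
    iu = np.triu_indices(n, k=1)
    dv = D[iu]

    def corr(perm):
        gv = G[np.ix_(perm, perm)][iu]
        return np.corrcoef(gv, dv)[0, 1]

    obs = corr(tuple(range(n)))
    count = sum(corr(p) >= obs - 1e-12 for p in permutations(range(n)))
    return count / math.factorial(n)


def spherical_law_of_cosines_km(lat1, lon1, lat2, lon2, radius=6371.0088):
    """Great-circle distance via the spherical law of cosines (not haversine)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    x = math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(dl)
    return radius * math.acos(min(1.0, max(-1.0, x)))
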