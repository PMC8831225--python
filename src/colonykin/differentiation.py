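"""Exact tests of genic/genotypic differentiation and p-value combination.

The exact test conditions on the margins of the genotype-by-class
contingency table.  Under the null every table with the observed margins has
the multiple hypergeometric probability

    P(T) = prod(row totals!) * prod(col totals!) / (N! * prod(cells!))

and the two-sided p-value is the total probability of tables no more
probable than the observed one (the "probability ordering" convention of the
classical exact-test programs).  Small tables are enumerated exhaustively;
larger ones are sampled with a Metropolis Markov chain over +/-1 rectangle
moves with a dememorization phase and batch-mean Monte-Carlo errors
(defaults 10,000 dememorization steps, 100 batches of 5,000 iterations).

Across loci p-values combine by Fisher's product method (chi-square with
df = 2L); across colonies by Stouffer's Z-transform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .datatypes import GenotypeDataset


@dataclass(frozen=True)
class ExactTestResult:
    locus: str
    p: float
    mc_se: float          # 0.0 when exhaustively enumerated
    table_dims: tuple
    method: str           # "enumeration" | "mcmc" | "degenerate"

    def __post_init__(self):
        assert 0.0 <= self.p <= 1.0


@dataclass(frozen=True)
class CombinedP:
    method: str           # "fisher" | "stouffer"
    statistic: float      # chi-square or Z
    df: Optional[int]
    p: float
    k: int


# ---------------------------------------------------------------------------
# table machinery
# ---------------------------------------------------------------------------

def _log_table_prob(table: np.ndarray, log_const: float) -> float:
    return log_const - sum(math.lgamma(v + 1) for v in table.ravel())


def _log_const(table: np.ndarray) -> float:
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    return (sum(math.lgamma(v + 1) for v in rows)
            + sum(math.lgamma(v + 1) for v in cols)
            - math.lgamma(n + 1))


def count_tables(row_sums: Sequence[int], col_sums: Sequence[int],
                 cap: int = 10 ** 6) -> int:
    """Number of contingency tables with the given margins, capped at ``cap``.

    Dynamic program over rows; the state is the remaining column sums.  Used
    to decide between exhaustive enumeration and the Markov chain.
    """
    cols = tuple(col_sums)
    rows = list(row_sums)

    from functools import lru_cache

    def row_fillings(row_total: int, remaining: tuple):
        if len(remaining) == 1:
            if row_total <= remaining[0]:
                yield (row_total,)
            return
        for v in range(min(row_total, remaining[0]) + 1):
            for rest in row_fillings(row_total - v, remaining[1:]):
                yield (v,) + rest

    @lru_cache(maxsize=None)
    def count(ri: int, remaining: tuple) -> int:
        if ri == len(rows) - 1:
            return 1  # last row forced by margins (feasibility guaranteed)
        total = 0
        for filling in row_fillings(rows[ri], remaining):
            new_rem = tuple(r - v for r, v in zip(remaining, filling))
            total += count(ri + 1, new_rem)
            if total > cap:
                return cap + 1
        return total

    return count(0, cols)


def _enumerate_pvalue(table: np.ndarray) -> float:
    """Exhaustive two-sided exact p by probability ordering."""
    rows = table.sum(axis=1)
    cols = tuple(table.sum(axis=0))
    log_c = _log_const(table)
    obs_logp = _log_table_prob(table, log_c)
    tol = 1e-9

    def row_fillings(row_total, remaining):
        if len(remaining) == 1:
            if row_total <= remaining[0]:
                yield (row_total,)
            return
        for v in range(min(row_total, remaining[0]) + 1):
            for rest in row_fillings(row_total - v, remaining[1:]):
                yield (v,) + rest

    total_p = 0.0

    def rec(ri, remaining, partial_lgam):
        nonlocal total_p
        if ri == len(rows) - 1:
            lg = partial_lgam + sum(math.lgamma(v + 1) for v in remaining)
            logp = log_c - lg
            if logp <= obs_logp + tol:
                total_p += math.exp(logp)
            return
        for filling in row_fillings(rows[ri], remaining):
            new_rem = tuple(r - v for r, v in zip(remaining, filling))
            rec(ri + 1, new_rem, partial_lgam + sum(math.lgamma(v + 1) for v in filling))

    rec(0, cols, 0.0)
    return min(total_p, 1.0)


def _mcmc_pvalue(table: np.ndarray, rng: np.random.Generator,
                 dememorization: int, batches: int, batch_size: int):
    """GENEPOP-style Markov chain estimate of the exact p-value."""
    T = [list(map(int, row)) for row in table]  # plain lists: fastest scalar access
    nr, nc = table.shape
    log_c = _log_const(table)
    obs_logp = _log_table_prob(table, log_c)
    cur_logp = obs_logp
    tol = 1e-9
    log = math.log

    def run_block(n_steps, count_hits):
        """Advance the chain n_steps; randomness pregenerated in bulk."""
        nonlocal cur_logp
        ri1 = rng.integers(0, nr, size=n_steps)
        ri2 = (ri1 + rng.integers(1, nr, size=n_steps)) % nr
        rj1 = rng.integers(0, nc, size=n_steps)
        rj2 = (rj1 + rng.integers(1, nc, size=n_steps)) % nc
        direction = rng.random(n_steps) < 0.5
        accept_u = rng.random(n_steps)
        hits = 0
        threshold = obs_logp + tol
        for s in range(n_steps):
            i1, i2, j1, j2 = ri1[s], ri2[s], rj1[s], rj2[s]
            if direction[s]:
                j1, j2 = j2, j1
            # propose +1 on (i1,j1),(i2,j2); -1 on (i1,j2),(i2,j1)
            d1, d2 = T[i1][j2], T[i2][j1]
            if d1 and d2:
                ratio = (d1 * d2) / ((T[i1][j1] + 1) * (T[i2][j2] + 1))
                if ratio >= 1.0 or accept_u[s] < ratio:
                    T[i1][j1] += 1; T[i2][j2] += 1
                    T[i1][j2] = d1 - 1; T[i2][j1] = d2 - 1
                    cur_logp += log(ratio)
            if count_hits and cur_logp <= threshold:
                hits += 1
        return hits

    run_block(dememorization, count_hits=False)
    batch_means = np.empty(batches)
    for b in range(batches):
        batch_means[b] = run_block(batch_size, count_hits=True) / batch_size
    p = float(batch_means.mean())
    se = float(batch_means.std(ddof=1) / math.sqrt(batches))
    return min(max(p, 0.0), 1.0), se


def exact_table_test(table: np.ndarray, seed: int = 0,
                     dememorization: int = 10_000, batches: int = 100,
                     batch_size: int = 5_000,
                     enumeration_limit: int = 10 ** 6) -> ExactTestResult:
    """Conditional exact test on an arbitrary contingency table.

    Enumeration is used automatically when the number of tables sharing the
    observed margins is at most ``enumeration_limit``; otherwise the Markov
    chain (seeded) is run and a batch-mean Monte-Carlo SE is reported.
    """
    table = np.asarray(table, dtype=np.int64)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return ExactTestResult("", 1.0, 0.0, tuple(table.shape), "degenerate")
    support = count_tables(table.sum(axis=1), table.sum(axis=0), cap=enumeration_limit)
    if support <= enumeration_limit:
        p = _enumerate_pvalue(table)
        return ExactTestResult("", p, 0.0, tuple(table.shape), "enumeration")
    rng = np.random.default_rng(seed)
    p, se = _mcmc_pvalue(table, rng, dememorization, batches, batch_size)
    return ExactTestResult("", p, se, tuple(table.shape), "mcmc")


# ---------------------------------------------------------------------------
# dataset-level tests
# ---------------------------------------------------------------------------

def genotype_class_table(dataset: GenotypeDataset, locus: str, partition) -> np.ndarray:
    """Genotype-count x class contingency table at one locus.

    ``partition`` maps an :class:`Individual` to a class label (or None to
    drop).  Genotypes are unordered allele pairs (single alleles for males);
    rare genotypes are never pooled.
    """
    classes: dict = {}
    for ind in dataset.individuals:
        label = partition(ind)
        g = ind.genotype.get(locus)
        if label is None or g is None:
            continue
        key = tuple(sorted(g))
        classes.setdefault(label, {}).setdefault(key, 0)
        classes[label][key] += 1
    labels = sorted(classes)
    genotypes = sorted({g for d in classes.values() for g in d})
    tab = np.zeros((len(genotypes), len(labels)), dtype=np.int64)
    for j, lab in enumerate(labels):
        for i, g in enumerate(genotypes):
            tab[i, j] = classes[lab].get(g, 0)
    return tab


def genotypic_exact_test(dataset: GenotypeDataset, locus: str, partition,
                         seed: int = 0, **mc_kwargs) -> ExactTestResult:
    """Exact test of genotypic differentiation between partition classes."""
    tab = genotype_class_table(dataset, locus, partition)
    if tab.size == 0 or tab.shape[1] < 2:
        raise ValueError(f"partition yields fewer than 2 non-empty classes at {locus}")
    if tab.shape[0] < 2:
        # monomorphic genotype distribution: uninformative
        return ExactTestResult(locus, 1.0, 0.0, tuple(tab.shape), "degenerate")
    res = exact_table_test(tab, seed=seed, **mc_kwargs)
    return ExactTestResult(locus, res.p, res.mc_se, res.table_dims, res.method)


def caste_differentiation_test(dataset: GenotypeDataset, colony: str,
                               classes=("gyne", "worker"), seed: int = 0,
                               **mc_kwargs):
    """Per-locus gyne-vs-worker exact tests in one colony, Fisher-combined.

    Returns ``(combined: CombinedP, per_locus: list[ExactTestResult])`` with
    only informative loci entering the combination.
    """
    def partition(ind):
        if ind.colony != colony or ind.caste not in classes:
            return None
        return ind.caste

    per_locus = []
    for k, locus in enumerate(dataset.panel.locus_names):
        try:
            res = genotypic_exact_test(dataset, locus, partition,
                                       seed=seed + 1000 * k, **mc_kwargs)
        except ValueError:
            continue
        if res.method != "degenerate":
            per_locus.append(res)
    if not per_locus:
        raise ValueError(f"no informative loci for colony {colony}")
    combined = combine_fisher([r.p for r in per_locus])
    return combined, per_locus


def combine_fisher(p_values: Sequence[float]) -> CombinedP:
    """Fisher's product method: chi2 = -2 sum ln p, df = 2k."""
    p = np.asarray(p_values, dtype=float)
    if np.any(p > 1) or np.any(p < 0):
        raise ValueError("p-values must lie in [0, 1]")
    tiny = np.finfo(float).tiny
    if np.any(p == 0):
        import warnings
        warnings.warn("p = 0 clamped to the smallest positive float for Fisher combination")
        p = np.clip(p, tiny, 1.0)
    chi2 = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return CombinedP("fisher", chi2, df, float(stats.chi2.sf(chi2, df)), p.size)


def combine_stouffer(p_values: Sequence[float]) -> CombinedP:
    """Stouffer's Z-transform: Z = sum Phi^-1(1 - p_i) / sqrt(k), one-sided.

    Small input p-values (strong evidence) map to large positive Z; the
    combined p is the upper normal tail.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("Stouffer combination requires p-values strictly inside (0, 1)")
    z = float(stats.norm.isf(p).sum() / np.sqrt(p.size))
    return CombinedP("stouffer", z, None, float(stats.norm.sf(z)), p.size)


def satellite_merge_test(dataset: GenotypeDataset, parent_colony: str,
                         satellite_colony: str, alpha: float = 0.05,
                         seed: int = 0, **mc_kwargs) -> dict:
    """Genotypic differentiation between a parent nest and its satellite.

    Runs the per-caste exact test (Fisher-combined across loci) for every
    caste present in both nests and recommends merging when no caste rejects
    at ``alpha``.  Castes absent from either nest are skipped with a note.
    """
    sat = dataset.colony_map.get(satellite_colony)
    if sat is None or sat.satellite_of != parent_colony:
        raise ValueError(f"{satellite_colony} is not registered as a satellite of {parent_colony}")
    out = {"per_caste": {}, "skipped": []}
    for caste in ("worker", "gyne", "male"):
        present = {c: any(i.colony == c and i.caste == caste for i in dataset.individuals)
                   for c in (parent_colony, satellite_colony)}
        if not all(present.values()):
            out["skipped"].append(caste)
            continue

        def partition(ind, caste=caste):
            if ind.caste != caste or ind.colony not in (parent_colony, satellite_colony):
                return None
            return ind.colony

        per_locus = []
        for k, locus in enumerate(dataset.panel.locus_names):
            try:
                res = genotypic_exact_test(dataset, locus, partition,
                                           seed=seed + 1000 * k, **mc_kwargs)
            except ValueError:
                continue
            if res.method != "degenerate":
                per_locus.append(res)
        if not per_locus:
            out["skipped"].append(caste)
            continue
        combined = combine_fisher([r.p for r in per_locus])
        out["per_caste"][caste] = combined.p
    out["merge"] = all(p > alpha for p in out["per_caste"].values()) if out["per_caste"] else False
    return out
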