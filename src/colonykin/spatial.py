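"""Great-circle distances between colonies and isolation-by-distance tests.

Geographic distances are haversine great circles on a sphere of mean Earth
radius 6371.0088 km.  Isolation by distance is tested with a Mantel matrix
permutation test (one-sided, positive association, the convention for IBD)
on the off-diagonal pairs, with Spearman's rank correlation reported
alongside.  The genetic matrix can enter raw (F_ST vs km) or linearised
(F_ST/(1-F_ST) vs ln km).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class MantelResult:
    statistic: float
    p_perm: float
    n_perm: int
    spearman_rs: float
    seed: int

    def __post_init__(self):
        assert -1.0 - 1e-12 <= self.statistic <= 1.0 + 1e-12
        assert 0.0 < self.p_perm <= 1.0


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance between two WGS84 decimal-degree points, in km."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    h = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


def haversine_matrix(colonies: Sequence) -> pd.DataFrame:
    """Symmetric colony-by-colony great-circle distance matrix (km).

    ``colonies`` is a sequence of :class:`ColonyMeta`; colonies without
    coordinates are excluded with a warning.
    """
    import warnings
    usable = []
    for c in colonies:
        if c.latitude is None or c.longitude is None:
            warnings.warn(f"colony {c.colony_id} lacks coordinates; excluded from distances")
            continue
        usable.append(c)
    ids = [c.colony_id for c in usable]
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    for i, ci in enumerate(usable):
        for cj in usable[i + 1:]:
            d = haversine_km(ci.latitude, ci.longitude, cj.latitude, cj.longitude)
            mat.loc[ci.colony_id, cj.colony_id] = mat.loc[cj.colony_id, ci.colony_id] = d
    return mat


def _offdiag(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices_from(mat, k=1)
    return mat[iu]


def mantel_test(genetic: pd.DataFrame, distance: pd.DataFrame,
                n_perm: int = 9_999, seed: int = 0,
                transform: str = "raw") -> MantelResult:
    """One-sided Mantel permutation test of genetic vs geographic distance.

    Matrices must be symmetric with the same colony ordering.  The statistic
    is the Pearson correlation of the off-diagonal pairs; the permutation p
    is ``(# permutations >= observed + 1) / (n_perm + 1)`` over simultaneous
    row/column relabelings of the genetic matrix.  ``transform='rousset'``
    correlates F_ST/(1-F_ST) with ln(km).
    """
    if list(genetic.index) != list(distance.index) or genetic.shape != distance.shape:
        raise ValueError("matrices must share shape and colony order")
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    G = genetic.to_numpy(dtype=float).copy()
    D = distance.to_numpy(dtype=float).copy()
    if transform == "rousset":
        with np.errstate(divide="ignore", invalid="ignore"):
            G = G / (1.0 - G)
            D = np.log(D, where=D > 0, out=np.zeros_like(D))
    elif transform != "raw":
        raise ValueError(f"unknown transform {transform!r}")

    gv, dv = _offdiag(G), _offdiag(D)
    if not (np.all(np.isfinite(gv)) and np.all(np.isfinite(dv))):
        raise ValueError("matrices contain non-finite off-diagonal entries; "
                         "drop the affected colonies first")
    obs = float(np.corrcoef(gv, dv)[0, 1])
    rs = float(stats.spearmanr(gv, dv).statistic)

    rng = np.random.default_rng(seed)
    n = G.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pv = _offdiag(G[np.ix_(perm, perm)])
        r = np.corrcoef(pv, dv)[0, 1]
        if r >= obs - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return MantelResult(obs, float(p), n_perm, rs, seed)
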