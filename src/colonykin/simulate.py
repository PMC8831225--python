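"""Forward simulator of annual and perennial social-wasp colony genetics.

The generative model mirrors the biology of the southern yellowjacket:

* **annual colonies** are headed by a single queen (monogyny) mated to
  several males (polyandry).  Daughters receive one maternal allele and the
  paternal allele; haploid sons receive a single maternal allele.
* **perennial colonies** are headed by the foundress plus ``Q - 1`` queens
  recruited from her own gynes (natal recruitment, one overlapping
  generation), so the whole colony shares one matriline and one mtDNA
  haplotype; every recruited queen mates with fresh non-nestmate males drawn
  from the population.  A ``foreign`` recruitment mode draws unrelated
  queens instead, each importing her own matriline.
* per-queen paternity shares are equal or Dirichlet-distributed; the truth
  record reports the realised effective paternity ``m_e = 1 / sum q_i^2``
  per queen, so pedigree expectations such as ``r = 0.25 + 0.5/m_e`` can be
  recomputed exactly.
* optional caste skew gives each queen separate contributions to gynes and
  workers, the scenario behind caste-differentiation tests.

All randomness flows from ``config.seed``; two runs with the same config are
identical.  The truth record carries every pedigree assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .datatypes import (ColonyMeta, GenotypeDataset, Individual, MarkerPanel,
                        SequenceAlignment)

# Locus panel emulating a 10-marker microsatellite study: names, observed
# allele counts and amplicon size ranges typical of the markers.
DEFAULT_LOCI = (
    ("LIST2003", 35, (172, 226)),
    ("LIST2004", 15, (119, 160)),
    ("LIST2007", 30, (141, 194)),
    ("LIST2008", 29, (125, 161)),
    ("LIST2013", 26, (169, 205)),
    ("LIST2015", 9, (162, 174)),
    ("LIST2019", 3, (122, 133)),
    ("LIST2020", 21, (324, 415)),
    ("RUFA5", 13, (154, 175)),
    ("VMA6", 29, (269, 303)),
)

#: Founding-matriline mtDNA haplotype frequencies in the population pool
#: (five haplotypes, skewed spectrum).
DEFAULT_MTDNA_FREQS = (0.45, 0.25, 0.15, 0.10, 0.05)


@dataclass(frozen=True)
class SimConfig:
    """Study-condition defaults for the colony simulator.

    ``queens=20`` and ``mates=4`` reflect heavily polygynous perennial
    colonies and moderately polyandrous queens; annual colonies always get a
    single queen regardless of ``queens``.
    """

    n_annual: int = 13
    n_perennial: int = 8
    queens: int = 20                      # Q per perennial colony
    mates: int = 4                        # m per queen
    paternity_alpha: Optional[float] = None   # Dirichlet conc. for paternity shares (None = equal)
    brood_alpha: Optional[float] = None       # per-queen brood shares (None = equal)
    caste_skew_alpha: Optional[float] = None  # separate gyne shares (None = same as workers)
    queen_recruitment: str = "natal"          # or "foreign"
    allele_counts: Sequence[int] = tuple(k for _, k, _ in DEFAULT_LOCI)
    freq_law: str = "dirichlet"               # or "equifrequent"
    dirichlet_alpha: float = 1.0
    workers_annual: int = 40
    workers_perennial: int = 78
    gynes_perennial: int = 12
    males_perennial: int = 9
    mtdna_samples_annual: int = 2
    mtdna_samples_perennial: int = 14
    mtdna_freqs: Sequence[float] = DEFAULT_MTDNA_FREQS
    mtdna_length: int = 458
    annual_locus_subset: Optional[int] = None  # leading loci genotyped in annual colonies
    missing_rate: float = 0.0
    planted_foreign_worker: bool = False       # inject one foreign-matriline worker
    seed: int = 0


@dataclass
class ColonyPlan:
    name: str
    form: str
    latitude: float
    longitude: float
    n_workers: int
    n_gynes: int
    n_males: int
    n_mtdna: int


@dataclass
class SimResult:
    dataset: GenotypeDataset
    alignment: SequenceAlignment
    truth: dict
    config: SimConfig


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _population_loci(config: SimConfig, rng: np.random.Generator):
    loci = []
    for (name, _, (lo, hi)), k in zip(DEFAULT_LOCI, config.allele_counts):
        labels = np.sort(rng.choice(np.arange(lo, hi + 1), size=k, replace=False))
        if config.freq_law == "equifrequent":
            freqs = np.full(k, 1.0 / k)
        elif config.freq_law == "dirichlet":
            freqs = rng.dirichlet(np.full(k, config.dirichlet_alpha))
        else:
            raise ValueError(f"unknown freq_law {config.freq_law!r}")
        loci.append({"name": name, "labels": labels, "freqs": freqs})
    return loci


def _draw_female(loci, rng):
    return {l["name"]: tuple(rng.choice(l["labels"], size=2, p=l["freqs"])) for l in loci}


def _draw_male(loci, rng):
    return {l["name"]: (int(rng.choice(l["labels"], p=l["freqs"])),) for l in loci}


def _shares(k: int, alpha: Optional[float], rng) -> np.ndarray:
    if k == 1:
        return np.ones(1)
    if alpha is None:
        return np.full(k, 1.0 / k)
    return rng.dirichlet(np.full(k, float(alpha)))


def _mtdna_pool(config: SimConfig, rng: np.random.Generator):
    """Five-haplotype pool: a base sequence plus substitutions at five sites
    inside the standard analysis window."""
    n = len(config.mtdna_freqs)
    base = rng.choice(list("ACGT"), size=config.mtdna_length)
    lo = 120 if config.mtdna_length >= 458 else 0
    hi = min(lo + 338, config.mtdna_length)
    sites = np.sort(rng.choice(np.arange(lo, hi), size=n, replace=False))
    haps = []
    for i in range(n):
        seq = base.copy()
        if i > 0:
            alt = {"A": "G", "G": "A", "C": "T", "T": "C"}
            seq[sites[i - 1]] = alt[seq[sites[i - 1]]]
            if i == n - 1:  # last haplotype differs at two sites
                seq[sites[n - 1]] = alt[seq[sites[n - 1]]]
        haps.append((f"hap{i + 1}", "".join(seq)))
    return haps, np.asarray(config.mtdna_freqs, dtype=float)


# ---------------------------------------------------------------------------
# main entry points
# ---------------------------------------------------------------------------

def default_plans(config: SimConfig) -> list:
    """Colony plans implied by the config (uniform sample sizes per form)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0]))
    plans = []
    for i in range(config.n_perennial):
        plans.append(ColonyPlan(f"P{i + 1:02d}", "perennial",
                                float(rng.uniform(31.0, 34.0)), float(rng.uniform(-88.0, -85.0)),
                                config.workers_perennial, config.gynes_perennial,
                                config.males_perennial, config.mtdna_samples_perennial))
    for i in range(config.n_annual):
        plans.append(ColonyPlan(f"A{i + 1:02d}", "annual",
                                float(rng.uniform(33.5, 34.7)), float(rng.uniform(-84.7, -83.3)),
                                config.workers_annual, 0, 0, config.mtdna_samples_annual))
    return plans


def simulate_dataset(config: SimConfig, plans: Optional[Sequence[ColonyPlan]] = None) -> SimResult:
    """Simulate a full study dataset: genotypes, mtDNA alignment, truth record."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    loci = _population_loci(config, rng)
    hap_pool, hap_freqs = _mtdna_pool(config, rng)
    hap_seq = dict(hap_pool)
    plans = list(plans) if plans is not None else default_plans(config)

    individuals = []
    colonies = []
    records = []
    truth = {"colonies": {}, "individuals": {}, "loci": [
        {"name": l["name"], "labels": l["labels"].tolist(), "freqs": l["freqs"].tolist()}
        for l in loci], "seed": config.seed}

    for plan in plans:
        colonies.append(ColonyMeta(plan.name, plan.form, plan.latitude, plan.longitude))
        Q = config.queens if plan.form == "perennial" else 1

        # --- queens and their mates --------------------------------------
        queens = []
        if plan.form == "perennial" and config.queen_recruitment == "natal" and Q > 1:
            foundress = _draw_female(loci, rng)
            f_mates = [_draw_male(loci, rng) for _ in range(config.mates)]
            f_shares = _shares(config.mates, config.paternity_alpha, rng)
            founder_hap = hap_pool[rng.choice(len(hap_pool), p=hap_freqs)][0]
            queens.append({"genotype": foundress, "haplotype": founder_hap,
                           "mates": f_mates, "shares": f_shares})
            for _ in range(Q - 1):
                # recruited queen: a daughter of the foundress line
                geno = {}
                father = f_mates[rng.choice(config.mates, p=f_shares)]
                for l in loci:
                    nm = l["name"]
                    geno[nm] = (foundress[nm][rng.integers(2)], father[nm][0])
                queens.append({"genotype": geno, "haplotype": founder_hap,
                               "mates": [_draw_male(loci, rng) for _ in range(config.mates)],
                               "shares": _shares(config.mates, config.paternity_alpha, rng)})
        else:
            for _ in range(Q):
                hap = hap_pool[rng.choice(len(hap_pool), p=hap_freqs)][0]
                queens.append({"genotype": _draw_female(loci, rng), "haplotype": hap,
                               "mates": [_draw_male(loci, rng) for _ in range(config.mates)],
                               "shares": _shares(config.mates, config.paternity_alpha, rng)})

        worker_w = _shares(Q, config.brood_alpha, rng)
        gyne_w = (_shares(Q, config.caste_skew_alpha, rng)
                  if config.caste_skew_alpha is not None else worker_w)
        truth["colonies"][plan.name] = {
            "form": plan.form, "n_queens": Q,
            "queens": [{"genotype": {k: tuple(map(int, v)) for k, v in q["genotype"].items()},
                        "haplotype": q["haplotype"],
                        "mates": [{k: (int(v[0]),) for k, v in m.items()} for m in q["mates"]],
                        "paternity_shares": q["shares"].tolist(),
                        "m_e": float(1.0 / np.sum(q["shares"] ** 2))}
                       for q in queens],
            "worker_weights": worker_w.tolist(), "gyne_weights": gyne_w.tolist()}

        # --- brood --------------------------------------------------------
        def make_offspring(caste: str, index: int):
            weights = gyne_w if caste == "gyne" else worker_w
            qi = int(rng.choice(Q, p=weights))
            queen = queens[qi]
            geno = {}
            if caste == "male":
                fi = None
                for l in loci:
                    nm = l["name"]
                    geno[nm] = (int(queen["genotype"][nm][rng.integers(2)]),)
            else:
                fi = int(rng.choice(config.mates, p=queen["shares"]))
                father = queen["mates"][fi]
                for l in loci:
                    nm = l["name"]
                    geno[nm] = (int(queen["genotype"][nm][rng.integers(2)]),
                                int(father[nm][0]))
            iid = f"{plan.name}_{caste[0]}{index:03d}"
            truth["individuals"][iid] = {"colony": plan.name, "caste": caste,
                                         "mother": qi, "father": fi}
            return iid, geno, queen["haplotype"]

        members = []
        for caste, count in (("worker", plan.n_workers), ("gyne", plan.n_gynes),
                             ("male", plan.n_males)):
            for j in range(count):
                members.append((*make_offspring(caste, j + 1), caste))

        # annual colonies may be genotyped at a marker subset only
        typed = {l["name"] for l in loci}
        if plan.form == "annual" and config.annual_locus_subset is not None:
            typed = {l["name"] for l in loci[: config.annual_locus_subset]}

        # mtDNA subset: first n_mtdna members in sampling order
        sequenced = {m[0] for m in members[: plan.n_mtdna]}
        for iid, geno, hap, caste in members:
            final = {}
            for l in loci:
                nm = l["name"]
                if nm not in typed or rng.random() < config.missing_rate:
                    final[nm] = None
                else:
                    g = geno[nm]
                    final[nm] = g if len(g) == 1 else tuple(sorted(g))
            individuals.append(Individual(iid, plan.name, caste, plan.form, final,
                                          mtdna_haplotype=hap if iid in sequenced else None))
            if iid in sequenced:
                records.append((iid, hap_seq[hap]))

    # planted foreign-matriline worker (drift / contamination scenario)
    if config.planted_foreign_worker:
        target = next(i for i, ind in enumerate(individuals)
                      if ind.form == "perennial" and ind.caste == "worker"
                      and ind.mtdna_haplotype is not None)
        ind = individuals[target]
        foreign = next(h for h, _ in hap_pool if h != ind.mtdna_haplotype)
        individuals[target] = Individual(ind.id, ind.colony, ind.caste, ind.form,
                                         dict(ind.genotype), mtdna_haplotype=foreign)
        records = [(rid, hap_seq[foreign]) if rid == ind.id else (rid, s)
                   for rid, s in records]
        truth["planted_foreign_worker"] = ind.id

    panel = MarkerPanel.from_genotypes([l["name"] for l in loci], individuals)
    dataset = GenotypeDataset(panel, individuals, colonies)
    alignment = SequenceAlignment(tuple(records))
    return SimResult(dataset, alignment, truth, config)


# ---------------------------------------------------------------------------
# study-shaped preset
# ---------------------------------------------------------------------------

# (colony, lat, lon, workers, gynes, males, mtdna) for the perennial arm and
# (colony, lat, lon, workers, mtdna) for the annual arm of the emulated
# sampling design.
PERENNIAL_DESIGN = (
    ("HA", 33.1175, -86.1227, 80, 0, 0, 13),
    ("KL", 32.1253, -85.9370, 80, 48, 0, 24),
    ("MA", 33.9681, -87.8050, 82, 2, 24, 24),
    ("MC", 33.2197, -86.3014, 80, 4, 30, 30),
    ("MO", 32.3855, -86.3099, 75, 33, 18, 56),
    ("SP", 32.4669, -87.2127, 66, 0, 0, 14),
    ("ST", 31.1180, -87.4632, 80, 5, 0, 18),
    ("WA", 31.0482, -87.7152, 80, 3, 0, 16),
)
ANNUAL_DESIGN = (
    ("2", 33.8952, -84.6341, 40, 2), ("4", 33.9926, -84.2873, 11, 2),
    ("5", 33.7916, -84.3741, 40, 2), ("6", 33.7916, -84.3741, 40, 2),
    ("11", 34.5877, -84.0029, 40, 2), ("12", 34.5895, -84.0051, 40, 2),
    ("21", 33.7330, -84.3737, 40, 2), ("22", 33.7330, -84.3737, 40, 2),
    ("26", 34.0933, -84.1946, 40, 2), ("31", 33.9650, -84.5408, 40, 2),
    ("32", 33.9302, -83.3941, 40, 1), ("42", 34.0027, -84.3816, 35, 2),
    ("48", 33.7330, -84.3737, 39, 2),
)

PRESETS = ("paper-shape",)


def emulate_study(preset: str = "paper-shape", seed: int = 0,
                  caste_skew_alpha: Optional[float] = None,
                  planted_foreign_worker: bool = False) -> SimResult:
    """Simulate a dataset with the study's sampling design.

    The ``paper-shape`` preset reproduces the published design structurally:
    8 perennial colonies (66-82 workers each, gynes and males where
    sampled) and 13 annual single-queen colonies (~40 workers, typed at 7 of
    the 10 loci), at the published colony coordinates.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; available: {PRESETS}")
    config = SimConfig(seed=seed, annual_locus_subset=7,
                       caste_skew_alpha=caste_skew_alpha,
                       planted_foreign_worker=planted_foreign_worker)
    plans = [ColonyPlan(n, "perennial", lat, lon, w, g, m, mt)
             for n, lat, lon, w, g, m, mt in PERENNIAL_DESIGN]
    plans += [ColonyPlan(n, "annual", lat, lon, w, 0, 0, mt)
              for n, lat, lon, w, mt in ANNUAL_DESIGN]
    return simulate_dataset(config, plans)


def mendelian_consistent(result: SimResult) -> bool:
    """Exhaustive check of offspring genotypes against the truth pedigree."""
    for ind in result.dataset.individuals:
        info = result.truth["individuals"][ind.id]
        queen = result.truth["colonies"][ind.colony]["queens"][info["mother"]]
        for locus, g in ind.genotype.items():
            if g is None:
                continue
            mg = queen["genotype"][locus]
            if len(g) == 1:
                if g[0] not in mg:
                    return False
            else:
                fg = queen["mates"][info["father"]][locus][0]
                ok = (g[0] in mg and g[1] == fg) or (g[1] in mg and g[0] == fg)
                # both orders, and the maternal/paternal allele may coincide
                if not ok and not (fg in g and any(a in mg for a in g)):
                    return False
    return True
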