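"""End-to-end analysis orchestration.

``run_analysis`` executes the full colony-genetics workflow on a dataset
(loaded from files or simulated from a preset) and writes a report bundle:

1. per-locus variability table (plus between-form comparisons)
2. gyne-vs-worker differentiation per colony with a Stouffer "All" row
3. caste-level nestmate relatedness with SEM and 95% CI
4. pairwise colony F_ST matrix
5. hierarchical theta (social form / colony-within-form) with bootstrap CIs
6. queen-number table (exclusion bound + sibship-partition estimate)
7. per-colony mtDNA haplotype composition and diversity
8. Mantel isolation-by-distance results

plus a run log with seeds, versions, config hash and per-stage status.  A
failed stage marks the bundle partial and downstream dependents are skipped.
Identical inputs, config and seeds give a bit-identical bundle.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import GenotypeDataset, SequenceAlignment
from .differentiation import caste_differentiation_test, combine_stouffer, satellite_merge_test
from .f_statistics import hierarchical_theta, pairwise_fst
from .genotype_io import read_fasta, read_sample_table
from .locus_stats import (alleles_segregating_per_form, compare_forms_paired,
                          locus_table)
from .mtdna import (call_haplotypes, haplotype_diversity, haplotype_form_test,
                    matriline_summary, trim_alignment)
from .queen_number import SibshipConfig, sibship_partition
from .relatedness import pamilo_relatedness
from .simulate import emulate_study
from .spatial import haversine_matrix, mantel_test


@dataclass
class AnalysisConfig:
    """Declarative configuration for a full analysis run."""

    outdir: str = "colonykin-report"
    sample_table: Optional[str] = None      # CSV genotype input
    fasta: Optional[str] = None             # aligned mtDNA input
    preset: Optional[str] = None            # simulate instead of loading
    seed: int = 0
    merge_satellites: bool = True
    caste_filter: Optional[str] = None      # restrict pairwise F_ST to one caste
    n_boot: int = 1000
    n_perm: int = 9999
    mc_dememorization: int = 10_000
    mc_batches: int = 100
    mc_batch_size: int = 5_000
    alpha: float = 0.05
    max_queens: int = 40
    trim_window: Optional[tuple] = None

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "trim_window" in data and data["trim_window"] is not None:
            data["trim_window"] = tuple(data["trim_window"])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_inputs(config: AnalysisConfig):
    """Resolve the configured inputs to (dataset, alignment-or-None)."""
    if config.preset is not None:
        sim = emulate_study(config.preset, seed=config.seed)
        return sim.dataset, sim.alignment
    if config.sample_table is None:
        raise ValueError("config needs either a preset or a sample_table path")
    dataset = read_sample_table(config.sample_table)
    alignment = read_fasta(config.fasta) if config.fasta else None
    return dataset, alignment


def validate_dataset(dataset: GenotypeDataset) -> dict:
    """Structural diagnostics: ploidy/caste consistency, missingness, sizes."""
    violations = []
    for ind in dataset.individuals:
        want = 1 if ind.caste == "male" else 2
        for locus, g in ind.genotype.items():
            if g is not None and len(g) != want:
                violations.append(f"{ind.id}: {len(g)} alleles at {locus} for caste {ind.caste}")
    miss = {}
    mono = []
    for locus in dataset.panel.locus_names:
        genos = [ind.genotype.get(locus) for ind in dataset.individuals]
        n = len(genos)
        miss[locus] = sum(g is None for g in genos) / n if n else float("nan")
        observed = {a for g in genos if g is not None for a in g}
        if len(observed) <= 1:
            mono.append(locus)
    sizes = pd.Series([i.colony for i in dataset.individuals]).value_counts().to_dict()
    return {"ploidy_violations": violations,
            "missingness": miss,
            "high_missingness": sorted(l for l, f in miss.items() if f > 0.2),
            "monomorphic_loci": mono,
            "colony_sizes": sizes,
            "n_individuals": len(dataset.individuals),
            "n_colonies": len(dataset.colonies)}


def run_analysis(config: AnalysisConfig) -> dict:
    """Run every stage and write the report bundle to ``config.outdir``.

    Returns the run log (also written as ``run_log.json``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = {"version": __version__, "python": platform.python_version(),
           "seed": config.seed, "config_hash": config.config_hash(),
           "config": asdict(config), "stages": {}, "partial": False}

    def stage(name, fn, depends=()):
        for dep in depends:
            if log["stages"].get(dep, {}).get("status") != "ok":
                log["stages"][name] = {"status": "skipped", "reason": f"dependency {dep} failed"}
                return None
        try:
            out = fn()
            log["stages"][name] = {"status": "ok"}
            return out
        except Exception as exc:  # a failed stage must not sink the bundle
            log["stages"][name] = {"status": "error", "error": f"{type(exc).__name__}: {exc}"}
            log["partial"] = True
            return None

    loaded = stage("load", lambda: load_inputs(config))
    if loaded is None:
        _write_log(outdir, log)
        return log
    dataset, alignment = loaded
    if config.merge_satellites and any(c.satellite_of for c in dataset.colonies):
        sat_pairs = [(c.satellite_of, c.colony_id) for c in dataset.colonies if c.satellite_of]
        stage("satellite_tests", lambda: _satellite_stage(dataset, sat_pairs, config, outdir))
        dataset = dataset.merge_satellites()

    stage("validate", lambda: _dump_json(outdir / "diagnostics.json", validate_dataset(dataset)))
    mc = dict(dememorization=config.mc_dememorization, batches=config.mc_batches,
              batch_size=config.mc_batch_size)

    stage("locus_table", lambda: _locus_stage(dataset, outdir))
    stage("caste_tests", lambda: _caste_stage(dataset, config, mc, outdir))
    stage("relatedness", lambda: _relatedness_stage(dataset, outdir))
    fst = stage("pairwise_fst", lambda: _fst_stage(dataset, config, outdir))
    stage("hierarchical_theta", lambda: _hier_stage(dataset, config, outdir))
    stage("queen_number", lambda: _queens_stage(dataset, config, outdir))
    stage("mtdna", lambda: _mtdna_stage(dataset, alignment, config, mc, outdir))
    stage("ibd", lambda: _ibd_stage(dataset, fst, config, outdir), depends=("pairwise_fst",))

    _write_log(outdir, log)
    return log


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _dump_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def _write_log(outdir: Path, log: dict) -> None:
    _dump_json(outdir / "run_log.json", log)


def _satellite_stage(dataset, sat_pairs, config, outdir):
    out = {}
    for parent, sat in sat_pairs:
        out[f"{parent}~{sat}"] = satellite_merge_test(
            dataset, parent, sat, alpha=config.alpha, seed=config.seed,
            dememorization=config.mc_dememorization, batches=config.mc_batches,
            batch_size=config.mc_batch_size)
    _dump_json(outdir / "satellite_tests.json", out)


def _locus_stage(dataset, outdir):
    forms = {i.form for i in dataset.individuals}
    tabs = []
    for form in sorted(forms):
        inds = [i for i in dataset.individuals if i.form == form]
        t = locus_table(dataset, inds)
        t.insert(0, "form", form)
        tabs.append(t)
    table = pd.concat(tabs, ignore_index=True) if tabs else pd.DataFrame()
    table["provenance"] = "locus_stats.summarize_locus"
    table.to_csv(outdir / "locus_table.csv", index=False)
    if len(forms) == 2:
        seg = alleles_segregating_per_form(dataset)
        shared = seg[(seg["A_n_annual"] > 0) & (seg["A_n_perennial"] > 0)]
        if len(shared) >= 3:
            cmp_res = compare_forms_paired(shared["A_n_annual"], shared["A_n_perennial"])
            _dump_json(outdir / "form_allele_comparison.json",
                       {"per_locus": shared.to_dict("records"),
                        "paired_t": cmp_res.t_statistic, "t_p": cmp_res.t_p,
                        "wilcoxon_p": cmp_res.wilcoxon_p, "n_pairs": cmp_res.n_pairs,
                        "provenance": "locus_stats.compare_forms_paired"})


def _caste_stage(dataset, config, mc, outdir):
    rows = []
    colonies = sorted({i.colony for i in dataset.individuals if i.form == "perennial"})
    for colony in colonies:
        has = {c: sum(1 for i in dataset.individuals if i.colony == colony and i.caste == c)
               for c in ("gyne", "worker")}
        if min(has.values()) < 2:
            continue
        try:
            combined, per_locus = caste_differentiation_test(
                dataset, colony, seed=config.seed, **mc)
        except ValueError:
            continue
        rows.append({"colony": colony, "N_G": has["gyne"], "N_W": has["worker"],
                     "chi2": combined.statistic, "df": combined.df, "p": combined.p})
    tab = pd.DataFrame(rows)
    if len(tab):
        usable = tab[(tab["p"] > 0) & (tab["p"] < 1)]
        if len(usable) >= 2:
            z = combine_stouffer(usable["p"].tolist())
            all_row = pd.DataFrame([{"colony": "All", "N_G": None, "N_W": None,
                                     "chi2": z.statistic, "df": None, "p": z.p}])
            tab = pd.concat([tab, all_row], ignore_index=True)
    tab["provenance"] = "differentiation.caste_differentiation_test"
    tab.to_csv(outdir / "caste_tests.csv", index=False)


def _relatedness_stage(dataset, outdir):
    rows = []
    for form in ("perennial", "annual"):
        for caste in ("worker", "gyne", "male"):
            try:
                est = pamilo_relatedness(dataset, caste, form)
            except Exception:
                continue
            rows.append({"form": form, "caste": caste, "r": est.r, "sem": est.sem,
                         "ci_lo": est.ci95[0], "ci_hi": est.ci95[1],
                         "n_individuals": est.n_individuals, "n_colonies": est.n_colonies,
                         "n_loci": est.per_locus_r.size})
    tab = pd.DataFrame(rows)
    tab["provenance"] = "relatedness.pamilo_relatedness"
    tab.to_csv(outdir / "relatedness.csv", index=False)


def _fst_stage(dataset, config, outdir):
    mat = pairwise_fst(dataset, caste=config.caste_filter)
    mat.to_csv(outdir / "pairwise_fst.csv")
    return mat


def _hier_stage(dataset, config, outdir):
    h = hierarchical_theta(dataset, n_boot=config.n_boot, seed=config.seed)
    _dump_json(outdir / "hierarchical_theta.json",
               {"theta_S": h.theta_S, "theta_C": h.theta_C,
                "ci95_S": list(h.ci95_S), "ci95_C": list(h.ci95_C),
                "n_boot": h.n_boot, "seed": h.seed,
                "provenance": "f_statistics.hierarchical_theta"})


def _queens_stage(dataset, config, outdir):
    rows = []
    sib_cfg = SibshipConfig(max_queens=config.max_queens, seed=config.seed)
    for colony in sorted({i.colony for i in dataset.individuals if i.form == "perennial"}):
        res = sibship_partition(dataset, colony, sib_cfg)
        rows.append({"colony": colony, "lower_bound": res.lower_bound,
                     "partition_estimate": res.partition_estimate,
                     "loglik": res.loglik})
    tab = pd.DataFrame(rows)
    tab["provenance"] = "queen_number.sibship_partition"
    tab.to_csv(outdir / "queen_number.csv", index=False)


def _mtdna_stage(dataset, alignment, config, mc, outdir):
    if alignment is None:
        raise ValueError("no mtDNA alignment provided")
    trimmed = trim_alignment(alignment, config.trim_window)
    colony_map = {i.id: i.colony for i in dataset.individuals}
    hapset = call_haplotypes(trimmed, colony_map)
    summary = matriline_summary(hapset)
    summary["provenance"] = "mtdna.matriline_summary"
    summary.to_csv(outdir / "matrilines.csv", index=False)
    hapset.per_colony_counts.to_csv(outdir / "haplotype_counts.csv")
    form_map = {c.colony_id: c.form for c in dataset.colonies}
    total = haplotype_diversity(
        [sum(1 for h in hapset.assignment.values() if h == hap)
         for hap in hapset.haplotypes])
    div = {"total_h": total.h, "n": total.n, "k": total.k}
    for form in ("annual", "perennial"):
        cols = [c for c in hapset.per_colony_counts.index if form_map.get(c) == form]
        if cols:
            counts = hapset.per_colony_counts.loc[cols].sum(axis=0)
            if counts.sum() >= 2 and (counts > 0).any():
                d = haplotype_diversity(counts.tolist())
                div[f"{form}_h"] = d.h
                div[f"{form}_n"] = d.n
    try:
        test = haplotype_form_test(hapset, form_map, seed=config.seed, **mc)
        div["form_test_p"] = test.p
    except ValueError as exc:
        div["form_test_error"] = str(exc)
    div["segregating_sites_1based"] = list(hapset.segregating_sites_1based)
    div["provenance"] = "mtdna.haplotype_diversity"
    _dump_json(outdir / "haplotype_diversity.json", div)


def _ibd_stage(dataset, fst, config, outdir):
    if fst is None:
        raise ValueError("pairwise F_ST unavailable")
    dist = haversine_matrix(dataset.colonies)
    form_map = {c.colony_id: c.form for c in dataset.colonies}
    out = {}
    subsets = {"all": list(fst.index)}
    for form in ("annual", "perennial"):
        subsets[form] = [c for c in fst.index if form_map.get(c) == form]
    for name, cols in subsets.items():
        cols = [c for c in cols if c in dist.index]
        if len(cols) < 4:
            continue
        g = fst.loc[cols, cols]
        d = dist.loc[cols, cols]
        try:
            res = mantel_test(g, d, n_perm=config.n_perm, seed=config.seed)
        except ValueError as exc:
            out[name] = {"error": str(exc)}
            continue
        out[name] = {"mantel_r": res.statistic, "p": res.p_perm,
                     "spearman_rs": res.spearman_rs, "n_colonies": len(cols),
                     "n_perm": res.n_perm}
    out["provenance"] = "spatial.mantel_test"
    _dump_json(outdir / "ibd.json", out)
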