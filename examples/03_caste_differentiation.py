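"""Do queens contribute differentially to gynes and workers?

Exact genotypic tests per locus (gyne vs worker within a colony) are
Fisher-combined across loci; Stouffer's Z then combines colonies.  Here one
simulated colony has strong per-queen caste skew and one has none.
"""

from colonykin import SimConfig, simulate_dataset, caste_differentiation_test, combine_stouffer

mc = dict(dememorization=2000, batches=20, batch_size=500)
base = dict(n_annual=0, n_perennial=1, queens=6, mates=1,
            allele_counts=[8] * 10, freq_law="equifrequent",
            workers_perennial=60, gynes_perennial=60, males_perennial=0,
            mtdna_samples_perennial=0)

ps = []
for label, skew, seed in [("skewed", 0.1, 80), ("no skew", None, 81)]:
    sim = simulate_dataset(SimConfig(**base, caste_skew_alpha=skew, seed=seed))
    combined, per_locus = caste_differentiation_test(sim.dataset, "P01", seed=1, **mc)
    print(f"{label:8s}: chi2 = {combined.statistic:7.2f}, df = {combined.df}, "
          f"p = {combined.p:.4g} over {combined.k} loci")
    ps.append(min(max(combined.p, 1e-12), 1 - 1e-12))

z = combine_stouffer(ps)
print(f"across colonies (Stouffer): Z = {z.statistic:.2f}, p = {z.p:.4g}")
# Queens that split their effort unevenly between castes leave a detectable
# genotype-frequency difference between gynes and workers.
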