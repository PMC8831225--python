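"""mtDNA haplotypes mark matrilines: are perennial colonies closed societies?

Maternal inheritance means a colony recruiting queens from its own nest
stays a single haplotype; foreign queens import new matrilines.  A planted
foreign-haplotype worker demonstrates anomaly detection.
"""

from colonykin import call_haplotypes, emulate_study, haplotype_diversity, matriline_summary, trim_alignment

sim = emulate_study("paper-shape", seed=7, planted_foreign_worker=True)
cmap = {i.id: i.colony for i in sim.dataset.individuals}

hapset = call_haplotypes(trim_alignment(sim.alignment), cmap)
print(f"{len(hapset.haplotypes)} haplotypes across "
      f"{len(hapset.segregating_sites)} segregating sites "
      f"(positions {hapset.segregating_sites_1based})")

counts = [sum(1 for h in hapset.assignment.values() if h == hap)
          for hap in hapset.haplotypes]
print(f"total haplotype diversity h = {haplotype_diversity(counts).h:.4f}")

summary = matriline_summary(hapset)
flagged = summary[summary["multiple_matrilines"]]
print(f"{(~summary['multiple_matrilines']).sum()} of {len(summary)} colonies "
      f"are single-matriline")
for _, row in flagged.iterrows():
    print(f"colony {row['colony']}: {row['n_haplotypes']} haplotypes; "
          f"minority record(s): {row['minority_records']}")
# The one flagged record is the planted foreign worker - the same signature
# as a drifted worker or contamination in real data.
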