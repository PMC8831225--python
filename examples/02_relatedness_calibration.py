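"""Nestmate relatedness: estimator vs haplodiploid pedigree expectations.

Simulates single-queen colonies and checks the two calibration benchmarks:
full sisters (r = 0.75 when the queen mated once) and brothers (r = 0.5).
Then shows how polygyny erodes relatedness toward (0.25 + 0.5/m_e)/Q.
"""

from colonykin import SimConfig, simulate_dataset, pamilo_relatedness, expected_relatedness

cfg = SimConfig(n_annual=0, n_perennial=50, queens=1, mates=1,
                allele_counts=[10] * 10, freq_law="equifrequent",
                workers_perennial=20, gynes_perennial=0, males_perennial=20,
                mtdna_samples_perennial=0, seed=11)
sim = simulate_dataset(cfg)

workers = pamilo_relatedness(sim.dataset, "worker")
males = pamilo_relatedness(sim.dataset, "male")
print(f"full sisters : r = {workers.r:.3f} +/- {workers.sem:.3f} (expect 0.750)")
print(f"brothers     : r = {males.r:.3f} +/- {males.sem:.3f} (expect 0.500)")

for Q in (2, 5, 10):
    cfg = SimConfig(n_annual=0, n_perennial=50, queens=Q, mates=4,
                    queen_recruitment="foreign", allele_counts=[10] * 10,
                    freq_law="equifrequent", workers_perennial=20,
                    gynes_perennial=0, males_perennial=0,
                    mtdna_samples_perennial=0, seed=100 + Q)
    est = pamilo_relatedness(simulate_dataset(cfg).dataset, "worker")
    want = expected_relatedness(Q, 4)["worker"]
    print(f"Q = {Q:2d}, m_e = 4: r = {est.r:.3f} (pedigree expectation {want:.3f})")
# The estimates track the analytic expectations: many queens mated to many
# unrelated males make nestmates nearly unrelated, the perennial-colony
# signature.
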