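# Methods

## The problem

Annual colonies of yellowjacket wasps (*Vespula*) are headed by one
polyandrous queen and die each winter; in warm climates some colonies
persist for years, grow enormous, and recruit many reproductive queens.
Colony-structured genetic data can resolve how such perennial societies are
organised: how related nestmates are, how many queens reproduce, whether
recruited queens come from the natal nest (one matriline, one mtDNA
haplotype per colony) or from outside, and whether the two social forms are
genetically differentiated at all. This package implements that full
analysis and a generative simulator to validate it.

## Variance components and F-statistics

All F-statistics derive from a method-of-moments nested random-effects
ANOVA on allele indicator variables (Henderson's method I). Each gene copy
is one observation; copies nest in individuals, individuals in colonies,
colonies (optionally) in social forms. For every grouping g we accumulate
T_g = Σ_cells (cell total)²/n_cell per allele and solve the linear system
given by E[T_g] − E[T_grand] = Σ_v k(g,v)·σ²_v for the per-level components,
summing over alleles. For all-diploid data with colonies as groups this
reproduces the Weir–Cockerham (1984) components (a, b, c) exactly,
including the unbalanced-sample-size corrections — the test suite verifies
agreement with the closed-form estimator to 1e-10 on random datasets.
Haploid males enter as individuals carrying a single gene copy: they
contribute to among-group frequency variance but have no within-individual
term; an all-haploid analysis collapses to the one-level ANOVA.

Conventions: multilocus estimates are ratios of summed components, never
means of per-locus ratios; negative estimates are retained (truncation
would bias downstream relatedness); the resampling unit is always the locus
(delete-one jackknife for SEs, bootstrap with ≥1000 seeded draws for CIs).
In the hierarchical analysis θ_S = σ²_form/σ²_total and
θ_C = σ²_colony/(σ²_colony + σ²_ind + σ²_copy), the standard nested
F-statistic layout; a locus informs the form level only if both forms carry
data at it. Pairwise colony F_ST pools castes by default (a caste filter is
available) because the underlying tool conventions leave this open.

## Relatedness

Group relatedness for diploid nestmates is Pamilo's r = 2θ/(1 + F_IT),
computed per locus and from summed components, with colonies as groups and
only the focal caste included (caste-level nestmate relatedness). SEM is
the standard deviation of per-locus estimates over √L; 95% CIs are
r ± 1.96·SEM, and two estimates differ significantly when their intervals
are disjoint. For haploid males the diploid transformation would give 2/3
for brothers; relatedness among haploids is therefore the allele intraclass
correlation θ itself, which equals the 0.5 pedigree value for single-queen
broods — this benchmark is a test.

Analytic expectations used for calibration, with Q equally contributing
queens of mutual relatedness g, each with effective paternity
m_e = 1/Σq_i² (q_i = paternity shares): sisters within a matriline
0.25 + 0.5/m_e, across matrilines g/4; brothers 0.5 within, g/2 across; a
random nestmate pair is within-matriline with probability 1/Q.

## Exact differentiation tests

Genotype-by-class contingency tables are tested against the conditional
(margins-fixed) null, under which a table has the multiple hypergeometric
probability P(T) ∝ 1/Π n_ij!. The two-sided p is the total probability of
tables no more probable than the observed one (probability ordering, the
convention of the classical exact-test programs). When the number of tables
sharing the margins (counted by dynamic programming) is at most 10⁶ the
support is enumerated exhaustively; otherwise a Metropolis chain over ±1
rectangle moves is run with defaults of 10,000 dememorization steps and 100
batches of 5,000 iterations, reporting a batch-mean Monte-Carlo SE. Chains
are seeded and fully reproducible. Rare genotypes are never pooled.

Across loci, p-values combine by Fisher's product method (χ² = −2Σln p,
df = 2L), which is what a per-colony χ²/df table implies; across colonies
by Stouffer's Z = ΣΦ⁻¹(1−p_i)/√k (one-sided: small p ⇒ large Z). Exact
p-values of 1 or Monte-Carlo zeros are clamped away from the open-interval
boundary with a warning before Stouffer combination. Satellite-nest tests
run the per-caste exact test between parent and satellite, Fisher-combined
across loci, and recommend merging when no caste rejects at α = 0.05 (the
pipeline merges satellites into parents by default).

## Queen number

The exclusion bound uses the haplodiploid constraint that a single queen
exposes at most two maternal alleles per locus: homozygous diploid
offspring and haploid male alleles are provably maternal, so the bound is
max over loci of ⌈|maternal set|/2⌉, raised to 2 whenever no single
two-allele maternal genotype can cover every diploid offspring at some
locus. Males are assumed queen-produced (workers can produce males only in
queenless colonies); a flag excludes them.

The sibship-partition estimate is a deliberately simple heuristic, not a
reimplementation of full-pedigree MCMC programs, and is validated purely by
parameter recovery on simulations. For every offspring pair it computes the
log-likelihood ratio of maternal sibship versus unrelatedness, integrating
the unknown maternal genotype over Hardy–Weinberg priors built from
population allele frequencies; fathers are modelled as independent
population draws, which is conservative under polyandry. Average-linkage
hierarchical clustering on the pairwise LLR matrix is cut at every
candidate queen number K, scored by the sum of within-cluster LLRs minus a
BIC-style penalty of log(n) per extra matriline, and the best K (floored at
the exclusion bound) is reported. A per-locus genotyping error rate can be
folded into the pair likelihoods (default 0). On the validation grid the
method recovers Q = 1 essentially always (20 offspring, 10 ten-allele
loci) and Q = 5 within ±1 in well over 70% of replicates at 80 offspring;
at very large Q (tens of queens, few offspring per matriline) it
underestimates, as any sibship method must with this marker information.

## mtDNA matrilines

Sequences are trimmed to a common analysis window (0-based half-open;
458-bp amplicons default to a 338-bp window starting at offset 120, since
single-primer reads degrade from the start; both are configurable).
Segregating sites are columns with at least two unambiguous bases; a
haplotype is the string over those sites; records with ambiguity codes at
segregating sites are flagged or dropped by policy. Haplotype diversity is
h = n/(n−1)(1−Σp²). Because mtDNA is maternal, per-colony haplotype counts
identify matrilines; multi-haplotype colonies are flagged with their
minority records named (drift or contamination suspects). The between-form
haplotype test first collapses each colony to its modal haplotype — one
record per colony — to remove the pseudo-replication of sampling many wasps
from one matriline, then runs the exact frequency test.

## Isolation by distance

Great-circle distances use the haversine formula on a sphere of radius
6371.0088 km. The Mantel statistic is the Pearson correlation of
off-diagonal pairs, tested one-sided (positive association, the IBD
convention) against simultaneous row/column permutations with
p = (#{r_perm ≥ r_obs} + 1)/(n_perm + 1); Spearman's r_s is reported on the
same pairs. The default correlates raw F_ST with km; the linearised option
uses F_ST/(1−F_ST) against ln km.

## The simulator

`simulate_dataset` draws per-locus population allele frequencies
(equifrequent or Dirichlet over a configurable allele count per locus),
then builds colonies: an annual colony is one population-drawn queen mated
to m males; a perennial colony is a foundress plus Q−1 queens recruited
from her own daughters (one overlapping generation), every queen mated to m
fresh population males — so natal-mode colonies are single matrilines by
construction, while the foreign mode draws unrelated queens with their own
mtDNA haplotypes. Paternity shares per queen are equal or Dirichlet(α),
with the realised m_e recorded; brood is assigned to queens by equal or
Dirichlet weights, with an optional separate gyne-weight vector
(caste skew). Daughters receive one maternal allele and the paternal
allele; sons one maternal allele; loci are unlinked. Missing genotypes are
injected at a configurable rate. All randomness flows from one seed and the
truth record carries every pedigree assignment, so Mendelian consistency
and every pedigree expectation can be checked exactly.

Defaults encode the study conditions the package targets: 8 perennial
colonies with Q = 20 queens (heavily polygynous perennial nests) and
m = 4 mates (typical *Vespula* effective paternity, which puts monogyne
worker relatedness near 0.37), 13 annual single-queen colonies, 10 loci
with realistic microsatellite allele counts (3–35 alleles) and
fragment-size allele labels. The `paper-shape` preset reproduces a
published sampling design structurally — per-colony worker/gyne/male and
mtDNA sample counts, real colony coordinates, annual colonies typed at the
7 shared loci — for end-to-end exercises. The mtDNA pool holds five
haplotypes at frequencies (0.45, 0.25, 0.15, 0.10, 0.05), a plausible
skewed spectrum chosen once; rare haplotypes may be absent from any given
simulated sample, as in real surveys.

What the simulator does **not** model: microsatellite mutation (stepwise or
otherwise), genotyping artefacts beyond random missingness, selection,
inbreeding, queen turnover across seasons deeper than one generation, and
spatial genetic structure (colonies are exchangeable draws from one gene
pool). Passing tests therefore demonstrate estimator correctness under the
stated generative model, not robustness to those real-data complications;
in particular the isolation-by-distance machinery is validated for null
calibration, not power.

## Numerical conventions and test scale

Degenerate inputs are handled explicitly: monomorphic loci yield zero
variance components flagged uninformative and exact-test p = 1; all-haploid
subsets leave H_o undefined (flagged, not an error) and collapse the
individual ANOVA level; colony pairs sharing no informative locus get NaN
F_ST. Exact-test ties use a 1e-9 log-probability tolerance. Bootstrap CIs
are widened, if necessary, to contain the point estimate (relevant only at
tiny locus counts). The paired form comparison returns the exact
signed-rank distribution up to 15 pairs and the normal approximation above.

The test suite validates at deliberately compact problem sizes chosen to
keep the full run in minutes: relatedness calibrations use 50 colonies of
20 offspring across a Q × m_e grid; oracle-equivalence sweeps use datasets
of ≤30 gene copies and contingency tables with ≤10⁴-table support;
chain-vs-enumeration and Mantel-vs-exhaustive comparisons run at 3
Monte-Carlo SEs; the label-permutation null for the combined caste test
uses 1000 replicates of a 25-vs-25 colony at ten 4-allele loci with
shortened (but seeded) chains, where a Kolmogorov–Smirnov test confirms
uniformity. Pipeline defaults keep the full GENEPOP-scale chain settings.
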