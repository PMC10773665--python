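# Methods

This note records the models behind each stage, the parameters that
matter, what the synthetic data do and do not emulate, and the numerical
choices a user comparing against other tools should know about.

## The question and the analysis chain

A recessive disease allele segregates at high frequency in a closed breed.
Once genetic testing makes carrier status visible, breeders can change
mate choice and stock selection; the analyses here ask (i) whether the
observed allele-frequency decline exceeds random drift, (ii) whether the
genome shows a localized selection signature at the locus, and (iii)
whether the intervention narrowed the breeding pool (inbreeding, diversity,
contemporary Ne). Stages run independently or through
`selectwatch.pipeline.run_pipeline`.

## Drift null

The null model is a discrete-generation Wright–Fisher population with
unequal sex numbers: each generation Nm sires contribute an allele count
drawn Binomial(2·Nm, q) and Nf dams Binomial(2·Nf, q); the next frequency
is the mean of the two sex-specific frequencies. This scheme has
first-generation variance q(1−q)/(2·Ne_eff) with Ne_eff = 4·Nm·Nf/(Nm+Nf),
the textbook unequal-sex-ratio effective size, which the test suite
verifies to within Monte-Carlo error. Nm is round-half-up(mf·Ne) — with
Ne = 540 and mf = 0.2 that gives 108 sires and 432 dams, Ne_eff = 345.6.
Absorption at 0 and 1 is exact. The empirical p-value is the share of
simulated frequencies *strictly below* the observed one (ties therefore
count against significance); a zero count is reported as 0.5/replicates so
that "below every simulated value" remains representable and ordering in
the observed value is preserved. One-sided lower-tail testing at 0.05 is
the default decision rule.

The binomial confidence interval on an observed frequency counts
chromosomes (2n) by default; callers who want dog-level counts can pass k
and n directly to `clopper_pearson`.

## Fisher's exact test for r×c tables

The p-value is the total conditional probability (multivariate
hypergeometric, margins fixed) of all tables whose probability does not
exceed the observed table's, with a 1e-7 relative tolerance on the
comparison to absorb floating-point ties. Tables are enumerated
recursively when a cheap bound on the table count stays below 10⁷;
otherwise a Monte-Carlo over margin-preserving random assignments is used
and the MC standard error reported. All-zero rows and columns are dropped
first (they carry no information conditional on the margins); if fewer
than two informative rows or columns remain, p = 1 by convention. The 2×2
path is cross-checked against scipy's implementation in the tests.

## QC and kinship

Filter order is fixed: non-autosomal markers out, then per-SNP
missingness, then per-sample missingness, then MAF — mirroring the
conventional PLINK order, so per-sample rates are computed on the
already-SNP-filtered panel. The counted allele (A2) is the
alphabetically-second allele observed at first read and is recorded in the
marker map, making downstream frequencies orientation-stable across
round-trips. KING-robust kinship is the between-family estimator
(N_Aa,Aa − 2·N_AA,aa)/(N_Aa(i)+N_Aa(j)) over pairwise-complete SNPs; it is
0.5 for duplicates, ≈0.25 for first-degree pairs, and robust to
population-wide allele-frequency structure, though in extremely
bottlenecked founder sets (a handful of ancestral haplotypes) it loses
calibration — one reason the pruning cutoff (0.176) is configurable.
Pruning is greedy: repeatedly drop the sample with the most above-cutoff
pairs (ties to the higher sample index) until none remain.

## Weir–Cockerham F_ST

Per SNP, with two groups, the 1984 variance components a (among
population), b (among individuals within) and c (within individuals) are
computed from group sample sizes, allele frequencies and observed
heterozygote fractions on complete cases; F_ST = a/(a+b+c), undefined for
SNPs monomorphic across both groups, slightly negative values retained as
estimator behaviour. The top-fraction flag keeps every SNP tied at the
k-th largest value, k = ceil(fraction × defined SNPs) — at 143,013 SNPs
and 0.1% that is 144 flagged.

## EHH

For the haplotypes carrying the chosen core allele, EHH at flanking SNP x
is Σ_h C(n_h,2)/C(n,2) over groups of haplotypes identical along the whole
interval [core, x], evaluated at marker positions within the window (1 Mbp
default), with no interpolation. The curve equals 1 at the core and is
non-increasing outward. "Derived" is undefined without an outgroup, so
the caller names the core allele; the CLI default is the allele commoner
in the later cohort.

## ROH and F_ROH

The consecutive-runs method: maximal stretches of homozygous calls
(tolerating up to max_het heterozygous and max_miss missing calls, both 0
by default), broken where adjacent SNPs are more than max_gap apart, then
filtered on all of n_snps ≥ 41, length ≥ 50 kb and density ≥ 1 SNP per
5,000 bp. Density is per base pair here — note that the R package whose
parameter names these thresholds echo measures density per kilobase, so
its numerically identical setting is far more permissive; with this
package's reading, panels sparser than ~1 SNP/5 kb cannot yield ROH, which
drove the simulator's marker-spacing default (below). F_ROH divides summed
run length by the genotyped span (per-autosome last-minus-first marker
position), not the assembly length, so denominators match the observed
panel. Group comparisons use Welch's unequal-variance t-test.

## Structure and Ne

PCA mean-centres each SNP and divides by √(p(1−p)) (Patterson scaling),
mean-imputes missing calls, and eigendecomposes the sample-by-sample
covariance; zero-variance SNPs are skipped. p-distance counts genotype-
state mismatches (hom/het/hom as three states) over pairwise-complete
SNPs — the simplest reading of a p-distance on genotype pseudo-sequences,
which may diverge from tools that expand genotypes to IUPAC codes.
Neighbor joining follows Saitou–Nei with the Q-criterion, label-order tie
breaking, and negative branch lengths clamped to zero with the excess
moved to the sister branch; on additive matrices it reproduces the
generating tree exactly (verified against an independent implementation).
Nei's D uses the original 1972 gene identities without small-sample
correction.

LD-Ne uses Burrows' composite Δ from unphased genotypes,
Δ = S/(S−1)·(mean(XY)/2 − 2p_Ap_B), normalized by (p_Aq_A+D_A)(p_Bq_B+D_B)
where D_A is the homozygote excess; r̂² is averaged over locus pairs on
*different* chromosomes only (MAF ≥ 0.01, complete cases, seeded
subsampling beyond 500,000 pairs). Restricting to inter-chromosomal pairs
avoids physical-linkage bias; tools that also use within-chromosome pairs
will give somewhat different estimates. The drift signal r²' subtracts the
sampling expectation (1/S + 3.19/S² for S ≥ 30, the small-S variant
otherwise) and inverts the random-mating relation
Ne = (1/3 + √(1/9 − 2.76·r²'))/(2·r²'); non-positive r²' reports Ne as
infinite, and the parametric CI comes from the chi-square interval on the
mean r² with one degree of freedom per pair. The estimator presumes
unrelated samples — in pedigree cohorts, prune relatives (or sample one
pup per litter) first, as the pipeline does.

## The synthetic breed

The generator aims at the *statistical structure* the estimators assume,
not at coalescent realism. Founders draw each chromosome as a mosaic of a
small pool of ancestral haplotype templates (default 4), switching
templates at rate 1e-6/bp — a closed breed descends from few haplotypes,
already shuffled by pre-founding recombination. The mutant focal allele
lives on exactly one template; on the focal chromosome each founder
haplotype copies that template (locally) with probability q0, so the
realized frequency is Binomial(2N, q0) while the allele rides a single
haplotype background, the configuration that produces a localized F_ST
peak and an EHH contrast when selection hits. A switch rate of 0 recovers
exact template copies.

Breeding runs on a yearly cycle with overlapping generations (breeding
ages 1–8): n_dams_per_year dams and a sire pool sized so males are
male_fraction_breeding (default 20%) of breeders, Poisson litter sizes
(mean 5). Selection policies from a chosen year: reject carrier×carrier
matings (re-drawing the sire, with a fallback to any tested-clear eligible
male); cull at-risk homozygote offspring; and optionally down-weight
carriers as breeding candidates (`carrier_breeding_penalty`) and widen the
dam pool (`n_dams_post`) — the latter two emulate the documented breeder
response of selecting tested-clear stock while deliberately broadening
lineage use. The reference scenario (`study_scenario`) combines mating
avoidance, penalty 0.8 and a doubled post-testing dam pool; under it the
risk allele falls from ~0.6 to below 0.1 in five cycles while at-risk
births stop, the pattern the trend analysis is designed to detect.

Default scale is 2 chromosomes × 10 Mbp with 5,000 SNPs (~4 kb spacing)
and recombination 3e-8/bp. The spacing keeps ROH detectable under the
per-bp density threshold above; the elevated per-bp recombination rate
compensates for the short chromosomes so that haplotype sharing still
decays visibly within the 1 Mbp EHH window over the simulated decade.
Tests that need many independent IBD segments (pedigree-F recovery) use
configs with 8–10 shorter chromosomes instead.

Per-SNP identity-by-descent from founder haplotypes is tracked through
every meiosis, giving oracle truths: pedigree kinship/inbreeding by the
tabular method, true autozygous segments, and true allele frequencies per
year. These are exported in `truth.json` beside the PED/MAP/metadata and
phased-haplotype files.

What the generator does *not* emulate: mutation, genotyping error, strand
flips, array ascertainment, realistic chromosome counts and lengths, age
structure beyond the eligibility window, and migration from outside
populations. Passing tests therefore demonstrate estimator correctness
and qualitative reproduction of the selection signatures under these
idealized conditions, not calibrated real-data performance.

## Determinism and problem sizes

Every stochastic operation takes an explicit seed (package default
20231218); the pipeline expands one root seed with fixed per-stage
offsets, so identical configs yield byte-identical reports. The test
suite and the reproduction script keep simulations at desk scale by
choice: 10–20 replicates for stochastic properties, 2,000–5,000 SNPs,
populations of one to three thousand dogs — sizes at which every
documented property is already measurable with comfortable margins.

## Known limitations

* The drift simulator treats generations as discrete even though the
  breed breeds in overlapping yearly cycles; Ne in the null is the
  user's census of breeding animals, not an estimate.
* KING-robust kinship and LD-Ne both degrade in strongly bottlenecked or
  family-structured samples (see above); the pipeline's prune-then-
  estimate order mitigates but does not remove this.
* The r×c exact test's Monte-Carlo fallback returns a p with sampling
  error; the reported `mc_se` should accompany any borderline call.
* p-distance on genotype states weighs het/hom mismatches equally, which
  halves sensitivity to allele-dosage differences relative to allele-
  sharing distances.
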