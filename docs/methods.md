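# Methods

This note records the models implemented in `hybridscan`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
data generator does and does not emulate.

## Barcoding statistics

Sequences are assumed pre-aligned. The Kimura two-parameter distance
d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q) treats transition (P) and transversion
(Q) proportions separately; sites with `N` or a gap in *either* member of a
pair are excluded pairwise (not alignment-wide), the default behaviour of
the MEGA-style tools this mirrors. When 1 − 2P − Q ≤ 0 or 1 − 2Q ≤ 0 the
correction is undefined and a `SaturationError` is raised rather than
returning a clipped value.

Group divergence is the mean over *individual* pairs: haplotype pairs are
weighted by the product of carrier counts and within-group self-pairs by
count·(count−1)/2. The ± value attached to divergence means is a
nonparametric bootstrap SE over alignment columns (seeded; default 1,000
replicates). Nucleotide diversity uses Nei's estimator with the n/(n−1)
small-sample factor.

Haplogroup delimitation is not standardised in the barcoding literature;
we use single-linkage clustering of K2P distances cut at a threshold
(default 0.02, the classic barcoding-gap heuristic), because it is
deterministic, order-independent and auditable. Groups are labelled by
descending carrier count.

## Microsatellite statistics

* He is Nei's unbiased estimator 2n/(2n−1)·(1 − Σp²); Ho is the
  heterozygote fraction among typed individuals.
* Allelic richness is rarefied (hypergeometric expectation) to the
  smallest per-locus typed copy count across the compared groups — the
  FSTAT convention.
* The private-allele rule flags an allele for species X when its
  frequency in the other species is below 1% (strict) while reaching at
  least 1% in X; this absorbs genotyping and sampling error in the
  "private" definition.
* θ is Weir & Cockerham's estimator, multi-locus as the ratio of summed
  variance components over alleles and loci. Loci with fewer than two
  typed individuals in a population, or no variation, are skipped.
* The two-level AMOVA decomposes variance among species, among populations
  within species and within populations. Distances are computed between
  *allele copies* (each individual contributes its two copies; mismatch
  0/1 per locus, summed over jointly typed loci). An individual-level
  genotype-mismatch distance was rejected because the between-individual
  component then carries twice the allele-level variance and the
  F-statistics no longer estimate the underlying coancestries (measured
  inflation from a configured F_CT = 0.25 to ≈ 0.32); the allele-copy
  decomposition recovers configured values (see the acceptance suite).
  Negative variance components are clamped to zero and flagged.
  Permutation p-values shuffle whole individuals: among populations within
  species (tests F_SC), whole populations among species (F_CT), and
  individuals among populations without restriction (F_ST).
* Nei's 1972 distance sums gene identities over loci before taking the
  ratio. When no alleles are shared at any locus the distance is +∞ and is
  *flagged*, never silently capped; `upgma` refuses infinite entries and
  points the caller to the explicit capping option. Locus-bootstrap trees
  cap infinite replicate distances at twice the largest finite value so
  the replicate still contributes a topology.
* UPGMA breaks distance ties by the lexicographically smallest pair of
  cluster representative labels, making the tree deterministic under
  input reordering. Node support is the fraction of locus-bootstrap
  replicates containing the same leaf set (default 1,000 replicates; the
  count is a parameter).
* The HWE test permutes allele copies into new genotypes with statistic
  |Ho − He|. Allele counts are permutation-invariant, so He is constant
  and Ho is discrete; ties between permuted and observed statistics are
  therefore frequent, and a deterministic "count ties as extreme" rule
  makes the p-value distribution markedly super-uniform. We instead break
  ties with a seeded uniform draw (the randomized permutation p-value),
  which is exactly uniform under the null — the property the test suite
  checks — at the cost of a small seed-dependence in reported p-values.
  The gametic-disequilibrium test permutes one locus's genotypes across
  individuals with a G statistic on the genotype×genotype table; G is
  nearly continuous there and keeps the conservative tie rule.
* Holm's sequential Bonferroni is the stepwise rejection rule
  p₍ᵢ₎ ≤ α/(m − i + 1), stopping at the first failure.

## Admixture model

The sampler implements the standard admixture model for unlinked
codominant markers at K = 2 (K is a parameter): allele copy origins Z are
latent, cluster allele frequencies have independent Dirichlet(λ = 1)
priors, individual admixture vectors have Dirichlet(α = 1) priors with α
fixed, not inferred — a deliberate simplification, configurable. The
correlated-allele-frequencies prior used by the standard tool is *not*
implemented: for clusters as diverged as two species (F_ST ≈ 0.25–0.3)
assignment is insensitive to that choice, and the uncorrelated model has a
fully auditable collapsed form. Missing genotypes contribute nothing to
the likelihood and are never imputed.

Reported Q is the posterior mean over post-burn-in sweeps. Desk-scale
defaults are burn-in 2,000 / 8,000 sweeps / 5 replicate chains (the
classic long settings of 25,000 / 100,000 / 20 remain available through
parameters); replicate chains are label-aligned against the first run (for
K = 2 the optimal permutation is exact) and averaged — the usual
CLUMPP-style step.

With L fully diagnostic loci a purebred's 2L copy origins are forced, so
its posterior mean membership is analytically (2L + α)/(2L + Kα) = 23/24
at L = 11; the test suite uses this as an exactness check on the sampler.

## Hybrid classification

References are individuals with Q > 0.9 (configurable; a minimum reference
size of 20 is enforced). Six classes are simulated from reference allele
frequencies — both parentals, F1, F2, backcross×A, backcross×B — with 100
individuals per class, 10 repetitions by default, and the admixture model
is rerun on each simulated batch without labels.

Thresholds: `Q_pure` is the minimum max-membership among simulated
purebreds; `Q_hyb_max` is the maximum among simulated *F1s*. F2 and
backcross distributions are summarised (`Q_late_max`) but excluded from
the hybrid envelope: their max-membership ranges overlap the purebred
range for marker panels of this size, so a rule including them degenerates.
Individuals with max-membership between `Q_hyb_max` and `Q_pure` are
reported as **ambiguous** — operationally, "possible late-generation
hybrid, unresolvable with these markers". A calibration where the F1 range
reaches the purebred floor is flagged `no_power` and refuses to classify.

Loci with a per-group typing rate below 50% are excluded before admixture;
markers that barely amplify in one species carry almost no assignment
information and distort missing-data handling.

Hybrid maternal species is read off the mtDNA haplogroup; carried alleles
private to the species *opposite* the maternal lineage are listed as
introgression witnesses. Removing the mtDNA channel changes directionality
fields only, never the purebred/hybrid call.

PCA encodes individuals as per-allele copy counts (0/1/2), imputes missing
entries with the column mean (deterministic), centres columns and
eigen-decomposes the covariance; the largest-magnitude loading of each
component is made positive so signs are reproducible. How strongly "PCA
identifies hybrids" is left to the user: the pipeline reports coordinates
and the tests check intermediacy of F1s between the purebred centroids.

## Synthetic-study generator

The generator is first-class, tested code; its defaults *are* the study
conditions the analyses are validated under:

* 456 individuals in four regions (two Chilean, two Falkland), 337 of
  species A, 116 of species B and 3 F1 hybrids, matching the layout of the
  published survey the pipeline targets;
* 13 microsatellites with 10 alleles per locus, a 70% private-allele
  fraction and two diagnostic loci where species B is monomorphic for an
  allele absent in A; two loci fail to amplify in species B at rates 67%
  and 94% (typing rates 33% and 6%);
* within-species site structure by Balding–Nichols perturbation of the
  species base frequencies — site frequencies are Dirichlet(p·(1−F)/F)
  draws, the standard one-parameter model whose expected pairwise F_ST
  equals F; the default target is 0.045;
* a 515-column mtDNA alignment built from one ancestral sequence; species
  B's root differs at exactly the configured number of columns (default
  38) and each intraspecific haplotype adds one private mutation at a
  fresh column, so fixed differences are exact by construction.
  Intraspecific haplotype weights default to the count spectra of the
  published survey (six A-haplotypes, four B-haplotypes, one common
  haplotype dominating each species);
* hybrids are generated by explicit crosses (F1: one allele from each
  parental pool per locus; F2: two simulated F1 parents each transmitting
  one allele, preserving within-individual correlation; backcrosses: F1 ×
  purebred) and carry the maternal species' mtDNA — the HYBRIDLAB scheme;
* misidentification is asymmetric: genetic-A fish are always labelled A,
  genetic-B fish (and hybrids, which field keys cannot recognise) are
  labelled A with probability 0.74. A logistic fork-length dependence is
  available (slope default 0); the size dependence of misidentification is
  qualitative knowledge only, so the logistic form is a stand-in, not an
  estimate;
* morphometrics: species-level fork-length and condition-factor normals
  (B larger and more streamlined than A; Falkland fish +15 mm), weight
  derived from Fulton's K, total length from the inverse of the standard
  conversion line.

All randomness descends from one master seed through spawned
`SeedSequence` streams: identical config + seed gives bit-identical
genotypes, sequences, metadata and truth tables.

What the generator does **not** emulate: linkage between loci, selection,
null alleles and allele-size homoplasy, coalescent-realistic sequence
variation, within-site family structure, and observation-level genotyping
error beyond whole-locus dropout. Passing tests therefore demonstrate that
the pipeline recovers the structure *it assumes*, not that it is robust to
every artefact of real microsatellite data.

## Problem sizes used in validation

The test and acceptance runs use desk-scale MCMC settings (burn-in 300–500,
1,200–3,000 sweeps, 3–5 replicate chains, 10 calibration repetitions of 100
individuals per class). These were chosen as the smallest settings at which
the analytic posterior checks hold to ~0.005 and replicate chains agree;
the longer classical settings are exposed as parameters throughout. AMOVA
recovery uses 10–12 independent studies of 200 individuals each.

## Known limitations

* The admixture sampler's uncorrelated-frequencies prior loses power for
  weakly diverged clusters (F_ST ≪ 0.1); this package targets clearly
  distinct species.
* F2-vs-backcross discrimination is reported but unreliable with ~11
  moderately diagnostic loci, and is deliberately surfaced as the
  `ambiguous` class plus `Q_late_max` rather than a hard call.
* The G-test, McNemar and Fisher conventions (no Williams correction, no
  continuity correction, probability-mass two-sided rule) match how these
  statistics are conventionally reported in this literature; other
  conventions will give slightly different values.
* Haplogroup delimitation by single linkage assumes a clean barcoding gap;
  it will merge groups connected by a chain of intermediate haplotypes.
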