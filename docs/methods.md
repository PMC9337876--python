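# Methods

This note documents the models and estimators implemented in `pramenka`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that make runs
reproducible.

## Genotype representation and I/O

Genotypes are a samples × SNPs matrix of int8 codes counting copies of
each marker's second allele (a2): 0, 1, 2, with −1 for missing. Missing
calls are never imputed (PCA's zero-after-centring is the single,
documented exception). Coordinates are 1-based inclusive; chromosome
codes follow the `.bim` file verbatim, with 1–26 treated as sheep
autosomes. The binary PLINK codec implements the v1 SNP-major layout
(magic `6c 1b 01`, two bits per genotype, least-significant pair first);
round-trips are bit-exact. A `.ped/.map` text reader re-derives per-SNP
alleles with a1 = minor (ties alphabetical).

**Merging** intersects marker sets by SNP id. Markers whose a1/a2 are
swapped between datasets are recoded (g → 2−g); markers whose alleles
conflict, or match only under strand complementation (A/T- and C/G-type
ambiguity, unresolvable without frequencies), are dropped and reported.

**Quality control** removes, in order: non-autosomal and position-less
SNPs, SNPs with more than 10% missing genotypes, and individuals with
more than 5% missing genotypes re-evaluated on the surviving SNPs.
Because removing an individual can push a SNP's missing fraction over
threshold (and vice versa), the SNP/sample passes repeat until stable.
This makes the filter idempotent — a property the test suite asserts —
at the cost of occasionally removing slightly more than a single-pass
implementation would; the report carries cumulative counts per rule.
No minor-allele-frequency filter is applied: monomorphic SNPs are
legitimate content for diversity denominators and F_ROH.

**LD pruning** slides a 50-SNP window in steps of 5 along each chromosome
(never across chromosomes). Within a window, while any retained pair has
r² above 0.1, the largest-r² pair is found (ties: first in index order)
and one member removed — the SNP with higher missingness, or the larger
index on a tie — so output is deterministic. r² is the squared Pearson
correlation of dosages over pairwise-complete samples (unphased,
Rogers–Huff style); pairs with fewer than 10 complete samples or a
monomorphic member are undefined and never trigger removal. Because
removing a SNP does not change the r² of remaining pairs, the window's
correlation matrix is computed once.

## Diversity statistics

Aggregation bases are chosen to mirror the magnitudes such breed tables
report (per-individual SEs of order 10⁻³ for H_o over tens of animals,
per-SNP SEs of order 10⁻⁴ for H_e over 10⁵ markers):

* H_o: per-individual fraction of heterozygous calls among non-missing
  calls; mean ± SE over individuals.
* H_e: per-SNP unbiased `2p̂(1−p̂)·2n/(2n−1)` from breed allele
  frequencies (n = individuals observed at that SNP); mean ± SE over
  SNPs, monomorphic SNPs included. The correction factor makes H_e at
  least the plug-in `2p̂q̂` at every SNP for finite n.
* F_IS: per individual, `(O_hom − E_hom)/(L_obs − E_hom)` where `E_hom`
  sums `1 − H_e(snp)` over the SNPs that individual observed (the
  standard method-of-moments statistic); mean ± SE over individuals.
  Negative values are reported as computed.

## F_ST and genetic distances

The default estimator is Weir & Cockerham (1984) for two populations:
per-SNP variance components a (between populations), b (between
individuals within), c (within individuals), combined across SNPs as a
ratio of averages `Σa/Σ(a+b+c)`. SNPs monomorphic across the pooled pair
or unobserved in either breed are excluded; estimates are not truncated
at zero. The original study computed F_ST in a commercial package without
naming the estimator; Weir–Cockerham is the field default and is
well-defined for unbalanced samples. The Hudson estimator (Bhatia et al.
2013, ratio of averages) is provided as an alternative. A breed's mean
F_ST (MF_ST) is the arithmetic mean of its off-diagonal pairwise values.

Nei's (1972) standard distance is the default distance:
`D = −ln(J_xy/√(J_x J_y))`, gene identities summed over both alleles and
all pairwise-complete loci before the ratio, clipped at 0 against float
noise. Because the literature the study cites is ambiguous between Nei's
D and a drift-corrected variant, a Reynolds-type coancestry distance
`θ = Σ(p₁−p₂)² / Σ(1 − p₁p₂ − q₁q₂)` is exposed as an option. Note that
D carries an upward sampling bias of order `(Σ2pq/2n)/ΣJ` with no
sample-size correction — visible as a small positive D between two
samples of one population (quantified in the test suite).

PCA follows Patterson scaling: dosages centred at `2p̂` and divided by
`√(p̂(1−p̂))` with frequencies over all samples, missing cells zero after
centring (mean imputation — deterministic and standard for genotype
PCA), monomorphic SNPs dropped, eigendecomposition of the sample
covariance `XXᵀ/L`. Coordinates are eigenvectors scaled by the square
root of their eigenvalues; variance fractions are percentages of the
non-negative spectrum, hence non-increasing with sum ≤ 100.

## Runs of homozygosity

A run is a maximal stretch of one individual's genotypes on one autosome
satisfying all of:

1. at least `l_min` SNPs, with
   `l_min = max(1, ⌊ln(α/(n_s·n_i)) / ln(1−het)⌋)` — the expected number
   of chance all-homozygous stretches of that length across the whole
   dataset is below α (default 0.05). By default `het` is the dataset's
   mean observed heterozygosity across SNPs and n_s, n_i its own marker
   and sample counts; all are overridable. At high-density-array scale
   (470,962 SNPs, 211 individuals, het 0.343) the bound floors to 50.
2. no adjacent-SNP gap above 250 kb;
3. at least one SNP per 50 kb over the run's span;
4. span at least 2 Mb (end − start + 1, inclusive).

Runs are classified by physical length into half-open classes [2,4),
[4,8), [8,16), [16,∞) Mb — a partition, so class F_ROH values add
exactly to the >2 Mb total. Each class tolerates a number of
heterozygous/missing calls that grows with length (defaults 0/1/2/4 het
and 2/4/8/16 missing), reflecting genotyping error on long tracts; the
cited conventions do not print numbers, so these defaults follow their
spirit and are configurable. Run endpoints must be homozygous
non-missing calls.

Selection is deterministic: among all intervals satisfying every
criterion, segments are chosen longest-first (ties: leftmost), dropping
any candidate that overlaps a chosen segment. The implementation finds
the globally longest valid interval and recurses on the free flanks,
which provably yields the same selection without enumerating the
quadratic interval set inside long homozygous tracts; an exhaustive
O(n²) oracle in the test suite confirms exact equivalence on 100 random
fixtures.

`F_ROH` divides summed segment length by the SNP-covered autosomal
genome (per chromosome: last − first marker position + 1), the same
denominator for every length class. Segments export as BED-like TSV
(0-based half-open, flagged in the header).

## Effective population size from LD

Physical distance maps to recombination fraction through a uniform
genetic map (default 1 cM/Mb, configurable — no sheep-specific map is
assumed) and Haldane's function `c = (1 − e^(−2d))/2`. Within-chromosome
SNP pairs are binned by c (default edges 0.001…0.25); bins with fewer
than 500 usable pairs are flagged unusable, and pairs are subsampled
with a recorded seed above a per-bin cap. Each usable bin inverts the
Sved relation with Hill's sampling term for n diploids:

    r²_adj = r²_mean − 1/n,   N_e = (1/r²_adj − 1)/(4c),   t = 1/(2c)

yielding one (t, N_e) point per bin, truncated to t ≤ 50 by default for
comparability across datasets; the "current" N_e is the largest-c usable
bin. Bins with non-positive r²_adj are flagged undefined rather than
clamped. α-weighting refinements and genetic-algorithm demographic fits
(GONE and relatives) are deliberately out of scope: this inversion is
transparent and testable by simulation recovery, and absolute agreement
with optimizer-based software is not expected — LD-based N_e is known to
be software-dependent.

Calibration on constant-size Wright–Fisher simulations (26 × 100 Mb
chromosomes, 7,800 markers, 150-generation burn-in, 100 sampled
individuals, bins c ∈ [0.01, 0.035]) recovers N_e ∈ {50, 100, 500}
within +13% to +21% (median over 5 replicates). The residual upward bias
has two understood sources: the sampled cohort is one random-union
generation removed from the parental pool, attenuating r² by roughly
(1−c)² per pair, and Sved's hyperbola is itself an approximation to the
unphased genotype r². Both grow with c, which is why the recovery study
reads the low-c bins; the bias is left uncorrected rather than fitted
away, and the test suite asserts the ±30% envelope.

## The synthetic-data generator

The simulator emulates the statistical structure a breed survey rests
on: multiple populations diverged from a common ancestor by pure drift,
individual autozygosity from close-relative matings, 26 autosomes with
bp positions, and array-like missingness.

* Discrete generations, N diploids per epoch; each offspring draws two
  parents uniformly with replacement (selfing allowed, as in the
  canonical Wright–Fisher model), so per-generation drift variance is
  exactly `p(1−p)/2N` — the drift-variance and martingale tests assert
  this against the realized founder frequencies.
* Recombination: Poisson crossover count per gamete at the map length,
  positions uniform, no interference; chromosomes assort independently
  via a fair phase flip at each chromosome start.
* No mutation: fixtures start from standing variation with founder
  frequencies U(0.05, 0.95), mirroring the ascertained content of SNP
  arrays. Marker positions are uniform random distinct bp.
* Sheep-like defaults: 26 chromosomes × 100 Mb, ~1,500 SNPs per
  chromosome, 1 cM/Mb, missing rate 0.005.
* Sampling: emitted individuals form a random-union offspring cohort of
  the final generation rather than a without-replacement draw of its
  members. Picking members of a small population removes one
  generation's drift from what an F-statistic can see (the estimator's
  sampling correction absorbs it, giving E[θ̂] = 1−(1−1/2N)^(t−1)); the
  cohort makes the textbook expectation `1−(1−1/2N)^t` exact, which the
  drift-recovery test verifies to within Monte-Carlo error.
* Splits copy the ancestral haplotype pool into isolated descendants;
  planted matings (sire × daughter, or full-sib) produce individuals
  with pedigree F = 1/4 whose IBD tracts come from the same
  recombination process. All randomness flows from a single seed through
  `numpy.random.SeedSequence` spawning; fixtures regenerate bit-for-bit
  from their stored YAML.

What the generator does **not** emulate: mutation, selection,
ascertainment bias beyond the founder-frequency law, genotyping error
(missingness is random, not clustered), sex chromosomes, overlapping
generations, migration, and population substructure within a breed.
Passing tests therefore demonstrate estimator correctness under the
idealized neutral model, not robustness to those real-data features.

## Problem sizes used by the test suite

Chosen once as the smallest scales at which the tested expectations are
statistically resolvable: drift calibration at N = 10,000 for 5
generations over 2,000 SNPs (χ² at 1%); F_ST drift recovery at N = 100,
t = 10, 5,000 SNPs, 50 samples per side, 5 seeds; pedigree-F recovery
with 20 matings and 20 controls on a 20 × 100 Mb genome at 2,500 SNPs
per chromosome (50 kb median spacing keeps the density criterion
satisfiable) over a 2-generation N = 100 base population, so controls
carry background F ≈ 0.01; N_e recovery as described above; the
three-breed pipeline fixture at 6 × 250 SNPs.

## Numerical conventions

Ties and degenerate inputs are resolved deterministically everywhere
(documented per operation above). Report tables are TSV with
`#`-prefixed metadata headers carrying the SHA-256 configuration hash
and seed; floats print at %.6g. Byte-identical reruns are guaranteed for
a fixed config, inputs and platform; cross-platform bit-exactness of
floating point is not promised and the manifest records versions for
that reason. Breeds with fewer than 10 individuals, or with no usable
recombination bin, are skipped by the N_e stage with a warning (reported
as NA) rather than failing the whole run, since small census sizes are
expected in conservation datasets.

## Known limitations

* The ROH scanner's proprietary counterparts differ in window semantics;
  equality with tables produced by such software is expected only
  approximately.
* N_e estimates inherit the Sved-inversion bias characterized above and
  are sensitive to admixture and substructure, which inflate LD.
* Nei's D lacks a small-sample correction (by definition); distances
  between small samples of similar populations are biased upward.
* The merge step drops strand-ambiguous markers instead of attempting
  frequency-based strand resolution.
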