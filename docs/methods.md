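# Methods

`clinepool` re-implements, as a reusable and fully testable pipeline, a
pool-seq analysis of latitudinal differentiation among three *Drosophila
melanogaster* populations (a southern, an intermediate and a northern pool
along the North American east coast). This note records the statistical
models, the defaults and why they were chosen, the numerical conventions,
and the limits of what the synthetic validation can show.

## The data model

Pool-seq estimates allele frequencies from read counts over a pooled DNA
sample rather than from genotypes. Two nested sampling layers separate the
population frequency *p* from the observed read frequency:

1. the pool holds *n* chromosomes drawn from the population
   (k ~ Binomial(n, p));
2. sequencing draws M reads, effectively with replacement, from the pool
   (reads ~ Binomial(M, k/n)), plus a per-base error ε that relabels a read
   uniformly among the other three nucleotides.

All estimators correct for both layers. Pool sizes are counted in
chromosomes: a pool of f diploid females contributes n = 2f copies of every
chromosome, including the X (the default study pools F/P/M use n = 78, 204
and 172, at latitudes 25.53, 39.88 and 44.02 °N). Relatedness within
isofemale lines (which reduces the effective pool size) is deliberately not
modelled; the estimators being validated ignore it too, so modelling it
would test a different procedure than the one implemented.

## Site filtering

A site enters the analysis SNP set iff (i) each pool's nucleotide coverage
lies in [10, cap_pool], where cap_pool is the empirical 98% quantile
(linear interpolation) of that pool's coverage — absolute caps from any
particular sequencing run are data-specific, so caps are always recomputed
from the input; (ii) the site lies in the configured normally recombining
regions and outside repeat/indel masks; and (iii) the second-most-frequent
allele, summed over all pools, has count ≥ 6. The threshold is interpreted
as a *pooled* count (about two copies per population on average), not
per-pool. Major/minor alleles are chosen by pooled counts with alphabetical
tie-breaks for determinism; at sites with a third allele the two most
frequent are kept and flagged multiallelic. Downstream exact tests and
F_ST use only those two alleles; the handful of third-allele (mostly
error) reads are excluded from the effective coverage there.

## Diversity estimators

Per-site heterozygosity:

    pi = [n/(n-1)] [M/(M-1)] (1 - sum_a (c_a/M)^2)

which is unbiased for the population heterozygosity 2p(1-p) under the
two-layer model (verified by Monte-Carlo in the test suite). The min-count
truncation applied during SNP calling biases pi slightly at the rare end;
this is accepted and quantified by the same Monte-Carlo oracle, because the
statistic is used comparatively.

Watterson's theta divides the segregating-site indicator by a
detectability-corrected denominator

    a*(n, M, b) = sum_{i=1}^{n-1} (1/i) P(b <= K_i <= M-b),
    K_i ~ Binomial(M, i/n)

with minimum count b (default 2): the classical harmonic sum, with each
frequency class weighted by the probability that it is actually observed at
least b times in M reads. As M grows with b = 1 this recovers the classical
denominator. An independently coded brute-force double sum serves as the
oracle over the full (n ≤ 20, M ≤ 50, b ≤ 3) grid.

Tajima's D is computed after subsampling every site without replacement
(hypergeometric, seeded) to a fixed coverage of 25 reads with b = 1; sites
below 25 reads are dropped, not up-sampled. Tajima's variance constants are
evaluated at the nominal sample size min(n, 25). Because D here depends on
the subsampling coverage and window size, it supports only relative
comparisons among pools processed identically — never absolute comparisons
across studies.

Window summaries use non-overlapping 200-kb windows; a window is flagged
invalid when fewer than 60% of its SNPs meet the coverage criteria.

## Pairwise F_ST

The heterozygosity-partition form is used: pi_within is the mean of the two
pools' unbiased per-site estimates; pi_total applies the same estimator to
the summed read counts at pool size n_i + n_j and coverage M_i + M_j;
F_ST = (pi_total - pi_within)/pi_total. Negative values are retained (they
only populate the lower tail, which candidate calling never touches), and
sites monomorphic in the combined sample are undefined.

Two numerical consequences are worth knowing:

* identical count vectors do not give exactly 0 but the fixed offset
  1 - mean(C_i, C_j)/C_pair with C = [n/(n-1)][M/(M-1)] — about
  -(1/(2M) + 1/(2n)). A variant that is exactly zero on identical input
  exists (sharing one correction factor) but carries a compensating
  positive bias of the same magnitude on every site, which destroys
  calibration; the unbiased convention was kept.
* for two demes drawn from a Balding–Nichols model with per-deme divergence
  F, the estimand of this statistic is F/(2-F), not F: the pooled pair is
  itself differentiated from the ancestor by only half the variance. The
  calibration test therefore compares the genome-wide (ratio-of-sums)
  estimate against F/(2-F); the median of per-site ratios is *not* a
  calibrated estimator of anything at low F (per-site F_ST at F ≈ 0.02 and
  coverage 45 is noise-dominated and skewed), which is why gene- and
  window-level means, and rank-based outlier selection, are the quantities
  the pipeline actually interprets.

Gene-level F_ST is the mean of defined SNP-wise values over the gene span
(UTR to UTR) ± 1 kb, with SNPs in overlapping genes counted for every gene.

## Candidate calling

Two-pronged: (1) SNPs in the upper 0.5% tail of the pairwise F_ST
distribution (rank-based, floor(0.005 N) SNPs; cutoff ties broken by
smaller exact-test p, then genomic position), conditioned on a two-sided
Fisher exact test of the major/minor counts in the two pools surviving
FDR control at q < 0.01; (2) genes in the upper 5% tail of mean gene F_ST,
with the overlap fraction |SNP-defined ∩ gene-defined| / |gene-defined|
reported. Exact-test p-values are computed for *all* SNPs — they are also
the input of the decay profile — and q-values are taken over all of them.
Benjamini–Hochberg with π0 = 1 is the default FDR (an LBE-style π0
estimate would be less conservative but adds a tuning choice; a Storey-λ
option exists behind a flag). The exact test itself is a vectorised
log-gamma hypergeometric enumeration with a 1e-7 relative tie tolerance;
it matches a full enumeration for every table with margins ≤ 30 and
scipy's implementation on random tables.

Candidate-set overlap against an external gene set is assessed by
permutation: |set1| genes drawn uniformly from the universe, p =
(1 + #{perm ≥ obs})/(1 + n_perm).

## Decay of significance around candidates

For each candidate, flanking SNPs within ±100 kb are binned by signed
distance (floor(d/window), window 100 bp coarse / 10 bp fine), the focal
SNP's own p excluded at offset zero; -log10(p) values are pooled across
focal SNPs (not median-of-medians) and the per-bin median reported. The
background repeats this around an equally sized, per-arm, seeded random
draw of non-candidate SNPs at least a configurable distance (500 kb at
genome scale) from every candidate. On desk-scale synthetic arms (a few
Mb) that exclusion radius leaves no eligible SNPs, so validation runs use
a proportionally smaller radius (20 kb on a ~7.5 Mb arm); the quantity
being checked — flat profile without linkage, elevated plateau inside an
inversion block — is unaffected by the radius.

## Feature annotation

Each SNP receives exactly one feature by severity precedence:
nonsynonymous > synonymous > 5'UTR > 3'UTR > intron > upstream 1 kb >
downstream 1 kb > other > intergenic ("other" = genic but unclassifiable,
e.g. inconsistent CDS phase or missing coding sequence, so it outranks
intergenic). Synonymy is decided by translating the codon with each
segregating allele substituted (standard codon table, strand-aware,
evaluated across all isoforms of all covering genes). Enrichment of
candidates per feature uses 2×2 chi-squared tests without continuity
correction (1 df, α = 0.01), falling back to Fisher's exact test when an
expected cell is below 5 (flagged in the output).

## GO enrichment with gene-length correction

Long genes hold more SNPs and therefore collect more false-positive
candidate SNPs; gene-level tests against a uniform-gene null inherit that
bias. The permutation test draws |candidates| SNPs uniformly from all
analysed SNPs in each permutation, maps them to genes (± 1 kb, all
overlapping genes), and counts *distinct* genes per category (complete
linkage of SNPs within a gene). Categories with fewer than 5 annotated
genes in the universe are excluded. p = (1 + #{perm ≥ obs})/(1 + n_perm)
with BH FDR across categories. The reference tool for this design runs
10^7 permutations; the default here is 10^5 (configurable) — at the
category sizes of a desk-scale study the attainable resolution is the
binding constraint well before permutation count.

Because the count statistic is discrete, the reported p is conservative by
construction (ties count against the candidate set) and is *not* exactly
uniform under the null. The output therefore also carries a Lancaster
mid-p column (`p_mid`, half-weight on ties), which is the appropriate
quantity for calibration diagnostics; the validation suite checks KS
uniformity of the mid-p and, separately, that the reported p is never
anti-conservative. A deliberately length-biased fixture (60 long genes
holding five times the SNP density of 600 short ones) demonstrates that a
naive gene-sampling hypergeometric test is strongly anti-conservative for
the long-gene category while the SNP-permutation p is calibrated.

## Inversions

Breakpoint-delimited spans (e.g. In(3R)Payne) are configuration input —
cytological-to-sequence conversion is out of scope. Per population, a
Fisher exact test compares candidate proportions inside versus outside the
span (same arm only; an all-zero candidate column is a valid degenerate
table with p = 1). Per pair, a two-sided Wilcoxon rank-sum test compares
SNP-wise F_ST inside versus outside, with medians reported. Inversion
frequencies are estimated from diagnostic marker SNPs as inversion-allele
read fraction per pool, summarised by the median across markers; marker
homogeneity is tested by a seeded Monte-Carlo exact test on the K×2
marker-count table (sampling tables with fixed margins via the
multivariate hypergeometric). The published 8-bp indel marker has a SNP
surrogate in synthetic data — indel genotyping requires alignment-level
evidence that a count pipeline does not carry.

## Clinal trajectories

Candidate SNPs are oriented to the allele that rises (weakly) from the
southernmost to the northernmost pool (exact ties keep the minor allele
and are classed "tie"); slopes s1 (south→mid) and s2 (mid→north) are
frequency change per degree latitude; classes are the sign pairs ++, +-,
-+ (zero slopes excluded from ++ for determinism). The core clinal set is
the union of ++ SNPs over the three pairwise candidate sets, de-duplicated
by position, with contributing pairs recorded. Significance requires class
++ plus pairwise-disjoint exact 95% Clopper–Pearson intervals (Beta
quantile form; x = 0 and x = n use the closed-form bounds) for all three
pool pairs, on the oriented allele count with n = read coverage — reads
are the observed binomial trials; using min(coverage, pool size) instead
is available behind a flag. Touching intervals are not disjoint. Under
the rising orientation, F–P and P–M disjointness implies F–M disjointness
(asserted as a property).

Note the power implication: at ~45× coverage the 95% CI half-width near
p = 0.5 is ≈ 0.15, so significance effectively requires adjacent-pool
frequency gaps ≳ 0.28. Linear-in-latitude clines concentrate only 22% of
their total change between the intermediate and northern pools, so even a
Δp = 0.6 cline is rarely flagged at this coverage — the flag identifies
steep, well-measured clines only, which is its purpose.

## Comparative statistics

Window means are compared by a two-way ANOVA on globally rank-transformed
values with factors chromosome arm and population/pair, without the
interaction term (uninterpretable after rank transformation), followed by
Tukey's HSD per significant factor; and by Kruskal–Wallis tests on 200-kb
window values with pairwise Wilcoxon rank-sum post-hocs reported only when
the omnibus p < 0.05. Standard test implementations come from statsmodels
and scipy; this module owns only the design (global ranking, no
interaction, window granularity).

## The synthetic generator: what it does and does not emulate

`synthetic_data` generates the full study — sync counts, truth tables,
gene models tiling each arm (two length classes, so GO length bias is
reproducible), GO associations, CDS sequences, masks and inversion
configuration — deterministically: identical config and seed give
byte-identical files.

Frequency classes: neutral SNPs draw an ancestral frequency from a
truncated Beta(0.5, 0.5) on [0.05, 0.95] (a rough U-shaped spectrum that
avoids sites doomed to fail the count filter) and per-pool frequencies
from Balding–Nichols at baseline F_ST 0.02 (weak neutral structure);
clinal SNPs run linearly in latitude from a base frequency of 0.1 with a
configurable total change Δp (default 0.5); SNPs inside a configured
inversion span are pulled toward the inversion frequency q_pool with
linkage coefficient L (p = L·q + (1-L)·p_neutral); marker SNPs sit at
q_pool exactly. Coverage is Poisson(45) truncated at ≥ 1 — the study
design this emulates had uniform coverage, so positional coverage
structure is not modelled. Linkage is represented at the frequency level
only: no haplotypes, no recombination, no LD between neighbouring SNPs.

Consequently, passing tests demonstrate correctness of the estimators and
error control *under the stated sampling model* — they say nothing about
mapping artefacts, allele-specific error structure, LD-induced
non-independence of SNPs (the decay profile on synthetic data is flat by
construction except inside the inversion block), or isofemale-line
relatedness. Problem sizes in the validation suite (one arm of 50,000
SNPs for candidate recovery, 20,000 for the inversion study, 10 × 50,000
null SNPs for FDR control, 200 × 10^4 permutations for GO calibration)
were chosen as the smallest scales at which the target quantities are
statistically resolvable.

## Known limitations

* Tajima's D normalisation at min(n, 25) is conventional, not exact, for
  pooled data; only relative use is supported.
* The per-site F_ST distribution at low differentiation is dominated by
  sampling noise; interpret tails (outliers) and aggregates, not per-site
  values.
* The candidate pipeline's recovery of planted clines depends strongly on
  effect size relative to the empirical outlier threshold; at Δp = 0.5,
  coverage 45 and a 0.5% tail, about a third of planted SNPs fall below
  the threshold by sampling noise alone.
* GO annotations are taken as given (no GO-graph propagation).
* snpEff-style effect ontology beyond the feature classes above (splice
  sites, start/stop changes, multi-nucleotide variants) is out of scope.
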