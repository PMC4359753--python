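# Methods

`poolinv` infers the frequencies and dynamics of polymorphic chromosomal
inversions from pooled sequencing (Pool-Seq) data. Inversions suppress
recombination in heterokaryotypes, so chromosomes carrying an inversion
accumulate diagnostic sequence differences from all other arrangements on
the same arm. The package discovers such diagnostic marker SNPs from
karyotyped haplotype panels, reads an inversion's frequency in a pooled
sample off the mean frequency of its marker alleles, tests frequency change
across replicates, and compares observed changes against a neutral
Wright–Fisher null. This note records the models, parameter choices and
numerical conventions.

## Paternal-haplotype reconstruction

Karyotyped males of unknown genotype are crossed to females of a strain
homozygous for standard arrangements; sequencing an F1 larva then exposes
the paternal haplotype: at a site where the larva is heterozygous the
non-reference allele is paternal, at a homozygous-reference site the
paternal allele equals the reference. Calls are made per site and larva
after a filter cascade:

1. sites residually polymorphic in the maternal reference strain
   (minor allele frequency > 10% in a sequenced pool of reference females)
   are excluded outright;
2. (i) larva coverage < 15 → filtered (sampling error makes heterozygote
   detection unreliable);
3. (ii) larva coverage above the 95th percentile of that larva's
   genome-wide per-arm coverage distribution → filtered (duplications,
   mismapping);
4. (iii) alleles with summed count < 20 across all larvae → dropped;
5. (iv) more than two surviving alleles → the two most frequent retained
   (an exact tie between ranks 2 and 3 is undecidable and filters the site);
6. (v) a larva showing both retained alleles must have both counts inside
   the central equal-tailed 90% exact binomial interval for p = 0.5 at its
   coverage (boundaries inclusive; the interval is symmetric about
   coverage/2). For 20× the acceptance region is [6, 14]: 10/10 passes,
   17/3 fails.

Two conventions deserve note. The upper-coverage percentile uses the
nearest-rank definition (the smallest observed value with at least 95% of
observations at or below it), so the threshold is always an observed integer
coverage and is exactly reproducible. And a larva with *any* read support
for an allele that (iii)/(iv) dropped at the site level is filtered rather
than coerced to a homozygous-reference call: such a larva may be a true
heterozygote whose paternal allele fell below the site-wide count minimum,
and calling it reference would be systematically wrong. This strictness
makes reconstruction exact in the noiseless limit (verified by simulation)
and keeps accuracy at ~100% under a 1% sequencing-error model, at the cost
of call rate — a larva carrying a single stray error read at a site is not
called there.

## Marker discovery

A marker for inversion *I* is a biallelic position on *I*'s arm where all
informative chromosomes carrying *I* share one allele, all informative
chromosomes not carrying *I* (standard arrangements pooled with overlapping
inversions) share a different allele, and at least 80% of chromosomes in
each class are informative (non-missing). Missing data counts against
informativeness only; fixation is judged over informative chromosomes.
Sites with more than two alleles across the pooled comparison are excluded:
a fixed difference is biallelic by definition. Fixation is strict — a single
discordant informative chromosome disqualifies a site — with the
informativeness threshold (`informative_min`) as the only relaxation knob.

## Pool frequency estimation

For each pool, an inversion's frequency is the unweighted arithmetic mean
over its markers of inverted-allele count / (A+T+C+G coverage). N and
deletion counts never enter the denominator (the markers are SNPs).
Markers are dropped below a minimum coverage (default 10×; a 3× preset
suits shallow data sets) and above the 95th percentile of that pool's
genome-wide coverage distribution, computed from all sync records of the
pool, not just marker positions. A pool–inversion pair where no marker
survives yields an explicitly missing estimate (NaN), never zero. A
coverage-weighted mean is available behind a flag but is not the default:
with the binomial read-sampling model the unweighted mean is already
unbiased, and weighting couples the estimate to coverage heterogeneity.

At 30× mean coverage and 40 markers the estimator's standard error is about
√(p(1−p)/(40·30)) ≈ 0.013 at p = 0.25; simulation with 1,000 pools gives
|bias| < 0.005 and mean absolute error < 0.02, as the acceptance suite
verifies.

## Statistical tests

**CMH across replicates.** Frequency change between two time points with
replicate populations is tested per marker by a Cochran–Mantel–Haenszel
chi-square over the replicate strata (2×2 tables of inverted/other allele
counts at the two time points), without continuity correction by default.
The classical hypergeometric variance with its n−1 term is used, matching
R's `mantelhaen.test` and statsmodels; for a single stratum the statistic
equals (n−1)/n times the Pearson chi-square. Strata with an empty margin
are uninformative and dropped with a warning. Per-marker p-values are
summarized by their arithmetic mean. That mean is a descriptive summary —
it is *not* a calibrated combined test and is labelled `summary_p`;
Fisher's method is available for a calibrated combination.

**FET along clines.** Without replicates (latitudinal data), each marker is
tested by a two-sided Fisher's exact test between the lowest-latitude
population and every other population, with the same mean-p summary.

**Two-way ANOVA on karyotype frequencies.** Per-replicate inversion
frequencies (count/n) are fitted with the fully factorial fixed-effects
model frequency ~ inversion + regime + inversion×regime. The bundled
6 × 2 × 3 layout is balanced, so the sums-of-squares type is immaterial;
an unbalanced layout is rejected. An effect whose sum of squares is exactly
zero reports F = 0 (p = 1) rather than 0/0. Inputs are exact count/n
frequencies; a `round_to=2` option reproduces analyses run on 2-decimal
published tables (the two differ by ~1% in F on the bundled data).

## Diversity and LD within arrangements

π uses the unbiased site-frequency form Σ n/(n−1)(1 − Σ p²) divided by the
accessible site count (sites with ≥ 2 informative haplotypes); on biallelic
sites this is n/(n−1)·2p(1−p) and equals the mean pairwise difference per
site exactly. The default window is 100 kb, non-overlapping; a flag divides
by the nominal window length instead of accessible sites when the input
covers every unmasked base. F_ST between arrangements is the π-based
Hudson-style (π_total − π̄_within)/π_total with the unweighted mean of the
two group diversities; negative estimates are clamped to zero with a
warning, and groups below 5 haplotypes trigger a small-sample warning
(minimum 2 — arrangement classes as small as 3 chromosomes occur in real
panels and are accepted).

LD is r² = D²/(p_A(1−p_A)p_B(1−p_B)) with pairwise deletion of haplotypes
missing either allele; monomorphic sites are undefined and excluded from
sampling. The inverted/standard LD contrast inside an inversion is the
ratio of mean r² over sampled polymorphic SNP pairs (default 5,000 SNPs)
after seeded subsampling of the more frequent arrangement to match group
sizes, since r² depends strongly on haplotype number. All subsampling is
reproducible bit-for-bit given a seed.

## Wright–Fisher null

Neutral drift is simulated forward by binomial resampling of n_copies
chromosome copies per generation with absorption at 0 and 1. The effective
size parameter N (default 200) is read as a diploid size, n_copies = 2N:
inversions segregate on chromosomes in diploid populations. A haploid
reading (n_copies = N) is available behind a flag; the choice shifts the
drift variance by roughly a factor two and should follow how N was
estimated. Replicates start at their observed (marker-based) starting
frequencies and run for their own generation counts (e.g. 60 for a hot
regime, 34 for a cold one). The empirical p-value over 100,000 iterations
(default) is the fraction of simulated experiments in which the polarized
change — signed by each replicate's observed direction — strictly exceeds
the observed change in *every* replicate. A replicate with zero observed
change has no polarity; it is flagged and its exceedance condition becomes
|simulated change| > 0. Zero exceedances are reported as p < 1/iterations.
The simulator satisfies the drift martingale (E p_t = p0) and the closed
form Var p_t = p0(1−p0)[1−(1−1/n_copies)^t] within Monte-Carlo error.

## Synthetic data

The generators emulate the structure of the real study designs with exact
ground truth:

* **Panels** plant a configurable number of diagnostic fixed differences
  inside the inversion interval (uniform, or clustered within a window of
  either breakpoint to mimic inversions whose divergence is confined to the
  breakpoints) on a background of shared SNPs whose allele frequencies are
  independent of karyotype, with independent per-genotype missingness.
  Shared sites are re-drawn (keeping their missingness mask) if sampling
  noise would leave them fixed-different after masking, so the planted set
  is provably the complete marker truth — without this guarantee
  "zero false positives" is not a well-defined target at 20% missingness.
* **Pools** draw per-position coverage Poisson (negative-binomial option
  for overdispersion robustness) and inverted-allele counts binomially at
  the pool's true frequency, plus background positions that give the
  genome-wide coverage distribution mass away from markers.
* **F1 counts** draw reads 50:50 from the paternal and maternal allele with
  a symmetric error model flipping reads to a random other base.
* **LD panels** contrast complete recombination suppression (every
  haplotype an intact copy of one of two founders → r² = 1 between all
  polymorphic pairs) with free recombination (independent assortment per
  site → r² ≈ 0), a deliberately extreme caricature of the
  suppressed-recombination mechanism.
* **Selection trajectories** apply the deterministic genic-selection update
  p* = p(1+s)/(1+ps) before binomial drift, for generating non-neutral
  test data only — no selection inference is provided.

What the synthetic data do not emulate: linked background variation around
markers, mapping and reference bias, overdispersed pool sampling beyond the
negative-binomial coverage option, gene conversion and double crossovers
inside inversions, and realistic site-frequency spectra. Passing tests
therefore demonstrate correctness of the algorithms under their stated
sampling models, not robustness to every artifact of real Pool-Seq data.

## Problem sizes and defaults

Default test and acceptance problem sizes are chosen to make sampling error
negligible relative to the tolerances tested: 100 seeded panels
(30 planted markers, 1,000 shared SNPs, 0–20% missingness) for marker
recovery; 1,000 pools × 40 markers × 30× for estimator calibration; 10,000
null simulations for CMH size; 100,000 iterations for the Wright–Fisher
moments and empirical p-values; 1,000 trials per diversity/LD oracle.

## Known limitations

* The mean-p summary has no significance calibration; treat it as a
  descriptive index unless Fisher's method is selected.
* Marker discovery requires strict fixation; a single mis-karyotyped
  chromosome in the panel removes every marker it contradicts.
* The frequency estimator assumes markers remain diagnostic in the target
  population; introgression or gene flux near breakpoints violates this.
* r² on very small matched groups (n < 5) is noisy and its ratio should be
  read qualitatively.
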