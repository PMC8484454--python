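# Methods

## Scope and data model

germflow analyzes cohorts of diploid individuals partitioned into named
groups (regional cultivar groups, wild relatives, and an outgroup species),
starting from a biallelic-SNP VCF. Genotypes are reduced to per-site ALT
dosages (0/1/2, −1 missing); phase is discarded because every statistic in
the package is a function of allele counts. Internal coordinates are
0-based half-open (VCF positions converted on read, BED written natively);
multiallelic records and non-SNPs are skipped and tallied rather than
split, since no splitting rule can be inferred for an externally filtered
SNP set.

## Windowed diversity

Statistics are computed per group in sliding windows (defaults 20 kb / 10 kb
step; the terminal truncated window is emitted and normally removed later
by the effective-site filter).

* π uses the unbiased pairwise estimator `2d(n−d)/(n(n−1))` per site with
  the site's actual called-allele count n.
* H_E deliberately uses the *plugin* estimator `1 − p² − q²` with no
  `n/(n−1)` correction. The two estimators then satisfy
  `H_E = π(2N−1)/(2N)` at full call rate, a systematic π > H_E offset that
  grows as group size shrinks — the pattern germplasm summary tables show
  when both statistics are reported side by side.
* θ_W = S/(a₁·L) and Tajima's D use n = 2N, the group's maximum allele
  count. Per-site n varies with missingness and there is no standard
  windowed correction for that; at the default 0.8 call-rate threshold the
  approximation error is second-order.
* **Effective sites**: the accessible bases of the window (the whole window
  without a mask) minus polymorphic records failing the group's call-rate
  threshold (default 0.8) or with fewer than two called alleles. Invariant
  accessible bases count as callable — the package assumes a SNP-only VCF
  plus an optional accessibility BED, so absence of a record means an
  invariant (not an uncallable) base. Windows need ≥ 8,000 effective sites
  to enter genome-wide summaries.
* Genome-wide summaries are effective-site-weighted means of per-window
  per-bp values (windows overlap at step < size, so this is a smoothed
  mean, not a disjoint partition; Tajima's D is aggregated the same way
  rather than recomputed from pooled counts, which would double-count
  overlapping windows in its nonlinear variance term).
* F_ST uses Hudson's estimator as a ratio of summed per-site components
  within the window and across the genome ("ratio of averages": robust to
  rare alleles, and negatives are reported as computed). Sites fixed for
  the same allele in both groups (0/0 terms) are skipped.
* The sample distance matrix is the p-distance `mean(|dᵢ−dⱼ|/2)` over
  co-called SNP sites, written as a PHYLIP square matrix; because the input
  is SNP-only, distances are relative to segregating sites, which is what
  downstream neighbor-joining on a fixed variant set expects.

## Introgression scans

Sites are polarized against a sampled outgroup *population*: the ancestral
allele is the outgroup's major allele only where its frequency reaches the
fixation threshold (default 0.9); polymorphic-outgroup and
missing-outgroup sites are excluded, as are sites without calls in one of
P1/P2/P3. This treats the outgroup symmetrically with the ingroups rather
than as a single haploid genome.

Patterson's D uses frequency-weighted patterns ABBA = (1−w)xy,
BABA = w(1−x)y, with (w, x, y) the derived frequencies of (P1, P2, P3). The
default reported orientation is `(ΣBABA − ΣABBA)/(ΣABBA + ΣBABA)`, i.e.
**negative D = excess P2–P3 sharing**, matching the convention used when
quartets are read as "recipient = P2, donor = P3"; a flag restores the
textbook orientation. Note the frequency form is antisymmetric under
P1↔P2 (the numerator is y(x−w)), *not* under P2↔P3.

Significance uses a weighted delete-one-block jackknife (Busing, Meijer &
van der Leeden 1999) over fixed coordinate bins (default 5 Mb; the terminal
short bin of each chromosome is kept as its own block; blocks are weighted
by their polarized-site counts). With equal blocks this reduces to the
classic jackknife SE. Two caveats the tests exercise: the SE is 0 (Z
undefined) when all blocks are identical, and localized signal inflates the
SE because signal-bearing blocks deviate from the rest — concentrated
introgression therefore caps attainable |Z| regardless of site count.

f_d follows Martin, Davey & Jiggins (2015): the numerator is the windowed
ABBA−BABA sum and the denominator is the same sum with both P2 and P3
replaced per site by the dynamic donor p_D = max(x, y), bounding the
windowed admixture proportion. Windows with windowed D ≤ 0 get f_d = 0
(retained, so the top-quantile threshold has a defined support); windows
with fewer than 30 polarized SNPs, or with no informative site, are
excluded. Candidate regions are the top 5% of f_d values over all
non-excluded windows pooled across chromosomes (per event; ties at the
threshold are all retained, threshold = k-th largest with k = ⌈q·n⌉),
merged across the window overlap. Event unions are de-duplicated interval
unions; both per-event and union genome fractions are reported.

## Mask-and-recompute contribution analysis

"Removing" a region set drops the SNPs inside it and shrinks the
accessibility mask to the genomic complement, so effective sites contract
accordingly; the windowed summary is then recomputed and the percent
reduction `100(before−after)/before` reported for both π and H_E. Masking
is order-insensitive (union-then-mask equals sequential masking). The
causal contrast — masking top-f_d windows reduces diversity more than
masking an equally sized random window set — holds when introgressed tracts
carry *mixed* donor/recipient ancestry: for a tract with donor-ancestry
proportion α the pooled frequency is (1−α)·p_R + α·p_D, whose variance
deficit raises expected heterozygosity by a factor ≈ (1 − (1−2α(1−α))F) /
(1 − F) relative to background. Fully donor-replaced tracts (α = 1) have
*no* inflation — they are simply donor sequence — so the contribution
analysis is demonstrated on heterozygous-ancestry cohorts.

## Synthetic cohorts

The generator uses the Balding–Nichols frequency model: ancestral
frequency p ~ Uniform(0.05, 0.95) per SNP; each group draws
p_k ~ Beta(p(1−F)/F, (1−p)(1−F)/F) (F = 0 copies p exactly); dosages are
Binomial(2, p_k). Design features mirrored from a real germplasm
resequencing design: nine groups of unequal size (38, 30, 29, 28, 21, 11,
10, 7, 6 diploids) plus a 2-sample outgroup; the outgroup is near-fixed
ancestral with a 0.5% intermediate-frequency polymorphism rate (so
polarization exclusions are exercised); 5% of sites have REF/ALT swapped
relative to ancestral/derived (exercising allele-flip polarization); 2%
missing calls. Realized Hudson F_ST closely tracks the model F and is
rank-monotone in it.

Introgression is injected as tract transfer: inside a tract, each selected
recipient individual (selection probability = admixture fraction) has one
haploid allele per site redrawn as Bernoulli(donor p_k) — heterozygous
introgressed ancestry, tract-level α = fraction/2 — or, with
`haplotypes=2`, both alleles (full replacement, α = fraction). Truth-tract
coordinates, donor/recipient labels and the replaced individuals are
recorded and emitted as BED alongside the VCF, popmap and a JSON model log;
a cohort regenerated from the same seed is byte-identical, and runs with
and without tracts share the same base cohort (paired replicates).

**What the generator does not emulate**: linkage disequilibrium (every SNP
is an independent draw; within tracts the *individuals* carrying donor
ancestry are consistent, but donor alleles are per-site draws), shared
drift between sister groups (all groups radiate independently from one
ancestral pool), demographic history, and selection. Consequently windowed
statistics fluctuate like averages of independent sites (noise ∝ 1/√SNPs
per window, more favorable than real linked data), while quartet "treeness"
noise is larger than in real sister-group comparisons because P1 and P2
share no drift. Passing tests therefore validate the estimators and the
pipeline logic, not performance on linked, demographically structured
genomes.

## Problem sizes and presets

* **Desk preset** (default; smoke runs, null calibration): 2 × 2 Mb genome
  at 4 SNPs/kb (~16,000 SNPs), jackknife block 100 kb (~40 blocks — the
  same block:genome ratio regime as 5 Mb blocks on a ~250 Mb genome; the
  full-genome-scale 5 Mb default would give 2 blocks here and no usable SE).
* **Signal preset** (tract recovery and D significance): 2 × 25 Mb at
  8 SNPs/kb (~400,000 SNPs), 1 Mb blocks, 5% tract coverage split into
  20 × 62.5 kb tracts per chromosome with full donor replacement. The size
  follows from the noise floor: with independent Balding–Nichols sites at
  F = 0.1 the per-site ABBA−BABA deviate has sd ≈ 0.11 against a mean
  denominator ≈ 0.18, so genome-wide D noise is ≈ 0.62/√N while the signal
  from 5% coverage at full replacement is ≈ 0.005 — |Z| ≥ 3 needs N in the
  hundreds of thousands, and the coverage must be spread across many blocks
  (see the jackknife caveat above). Window ranking similarly needs
  ~160 SNPs/window at full replacement (heterozygous-only tracts would need
  window SNP counts beyond even the unscaled study density).
* Null calibration uses 100 seeded desk cohorts at F = 0.05 (|Z| < 3 in
  ≥ 95%; empirical Z sd ≈ 1.02). Signal recovery uses 20 seeded replicates.
  The heterozygous-ancestry masking contrast uses F = 0.25 with 15% tract
  coverage, where the predicted tract heterozygosity inflation (~17%) is
  resolvable over a 4 Mb genome.

## Enrichment

Gene–region overlap is ≥ 1 bp on half-open intervals (a gene abutting a
region boundary does not count). The background universe defaults to every
gene in the annotation table, with an `annotated`-only option for pathway
tables that cover a subset of genes. P-values are upper-tail hypergeometric
(`P(X ≥ k)`; identical to R's `phyper(k−1, …, lower.tail=FALSE)`), q-values
are Benjamini–Hochberg, and pathway hierarchies are treated as flat labels
(hierarchical grouping is a reporting concern, not a statistical one).
Because the hypergeometric test is discrete it is conservative: under a
permuted annotation the raw p < 0.05 rate sits at or below 5%.

## Known limitations

* No LD-aware SE for windowed statistics; only genome-wide D carries a
  block-jackknife error.
* Tajima's D with n = 2N mildly overstates n at incompletely called sites.
* The f_d denominator is noisy in windows where P2 and P3 are both near the
  ancestral frequency; the D ≤ 0 → f_d = 0 rule and the SNP floor bound,
  but do not eliminate, heavy-tailed background values.
* The generator's independence assumptions (above) make absolute power
  estimates optimistic per SNP and pessimistic per window relative to real
  linked data.
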