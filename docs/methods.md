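# Methods

This note records the estimator and design choices in `fusescan`, the
assumptions of the synthetic-data generator, and the caveats a user should
know before interpreting output. Problem sizes quoted here (window sizes,
interval lengths, iteration counts) are package defaults chosen to be
meaningful at desk scale; all are configurable.

## Pool-seq window statistics

**SNP filters** (defaults; `filter_snps`): per-pool read depth in [20, 200]
(a `summed` across-pools rule is available), every observed allele supported
by ≥ 4 reads summed over pools, and pooled minor-allele frequency > 0.05.
Removals are tallied by the first failed rule in that order.

**F_ST.** Per site and per pool pair, a Hudson-type estimator with a
read-depth bias correction that uses depth as the sample size:

    num = (p1 − p2)² − p1(1−p1)/(d1−1) − p2(1−p2)/(d2−1)
    den = p1(1−p2) + p2(1−p1)

where `p` are alt-allele read frequencies and `d` read depths. Subtracting
the binomial sampling variance of each `p` makes the numerator unbiased for
the squared frequency difference, so the estimator has expectation ≈ 0
under no differentiation instead of a depth-dependent positive bias (the
unit suite verifies the zero-mean property by Monte Carlo). Under the
Balding–Nichols model the window-level expectation is the drift parameter
`c`, which the acceptance suite verifies at c = 0.1. Sites fixed for the
same allele contribute (0, 0). Per 10 kb window (5 kb step), F_ST is the
**ratio of averages** — sum of numerators over sum of denominators, pooled
over all native × invasive pool pairs — which is robust to variable SNP
density, unlike averaging per-site ratios.

**θπ.** Per site and pool, the unbiased pooled-read estimator
`π = d/(d−1) · 2p(1−p)`; per window, the per-class mean across pools is
summed over sites and divided by window length in bp. Callable-site masks
are not modelled: absolute π is therefore a lower bound on a real genome,
but the invasive/native **ratio** is unaffected because both classes share
the denominator. The ratio is reported as `log2((π_inv + ε)/(π_nat + ε))`
with ε = 1e−8, so windows monomorphic in both classes get exactly 0.

## Outlier calling

Windows with ≥ 1 SNP are ranked genome-wide. A window is a top-5% (top-1%)
outlier when it is simultaneously at or above the 95% (99%) type-7 quantile
of F_ST and at or below the 5% (1%) quantile of the log2 diversity ratio;
ties at the threshold are included. A second layer (`flag_bf`) additionally
requires ≥ 1 SNP in the window with salinity-association Bayes factor
strictly above 10.

Bayes factors are designed to be **imported** from an external
genotype–environment association run. The built-in surrogate exists so the
pipeline runs end to end without MCMC: per SNP, the Pearson correlation r
between across-pool standardized allele frequencies and standardized
salinity, converted by `BF = exp(ΔBIC/2)` for the slope-vs-intercept linear
model (`ΔBIC = −n·ln(1−r²) − ln n`). With only 4 pools this is a weak,
heavily discretized score; it is labelled `source="surrogate"` everywhere
and is **not equivalent** to an auxiliary-model Bayes factor. Use imports
for inference.

## Enrichment at fusion sites

The background distribution of flagged-window counts is built per
chromosome by sampling N random intervals of fixed length (1 Mb and 2 Mb
defaults) with uniformly drawn starts; window membership is by window
midpoint, which prevents double counting across half-overlapping windows.
The interval centered on each fusion site (shifted to stay on the
chromosome) is scored two ways:

* `p_emp = (1 + #{background ≥ observed}) / (1 + N)` — one-sided, floored
  at 1/(N+1). **This is the primary measure.**
* `significant = observed ≥ 95% background quantile` — with heavily tied
  discrete backgrounds (few flags, small intervals) the 95% quantile can
  coincide with the bulk of the distribution, and this rule then fires at
  far above 5% (including on observed = 0 when the quantile is 0). The
  null-calibration acceptance test verifies ~5% behavior in the
  quasi-continuous regime it is meant for.

Backgrounds are *not* masked around fusion sites, so a true signal spanning
a large fraction of a chromosome contaminates its own null; `p_emp` is then
bounded below by the probability that a random interval covers the signal
— intentional conservatism, not an error.

Set-level tests compare all fusion-site counts on a chromosome, or genome
wide against a background pooled across chromosomes with length-weighted
resampling, using two-sample Kolmogorov–Smirnov and Cramér–von Mises tests.
The CvM p-value is asymptotic when both samples have n ≥ 10; below that it
falls back to a seeded permutation test, subsampling the pooled background
to 2 000 values for tractability (the statistic is computed on the full
samples; only the permutation null is subsampled).

## Gene repositioning

A gene's position value is `100 · min(m, L − m) / L` with `m` the gene
midpoint and `L` the chromosome length — 0 at a telomere, 50 at the exact
center. The midpoint anchor is the default because it is invariant under
chromosome reflection; the start coordinate is available for sensitivity
checks. Comparisons (same gene set across two genomes matched by gene id,
or selected vs comparison sets within a genome) report Welch's t and the
Mann–Whitney U with means, medians and sample sizes.

The permutation analysis draws `n_iter` (default 10^6) same-size subsets
from a gene pool without replacement and records the fraction of draws
against which the selected set tests significant (two-sided p < 0.05) *and*
more central (higher mean for Welch, higher median for MWU; the direction
filter can be disabled). The MWU inside the loop uses the normal
approximation with tie and continuity corrections — appropriate at these
sample sizes and necessary for a vectorized 10^6-iteration run (about 10 s
on one core); the top-level `mann_whitney_u` uses the exact distribution
for tie-free samples up to `nx·ny ≤ 10^4`.

## LD

LD between two SNPs is the squared Pearson correlation of diploid dosage
vectors (composite, Rogers–Huff), requiring no phasing. Pairs are formed at
distances 20–300 000 bp; pairs with fewer than 4 pairwise-complete
individuals or zero dosage variance are skipped. Profiles average r² at
**exact integer distances**; the fusion-vs-background comparison is a
paired t-test across distances shared by both profiles, df = shared − 1
exactly. Exact-distance pairing is why the generator places genotype SNPs
on a regular grid; with irregular real data, shared exact distances are
rare and binning (by the caller) is advisable.

## Synthetic-data generator

* **Pools** (`simulate_pools`): ancestral frequencies uniform on
  (0.05, 0.95); each pool draws its frequency from
  Beta(p(1−c)/c, (1−p)(1−c)/c), the Balding–Nichols model, so the drift
  parameter c equals the expected F_ST in closed form — estimator recovery
  is testable without a coalescent simulator. Sweeps push the
  invasive-class frequency toward fixation, `p' = (1−s)·p + s·round(p)`,
  producing the joint elevated-F_ST / depressed-invasive-π signal. Depths
  are Poisson(25) clipped to [20, 200]; reads are binomial. Limits: sites
  are independent (no LD in the pool data), no sequencing error, and drift
  is exchangeable across pools rather than hierarchical by class.
* **Genes** (`simulate_genes`): non-selected midpoints are uniform;
  selected midpoints follow a symmetric Beta(a, a) with `a` solved
  numerically so that E[100·min(U, 1−U)] hits the target mean position
  value (uniform gives 25; targets must lie in (0, 50)).
* **Genotypes** (`simulate_genotypes`): haplotypes are mosaics over 20
  founder haplotypes with switch probability `1 − exp(−r·gap)` between
  adjacent grid SNPs; `r` is multiplied by 0.1 inside fusion regions. This
  is a haplotype-copying approximation, not a coalescent: absolute r²
  levels depend on the founder count, but the fusion-vs-background
  *contrast* is planted by construction and recovered in ≥ 90% of seeds.

Fixture sets written by `make_fixture_set` are byte-identical for a given
config (no timestamps) and carry a manifest with the config hash.

## Acceptance designs

Recorded here because the choices are easy to misread as arbitrary:

* *Null calibration*: flag density 0.3 on a 20 Mb chromosome with 2 Mb
  intervals gives a background spread wide enough that the 95%-quantile
  rule is near-nominal; sparser designs are dominated by quantile ties
  (see caveat above) and do not measure the rule's calibration.
* *Planted recovery*: 5 × 40 Mb chromosomes, base density 0.05 vs 0.25 in
  2 Mb regions at 10 sites, N = 10^5 — the planted regions occupy 10% of
  the genome, so background contamination leaves p_emp well below 0.05.
* *Repositioning recovery*: the planted alternative is directional
  (selected genes more central by +10 points), so recovery is assessed
  with the one-sided Welch test at 0.05. Two-sided power at n = 25 for
  this effect size is ≈ 0.78 — an honest property of t-tests at that
  sample size, not of the implementation; the one-sided design measures
  recovery of the planted direction.
* *Permutation fractions* reported by `scripts/acceptance.py` are
  properties of the simulated gene configuration (they vary across seeds
  by design); the reproduction of the published fractions requires the
  original gene-position table (acceptance test 1).
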