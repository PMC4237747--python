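# Methods

## Environmental covariate

Day length comes from the sunrise equation with the CBM declination
approximation: δ(d) = −23.44°·cos(360°·(d+10)/365), cos ω = −tan φ·tan δ,
day length = 2ω/15 hours, clamped to 0 h when cos ω > 1 (polar night) and
24 h when cos ω < −1 (polar day).  The year has 365 days and the horizon is
geometric — no atmospheric refraction or twilight correction.  This is
deliberate: the scan is rank-based, and any day-length model monotone in
|latitude| produces identical ranks of Δphotoperiod across populations, so
refinements of the solar geometry cannot change a single scan outcome.
Annual extremes are taken as the min/max over days 1–365 (they fall at the
solstices below the polar circles).  Latitude-range midpoints are the
caller's responsibility.  Other covariates (temperature, radiation flux)
are opaque user-supplied columns of the environment table; the package
never fetches climatologies.

## Correlation scan and empirical ranks

For each SNP the frequency of one fixed allele (allele_b; the choice only
flips the sign of τ) is correlated with the covariate by Kendall τ-b with
the tie-adjusted normal approximation for the two-sided p-value
(scipy.stats.kendalltau).  Tie correction matters here: low-MAF SNPs
produce many identical frequencies across populations.  SNPs with fewer
than three pairwise-complete populations or a constant frequency vector
are flagged, never silently dropped.

Demography moves the whole genome-wide τ distribution, and the power of a
rank correlation also depends on the SNP's frequency.  Both effects are
absorbed empirically: each SNP's |τ| receives a mid-rank percentile
((strictly below + half ties) / bin size) among all SNPs whose average MAF
(folded unweighted mean of per-population frequencies) falls in the same
right-open 0.01-wide bin.  A single-SNP bin gets rank 0.5 with a warning.
Significance is the dual gate: Bonferroni-corrected p < 0.05 (denominator
= the number of SNPs in the analyzed set) AND τ rank strictly > 0.95, as
printed.  Per-gene reduction keeps the significant SNP with the highest
rank, breaking ties by smaller p, then position, then id — deterministic.

A calibration subtlety the test suite documents: under the structured
neutral model below, raw Kendall p-values are *not* uniform, because the
drift variance itself grows with latitude and therefore correlates with
Δphotoperiod; p-value uniformity holds only under an exchangeable null
(frequencies iid across populations).  This is precisely why significance
runs through MAF-binned empirical ranks rather than raw p-values, and why
the rank-gate calibration (≈5% of neutral SNPs above 0.95) is checked on
the structured null.

## Resampling enrichment

The probability of observing n genes with ≥1 significant SNP in a set of m
genes is estimated by drawing m genes without replacement from the
universe of genes covered by ≥1 SNP, re-applying the Bonferroni correction
with *that sample's* total SNP count, and counting samples with ≥ n such
genes over 10,000 repetitions.  The estimator is (count+1)/(reps+1), which
is never 0 and differs from the raw proportion by ≤ 1/10001.  SNP-matched
variants draw genes with the same SNP count (nearest count within a
factor-of-two window when the exact count is absent), and MAF-matched SNP
resampling draws each control within ±0.01 of one observed SNP's average
MAF.  The simpler excess test against a fixed null rate (the 5% rank-gate
expectation) is a two-sided Fisher exact test on
[[observed, total−observed], [round(0.05·total), total−round(0.05·total)]]
with a one-sided binomial tail as a cross-check; the original publication
does not state its 2×2 construction, so these values are reported as this
package's convention and are not tuned to match printed P values.

## Pairwise F_ST

Weir & Cockerham's (1984) two-population θ̂ = a/(a+b+c) from genotype
counts, with observed (not HWE-expected) heterozygosity entering the
within-individual component.  Monomorphic-across-both sites are flagged
missing; pairs with fewer than 2 genotyped individuals are excluded.
Negative estimates are retained: clamping would distort exactly the low
tail that the "below the 0.05 percentile" analysis uses to detect
*similar* allele frequencies in geographically distant, Δphotoperiod-
concordant populations.  Because θ depends on allele frequency, per-pair
values are mid-ranked within 50 equal-width average-MAF classes on
[0, 0.5], and each class's 95th percentile is reported alongside.

## Haplotype tests

**DIND.**  At a polarized focal SNP, iπ_A and iπ_D are the mean pairwise
difference counts among ancestral- and derived-allele carriers over a
window of 20 flanking variants per side (windows are variant-counted, not
distance-counted; chromosome-edge truncation is logged).  DIND = iπ_A/iπ_D;
when iπ_D = 0 the value is capped at the dataset's maximum finite DIND
plus 20, so fully swept sites sort above everything without producing
infinities.  Significance is empirical: above the 95th percentile of a
background DIND–DAF distribution binned into 100 derived-allele-frequency
classes.  A class is not evaluable when its 95th percentile is itself a
capped value (low-DAF classes are dominated by iπ_D = 0) or when it holds
fewer than 20 background values — a percentile from a handful of points
carries no 5%-tail meaning; the lowest evaluable DAF is reported as the
test's empirical floor, mirroring the DAF floors that arise on real panels.

**EHHS / iES / lnRsb.**  Site-EHH at distance k from the focal SNP is the
probability that two haplotypes drawn without replacement are identical
over the interval, Σ n_h(n_h−1)/(n(n−1)) over haplotype classes,
normalized to 1 at the focal site and followed outward until it drops
below 0.05 (the crossing point is kept so the integral covers the decay).
iES is the trapezoid integral of the two-sided curve over physical
position.  lnRsb = ln(iES_pop1/iES_pop2) is computed for every SNP within
100 kb of each selected variant, median-centered over the pooled region
SNPs, and assigned a mid-rank percentile in that pooled empirical
distribution; significance is rank ≥ 0.95 (the tail where pop1's
homozygosity extends farther).  Both the raw and centered values are
exposed; no parametric standardization is applied, matching the
empirical-distribution approach.  Panels carry no missing calls by
construction (the VCF reader rejects missing or unphased genotypes).

## Synthetic data

The generator emulates a worldwide SNP panel's design, not its exact
allele-frequency spectra.  Defaults are the study conditions: 52
populations evenly spaced over 0–70° latitude with an equatorial origin
and 25 diploids each; 10,000 biallelic SNPs with ancestral frequency
p₀ ~ U(0.05, 0.95).

* **Neutral drift** is Balding–Nichols: population k draws its frequency
  from Beta(p₀(1−F_k)/F_k, (1−p₀)(1−F_k)/F_k) with
  F_k = drift_scale·|lat_k − origin|.  The default drift_scale of 0.002
  per degree yields F up to ~0.14 at 70°, in the range of human
  continental differentiation, and reproduces the serial diversity
  gradient the empirical ranks must absorb.  No coalescent machinery is
  used; marker independence is acceptable because every downstream
  statistic is per-SNP.
* **Clines**: a fraction of SNPs shifts the Beta mean on the logit scale
  by ±cline_strength·Δphotoperiod_k (random direction per SNP).  The
  default 0.25 logit/hour makes planted clines reach |τ| ≈ 0.7 over 52
  populations, the regime in which the dual gate is expected to fire.
* **Haplotypes**: polymorphic sites sit on a regular grid (0.5 sites/kb
  over 400 kb by default) with independent per-site derived frequencies —
  no background LD.  A planted sweep places a sweep_daf fraction of
  haplotypes on one core haplotype over per-carrier intervals with
  Exponential(recomb_decay = 50 kb) half-lengths, so identity with the
  core decays with distance, creating the iπ_D collapse and extended EHHS
  that DIND and lnRsb detect.  This copying construction is fast enough
  for 50-replicate power runs on one CPU; what it does **not** emulate is
  neutral background LD, mutation/recombination heterogeneity, or soft
  sweeps, so passing benchmarks demonstrate correct statistics and
  calibration on hard-sweep-like signals, not performance on real panels.

All generators draw from explicit per-stream generators seeded by
(seed, stream name); identical configurations are byte-identical, and no
global random state is touched.

## Numerical and design choices

* Coordinates are 1-based inclusive everywhere; the gene-assignment
  upstream window is strand-aware, [TSS−500, TSS−1] on + genes and
  mirrored on − genes (whether the original analysis was strand-aware is
  unstated; strand-awareness is the defensible reading of "upstream").
* LD collapsing (r² ≥ 0.4) is a single greedy pass in genomic order with a
  seeded coin deciding each pairwise conflict; a candidate replaces a
  retained SNP only when it conflicts with nothing else, so the output
  always satisfies the pairwise r² < 0.4 audit and is reproducible.
* Missing frequencies are excluded from denominators; a population drops
  out of any per-SNP statistic where it is missing.  Multi-allelic VCF
  records are skipped with a warning at ingest.
* "Normalized DAF" profiles are per-SNP z-scores over non-missing
  populations (the normalization in the original figure is undefined);
  numerically constant SNPs (sd ≤ 1e-12) get flat zero profiles.
* Percentile ranks use the mid-rank convention throughout, so the 0.95
  gates are reproducible and rank antisymmetry (pop-swap in lnRsb) is
  exact.
* Table-fixture gates: ranks in the packaged tables are printed to 2–3
  decimals, so high-tail gates are applied inclusively at the printed
  value (a printed 0.950 counts as above the 0.95 gate, matching the
  published tail counts).

## Benchmark scales

The shipped tests and the acceptance script use desk-scale problem sizes
chosen to make each check statistically meaningful on one CPU: 10⁴ SNPs ×
52 populations for scan calibration and recovery, 20 pooled neutral panels
(~4,000 sites) as the DIND background, 50 seeded replicates for DIND and
lnRsb power, and 10 neutral panels (~2,000 sites) for the DIND type-I
rate.  Genome-scale results that depend on real worldwide genotype panels
(e.g. specific empirical P values for real gene sets) are outside what
synthetic data can reproduce and are represented instead by the packaged
worked-example tables.

## Known limitations

* The asymptotic τ p-value is an approximation at 52 populations; extreme
  tails are approximate, which is one more reason the gates are empirical
  ranks rather than nominal p-values.
* The sweep generator produces hard-sweep signatures only; power numbers
  do not transfer to soft sweeps or selection on standing variation.
* The Fisher excess test's 2×2 construction is a package convention (see
  above); only qualitative agreement with published excess P values is
  claimed.
* lnRsb significance is one-tailed toward extended homozygosity in the
  first population; swap the panels for the other tail.
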