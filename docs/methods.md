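# Methods

This note documents the statistical procedures implemented in
`smoltmir`, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the package's known
limitations.

## Study design assumed

Six timepoints labeled T1..T6: T1 before photoperiod manipulation,
T2–T4 during smoltification, T5 one week and T6 one month after
seawater transfer. Small-RNA counts come from 8 replicates per
timepoint (48 samples); microarray-like log2 intensities from 5
replicates per timepoint by default. All fold changes are per-contrast
against T1.

## Small-RNA quantification

Reads are trimmed at the leftmost exact match of a prefix of the 3′
sequencing adapter (`AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC`), minimum
overlap 3 nt; a partial adapter running off the 3′ end still trims.
Error-tolerant adapter alignment is deliberately not implemented: the
synthetic reads are error-free, and the exact-prefix rule is simple to
reason about and to oracle-test. Trimmed inserts outside 18–25 nt
(inclusive) are discarded. Mapping is bounded-mismatch end-to-end
comparison against mature sequences (default 0 mismatches,
U/T-insensitive); a read counts for a feature only when it matches
exactly one reference entry — multi-mappers are tallied but never
counted, so no tie-breaking rule is needed. This replaces a genomic
spliced aligner and is adequate because mature references are ≤ 30 nt
and reads are size-matched; real-data users needing indel tolerance
should map externally and import the count TSV.

A conservation identity (raw reads = adapter-discarded +
length-discarded + no-hit + multi-hit + counted) is enforced in the
mapping statistics.

## Differential expression

**Counts.** Size factors are median-of-ratios over features with
all-positive counts, rescaled to geometric mean 1. Per feature and
contrast, the test is a Wald z on log2 fold change:
log2FC = log2(mean_B + 0.5) − log2(mean_A + 0.5) on normalized counts,
with variance from the NB delta method,
Var(log2 mean) ≈ (1/μ + α)/(n ln²2). Dispersion α is the pooled
within-group method-of-moments estimate max(0, (s² − m̄)/m̄²), shrunk
toward a trend α(μ) = a₀ + a₁/μ fitted across features by least
squares; the final value is 0.25·α̂ + 0.75·α_trend. The heavy trend
weight reflects that the moment estimator has ~14 df at n = 8 and is
the main driver of miscalibration; with it, the empirical type-I error
on a 2000-feature null simulation sits near the nominal 0.05 (checked
in the test suite). Exact equality with any external count-DE package
is explicitly not a goal; the threshold semantics (BH-adjusted
p ≤ 0.05, |log2FC| ≥ 1, baseMean ≥ 10, all inclusive) are preserved.
"log2 fold-change with absolute value ≤ −1.0 or ≥ 1.0" is read as
log2FC ≤ −1 or ≥ +1.

**Intensities.** Per-gene Welch two-sample t-test per contrast on log2
intensities; DE at p ≤ 0.05 and |log2FC| ≥ 0.8 (inclusive). The
original microarray processing stack is proprietary; a t-test on log2
intensities is the transparent stand-in, and quantile normalization is
applied only in real-data mode (synthetic intensities are already on a
common scale).

BH adjustment is the step-up procedure with monotonicity enforcement,
applied within each contrast; adjusting across all five contrasts
jointly is available but off by default, since the contrasts are
reported separately. `de_any` (DE in ≥ 1 contrast) defines membership
in the DE sets.

## Clustering and cluster number

Clustering operates on the 5-vector of log2FC values (T2..T6 vs T1).
Distance is 1 − Spearman ρ (average ranks on ties); constant profiles
are rejected by name rather than silently dropped. Complete linkage is
implemented directly so the tie-break is defined: among equal merge
heights, the smallest (i, j) cluster-index pair merges first; the
result is the standard linkage matrix and is checked against an
independent reference implementation for small n.

Two clustering procedures meet in this design — a hierarchical heatmap
and k-means with the gap statistic — and are reconciled as follows:
the gap statistic on k-means (Euclidean, best of 25 restarts;
reference sets uniform over each dimension's observed range; B = 50
reference draws by default; firstSEmax rule,
Gap(k) ≥ Gap(k+1) − s_{k+1}) chooses k; the hierarchical tree is cut
at that k for the final labels; k-means labels at the same k are
written alongside for comparison. Cluster labels are renumbered by
first appearance along the dendrogram leaf order, making numbering
deterministic.

A shape classifier names cluster-mean trajectories: sustained_decrease
(all ≤ 0, minimum at T6), transient_t5_dip (minimum at T5),
sustained_increase (all ≥ 0). The shipped transcriptions of the
published per-miRNA profile tables reproduce these three shapes from
their cluster means, which is what the classifier is tested against.

## Correlation integration

The expressed filter keeps miRNAs with raw count > 10 (strict) in at
least ⌈2n/3⌉ samples. Gene profiles are per-contrast mean log2FC
vectors, matching the miRNA profile construction. The correlation
coefficient is Pearson by default ("r" conventionally denotes
Pearson); Spearman is a flag, since with only five points both are
defensible. Direction is negative iff r < −0.67 and positive iff
r > +0.67, strict on both sides. A gene negative to several clusters
is reported once, under the cluster with the largest |r| — the
published groups are disjoint but no rule is stated, so argmax |r| is
the package's documented choice.

## Duplex target prediction

The screen requires a perfect Watson–Crick reverse complement of miRNA
positions 2–8 in the UTR (G:U explicitly not a seed match) and a
duplex MFE ≤ −18 kcal/mol, inclusive.

The energy model (`smoltmir.energy`, version `smoltmir-nn-1.0`) is a
nearest-neighbor RNA/RNA set at 37 °C: Watson–Crick stack free
energies from the published Xia/Turner values, approximate published
values for stacks involving G:U wobbles, duplex initiation
+4.09 kcal/mol, +0.45 per A:U or G:U closing pair, and simplified
loop penalties that are monotone non-decreasing in loop size (bulge
3.8 + 0.5·(n−1); internal loop 1.7 + 0.3·(size−2); no stacking energy
across an interrupted step, no asymmetry term). The published bulge
table is non-monotone at n = 2; monotonicity was preferred so that
larger loops are never rewarded. Because the original screen's tool
and parameter set are not bit-reproduced, MFE values are comparable in
rank but not identical to other predictors; only threshold behavior is
asserted anywhere.

The optimizer is a dynamic program over purely intermolecular,
antiparallel pairings (neither strand folds on itself): "helix
constraint 2–8" forces miRNA positions 2–8 to pair contiguously at the
seed site; position 1 and positions ≥ 9 are extended on each side only
where that lowers the energy, with bulges ≤ 9 nt and internal loops
≤ 9 nt per side ("loop constraints 9–9"). G:U pairs are allowed
outside the seed. The scan window is the seed site ± (miRNA length
+ 9) nt, which provably contains every loop-legal structure. The DP is
verified against exhaustive enumeration of all pairings on small
windows, and every reported structure re-scores to its reported energy
through an independent structure-scoring function. Coordinates are
1-based inclusive on the UTR sense strand. Overlapping hits of a
(miRNA, UTR) pair collapse to the lowest-MFE site.

Out of scope by design: target-site accessibility (no intramolecular
folding), conservation filtering, 3′-supplementary context scoring,
and p-values for hits.

## Enrichment

One-sided overrepresentation only: per term,
p = P(X ≥ k | N, K, n) (hypergeometric upper tail, identical to
one-sided Fisher on the 2×2 table, which the tests assert), BH
adjustment, significant at FDR < 0.05 strict. The background defaults
to all genes in the annotation table. Annotations are a user-supplied
gene–term TSV with optional parent links; significant terms are
grouped under their most general significant ancestor (alphabetical
tie-break when several topmost ancestors exist), and a gene may appear
in several groups. External ontology snapshots and cross-species id
mapping are inputs, not package responsibilities, so published
per-term gene counts that depend on a database version are not
reproduction targets.

## Pair table

A predicted hit enters the final table iff its gene is annotated
negative to the targeting miRNA's cluster; rows carry the cluster
label, correlation, site coordinates, MFE and the major-expressed
flag. Major-expressed: within each miRNA family, the mature with the
highest mean normalized count over all samples (ties flag all). An
independent validator pass re-checks every row (seed site present, MFE
at threshold, direction negative). The summary reports distinct gene
and miRNA counts, degree distributions, per-cluster breakdowns and the
fraction of genes covered by ≥ 1 major-expressed miRNA.

## Synthetic data: what it emulates, and what it does not

Defaults (one full dataset in ~15 s): 80 mature miRNAs in 2-member
families, 28 DE across the archetypes (12 sustained decrease, 6
transient T5 dip, 10 sustained increase), archetype trajectories
(T2..T6) of (−0.6, −1.2, −1.8, −2.0, −2.4), (−0.3, −0.2, −0.4, −1.8,
−0.2) and (0.5, 1.0, 1.3, 1.6, 2.0); NB dispersion 0.05 shared across
features; basemeans log-uniform in [100, 500]; per-sample size factors
log-uniform in [0.5, 2] (library sizes in the emulated design vary
more than 3-fold, so normalization must matter); 400 genes with 32
anti-correlated ones (12 to archetype I, 20 to III, none to II,
mirroring the published groups A/B pattern), Gaussian log2 noise
SD 0.25 and unit anti-correlation gain; 24 planted (miRNA, gene) pairs
whose UTR sites are the full reverse complement of the miRNA (verified
≥ 4 kcal/mol below the −18 threshold at construction); decoy UTRs
redrawn until free of any planted seed complement; 75 nt reads with a
2% contaminant fraction outside 18–25 nt; a 50-decoy-term annotation
with one planted enriched term. The generator rejects configurations
whose expected planted |r| falls below 0.67 (truth would be
unrecoverable by construction, not by failure of the method).

Sample sizes, thresholds and the archetype shapes are the emulated
study's conditions; counts per feature are desk-scale (hundreds rather
than the study's 10⁵–10⁶ mapped reads per sample) so that a complete
run, the test suite and the acceptance script stay fast. The simulator
does not model sequencing errors, per-feature dispersion, isomiRs,
cross-hybridization, batch effects, or the salmonid genome
duplication's paralog structure. Passing recovery tests therefore
demonstrates internal consistency of the pipeline under its own
assumptions — planted signal in, planted signal out — not performance
on real libraries, where mapping ambiguity and dispersion
heterogeneity are the dominant difficulties.

## Numerical and procedural choices

- All randomness flows through one `numpy` Generator per dataset;
  identical configs (including seed) produce bit-identical outputs,
  including the run summary JSON.
- NB sampling uses the (n = 1/α, p = n/(n+μ)) parameterization and
  falls back to Poisson for α ≤ 1e-12.
- Welch p-values for zero-variance/equal-mean degenerate genes are set
  to 1 (flagged path, not an error).
- All-zero count features get log2FC 0, p = 1, flagged.
- k-means empty-cluster events are handled by scikit-learn's restart
  machinery (best of 25 restarts).
- Tie-breaks are everywhere deterministic: smallest-index merges in
  linkage, first-appearance cluster renumbering, alphabetical rollup
  roots, stable sorts in BH.

## Known limitations

- The NB Wald test is a documented simplification; features with very
  low counts lean on the dispersion trend, and no outlier handling or
  independent filtering is performed.
- The duplex model ignores target-site accessibility, so it
  over-reports sites buried in mRNA structure; this matches the
  screen being reimplemented, not the state of the art.
- With five-point profiles, correlation thresholds are coarse: |r|
  near the 0.67 boundary is fragile under noise, which is why the
  planted effect sizes sit well away from it.
- Real-data mode expects externally produced count/intensity TSVs to
  be comparable across samples; only quantile normalization is offered
  for intensities.
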