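# Methods

## Scope and data model

The package analyses CpG methylation only. The atomic datum is a CpG's
(methylated, unmethylated) read-count pair in one sample; calls enter as
Bismark coverage files (1-based positions) and every derived interval —
windows, genes, promoters, element tracks — is handled 0-based half-open,
with conversion confined to the readers and writers. Replicates of a
treatment group are pooled by summing counts per CpG before testing;
between-replicate variance is therefore *not* modelled at the windowed
testing stage (see Limitations).

## Filters

**Observation-density filter.** The genome is tiled with non-overlapping
25-kb windows; each window's total observation count (methylated +
unmethylated over all samples) is compared with the box-whisker outlier
rule: flag when count > Q3 + s·IQR with stringency s = 10 and quartiles by
linear interpolation. CpGs in flagged windows are removed. Only tiles
containing at least one observation enter the count distribution —
coverage files carry no information about truly empty tiles. With
s → ∞ the filter is a no-op.

**Coverage filter.** A CpG is retained iff its pooled coverage reaches the
threshold in *every* compared group (default 3 for windowed whole-genome
analysis; 5 for the per-CpG reduced-representation path). For marker-CpG
readouts the rule relaxes to ≥ 3 in *at least one* group, mirroring the
descriptive (non-testing) use of those CpGs. The filter applies to pooled
group counts, not per replicate.

## Adaptive windows

Windows contain exactly `window` = 50 retained CpGs and start every
`step` = 25 CpGs, per chromosome; 20/10 and 10/5 variants are provided for
sensitivity checks. Trailing CpGs that cannot fill a complete window are
dropped rather than emitted short, keeping data content — and hence
technical noise and statistical power — uniform across windows. A
window's genomic span is [first member CpG, last member CpG + 1). Window
methylation per group is the **unweighted mean of per-CpG methylation
percentages**, not the pooled-count ratio, so deeply covered CpGs do not
dominate; the count-based test below deliberately uses a different
summary, and both coexist by design. Windows are recomputed per analysis
cohort, because the retained-CpG set depends on which groups are compared.

Fixed-width bins (default 500 bp every 100 bp, i.e. 400 bp overlap) serve
high-resolution locus profiles; bins without covered CpGs carry a missing
value, never 0%.

## Differential methylation tests

**Windowed (WGBS) test.** Per window and contrast, member-CpG counts are
summed per group into a 2×2 table and tested with Pearson's chi-squared,
df = 1, no continuity correction (pooled window counts are large; the
correction is configurable). Degenerate tables — an empty row or column —
get p = 1 rather than NaN so the FDR input is total. p-values are
Benjamini–Hochberg adjusted across all tested windows of the contrast
(the correction method is configurable; BH is the genome-wide screening
default). A window is a DMR iff p_adj < 0.05 **and** |Δ| ≥ 10 percentage
points, Δ being the difference of unweighted window means; the boundary
is inclusive. Both cutoffs tighten monotonically: raising the delta
cutoff or lowering α can only shrink the DMR set.

**Per-CpG (RRBS) test.** The same chi-squared applied to single-CpG
counts with a ≥ 5-observation filter in both groups, BH across tested
CpGs, same joint cutoff.

**Replicate-sensitive (amplicon) test.** For targeted deep-sequencing
designs with ≥ 2 replicates per group, a binomial GLM of the methylated
proportion on the group indicator (observations weighted by coverage) is
compared against the intercept-only model with a likelihood-ratio test,
df = 1; BH across CpGs; no minimal-difference cutoff. When one group sits
entirely at the 0/1 boundary the MLE diverges (perfect separation); the
model is then refit after adding 0.5 to every cell (Haldane continuity)
and the result is flagged `separation_fallback`.

## Comparative statistics

**Set overlap.** DMR sets live over one shared universe of tested
windows; overlap significance is a one-sided Fisher's exact test on
[[|A∩B|, |A\B|], [|B\A|, rest]] with the *entire tested methylome* as
background, not a directional subset.

**Gene aggregation.** A DMR overlaps a gene when the window span
intersects the transcription span (TSS–TES, introns included) by ≥ 1 bp.
A gene is called differentially methylated when ≥ 2 DMRs overlap it and
the average of their deltas reaches ±10 pp — the averaging deliberately
discards genes with equal extents of hyper- and hypomethylation. Across
conditions, "common" genes need ≥ 2 DMRs per condition, not identical
windows.

**Quadrant directionality.** Windows significant in condition A are
matched to their (unthresholded) deltas in condition B; zero deltas are
excluded; the 2×2 sign table is tested with one-sided Fisher for positive
association.

**Consensus and markers.** The age consensus takes windows carrying a
directional DMR in ≥ 2 strains. Marker candidates are the intersection of
hypermethylated DMR sets across *all* interventions minus every window
genomically overlapping the age-related hypomethylation consensus
(overlap matters because windows overlap their neighbours by
construction). Each marker is refined to a 500-bp subregion for PCR-based
assays by scanning 1-bp candidate starts and maximizing member-CpG count,
ties broken by larger mean |Δ|, then leftmost — an automated, explicit
objective replacing manual curation. Regions shorter than 500 bp are
returned whole and flagged.

**Per-CpG readout.** Methylation change across a marker's CpGs is tested
with the Wilcoxon signed-rank test on paired per-CpG percentages,
two-sided, zero differences dropped; with < 6 informative pairs the exact
null distribution is used and the result flagged small-n. Direction is
reported as the median delta, not folded into sidedness.

## Element enrichment

Enrichment of a DMR set over an element track is the ratio of overlap
frequencies, (n_dmr_overlap/n_dmr) / (n_bg_overlap/n_bg), with the
background = all tested windows of the cohort — not the nucleotide genome
— and overlap binary per window (≥ 1 bp, half-open boundaries exclusive).
Significance by one-sided Fisher with BH across tracks. Tracks are plain
BED, so chromatin states, exon/intron sets, transcription-factor sites
and derived promoter/uiDMR/CGI-class tracks share one code path. Note
that E[log2 ratio] under random DMR draws carries a small negative Jensen
bias when expected overlap counts are tiny.

## Derived annotations and expression integration

Promoters span TSS−5000 … TSS+100 on the plus strand, mirrored on the
minus strand (where the mirrored interval spans TSS−100 … TSS+5000
inclusive of the TSS base, one bp longer by the half-open convention).
uiDMRs — intragenic regions where methylation anticorrelates with
expression — span TSS+300 … TSS+8000, restricted to genes ≥ 16 kb, and by
construction never overlap the same gene's promoter. CGIs are classified
exhaustively and exclusively as promoter / gene / intergenic, promoter
taking precedence.

Expression enters as a precomputed differential-expression table
(gene_id, log2FC, adjusted p, expressed flag); "differentially expressed"
means p_adj < 0.05 with no fold-change cutoff. Gene-level methylation
calls (gene-body variant: ≥ 2 DMRs; uiDMR variant: ≥ 1 DMR on the uiDMR
interval) are crossed with expression signs into quadrants; genes with
|average Δ| < 10 pp are excluded from the statistic but reported. Among
hypermethylated + differentially expressed genes, an exact binomial test
(p₀ = 0.5, two-sided by default — sidedness configurable since the
convention is not fixed by the analysis itself) probes the trend towards
down-regulation.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, at desk scale:

- **Defaults** (chosen once as the reference study conditions): 2
  chromosomes × 25,000 CpGs; geometric inter-CpG gaps, mean 80 bp, with
  dense CGI clusters (30 CpGs, mean gap 12 bp, cluster rate 0.002);
  2 groups × 3 replicates; negative-binomial coverage, mean 10,
  dispersion 5; background methylation μ_bg = 0.80 with beta
  concentration 30, CGI methylation μ_cgi = 0.05; 50 planted
  hypermethylated blocks of 60 consecutive CpGs at +25 pp; genes tiled at
  20 kb with 10 kb gaps, alternating strands; expression coupling
  P(down | hyper) = 0.8, log2FC noise SD 0.5, effect 1.0.
- **Noise architecture.** Each CpG's true methylation level is one beta
  draw around its regional mean, shared by *all* samples: locus-to-locus
  variation is a property of the site, not the animal. Coverage is a
  per-CpG gamma depth propensity (mappability) shared by all samples with
  Poisson draws per replicate — marginally negative-binomial, and
  correlated across samples the way alignment depth is in real libraries.
  Counts are binomial given level and coverage, hence marginally
  beta-binomial (overdispersed). Under this architecture the pooled 2×2
  factorises into independent Poisson margins under the null, so the
  windowed chi-squared is calibrated even across heterogeneous windows
  (CGI/background mixtures) — the measured null raw-p rate sits within 3
  binomial SDs of α on 20-seed cohorts.
- **What it does not emulate:** between-animal biological variance
  (available as `rep_concentration`, under which the pooled test is
  anti-conservative — see Limitations), sequencing error, strand bias,
  read-level structure, SNP-induced artefacts, and non-CpG contexts.
  Passing tests therefore certify the statistical machinery and its
  calibration under the stated noise model, not robustness to replicate
  heterogeneity in real cohorts.
- Planted blocks are placed in disjoint index slots per chromosome so
  they never overlap; shifted levels are clipped to [0, 1] with a warning
  naming the number of saturated CpGs (with the default +25 pp on an 80%
  background, CpGs in the upper beta tail do saturate, so the realized
  block delta is somewhat below the nominal +25 pp — still far above the
  10 pp call cutoff).
  All randomness derives from one integer seed; identical seeds give
  byte-identical output files.

## Numerical and degenerate-input choices

- Chi-squared degenerate margins → (0, 1), never NaN.
- BH via statsmodels' step-up; inputs validated to [0, 1].
- Fisher/hypergeometric tails via scipy's exact routines.
- Window methylation requires positive coverage at every member CpG in
  every group and fails loudly otherwise (the coverage filter guarantees
  it upstream).
- Destranding (merging pos/pos+1 dyads) is optional in the reader; calls
  are otherwise assumed destranded upstream.
- Refinement tie-breaks are total (count, then mean |Δ|, then leftmost),
  making marker refinement deterministic.

## Problem sizes

Unit and property tests run on 1-chromosome cohorts of ~1,500–10,000
CpGs; calibration and recovery checks use the default 50,000-CpG cohort
(≈ 2,000 windows) over 20 and 1 seeds respectively; coupling power/size
use 100 and 1,000 expression simulations of 200 genes. The full suite
completes in well under a minute on one CPU.

## Limitations

- Pooling replicates before the chi-squared test discards between-animal
  variance; with real biological replicate heterogeneity the test is
  anti-conservative. This mirrors the analysis design faithfully; the
  FDR + 10 pp joint cutoff is the practical guard.
- The chi-squared window test and the mean-based delta use different
  summaries (counts vs unweighted means); a window can be significant by
  counts yet miss the delta cutoff, by construction.
- Enrichment is binary per window and ignores overlap extent.
- The marker-refinement objective is a reasonable automation of a
  manual choice, not a reimplementation of it.
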