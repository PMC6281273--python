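# longmeth

Windowed differential-methylation analysis of replicated bisulfite
sequencing cohorts, built for studies that compare hepatic methylomes
across longevity interventions (dietary restriction, growth-hormone
deficiency, rapamycin) and across age.

## Who this is for

Anyone with per-CpG methylation call tables (Bismark coverage files), a
gene annotation, element tracks (CpG islands, chromatin states) and,
optionally, gene-level differential-expression tables, who wants to go
from raw calls to differentially methylated regions (DMRs),
cross-condition shared signatures, element enrichments, candidate marker
regions, and methylation–expression coupling statistics — with every step
scriptable from Python or a shell.

## The method

1. **Pooling and filtering.** Replicates of a treatment group are pooled
   by summing per-CpG methylated/unmethylated counts. 25-kb tiles with
   outlier observation counts (box-whisker rule, count > Q3 + 10·IQR) are
   removed, and only CpGs covered by ≥ 3 observations in every compared
   group are kept (≥ 5 for per-CpG reduced-representation tests).
2. **Adaptive windowing.** The methylome is binned into windows of exactly
   50 retained CpGs, starting every 25 CpGs, so every window carries the
   same amount of data (similar technical noise and power) while its
   genomic span adapts to CpG density. 20/10 and 10/5 variants are
   available, as are fixed-width 500 bp / 100 bp bins for locus plots.
3. **DMR calling.** Per window, a Pearson chi-squared test (df = 1, no
   continuity correction) on the summed 2×2 counts of the two groups,
   Benjamini–Hochberg correction across windows, and a minimal difference
   cutoff: a window is a DMR iff p_adj < 0.05 **and** |Δ| ≥ 10
   percentage points, where Δ is the difference of the *unweighted* window
   means of per-CpG methylation percent. Single-CpG (dCpG) and
   replicate-sensitive logistic-regression variants cover RRBS and
   amplicon designs.
4. **Comparative statistics.** One-sided Fisher tests for DMR-set overlap
   against the full tested-window universe; gene-level aggregation
   (≥ 2 DMRs and |average Δ| ≥ 10 per gene); sign-quadrant directionality
   tests; directional consensus across strains; marker selection =
   (hypermethylated in *all* interventions) minus (age-related
   hypomethylation), refined to assay-sized 500 bp subregions; paired
   Wilcoxon signed-rank readout across marker CpGs.
5. **Enrichment and integration.** Observed/expected DMR frequency over
   element tracks with one-sided Fisher + BH across tracks; promoter
   (TSS−5 kb … TSS+100 bp) and uiDMR (TSS+0.3 … 8 kb, genes ≥ 16 kb)
   intervals; CGI classification (promoter > gene > intergenic); exact
   binomial test for down-regulation of hypermethylated, differentially
   expressed genes.
6. **Synthetic cohorts.** A seeded generator produces Bismark-format
   methylomes with CGI-structured CpG landscapes, negative-binomial
   coverage, beta-binomial methylation, planted hypermethylated blocks and
   coupled expression tables, plus ground truth for scoring recovery and
   false-positive rates.

## Worked example

```python
from longmeth import simulate as sim, io as mio, binning, dmr

cfg = sim.SimulationConfig(seed=1)          # 2 chroms x 25,000 CpGs, 3 reps/group,
cohort = sim.simulate_cohort(cfg)           # 50 planted +25pp blocks of 60 CpGs
pooled = mio.pool_replicates(cohort["samples"])
retained = mio.filter_min_coverage(pooled, min_cov=3)
ws = binning.build_cpg_windows(retained, window=50, step=25)
win = binning.window_methylation(ws, pooled)
res = dmr.call_dmrs(win, contrast=("control", "treated"))
print(len(res), int(res["is_dmr"].sum()),
      int((res["is_dmr"] & (res["direction"] == "hyper")).sum()))
```

prints

```
1998 117 117
```

— 1,998 tested 50-CpG windows, of which 117 pass the joint
p_adj < 0.05 / |Δ| ≥ 10 pp cutoff, all hypermethylated: the planted blocks
(each spanning 60 CpGs, hence overlapping 2–3 windows) and no
wrong-direction calls.

The same run from a shell:

```bash
longmeth simulate --seed 1 --out cohort/
longmeth dmr --samples cohort/samples.tsv --contrast treated:control --out dmrs
longmeth run --config run.yaml        # full pipeline with manifest
```

## Layout

- `src/longmeth/io.py` — Bismark coverage / BED / GTF / TSV I/O, replicate
  pooling, density and coverage filters
- `src/longmeth/binning.py` — fixed-CpG-count and fixed-width windows
- `src/longmeth/dmr.py` — chi-squared DMR/dCpG tests, logistic amplicon
  test, FDR adjustment
- `src/longmeth/comparative.py` — set overlaps, gene aggregation,
  consensus, marker selection, paired Wilcoxon
- `src/longmeth/enrichment.py` — observed/expected element enrichment
- `src/longmeth/integration.py` — promoters, uiDMRs, CGI classes,
  methylation–expression quadrants
- `src/longmeth/simulate.py` — synthetic cohort generator with ground truth
- `src/longmeth/pipeline.py`, `src/longmeth/cli.py` — orchestration,
  manifests, `longmeth` CLI

See `docs/methods.md` for the statistical model, parameter defaults and
known limitations.
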