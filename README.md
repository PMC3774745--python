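# cnaloh

Paired tumor/normal SNP-array copy-number and loss-of-heterozygosity
analysis, built around the genomics of adrenocortical tumors.

Adrenocortical adenomas (ACA, benign) and carcinomas (ACC, malignant)
are hard to tell apart short of expert histology, yet their genomes
differ sharply: carcinomas accumulate many large copy-number
alterations (CNAs) with an excess of losses, genome-wide copy-neutral
LOH (cnLOH, uniparental disomy), and — in roughly three quarters of
cases — amplification of most of chromosome 5, while adenomas carry
few, mostly small gains. `cnaloh` implements the complete analysis that
turns paired per-marker array signals into those observations, for
anyone who wants to study or extend tumor/normal SNP-array pipelines
with full ground-truth control:

* **synthetic cohort** — paired log R ratio (LRR) / B-allele frequency
  (BAF) profiles with implanted gains, losses and cnLOH, plus clinical
  covariates (tumor size coupled to LOH burden, two survival strata);
* **paired CNA calling** — per-marker paired log ratio, CBS-style
  segmentation (binary breakpoints plus segment-vs-rest windows,
  Benjamini–Hochberg step-up acceptance at α = 0.05), gain/loss calls
  at ±0.15 with a >100 kb large-CNA flag;
* **LOH** — genotypes from BAF, then a two-state hidden Markov model
  decoded by Viterbi over markers heterozygous in the matched normal;
* **cnLOH** — LOH × copy-number merge classifying each LOH base as
  cnLOH, LOH+loss or LOH+gain, with exact length conservation;
* **recurrence** — minimal overlapping regions (≥4 samples),
  between-group intersections, BED-based gene annotation;
* **diagnostics** — the chromosome-5 rule (gain fraction > 0.60) and
  the combined rule (>50 large CNAs and >10 cnLOH), with
  sensitivity/specificity/PPV/NPV;
* **cohort statistics** — genomic binning, Euclidean/complete-linkage
  clustering, PCA, Kaplan–Meier and log-rank survival analysis, and
  the small tests used for clinical correlation.

## Worked example

The metric layer applied to the cohort's observed counts — 17 of 22
carcinomas and 0 of 24 adenomas positive under the chromosome-5 rule:

```python
>>> from cnaloh import ConfusionTable, confusion_metrics
>>> confusion_metrics(ConfusionTable(tp=17, fp=0, fn=5, tn=24))
{'sensitivity': 77.3, 'specificity': 100.0, 'ppv': 100.0, 'npv': 82.8}
```

A sensitivity of 77.3% with perfect specificity means the rule misses a
quarter of carcinomas but never mislabels an adenoma.

The full pipeline on the default synthetic cohort (46 samples, ~46k
markers, about a minute on one CPU):

```python
>>> from cnaloh.pipeline import PipelineConfig, run_pipeline
>>> report = run_pipeline(PipelineConfig(), "run", seed=17)
>>> report["classification"]["chr5"]["metrics"]
{'sensitivity': 81.8, 'specificity': 100.0, 'ppv': 100.0, 'npv': 85.7}
>>> report["classification"]["chr5"]["matches_truth"]
True
>>> round(report["loh_size_correlation"]["pearson_r_truth"], 2)
0.39
```

Here the chromosome-5 classifier applied to the *detected* segments
reproduces the generator's ground-truth confusion table exactly
(`matches_truth`), and tumor size correlates positively with the true
LOH burden (r ≈ 0.4 on this cohort draw). The run directory contains
the SEG file, LOH tables, per-sample summaries, minimal overlapping
regions, predictions, cluster assignments, survival results and a
`report.json`; rerunning with the same configuration and seed
regenerates every file byte-identically.

The same stages are available from the shell:

```bash
cnaloh defaults                 # print the full default configuration
cnaloh run-all --seed 17 --outdir run
cnaloh simulate --outdir sim    # marker tables + ground truth
cnaloh segment --indir sim --out segments.seg
cnaloh survive --phenotypes run/phenotypes.tsv --group-col cluster_group
```

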