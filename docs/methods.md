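# Methods

`cnaloh` implements a paired tumor/normal SNP-array analysis for
adrenocortical tumors — copy-number segmentation, HMM-based
loss-of-heterozygosity (LOH) detection, copy-neutral LOH (cnLOH)
derivation, cohort recurrence analysis, rule-based malignancy
classification, genomic clustering and survival analysis — together with
a synthetic-cohort generator that provides ground truth for every stage.
This note records the models, the parameters that matter, and the design
choices where the design was genuinely open.

## Signal model and synthetic cohort

Each sample is a pair of per-marker tracks aligned to a genome map
(autosomes 1–22 plus X): log R ratio (LRR, log2 of total intensity
relative to diploid) and B-allele frequency (BAF). The generator's
model is deliberately minimal:

* normal LRR ~ N(0, σ_LRR); tumor LRR ~ N(log2(CN/2), σ_LRR) inside an
  implanted event with total copy number CN, N(0, σ_LRR) outside;
* genotypes are drawn per marker with heterozygosity 1/3 (AA/AB/BB);
  BAF is the allelic ratio plus N(0, σ_BAF), clipped to [0, 1]. A CN=3
  gain moves heterozygous BAF to 1/3 or 2/3 (one parental allele
  duplicated per event); losses (CN=1) and cnLOH (CN=2) drive normal-het
  markers to homozygosity for the retained allele;
* the tumor genotype equals the normal genotype up to a genotype-error
  rate ε; a no-call rate masks markers independently per track.

Noise defaults: σ_LRR = 0.20, σ_BAF = 0.04, ε = 0.01, no-call 0.02.
These are typical marker-level magnitudes for high-density SNP arrays;
the paired log ratio then carries noise σ ≈ 0.28 per marker. All events
are fully clonal; there is no tumor-purity dilution, no probe-level or
GC-wave structure, no intensity saturation, and no subclonality. Passing
tests therefore demonstrate correctness of the algorithms under an
idealized array, not robustness to the artifacts of real CEL-derived
data.

The default genome is down-scaled for desk use: 23 chromosomes of 10 Mb
with one marker per 5 kb (≈46k markers). Full-scale maps in the same
format are accepted by every stage. Coordinates are 1-based inclusive in
all files; BED input/output is converted at the boundary.

### Cohort architecture

The default cohort is 24 adenomas (ACA) and 22 carcinomas (ACC), the
sizes of the cohort this package models. Per group:

* ACA: ~6 small gains (50–300 kb), ~1 small loss, LOH present with
  probability 7/24 (1 + NB-distributed cnLOH events of 0.5–1.2 Mb when
  present);
* ACC: a gain covering 65–95% of chromosome 5 with probability 17/22;
  with probability 13/22 a recurrent "pattern" (large gains on
  chromosomes 7, 12, 19 and large losses on 1, 2, 13, 17, 22); ~8
  mid-size gains; losses of 0.5–1.5 Mb; cnLOH count 1 + NB(mean 13,
  dispersion 0.5) with probability 20/22, giving the heavy-tailed,
  genome-wide cnLOH burden characteristic of carcinomas;
* both groups share a set of recurrent gain hotspot loci (expressed as
  chromosome fractions so they scale with the map), hit with probability
  0.25 per locus in ACA and 0.55 in ACC. This reproduces the observation
  that most recurrent benign gains recur in carcinomas as well.

A sample's "true LOH count" is its number of loss/cnLOH events of at
least 500 kb — the scale at which an event reliably holds the 25
informative markers the LOH caller requires at the default marker
density. Tumor size is an affine function of that count
(size = base + 0.06·n_LOH + N(0, 5.0) cm, base 4.0/9.0 cm for ACA/ACC,
floored at 1 cm). The coupling and noise were calibrated once so that
the ground-truth Pearson correlation between LOH count and size on the
default cohort averages ≈0.41 over seeds (band 0.25–0.55); the heavy
cnLOH dispersion is what keeps the correlation moderate despite the
strong group contrast, mirroring the enormous spread of cnLOH counts in
real carcinoma cohorts.

Overall survival is exponential per stratum — median 72.2 months for
"pattern" carcinomas, 35.4 for the rest, 150 for adenomas — with
uniform administrative censoring at 12–120 months of follow-up.
Randomness is a single global seed; each sample consumes a substream
derived from (seed, sample index), so truth tables and profiles are
byte-reproducible.

Contaminated normals (a minority of blood references showing many CNAs,
as happens in practice) can be enabled via `contaminated_normal_prob`;
the flag is off by default.

Male X is diploid by default; `haploid_x=True` halves the X baseline
and forces hemizygous genotypes there.

## Copy-number segmentation

The per-marker statistic is the paired log ratio (tumor LRR − normal
LRR; missing markers dropped). Each chromosome is segmented by CBS-style
recursive splitting:

1. Candidate changepoints of an interval are (a) every left/right
   breakpoint and (b) every segment-vs-rest window over a geometric
   ladder of widths (×1.4 steps from the minimum marker count). The
   window family is essential: a short event in the middle of a long
   interval barely moves a one-cut mean and is invisible to plain binary
   splitting.
2. Each candidate gets a pooled two-sample t p-value; the whole
   candidate family enters one Benjamini–Hochberg step-up at
   α = 0.05. If any candidate survives, the interval is split at the
   smallest-p (then largest-|t|) survivor and recursion continues. The
   |t| tie-break matters because p-values underflow to zero on strong
   signals.
3. Shared breakpoints are locally re-placed at the argmax-|t| position
   of each adjacent pair (ladder-resolution cuts become marker-exact).
4. Stale cuts inside long events are pruned: a boundary is kept only if
   its two flanking segments differ at the Bonferroni bar α/m of the
   original chromosome scan (m = candidate count). Without pruning,
   selection-inflated mean differences of ~0.1 routinely exceed the
   plain merge tolerance and long events stay fragmented.
5. Segments shorter than the minimum marker count (default 10) are
   absorbed into the closer neighbor, and adjacent segments whose means
   differ by less than the merge tolerance (0.05) are merged.

Segments span their first to last marker; tiling invariants hold at
marker resolution (every marker belongs to exactly one segment). States
are called against symmetric thresholds on the mean paired log ratio,
±0.15 (inclusive), i.e. ≈2.2 and ≈1.8 copies; segments longer than
100 kb (strict) carry the large-CNA flag. The thresholds and the
minimum marker count are this package's choices — the commercial
segmentation tool this stage stands in for does not publish its
statistic or defaults — and all are exposed in `SegmentationParams`.

On the default cohort (fixed seed) implanted gains/losses spanning ≥25
markers are recovered with sensitivity ≥0.99 at 80% reciprocal overlap,
with ≤2 spurious gain/loss segments per genome.

## LOH detection

Genotypes are called from BAF with fixed thresholds (AA < 0.25 ≤ AB ≤
0.75 < BB; boundaries inclusive for the heterozygous call). LOH is
defined against the matched normal: informative markers are those
heterozygous in the normal with a tumor call present. Per chromosome, a
two-state HMM (retained / LOH) is decoded by Viterbi over informative
markers:

* emissions: P(het | retained) = 1 − δ, P(het | LOH) = ε, with
  δ = 0.05 absorbing stray het loss (array noise, genotype error) and
  ε = 0.02 absorbing residual heterozygous calls inside true LOH;
* transitions: homogeneous switch probability 5×10⁻⁴ per informative
  marker (no genetic-map scaling — sufficient at desk scale);
* uniform initial state; score ties resolve toward "retained".

Maximal LOH runs holding ≥25 informative markers are reported, spanning
the first to last informative marker. The minimum suppresses chance
homozygous runs (a 20-marker all-hom run has probability ~(2/3)·2⁻²⁰
per locus under heterozygosity 1/3, but the genome offers millions of
starting points). All parameters are package choices, exposed in
`HMMParams`; the decoder is verified against exhaustive path
enumeration on small instances.

## cnLOH derivation

LOH events are partitioned at copy-number segment boundaries; each
piece inherits its segment's state and is classified cnLOH (neutral),
LOH+loss, or LOH+gain. Adjacent same-class pieces re-merge, and each
maximal same-class piece counts as one event — a per-base rule rather
than a majority vote, so total LOH length is conserved exactly. For
classification, a segment's effective interval extends to just before
the next segment's start (segments themselves span marker positions,
which would otherwise leave inter-marker gaps). Informative-marker
counts are distributed across pieces proportionally to length with
largest-remainder rounding, conserving the total.

## Recurrence analysis

A minimal overlapping region (MOR) is computed by atomizing each
chromosome at all interval breakpoints, counting distinct supporting
samples per atom, keeping atoms supported by ≥4 samples (the default),
and merging adjacent atoms with *identical* support sets — identity of
support, not mere adjacency, is what makes the regions minimal. The
sample minimum is primary; the reported frequency (4/24 = 16.7%,
4/22 = 18.2%) is derived from it. Group comparisons intersect same-type
MOR lists and report per-pair intersection lengths, overlap fractions
relative to the first group, and the fraction of first-group regions
with any match. Gene annotation assigns genes at ≥1 bp overlap from a
BED map.

## Malignancy rules and metrics

Two rules, both with strict inequalities as printed in the source
material for this cohort:

* chromosome-5 rule: malignant iff the union of called gains covers
  >60% of chromosome 5;
* combined rule: malignant iff >50 large CNAs (>100 kb) and >10 cnLOH
  events simultaneously.

Sensitivity, specificity, PPV and NPV are reported as percentages
rounded half-up to one decimal; a zero denominator yields an undefined
(None) metric, never 0. Note the combined rule's count cutoffs are
full-genome quantities; on the 230 Mb desk genome the pipeline reports
the rule's output but desk-scale counts sit far below the cutoffs.

## Clustering, PCA, survival

The genomic matrix bins called segments into fixed windows (1 Mb
default), length-weighting states mapped to {−1, 0, +1} (a mean-log-
ratio mode exists). Clustering is Euclidean-distance agglomerative with
complete linkage (SciPy), cut to k groups, labels renumbered by first
appearance for reproducibility; the default analysis clusters the
cohort on chromosome 5 alone and the carcinomas on the chromosome set
{1, 2, 4, 5, 7, 12, 13, 14, 17, 18, 20, 22, X}. The binning and scale
are this package's stand-in — the original tool's are unpublished. PCA
is centered SVD with the sign convention that each component's
largest-magnitude loading is positive.

Survival uses the Kaplan–Meier product-limit estimator and the
two-group log-rank test (delegated to `lifelines`; hand-computed
oracles in the test suite). The median is the smallest time with
S(t) ≤ 0.5 and is undefined when the curve never reaches 0.5. At the
carcinoma cluster sizes (13 vs 9) with exponential medians 72.2 vs 35.4
months, the log-rank test rejects at α = 0.05 in roughly a third of
replicates — borderline power, which is why a survival contrast of this
magnitude at this cohort size hovers near significance.

Small clinical-correlation statistics (Fisher exact, chi-square, t,
one-way ANOVA, Pearson) delegate to SciPy; Fisher is cross-checked
against explicit hypergeometric enumeration in tests. Relative qPCR
expression uses the ΔCT method, 2^−(CT_target − CT_reference), with
replicate wells combined by geometric mean.

## Numerical choices and degenerate inputs

* Sum-of-squares terms in the t statistics are clamped at zero:
  catastrophic cancellation on constant runs otherwise produces NaN at
  perfect boundaries.
* A chromosome with fewer than twice the minimum marker count yields a
  single segment with a logged warning; a chromosome with no
  informative markers yields no LOH calls with a warning.
* Boundary conventions are documented and tested: BAF 0.25/0.75 call
  heterozygous; segment mean exactly at ±0.15 calls gain/loss; rule
  cutoffs are strict.
* Every output file begins with a header comment carrying the tool
  version and a hash of the configuration; reruns with the same config
  and seed are byte-identical.

## Problem sizes

Default runs use the down-scaled genome (≈46k markers × 46 samples);
the full pipeline completes in about a minute on one CPU, and the
Monte-Carlo analyses (correlation band, log-rank power) use 12 and 500
replicates respectively. These sizes were chosen so that the complete
analysis is comfortably reproducible on a laptop while leaving every
algorithmic property measurable.

## Known limitations

* The signal model omits purity, ploidy shifts, subclonality and wave
  artifacts; recovery figures do not transfer to raw-array data.
* LOH+gain regions arise in the merge layer but the generator never
  produces them (its events are non-overlapping and a CN=3 gain keeps
  heterozygous BAF off-homozygous), so that class is exercised by
  constructed cases only.
* The segmentation statistic, HMM parameterization, clustering scale
  and genotype thresholds stand in for unpublished proprietary
  counterparts; they are exposed as configuration, not claimed to match
  the originals.
* Survival strata are assigned from the generator's pattern flag, not
  re-derived from the clustering, when phenotypes are simulated.
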