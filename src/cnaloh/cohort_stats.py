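"""Genomic clustering, PCA, survival analysis and clinical-correlation stats.

The genomic matrix bins each sample's called segments into fixed-size
windows (default 1 Mb), mapping states to {loss: -1, neutral: 0,
gain: +1} (length-weighted) or averaging the mean log ratio. Clustering
is unsupervised Euclidean-distance agglomerative clustering with complete
linkage. Survival uses the Kaplan–Meier product-limit estimator and the
two-group log-rank test (delegated to lifelines); the median is the
smallest time at which the survival function drops to 0.5 or below.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage

from .genome import GenomeMap
from .segmentation import GAIN, LOSS, Segment

_STATE_VALUE = {LOSS: -1.0, None: 0.0, GAIN: 1.0, "neutral": 0.0}


def _effective_spans(segments: list[Segment], chrom_len: int) -> list[tuple[int, int, Segment]]:
    segs = sorted(segments, key=lambda s: s.start)
    spans = []
    for i, seg in enumerate(segs):
        end = segs[i + 1].start - 1 if i + 1 < len(segs) else chrom_len
        spans.append((seg.start, end, seg))
    return spans


def build_matrix(
    segments_by_sample: dict[str, list[Segment]],
    genome: GenomeMap,
    bin_size: int = 1_000_000,
    mode: str = "state",
    chromosomes: tuple[str, ...] | None = None,
) -> tuple[np.ndarray, list[str], pd.DataFrame]:
    """Samples x genomic-bins matrix from called segments.

    ``mode='state'`` maps segment states to {-1, 0, +1}; ``mode='lrr'``
    uses the segment mean log ratio. Bin values are length-weighted means
    of the overlapping segment values; uncovered bases count as neutral
    (0). Returns (matrix, sample ids, bin table).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if mode not in ("state", "lrr"):
        raise ValueError("mode must be 'state' or 'lrr'")
    chroms = tuple(chromosomes) if chromosomes else genome.chromosomes
    for c in chroms:
        if c not in genome.lengths:
            raise ValueError(f"chromosome {c!r} absent from genome map")

    bins = []
    for chrom in chroms:
        clen = genome.lengths[chrom]
        for lo in range(1, clen + 1, bin_size):
            bins.append((chrom, lo, min(lo + bin_size - 1, clen)))
    bin_table = pd.DataFrame(bins, columns=["chrom", "start", "end"])

    sample_ids = list(segments_by_sample)
    x = np.zeros((len(sample_ids), len(bin_table)))
    bin_index: dict[str, list[int]] = {}
    for i, row in bin_table.iterrows():
        bin_index.setdefault(row["chrom"], []).append(i)

    for si, sid in enumerate(sample_ids):
        by_chrom: dict[str, list[Segment]] = {}
        for seg in segments_by_sample[sid]:
            if seg.chrom in bin_index:
                by_chrom.setdefault(seg.chrom, []).append(seg)
        for chrom, segs in by_chrom.items():
            spans = _effective_spans(segs, genome.lengths[chrom])
            for bi in bin_index[chrom]:
                b = bin_table.iloc[bi]
                acc = 0.0
                for lo, hi, seg in spans:
                    o_lo, o_hi = max(lo, b["start"]), min(hi, b["end"])
                    if o_lo > o_hi:
                        continue
                    value = seg.mean if mode == "lrr" else _STATE_VALUE.get(seg.state, 0.0)
                    acc += value * (o_hi - o_lo + 1)
                x[si, bi] = acc / (b["end"] - b["start"] + 1)
    return x, sample_ids, bin_table


def hierarchical_cluster(matrix: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Euclidean / complete-linkage agglomerative clustering cut at k groups.

    Returns (labels, dendrogram leaf order). Labels are renumbered 1..k in
    order of first appearance so the output is stable for a fixed sample
    order.
    """
    matrix = np.asarray(matrix, dtype=float)
    if k > matrix.shape[0]:
        raise ValueError(f"k={k} exceeds number of samples {matrix.shape[0]}")
    z = linkage(matrix, method="complete", metric="euclidean")
    raw = fcluster(z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels = np.empty_like(raw)
    for i, r in enumerate(raw):
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        labels[i] = relabel[r]
    return labels, leaves_list(z)


def pca(matrix: np.ndarray, n_components: int) -> np.ndarray:
    """Centered principal-component scores via SVD.

    Sign convention: each component is flipped so that its
    largest-magnitude loading is positive.
    """
    x = np.asarray(matrix, dtype=float)
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    n_components = min(n_components, len(s))
    for j in range(n_components):
        lead = vt[j, np.argmax(np.abs(vt[j]))]
        if lead < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    return u[:, :n_components] * s[:n_components]


def kaplan_meier(
    times: np.ndarray, events: np.ndarray
) -> tuple[pd.DataFrame, float | None]:
    """Product-limit survival estimate and median survival.

    Returns a step table (time, survival) and the median — the smallest
    time with S(t) <= 0.5, or None if the curve never reaches 0.5.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("at least one record required")
    if np.any(times < 0):
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_.reset_index()
    sf.columns = ["time", "survival"]
    median = kmf.median_survival_time_
    return sf, (None if np.isinf(median) else float(median))


def logrank(
    times_a: np.ndarray,
    events_a: np.ndarray,
    times_b: np.ndarray,
    events_b: np.ndarray,
) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic, p-value).

    Tied event times are handled by simultaneous risk-set accounting. Two
    groups with no observed events at all give statistic 0, p 1.
    """
    if len(times_a) == 0 or len(times_b) == 0:
        raise ValueError("both groups must be non-empty")
    if int(np.sum(events_a)) + int(np.sum(events_b)) == 0:
        return 0.0, 1.0
    res = _ll_logrank(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# small clinical-correlation statistics
# ---------------------------------------------------------------------------


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table: (odds ratio, p)."""
    odds, p = sps.fisher_exact(np.asarray(table), alternative="two-sided")
    return float(odds), float(p)


def chi_square(table) -> tuple[float, float]:
    """Chi-square test of independence on a contingency table."""
    res = sps.chi2_contingency(np.asarray(table))
    return float(res.statistic), float(res.pvalue)


def t_test(a, b) -> tuple[float, float]:
    """Two-sided two-sample t test."""
    res = sps.ttest_ind(np.asarray(a, float), np.asarray(b, float))
    return float(res.statistic), float(res.pvalue)


def one_way_anova(*groups) -> tuple[float, float]:
    res = sps.f_oneway(*[np.asarray(g, float) for g in groups])
    return float(res.statistic), float(res.pvalue)


def pearson(x, y) -> tuple[float, float]:
    """Pearson correlation with two-sided p-value."""
    res = sps.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return float(res.statistic), float(res.pvalue)


def relative_expression(ct_target, ct_reference) -> float:
    """Relative expression by the delta-CT method: 2^-(CT_target - CT_ref).

    With replicate wells the per-well relative levels are combined by
    geometric mean (equivalently, 2^-mean(delta CT)).
    """
    t = np.atleast_1d(np.asarray(ct_target, dtype=float))
    r = np.atleast_1d(np.asarray(ct_reference, dtype=float))
    if np.any(t <= 0) or np.any(r <= 0):
        raise ValueError("CT values must be positive")
    if t.shape != r.shape:
        raise ValueError("target and reference wells must align")
    return float(2.0 ** (-np.mean(t - r)))
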