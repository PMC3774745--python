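"""Paired copy-number analysis: log ratios, segmentation, gain/loss calls.

The tumor signal is compared against the matched normal marker by marker
(paired log ratio), each chromosome is segmented by CBS-style recursive
splitting with two-sample t statistics — candidate changepoints comprise
plain breakpoints and segment-vs-rest windows over a ladder of widths, so
events much shorter than the chromosome remain detectable (a published
stand-in for proprietary "genomic segmentation" implementations).
Candidate splits are accepted through a Benjamini–Hochberg step-up at a
configurable alpha, shared breakpoints are locally refined, and
segments are called gain / loss / neutral against symmetric mean-log-ratio
thresholds. Segments longer than 100 kb carry the "large CNA" flag used by
the malignancy rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sps
from scipy.stats import false_discovery_control

from .genome import GenomeMap

log = logging.getLogger(__name__)

LARGE_CNA_BP = 100_000  # "large CNA" means longer than this (strict)

GAIN = "gain"
LOSS = "loss"
NEUTRAL = "neutral"


@dataclass
class PairedProfile:
    """Aligned per-marker signals for one tumor and its matched normal.

    All vectors follow the marker order of the :class:`~cnaloh.genome.GenomeMap`
    the profile was built against. ``tumor_mask`` / ``normal_mask`` are True
    where the marker is a no-call; masked BAF/LRR values are ignored
    downstream.
    """

    sample_id: str
    tumor_lrr: np.ndarray
    tumor_baf: np.ndarray
    normal_lrr: np.ndarray
    normal_baf: np.ndarray
    tumor_mask: np.ndarray
    normal_mask: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.tumor_lrr)
        for name in ("tumor_baf", "normal_lrr", "normal_baf", "tumor_mask", "normal_mask"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} not aligned: {len(getattr(self, name))} vs {n}")
        for name in ("tumor_baf", "normal_baf"):
            baf = getattr(self, name)
            ok = np.isnan(baf) | ((baf >= 0.0) & (baf <= 1.0))
            if not np.all(ok):
                raise ValueError(f"{name} outside [0, 1]")

    @property
    def n_markers(self) -> int:
        return len(self.tumor_lrr)


@dataclass(frozen=True)
class SegmentationParams:
    """Tuning knobs of the segmentation stage.

    ``alpha`` is the FDR level of the step-up acceptance of candidate
    breakpoints. Gain/loss thresholds are on the mean paired log ratio
    (log2 scale: +0.15 ≈ 2.2 copies, −0.15 ≈ 1.8 copies).
    """

    min_markers: int = 10
    alpha: float = 0.05
    gain_threshold: float = 0.15
    loss_threshold: float = -0.15
    merge_tolerance: float = 0.05

    def __post_init__(self) -> None:
        if not (self.loss_threshold < 0.0 < self.gain_threshold):
            raise ValueError("thresholds must satisfy loss < 0 < gain")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.min_markers < 1:
            raise ValueError("min_markers must be >= 1")


@dataclass
class Segment:
    """One contiguous copy-number segment (1-based inclusive coordinates)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    n_markers: int
    mean: float
    state: str | None = None
    large: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def paired_log_ratio(profile: PairedProfile) -> np.ndarray:
    """Per-marker tumor-minus-normal log ratio; missing markers become NaN."""
    lr = profile.tumor_lrr - profile.normal_lrr
    missing = profile.tumor_mask | profile.normal_mask
    lr = np.where(missing, np.nan, lr)
    return lr


def _pooled_t(
    n: int, n_in, sum_in, ss_in, total_sum: float, total_ss: float
) -> np.ndarray:
    """Pooled two-sample t comparing a sub-collection against the rest."""
    n_in = np.asarray(n_in, dtype=float)
    n_out = n - n_in
    sum_out = total_sum - sum_in
    m_in = sum_in / n_in
    m_out = sum_out / n_out
    # clamp: cancellation can leave tiny negative residuals on constant runs
    ssd_in = np.maximum(ss_in - sum_in * sum_in / n_in, 0.0)
    ssd_out = np.maximum((total_ss - ss_in) - sum_out * sum_out / n_out, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pooled = (ssd_in + ssd_out) / (n - 2)
        se = np.sqrt(pooled * (1.0 / n_in + 1.0 / n_out))
        t = (m_in - m_out) / se
    return t


def _t_to_p(t: np.ndarray, df: int) -> np.ndarray:
    p = 2.0 * sps.t.sf(np.abs(t), df=df)
    p[np.isinf(t)] = 0.0          # zero within-variance, non-zero jump
    p[np.isnan(t)] = 1.0          # degenerate: both sides constant and equal
    return p


def _candidates(
    x: np.ndarray, min_markers: int
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Candidate changepoints of ``x``: p-values and their cut positions.

    Two candidate families share one multiple-testing family: plain
    breakpoints (left vs right halves) and windowed segments (a window of
    markers against the rest, over a geometric ladder of window widths),
    which make events much shorter than the interval visible. Each
    candidate is a pair of cut positions (j = 0 means a single cut).
    """
    n = len(x)
    cs = np.concatenate(([0.0], np.cumsum(x)))
    css = np.concatenate(([0.0], np.cumsum(x * x)))
    total_sum, total_ss = cs[-1], css[-1]
    pvals: list[np.ndarray] = []
    tvals: list[np.ndarray] = []
    cuts: list[tuple[int, int]] = []

    # family 1: binary breakpoints
    ks = np.arange(min_markers, n - min_markers + 1)
    t = _pooled_t(n, ks, cs[ks], css[ks], total_sum, total_ss)
    pvals.append(_t_to_p(t, n - 2))
    tvals.append(t)
    cuts.extend((int(k), 0) for k in ks)

    # family 2: window-vs-rest at a geometric ladder of widths
    w = min_markers
    while 2 * w <= n - min_markers:
        starts = np.arange(0, n - w + 1)
        sum_in = cs[starts + w] - cs[starts]
        ss_in = css[starts + w] - css[starts]
        t = _pooled_t(n, w, sum_in, ss_in, total_sum, total_ss)
        pvals.append(_t_to_p(t, n - 2))
        tvals.append(t)
        cuts.extend((int(s), int(s + w)) for s in starts)
        w = max(w + 1, int(round(w * 1.4)))

    return np.concatenate(pvals), np.concatenate(tvals), cuts


def _best_split(x: np.ndarray, params: SegmentationParams) -> tuple[int, int] | None:
    """Best FDR-surviving candidate of ``x``, or None if no split is accepted."""
    n = len(x)
    if n < 2 * params.min_markers:
        return None
    p, t, cuts = _candidates(x, params.min_markers)
    adj = false_discovery_control(p, method="bh")
    surviving = np.flatnonzero(adj <= params.alpha)
    if surviving.size == 0:
        return None
    # smallest p, then sharpest |t| (p underflows to 0 for many candidates
    # on strong signals); remaining ties -> leftmost candidate
    p_min = p[surviving].min()
    pool = surviving[p[surviving] == p_min]
    abs_t = np.abs(np.where(np.isnan(t[pool]), 0.0, t[pool]))
    best = pool[np.argmax(abs_t)]
    return cuts[best]


def _segment_indices(x: np.ndarray, params: SegmentationParams) -> list[tuple[int, int]]:
    """Recursive segmentation; returns half-open index intervals."""
    out: list[tuple[int, int]] = []
    stack = [(0, len(x))]
    while stack:
        i0, i1 = stack.pop()
        best = _best_split(x[i0:i1], params)
        if best is None:
            out.append((i0, i1))
            continue
        i, j = best
        pieces = [i0, i0 + i] + ([i0 + j] if j else []) + [i1]
        pieces = sorted(set(k for k in pieces if i0 <= k <= i1))
        for a, b in zip(pieces, pieces[1:]):
            stack.append((a, b))
    out.sort()
    return out


def _refine_breakpoints(
    x: np.ndarray, intervals: list[tuple[int, int]], min_markers: int, passes: int = 2
) -> list[tuple[int, int]]:
    """Re-place each shared breakpoint at the local argmax-|t| position.

    The window scan locates events at ladder resolution; this local
    binary-split refinement over each adjacent segment pair restores
    marker-level breakpoint accuracy.
    """
    intervals = list(intervals)
    for _ in range(passes):
        moved = False
        for idx in range(len(intervals) - 1):
            a0, _ = intervals[idx]
            b0, b1 = intervals[idx + 1]
            seg = x[a0:b1]
            n = len(seg)
            if n < 2:
                continue
            # sides may temporarily undercut the minimum-marker rule here;
            # pruning and the final cleanup restore it
            ks = np.arange(1, n)
            cs = np.concatenate(([0.0], np.cumsum(seg)))
            css = np.concatenate(([0.0], np.cumsum(seg * seg)))
            t = _pooled_t(n, ks, cs[ks], css[ks], cs[-1], css[-1])
            t = np.where(np.isnan(t), 0.0, t)
            if np.max(np.abs(t)) <= 0.0:
                continue  # both sides constant and equal: nothing to refine
            k_new = a0 + int(ks[np.argmax(np.abs(t))])
            if k_new != b0:
                intervals[idx] = (a0, k_new)
                intervals[idx + 1] = (k_new, b1)
                moved = True
        if not moved:
            break
    return intervals


def _n_candidates(n: int, min_markers: int) -> int:
    """Size of the candidate family the chromosome scan tests."""
    total = max(0, n - 2 * min_markers + 1)
    w = min_markers
    while 2 * w <= n - min_markers:
        total += n - w + 1
        w = max(w + 1, int(round(w * 1.4)))
    return max(total, 1)


def _prune_indices(
    x: np.ndarray, intervals: list[tuple[int, int]], params: SegmentationParams
) -> list[tuple[int, int]]:
    """Remove breakpoints that cannot stand on their own.

    Recursive splitting leaves stale cuts inside long events (the chosen
    window edges rarely coincide with the true boundaries found later).
    A kept boundary must separate its two flanking segments at the same
    Bonferroni bar the chromosome-wide scan imposed; the weakest boundary
    is removed first and the test repeated until all survive.
    """
    bar = params.alpha / _n_candidates(len(x), params.min_markers)
    intervals = list(intervals)
    while len(intervals) > 1:
        worst_p, worst_idx = -1.0, -1
        for idx in range(len(intervals) - 1):
            a0, a1 = intervals[idx]
            b0, b1 = intervals[idx + 1]
            left, right = x[a0:a1], x[b0:b1]
            n = len(left) + len(right)
            t = _pooled_t(
                n,
                np.array([len(left)]),
                np.array([left.sum()]),
                np.array([np.sum(left * left)]),
                left.sum() + right.sum(),
                np.sum(left * left) + np.sum(right * right),
            )
            p = float(_t_to_p(t, max(n - 2, 1))[0])
            if p > worst_p:
                worst_p, worst_idx = p, idx
        if worst_p <= bar:
            break
        a0, _ = intervals[worst_idx]
        _, b1 = intervals[worst_idx + 1]
        intervals[worst_idx : worst_idx + 2] = [(a0, b1)]
    return intervals


def _enforce_min_markers(
    x: np.ndarray, intervals: list[tuple[int, int]], min_markers: int
) -> list[tuple[int, int]]:
    """Absorb segments shorter than the minimum into the closer neighbor."""
    intervals = list(intervals)
    while len(intervals) > 1:
        sizes = [b - a for a, b in intervals]
        idx = int(np.argmin(sizes))
        if sizes[idx] >= min_markers:
            break
        mean = np.mean(x[intervals[idx][0] : intervals[idx][1]])
        left_diff = (
            abs(np.mean(x[intervals[idx - 1][0] : intervals[idx - 1][1]]) - mean)
            if idx > 0
            else np.inf
        )
        right_diff = (
            abs(np.mean(x[intervals[idx + 1][0] : intervals[idx + 1][1]]) - mean)
            if idx + 1 < len(intervals)
            else np.inf
        )
        if left_diff <= right_diff:
            intervals[idx - 1 : idx + 1] = [(intervals[idx - 1][0], intervals[idx][1])]
        else:
            intervals[idx : idx + 2] = [(intervals[idx][0], intervals[idx + 1][1])]
    return intervals


def _merge_indices(
    x: np.ndarray, intervals: list[tuple[int, int]], tol: float
) -> list[tuple[int, int]]:
    """Merge adjacent intervals whose means differ by less than ``tol``."""
    changed = True
    while changed:
        changed = False
        merged: list[tuple[int, int]] = []
        for iv in intervals:
            if merged:
                j0, j1 = merged[-1]
                if abs(np.mean(x[j0:j1]) - np.mean(x[iv[0]:iv[1]])) < tol:
                    merged[-1] = (j0, iv[1])
                    changed = True
                    continue
            merged.append(iv)
        intervals = merged
    return intervals


def segment(
    log_ratios: np.ndarray,
    genome: GenomeMap,
    params: SegmentationParams | None = None,
    sample_id: str = "sample",
) -> list[Segment]:
    """Segment a genome-wide paired log-ratio vector chromosome by chromosome.

    Missing (NaN) markers are dropped before segmentation; segment marker
    counts refer to the remaining markers. Each segment spans its first to
    last marker position. Chromosomes with fewer than twice the minimum
    marker count yield a single segment (warning logged).
    """
    params = params or SegmentationParams()
    if len(log_ratios) != genome.n_markers:
        raise ValueError("log-ratio vector not aligned to genome map")
    segments: list[Segment] = []
    for chrom in genome.chromosomes:
        sl = genome.chrom_slice(chrom)
        values = np.asarray(log_ratios[sl], dtype=float)
        positions = genome.positions[chrom]
        keep = ~np.isnan(values)
        values = values[keep]
        positions = positions[keep]
        if len(values) == 0:
            log.warning("chromosome %s has no usable markers; skipped", chrom)
            continue
        if len(values) < 2 * params.min_markers:
            log.warning(
                "chromosome %s has %d markers (< %d); emitting a single segment",
                chrom, len(values), 2 * params.min_markers,
            )
            intervals = [(0, len(values))]
        else:
            intervals = _segment_indices(values, params)
            intervals = _refine_breakpoints(values, intervals, params.min_markers)
            intervals = _prune_indices(values, intervals, params)
            intervals = _refine_breakpoints(values, intervals, params.min_markers)
            intervals = _enforce_min_markers(values, intervals, params.min_markers)
            intervals = _merge_indices(values, intervals, params.merge_tolerance)
        for i0, i1 in intervals:
            segments.append(
                Segment(
                    sample_id=sample_id,
                    chrom=chrom,
                    start=int(positions[i0]),
                    end=int(positions[i1 - 1]),
                    n_markers=i1 - i0,
                    mean=float(np.mean(values[i0:i1])),
                )
            )
    return segments


def call_states(
    segments: list[Segment],
    params: SegmentationParams | None = None,
    large_bp: int = LARGE_CNA_BP,
) -> list[Segment]:
    """Assign gain/loss/neutral states and the large-CNA flag.

    A segment is a gain when its mean is at or above the gain threshold and
    a loss when at or below the loss threshold (inclusive boundaries).
    """
    params = params or SegmentationParams()
    called = []
    for seg in segments:
        if seg.mean >= params.gain_threshold:
            state = GAIN
        elif seg.mean <= params.loss_threshold:
            state = LOSS
        else:
            state = NEUTRAL
        called.append(replace(seg, state=state, large=seg.length > large_bp))
    return called


def summarize_calls(segments: list[Segment]) -> dict[str, int]:
    """Per-sample counts of called alterations (gains, losses, large CNAs)."""
    n_gain = sum(1 for s in segments if s.state == GAIN)
    n_loss = sum(1 for s in segments if s.state == LOSS)
    n_large = sum(1 for s in segments if s.state in (GAIN, LOSS) and s.large)
    return {
        "n_cna": n_gain + n_loss,
        "n_gain": n_gain,
        "n_loss": n_loss,
        "n_large_cna": n_large,
    }
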