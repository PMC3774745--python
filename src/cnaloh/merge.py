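"""Merge LOH calls with copy-number segments to derive cnLOH.

Each LOH event is partitioned at copy-number segment boundaries; every
piece inherits the state of its segment and is classified copy-neutral
LOH (neutral segment), LOH+loss or LOH+gain. Adjacent same-class pieces
are re-merged, and each maximal same-class piece counts as one event.

Copy-number segments span their first to last marker, so two adjacent
segments leave an inter-marker gap between them. For classification each
segment's effective interval extends to just before the next segment's
start (the last segment extends beyond its final marker), which makes the
length-conservation invariant exact: the summed length of classified
pieces equals the original LOH length.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .genome import GenomeMap
from .loh import CNLOH_CLASS, LOH_GAIN, LOH_LOSS, LOHEvent
from .segmentation import GAIN, LOSS, NEUTRAL, Segment

_STATE_TO_CLASS = {NEUTRAL: CNLOH_CLASS, LOSS: LOH_LOSS, GAIN: LOH_GAIN}


def _effective_intervals(segments: list[Segment]) -> list[tuple[int, int, str]]:
    """Tiled (start, end, state) intervals covering the segmented span."""
    segs = sorted(segments, key=lambda s: s.start)
    out = []
    for i, seg in enumerate(segs):
        if seg.state is None:
            raise ValueError("segments must have called states before merging")
        end = segs[i + 1].start - 1 if i + 1 < len(segs) else np.iinfo(np.int64).max
        out.append((seg.start, end, seg.state))
    return out


def _distribute_counts(total: int, lengths: list[int]) -> list[int]:
    """Split an informative-marker count across pieces ∝ length (sum exact)."""
    weights = np.asarray(lengths, dtype=float)
    raw = total * weights / weights.sum()
    counts = np.floor(raw).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    for i in order[:remainder]:
        counts[i] += 1
    return counts.tolist()


def merge_loh_cn(
    loh_events: list[LOHEvent],
    segments: list[Segment],
    genome: GenomeMap | None = None,
) -> list[LOHEvent]:
    """Classify LOH events against copy-number segments of the same sample.

    Returns one event per maximal same-class piece. If a genome map is
    given, pieces containing no array marker are discarded; otherwise all
    pieces are kept (and total length is conserved exactly).
    """
    by_chrom: dict[str, list[Segment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    intervals = {c: _effective_intervals(s) for c, s in by_chrom.items()}

    out: list[LOHEvent] = []
    for ev in sorted(loh_events, key=lambda e: (e.chrom, e.start)):
        ivs = intervals.get(ev.chrom)
        if not ivs or ev.start < ivs[0][0]:
            raise ValueError(
                f"LOH event {ev.chrom}:{ev.start}-{ev.end} overlaps no copy-number "
                "segment (tiling violated)"
            )
        pieces: list[tuple[int, int, str]] = []
        for s, e, state in ivs:
            lo, hi = max(s, ev.start), min(e, ev.end)
            if lo > hi:
                continue
            cls = _STATE_TO_CLASS[state]
            if pieces and pieces[-1][2] == cls and pieces[-1][1] + 1 == lo:
                pieces[-1] = (pieces[-1][0], hi, cls)
            else:
                pieces.append((lo, hi, cls))
        if not pieces:
            raise ValueError(
                f"LOH event {ev.chrom}:{ev.start}-{ev.end} overlaps no copy-number "
                "segment (tiling violated)"
            )
        if genome is not None:
            kept = []
            for lo, hi, cls in pieces:
                if len(genome.marker_index(ev.chrom, lo, hi)) > 0:
                    kept.append((lo, hi, cls))
            pieces = kept
        if not pieces:
            continue
        counts = _distribute_counts(ev.n_informative, [hi - lo + 1 for lo, hi, _ in pieces])
        for (lo, hi, cls), n_inf in zip(pieces, counts):
            out.append(replace(ev, start=lo, end=hi, cls=cls, n_informative=n_inf))
    return out


def count_loh_classes(classified: list[LOHEvent]) -> dict[str, int]:
    """Event counts per class after the merge."""
    counts = {CNLOH_CLASS: 0, LOH_LOSS: 0, LOH_GAIN: 0}
    for ev in classified:
        counts[ev.cls] += 1
    return counts


def sample_alteration_summary(
    segments: list[Segment], classified_loh: list[LOHEvent]
) -> dict[str, int]:
    """Per-sample alteration counts (CNAs, gains, losses, large CNAs, LOH, cnLOH)."""
    from .segmentation import summarize_calls

    counts = summarize_calls(segments)
    cls_counts = count_loh_classes(classified_loh)
    counts["n_loh"] = len(classified_loh)
    counts["n_cnloh"] = cls_counts[CNLOH_CLASS]
    counts["n_loh_loss"] = cls_counts[LOH_LOSS]
    counts["n_loh_gain"] = cls_counts[LOH_GAIN]
    return counts


def cohort_summary_table(
    per_sample: dict[str, dict[str, int]], phenotypes: pd.DataFrame
) -> pd.DataFrame:
    """Cohort-level medians and ranges per group, one row per count type."""
    df = pd.DataFrame.from_dict(per_sample, orient="index")
    df.index.name = "sample_id"
    df = df.join(phenotypes.set_index("sample_id")["group"])
    rows = []
    for col in [c for c in df.columns if c != "group"]:
        for group, sub in df.groupby("group", sort=True):
            rows.append(
                {
                    "alteration": col,
                    "group": group,
                    "median": float(sub[col].median()),
                    "min": int(sub[col].min()),
                    "max": int(sub[col].max()),
                }
            )
    return pd.DataFrame(rows)
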