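"""Cohort-level recurrence: minimal overlapping regions (MORs), group
intersections and gene annotation.

A MOR is the intersection core of same-type alterations shared by at
least ``min_samples`` samples: chromosomes are atomized at every interval
breakpoint, atoms are kept when enough distinct samples cover them, and
adjacent kept atoms with identical supporting-sample sets are merged.
With the default cohort sizes, ``min_samples=4`` corresponds to a
frequency above 15% in either group (4/24 = 16.7%, 4/22 = 18.2%).
"""

from __future__ import annotations

import pandas as pd

MOR_COLUMNS = ["chrom", "start", "end", "type", "support", "frequency", "samples"]


def minimal_overlapping_regions(
    intervals: pd.DataFrame,
    min_samples: int = 4,
    group_size: int | None = None,
    alteration_type: str | None = None,
) -> pd.DataFrame:
    """Minimal overlapping regions of one alteration type within one group.

    Parameters
    ----------
    intervals:
        DataFrame with columns sample_id, chrom, start, end (1-based
        inclusive) and optionally ``type``; one row per per-sample altered
        interval.
    min_samples:
        Minimum number of distinct supporting samples (>= 1).
    group_size:
        Denominator of the reported frequency; defaults to the number of
        distinct samples in ``intervals``.
    alteration_type:
        Label written to the ``type`` column (taken from the input column
        if absent).
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    required = {"sample_id", "chrom", "start", "end"}
    if not required.issubset(intervals.columns):
        raise ValueError(f"intervals must have columns {sorted(required)}")
    group_size = group_size or intervals["sample_id"].nunique()
    rows = []
    for chrom, sub in intervals.groupby("chrom", sort=True):
        bounds = sorted(set(sub["start"]).union(e + 1 for e in sub["end"]))
        ivs = list(zip(sub["start"], sub["end"], sub["sample_id"]))
        atoms = []  # (start, end, frozenset of supporting samples)
        for lo, hi in zip(bounds, bounds[1:]):
            support = frozenset(s for a, b, s in ivs if a <= lo and b >= hi - 1)
            if len(support) >= min_samples:
                atoms.append((lo, hi - 1, support))
        merged: list[tuple[int, int, frozenset]] = []
        for lo, hi, support in atoms:
            if merged and merged[-1][2] == support and merged[-1][1] + 1 == lo:
                merged[-1] = (merged[-1][0], hi, support)
            else:
                merged.append((lo, hi, support))
        atype = alteration_type
        if atype is None and "type" in sub.columns and len(sub):
            atype = str(sub["type"].iloc[0])
        for lo, hi, support in merged:
            rows.append(
                {
                    "chrom": chrom,
                    "start": lo,
                    "end": hi,
                    "type": atype,
                    "support": len(support),
                    "frequency": len(support) / group_size,
                    "samples": ",".join(sorted(support)),
                }
            )
    return pd.DataFrame(rows, columns=MOR_COLUMNS)


def intersect_group_regions(
    group_a: pd.DataFrame, group_b: pd.DataFrame
) -> tuple[pd.DataFrame, float]:
    """Pairwise same-type intersections of two MOR lists.

    Returns the intersection table (one row per overlapping A/B pair, with
    intersection length and the overlap fraction relative to the A region)
    and the summary statistic: the fraction of A regions with at least one
    same-type overlap in B.
    """
    rows = []
    hit = 0
    for _, a in group_a.iterrows():
        any_overlap = False
        for _, b in group_b.iterrows():
            if a["chrom"] != b["chrom"] or a["type"] != b["type"]:
                continue
            lo = max(a["start"], b["start"])
            hi = min(a["end"], b["end"])
            if lo > hi:
                continue
            any_overlap = True
            length = int(hi - lo + 1)
            rows.append(
                {
                    "chrom": a["chrom"],
                    "type": a["type"],
                    "a_start": int(a["start"]),
                    "a_end": int(a["end"]),
                    "b_start": int(b["start"]),
                    "b_end": int(b["end"]),
                    "intersection_len": length,
                    "overlap_fraction": length / (a["end"] - a["start"] + 1),
                }
            )
        hit += any_overlap
    frac = hit / len(group_a) if len(group_a) else 0.0
    table = pd.DataFrame(
        rows,
        columns=[
            "chrom", "type", "a_start", "a_end", "b_start", "b_end",
            "intersection_len", "overlap_fraction",
        ],
    )
    return table, frac


def annotate_genes(regions: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Assign genes overlapping each region by at least one base.

    ``genes`` uses internal 1-based inclusive coordinates (BED input is
    converted on read) with columns chrom, start, end, name. Returns the
    regions with added ``genes`` (comma-joined names) and ``n_genes``.
    """
    out = regions.copy().reset_index(drop=True)
    gene_lists = []
    by_chrom = {c: sub for c, sub in genes.groupby("chrom")}
    for _, region in out.iterrows():
        sub = by_chrom.get(region["chrom"])
        if sub is None:
            gene_lists.append([])
            continue
        mask = (sub["start"] <= region["end"]) & (sub["end"] >= region["start"])
        gene_lists.append(list(sub.loc[mask, "name"]))
    out["genes"] = [",".join(g) for g in gene_lists]
    out["n_genes"] = [len(g) for g in gene_lists]
    return out
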