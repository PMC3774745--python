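"""Ground-truth evaluation of pipeline calls on simulated cohorts.

Used to quantify recovery of implanted events: sensitivity of
copy-number event detection at a reciprocal-overlap criterion, false
segments per genome, and LOH presence/boundary agreement.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import GenomeMap
from .loh import LOHEvent
from .segmentation import GAIN, LOSS, Segment

_EXPECTED_MEAN = {GAIN: None, LOSS: None}  # derived from CN below


def expected_log_ratio(cn: int) -> float:
    """Noise-free paired log ratio of a fully clonal event with total CN."""
    if cn <= 0:
        return -3.0
    return float(np.log2(cn / 2.0))


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def event_recovery(
    truth_events: pd.DataFrame,
    segments_by_sample: dict[str, list[Segment]],
    genome: GenomeMap,
    min_markers: int = 25,
    min_abs_mean: float = 0.4,
    reciprocal: float = 0.8,
) -> dict:
    """Sensitivity of implanted CN-event recovery and false segments.

    An implanted gain/loss is *eligible* when it spans at least
    ``min_markers`` markers and its noise-free |log ratio| is at least
    ``min_abs_mean``. It counts as recovered when a called segment of the
    same direction overlaps it with reciprocal overlap >= ``reciprocal``.
    A called gain/loss segment overlapping no same-direction implanted
    event at all is a false segment.
    """
    state_of = {"gain": GAIN, "loss": LOSS}
    eligible = 0
    recovered = 0
    false_by_sample: dict[str, int] = {sid: 0 for sid in segments_by_sample}
    truth_by_sample: dict[str, list] = {sid: [] for sid in segments_by_sample}
    for _, ev in truth_events.iterrows():
        if ev["class"] not in state_of:
            continue
        truth_by_sample.setdefault(ev["sample_id"], []).append(ev)

    for sid, segs in segments_by_sample.items():
        calls = [s for s in segs if s.state in (GAIN, LOSS)]
        matched_any = {id(s): False for s in calls}
        for ev in truth_by_sample.get(sid, []):
            state = state_of[ev["class"]]
            n_mk = len(genome.marker_index(ev["chrom"], int(ev["start"]), int(ev["end"])))
            is_eligible = (
                n_mk >= min_markers
                and abs(expected_log_ratio(int(ev["cn"]))) >= min_abs_mean
            )
            if is_eligible:
                eligible += 1
            hit = False
            for seg in calls:
                if seg.chrom != ev["chrom"] or seg.state != state:
                    continue
                ov = _overlap(seg.start, seg.end, int(ev["start"]), int(ev["end"]))
                if ov > 0:
                    matched_any[id(seg)] = True
                if (
                    ov / (ev["end"] - ev["start"] + 1) >= reciprocal
                    and ov / seg.length >= reciprocal
                ):
                    hit = True
            if is_eligible and hit:
                recovered += 1
        false_by_sample[sid] = sum(1 for s in calls if not matched_any[id(s)])

    n_samples = max(len(segments_by_sample), 1)
    return {
        "eligible_events": eligible,
        "recovered_events": recovered,
        "sensitivity": recovered / eligible if eligible else float("nan"),
        "false_segments_total": int(sum(false_by_sample.values())),
        "false_segments_per_sample": sum(false_by_sample.values()) / n_samples,
        "max_false_segments": max(false_by_sample.values(), default=0),
    }


def loh_presence_agreement(
    truth_flags: pd.DataFrame,
    loh_by_sample: dict[str, list[LOHEvent]],
    group: str | None = None,
) -> dict:
    """Fraction of samples with >=1 detected LOH vs the generated fraction."""
    flags = truth_flags
    if group is not None:
        flags = flags[flags["group"] == group]
    ids = list(flags["sample_id"])
    generated = flags.set_index("sample_id")["loh_positive"].astype(bool)
    detected = {sid: len(loh_by_sample.get(sid, [])) > 0 for sid in ids}
    n = len(ids)
    return {
        "n": n,
        "generated_fraction": float(generated.mean()) if n else float("nan"),
        "detected_fraction": sum(detected.values()) / n if n else float("nan"),
        "agreement": sum(detected[s] == bool(generated[s]) for s in ids) / n
        if n
        else float("nan"),
    }
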