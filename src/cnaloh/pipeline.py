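"""End-to-end pipeline: simulate -> segment -> LOH -> merge -> recurrence
-> classify -> cluster -> survival, with all outputs written to disk.

The pipeline is deterministic for a fixed (config, seed): rerunning it
produces byte-identical outputs. Every stage failure is re-raised with
the stage name for context.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .cohort_stats import build_matrix, hierarchical_cluster, kaplan_meier, logrank, pearson
from .diagnostics import (
    MALIGNANT,
    DiagnosticThresholds,
    chr5_gain_fraction,
    classify_chr5,
    classify_combined,
    confusion_from_predictions,
    confusion_metrics,
)
from .genome import default_genome
from .loh import CNLOH_CLASS, HMMParams, call_genotypes, detect_loh
from .merge import cohort_summary_table, merge_loh_cn, sample_alteration_summary
from .recurrence import intersect_group_regions, minimal_overlapping_regions
from .segmentation import GAIN, LOSS, SegmentationParams, call_states, paired_log_ratio, segment
from .simulate import ACC, CohortConfig, simulate_cohort

FIG8_CHROMS = ("1", "2", "4", "5", "7", "12", "13", "14", "17", "18", "20", "22", "X")


@dataclass
class PipelineConfig:
    """Full pipeline configuration (genome, cohort, and all stage knobs)."""

    chrom_length: int = 10_000_000
    marker_spacing: int = 5_000
    cohort: CohortConfig = field(default_factory=CohortConfig)
    seg: SegmentationParams = field(default_factory=SegmentationParams)
    hmm: HMMParams = field(default_factory=HMMParams)
    thresholds: DiagnosticThresholds = field(default_factory=DiagnosticThresholds)
    bin_size: int = 1_000_000
    cluster_chromosomes: tuple[str, ...] = ("5",)
    acc_cluster_chromosomes: tuple[str, ...] = FIG8_CHROMS
    cluster_k: int = 2
    min_mor_samples: int = 4
    write_profiles: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        from .simulate import GroupEventParams, NoiseModel

        def _tup(x):
            if isinstance(x, list):
                return tuple(_tup(v) for v in x)
            return x

        if "cohort" in d and isinstance(d["cohort"], dict):
            c = dict(d["cohort"])
            for key in ("aca", "acc"):
                if key in c and isinstance(c[key], dict):
                    c[key] = GroupEventParams(
                        **{k: _tup(v) for k, v in c[key].items()}
                    )
            if "noise" in c and isinstance(c["noise"], dict):
                c["noise"] = NoiseModel(**c["noise"])
            c = {k: _tup(v) for k, v in c.items()}
            d["cohort"] = CohortConfig(**c)
        for key, klass in (
            ("seg", SegmentationParams),
            ("hmm", HMMParams),
            ("thresholds", DiagnosticThresholds),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = klass(**d[key])
        for key in ("cluster_chromosomes", "acc_cluster_chromosomes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # pragma: no cover - context plumbing
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_pipeline(
    config: PipelineConfig | None = None,
    outdir: str | Path = "cnaloh_run",
    seed: int | None = None,
) -> dict:
    """Run the full analysis on a synthetic cohort; returns the report dict."""
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.cohort.seed if seed is None else seed
    chash = cio.config_hash({**config.to_dict(), "seed": seed})
    meta = f"config_hash={chash} seed={seed}"

    genome = default_genome(config.chrom_length, config.marker_spacing)
    cohort = _simulate(config, genome, seed)
    truth = cohort.truth
    phenotypes = truth.phenotypes

    cio.write_genome(outdir / "genome.tsv", genome, meta)
    cio.write_events(outdir / "truth_events.tsv", truth.events, meta)
    cio.write_phenotypes(outdir / "phenotypes.tsv", phenotypes, meta)
    cio.write_tsv(truth.flags, outdir / "truth_flags.tsv", meta)

    if config.write_profiles:
        pdir = outdir / "profiles"
        pdir.mkdir(exist_ok=True)
        for sid, prof in cohort.profiles.items():
            t_lrr = np.where(prof.tumor_mask, np.nan, prof.tumor_lrr)
            t_baf = np.where(prof.tumor_mask, np.nan, prof.tumor_baf)
            n_lrr = np.where(prof.normal_mask, np.nan, prof.normal_lrr)
            n_baf = np.where(prof.normal_mask, np.nan, prof.normal_baf)
            cio.write_marker_table(pdir / f"{sid}_tumor.tsv", genome, t_lrr, t_baf, meta)
            cio.write_marker_table(pdir / f"{sid}_normal.tsv", genome, n_lrr, n_baf, meta)

    segments_by_sample, loh_by_sample, classified_by_sample = _call_all(config, genome, cohort)

    all_segments = [s for segs in segments_by_sample.values() for s in segs]
    cio.write_segments(outdir / "segments.seg", all_segments, meta)
    all_loh = [e for evs in loh_by_sample.values() for e in evs]
    cio.write_loh(outdir / "loh_events.tsv", all_loh, meta)
    all_classified = [e for evs in classified_by_sample.values() for e in evs]
    cio.write_loh(outdir / "loh_classified.tsv", all_classified, meta)

    per_sample = {
        sid: sample_alteration_summary(segments_by_sample[sid], classified_by_sample[sid])
        for sid in cohort.sample_ids
    }
    summary_df = pd.DataFrame.from_dict(per_sample, orient="index").reset_index(
        names="sample_id"
    )
    cio.write_tsv(summary_df, outdir / "sample_summary.tsv", meta)
    cio.write_tsv(
        cohort_summary_table(per_sample, phenotypes), outdir / "cohort_summary.tsv", meta
    )

    mor_report = _recurrence(config, outdir, meta, segments_by_sample,
                             classified_by_sample, phenotypes)
    classify_report, predictions = _classify(
        config, genome, segments_by_sample, per_sample, phenotypes, truth
    )
    cio.write_tsv(predictions, outdir / "predictions.tsv", meta)
    cluster_report, cluster_df = _cluster(config, genome, segments_by_sample, phenotypes, truth)
    cio.write_tsv(cluster_df, outdir / "clusters.tsv", meta)
    survival_report, survival_df = _survival(phenotypes)
    cio.write_tsv(survival_df, outdir / "survival.tsv", meta)

    # LOH burden vs tumor size (detected and ground truth)
    n_loh_detected = summary_df.set_index("sample_id")["n_loh"]
    merged = phenotypes.set_index("sample_id").join(n_loh_detected)
    r_detected, p_detected = pearson(merged["n_loh"], merged["size_cm"])
    truth_merged = phenotypes.set_index("sample_id").join(
        truth.flags.set_index("sample_id")["n_loh"], rsuffix="_truth"
    )
    r_truth, p_truth = pearson(truth_merged["n_loh"], truth_merged["size_cm"])

    report = {
        "version": "cnaloh",
        "config_hash": chash,
        "seed": seed,
        "n_samples": len(phenotypes),
        "recurrence": mor_report,
        "classification": classify_report,
        "clustering": cluster_report,
        "survival": survival_report,
        "loh_size_correlation": {
            "pearson_r_detected": r_detected,
            "p_detected": p_detected,
            "pearson_r_truth": r_truth,
            "p_truth": p_truth,
        },
    }
    cio.write_json(outdir / "report.json", report)
    cio.write_json(outdir / "config.json", {**config.to_dict(), "seed": seed})
    return report


@_stage("simulate")
def _simulate(config, genome, seed):
    return simulate_cohort(config.cohort, genome, seed=seed)


@_stage("call")
def _call_all(config, genome, cohort):
    segments_by_sample = {}
    loh_by_sample = {}
    classified_by_sample = {}
    for sid in cohort.sample_ids:
        prof = cohort.profiles[sid]
        lr = paired_log_ratio(prof)
        segs = segment(lr, genome, config.seg, sample_id=sid)
        segs = call_states(segs, config.seg, large_bp=config.thresholds.large_cna_bp)
        segments_by_sample[sid] = segs
        tumor_gt = call_genotypes(prof.tumor_baf, prof.tumor_mask)
        normal_gt = call_genotypes(prof.normal_baf, prof.normal_mask)
        loh = detect_loh(tumor_gt, normal_gt, genome, config.hmm, sample_id=sid)
        loh_by_sample[sid] = loh
        classified_by_sample[sid] = merge_loh_cn(loh, segs, genome)
    return segments_by_sample, loh_by_sample, classified_by_sample


@_stage("recurrence")
def _recurrence(config, outdir, meta, segments_by_sample, classified_by_sample, phenotypes):
    groups = dict(zip(phenotypes["sample_id"], phenotypes["group"]))
    group_sizes = phenotypes["group"].value_counts().to_dict()
    mors = {}
    for group in sorted(group_sizes):
        for kind, state in (("gain", GAIN), ("loss", LOSS)):
            rows = [
                {"sample_id": s.sample_id, "chrom": s.chrom, "start": s.start, "end": s.end}
                for segs in segments_by_sample.values()
                for s in segs
                if s.state == state and groups[s.sample_id] == group
            ]
            df = pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end"])
            mor = minimal_overlapping_regions(
                df, config.min_mor_samples, group_size=group_sizes[group],
                alteration_type=kind,
            )
            mors[(group, kind)] = mor
            cio.write_tsv(mor, outdir / f"mor_{group}_{kind}.tsv", meta)
        rows = [
            {"sample_id": e.sample_id, "chrom": e.chrom, "start": e.start, "end": e.end}
            for evs in classified_by_sample.values()
            for e in evs
            if e.cls == CNLOH_CLASS and groups[e.sample_id] == group
        ]
        df = pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end"])
        mor = minimal_overlapping_regions(
            df, config.min_mor_samples, group_size=group_sizes[group],
            alteration_type="cnLOH",
        )
        mors[(group, "cnLOH")] = mor
        cio.write_tsv(mor, outdir / f"mor_{group}_cnLOH.tsv", meta)

    shared = {}
    if ("ACA", "gain") in mors and ("ACC", "gain") in mors:
        table, frac = intersect_group_regions(mors[("ACA", "gain")], mors[("ACC", "gain")])
        cio.write_tsv(table, outdir / "mor_shared_gains.tsv", meta)
        shared["aca_gain_fraction_shared_with_acc"] = frac
    counts = {
        f"{group}_{kind}": int(len(m)) for (group, kind), m in sorted(mors.items())
    }
    return {"mor_counts": counts, **shared}


@_stage("classify")
def _classify(config, genome, segments_by_sample, per_sample, phenotypes, truth):
    thr = config.thresholds
    flags = truth.flags.set_index("sample_id")
    rows = []
    for sid in phenotypes["sample_id"]:
        frac = chr5_gain_fraction(segments_by_sample[sid], genome)
        truth_frac = float(flags.loc[sid, "chr5_gain_fraction"])
        rows.append(
            {
                "sample_id": sid,
                "group": flags.loc[sid, "group"],
                "chr5_fraction": round(frac, 4),
                "chr5_fraction_truth": round(truth_frac, 4),
                "chr5_call": classify_chr5(frac, thr),
                "chr5_call_truth": classify_chr5(min(truth_frac, 1.0), thr),
                "combined_call": classify_combined(
                    per_sample[sid]["n_large_cna"], per_sample[sid]["n_cnloh"], thr
                ),
            }
        )
    pred = pd.DataFrame(rows)
    is_acc = (pred["group"] == ACC).tolist()
    chr5_table = confusion_from_predictions(is_acc, (pred["chr5_call"] == MALIGNANT).tolist())
    chr5_truth_table = confusion_from_predictions(
        is_acc, (pred["chr5_call_truth"] == MALIGNANT).tolist()
    )
    combined_table = confusion_from_predictions(
        is_acc, (pred["combined_call"] == MALIGNANT).tolist()
    )
    report = {
        "chr5": {
            "table": dataclasses.asdict(chr5_table),
            "truth_table": dataclasses.asdict(chr5_truth_table),
            "metrics": confusion_metrics(chr5_table),
            "matches_truth": dataclasses.asdict(chr5_table)
            == dataclasses.asdict(chr5_truth_table),
        },
        "combined": {
            "table": dataclasses.asdict(combined_table),
            "metrics": confusion_metrics(combined_table),
        },
    }
    return report, pred


@_stage("cluster")
def _cluster(config, genome, segments_by_sample, phenotypes, truth):
    x, sample_ids, _ = build_matrix(
        segments_by_sample, genome, config.bin_size, "state", config.cluster_chromosomes
    )
    labels, order = hierarchical_cluster(x, config.cluster_k)
    df = pd.DataFrame({"sample_id": sample_ids, "cluster": labels})
    df["scope"] = "cohort_chr5"

    acc_ids = [
        sid for sid in sample_ids
        if phenotypes.set_index("sample_id").loc[sid, "group"] == ACC
    ]
    acc_report = {}
    if len(acc_ids) >= config.cluster_k:
        xa, ids_a, _ = build_matrix(
            {sid: segments_by_sample[sid] for sid in acc_ids},
            genome, config.bin_size, "state", config.acc_cluster_chromosomes,
        )
        labels_a, _ = hierarchical_cluster(xa, config.cluster_k)
        df_a = pd.DataFrame({"sample_id": ids_a, "cluster": labels_a})
        df_a["scope"] = "acc_pattern"
        df = pd.concat([df, df_a], ignore_index=True)
        acc_report["acc_cluster_sizes"] = (
            pd.Series(labels_a).value_counts().sort_index().tolist()
        )
    report = {
        "cohort_cluster_sizes": pd.Series(labels).value_counts().sort_index().tolist(),
        **acc_report,
    }
    return report, df


@_stage("survival")
def _survival(phenotypes):
    acc = phenotypes[phenotypes["group"] == ACC]
    report = {}
    df = acc[["sample_id", "os_months", "event", "cluster_group"]].copy()
    groups = sorted(acc["cluster_group"].unique())
    medians = {}
    for g in groups:
        sub = acc[acc["cluster_group"] == g]
        _, med = kaplan_meier(sub["os_months"].to_numpy(), sub["event"].to_numpy())
        medians[g] = med
    report["km_median_by_cluster"] = medians
    if len(groups) == 2:
        a = acc[acc["cluster_group"] == groups[0]]
        b = acc[acc["cluster_group"] == groups[1]]
        stat, p = logrank(
            a["os_months"].to_numpy(), a["event"].to_numpy(),
            b["os_months"].to_numpy(), b["event"].to_numpy(),
        )
        report["logrank"] = {"statistic": stat, "p_value": p}
    return report, df
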