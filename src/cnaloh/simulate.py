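"""Synthetic paired tumor/normal SNP-array cohort with ground truth.

Emulates the genomic architecture of an adrenocortical tumor cohort:
benign adenomas (ACA) carry few, mostly small copy-number gains and rarely
show LOH, while carcinomas (ACC) carry many large CNAs with an excess of
losses, genome-wide copy-neutral LOH, and — in roughly three quarters of
samples — a gain covering most of chromosome 5. Clinical covariates are
generated alongside: tumor size is positively coupled to the sample's true
LOH burden, and overall survival follows two strata (a recurrent
"pattern" cluster of carcinomas with longer survival versus the rest).

The raw-signal model is deliberately simple: LRR is log2(CN/2) plus
Gaussian noise, BAF reflects the tumor allelic ratio at each marker, and
all events are fully clonal. See docs/methods.md for what this does and
does not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import GenomeMap
from .segmentation import PairedProfile

GAIN = "gain"
LOSS = "loss"
CNLOH = "cnLOH"

# genotype codes shared with the LOH stage
AA, AB, BB, NC = 0, 1, 2, -1
_BAF_MEAN = np.array([0.0, 0.5, 1.0])

ACA = "ACA"
ACC = "ACC"


@dataclass(frozen=True)
class EventSpec:
    """One implanted lesion: a gain (CN>=3), loss (CN<=1) or cnLOH (CN=2).

    Coordinates are 1-based inclusive. ``origin`` names the retained
    parental allele for LOH-producing events ('A', 'B' or None = random
    per event at simulation time).
    """

    chrom: str
    start: int
    end: int
    kind: str
    cn: int
    origin: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"event start {self.start} > end {self.end}")
        if self.kind == GAIN and self.cn < 3:
            raise ValueError("gain requires cn >= 3")
        if self.kind == LOSS and self.cn > 1:
            raise ValueError("loss requires cn <= 1")
        if self.kind == CNLOH and self.cn != 2:
            raise ValueError("cnLOH requires cn == 2")
        if self.kind not in (GAIN, LOSS, CNLOH):
            raise ValueError(f"unknown event kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class NoiseModel:
    """Marker-level noise: Gaussian LRR/BAF jitter, genotype errors, no-calls."""

    lrr_sd: float = 0.20
    baf_sd: float = 0.04
    genotype_error: float = 0.01
    no_call_rate: float = 0.02

    def __post_init__(self) -> None:
        for name in ("lrr_sd", "baf_sd", "genotype_error", "no_call_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (self.genotype_error <= 1 and self.no_call_rate <= 1):
            raise ValueError("rates must be <= 1")


@dataclass(frozen=True)
class GroupEventParams:
    """Event-generation parameters for one tumor group."""

    n_gains_mean: float
    gain_len: tuple[int, int]
    n_losses_mean: float
    loss_len: tuple[int, int]
    small_loss_len: tuple[int, int]
    loh_positive_prob: float
    cnloh_extra_mean: float
    cnloh_dispersion: float
    cnloh_len: tuple[int, int]


def _default_aca() -> GroupEventParams:
    return GroupEventParams(
        n_gains_mean=6.0,
        gain_len=(50_000, 300_000),
        n_losses_mean=1.0,
        loss_len=(50_000, 250_000),
        small_loss_len=(50_000, 250_000),
        loh_positive_prob=7 / 24,
        cnloh_extra_mean=1.2,
        cnloh_dispersion=5.0,
        cnloh_len=(500_000, 1_200_000),
    )


def _default_acc() -> GroupEventParams:
    return GroupEventParams(
        n_gains_mean=8.0,
        gain_len=(100_000, 1_000_000),
        n_losses_mean=2.0,
        loss_len=(500_000, 1_500_000),
        small_loss_len=(100_000, 250_000),
        loh_positive_prob=20 / 22,
        cnloh_extra_mean=13.0,
        cnloh_dispersion=0.5,
        cnloh_len=(500_000, 2_000_000),
    )


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of the default synthetic cohort.

    Group sizes, the chromosome-5 gain probability, the LOH-presence
    probabilities and the survival medians mirror the observed cohort
    (24 adenomas / 22 carcinomas; 17/22 carcinomas with a >60% chr-5 gain;
    7/24 vs 20/22 samples with LOH; median overall survival 72.2 vs 35.4
    months in the two carcinoma clusters). The size–LOH coupling is
    calibrated so the ground-truth Pearson correlation between LOH count
    and tumor size falls in the observed range (~0.4).
    """

    n_aca: int = 24
    n_acc: int = 22
    chr5_gain_prob: float = 17 / 22
    chr5_gain_frac: tuple[float, float] = (0.65, 0.95)
    pattern_prob: float = 13 / 22
    pattern_gain_chroms: tuple[str, ...] = ("7", "12", "19")
    pattern_gain_frac: tuple[float, float] = (0.50, 0.90)
    pattern_loss_chroms: tuple[str, ...] = ("1", "2", "13", "17", "22")
    pattern_loss_frac: tuple[float, float] = (0.40, 0.80)
    # recurrent gain loci shared by both groups (fractions of chromosome
    # length, so the same config works at any genome scale); stand-ins for
    # the hotspot cytobands where benign gains recur (terminal 1p, 5p, 8q,
    # 9q, 11p, 16p, 19p, distal 20q)
    hotspot_gain_loci: tuple[tuple[str, float, float], ...] = (
        ("1", 0.00, 0.03),
        ("5", 0.00, 0.03),
        ("8", 0.92, 0.95),
        ("9", 0.76, 0.80),
        ("11", 0.02, 0.05),
        ("16", 0.00, 0.03),
        ("19", 0.00, 0.04),
        ("20", 0.92, 0.96),
    )
    hotspot_gain_prob_aca: float = 0.25
    hotspot_gain_prob_acc: float = 0.55
    aca: GroupEventParams = field(default_factory=_default_aca)
    acc: GroupEventParams = field(default_factory=_default_acc)
    gain_cn: int = 3
    loss_cn: int = 1
    loh_detectable_bp: int = 500_000
    size_base_aca: float = 4.0
    size_base_acc: float = 9.0
    size_loh_coeff: float = 0.06
    size_sd: float = 5.0
    survival_median_pattern: float = 72.2
    survival_median_variable: float = 35.4
    survival_median_benign: float = 150.0
    followup_range: tuple[float, float] = (12.0, 120.0)
    noise: NoiseModel = field(default_factory=NoiseModel)
    het_rate: float = 1 / 3
    haploid_x: bool = False
    contaminated_normal_prob: float = 0.0
    seed: int = 17

    def __post_init__(self) -> None:
        if self.n_aca < 0 or self.n_acc < 0:
            raise ValueError("group counts must be >= 0")
        for p in (self.chr5_gain_prob, self.pattern_prob, self.contaminated_normal_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        for m in (
            self.survival_median_pattern,
            self.survival_median_variable,
            self.survival_median_benign,
        ):
            if m <= 0:
                raise ValueError("survival medians must be > 0")


@dataclass
class PairTruth:
    """Ground truth of one simulated pair."""

    events: list[EventSpec]
    cn: np.ndarray
    normal_genotypes: np.ndarray
    tumor_genotypes: np.ndarray
    loh_mask: np.ndarray


def validate_events(events: list[EventSpec], genome: GenomeMap) -> None:
    """Check bounds and per-chromosome non-overlap of an event list."""
    by_chrom: dict[str, list[EventSpec]] = {}
    for ev in events:
        if ev.chrom not in genome.lengths:
            raise ValueError(f"event on unknown chromosome {ev.chrom!r}")
        if ev.end > genome.lengths[ev.chrom]:
            raise ValueError(
                f"event {ev.chrom}:{ev.start}-{ev.end} exceeds chromosome length "
                f"{genome.lengths[ev.chrom]}"
            )
        by_chrom.setdefault(ev.chrom, []).append(ev)
    for chrom, evs in by_chrom.items():
        evs = sorted(evs, key=lambda e: e.start)
        for a, b in zip(evs, evs[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"overlapping events on chromosome {chrom}: "
                    f"{a.start}-{a.end} and {b.start}-{b.end}; "
                    "normalize the event list so same-chromosome events are disjoint"
                )


def simulate_pair(
    genome: GenomeMap,
    events: list[EventSpec],
    noise: NoiseModel | None = None,
    seed: int | np.random.Generator = 0,
    sample_id: str = "sample",
    het_rate: float = 1 / 3,
    normal_events: list[EventSpec] | None = None,
    haploid_x: bool = False,
) -> tuple[PairedProfile, PairTruth]:
    """Simulate one tumor/normal pair with implanted events.

    Normal LRR is zero-mean Gaussian; genotypes are drawn per marker with
    the given heterozygosity; tumor LRR is centred at log2(CN/2) inside
    events and 0 outside. Inside LOH-producing events (loss, cnLOH) every
    normal-het marker becomes homozygous for the retained allele; inside a
    CN=3 gain heterozygous BAF moves to 1/3 or 2/3 according to which
    allele was duplicated. Outside events the tumor genotype equals the
    normal genotype up to the genotype-error rate.
    """
    noise = noise or NoiseModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    validate_events(events, genome)
    if normal_events:
        validate_events(normal_events, genome)
    n = genome.n_markers

    p_het = het_rate
    p_hom = (1.0 - p_het) / 2.0
    normal_gt = rng.choice(
        np.array([AA, AB, BB], dtype=np.int8), size=n, p=[p_hom, p_het, p_hom]
    ).astype(np.int8)

    normal_cn = np.full(n, 2, dtype=np.int16)
    if haploid_x and "X" in genome.lengths:
        sl = genome.chrom_slice("X")
        normal_cn[sl] = 1
        # haploid X carries a single allele: force homozygous calls
        x_gt = normal_gt[sl]
        x_gt[x_gt == AB] = np.where(rng.random(np.sum(x_gt == AB)) < 0.5, AA, BB)
        normal_gt[sl] = x_gt
    for ev in normal_events or []:
        idx = genome.marker_index(ev.chrom, ev.start, ev.end)
        normal_cn[idx] = ev.cn

    with np.errstate(divide="ignore"):
        normal_base = np.where(normal_cn > 0, np.log2(normal_cn / 2.0), -3.0)
    normal_lrr = normal_base + rng.normal(0.0, noise.lrr_sd, n)
    normal_baf = _BAF_MEAN[normal_gt] + rng.normal(0.0, noise.baf_sd, n)
    normal_baf = np.clip(normal_baf, 0.0, 1.0)

    # tumor genotypes: copy of normal with sporadic errors, then events override
    tumor_gt = normal_gt.copy()
    if noise.genotype_error > 0:
        err = rng.random(n) < noise.genotype_error
        shift = rng.integers(1, 3, size=n).astype(np.int8)
        tumor_gt = np.where(err, (tumor_gt + shift) % 3, tumor_gt).astype(np.int8)

    cn = normal_cn.copy()
    loh_mask = np.zeros(n, dtype=bool)
    tumor_baf_mean = np.empty(n)
    tumor_baf_mean[:] = _BAF_MEAN[tumor_gt]
    for ev in events:
        idx = genome.marker_index(ev.chrom, ev.start, ev.end)
        cn[idx] = ev.cn
        origin = ev.origin or ("A" if rng.random() < 0.5 else "B")
        het = normal_gt[idx] == AB
        if ev.kind in (LOSS, CNLOH):
            loh_mask[idx] = True
            kept = AA if origin == "A" else BB
            gt = normal_gt[idx].copy()
            gt[het] = kept
            tumor_gt[idx] = gt
            tumor_baf_mean[idx] = _BAF_MEAN[gt]
        else:  # gain: duplicated allele shifts heterozygous BAF off 0.5
            gt = normal_gt[idx].copy()
            tumor_gt[idx] = gt
            baf = _BAF_MEAN[gt].copy()
            n_b = 1 + (ev.cn - 2 if origin == "B" else 0)
            baf[het] = n_b / ev.cn
            tumor_baf_mean[idx] = baf

    with np.errstate(divide="ignore"):
        tumor_base = np.where(cn > 0, np.log2(cn / 2.0), -3.0)
    tumor_lrr = tumor_base + rng.normal(0.0, noise.lrr_sd, n)
    tumor_baf = np.clip(tumor_baf_mean + rng.normal(0.0, noise.baf_sd, n), 0.0, 1.0)

    tumor_mask = rng.random(n) < noise.no_call_rate
    normal_mask = rng.random(n) < noise.no_call_rate

    profile = PairedProfile(
        sample_id=sample_id,
        tumor_lrr=tumor_lrr,
        tumor_baf=tumor_baf,
        normal_lrr=normal_lrr,
        normal_baf=normal_baf,
        tumor_mask=tumor_mask,
        normal_mask=normal_mask,
    )
    truth = PairTruth(
        events=list(events),
        cn=cn,
        normal_genotypes=normal_gt,
        tumor_genotypes=tumor_gt,
        loh_mask=loh_mask,
    )
    return profile, truth


# ---------------------------------------------------------------------------
# cohort-level generation
# ---------------------------------------------------------------------------


def _sample_rng(seed: int, index: int) -> np.random.Generator:
    """Deterministic per-sample substream from (cohort seed, sample index)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(index)]))


def _place_random_event(
    rng: np.random.Generator,
    genome: GenomeMap,
    placed: dict[str, list[tuple[int, int]]],
    length: int,
    kind: str,
    cn: int,
    max_tries: int = 40,
) -> EventSpec | None:
    chroms = list(genome.chromosomes)
    weights = np.array([genome.lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    for _ in range(max_tries):
        chrom = rng.choice(chroms, p=weights)
        clen = genome.lengths[chrom]
        if length >= clen:
            continue
        start = int(rng.integers(1, clen - length + 2))
        end = start + length - 1
        if any(start <= e and s <= end for s, e in placed.get(chrom, [])):
            continue
        placed.setdefault(chrom, []).append((start, end))
        origin = "A" if rng.random() < 0.5 else "B"
        return EventSpec(chrom, start, end, kind, cn, origin if kind != GAIN else origin)
    return None


def _place_fraction_event(
    rng: np.random.Generator,
    genome: GenomeMap,
    placed: dict[str, list[tuple[int, int]]],
    chrom: str,
    frac: float,
    kind: str,
    cn: int,
) -> EventSpec | None:
    clen = genome.lengths[chrom]
    length = max(1, int(round(frac * clen)))
    start = int(rng.integers(1, clen - length + 2))
    end = start + length - 1
    if any(start <= e and s <= end for s, e in placed.get(chrom, [])):
        return None
    placed.setdefault(chrom, []).append((start, end))
    origin = "A" if rng.random() < 0.5 else "B"
    return EventSpec(chrom, start, end, kind, cn, origin)


def _nb_count(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Negative-binomial draw parameterized by mean and dispersion k."""
    if mean <= 0:
        return 0
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def _uniform_len(rng: np.random.Generator, bounds: tuple[int, int]) -> int:
    return int(rng.integers(bounds[0], bounds[1] + 1))


def _draw_sample_events(
    rng: np.random.Generator, config: CohortConfig, genome: GenomeMap, group: str
) -> tuple[list[EventSpec], dict]:
    gp = config.aca if group == ACA else config.acc
    placed: dict[str, list[tuple[int, int]]] = {}
    events: list[EventSpec] = []

    chr5_positive = False
    pattern = False
    loh_positive = rng.random() < gp.loh_positive_prob

    if group == ACC:
        chr5_positive = rng.random() < config.chr5_gain_prob
        pattern = rng.random() < config.pattern_prob
        if chr5_positive:
            frac = rng.uniform(*config.chr5_gain_frac)
            ev = _place_fraction_event(rng, genome, placed, "5", frac, GAIN, config.gain_cn)
            if ev:
                events.append(ev)
        if pattern:
            for chrom in config.pattern_gain_chroms:
                frac = rng.uniform(*config.pattern_gain_frac)
                ev = _place_fraction_event(rng, genome, placed, chrom, frac, GAIN, config.gain_cn)
                if ev:
                    events.append(ev)
            if loh_positive:
                for chrom in config.pattern_loss_chroms:
                    frac = rng.uniform(*config.pattern_loss_frac)
                    ev = _place_fraction_event(
                        rng, genome, placed, chrom, frac, LOSS, config.loss_cn
                    )
                    if ev:
                        events.append(ev)

    hotspot_p = (
        config.hotspot_gain_prob_aca if group == ACA else config.hotspot_gain_prob_acc
    )
    for chrom, f0, f1 in config.hotspot_gain_loci:
        if chrom not in genome.lengths or rng.random() >= hotspot_p:
            continue
        clen = genome.lengths[chrom]
        start = max(1, int(round(f0 * clen)) + 1)
        end = min(clen, int(round(f1 * clen)))
        if start > end or any(
            start <= e and s <= end for s, e in placed.get(chrom, [])
        ):
            continue
        placed.setdefault(chrom, []).append((start, end))
        origin = "A" if rng.random() < 0.5 else "B"
        events.append(EventSpec(chrom, start, end, GAIN, config.gain_cn, origin))

    for _ in range(rng.poisson(gp.n_gains_mean)):
        ev = _place_random_event(
            rng, genome, placed, _uniform_len(rng, gp.gain_len), GAIN, config.gain_cn
        )
        if ev:
            events.append(ev)
    loss_len = gp.loss_len if loh_positive else gp.small_loss_len
    for _ in range(rng.poisson(gp.n_losses_mean)):
        ev = _place_random_event(
            rng, genome, placed, _uniform_len(rng, loss_len), LOSS, config.loss_cn
        )
        if ev:
            events.append(ev)
    if loh_positive:
        n_cnloh = 1 + _nb_count(rng, gp.cnloh_extra_mean, gp.cnloh_dispersion)
        for _ in range(n_cnloh):
            ev = _place_random_event(
                rng, genome, placed, _uniform_len(rng, gp.cnloh_len), CNLOH, 2
            )
            if ev:
                events.append(ev)

    n_loh = sum(
        1
        for ev in events
        if ev.kind in (LOSS, CNLOH) and ev.length >= config.loh_detectable_bp
    )
    chr5_len = genome.lengths.get("5", 0)
    chr5_gain_bp = sum(
        ev.length for ev in events if ev.chrom == "5" and ev.kind == GAIN
    )
    flags = {
        "chr5_positive": chr5_positive,
        "pattern": pattern,
        "loh_positive": loh_positive,
        "n_loh": n_loh,
        "chr5_gain_fraction": chr5_gain_bp / chr5_len if chr5_len else 0.0,
    }
    return events, flags


_HORMONE_CATEGORIES = ("nonsecreting", "cortisol", "aldosterone", "androgen")
_HORMONE_PROBS = {
    ACA: (8 / 24, 16 / 24, 0.0, 0.0),
    ACC: (3 / 22, 15 / 22, 1 / 22, 3 / 22),
}
_ENSAT_PROBS = (6 / 22, 6 / 22, 4 / 22, 6 / 22)  # stages 1..4


def _draw_phenotype(
    rng: np.random.Generator, config: CohortConfig, sample_id: str, group: str, flags: dict
) -> dict:
    size = (
        (config.size_base_aca if group == ACA else config.size_base_acc)
        + config.size_loh_coeff * flags["n_loh"]
        + rng.normal(0.0, config.size_sd)
    )
    size = round(max(size, 1.0), 1)
    hormone = str(rng.choice(_HORMONE_CATEGORIES, p=_HORMONE_PROBS[group]))
    ensat = int(rng.choice([1, 2, 3, 4], p=_ENSAT_PROBS)) if group == ACC else 0
    if group == ACC:
        cluster = "pattern" if flags["pattern"] else "variable"
        median = (
            config.survival_median_pattern
            if flags["pattern"]
            else config.survival_median_variable
        )
    else:
        cluster = "benign"
        median = config.survival_median_benign
    death = rng.exponential(median / np.log(2.0))
    followup = rng.uniform(*config.followup_range)
    event = bool(death <= followup)
    os_months = round(min(death, followup), 1)
    return {
        "sample_id": sample_id,
        "group": group,
        "size_cm": size,
        "hormone": hormone,
        "ensat": ensat,
        "os_months": os_months,
        "event": int(event),
        "cluster_group": cluster,
    }


@dataclass
class CohortTruth:
    """Ground-truth tables of a simulated cohort."""

    events: pd.DataFrame       # sample_id, chrom, start, end, class, cn, origin
    phenotypes: pd.DataFrame
    flags: pd.DataFrame        # per-sample generation flags and true quantities

    def events_of(self, sample_id: str) -> list[EventSpec]:
        sub = self.events[self.events["sample_id"] == sample_id]
        return [
            EventSpec(r.chrom, int(r.start), int(r.end), r["class"], int(r.cn), r.origin)
            for _, r in sub.iterrows()
        ]


@dataclass
class Cohort:
    """Simulated cohort: ground truth plus (optionally) the raw profiles."""

    config: CohortConfig
    genome: GenomeMap
    truth: CohortTruth
    profiles: dict[str, PairedProfile] = field(default_factory=dict)
    pair_truths: dict[str, PairTruth] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.truth.phenotypes["sample_id"])


def draw_cohort_truth(
    config: CohortConfig, genome: GenomeMap, seed: int | None = None
) -> CohortTruth:
    """Draw ground-truth events, flags and phenotypes (no signal synthesis).

    Fully deterministic in (config, seed): running twice yields identical
    tables.
    """
    seed = config.seed if seed is None else seed
    sample_plan = [(ACA, i + 1) for i in range(config.n_aca)] + [
        (ACC, i + 1) for i in range(config.n_acc)
    ]
    event_rows = []
    pheno_rows = []
    flag_rows = []
    for index, (group, k) in enumerate(sample_plan):
        sample_id = f"{group}_{k:02d}"
        rng = _sample_rng(seed, index)
        events, flags = _draw_sample_events(rng, config, genome, group)
        for ev in sorted(events, key=lambda e: (genome.chromosomes.index(e.chrom), e.start)):
            event_rows.append(
                {
                    "sample_id": sample_id,
                    "chrom": ev.chrom,
                    "start": ev.start,
                    "end": ev.end,
                    "class": ev.kind,
                    "cn": ev.cn,
                    "origin": ev.origin,
                }
            )
        pheno_rows.append(_draw_phenotype(rng, config, sample_id, group, flags))
        flag_rows.append({"sample_id": sample_id, "group": group, **flags})
    events = pd.DataFrame(
        event_rows,
        columns=["sample_id", "chrom", "start", "end", "class", "cn", "origin"],
    )
    phenotypes = pd.DataFrame(pheno_rows)
    flags = pd.DataFrame(flag_rows)
    return CohortTruth(events=events, phenotypes=phenotypes, flags=flags)


def simulate_cohort(
    config: CohortConfig | None = None,
    genome: GenomeMap | None = None,
    seed: int | None = None,
    with_signals: bool = True,
) -> Cohort:
    """Generate the full cohort: ground truth and per-sample paired profiles."""
    from .genome import default_genome

    config = config or CohortConfig()
    genome = genome or default_genome()
    seed = config.seed if seed is None else seed
    truth = draw_cohort_truth(config, genome, seed)
    cohort = Cohort(config=config, genome=genome, truth=truth)
    if not with_signals:
        return cohort
    n_samples = len(truth.phenotypes)
    for index in range(n_samples):
        sample_id = truth.phenotypes["sample_id"].iloc[index]
        # independent substream for the signal layer
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(index), 1]))
        normal_events: list[EventSpec] = []
        if config.contaminated_normal_prob > 0 and rng.random() < config.contaminated_normal_prob:
            placed: dict[str, list[tuple[int, int]]] = {}
            for _ in range(rng.poisson(20)):
                ev = _place_random_event(
                    rng, genome, placed, int(rng.integers(100_000, 1_000_000)), GAIN, 3
                )
                if ev:
                    normal_events.append(ev)
        profile, pair_truth = simulate_pair(
            genome,
            truth.events_of(sample_id),
            noise=config.noise,
            seed=rng,
            sample_id=sample_id,
            het_rate=config.het_rate,
            normal_events=normal_events or None,
            haploid_x=config.haploid_x,
        )
        cohort.profiles[sample_id] = profile
        cohort.pair_truths[sample_id] = pair_truth
    return cohort
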