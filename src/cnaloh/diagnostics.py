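"""Rule-based malignancy classifiers and confusion-matrix metrics.

Two rules distinguish carcinoma (malignant) from adenoma (benign):

* chromosome-5 rule — malignant iff the union of called gains covers
  strictly more than 60% of chromosome 5;
* combined rule — malignant iff the sample has strictly more than 50
  large CNAs (>100 kb) AND strictly more than 10 cnLOH events.

Metrics are reported as percentages rounded half-up to one decimal, the
precision at which such diagnostic figures are conventionally printed.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .genome import GenomeMap
from .segmentation import GAIN, Segment

MALIGNANT = "malignant"
BENIGN = "benign"


@dataclass(frozen=True)
class DiagnosticThresholds:
    """Cutoffs of the two malignancy rules (all strict '>' comparisons)."""

    chr5_fraction: float = 0.60
    large_cna_count: int = 50
    cnloh_count: int = 10
    large_cna_bp: int = 100_000

    def __post_init__(self) -> None:
        for name in ("chr5_fraction", "large_cna_count", "cnloh_count", "large_cna_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ConfusionTable:
    """TP/FP/FN/TN counts (positive = malignant)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (12.25 -> 12.3)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(k: int, n: int, ndigits: int = 0) -> float:
    """``k`` out of ``n`` as a percentage, rounded half-up."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return round_half_up(100.0 * k / n, ndigits)


def chr5_gain_fraction(
    segments: list[Segment], genome: GenomeMap, chrom: str = "5"
) -> float:
    """Fraction of chromosome 5 covered by the union of called gain segments."""
    if chrom not in genome.lengths:
        raise ValueError(f"chromosome {chrom!r} absent from genome map")
    clen = genome.lengths[chrom]
    ivs = sorted(
        (max(1, s.start), min(clen, s.end))
        for s in segments
        if s.chrom == chrom and s.state == GAIN
    )
    covered = 0
    cur_lo, cur_hi = None, None
    for lo, hi in ivs:
        if cur_hi is None or lo > cur_hi + 1:
            if cur_hi is not None:
                covered += cur_hi - cur_lo + 1
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    if cur_hi is not None:
        covered += cur_hi - cur_lo + 1
    return covered / clen


def classify_chr5(fraction: float, thresholds: DiagnosticThresholds | None = None) -> str:
    """Chromosome-5 rule: malignant iff the gain fraction exceeds the cutoff."""
    thresholds = thresholds or DiagnosticThresholds()
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    return MALIGNANT if fraction > thresholds.chr5_fraction else BENIGN


def classify_combined(
    n_large_cna: int, n_cnloh: int, thresholds: DiagnosticThresholds | None = None
) -> str:
    """Combined rule: malignant iff both counts exceed their cutoffs (strict)."""
    thresholds = thresholds or DiagnosticThresholds()
    if n_large_cna < 0 or n_cnloh < 0:
        raise ValueError("counts must be >= 0")
    malignant = (
        n_large_cna > thresholds.large_cna_count and n_cnloh > thresholds.cnloh_count
    )
    return MALIGNANT if malignant else BENIGN


def confusion_from_predictions(truth_malignant, predicted_malignant) -> ConfusionTable:
    """Build a confusion table from aligned boolean truth/prediction vectors."""
    if len(truth_malignant) != len(predicted_malignant):
        raise ValueError("truth and prediction vectors must align")
    tp = fp = fn = tn = 0
    for t, p in zip(truth_malignant, predicted_malignant):
        if t and p:
            tp += 1
        elif not t and p:
            fp += 1
        elif t and not p:
            fn += 1
        else:
            tn += 1
    return ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)


def confusion_metrics(table: ConfusionTable) -> dict[str, float | None]:
    """Sensitivity, specificity, PPV and NPV as percentages (one decimal).

    A metric whose denominator is zero is undefined and reported as None,
    never as 0.
    """
    if table.total <= 0:
        raise ValueError("confusion table is empty")

    def ratio(num: int, den: int) -> float | None:
        if den == 0:
            return None
        return round_half_up(100.0 * num / den, 1)

    return {
        "sensitivity": ratio(table.tp, table.tp + table.fn),
        "specificity": ratio(table.tn, table.tn + table.fp),
        "ppv": ratio(table.tp, table.tp + table.fp),
        "npv": ratio(table.tn, table.tn + table.fn),
    }
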