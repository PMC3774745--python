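"""Genotype calling from BAF and HMM-based LOH detection.

Genotypes are called from B-allele frequency with fixed thresholds
(AA < 0.25 <= AB <= 0.75 < BB). LOH is defined against the matched
normal: only markers heterozygous in the normal are informative, and a
two-state hidden Markov model (retained vs LOH) is decoded by Viterbi
over the informative markers of each chromosome. Maximal LOH-state runs
holding at least a minimum number of informative markers are reported.

Emission model (per informative marker):
    P(tumor het | retained) = 1 - delta      (delta absorbs stray het loss)
    P(tumor het | LOH)      = epsilon        (epsilon absorbs genotype error)
The transition probability is homogeneous per informative marker (no
genetic-map scaling).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genome import GenomeMap

log = logging.getLogger(__name__)

AA, AB, BB, NC = 0, 1, 2, -1
_CODE_TO_STR = {AA: "AA", AB: "AB", BB: "BB", NC: "NC"}
_STR_TO_CODE = {v: k for k, v in _CODE_TO_STR.items()}

UNCLASSIFIED = "unclassified"
CNLOH_CLASS = "cnLOH"
LOH_LOSS = "LOH_loss"
LOH_GAIN = "LOH_gain"


@dataclass(frozen=True)
class HMMParams:
    """Two-state LOH HMM parameters (all probabilities per informative marker)."""

    switch_prob: float = 5e-4
    epsilon: float = 0.02   # P(het observed | LOH)
    delta: float = 0.05     # P(hom observed | retained)
    min_informative: int = 25

    def __post_init__(self) -> None:
        for name in ("switch_prob", "epsilon", "delta"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.min_informative < 1:
            raise ValueError("min_informative must be >= 1")


@dataclass
class LOHEvent:
    """A contiguous LOH call; class stays 'unclassified' until the CN merge."""

    sample_id: str
    chrom: str
    start: int
    end: int
    n_informative: int
    cls: str = UNCLASSIFIED

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def call_genotypes(baf: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Threshold BAF into genotype codes (AA=0, AB=1, BB=2, NC=-1).

    Boundaries are inclusive for AB: BAF of exactly 0.25 or 0.75 is called
    heterozygous. Masked or NaN markers become no-calls.
    """
    baf = np.asarray(baf, dtype=float)
    finite = ~np.isnan(baf)
    if np.any((baf[finite] < 0.0) | (baf[finite] > 1.0)):
        raise ValueError("BAF outside [0, 1]")
    gt = np.full(baf.shape, AB, dtype=np.int8)
    gt[baf < 0.25] = AA
    gt[baf > 0.75] = BB
    gt[~finite] = NC
    if mask is not None:
        gt[np.asarray(mask, dtype=bool)] = NC
    return gt


def genotype_strings(gt: np.ndarray) -> np.ndarray:
    return np.array([_CODE_TO_STR[int(g)] for g in gt], dtype=object)


def genotype_codes(strings) -> np.ndarray:
    return np.array([_STR_TO_CODE[s] for s in strings], dtype=np.int8)


def _log_emissions(params: HMMParams) -> np.ndarray:
    """log P(observation | state): rows = state (0 retained, 1 LOH),
    columns = observation (0 hom, 1 het)."""
    return np.log(
        np.array(
            [
                [params.delta, 1.0 - params.delta],
                [1.0 - params.epsilon, params.epsilon],
            ]
        )
    )


def viterbi_loh(obs_het: np.ndarray, params: HMMParams) -> np.ndarray:
    """Viterbi decoding of the two-state LOH HMM.

    ``obs_het`` is a boolean vector over informative markers (True = tumor
    heterozygous). Returns a boolean vector (True = LOH state). Initial
    state distribution is uniform; score ties prefer the retained state.
    """
    obs = np.asarray(obs_het, dtype=int)
    n = len(obs)
    if n == 0:
        return np.zeros(0, dtype=bool)
    le = _log_emissions(params)
    stay = np.log1p(-params.switch_prob)
    switch = np.log(params.switch_prob)
    score = np.array([np.log(0.5) + le[0, obs[0]], np.log(0.5) + le[1, obs[0]]])
    back = np.zeros((n, 2), dtype=np.int8)
    for i in range(1, n):
        new = np.empty(2)
        for s in (0, 1):
            from_r = score[0] + (stay if s == 0 else switch)
            from_l = score[1] + (switch if s == 0 else stay)
            # ties resolved toward the retained predecessor
            if from_l > from_r:
                back[i, s] = 1
                new[s] = from_l + le[s, obs[i]]
            else:
                back[i, s] = 0
                new[s] = from_r + le[s, obs[i]]
        score = new
    path = np.zeros(n, dtype=np.int8)
    path[-1] = 1 if score[1] > score[0] else 0
    for i in range(n - 1, 0, -1):
        path[i - 1] = back[i, path[i]]
    return path.astype(bool)


def path_log_likelihood(obs_het: np.ndarray, path_loh: np.ndarray, params: HMMParams) -> float:
    """Joint log-likelihood of (state path, observations) under the HMM."""
    obs = np.asarray(obs_het, dtype=int)
    path = np.asarray(path_loh, dtype=int)
    le = _log_emissions(params)
    stay = np.log1p(-params.switch_prob)
    switch = np.log(params.switch_prob)
    ll = np.log(0.5) + le[path[0], obs[0]]
    for i in range(1, len(obs)):
        ll += stay if path[i] == path[i - 1] else switch
        ll += le[path[i], obs[i]]
    return float(ll)


def informative_markers(tumor_gt: np.ndarray, normal_gt: np.ndarray) -> np.ndarray:
    """Boolean mask: normal heterozygous and both genotypes called."""
    return (normal_gt == AB) & (tumor_gt != NC)


def detect_loh(
    tumor_gt: np.ndarray,
    normal_gt: np.ndarray,
    genome: GenomeMap,
    params: HMMParams | None = None,
    sample_id: str = "sample",
) -> list[LOHEvent]:
    """Detect LOH segments of the tumor relative to the matched normal.

    Decodes the two-state HMM per chromosome over informative markers and
    reports maximal LOH runs with at least ``params.min_informative``
    informative markers, spanning the first to last informative marker
    position of the run.
    """
    params = params or HMMParams()
    if len(tumor_gt) != genome.n_markers or len(normal_gt) != genome.n_markers:
        raise ValueError("genotype tracks not aligned to genome map")
    events: list[LOHEvent] = []
    for chrom in genome.chromosomes:
        sl = genome.chrom_slice(chrom)
        t = tumor_gt[sl]
        nrm = normal_gt[sl]
        info = informative_markers(t, nrm)
        if not info.any():
            log.warning("chromosome %s has no informative markers", chrom)
            continue
        pos = genome.positions[chrom][info]
        obs_het = t[info] == AB
        path = viterbi_loh(obs_het, params)
        # maximal runs of the LOH state
        padded = np.concatenate(([False], path, [False]))
        starts = np.flatnonzero(~padded[:-1] & padded[1:])
        ends = np.flatnonzero(padded[:-1] & ~padded[1:])
        for i0, i1 in zip(starts, ends):
            if i1 - i0 >= params.min_informative:
                events.append(
                    LOHEvent(
                        sample_id=sample_id,
                        chrom=chrom,
                        start=int(pos[i0]),
                        end=int(pos[i1 - 1]),
                        n_informative=int(i1 - i0),
                    )
                )
    return events
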