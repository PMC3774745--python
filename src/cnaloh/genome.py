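"""Genome map: chromosome lengths and ordered SNP-marker positions.

Every stage of the pipeline is aligned to a :class:`GenomeMap` — a fixed,
ordered set of chromosomes (autosomes 1–22 plus X) with 1-based marker
positions. The default map is deliberately down-scaled (10 Mb chromosomes,
one marker every 5 kb, ~46k markers genome-wide) so that a full cohort run
completes on a desktop; a full-scale map in the same format is accepted
everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_CHROMOSOMES: tuple[str, ...] = tuple(str(c) for c in range(1, 23)) + ("X",)


@dataclass
class GenomeMap:
    """Ordered chromosomes, their lengths (bp) and marker positions.

    Parameters
    ----------
    chromosomes:
        Chromosome names in genome order.
    lengths:
        Mapping chromosome -> length in bp (positive).
    positions:
        Mapping chromosome -> strictly increasing 1-based marker positions,
        each within ``[1, length]``.
    """

    chromosomes: tuple[str, ...]
    lengths: dict[str, int]
    positions: dict[str, np.ndarray]
    _offsets: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.chromosomes = tuple(self.chromosomes)
        offsets: dict[str, int] = {}
        total = 0
        for chrom in self.chromosomes:
            if chrom not in self.lengths or chrom not in self.positions:
                raise ValueError(f"chromosome {chrom!r} missing length or positions")
            if self.lengths[chrom] <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length")
            pos = np.asarray(self.positions[chrom], dtype=np.int64)
            if pos.ndim != 1 or len(pos) == 0:
                raise ValueError(f"chromosome {chrom!r} has no markers")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"marker positions on {chrom!r} not strictly increasing")
            if pos[0] < 1 or pos[-1] > self.lengths[chrom]:
                raise ValueError(f"marker positions on {chrom!r} out of bounds")
            self.positions[chrom] = pos
            offsets[chrom] = total
            total += len(pos)
        self._offsets = offsets

    @property
    def n_markers(self) -> int:
        return sum(len(self.positions[c]) for c in self.chromosomes)

    def offset(self, chrom: str) -> int:
        """Index of the chromosome's first marker in genome-wide arrays."""
        return self._offsets[chrom]

    def chrom_slice(self, chrom: str) -> slice:
        start = self._offsets[chrom]
        return slice(start, start + len(self.positions[chrom]))

    def marker_ids(self) -> np.ndarray:
        """Genome-ordered marker identifiers ``<chrom>:<pos>``."""
        ids = [
            f"{chrom}:{pos}"
            for chrom in self.chromosomes
            for pos in self.positions[chrom]
        ]
        return np.asarray(ids, dtype=object)

    def marker_index(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Genome-wide indices of markers inside [start, end] (1-based incl.)."""
        pos = self.positions[chrom]
        lo = int(np.searchsorted(pos, start, side="left"))
        hi = int(np.searchsorted(pos, end, side="right"))
        return np.arange(lo, hi) + self._offsets[chrom]


def default_genome(
    chrom_length: int = 10_000_000,
    marker_spacing: int = 5_000,
    chromosomes: tuple[str, ...] = DEFAULT_CHROMOSOMES,
) -> GenomeMap:
    """Down-scaled desk genome: equal-length chromosomes, evenly spaced markers."""
    pos = np.arange(marker_spacing, chrom_length + 1, marker_spacing, dtype=np.int64)
    return GenomeMap(
        chromosomes=chromosomes,
        lengths={c: chrom_length for c in chromosomes},
        positions={c: pos.copy() for c in chromosomes},
    )
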