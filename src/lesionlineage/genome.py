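"""Genome binning layout and the elementary observation records.

Every track in the pipeline (simulated or real) lives on a shared
:class:`GenomeLayout`: an ordered set of chromosomes tiled by fixed-width,
0-based half-open bins.  The last bin of a chromosome may be short.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np


class BinDepth(NamedTuple):
    """Read-depth log-ratio (log2 tumor/normal) for one genomic bin."""

    chrom: str
    start: int
    end: int
    log_ratio: float


class HetSite(NamedTuple):
    """Germline heterozygous SNP with tumor allele counts.

    ``pos`` is 1-based (VCF convention); ``ref_count`` is the number of reads
    matching the reference allele out of ``depth`` total.
    """

    chrom: str
    pos: int
    ref_count: int
    depth: int


@dataclass
class GenomeLayout:
    """Chromosomes tiled into fixed-width bins.

    Parameters
    ----------
    chromosomes:
        Ordered ``(name, length_bp)`` pairs.
    bin_size:
        Bin width in bp.  Bins are 0-based half-open; the final bin of each
        chromosome is truncated at the chromosome end.
    """

    chromosomes: list[tuple[str, int]]
    bin_size: int
    # derived, filled in __post_init__
    bin_chrom_idx: np.ndarray = field(init=False, repr=False)
    bin_start: np.ndarray = field(init=False, repr=False)
    bin_end: np.ndarray = field(init=False, repr=False)
    chrom_slices: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError(f"bin_size must be positive, got {self.bin_size}")
        if not self.chromosomes:
            raise ValueError("layout needs at least one chromosome")
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length {length}")
        chrom_idx, starts, ends = [], [], []
        self.chrom_slices = {}
        offset = 0
        for ci, (name, length) in enumerate(self.chromosomes):
            n = -(-length // self.bin_size)  # ceil
            for b in range(n):
                s = b * self.bin_size
                chrom_idx.append(ci)
                starts.append(s)
                ends.append(min(s + self.bin_size, length))
            self.chrom_slices[name] = slice(offset, offset + n)
            offset += n
        self.bin_chrom_idx = np.asarray(chrom_idx, dtype=np.int32)
        self.bin_start = np.asarray(starts, dtype=np.int64)
        self.bin_end = np.asarray(ends, dtype=np.int64)

    @property
    def n_bins(self) -> int:
        return len(self.bin_start)

    @property
    def chrom_names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def chrom_length(self, chrom: str) -> int:
        return dict(self.chromosomes)[chrom]

    def bins(self) -> Iterator[tuple[str, int, int]]:
        names = self.chrom_names
        for ci, s, e in zip(self.bin_chrom_idx, self.bin_start, self.bin_end):
            yield names[ci], int(s), int(e)

    def bin_index(self, chrom: str, pos0: int) -> int:
        """Global bin index containing 0-based position ``pos0`` on ``chrom``."""
        sl = self.chrom_slices.get(chrom)
        if sl is None:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not 0 <= pos0 < self.chrom_length(chrom):
            raise ValueError(f"position {pos0} outside {chrom}")
        return sl.start + pos0 // self.bin_size

    def log_ratio_vector(self, bins: list[BinDepth]) -> np.ndarray:
        """Per-bin log-ratio array aligned to the layout (NaN where missing)."""
        out = np.full(self.n_bins, np.nan)
        for b in bins:
            i = self.bin_index(b.chrom, b.start)
            out[i] = b.log_ratio
        return out


def make_genome(n_chrom: int, chrom_len: int, bin_size: int) -> GenomeLayout:
    """Build a layout of ``n_chrom`` equal-length chromosomes named chr1..chrN.

    Raises
    ------
    ValueError
        If any argument is non-positive or ``bin_size`` exceeds ``chrom_len``.
    """
    if n_chrom <= 0 or chrom_len <= 0 or bin_size <= 0:
        raise ValueError("all arguments must be positive")
    if bin_size > chrom_len:
        raise ValueError("bin_size must not exceed chrom_len")
    return GenomeLayout([(f"chr{i + 1}", chrom_len) for i in range(n_chrom)], bin_size)
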