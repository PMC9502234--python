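"""Binned coverage: aggregate shifted tags into fixed-width windows.

Each chromosome is split into consecutive non-overlapping bins (default
200 bp); the per-bin tag count is the quantity the HMM models. An
optional input/control track is scaled down to the treatment depth and
subtracted bin-wise to correct chromatin and amplification biases.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genome import GenomeLayout
from .tags import TagCollection

DEFAULT_BIN_SIZE = 200


@dataclass
class BinnedCoverage:
    """Integer tag counts over fixed non-overlapping genomic bins.

    ``counts[chrom]`` has length ``ceil(chrom_length / bin_size)``; the
    last bin may be shorter than ``bin_size`` but is retained.
    """

    layout: GenomeLayout
    bin_size: int
    counts: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom in self.layout.names:
            expected = self.layout.n_bins(chrom, self.bin_size)
            got = len(self.counts[chrom])
            if got != expected:
                raise ValueError(
                    f"{chrom}: expected {expected} bins, got {got}"
                )

    @property
    def total(self) -> int:
        return int(sum(v.sum() for v in self.counts.values()))

    @property
    def n_bins(self) -> int:
        return sum(len(v) for v in self.counts.values())

    def bin_bounds(self, chrom: str, i: int) -> tuple[int, int]:
        start = i * self.bin_size
        return start, min(start + self.bin_size, self.layout.length(chrom))

    def to_bedgraph(self, path: str | Path) -> None:
        """Export as bedGraph (chrom, start, end, count) for browser inspection."""
        with open(path, "w") as fh:
            for chrom in self.layout.names:
                for i, c in enumerate(self.counts[chrom]):
                    start, end = self.bin_bounds(chrom, i)
                    fh.write(f"{chrom}\t{start}\t{end}\t{int(c)}\n")


def bin_counts(tags: TagCollection, bin_size: int = DEFAULT_BIN_SIZE) -> BinnedCoverage:
    """Count tags per bin; strand is ignored at this stage."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    counts = {}
    for chrom in tags.layout.names:
        nb = tags.layout.n_bins(chrom, bin_size)
        pos = tags.chrom_positions(chrom)
        counts[chrom] = np.bincount(pos // bin_size, minlength=nb).astype(np.int64)
    return BinnedCoverage(tags.layout, bin_size, counts)


def subtract_control(treatment: BinnedCoverage, control: BinnedCoverage) -> BinnedCoverage:
    """Scale the control track down to treatment depth and subtract it.

    The scale is ``s = min(1, treatment_total / control_total)`` — the
    control is never scaled up. Per bin the output is
    ``max(0, t - round(s * c))`` with round-half-to-even, so counts stay
    non-negative integers (valid negative-binomial support).
    """
    if treatment.layout != control.layout or treatment.bin_size != control.bin_size:
        raise ValueError("treatment and control must share layout and bin size")
    ctotal = control.total
    if ctotal <= 0:
        raise ValueError("control track has zero total count")
    s = min(1.0, treatment.total / ctotal)
    out = {}
    for chrom in treatment.layout.names:
        scaled = np.rint(s * control.counts[chrom]).astype(np.int64)
        out[chrom] = np.maximum(treatment.counts[chrom] - scaled, 0)
    return BinnedCoverage(treatment.layout, treatment.bin_size, out)
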