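"""Turn per-bin q-values into peaks and write BED output.

Bins whose q-value passes the FDR threshold are *enriched*; runs of
enriched bins separated by at most ``gap`` non-enriched bins merge into
one peak. The gap is counted in bins, so tuning grids stay integer and
independent of the bin size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import FormatError
from .hmm import BinScores

#: sentinel accepted for ``gap`` meaning "merge everything on a chromosome"
GAP_INF = math.inf


@dataclass
class Peak:
    """A called enrichment interval (0-based half-open coordinates).

    ``score`` is the BED score ``round(min(1000, 10 * -log10(q_min)))``;
    ``q_min`` is the minimum q-value among *member* (enriched) bins —
    non-enriched bins swallowed by a merge lie inside the coordinates but
    do not contribute to the score.
    """

    chromosome: str
    start: int
    end: int
    score: float
    q_min: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak start {self.start} must be < end {self.end}")

    def intersects(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


def peak_score(q_min: float) -> int:
    """BED score from a q-value: 10 * -log10(q), capped at 1000."""
    if q_min <= 0:
        return 1000
    return int(round(min(1000.0, 10.0 * -math.log10(q_min))))


def enriched_bins(scores: BinScores, fdr: float) -> dict[str, np.ndarray]:
    """Indices of bins with q-value <= fdr, per chromosome, sorted."""
    if not 0 < fdr < 1:
        raise ValueError(f"fdr must lie in (0, 1), got {fdr}")
    return {
        c: np.nonzero(scores.qvalue[c] <= fdr)[0] for c in scores.layout.names
    }


def merge_bins_to_peaks(
    enriched: dict[str, np.ndarray], gap: float, scores: BinScores
) -> list[Peak]:
    """Merge enriched bins into peaks, tolerating up to ``gap`` holes.

    Two consecutive enriched bins i < j on one chromosome join the same
    peak iff at most ``gap`` non-enriched bins lie between them
    (``j - i - 1 <= gap``). ``gap`` may be ``math.inf`` to force one peak
    per chromosome.
    """
    if gap != GAP_INF and (gap < 0 or int(gap) != gap):
        raise ValueError(f"gap must be a non-negative integer or inf, got {gap}")
    peaks: list[Peak] = []
    bin_size = scores.bin_size
    for chrom in scores.layout.names:
        idx = enriched.get(chrom)
        if idx is None or len(idx) == 0:
            continue
        clen = scores.layout.length(chrom)
        if gap == GAP_INF:
            groups = [idx]
        else:
            breaks = np.nonzero(np.diff(idx) - 1 > gap)[0] + 1
            groups = np.split(idx, breaks)
        q = scores.qvalue[chrom]
        for g in groups:
            q_min = float(q[g].min())
            start = int(g[0]) * bin_size
            end = min((int(g[-1]) + 1) * bin_size, clen)
            peaks.append(Peak(chrom, start, end, peak_score(q_min), q_min))
    return peaks


def call_peaks(scores: BinScores, fdr: float, gap: float) -> list[Peak]:
    """Threshold q-values at ``fdr`` and merge across gaps of <= ``gap`` bins."""
    return merge_bins_to_peaks(enriched_bins(scores, fdr), gap, scores)


def write_peaks_bed(peaks: list[Peak], path: str | Path) -> None:
    """Write sorted peaks as BED6 (name peak_N, integer score, strand '.')."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks, 1):
            fh.write(
                f"{p.chromosome}\t{p.start}\t{p.end}\tpeak_{i}\t{int(round(p.score))}\t.\n"
            )


def read_scored_peaks(path: str | Path) -> list[Peak]:
    """Read an external scored peak BED (MACS2/SICER dialects, score in column 5)."""
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise FormatError(
                    f"{path}: line {lineno}: scored peak BED needs >= 5 columns"
                )
            try:
                start, end, score = int(parts[1]), int(parts[2]), float(parts[4])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: bad coordinates or score") from exc
            if start >= end:
                raise FormatError(f"{path}: line {lineno}: start must be < end")
            peaks.append(Peak(parts[0], start, end, score))
    return peaks
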