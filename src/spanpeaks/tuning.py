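"""Markup labels and semi-supervised hyperparameter tuning.

The user annotates a handful of genomic regions with four label kinds:

* ``peaks``      — at least one peak must intersect the region (guards
  against overly conservative calling);
* ``noPeaks``    — no peak may intersect it (guards against liberal calling);
* ``peakStart``  — exactly one peak must have its left boundary inside;
* ``peakEnd``    — exactly one peak must have its right boundary inside
  (boundary kinds control peak lengths).

Tuning evaluates a peak calling over every (FDR, gap) grid pair and
returns the pair minimising the number of unsatisfied labels. Ties
break toward the smaller FDR, then the smaller gap — the most
statistically stringent equivalent solution. For externally called
scored peaks (e.g. MACS2 or SICER output), a score threshold is tuned
the same way over the distinct observed scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .errors import FormatError, SpanError
from .hmm import BinScores
from .peaks import Peak, call_peaks

KINDS = ("peaks", "noPeaks", "peakStart", "peakEnd")
_KIND_LOOKUP = {k.lower(): k for k in KINDS}

DEFAULT_FDR_GRID = (0.1, 0.05, 1e-2, 1e-3, 1e-4, 1e-6, 1e-8, 1e-10)
DEFAULT_GAP_GRID = (0, 1, 2, 3, 5, 10, 20, 50)


@dataclass(frozen=True)
class MarkupLabel:
    """One labeled interval (0-based half-open) of one of the four kinds."""

    chromosome: str
    start: int
    end: int
    kind: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"label start {self.start} must be < end {self.end}")
        if self.kind not in KINDS:
            raise ValueError(f"unknown label kind {self.kind!r}")


@dataclass
class TuningResult:
    """Exhaustive tuning grid plus the selected optimum."""

    grid: list[tuple]  # rows (fdr, gap, error_count, errors_by_kind)
    best: tuple
    best_errors: int


def parse_markup(path: str | Path) -> list[MarkupLabel]:
    """Parse a markup TSV/BED: chrom, start, end, kind (case-insensitive).

    BED files whose name column holds the kind parse identically; extra
    columns are ignored, overlapping labels are permitted and input
    order is preserved.
    """
    labels: list[MarkupLabel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(
                    f"{path}: line {lineno}: markup needs >= 4 columns (chrom, start, end, kind)"
                )
            kind = _KIND_LOOKUP.get(parts[3].strip().lower())
            if kind is None:
                raise FormatError(
                    f"{path}: line {lineno}: unknown label kind {parts[3]!r} "
                    f"(expected one of {', '.join(KINDS)})"
                )
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if start >= end:
                raise FormatError(f"{path}: line {lineno}: start must be < end")
            labels.append(MarkupLabel(parts[0], start, end, kind))
    return labels


def write_markup(labels: list[MarkupLabel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for lab in labels:
            fh.write(f"{lab.chromosome}\t{lab.start}\t{lab.end}\t{lab.kind}\n")


def label_satisfied(label: MarkupLabel, peaks: list[Peak]) -> bool:
    """Does the peak list satisfy one label?

    ``peakStart`` requires *exactly one* peak start in [start, end);
    ``peakEnd`` requires exactly one half-open peak end in (start, end],
    so a peak ending exactly at the label's start does not count —
    symmetric with ``peakStart``.
    """
    on_chrom = [p for p in peaks if p.chromosome == label.chromosome]
    if label.kind == "peaks":
        return any(p.intersects(label.start, label.end) for p in on_chrom)
    if label.kind == "noPeaks":
        return not any(p.intersects(label.start, label.end) for p in on_chrom)
    if label.kind == "peakStart":
        n = sum(1 for p in on_chrom if label.start <= p.start < label.end)
        return n == 1
    n = sum(1 for p in on_chrom if label.start < p.end <= label.end)
    return n == 1


def count_errors(labels: list[MarkupLabel], peaks: list[Peak]):
    """Number of unsatisfied labels, total and partitioned by kind."""
    by_kind = {k: 0 for k in KINDS}
    for lab in labels:
        if not label_satisfied(lab, peaks):
            by_kind[lab.kind] += 1
    return sum(by_kind.values()), by_kind


def tune_parameters(
    scores: BinScores,
    labels: list[MarkupLabel],
    fdr_grid=None,
    gap_grid=None,
) -> TuningResult:
    """Exhaustively evaluate the (FDR, gap) grid against the markup.

    The optimum minimises the total number of unsatisfied labels; ties
    break toward smaller FDR, then smaller gap. The full grid is kept in
    the result for reporting.
    """
    if not labels:
        raise SpanError(
            "markup is empty; provide at least one label (ideally >= 1 of each kind)"
        )
    fdr_grid = sorted(set(DEFAULT_FDR_GRID if fdr_grid is None else fdr_grid))
    gap_grid = sorted(set(DEFAULT_GAP_GRID if gap_grid is None else gap_grid))
    if not fdr_grid or not gap_grid:
        raise SpanError("tuning grids must be non-empty")
    grid = []
    best = None
    for fdr in fdr_grid:
        for gap in gap_grid:
            peaks = call_peaks(scores, fdr, gap)
            total, by_kind = count_errors(labels, peaks)
            grid.append((fdr, gap, total, by_kind))
            key = (total, fdr, gap)
            if best is None or key < best:
                best = key
    return TuningResult(grid=grid, best=(best[1], best[2]), best_errors=best[0])


def tune_score_threshold(scored_peaks: list[Peak], labels: list[MarkupLabel]):
    """Calibrate a score cutoff for an external peak list against the markup.

    Candidate thresholds are the distinct observed scores; each keeps
    peaks with ``score >= threshold``. Ties in the error count break
    toward the *smallest* threshold (retaining the most peaks). Returns
    ``(threshold, filtered_peaks, TuningResult)``.
    """
    if not scored_peaks:
        raise SpanError("cannot tune a score threshold on an empty peak list")
    if not labels:
        raise SpanError("markup is empty; provide at least one label")
    grid = []
    best = None
    for thr in sorted({p.score for p in scored_peaks}):
        kept = [p for p in scored_peaks if p.score >= thr]
        total, by_kind = count_errors(labels, kept)
        grid.append((thr, total, by_kind))
        key = (total, thr)
        if best is None or key < best:
            best = key
    threshold = best[1]
    filtered = [p for p in scored_peaks if p.score >= threshold]
    return threshold, filtered, TuningResult(grid=grid, best=(threshold,), best_errors=best[0])


def write_tuning_report(result: TuningResult, path: str | Path) -> None:
    """TSV of the full grid: fdr, gap, total and per-kind error counts."""
    with open(path, "w") as fh:
        fh.write("fdr\tgap\ttotal_errors\t" + "\t".join(f"errors_{k}" for k in KINDS) + "\n")
        for fdr, gap, total, by_kind in result.grid:
            fh.write(
                f"{fdr:g}\t{gap:g}\t{total}\t"
                + "\t".join(str(by_kind[k]) for k in KINDS)
                + "\n"
            )
        best = "\t".join(f"{v:g}" for v in result.best)
        fh.write(f"# best\t{best}\ttotal_errors={result.best_errors}\n")
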