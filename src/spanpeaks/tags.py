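"""Read alignments and reduce them to strand-aware 5' tags.

A *tag* is the 5'-most genomic position of an aligned read together with
its strand. The whole downstream pipeline (duplicate filtering,
fragment-size estimation by strand cross-correlation, tag shifting,
binning) operates on tags only; read sequences and qualities are never
kept. Coordinates are 0-based half-open throughout; BAM positions are
converted on ingestion.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

from ._kernels import cross_correlation_counts
from .errors import FormatError, SpanError
from .genome import GenomeLayout

log = logging.getLogger(__name__)

STRANDS = ("+", "-")

#: default scan limit for fragment-size estimation, bases
DEFAULT_MAX_SHIFT = 500
#: default lower bound of the scan, skipping the read-length "phantom" peak
DEFAULT_EXCLUSION = 50


@dataclass(frozen=True)
class Tag:
    """A single strand-aware 5' read position."""

    chromosome: str
    position: int
    strand: str


class TagCollection:
    """Multiset of tags grouped by chromosome and strand.

    Internally each (chromosome, strand) holds a sorted int64 position
    array; duplicates are allowed until :func:`deduplicate` is applied.
    """

    def __init__(self, layout: GenomeLayout, tags: dict[str, dict[str, np.ndarray]]):
        self.layout = layout
        self._tags: dict[str, dict[str, np.ndarray]] = {}
        for chrom in layout.names:
            per = tags.get(chrom, {})
            self._tags[chrom] = {
                s: np.sort(np.asarray(per.get(s, ()), dtype=np.int64)) for s in STRANDS
            }

    @classmethod
    def from_tags(cls, layout: GenomeLayout, tags) -> "TagCollection":
        """Build from an iterable of :class:`Tag` (or (chrom, pos, strand) tuples)."""
        acc: dict[str, dict[str, list[int]]] = {}
        for t in tags:
            chrom, pos, strand = (
                (t.chromosome, t.position, t.strand) if isinstance(t, Tag) else t
            )
            acc.setdefault(chrom, {"+": [], "-": []})[strand].append(pos)
        return cls(layout, {c: {s: np.array(v) for s, v in d.items()} for c, d in acc.items()})

    def positions(self, chromosome: str, strand: str) -> np.ndarray:
        return self._tags[chromosome][strand]

    def chrom_positions(self, chromosome: str) -> np.ndarray:
        """All positions on a chromosome, strands pooled (unsorted concat)."""
        d = self._tags[chromosome]
        return np.concatenate([d["+"], d["-"]])

    @property
    def library_size(self) -> int:
        return sum(len(d[s]) for d in self._tags.values() for s in STRANDS)

    def strand_size(self, strand: str) -> int:
        return sum(len(d[strand]) for d in self._tags.values())

    def iter_tags(self):
        for chrom in self.layout.names:
            for strand in STRANDS:
                for pos in self._tags[chrom][strand]:
                    yield Tag(chrom, int(pos), strand)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TagCollection):
            return NotImplemented
        if self.layout != other.layout:
            return False
        return all(
            np.array_equal(self._tags[c][s], other._tags[c][s])
            for c in self.layout.names
            for s in STRANDS
        )


# ---------------------------------------------------------------------------
# ingestion
# ---------------------------------------------------------------------------

_BED_SKIP_PREFIXES = ("#", "track", "browser")


def _resolve_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    name = path.name.lower()
    if name.endswith(".bam"):
        return "BAM"
    if name.endswith(".bed.gz"):
        return "BED.GZ"
    if name.endswith(".bed"):
        return "BED"
    raise FormatError(
        f"cannot resolve format of {path} from its extension; pass format explicitly"
    )


def _read_bed_tags(path: Path, gzipped: bool, layout: GenomeLayout):
    acc: dict[str, dict[str, list[int]]] = {
        c: {"+": [], "-": []} for c in layout.names
    }
    dropped_chrom = 0
    dropped_range = 0
    opener = gzip.open if gzipped else open
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_BED_SKIP_PREFIXES):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(
                    f"{path}: line {lineno}: BED record lacks a strand column (need >= 6 fields)"
                )
            chrom, start_s, end_s, strand = parts[0], parts[1], parts[2], parts[5]
            if strand not in STRANDS:
                raise FormatError(
                    f"{path}: line {lineno}: invalid strand {strand!r}"
                )
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if chrom not in layout:
                dropped_chrom += 1
                continue
            pos = start if strand == "+" else end - 1  # 5' end, half-open intervals
            if not 0 <= pos < layout.length(chrom):
                dropped_range += 1
                continue
            acc[chrom][strand].append(pos)
    return acc, dropped_chrom, dropped_range


def _read_bam_tags(path: Path, layout: GenomeLayout):
    acc: dict[str, dict[str, list[int]]] = {
        c: {"+": [], "-": []} for c in layout.names
    }
    dropped_chrom = 0
    dropped_flag = 0
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                dropped_flag += 1
                continue
            chrom = rec.reference_name
            if chrom not in layout:
                dropped_chrom += 1
                continue
            if rec.is_reverse:
                pos, strand = rec.reference_end - 1, "-"
            else:
                pos, strand = rec.reference_start, "+"
            if 0 <= pos < layout.length(chrom):
                acc[chrom][strand].append(pos)
    return acc, dropped_chrom, dropped_flag


def read_alignments(
    path: str | Path, layout: GenomeLayout, format: str = "auto"
) -> TagCollection:
    """Read an alignment file into a :class:`TagCollection`.

    Each usable alignment contributes exactly one tag at its 5' end
    (interval start for ``+`` reads, ``end - 1`` for ``-`` reads under
    half-open coordinates). Unmapped/secondary/supplementary BAM records
    and records on chromosomes absent from ``layout`` are dropped; the
    dropped counts are logged.

    Parameters
    ----------
    path
        Alignment file in BAM, BED or BED.GZ format.
    layout
        Genome coordinate frame; defines which chromosomes are kept.
    format
        One of ``BAM``, ``BED``, ``BED.GZ`` or ``auto`` (resolve by
        file extension).
    """
    path = Path(path)
    if not path.exists():
        raise SpanError(f"alignment file not found: {path}")
    fmt = _resolve_format(path, format)
    if fmt == "BAM":
        acc, d_chrom, d_flag = _read_bam_tags(path, layout)
        if d_flag:
            log.info("%s: dropped %d unmapped/secondary/supplementary records", path, d_flag)
        d_range = 0
    elif fmt in ("BED", "BED.GZ"):
        acc, d_chrom, d_range = _read_bed_tags(path, fmt == "BED.GZ", layout)
    else:
        raise FormatError(f"unknown format {fmt!r}; expected BAM, BED, BED.GZ or auto")
    if d_chrom:
        log.warning("%s: dropped %d records on chromosomes absent from layout", path, d_chrom)
    if d_range:
        log.warning("%s: dropped %d records with out-of-range coordinates", path, d_range)
    coll = TagCollection(
        layout, {c: {s: np.array(v, dtype=np.int64) for s, v in d.items()} for c, d in acc.items()}
    )
    if coll.library_size == 0:
        log.warning("%s: no usable tags after filtering", path)
    return coll


def write_tags_bed(tags: TagCollection, path: str | Path, read_length: int = 1) -> None:
    """Write tags back as a BED6 file (one ``read_length``-wide interval per tag).

    Intervals are laid out so that re-reading the file recovers the exact
    same tag positions: a ``+`` tag at p becomes ``[p, p + read_length)``
    and a ``-`` tag at p becomes ``[p - read_length + 1, p + 1)``, clipped
    to the chromosome.
    """
    path = Path(path)

    def _write(fh) -> None:
        i = 0
        for chrom in tags.layout.names:
            clen = tags.layout.length(chrom)
            rows = []
            for strand in STRANDS:
                for pos in tags.positions(chrom, strand):
                    pos = int(pos)
                    if strand == "+":
                        start, end = pos, min(pos + read_length, clen)
                    else:
                        start, end = max(pos - read_length + 1, 0), pos + 1
                    rows.append((start, end, strand))
            rows.sort()
            for start, end, strand in rows:
                i += 1
                fh.write(f"{chrom}\t{start}\t{end}\ttag_{i}\t0\t{strand}\n")

    if path.name.endswith(".gz"):
        # fixed mtime + empty internal name => byte-deterministic output
        with open(path, "wb") as raw:
            with gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0) as gz:
                with io.TextIOWrapper(gz, encoding="ascii", newline="") as fh:
                    _write(fh)
    else:
        with open(path, "w") as fh:
            _write(fh)


# ---------------------------------------------------------------------------
# tag-level operations
# ---------------------------------------------------------------------------


def deduplicate(tags: TagCollection) -> TagCollection:
    """Keep exactly one tag per distinct (chromosome, strand, position).

    Removes PCR-duplicate artifacts; idempotent and order-independent.
    """
    return TagCollection(
        tags.layout,
        {
            c: {s: np.unique(tags.positions(c, s)) for s in STRANDS}
            for c in tags.layout.names
        },
    )


def shift_tags(tags: TagCollection, fragment_size: int) -> TagCollection:
    """Shift tags by half the fragment size toward the fragment centre.

    ``+`` tags move right and ``-`` tags move left by
    ``floor(fragment_size / 2)``; results are clamped into the chromosome.
    Improves spatial resolution of the binned signal.
    """
    if fragment_size < 0:
        raise ValueError("fragment_size must be >= 0")
    half = fragment_size // 2
    out: dict[str, dict[str, np.ndarray]] = {}
    for chrom in tags.layout.names:
        clen = tags.layout.length(chrom)
        out[chrom] = {
            "+": np.clip(tags.positions(chrom, "+") + half, 0, clen - 1),
            "-": np.clip(tags.positions(chrom, "-") - half, 0, clen - 1),
        }
    return TagCollection(tags.layout, out)


def _chrom_correlations(tags, chrom, exclusion, max_shift):
    """Pearson correlation of + counts vs - counts advanced by d, all d in scan."""
    L = tags.layout.length(chrom)
    up, uc = np.unique(tags.positions(chrom, "+"), return_counts=True)
    vp, vc = np.unique(tags.positions(chrom, "-"), return_counts=True)
    if len(up) == 0 or len(vp) == 0:
        return None
    uc = uc.astype(np.float64)
    vc = vc.astype(np.float64)
    mx = uc.sum() / L
    sx2 = (uc**2).sum() / L - mx**2
    if sx2 <= 0:
        return None
    ds = np.arange(exclusion, max_shift + 1)
    # the advanced vector y_d[i] = y[i + d] keeps only - tags at position >= d
    cum_c = np.concatenate(([0.0], np.cumsum(vc)))
    cum_c2 = np.concatenate(([0.0], np.cumsum(vc**2)))
    idx = np.searchsorted(vp, ds)
    my = (vc.sum() - cum_c[idx]) / L
    sy2 = ((vc**2).sum() - cum_c2[idx]) / L - my**2
    cross = cross_correlation_counts(up, uc, vp, vc, max_shift)[exclusion:]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (cross / L - mx * my) / np.sqrt(sx2 * sy2)
    corr[~np.isfinite(corr)] = -np.inf
    return corr


def estimate_fragment_size(
    tags: TagCollection,
    max_shift: int = DEFAULT_MAX_SHIFT,
    exclusion: int = DEFAULT_EXCLUSION,
) -> int:
    """Estimate the library fragment size by strand cross-correlation.

    Scans shifts ``d`` in ``[exclusion, max_shift]`` and returns the one
    maximising the Pearson correlation between the per-base ``+`` strand
    tag-count vector and the ``-`` strand vector advanced by ``d``,
    aggregated across chromosomes with weights proportional to chromosome
    length. Ties break toward the smaller shift. ``exclusion`` (default
    50) skips the read-length "phantom" correlation peak.
    """
    if max_shift < 1:
        raise ValueError("max_shift must be >= 1")
    if not 0 <= exclusion <= max_shift:
        raise ValueError("exclusion must lie in [0, max_shift]")
    if tags.strand_size("+") == 0 or tags.strand_size("-") == 0:
        raise SpanError(
            "fragment-size estimation needs tags on both strands; "
            "pass an explicit fragment size instead"
        )
    per_chrom = []
    for chrom in tags.layout.names:
        corr = _chrom_correlations(tags, chrom, exclusion, max_shift)
        if corr is not None:
            per_chrom.append((tags.layout.length(chrom), corr))
    if not per_chrom:
        raise SpanError(
            "no chromosome has tags on both strands; pass an explicit fragment size"
        )
    total_w = sum(w for w, _ in per_chrom)
    agg = sum((w / total_w) * corr for w, corr in per_chrom)
    return int(exclusion + int(np.argmax(agg)))
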