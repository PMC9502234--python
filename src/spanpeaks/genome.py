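"""Genome coordinate frame: ordered chromosomes with lengths.

All coordinates in the package are 0-based, half-open (BED convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

from .errors import FormatError


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered list of chromosomes with their lengths in bases.

    Parameters
    ----------
    chromosomes
        Sequence of ``(name, length)`` pairs. Names must be unique and
        non-empty; lengths strictly positive.
    """

    chromosomes: tuple[tuple[str, int], ...]
    _index: dict = field(init=False, repr=False, compare=False, hash=False, default=None)

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(names) != len(set(names)):
            raise ValueError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if not name:
                raise ValueError("chromosome name must be non-empty")
            if length < 1:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        object.__setattr__(self, "_index", dict(self.chromosomes))

    @classmethod
    def from_pairs(cls, pairs) -> "GenomeLayout":
        return cls(tuple((str(n), int(l)) for n, l in pairs))

    @classmethod
    def from_chrom_sizes(cls, path: str | Path) -> "GenomeLayout":
        """Read a UCSC-style chrom.sizes file (``name<TAB>length``)."""
        pairs = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise FormatError(f"{path}: line {lineno}: expected 'name<TAB>length'")
                try:
                    length = int(parts[1])
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: line {lineno}: length {parts[1]!r} is not an integer"
                    ) from exc
                pairs.append((parts[0], length))
        return cls.from_pairs(pairs)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def length(self, name: str) -> int:
        return self._index[name]

    def n_bins(self, name: str, bin_size: int) -> int:
        return math.ceil(self.length(name) / bin_size)

    def write_chrom_sizes(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in self.chromosomes:
                fh.write(f"{name}\t{length}\n")
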