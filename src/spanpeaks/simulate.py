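"""Synthetic ChIP-seq study generator with planted ground truth.

Emulates the data regime the pipeline is built for: a small genome with
disjoint planted enrichment intervals, negative-binomial per-bin tag
counts (background mean inside unenriched bins, fold x background inside
truth bins), strand-aware reads with a fixed fragment length, optional
PCR duplicates, an optional input/control library with background
statistics everywhere, and markup labels derived from the truth.

Counts are drawn per bin and then positioned per base (the fragment
*midpoint* is uniform within its bin, the + tag sits at the fragment
start and the - tag at its last base), so binned re-aggregation after
tag shifting recovers the NB marginals exactly — the HMM's assumptions
are literally true for this generator. A harsher per-bin Poisson mode
is available for robustness testing.

All randomness flows from a single mandatory seed; sub-streams are
derived by stable keyed splitting so adding one component does not shift
another's draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import SimulationError
from .genome import GenomeLayout
from .peaks import Peak
from .tags import TagCollection, write_tags_bed
from .tuning import MarkupLabel, write_markup

_SUB_TRUTH, _SUB_TREATMENT, _SUB_CONTROL, _SUB_LABELS = 0, 1, 2, 3


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic experiment.

    Defaults describe a 10 Mb genome at moderate sequencing depth
    (1 background tag per 200 bp bin, ~10x enrichment in peaks,
    150 bp fragments, 5% PCR duplicates).
    """

    seed: int
    chromosome_lengths: tuple[int, ...] = (2_500_000, 2_500_000, 2_500_000, 2_500_000)
    bin_size: int = 200
    n_peaks: int = 200
    peak_length: tuple[int, int] = (1000, 5000)
    background_rate: float = 1.0  # expected background tags per bin
    enrichment_fold: float = 10.0  # signal mean / background mean
    dispersion_background: float = 2.0
    dispersion_signal: float = 2.0
    fragment_length: int = 150
    read_length: int = 50
    duplicate_rate: float = 0.05
    with_control: bool = True
    per_bin_poisson: bool = False  # robustness mode: Poisson instead of NB counts
    layout: GenomeLayout = field(init=False)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SimulationError("seed is mandatory (no implicit entropy)")
        if self.background_rate <= 0:
            raise SimulationError("background_rate must be > 0")
        if self.enrichment_fold <= 1:
            raise SimulationError("enrichment_fold must be > 1")
        if self.dispersion_background <= 0 or self.dispersion_signal <= 0:
            raise SimulationError("dispersions must be > 0")
        if self.duplicate_rate < 0 or self.duplicate_rate >= 1:
            raise SimulationError("duplicate_rate must lie in [0, 1)")
        if self.peak_length[0] > self.peak_length[1] or self.peak_length[0] < 1:
            raise SimulationError("peak_length must be (min, max) with 1 <= min <= max")
        self.layout = GenomeLayout.from_pairs(
            (f"chr{i + 1}", l) for i, l in enumerate(self.chromosome_lengths)
        )

    def rng(self, key: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(entropy=self.seed, spawn_key=(key,)))


Truth = dict[str, list[tuple[int, int]]]


def plant_truth(config: SimulationConfig) -> Truth:
    """Sample disjoint enrichment intervals, >= 2 bins apart, per chromosome."""
    layout = config.layout
    if config.n_peaks * config.peak_length[1] >= 0.5 * layout.total_length:
        raise SimulationError("requested peak bases exceed 50% of the genome")
    rng = config.rng(_SUB_TRUTH)
    lengths = np.array([l for _, l in layout.chromosomes], dtype=np.float64)
    probs = lengths / lengths.sum()
    margin = 2 * config.bin_size
    truth: Truth = {c: [] for c in layout.names}
    for _ in range(config.n_peaks):
        for attempt in range(500):
            chrom = layout.names[int(rng.choice(len(probs), p=probs))]
            plen = int(rng.integers(config.peak_length[0], config.peak_length[1] + 1))
            clen = layout.length(chrom)
            if clen <= plen:
                continue
            start = int(rng.integers(0, clen - plen))
            end = start + plen
            if all(
                start >= e + margin or end + margin <= s for s, e in truth[chrom]
            ):
                truth[chrom].append((start, end))
                break
        else:
            raise SimulationError(
                "could not place a truth interval after 500 attempts; genome too crowded"
            )
    for c in truth:
        truth[c].sort()
    return truth


def truth_bin_mask(truth: Truth, config: SimulationConfig) -> dict[str, np.ndarray]:
    """Boolean per-bin mask of bins overlapping any truth interval."""
    masks = {}
    for chrom in config.layout.names:
        nb = config.layout.n_bins(chrom, config.bin_size)
        m = np.zeros(nb, dtype=bool)
        for s, e in truth.get(chrom, ()):
            m[s // config.bin_size : math.ceil(e / config.bin_size)] = True
        masks[chrom] = m
    return masks


def truth_peaks(truth: Truth) -> list[Peak]:
    """Interpret the planted intervals themselves as a peak list."""
    return [
        Peak(chrom, s, e, 0.0)
        for chrom in sorted(truth)
        for s, e in truth[chrom]
    ]


def _simulate_library(
    config: SimulationConfig, truth: Truth | None, rng: np.random.Generator
) -> TagCollection:
    bin_size = config.bin_size
    L = config.fragment_length
    half = L // 2
    masks = truth_bin_mask(truth, config) if truth else None
    out = {}
    for chrom in config.layout.names:
        clen = config.layout.length(chrom)
        nb = config.layout.n_bins(chrom, bin_size)
        mean = np.full(nb, config.background_rate)
        disp = np.full(nb, config.dispersion_background)
        if masks is not None:
            mean[masks[chrom]] *= config.enrichment_fold
            disp[masks[chrom]] = config.dispersion_signal
        if config.per_bin_poisson:
            counts = rng.poisson(mean)
        else:
            counts = rng.negative_binomial(disp, disp / (disp + mean))
        bin_idx = np.repeat(np.arange(nb), counts)
        n = len(bin_idx)
        width = np.where(bin_idx == nb - 1, clen - (nb - 1) * bin_size, bin_size)
        mid = bin_idx * bin_size + rng.integers(0, width)
        strand_minus = rng.integers(0, 2, n).astype(bool)
        frag_start = mid - half
        pos = np.where(strand_minus, frag_start + L - 1, frag_start)
        if config.duplicate_rate > 0:
            dup = rng.random(n) < config.duplicate_rate
            pos = np.concatenate([pos, pos[dup]])
            strand_minus = np.concatenate([strand_minus, strand_minus[dup]])
        pos = np.clip(pos, 0, clen - 1)
        out[chrom] = {"+": pos[~strand_minus], "-": pos[strand_minus]}
    return TagCollection(config.layout, out)


def simulate_tags(truth: Truth, config: SimulationConfig):
    """Draw the treatment library (and control, if configured) from the truth.

    Returns ``(treatment, control)``; ``control`` is ``None`` when
    ``config.with_control`` is false. The control library has background
    statistics everywhere.
    """
    treatment = _simulate_library(config, truth, config.rng(_SUB_TREATMENT))
    control = (
        _simulate_library(config, None, config.rng(_SUB_CONTROL))
        if config.with_control
        else None
    )
    return treatment, control


def _chrom_boundaries(truth: Truth, chrom: str) -> list[int]:
    return [b for s, e in truth.get(chrom, ()) for b in (s, e)]


def derive_labels(
    truth: Truth,
    config: SimulationConfig,
    n_per_kind: int | tuple[int, int, int, int] = 15,
    peaks_region_pad: int = 600,
) -> list[MarkupLabel]:
    """Generate markup labels of all four kinds from the planted truth.

    ``peaks`` labels are padded copies of sampled truth intervals;
    ``noPeaks`` labels are sampled from truth-free regions (with a safety
    margin); ``peakStart``/``peakEnd`` labels straddle sampled left/right
    truth boundaries and contain no other truth boundary. Every label is
    satisfied by the truth intervals interpreted as peaks.
    """
    if isinstance(n_per_kind, int):
        n_per_kind = (n_per_kind,) * 4
    n_peaks_lab, n_nopeaks, n_starts, n_ends = n_per_kind
    flat = [(c, s, e) for c in config.layout.names for s, e in truth.get(c, ())]
    if not flat and (n_peaks_lab or n_starts or n_ends):
        raise SimulationError("truth is empty; only noPeaks labels can be derived")
    rng = config.rng(_SUB_LABELS)
    pad = peaks_region_pad
    labels: list[MarkupLabel] = []

    def pick_interval():
        c, s, e = flat[int(rng.integers(0, len(flat)))]
        return c, s, e

    for _ in range(n_peaks_lab):
        c, s, e = pick_interval()
        clen = config.layout.length(c)
        labels.append(MarkupLabel(c, max(0, s - pad), min(clen, e + pad), "peaks"))

    margin = pad + 2 * config.bin_size
    lengths = np.array([l for _, l in config.layout.chromosomes], dtype=np.float64)
    probs = lengths / lengths.sum()
    win = 10 * config.bin_size
    for _ in range(n_nopeaks):
        for attempt in range(500):
            c = config.layout.names[int(rng.choice(len(probs), p=probs))]
            clen = config.layout.length(c)
            start = int(rng.integers(0, max(1, clen - win)))
            end = start + win
            if all(
                start >= e + margin or end + margin <= s
                for s, e in truth.get(c, ())
            ):
                labels.append(MarkupLabel(c, start, end, "noPeaks"))
                break
        else:
            raise SimulationError("could not place a noPeaks label after 500 attempts")

    for kind, n_lab in (("peakStart", n_starts), ("peakEnd", n_ends)):
        for _ in range(n_lab):
            for attempt in range(500):
                c, s, e = pick_interval()
                clen = config.layout.length(c)
                inner = min(pad, (e - s) // 2)
                if kind == "peakStart":
                    wl, wr = max(0, s - pad), s + inner
                    anchor = s
                else:
                    wl, wr = e - inner, min(clen, e + pad)
                    anchor = e
                if wl >= wr:
                    continue
                others = [b for b in _chrom_boundaries(truth, c) if b != anchor]
                if any(wl <= b <= wr for b in others):
                    continue
                labels.append(MarkupLabel(c, wl, wr, kind))
                break
            else:
                raise SimulationError(
                    f"could not place a {kind} label after 500 attempts"
                )
    return labels


def export_fixture(
    truth: Truth,
    treatment: TagCollection,
    control: TagCollection | None,
    labels: list[MarkupLabel],
    outdir: str | Path,
    config: SimulationConfig,
) -> dict[str, Path]:
    """Write a complete CLI-consumable dataset; byte-deterministic given seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "chrom_sizes": outdir / "chrom.sizes",
        "treatment": outdir / "treatment.bed.gz",
        "truth": outdir / "truth.bed",
        "labels": outdir / "labels.tsv",
    }
    config.layout.write_chrom_sizes(paths["chrom_sizes"])
    write_tags_bed(treatment, paths["treatment"], read_length=config.read_length)
    if control is not None:
        paths["control"] = outdir / "control.bed.gz"
        write_tags_bed(control, paths["control"], read_length=config.read_length)
    with open(paths["truth"], "w") as fh:
        i = 0
        for chrom in config.layout.names:
            for s, e in truth.get(chrom, ()):
                i += 1
                fh.write(f"{chrom}\t{s}\t{e}\ttruth_{i}\t0\t.\n")
    write_markup(labels, paths["labels"])
    return paths


def bin_level_f1(
    peaks: list[Peak], truth: Truth, config: SimulationConfig
) -> float:
    """F1 of called peak bins against planted truth bins (genome-wide)."""
    masks = truth_bin_mask(truth, config)
    called = {
        c: np.zeros(config.layout.n_bins(c, config.bin_size), dtype=bool)
        for c in config.layout.names
    }
    for p in peaks:
        m = called[p.chromosome]
        m[p.start // config.bin_size : math.ceil(p.end / config.bin_size)] = True
    tp = fp = fn = 0
    for c in config.layout.names:
        tp += int(np.sum(called[c] & masks[c]))
        fp += int(np.sum(called[c] & ~masks[c]))
        fn += int(np.sum(~called[c] & masks[c]))
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)
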