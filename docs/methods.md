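# Methods

## Preprocessing

Alignments (BAM via pysam, BED/BED.GZ via a line parser that reports
offending line numbers) are reduced to strand-aware 5′ tags: interval start
for `+` reads, `end − 1` for `-` reads, all coordinates 0-based half-open.
Unmapped, secondary and supplementary BAM records, and records on
chromosomes absent from the supplied chrom.sizes, are dropped and counted in
the log. Duplicate filtering keeps one tag per (chromosome, strand,
position) — single-end semantics; mate information is ignored.

Fragment size is estimated by strand cross-correlation: for each shift d in
[exclusion, max_shift] the Pearson correlation between the per-base `+`
tag-count vector and the `-` vector advanced by d, aggregated over
chromosomes with length-proportional weights, ties toward the smaller shift.
The computation is sparse (only tag-bearing positions enter the pair count;
the moments of the shifted vector are corrected exactly), so no dense
per-base vectors are allocated. Defaults: max_shift 500 bp; exclusion 50 bp,
which skips the read-length "phantom" correlation peak. Both are
overridable, and an explicit `--fragment` bypasses estimation entirely —
required when a strand has no tags. Tags are then shifted by
⌊fragment/2⌋ toward the fragment centre and counted into fixed
non-overlapping bins (default 200 bp; the last partial bin is kept, its
shorter width ignored by the emission model — a known approximation).

With a control track, the control is scaled by s = min(1, T/C) (never up),
and each treatment bin becomes max(0, t − round(s·c)) with
round-half-to-even. Clipping at zero keeps counts in valid NB support;
signed residuals were rejected because the emission model is a count
distribution.

## The coverage HMM

States ZERO / NOISE / SIGNAL over per-bin counts. ZERO is a point mass at
count 0 (so any positive count has zero ZERO-posterior — an assertable
fact); NOISE and SIGNAL are negative binomial with mean m and dispersion r,
variance m + m²/r. Identifiability is enforced by the ordering
m_noise < m_signal, restored after every M-step by relabeling (a
likelihood-invariant operation).

Initialisation is deterministic (no RNG anywhere in fitting): noise mean =
mean of positive counts at or below their median; signal mean = mean of the
top 2% of all counts, forced ≥ 2× the noise mean; dispersions by method of
moments on the same subsets (floor 1e-2, and near-Poisson 1e4 when the
subset is under-dispersed); initial distribution uniform; transition 0.8 on
the diagonal.

Fitting is Baum–Welch EM with chromosomes as independent chains sharing
parameters; expected sufficient statistics are summed across chains in
chromosome order (hence independent of the worker thread count). Initial and
transition probabilities update in closed form; NB means as
posterior-weighted count means; each dispersion by bounded scalar
maximisation of the expected complete-data log-likelihood on
log r ∈ [log 1e-3, log 1e6] (no closed form exists), keeping the previous
value if the optimiser fails to improve it. Forward–backward runs in scaled
linear space after shifting each emission row by its log-space maximum, so
megabase chains cannot underflow; posteriors are renormalised against
floating-point drift. Convergence: relative log-likelihood change < 1e-6 or
50 iterations (both overridable). The trace is recorded; a decrease beyond
tolerance raises an error — EM monotonicity is treated as a bug sentinel,
not a warning.

Per-bin p-value = posterior(ZERO) + posterior(NOISE) — a posterior error
probability, not a frequentist tail probability; no separate null is
computed. q-values are Benjamini–Hochberg step-up over **all genome-wide
bins jointly**; per-chromosome adjustment was rejected because q-values
would then depend on the chromosome partition.

Models serialise to a versioned JSON container; reals round-trip exactly
(well within the 1e-12 contract) and wrong magic/version/corrupt files are
rejected with the expected version named.

## Peak calling

Enriched bins have q ≤ FDR. Two enriched bins i < j merge into one peak iff
j − i − 1 ≤ gap; the gap is counted in **bins**, not bases, so tuning grids
stay integer and bin-size independent. Swallowed non-enriched bins lie
inside the peak's coordinates but are excluded from the score: the BED score
is round(min(1000, 10·(−log10 q_min))) over member bins — a BED
compatibility convention. gap = ∞ is accepted as a sentinel (one peak per
chromosome with any enriched bin).

## Markup semantics and tuning

`peaks`: ≥ 1 peak intersects [start, end). `noPeaks`: none does.
`peakStart`: exactly one peak start in [start, end). `peakEnd`: exactly one
half-open peak end in (start, end] — tested on the open-left/closed-right
window so a peak ending exactly at the label start does not count,
symmetric with `peakStart`. "Single boundary" is read as exactly-one, not
at-least-one.

Tuning is an exhaustive grid evaluation; defaults
FDR ∈ {0.1, 0.05, 1e-2, 1e-3, 1e-4, 1e-6, 1e-8, 1e-10},
gap ∈ {0, 1, 2, 3, 5, 10, 20, 50}, spanning liberal-to-stringent and
narrow-to-broad regimes. Ties break toward smaller FDR then smaller gap —
the most stringent equivalent solution; this changes outputs and is
therefore stated prominently. The score-threshold tuner for external scored
peak lists enumerates the distinct observed scores and breaks ties toward
the smallest threshold (retaining the most peaks).

## The simulator

The generator emulates the data regime the model assumes: per-bin NB counts
(background mean 1 tag/bin; 10× enrichment inside planted intervals;
dispersion 2 in both regimes), 200 disjoint 1–5 kb intervals ≥ 2 bins apart
on a 4 × 2.5 Mb genome, 150 bp fragments, 5% PCR duplicates, an optional
control with background statistics everywhere, and markup labels derived
from the truth (boundary labels straddle truth boundaries with a 600 bp pad
and contain no other boundary). Each read carries one strand, chosen
uniformly; the fragment **midpoint** is anchored uniformly in its bin (tags
at mid − ⌊L/2⌋ on `+`, that + L − 1 on `-`), so after half-fragment shifting
the binned counts reproduce the drawn NB marginals exactly — the HMM's
assumptions are literally true, which is what makes clean parameter-recovery
and truth-recovery regimes possible. A per-bin Poisson mode exists for
robustness testing. Randomness comes from one mandatory seed with keyed
sub-streams (truth/treatment/control/labels), so fixtures are
byte-reproducible and adding a component does not shift another's draws.

What the generator does **not** emulate: GC and mappability bias, blacklist
artifact regions, copy-number variation, fragment-length variance, paired
ends. Passing tests therefore demonstrate correctness of the algorithms
under the model's own assumptions and graceful behaviour under NB noise —
not calibration on real chromatin.

One consequence of the single-strand-per-read design: `+` and `-` tag
positions are independent draws, so the strand cross-correlation peak is
triangular with ~2-bin width rather than a spike, and the fragment-size
argmax scatters by tens of bp at default depth (the estimator is exact; the
data are diffuse). The estimator's sharpness is therefore verified on a
paired-tag fixture, and its behaviour on simulator output at a tolerance
matching the triangular geometry.

## Problem sizes and verification

The shipped studies use 10 Mb genomes (50k bins), ten fixtures per
end-to-end run, 10 × 10k-bin chains for parameter recovery, and exhaustive
3^T path enumeration (T ≤ 8) as the decoding oracle — sizes at which the
oracles are exact and a full study runs in seconds on one core. Measured at
these conditions: aggregate label satisfaction ≈ 96% across ten fixtures
(individual fixtures 92–98%: an enriched edge bin drawing a low NB count can
truncate a called boundary by a bin, costing a `peakStart`/`peakEnd` label),
bin-level F1 vs planted truth ≥ 0.83 on every fixture, and median relative
error of refitted NB means < 1%. BH agrees with an independent reference
implementation; the tuner equals an independently coded brute force by
construction and by test.

## Known limitations

Single-end semantics throughout; no mapping-quality or blacklist filtering;
no GC/mappability correction; no differential (two-condition) calling; no
summit refinement below bin resolution; the posterior-error "p-values" are
not comparable across samples with different model fits — which is exactly
why the markup calibration exists.
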