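"""Score-threshold calibration for an externally called peak list.

Peaks from another caller (MACS2/SICER-style scored BED) are filtered by
the score threshold that minimises the number of unsatisfied markup
labels — no re-calling involved.
"""

import spanpeaks as sp

# three peaks of decreasing score, as another caller might report them
peaks = [
    sp.Peak("chr1", 0, 500, score=10.0),
    sp.Peak("chr1", 1_000, 1_500, score=5.0),
    sp.Peak("chr1", 2_000, 2_500, score=2.0),
]
# the user's markup: the first region must hold a peak, the last must not
labels = [
    sp.MarkupLabel("chr1", 100, 400, "peaks"),
    sp.MarkupLabel("chr1", 2_100, 2_400, "noPeaks"),
]

threshold, filtered, result = sp.tune_score_threshold(peaks, labels)
print(f"selected threshold: {threshold:g} "
      f"({result.best_errors} unsatisfied labels, {len(filtered)} peaks kept)")
for thr, errors, _ in result.grid:
    print(f"  threshold {thr:>4g}: {errors} label errors")
# Thresholds 5 and 10 both satisfy the markup; ties break toward the
# smallest threshold so the most peaks are retained.
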