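"""Shared helpers: tiny genomes, score containers, and independent oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from spanpeaks import BinScores, GenomeLayout, NegBinParams, SpanModel, TagCollection


def make_layout(*pairs) -> GenomeLayout:
    return GenomeLayout.from_pairs(pairs)


def make_tags(layout, tags) -> TagCollection:
    """Build a TagCollection from (chrom, pos, strand) tuples."""
    return TagCollection.from_tags(layout, tags)


def make_scores(layout, bin_size, qvalues: dict[str, list[float]]) -> BinScores:
    """BinScores with given q-values (posterior/pvalue mirrors q for simplicity)."""
    q = {c: np.asarray(v, dtype=np.float64) for c, v in qvalues.items()}
    for c in layout.names:
        q.setdefault(c, np.zeros(0))
        expected = layout.n_bins(c, bin_size)
        assert len(q[c]) == expected, f"{c}: want {expected} q-values, got {len(q[c])}"
    p = {c: v.copy() for c, v in q.items()}
    post = {c: np.column_stack([v / 2, v / 2, 1 - v]) for c, v in q.items()}
    return BinScores(layout, bin_size, post, p, q)


def random_model(rng, bin_size=200) -> SpanModel:
    """Random valid 3-state model for decoding tests."""
    initial = rng.dirichlet(np.ones(3))
    transition = rng.dirichlet(np.ones(3), size=3)
    noise_mean = rng.uniform(0.5, 5.0)
    signal_mean = noise_mean * rng.uniform(2.0, 10.0)
    m = SpanModel(
        bin_size=bin_size,
        fragment_size=0,
        initial=initial,
        transition=transition,
        noise=NegBinParams(noise_mean, rng.uniform(0.1, 10.0)),
        signal=NegBinParams(signal_mean, rng.uniform(0.1, 10.0)),
    )
    return m


def enumerate_posteriors(initial, transition, log_emission):
    """Exhaustive-path posterior oracle: sums over all K^T state paths.

    Independent of the forward-backward implementation; only usable for
    tiny T. Returns (posterior matrix, log-likelihood).
    """
    T, K = log_emission.shape
    post = np.zeros((T, K))
    total = 0.0
    for path in itertools.product(range(K), repeat=T):
        logp = np.log(initial[path[0]]) + log_emission[0, path[0]]
        for t in range(1, T):
            logp += np.log(transition[path[t - 1], path[t]]) + log_emission[t, path[t]]
        p = np.exp(logp)
        total += p
        for t, k in enumerate(path):
            post[t, k] += p
    return post / total, np.log(total)


@pytest.fixture
def rng():
    return np.random.default_rng(20241001)
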