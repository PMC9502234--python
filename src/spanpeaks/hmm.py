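"""Three-state HMM over binned ChIP-seq coverage.

The model separates genome bins into ZERO (empty), NOISE (background
coverage) and SIGNAL (enriched coverage) states. The ZERO state emits
count 0 with probability 1; NOISE and SIGNAL emit negative-binomial
counts parameterised by mean m and dispersion r (variance m + m^2/r),
which lets a single model family absorb experiments with arbitrary
signal-to-noise ratio. Parameters are fitted by Baum-Welch EM with
chromosomes as independent chains sharing parameters. The per-bin
"p-value" is the posterior probability of not being in the SIGNAL state
(a posterior error probability); q-values are Benjamini-Hochberg
adjusted over all genome-wide bins jointly.

All decoding runs in scaled linear space after a per-position log-space
shift of the emission row, so megabase chains neither under- nor
overflow. Model initialisation is quantile-based and deterministic; no
randomness enters this module.
"""

from __future__ import annotations

import json
import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import nbinom

from .coverage import BinnedCoverage
from .errors import ModelError
from .genome import GenomeLayout

ZERO, NOISE, SIGNAL = 0, 1, 2
STATE_NAMES = ("ZERO", "NOISE", "SIGNAL")

MODEL_FORMAT = "spanpeaks.model"
MODEL_VERSION = 1

DISPERSION_FLOOR = 1e-2
_LOG_DISP_LO, _LOG_DISP_HI = math.log(1e-3), math.log(1e6)


@dataclass
class NegBinParams:
    """Negative binomial in (mean, dispersion) form; variance = m + m^2/r."""

    mean: float
    dispersion: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mean) and self.mean > 0):
            raise ModelError(f"NB mean must be finite and > 0, got {self.mean}")
        if not (np.isfinite(self.dispersion) and self.dispersion > 0):
            raise ModelError(f"NB dispersion must be finite and > 0, got {self.dispersion}")

    @property
    def _p(self) -> float:
        # scipy's success probability for (n=r, mean m)
        return self.dispersion / (self.dispersion + self.mean)

    def logpmf(self, counts: np.ndarray) -> np.ndarray:
        return nbinom.logpmf(counts, self.dispersion, self._p)


@dataclass
class SpanModel:
    """Full parameter set of the 3-state coverage HMM.

    ``fit_log`` records the log-likelihood at the start of every EM
    iteration plus the final value; it is empty for an unfitted model.
    """

    bin_size: int
    fragment_size: int
    initial: np.ndarray
    transition: np.ndarray
    noise: NegBinParams
    signal: NegBinParams
    fit_log: list = field(default_factory=list)

    def validate(self) -> None:
        if abs(self.initial.sum() - 1.0) > 1e-9:
            raise ModelError("initial distribution does not sum to 1")
        if np.any(np.abs(self.transition.sum(axis=1) - 1.0) > 1e-9):
            raise ModelError("transition matrix rows do not sum to 1")
        if not self.noise.mean < self.signal.mean:
            raise ModelError("state ordering violated: noise.mean must be < signal.mean")

    @property
    def fitted(self) -> bool:
        return len(self.fit_log) > 0

    def copy(self) -> "SpanModel":
        return SpanModel(
            self.bin_size,
            self.fragment_size,
            self.initial.copy(),
            self.transition.copy(),
            NegBinParams(self.noise.mean, self.noise.dispersion),
            NegBinParams(self.signal.mean, self.signal.dispersion),
            list(self.fit_log),
        )


@dataclass
class BinScores:
    """Per-bin posteriors, p-values and genome-wide BH q-values."""

    layout: GenomeLayout
    bin_size: int
    posterior: dict[str, np.ndarray]
    pvalue: dict[str, np.ndarray]
    qvalue: dict[str, np.ndarray]


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------


def _moment_dispersion(x: np.ndarray, mean: float) -> float:
    """Method-of-moments dispersion r = m^2 / (var - m), floored and capped."""
    var = float(np.var(x)) if len(x) > 1 else 0.0
    if var > mean:
        r = mean**2 / (var - mean)
    else:
        r = 1e4  # under-dispersed sample: near-Poisson
    return float(min(max(r, DISPERSION_FLOOR), 1e6))


def initialize_model(
    coverage: BinnedCoverage, fragment_size: int = 0
) -> SpanModel:
    """Deterministic quantile-based starting point for EM.

    The noise mean is the mean of positive counts at or below their
    median; the signal mean is the mean of the top 2% of all counts,
    forced to at least twice the noise mean. Dispersions come from the
    method of moments on the same subsets.
    """
    counts = np.concatenate([coverage.counts[c] for c in coverage.layout.names])
    positive = counts[counts > 0]
    if len(positive) == 0:
        raise ModelError("no signal to model: coverage is all zero")
    med = np.median(positive)
    low = positive[positive <= med]
    noise_mean = float(low.mean())
    k = max(1, math.ceil(0.02 * len(counts)))
    top = np.sort(counts)[-k:]
    signal_mean = max(float(top.mean()), 2.0 * noise_mean)
    initial = np.full(3, 1.0 / 3.0)
    transition = np.full((3, 3), 0.1) + np.eye(3) * 0.7
    return SpanModel(
        bin_size=coverage.bin_size,
        fragment_size=fragment_size,
        initial=initial,
        transition=transition,
        noise=NegBinParams(noise_mean, _moment_dispersion(low, noise_mean)),
        signal=NegBinParams(signal_mean, _moment_dispersion(top, signal_mean)),
    )


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------


def _log_emission(model: SpanModel, counts: np.ndarray) -> np.ndarray:
    """(T, 3) emission log-likelihood matrix, computed on unique counts."""
    u, inv = np.unique(counts, return_inverse=True)
    logB_u = np.empty((len(u), 3))
    logB_u[:, ZERO] = np.where(u == 0, 0.0, -np.inf)
    for k, params in ((NOISE, model.noise), (SIGNAL, model.signal)):
        col = params.logpmf(u)
        if np.any(np.isnan(col)):
            raise ModelError(
                f"non-finite emission probability in state {STATE_NAMES[k]} "
                f"(mean={params.mean}, dispersion={params.dispersion})"
            )
        logB_u[:, k] = col
    return logB_u[inv]


def forward_backward(model: SpanModel, chain: np.ndarray):
    """Posterior decode one chromosome's count vector.

    Returns ``(posterior, log_likelihood)`` where ``posterior`` is a
    (T, 3) matrix whose rows sum to 1.
    """
    gamma, _, ll = _forward_backward_full(model, np.asarray(chain, dtype=np.int64))
    return gamma, ll


def _forward_backward_full(model: SpanModel, chain: np.ndarray):
    from ._kernels import forward_backward_kernel

    if len(chain) < 1:
        raise ModelError("chain must contain at least one bin")
    logB = _log_emission(model, chain)
    offsets = logB.max(axis=1)
    B = np.exp(logB - offsets[:, None])
    gamma, xi_sum, log_c = forward_backward_kernel(
        np.ascontiguousarray(model.initial, dtype=np.float64),
        np.ascontiguousarray(model.transition, dtype=np.float64),
        np.ascontiguousarray(B, dtype=np.float64),
    )
    ll = float(log_c + offsets.sum())
    if not np.isfinite(ll):
        raise ModelError("non-finite log-likelihood in forward-backward")
    return gamma, xi_sum, ll


# ---------------------------------------------------------------------------
# Baum-Welch
# ---------------------------------------------------------------------------


def _e_step(model: SpanModel, chains: list[np.ndarray], threads: int):
    """Expected sufficient statistics pooled over chains (deterministic order)."""
    if threads > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            results = list(pool.map(lambda ch: _forward_backward_full(model, ch), chains))
    else:
        results = [_forward_backward_full(model, ch) for ch in chains]

    cmax = max(int(ch.max()) for ch in chains)
    init_acc = np.zeros(3)
    xi_acc = np.zeros((3, 3))
    w_counts = np.zeros((3, cmax + 1))  # posterior mass per state per count value
    ll_total = 0.0
    for ch, (gamma, xi_sum, ll) in zip(chains, results):
        init_acc += gamma[0]
        xi_acc += xi_sum
        for k in (NOISE, SIGNAL):
            w_counts[k] += np.bincount(ch, weights=gamma[:, k], minlength=cmax + 1)
        ll_total += ll
    return init_acc, xi_acc, w_counts, ll_total


def _optimize_dispersion(w: np.ndarray, mean: float, current: float) -> float:
    """M-step for one NB dispersion: bounded 1-D maximisation on log r.

    Maximises the expected complete-data log-likelihood
    ``sum_c w[c] * log NB(c; mean, r)`` over ``log r`` in
    [log 1e-3, log 1e6]; ``w`` holds posterior weight per count value.
    """
    support = np.nonzero(w)[0]
    weights = w[support]

    def neg(logr: float) -> float:
        r = math.exp(logr)
        return -float(np.sum(weights * nbinom.logpmf(support, r, r / (r + mean))))

    res = minimize_scalar(neg, bounds=(_LOG_DISP_LO, _LOG_DISP_HI), method="bounded")
    best = math.exp(res.x)
    # keep the previous value if the optimiser failed to improve on it
    if neg(math.log(min(max(current, math.exp(_LOG_DISP_LO)), math.exp(_LOG_DISP_HI)))) < res.fun:
        best = current
    return float(best)


def _m_step(model: SpanModel, init_acc, xi_acc, w_counts) -> None:
    model.initial = init_acc / init_acc.sum()
    A = xi_acc.copy()
    rowsum = A.sum(axis=1, keepdims=True)
    for i in range(3):
        if rowsum[i, 0] > 0:
            A[i] /= rowsum[i, 0]
        else:
            A[i] = model.transition[i]  # state never left: keep previous row
    model.transition = A

    values = np.arange(w_counts.shape[1])
    for k, attr in ((NOISE, "noise"), (SIGNAL, "signal")):
        w = w_counts[k]
        total = w.sum()
        params: NegBinParams = getattr(model, attr)
        if total < 1e-12:
            continue  # state carries no posterior mass: keep previous params
        mean = max(float((w * values).sum() / total), 1e-8)
        disp = _optimize_dispersion(w, mean, params.dispersion)
        setattr(model, attr, NegBinParams(mean, disp))

    if model.noise.mean > model.signal.mean:
        _swap_states(model)


def _swap_states(model: SpanModel) -> None:
    """Relabel NOISE<->SIGNAL to restore the mean ordering (likelihood-invariant)."""
    model.noise, model.signal = model.signal, model.noise
    perm = [ZERO, SIGNAL, NOISE]
    model.initial = model.initial[perm]
    model.transition = model.transition[np.ix_(perm, perm)]


def baum_welch_fit(
    model: SpanModel,
    coverage: BinnedCoverage,
    tol: float = 1e-6,
    max_iter: int = 50,
    threads: int = 1,
) -> SpanModel:
    """Fit the HMM by EM over all chromosomes as independent chains.

    Transition and initial probabilities update in closed form; NB means
    are posterior-weighted count means; dispersions are updated by
    bounded 1-D maximisation on the log scale. Iteration stops when the
    relative log-likelihood improvement drops below ``tol`` or after
    ``max_iter`` EM steps. The log-likelihood trace is stored in
    ``fit_log`` and must be non-decreasing; a decrease raises
    :class:`ModelError` (an EM-implementation bug sentinel).
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if coverage.n_bins == 0:
        raise ModelError("empty coverage")
    chains = [
        np.ascontiguousarray(coverage.counts[c], dtype=np.int64)
        for c in coverage.layout.names
        if len(coverage.counts[c]) > 0
    ]
    model = model.copy()
    model.fit_log = []
    prev = None
    converged = False
    for _ in range(max_iter):
        init_acc, xi_acc, w_counts, ll = _e_step(model, chains, threads)
        _check_monotone(prev, ll)
        model.fit_log.append(ll)
        if prev is not None and abs(ll - prev) <= tol * abs(prev):
            converged = True
            break
        prev = ll
        _m_step(model, init_acc, xi_acc, w_counts)
    if not converged:
        # record the likelihood of the final parameter set
        *_, ll = _e_step(model, chains, threads)
        _check_monotone(prev, ll)
        model.fit_log.append(ll)
    model.validate()
    return model


def _check_monotone(prev, ll) -> None:
    if prev is not None and ll < prev - max(abs(prev) * 1e-6, 1e-8):
        raise ModelError(
            f"EM log-likelihood decreased from {prev:.6f} to {ll:.6f}"
        )


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    ``q_(i) = min_{j >= i} p_(j) * n / j`` capped at 1, mapped back to the
    input order; ties are handled stably.
    """
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def compute_scores(
    model: SpanModel, coverage: BinnedCoverage, threads: int = 1
) -> BinScores:
    """Posterior-decode every chromosome and attach p- and q-values.

    The p-value of a bin is the posterior probability of the ZERO or
    NOISE state (1 minus the SIGNAL posterior); q-values are BH-adjusted
    jointly over all genome-wide bins so they do not depend on how the
    genome is partitioned into chromosomes.
    """
    if not model.fitted:
        raise ModelError("model must be fitted before scoring (empty fit_log)")
    if model.bin_size != coverage.bin_size:
        raise ModelError(
            f"model bin size {model.bin_size} != coverage bin size {coverage.bin_size}"
        )
    chroms = [c for c in coverage.layout.names if len(coverage.counts[c]) > 0]

    def decode(chrom):
        gamma, _ = forward_backward(model, coverage.counts[chrom])
        return gamma

    if threads > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            gammas = dict(zip(chroms, pool.map(decode, chroms)))
    else:
        gammas = {c: decode(c) for c in chroms}

    posterior, pvalue = {}, {}
    for c in coverage.layout.names:
        g = gammas.get(c, np.zeros((0, 3)))
        posterior[c] = g
        pvalue[c] = np.clip(g[:, ZERO] + g[:, NOISE], 0.0, 1.0)
    flat = np.concatenate([pvalue[c] for c in coverage.layout.names])
    qflat = bh_adjust(flat)
    qvalue = {}
    offset = 0
    for c in coverage.layout.names:
        n = len(pvalue[c])
        qvalue[c] = qflat[offset : offset + n]
        offset += n
    return BinScores(coverage.layout, coverage.bin_size, posterior, pvalue, qvalue)


def sample_counts(
    model: SpanModel, chain_lengths: list[int], seed: int
) -> dict[str, np.ndarray]:
    """Sample per-bin counts from the generative model (one chain per entry).

    Used for parameter-recovery studies: data drawn here has the HMM's
    assumptions exactly true, so refitting should recover the generating
    parameters. Returns ``{"chain_i": counts}`` keyed in order.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for i, T in enumerate(chain_lengths):
        states = np.empty(T, dtype=np.int64)
        states[0] = rng.choice(3, p=model.initial)
        for t in range(1, T):
            states[t] = rng.choice(3, p=model.transition[states[t - 1]])
        counts = np.zeros(T, dtype=np.int64)
        for k, params in ((NOISE, model.noise), (SIGNAL, model.signal)):
            mask = states == k
            n = int(mask.sum())
            if n:
                counts[mask] = rng.negative_binomial(
                    params.dispersion, params._p, size=n
                )
        out[f"chain_{i}"] = counts
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_model(model: SpanModel, path: str | Path) -> None:
    """Write the model as a versioned JSON container (1e-12 numeric round-trip)."""
    doc = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "bin_size": model.bin_size,
        "fragment_size": model.fragment_size,
        "initial": model.initial.tolist(),
        "transition": model.transition.tolist(),
        "noise": {"mean": model.noise.mean, "dispersion": model.noise.dispersion},
        "signal": {"mean": model.signal.mean, "dispersion": model.signal.dispersion},
        "fit_log": list(map(float, model.fit_log)),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def load_model(path: str | Path) -> SpanModel:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelError(
            f"{path}: corrupt model file (expected {MODEL_FORMAT} version {MODEL_VERSION})"
        ) from exc
    if not isinstance(doc, dict) or doc.get("format") != MODEL_FORMAT:
        raise ModelError(
            f"{path}: not a model file (expected {MODEL_FORMAT} version {MODEL_VERSION})"
        )
    if doc.get("version") != MODEL_VERSION:
        raise ModelError(
            f"{path}: unsupported model version {doc.get('version')} "
            f"(expected {MODEL_VERSION})"
        )
    return SpanModel(
        bin_size=int(doc["bin_size"]),
        fragment_size=int(doc["fragment_size"]),
        initial=np.asarray(doc["initial"], dtype=np.float64),
        transition=np.asarray(doc["transition"], dtype=np.float64),
        noise=NegBinParams(**doc["noise"]),
        signal=NegBinParams(**doc["signal"]),
        fit_log=list(doc["fit_log"]),
    )
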