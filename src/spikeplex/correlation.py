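"""Directed pairwise dependency measures on binned spike trains.

Two model-free measures are provided, each evaluated over a grid of delays
with the maximum (and its arg-max) reported per ordered neuron pair:

* **Higher-order transfer entropy (TE)** -- the plug-in estimate of

  ``TE_{j->i}(d) = sum p(i_{t+1}, i_t^(k), j_{t+1-d}^(l))
                   log2[ p(i_{t+1} | i_t^(k), j_{t+1-d}^(l))
                         / p(i_{t+1} | i_t^(k)) ]``

  with spiking-history words of fixed orders ``k`` (target) and ``l``
  (source) and delay ``d`` in bins. Probabilities are empirical word
  frequencies (no smoothing); ``0 log 0`` terms contribute 0. The plug-in
  estimate is a conditional mutual information of the empirical
  distribution and therefore non-negative.

* **Gaussian-convolution correlation (CC)** -- each binary train is
  convolved with a normalised Gaussian kernel (standard deviation
  ``sigma``, interpreted in seconds on a 1 ms sampling grid) to obtain a
  continuous firing-rate signal; the delayed Pearson coefficient between
  target and source signals is evaluated over the delay grid with
  overlap truncation (no wraparound).

Matrix convention: ``values[i, j]`` holds the dependency of the ordered
pair ``j -> i`` (source along columns), matching the structural adjacency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.signal import fftconvolve

logger = logging.getLogger(__name__)

__all__ = [
    "TEParams",
    "CCParams",
    "CorrelationMatrix",
    "transfer_entropy",
    "hote_max",
    "gaussian_convolve",
    "delayed_pearson",
    "correlation_matrix",
]


@dataclass
class TEParams:
    """History orders ``k`` (target), ``l`` (source) and inclusive delay
    range 0..``d_max`` ms (1 ms bins)."""

    k: int = 5
    l: int = 5
    d_max: int = 30


@dataclass
class CCParams:
    """Kernel width ``sigma`` (seconds) and inclusive delay grid
    ``d_min``..``d_max`` ms. The kernel is truncated at ±4 sigma."""

    sigma: float = 0.2
    d_min: int = 1
    d_max: int = 30
    dt_sample: float = 0.001


@dataclass
class CorrelationMatrix:
    """Max-over-delay dependency per ordered pair.

    ``values[i, j]`` is the ``j -> i`` dependency (TE in bits, >= 0, or CC
    in [-1, 1]); undefined CC entries (zero variance at every delay) are
    NaN. ``best_delay[i, j]`` is the maximising delay in ms (smallest on
    ties). Diagonal entries are zero.
    """

    values: np.ndarray
    best_delay: np.ndarray
    method: str
    params: TEParams | CCParams = field(default=None)  # type: ignore[assignment]

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]


def _validate_pair(s_i: np.ndarray, s_j: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s_i = np.ascontiguousarray(np.asarray(s_i, dtype=np.uint8))
    s_j = np.ascontiguousarray(np.asarray(s_j, dtype=np.uint8))
    if s_i.shape != s_j.shape or s_i.ndim != 1:
        raise ValueError("spike trains must be 1-D and of equal length")
    return s_i, s_j


def _word_codes(s: np.ndarray, order: int) -> np.ndarray:
    """``codes[t] = sum_m s[t-m] 2^m`` (valid for ``t >= order-1``)."""
    kernel = (1 << np.arange(order)).astype(np.int64)
    return np.convolve(s.astype(np.int64), kernel)[: len(s)]


def _te_from_counts(counts: np.ndarray) -> float:
    """Plug-in TE (bits) from a joint count array of shape (2, K, L)."""
    n_total = counts.sum()
    if n_total == 0:
        return 0.0
    c_b = counts.sum(axis=(0, 2))  # (K,)
    c_bg = counts.sum(axis=0)  # (K, L)
    c_ab = counts.sum(axis=2)  # (2, K)
    a_idx, b_idx, g_idx = np.nonzero(counts)
    c = counts[a_idx, b_idx, g_idx].astype(float)
    ratio = c * c_b[b_idx] / (c_bg[b_idx, g_idx] * c_ab[a_idx, b_idx])
    return float(np.sum(c * np.log2(ratio)) / n_total)


def transfer_entropy(s_i, s_j, k: int = 5, l: int = 5, d: int = 0) -> float:
    """Higher-order transfer entropy from source ``s_j`` to target ``s_i`` (bits)."""
    s_i, s_j = _validate_pair(s_i, s_j)
    if k < 1 or l < 1 or d < 0:
        raise ValueError("orders must be >= 1 and delay >= 0")
    t_len = len(s_i)
    t_lo = max(k - 1, d + l - 2, 0)
    if t_len - 1 <= t_lo:
        raise ValueError("trains too short for the requested (k, l, d)")
    ts = np.arange(t_lo, t_len - 1)
    iw = _word_codes(s_i, k)
    jw = _word_codes(s_j, l)
    codes = (
        s_i[ts + 1].astype(np.int64) * (1 << (k + l))
        + iw[ts] * (1 << l)
        + jw[ts + 1 - d]
    )
    counts = np.bincount(codes, minlength=1 << (k + l + 1))
    return _te_from_counts(counts.reshape(2, 1 << k, 1 << l))


def hote_max(s_i, s_j, k: int = 5, l: int = 5, d_max: int = 30) -> tuple[float, int]:
    """Maximum TE over delays 0..``d_max`` and its arg-max (smallest on ties)."""
    if d_max < 0:
        raise ValueError("d_max must be >= 0")
    best, best_d = -1.0, 0
    for d in range(d_max + 1):
        te = transfer_entropy(s_i, s_j, k=k, l=l, d=d)
        if te > best:
            best, best_d = te, d
    return best, best_d


def gaussian_convolve(s, sigma: float = 0.2, dt_sample: float = 0.001) -> np.ndarray:
    """Convolve a binned train with a normalised Gaussian kernel.

    ``sigma`` and ``dt_sample`` are in seconds (1 ms sampling by default).
    The kernel is truncated at ±4 sigma; the output has the input's length
    ("same" alignment), with amplitudes on a rate-like 1/s scale so that
    ``sum(output) * dt_sample`` approximates the spike count.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    s = np.asarray(s, dtype=float)
    radius = int(np.ceil(4.0 * sigma / dt_sample))
    t = np.arange(-radius, radius + 1) * dt_sample
    kernel = np.exp(-0.5 * (t / sigma) ** 2) / (sigma * np.sqrt(2.0 * np.pi))
    return fftconvolve(s, kernel, mode="same")


def delayed_pearson(x_i, x_j, d: int) -> float:
    """Pearson coefficient between ``x_i[t]`` and ``x_j[t-d]`` on the overlap.

    Overlap truncation: ``t`` runs over ``d .. n-1``. Returns NaN when
    either signal is constant on the overlap (undefined marker).
    """
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    if x_i.shape != x_j.shape or x_i.ndim != 1:
        raise ValueError("signals must be 1-D and of equal length")
    if d < 0 or d >= len(x_i) - 1:
        raise ValueError("delay out of range")
    a = x_i[d:]
    b = x_j[: len(x_j) - d] if d > 0 else x_j
    sa = a.std()
    sb = b.std()
    if sa == 0.0 or sb == 0.0:
        return float("nan")
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


# ---------------------------------------------------------------------------
# fast all-pairs kernels


@njit(cache=True)
def _te_pair_delays(base_i, nz_i, jw, nz_j, t_len, k, l, d_max, hist):
    """Max-over-delay plug-in TE for one ordered pair, exploiting sparsity.

    ``base_i[t] = i_{t+1} * 2^(k+l) + iword(t) * 2^l`` and ``jw[t]`` is the
    source word code; only time bins where either code is non-zero are
    visited, the all-zero cell being recovered from the total count.
    """
    big_k = 1 << k
    big_l = 1 << l
    m_cells = 2 * big_k * big_l
    best = -1.0
    best_d = 0
    cb = np.zeros(big_k)
    cbg = np.zeros(big_k * big_l)
    cab = np.zeros(2 * big_k)
    for d in range(d_max + 1):
        t_lo = max(k - 1, d + l - 2)
        if t_lo < 0:
            t_lo = 0
        t_hi = t_len - 2  # inclusive
        if t_hi <= t_lo:
            continue
        n_total = t_hi - t_lo + 1
        # merge the two sorted non-zero index lists into hist
        cnt = 0
        pa = 0
        na = nz_i.shape[0]
        while pa < na and nz_i[pa] < t_lo:
            pa += 1
        pb = 0
        nb = nz_j.shape[0]
        # source word at time t is jw[t + 1 - d]; non-zero source positions
        # p = t + 1 - d map to t = p + d - 1
        while pb < nb and nz_j[pb] + d - 1 < t_lo:
            pb += 1
        while True:
            ta = nz_i[pa] if pa < na else t_len
            tb = nz_j[pb] + d - 1 if pb < nb else t_len
            t = ta if ta < tb else tb
            if t > t_hi:
                break
            if ta == t:
                pa += 1
            if tb == t:
                pb += 1
            code = base_i[t] + jw[t + 1 - d]
            hist[code] += 1
            cnt += 1
        hist[0] += n_total - cnt
        # marginals
        for x in range(big_k):
            cb[x] = 0.0
        for x in range(big_k * big_l):
            cbg[x] = 0.0
        for x in range(2 * big_k):
            cab[x] = 0.0
        for a in range(2):
            for b in range(big_k):
                row = a * big_k * big_l + b * big_l
                for g in range(big_l):
                    c = hist[row + g]
                    if c > 0:
                        cb[b] += c
                        cbg[b * big_l + g] += c
                        cab[a * big_k + b] += c
        te = 0.0
        for a in range(2):
            for b in range(big_k):
                row = a * big_k * big_l + b * big_l
                for g in range(big_l):
                    c = hist[row + g]
                    if c > 0:
                        te += c * np.log2(
                            c * cb[b] / (cbg[b * big_l + g] * cab[a * big_k + b])
                        )
        te /= n_total
        if te > best:
            best = te
            best_d = d
        for x in range(m_cells):
            hist[x] = 0
    if best < 0.0:
        best = 0.0
    return best, best_d


@njit(cache=True)
def _te_all_pairs(binned, k, l, d_max):
    n, t_len = binned.shape
    big_l = 1 << l
    values = np.zeros((n, n))
    delays = np.zeros((n, n), dtype=np.int64)
    # per-neuron word codes
    iw = np.zeros((n, t_len), dtype=np.int64)
    jw = np.zeros((n, t_len), dtype=np.int64)
    for i in range(n):
        # word code with bit m = s[t-m]
        for t in range(t_len):
            wk = 0
            for m in range(k):
                if t - m >= 0 and binned[i, t - m] != 0:
                    wk |= 1 << m
            wl = 0
            for m in range(l):
                if t - m >= 0 and binned[i, t - m] != 0:
                    wl |= 1 << m
            iw[i, t] = wk
            jw[i, t] = wl
    hist = np.zeros(2 * (1 << k) * big_l, dtype=np.int64)
    for i in range(n):
        base = np.zeros(t_len, dtype=np.int64)
        for t in range(t_len - 1):
            base[t] = binned[i, t + 1] * ((1 << (k + l))) + iw[i, t] * big_l
        nz_i = np.nonzero(base)[0]
        for j in range(n):
            if i == j:
                continue
            nz_j = np.nonzero(jw[j])[0]
            best, best_d = _te_pair_delays(
                base, nz_i, jw[j], nz_j, t_len, k, l, d_max, hist
            )
            values[i, j] = best
            delays[i, j] = best_d
    return values, delays


def _cc_all_pairs(binned: np.ndarray, params: CCParams) -> tuple[np.ndarray, np.ndarray]:
    n, t_len = binned.shape
    x = np.empty((n, t_len))
    for i in range(n):
        x[i] = gaussian_convolve(binned[i], sigma=params.sigma, dt_sample=params.dt_sample)
    s1 = np.cumsum(x, axis=1)
    s2 = np.cumsum(x * x, axis=1)
    tot1 = s1[:, -1]
    tot2 = s2[:, -1]
    best = np.full((n, n), -np.inf)
    best_d = np.zeros((n, n), dtype=np.int64)
    any_defined = np.zeros((n, n), dtype=bool)
    for d in range(params.d_min, params.d_max + 1):
        m = t_len - d
        cross = x[:, d:] @ x[:, :m].T  # [i, j] = sum_t x_i[t] x_j[t-d]
        sum_i = tot1 - (s1[:, d - 1] if d > 0 else 0.0)  # tail sums of targets
        sum2_i = tot2 - (s2[:, d - 1] if d > 0 else 0.0)
        sum_j = s1[:, m - 1]  # head sums of sources
        sum2_j = s2[:, m - 1]
        var_i = sum2_i - sum_i * sum_i / m
        var_j = sum2_j - sum_j * sum_j / m
        cov = cross - np.outer(sum_i, sum_j) / m
        with np.errstate(invalid="ignore", divide="ignore"):
            denom = np.sqrt(np.outer(var_i, var_j))
            r = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), np.nan)
        defined = np.isfinite(r)
        improve = defined & (r > best)
        best = np.where(improve, r, best)
        best_d = np.where(improve, d, best_d)
        any_defined |= defined
    values = np.where(any_defined, np.clip(best, -1.0, 1.0), np.nan)
    np.fill_diagonal(values, 0.0)
    np.fill_diagonal(best_d, 0)
    return values, best_d


def correlation_matrix(trains, method: str, params=None) -> CorrelationMatrix:
    """All ordered-pair max-over-delay dependencies for one spike-train set.

    ``trains`` is a :class:`~spikeplex.simulate.SpikeTrainSet` or an
    ``(n, T)`` binary matrix. ``method`` is ``"te"`` or ``"cc"``.
    Undefined CC entries (constant signal at every delay) are reported as
    NaN with a logged warning.
    """
    binned = trains.binned if hasattr(trains, "binned") else np.asarray(trains)
    binned = np.ascontiguousarray(binned.astype(np.uint8))
    if binned.ndim != 2 or binned.shape[0] < 2:
        raise ValueError("need a 2-D binned matrix with at least two neurons")
    method = method.lower()
    if method == "te":
        params = params or TEParams()
        values, delays = _te_all_pairs(binned, params.k, params.l, params.d_max)
        np.fill_diagonal(values, 0.0)
        np.fill_diagonal(delays, 0)
    elif method == "cc":
        params = params or CCParams()
        values, delays = _cc_all_pairs(binned, params)
        n_undef = int(np.isnan(values).sum())
        if n_undef:
            logger.warning("%d undefined CC entries (zero-variance overlap)", n_undef)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationMatrix(values=values, best_delay=delays, method=method, params=params)
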