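"""Approximate entropy (ApEn) of scalar time series.

ApEn(m, r, N) quantifies the irregularity of a series u(1)..u(N): regular,
self-similar signals score near zero, unpredictable ones score high. It is
computed from delay-embedded vectors X(i) = [u(i), ..., u(i+m-1)] and the
fraction C_i^m(r) of vectors within Chebyshev distance r of X(i):

    ApEn = mean_i log C_i^m(r)  -  mean_i log C_i^{m+1}(r)

with natural logarithms and self-matches counted, so every C > 0 and the
result is finite. The conventional parameters for short physiological and
driver-operation windows are m = 2 and r = 0.2 x SD of the window itself.

The implementation precomputes the N x N scalar distance matrix
|u(i) - u(j)|; the Chebyshev distance between k-dimensional embedded
vectors is then the running maximum of its shifted diagonals, which turns
the O(N^2 m) triple loop into a few vectorised boolean reductions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_io import InsufficientDataError, TimeSeriesSignal

__all__ = [
    "ApEnParams",
    "ApEnSeries",
    "embed",
    "scalar_distance_matrix",
    "correlation_integral",
    "tolerance_from_sd",
    "apen",
    "sliding_window_apen",
]


@dataclass(frozen=True)
class ApEnParams:
    """Parameters of windowed ApEn extraction.

    Attributes
    ----------
    m : int
        Embedding dimension (default 2).
    r_coefficient : float
        Tolerance as a multiple of the window standard deviation
        (default 0.2).
    window_s : float
        Analysis window length in seconds (default 2).
    step_s : float or None
        Window step in seconds; ``None`` means non-overlapping
        (step = window).
    global_r : bool
        If True, the tolerance is computed once from the whole signal's SD
        instead of per window. Default False: each window is scaled by its
        own variability.
    ddof : int
        Delta degrees of freedom for the SD (1 = sample SD, the default).
    """

    m: int = 2
    r_coefficient: float = 0.2
    window_s: float = 2.0
    step_s: float | None = None
    global_r: bool = False
    ddof: int = 1

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not self.r_coefficient > 0:
            raise ValueError("r_coefficient must be positive")
        if not self.window_s > 0:
            raise ValueError("window_s must be positive")
        if self.step_s is not None and not self.step_s > 0:
            raise ValueError("step_s must be positive")

    @property
    def effective_step_s(self) -> float:
        return self.window_s if self.step_s is None else self.step_s


@dataclass(frozen=True)
class ApEnSeries:
    """ApEn values of successive analysis windows (nats)."""

    values: np.ndarray
    window_starts: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        starts = np.asarray(self.window_starts, dtype=float)
        if values.shape != starts.shape:
            raise ValueError("values and window_starts must align")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "window_starts", starts)

    def __len__(self) -> int:
        return self.values.size


def embed(u, m: int) -> np.ndarray:
    """Delay-embed a scalar series into m-dimensional vectors.

    Returns the (N - m + 1, m) array whose i-th row is
    [u(i), u(i+1), ..., u(i+m-1)].
    """
    u = np.asarray(u, dtype=float)
    n = u.size
    if n < m:
        raise InsufficientDataError(f"need at least m={m} points, got {n}")
    idx = np.arange(n - m + 1)[:, None] + np.arange(m)[None, :]
    return u[idx]


def scalar_distance_matrix(u) -> np.ndarray:
    """N x N matrix of absolute scalar differences |u(i) - u(j)|.

    Symmetric with a zero diagonal. The Chebyshev distance between the
    embedded vectors X(i), X(j) of any dimension m is
    max_{k=0..m-1} D[i+k, j+k], so one matrix serves every embedding.
    """
    u = np.asarray(u, dtype=float)
    if u.size < 1:
        raise InsufficientDataError("need at least one point")
    return np.abs(u[:, None] - u[None, :])


def _chebyshev_within(dist: np.ndarray, k: int, r: float) -> np.ndarray:
    """Boolean (n_vec, n_vec) matrix of Chebyshev-distance-<=-r matches
    between k-dimensional embedded vectors, from the scalar distance matrix."""
    n = dist.shape[0]
    n_vec = n - k + 1
    within = dist <= r
    acc = within[:n_vec, :n_vec].copy()
    for off in range(1, k):
        acc &= within[off : off + n_vec, off : off + n_vec]
    return acc


def correlation_integral(u, i: int, k: int, r: float) -> float:
    """C_i^k(r): fraction of k-dimensional embedded vectors within r of X(i).

    Indices are 1-based to match the usual formulation; the self-match j = i
    is counted, so the result lies in (0, 1].
    """
    u = np.asarray(u, dtype=float)
    n = u.size
    n_vec = n - k + 1
    if n_vec < 1:
        raise InsufficientDataError(f"need at least k={k} points, got {n}")
    if not 1 <= i <= n_vec:
        raise IndexError(f"i must be in 1..{n_vec}, got {i}")
    if r < 0:
        raise ValueError("r must be non-negative")
    dist = scalar_distance_matrix(u)
    acc = _chebyshev_within(dist, k, r)
    return acc[i - 1].sum() / n_vec


def tolerance_from_sd(u, r_coefficient: float = 0.2, ddof: int = 1) -> float:
    """Tolerance r as a multiple of the series' standard deviation.

    Uses the sample SD (n-1 denominator) by default; a constant series
    yields r = 0, which still produces a finite ApEn because self-matches
    keep every correlation integral positive.
    """
    u = np.asarray(u, dtype=float)
    if u.size < 2:
        raise InsufficientDataError("need at least two points for an SD")
    return r_coefficient * float(np.std(u, ddof=ddof))


def _phi(dist: np.ndarray, k: int, r: float) -> float:
    """mean_i log C_i^k(r) from the precomputed scalar distance matrix."""
    acc = _chebyshev_within(dist, k, r)
    n_vec = acc.shape[0]
    counts = acc.sum(axis=1)
    return float(np.mean(np.log(counts / n_vec)))


def apen(u, m: int = 2, r: float | None = None, r_coefficient: float = 0.2) -> float:
    """Approximate entropy of a scalar series.

    Parameters
    ----------
    u : array-like
        Scalar series of length N >= m + 2.
    m : int
        Embedding dimension.
    r : float, optional
        Tolerance. If omitted, computed as ``r_coefficient`` times the
        sample SD of ``u``.

    Returns
    -------
    float
        ApEn in nats; non-negative up to floating-point rounding, and
        exactly 0 for a constant series.
    """
    u = np.asarray(u, dtype=float)
    n = u.size
    if n < m + 2:
        raise InsufficientDataError(f"need at least m+2={m + 2} points, got {n}")
    if r is None:
        r = tolerance_from_sd(u, r_coefficient)
    if r < 0:
        raise ValueError("r must be non-negative")
    dist = scalar_distance_matrix(u)
    return _phi(dist, m, r) - _phi(dist, m + 1, r)


def sliding_window_apen(signal: TimeSeriesSignal, params: ApEnParams) -> ApEnSeries:
    """ApEn of successive analysis windows of a signal.

    Windows start at t = 0, step, 2*step, ... and must fit entirely inside
    the signal; with the defaults (2-s window, non-overlapping) a 60-s
    channel at 100 Hz yields 30 values. The tolerance is recomputed from
    each window's own SD unless ``params.global_r`` is set.
    """
    n_win = int(round(params.window_s * signal.fs))
    n_step = int(round(params.effective_step_s * signal.fs))
    if n_win < params.m + 2:
        raise InsufficientDataError(
            f"window of {n_win} points too short for m={params.m}"
        )
    n = len(signal)
    if n < n_win:
        raise InsufficientDataError("signal shorter than one analysis window")
    global_r = None
    if params.global_r:
        global_r = tolerance_from_sd(signal.values, params.r_coefficient, params.ddof)
    values, starts = [], []
    for start in range(0, n - n_win + 1, n_step):
        window = signal.values[start : start + n_win]
        if global_r is not None:
            r = global_r
        else:
            r = tolerance_from_sd(window, params.r_coefficient, params.ddof)
        values.append(apen(window, params.m, r))
        starts.append(start / signal.fs)
    return ApEnSeries(np.asarray(values), np.asarray(starts))
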