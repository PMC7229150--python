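"""Gates that must pass before attractor modeling is trusted.

Two checks, applied to the isolated signal:

* nonlinear cross prediction — segments of the record forecast one another;
  a segment whose dynamics cannot be predicted from the others flags
  nonstationarity;
* surrogate data testing — a discriminating statistic on the original is
  ranked against IAAFT surrogates that share its amplitude distribution and
  power spectrum; failure to reject the linear-stochastic null means the
  apparent structure may be random forcing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .timeseries import UniformTimeSeries

__all__ = [
    "CrossPredictionResult",
    "SurrogateTestResult",
    "nonlinear_cross_prediction",
    "iaaft_surrogates",
    "surrogate_test",
    "prediction_error_statistic",
    "time_asymmetry_statistic",
]


@dataclass
class CrossPredictionResult:
    n_segments: int
    error_matrix: np.ndarray       # (i, j): error of segment j forecast from i
    heterogeneity_score: float     # worst row/column mean over grand mean
    stationary: bool
    threshold: float
    error_floor: float


def _one_step_errors(
    lib_x: np.ndarray,
    query_x: np.ndarray,
    E: int,
    tau: int,
    k: int,
    self_library: bool,
    theiler: int,
) -> float:
    """Normalized RMS one-step forecast error of ``query_x`` from ``lib_x``.

    Both series are mean-centered before embedding, so the error only sees
    relative geometry (shift invariance).  The error is normalized by the
    query segment's standard deviation.
    """
    lib_x = lib_x - lib_x.mean()
    query_x = query_x - query_x.mean()
    sd = query_x.std()
    if sd == 0:
        raise ValueError("constant segment: cross prediction undefined")
    span = (E - 1) * tau

    def emb(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n = x.size
        base = np.arange(n - span - 1)
        pts = np.column_stack([x[base + j * tau] for j in range(E)])
        tgt = x[base + span + 1]
        return pts, tgt

    lp, lt = emb(lib_x)
    qp, qt = emb(query_x)
    d = cdist(qp, lp)
    if self_library:
        # clamp the exclusion window so k admissible neighbors always remain
        theiler = max(0, min(theiler, (lp.shape[0] - k - 2) // 2))
        t = np.arange(lp.shape[0])
        d[np.abs(t[:, None] - t[None, :]) <= theiler] = np.inf
    if np.any(np.isfinite(d).sum(1) < k):
        raise ValueError(
            f"segment too short: fewer than k={k} admissible neighbors "
            f"(library of {lp.shape[0]} embedded points)"
        )
    nn = np.argsort(d, axis=1, kind="stable")[:, :k]
    nd = np.take_along_axis(d, nn, axis=1)
    dmin = np.maximum(nd[:, :1], 1e-300)
    w = np.exp(-nd / dmin)
    zero = nd[:, 0] == 0
    if np.any(zero):
        w[zero] = (nd[zero] == 0).astype(float)
    w /= w.sum(1, keepdims=True)
    pred = (w * lt[nn]).sum(1)
    return float(np.sqrt(np.mean((pred - qt) ** 2)) / sd)


def nonlinear_cross_prediction(
    ts: UniformTimeSeries,
    n_segments: int = 4,
    E: int = 3,
    tau: int = 1,
    threshold: float = 1.4,
    error_floor: float = 0.5,
) -> CrossPredictionResult:
    """Mutual one-step forecasts between contiguous equal segments.

    Entry (i, j) of the error matrix is the normalized RMS error of
    forecasting segment j from segment i's delay embedding (diagonal:
    leave-one-out in-sample error).  The record is declared nonstationary
    when some row or column mean of the matrix both exceeds ``threshold``
    times the grand mean and exceeds ``error_floor`` in absolute
    (SD-normalized) units; the floor keeps fluctuations among uniformly
    tiny errors from flagging a well-predicted record.
    """
    if ts.n_channels != 1:
        raise ValueError("nonlinear_cross_prediction expects a single channel")
    if n_segments < 2:
        raise ValueError("need at least 2 segments")
    x = ts.values[:, 0]
    seg_len = x.size // n_segments
    k = E + 1
    min_len = (E - 1) * tau + 1 + k + 1
    if seg_len < min_len:
        raise ValueError(
            f"segments of {seg_len} samples are too short for E={E}, tau={tau}; "
            f"need at least {min_len}"
        )
    segs = [x[i * seg_len : (i + 1) * seg_len] for i in range(n_segments)]
    err = np.empty((n_segments, n_segments))
    for i in range(n_segments):
        for j in range(n_segments):
            err[i, j] = _one_step_errors(
                segs[i], segs[j], E, tau, k,
                self_library=(i == j), theiler=tau * E,
            )
    grand = err.mean()
    row = err.mean(axis=1)
    col = err.mean(axis=0)
    worst = float(max(row.max(), col.max()))
    score = worst / grand
    nonstationary = score > threshold and worst > error_floor
    return CrossPredictionResult(
        n_segments=n_segments,
        error_matrix=err,
        heterogeneity_score=float(score),
        stationary=bool(not nonstationary),
        threshold=threshold,
        error_floor=error_floor,
    )


def iaaft_surrogates(
    ts: UniformTimeSeries,
    n_surrogates: int = 99,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> list[np.ndarray]:
    """Iterative amplitude-adjusted Fourier-transform surrogates.

    Each surrogate shares the original's sorted amplitudes exactly and its
    power spectrum approximately; iteration alternates spectrum matching
    and rank-order amplitude restoration until the spectral discrepancy
    stops improving (or ``max_iter``).
    """
    if ts.n_channels != 1:
        raise ValueError("iaaft_surrogates expects a single channel")
    if n_surrogates < 1:
        raise ValueError("n_surrogates must be >= 1")
    x = ts.values[:, 0]
    if x.std() == 0:
        raise ValueError("constant series: phase randomization undefined")
    rng = np.random.default_rng(seed)
    amp_sorted = np.sort(x)
    target_spec = np.abs(np.fft.rfft(x))
    spec_norm = np.linalg.norm(target_spec)
    out = []
    for _ in range(n_surrogates):
        y = rng.permutation(x)
        prev = np.inf
        for _ in range(max_iter):
            fy = np.fft.rfft(y)
            phase = np.where(np.abs(fy) > 0, fy / np.abs(fy), 1.0)
            y = np.fft.irfft(target_spec * phase, n=x.size)
            ranks = np.argsort(np.argsort(y))
            y = amp_sorted[ranks]
            err = np.linalg.norm(np.abs(np.fft.rfft(y)) - target_spec) / spec_norm
            if prev - err < tol:
                break
            prev = err
        out.append(y)
    return out


def prediction_error_statistic(x: np.ndarray, E: int = 3, tau: int = 1) -> float:
    """Leave-one-out one-step simplex forecast error (lower = more structure)."""
    return _one_step_errors(x, x, E=E, tau=tau, k=E + 1,
                            self_library=True, theiler=tau * E)


def time_asymmetry_statistic(x: np.ndarray, lag: int = 1) -> float:
    """Skewness of increments; zero in distribution for time-reversible
    (linear Gaussian) processes."""
    d = x[lag:] - x[:-lag]
    s2 = np.mean(d**2)
    if s2 == 0:
        raise ValueError("constant series: time asymmetry undefined")
    return float(np.mean(d**3) / s2**1.5)


_STATISTICS = {
    "prediction_error": ("less", prediction_error_statistic),
    "time_asymmetry": ("two_sided", time_asymmetry_statistic),
}


@dataclass
class SurrogateTestResult:
    statistic_name: str
    observed_value: float
    surrogate_values: np.ndarray
    n_surrogates: int
    method: str
    rank_p: float
    reject_linear_null: bool
    level: float


def surrogate_test(
    ts: UniformTimeSeries,
    statistic: str = "prediction_error",
    n_surrogates: int = 99,
    level: float = 0.05,
    seed: int = 0,
    **stat_kwargs,
) -> SurrogateTestResult:
    """Rank the observed discriminating statistic against IAAFT surrogates.

    rank_p = (1 + #{surrogates at least as extreme}) / (n_surrogates + 1),
    one-sided in the direction registered for the statistic (lower
    prediction error = more deterministic; larger |time asymmetry| = less
    reversible).  Rejection requires rank_p <= level.
    """
    if statistic not in _STATISTICS:
        raise ValueError(
            f"unknown statistic {statistic!r}; have {sorted(_STATISTICS)}"
        )
    needed = int(np.ceil(1.0 / level)) - 1
    if n_surrogates < needed:
        raise ValueError(
            f"level {level} unattainable with {n_surrogates} surrogates; "
            f"need at least {needed}"
        )
    direction, func = _STATISTICS[statistic]
    x = ts.values[:, 0]
    observed = func(x, **stat_kwargs)
    surrogates = iaaft_surrogates(ts, n_surrogates=n_surrogates, seed=seed)
    values = np.array([func(s, **stat_kwargs) for s in surrogates])
    if direction == "less":
        extreme = int(np.sum(values <= observed))
    else:
        extreme = int(np.sum(np.abs(values) >= np.abs(observed)))
    rank_p = (1 + extreme) / (n_surrogates + 1)
    return SurrogateTestResult(
        statistic_name=statistic,
        observed_value=float(observed),
        surrogate_values=values,
        n_surrogates=n_surrogates,
        method="iaaft",
        rank_p=float(rank_p),
        reject_linear_null=bool(rank_p <= level),
        level=level,
    )
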