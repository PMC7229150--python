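"""Attractor reconstruction, simplex forecasting, Lyapunov estimation.

Time-delay embeddings (single-channel or mixed-coordinate), automatic
delay/dimension selection, the shared simplex-projection prediction kernel
used everywhere downstream (stationarity testing, surrogate statistics,
cross mapping), and Kantz-style maximum Lyapunov exponent estimation from
neighbor-divergence curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .timeseries import UniformTimeSeries

__all__ = [
    "DelayEmbedding",
    "NeighborSpec",
    "LyapunovEstimate",
    "SimplexResult",
    "delay_embed",
    "mixed_embed",
    "select_delay",
    "select_dimension",
    "simplex_project",
    "max_lyapunov",
]


@dataclass
class DelayEmbedding:
    """Reconstructed state-space points with an explicit coordinate map.

    Row ``r`` holds, for each coordinate ``(channel, lag)``, the source
    value at time index ``valid_time_index[r] + lag``.
    """

    coordinates: list[tuple[str, int]]
    points: np.ndarray            # m x E
    source_length: int
    step: float                   # block duration (seconds)
    valid_time_index: np.ndarray  # m, base source index of each row

    @property
    def m(self) -> int:
        return self.points.shape[0]

    @property
    def E(self) -> int:
        return self.points.shape[1]


@dataclass
class NeighborSpec:
    """Nearest-neighbor search policy for the simplex kernel."""

    k: int = 3
    theiler_window: int = 0
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.theiler_window < 0:
            raise ValueError("theiler_window must be >= 0")
        if self.metric != "euclidean":
            raise ValueError("only the Euclidean metric is supported")


@dataclass
class SimplexResult:
    predictions: np.ndarray
    skill: float                  # Pearson rho; nan if undefined
    pred_rows: np.ndarray


@dataclass
class LyapunovEstimate:
    """Slope of the log mean-separation curve over its linear portion."""

    divergence_curve: np.ndarray  # mean log separation at horizon h = 0..H
    fit_range: tuple[int, int]    # inclusive period window used for the fit
    slope: float                  # per period (per embedding step)
    stderr: float
    r_squared: float
    params: dict = field(default_factory=dict)


def _channel_matrix(ts: UniformTimeSeries) -> dict[str, np.ndarray]:
    return {name: ts.values[:, j] for j, name in enumerate(ts.channels)}


def mixed_embed(ts: UniformTimeSeries, coordinates: list[tuple[str, int]]) -> DelayEmbedding:
    """General (channel, lag) embedding; lags may be negative.

    Row r has base index t_r with column j equal to channel_j[t_r + lag_j];
    base indices run over every t for which all lags are in range.
    """
    if not coordinates:
        raise ValueError("need at least one coordinate")
    cols = _channel_matrix(ts)
    for ch, _ in coordinates:
        if ch not in cols:
            raise KeyError(f"unknown channel {ch!r}; have {ts.channels}")
    lags = np.array([lag for _, lag in coordinates], dtype=int)
    lo = -min(lags.min(), 0)          # first feasible base index
    hi = ts.n - max(lags.max(), 0)    # one past last feasible base index
    m = hi - lo
    if m < 1:
        raise ValueError(
            f"series of length {ts.n} cannot host lags {lags.tolist()}"
        )
    base = np.arange(lo, hi)
    points = np.column_stack([cols[ch][base + lag] for ch, lag in coordinates])
    return DelayEmbedding(
        coordinates=list(coordinates),
        points=points,
        source_length=ts.n,
        step=ts.step,
        valid_time_index=base,
    )


def delay_embed(ts: UniformTimeSeries, channel: str | None = None,
                E: int = 2, tau: int = 1) -> DelayEmbedding:
    """Forward uniform embedding: rows (x_t, x_{t+tau}, ..., x_{t+(E-1)tau})."""
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if E < 1:
        raise ValueError("E must be >= 1")
    if channel is None:
        if ts.n_channels != 1:
            raise ValueError("channel must be named for multichannel input")
        channel = ts.channels[0]
    need = (E - 1) * tau + 1
    if ts.n < need:
        raise ValueError(
            f"series too short: need at least {need} samples for E={E}, "
            f"tau={tau}, got {ts.n}"
        )
    return mixed_embed(ts, [(channel, j * tau) for j in range(E)])


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def simplex_project(
    embedding: DelayEmbedding,
    target: np.ndarray,
    lib_rows: np.ndarray | None = None,
    pred_rows: np.ndarray | None = None,
    spec: NeighborSpec | None = None,
    allow_self: bool = False,
) -> SimplexResult:
    """Exponentially weighted nearest-neighbor prediction of ``target``.

    ``target`` holds one value per embedding row.  For each prediction row
    the k nearest library rows (Euclidean; self and rows within the Theiler
    window excluded unless ``allow_self``) vote with weights
    ``exp(-d_i / d_min)``; if the nearest distance is zero, the zero-distance
    ties share uniform weights.  Skill is the Pearson correlation between
    predictions and the true target values.
    """
    if spec is None:
        spec = NeighborSpec(k=embedding.E + 1)
    target = np.asarray(target, dtype=float)
    if target.size != embedding.m:
        raise ValueError(
            f"target length {target.size} != number of embedding rows {embedding.m}"
        )
    lib = np.arange(embedding.m) if lib_rows is None else np.asarray(lib_rows, int)
    pred = np.arange(embedding.m) if pred_rows is None else np.asarray(pred_rows, int)
    pts = embedding.points
    tidx = embedding.valid_time_index
    lib_pts = pts[lib]
    lib_t = tidx[lib]

    # all pairwise distances pred x lib (records here are small enough)
    d = np.sqrt(
        np.maximum(
            (pts[pred] ** 2).sum(1)[:, None]
            - 2.0 * pts[pred] @ lib_pts.T
            + (lib_pts**2).sum(1)[None, :],
            0.0,
        )
    )
    if not allow_self:
        excluded = np.abs(tidx[pred][:, None] - lib_t[None, :]) <= spec.theiler_window
        d = np.where(excluded, np.inf, d)

    k = spec.k
    admissible = np.isfinite(d).sum(axis=1)
    if np.any(admissible < k):
        bad = int(np.argmin(admissible))
        raise ValueError(
            f"prediction row {pred[bad]} has only {admissible[bad]} admissible "
            f"neighbors (< k={k}); shrink the Theiler window ({spec.theiler_window}) "
            "or enlarge the library"
        )
    # ties broken toward earlier library time index: argsort is stable over
    # libraries pre-sorted by time
    order = np.argsort(lib_t, kind="stable")
    d = d[:, order]
    lib_sorted = lib[order]
    nn = np.argsort(d, axis=1, kind="stable")[:, :k]
    nd = np.take_along_axis(d, nn, axis=1)
    dmin = nd[:, :1]
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.exp(-nd / dmin)
    zero_min = (dmin[:, 0] == 0)
    if np.any(zero_min):
        tied = (nd[zero_min] == 0).astype(float)
        w[zero_min] = tied
    w /= w.sum(axis=1, keepdims=True)
    neighbor_targets = target[lib_sorted[nn]]
    predictions = (w * neighbor_targets).sum(axis=1)
    truth = target[pred]
    return SimplexResult(
        predictions=predictions,
        skill=_pearson(predictions, truth),
        pred_rows=pred,
    )


def _mutual_information(x: np.ndarray, y: np.ndarray, bins: int) -> float:
    """Histogram MI estimate with Miller-Madow bias correction.

    The raw plug-in estimate is biased upward by roughly
    (K_xy - K_x - K_y + 1) / 2N (K = occupied cells), which would grow with
    lag as the paired sample shrinks and fake dependence where none exists.
    """
    h, _, _ = np.histogram2d(x, y, bins=bins)
    n = h.sum()
    p = h / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    mi = float(np.sum(p[mask] * np.log(p[mask] / (px @ py)[mask])))
    k_xy = int(mask.sum())
    k_x = int((px > 0).sum())
    k_y = int((py > 0).sum())
    bias = (k_xy - k_x - k_y + 1) / (2.0 * n)
    return max(mi - bias, 0.0)


def select_delay(ts: UniformTimeSeries, max_lag: int | None = None) -> int:
    """Embedding delay: first local minimum of average mutual information.

    Falls back to the first lag where the autocorrelation drops below 1/e.
    Ties (an immediately flat AMI profile, e.g. white noise) resolve to the
    smallest lag.
    """
    if ts.n_channels != 1:
        raise ValueError("select_delay expects a single channel")
    x = ts.values[:, 0]
    n = x.size
    if n < 20:
        raise ValueError(f"need at least 20 samples, got {n}")
    if x.std() == 0:
        raise ValueError("constant series: delay selection undefined")
    max_lag = max(2, n // 4) if max_lag is None else max_lag
    bins = max(4, int(np.sqrt(n / 5)))
    ami = np.array(
        [_mutual_information(x[:-lag], x[lag:], bins) for lag in range(1, max_lag + 1)]
    )
    # first lag reaching (within a margin) the global AMI minimum, accepted
    # only when the profile genuinely drops into and rises out of it —
    # histogram jitter on flat or monotone profiles falls through to the
    # autocorrelation rule instead
    if len(ami) >= 3:
        kernel = np.ones(3) / 3
        sm = np.convolve(np.pad(ami, 1, mode="edge"), kernel, mode="valid")
    else:
        sm = ami
    if ami.max() < 0.1:
        # no measurable dependence at any lag: flat profile, smallest lag wins
        return 1
    margin = 0.05 * (sm.max() - sm.min())
    gmin = sm.min()
    if margin > 0:
        first = int(np.argmax(sm <= gmin + margin))
        drops = sm[0] - gmin >= margin
        rises = np.any(sm[first + 1 :] > gmin + margin)
        if drops and rises:
            return first + 1
    # fallback: autocorrelation below 1/e
    xc = x - x.mean()
    denom = float(xc @ xc)
    for lag in range(1, max_lag + 1):
        ac = float(xc[:-lag] @ xc[lag:]) / denom
        if ac < 1.0 / np.e:
            return lag
    raise ValueError(
        f"no AMI minimum and autocorrelation never drops below 1/e within "
        f"{max_lag} lags"
    )


def select_dimension(
    ts: UniformTimeSeries,
    tau: int = 1,
    E_max: int = 8,
    theiler_window: int | None = None,
) -> int:
    """Smallest E in 1..E_max maximizing leave-one-out one-step skill.

    Ties (within 1e-6 of the best skill) break toward smaller E.
    """
    if E_max < 2:
        raise ValueError("E_max must be >= 2")
    if ts.n_channels != 1:
        raise ValueError("select_dimension expects a single channel")
    x = ts.values[:, 0]
    if x.std() == 0:
        raise ValueError("constant series: dimension selection undefined")
    skills = []
    for E in range(1, E_max + 1):
        emb = delay_embed(ts, ts.channels[0], E=E, tau=tau)
        # one-step-ahead target at the row's latest coordinate time + 1
        head = emb.valid_time_index + (E - 1) * tau + 1
        rows = np.where(head < ts.n)[0]
        emb_rows = DelayEmbedding(
            coordinates=emb.coordinates,
            points=emb.points[rows],
            source_length=emb.source_length,
            step=emb.step,
            valid_time_index=emb.valid_time_index[rows],
        )
        tw = tau * E if theiler_window is None else theiler_window
        tw = min(tw, (emb_rows.m - E - 2) // 2)
        if tw < 0:
            raise ValueError(f"series too short for E={E}, tau={tau}")
        res = simplex_project(
            emb_rows,
            x[head[rows]],
            spec=NeighborSpec(k=E + 1, theiler_window=max(tw, 0)),
        )
        skills.append(res.skill)
    skills = np.asarray(skills)
    best = np.nanmax(skills)
    for E, s in enumerate(skills, start=1):
        if s >= best - 1e-6:
            return E
    raise ValueError("no finite forecast skill at any dimension")


def max_lyapunov(
    embedding: DelayEmbedding,
    spec: NeighborSpec | None = None,
    radius: float | None = None,
    max_periods: int = 20,
    fit_range: tuple[int, int] | None = None,
    min_neighbors: int = 1,
) -> LyapunovEstimate:
    """Kantz divergence-curve estimate of the maximum Lyapunov exponent.

    For every reference point with neighbors initially within ``radius``
    (Theiler-excluded), the mean log distance to those neighbors after h
    periods is averaged over references, h = 0..max_periods.  The slope of
    the least-squares line over ``fit_range`` — by default the longest
    window with R^2 >= 0.95 — is the exponent per period.  Negative slope
    means converging (sink) dynamics.
    """
    if spec is None:
        spec = NeighborSpec(k=1, theiler_window=0)
    pts = embedding.points
    m = pts.shape[0]
    if m <= max_periods + 2:
        raise ValueError(
            f"embedding has {m} points; need more than max_periods + 2 = "
            f"{max_periods + 2}"
        )
    d = np.sqrt(
        np.maximum(
            (pts**2).sum(1)[:, None] - 2.0 * pts @ pts.T + (pts**2).sum(1)[None, :],
            0.0,
        )
    )
    tidx = embedding.valid_time_index
    excl = np.abs(tidx[:, None] - tidx[None, :]) <= spec.theiler_window
    d0 = np.where(excl, np.inf, d)
    finite = d0[np.isfinite(d0)]
    if radius is None:
        radius = float(np.percentile(finite, 2.0)) if finite.size else 0.0
        if radius == 0:
            radius = float(np.percentile(finite[finite > 0], 2.0))
    n_ref = m - max_periods
    curves = []
    for i in range(n_ref):
        nbrs = np.where(d0[i, :n_ref] <= radius)[0]
        nbrs = nbrs[nbrs != i]
        if nbrs.size < min_neighbors:
            continue
        h = np.arange(max_periods + 1)
        dists = d[i + h[:, None], nbrs[None, :] + h[:, None]]
        dists = np.maximum(dists, 1e-300)
        curves.append(np.log(dists.mean(axis=1)))
    if not curves:
        feasible = float(np.min(finite)) if finite.size else float("nan")
        raise ValueError(
            f"no reference point has neighbors within radius {radius:g}; "
            f"smallest feasible radius is {feasible:g}"
        )
    curve = np.mean(curves, axis=0)
    if fit_range is None:
        fit_range = _auto_fit_range(curve)
    a, b = fit_range
    if not (0 <= a < b <= max_periods):
        raise ValueError(f"fit_range {fit_range} outside curve domain 0..{max_periods}")
    h = np.arange(a, b + 1, dtype=float)
    y = curve[a : b + 1]
    slope, intercept = np.polyfit(h, y, 1)
    resid = y - (slope * h + intercept)
    dof = max(h.size - 2, 1)
    se = float(np.sqrt((resid @ resid) / dof / ((h - h.mean()) @ (h - h.mean()))))
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
    return LyapunovEstimate(
        divergence_curve=curve,
        fit_range=(int(a), int(b)),
        slope=float(slope),
        stderr=se,
        r_squared=r2,
        params={
            "radius": radius,
            "theiler_window": spec.theiler_window,
            "max_periods": max_periods,
            "n_references": len(curves),
        },
    )


def _auto_fit_range(curve: np.ndarray, r2_min: float = 0.95, min_len: int = 3) -> tuple[int, int]:
    """Longest window of the divergence curve with linear-fit R^2 >= r2_min."""
    H = curve.size - 1
    best: tuple[int, int] | None = None
    best_len = -1
    for a in range(0, H - min_len + 1):
        for b in range(a + min_len, H + 1):
            h = np.arange(a, b + 1, dtype=float)
            y = curve[a : b + 1]
            slope, intercept = np.polyfit(h, y, 1)
            resid = y - (slope * h + intercept)
            ss_tot = float(((y - y.mean()) ** 2).sum())
            r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
            if r2 >= r2_min and (b - a) > best_len:
                best = (a, b)
                best_len = b - a
    if best is None:
        return (0, min(min_len, H))
    return best
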