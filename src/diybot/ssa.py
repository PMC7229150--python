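"""Block aggregation and singular spectrum analysis (SSA).

High-frequency sensor records are reduced to analysis blocks by plain block
means, then each channel is decomposed by SSA: SVD of the Hankel trajectory
matrix, eigentriple grouping (explicit or by weighted correlation), diagonal
averaging back to series, and signal-strength percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import hankel

from .timeseries import UniformTimeSeries

__all__ = [
    "SSADecomposition",
    "aggregate_blocks",
    "ssa_decompose",
    "ssa_group",
    "ssa_reconstruct",
    "signal_strength",
    "wcorrelation_matrix",
]


def aggregate_blocks(ts: UniformTimeSeries, block_duration: float) -> UniformTimeSeries:
    """Mean-aggregate into contiguous non-overlapping blocks.

    ``block_duration`` is in seconds and must be a positive multiple of the
    sampling step.  The trailing partial block is discarded, never padded.
    """
    if block_duration < ts.step:
        raise ValueError(
            f"block_duration {block_duration} s is below the sampling step "
            f"{ts.step} s"
        )
    ratio = block_duration / ts.step
    k = int(round(ratio))
    if abs(ratio - k) > 1e-6 * ratio:
        raise ValueError(
            f"block_duration {block_duration} s is not a multiple of the "
            f"sampling step {ts.step} s"
        )
    n_blocks = ts.n // k
    if n_blocks < 2:
        raise ValueError(
            f"record too short: {ts.n} samples yield {n_blocks} block(s) of "
            f"{k} samples"
        )
    trimmed = ts.values[: n_blocks * k]
    means = trimmed.reshape(n_blocks, k, ts.n_channels).mean(axis=1)
    return UniformTimeSeries(
        values=means,
        step=block_duration,
        channels=list(ts.channels),
        start_time=ts.start_time,
    )


@dataclass
class SSADecomposition:
    """Full set of SSA eigentriples for one channel, plus optional grouping.

    ``groups`` maps a label to a list of eigentriple indices; a complete
    partition reconstructs the input exactly (diagonal-averaging identity).
    """

    series: np.ndarray
    window_length: int
    singular_values: np.ndarray
    left_vectors: np.ndarray   # L x d
    right_vectors: np.ndarray  # K x d
    step: float = 1.0
    channel: str = "signal"
    groups: dict[str, list[int]] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.series.size

    @property
    def n_components(self) -> int:
        return self.singular_values.size

    def component_strengths(self) -> np.ndarray:
        """Percent of total squared norm carried by each eigentriple."""
        s2 = self.singular_values**2
        total = s2.sum()
        if total == 0:
            raise ValueError("all-zero series: signal strength undefined")
        return 100.0 * s2 / total

    def elementary_series(self, index: int) -> np.ndarray:
        """Diagonal-averaged series of one eigentriple."""
        return _diagonal_average(
            self.singular_values[index],
            self.left_vectors[:, index],
            self.right_vectors[:, index],
        )


def _diagonal_average(s: float, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Hankelize the rank-1 matrix s * u v^T back to a series.

    The anti-diagonal sums of an outer product are a convolution; dividing
    by the anti-diagonal lengths gives the average.
    """
    L, K = u.size, v.size
    sums = np.convolve(u, s * v)  # length L + K - 1 = n
    n = L + K - 1
    counts = np.minimum(np.minimum(np.arange(1, n + 1), n - np.arange(n)), min(L, K))
    return sums / counts


def _group_series(decomp: SSADecomposition, idx: list[int]) -> np.ndarray:
    """Sum of elementary series for a set of eigentriples.

    For large groups the per-component convolutions are batched through one
    real FFT (convolution theorem), which keeps full-partition
    reconstruction O(g n log n) instead of O(g n^2).
    """
    if len(idx) == 0:
        return np.zeros(decomp.n)
    if len(idx) <= 8:
        out = np.zeros(decomp.n)
        for i in idx:
            out += decomp.elementary_series(i)
        return out
    n = decomp.n
    L = decomp.window_length
    K = n - L + 1
    U = decomp.left_vectors[:, idx]
    V = decomp.right_vectors[:, idx] * decomp.singular_values[idx]
    fu = np.fft.rfft(U, n=n, axis=0)
    fv = np.fft.rfft(V, n=n, axis=0)
    sums = np.fft.irfft((fu * fv).sum(axis=1), n=n)
    counts = np.minimum(np.minimum(np.arange(1, n + 1), n - np.arange(n)), min(L, K))
    return sums / counts


def ssa_decompose(ts: UniformTimeSeries, window_length: int | None = None) -> SSADecomposition:
    """SVD of the L x (n - L + 1) trajectory matrix of a single channel.

    Default window is the largest admissible, L = n // 2.  All eigentriples
    are returned, ungrouped.
    """
    if ts.n_channels != 1:
        raise ValueError(
            f"ssa_decompose expects a single channel, got {ts.n_channels}; "
            "use ts.single(name)"
        )
    x = ts.values[:, 0]
    n = x.size
    L = n // 2 if window_length is None else int(window_length)
    if not 2 <= L <= n // 2:
        raise ValueError(f"window_length must satisfy 2 <= L <= n/2, got {L} (n={n})")
    X = hankel(x[:L], x[L - 1 :])
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    return SSADecomposition(
        series=x.copy(),
        window_length=L,
        singular_values=s,
        left_vectors=U,
        right_vectors=Vt.T,
        step=ts.step,
        channel=ts.channels[0],
    )


def _wcorr_weights(n: int, L: int) -> np.ndarray:
    K = n - L + 1
    return np.minimum(np.minimum(np.arange(1, n + 1), n - np.arange(n)), min(L, K)).astype(float)


def wcorrelation_matrix(decomp: SSADecomposition, n_components: int | None = None) -> np.ndarray:
    """Weighted-correlation matrix of the leading elementary series."""
    m = decomp.n_components if n_components is None else min(n_components, decomp.n_components)
    w = _wcorr_weights(decomp.n, decomp.window_length)
    comps = np.stack([decomp.elementary_series(i) for i in range(m)])
    g = (comps * w) @ comps.T  # weighted Gram matrix
    norms = np.sqrt(np.clip(np.diag(g), 0, None))
    norms[norms == 0] = 1.0
    return g / np.outer(norms, norms)


def ssa_group(
    decomp: SSADecomposition,
    grouping_rule: dict[str, list[int]] | str = "wcorr",
    threshold: float = 0.5,
    max_components: int = 20,
) -> SSADecomposition:
    """Attach a grouping to a decomposition.

    ``grouping_rule`` is either an explicit ``{label: [indices]}`` partition
    or the string ``"wcorr"``: eigentriples among the leading
    ``max_components`` whose weighted correlation exceeds ``threshold`` are
    merged (transitively); merged clusters — and the cluster holding the
    leading eigentriple — are labeled signal groups in order of strength,
    everything else is the "noise" group.
    """
    if isinstance(grouping_rule, dict):
        groups = {k: sorted(int(i) for i in v) for k, v in grouping_rule.items()}
        seen: list[int] = []
        for idx in groups.values():
            seen.extend(idx)
        if len(seen) != len(set(seen)):
            raise ValueError("explicit grouping assigns an eigentriple twice")
        if any(i < 0 or i >= decomp.n_components for i in seen):
            raise ValueError(
                f"grouping index out of range 0..{decomp.n_components - 1}"
            )
        return replace(decomp, groups=groups)
    if grouping_rule != "wcorr":
        raise ValueError(f"unknown grouping rule {grouping_rule!r}")

    m = min(max_components, decomp.n_components)
    wc = np.abs(wcorrelation_matrix(decomp, m))
    adj = wc > threshold
    # connected components of the thresholded w-correlation graph
    labels = -np.ones(m, dtype=int)
    n_clusters = 0
    for i in range(m):
        if labels[i] >= 0:
            continue
        stack = [i]
        labels[i] = n_clusters
        while stack:
            j = stack.pop()
            for k in np.where(adj[j])[0]:
                if labels[k] < 0:
                    labels[k] = n_clusters
                    stack.append(int(k))
        n_clusters += 1
    clusters = [list(np.where(labels == c)[0]) for c in range(n_clusters)]
    s2 = decomp.singular_values**2
    signal_clusters = [c for c in clusters if len(c) >= 2 or 0 in c]
    signal_clusters.sort(key=lambda c: -s2[c].sum())
    groups: dict[str, list[int]] = {}
    for rank, c in enumerate(signal_clusters):
        label = "signal" if rank == 0 else f"signal_{rank + 1}"
        groups[label] = [int(i) for i in c]
    grouped = {i for c in signal_clusters for i in c}
    noise = [int(i) for i in range(decomp.n_components) if i not in grouped]
    groups["noise"] = noise
    return replace(decomp, groups=groups)


def ssa_reconstruct(decomp: SSADecomposition, group_label: str) -> UniformTimeSeries:
    """Diagonal-averaged reconstruction of one group."""
    if group_label not in decomp.groups:
        raise KeyError(
            f"unknown group {group_label!r}; have {sorted(decomp.groups)}"
        )
    out = _group_series(decomp, decomp.groups[group_label])
    return UniformTimeSeries(
        out, step=decomp.step, channels=[f"{decomp.channel}:{group_label}"]
    )


def ssa_smooth(
    ts: UniformTimeSeries,
    window_length: int | None = None,
    threshold: float = 0.5,
    max_components: int = 20,
) -> UniformTimeSeries:
    """Replace every channel by the sum of its SSA signal groups.

    Convenience wrapper (decompose -> w-correlation grouping -> reconstruct)
    used to denoise records before derivative estimation.
    """
    cols = []
    for ch in ts.channels:
        decomp = ssa_group(
            ssa_decompose(ts.single(ch), window_length),
            "wcorr", threshold=threshold, max_components=max_components,
        )
        signal = np.zeros(ts.n)
        for label in decomp.groups:
            if label.startswith("signal"):
                signal += ssa_reconstruct(decomp, label).values[:, 0]
        cols.append(signal)
    return UniformTimeSeries(
        np.column_stack(cols), step=ts.step, channels=list(ts.channels),
        start_time=ts.start_time,
    )


def signal_strength(decomp: SSADecomposition, group_label: str) -> float:
    """Percent of total squared singular value norm carried by a group."""
    if group_label not in decomp.groups:
        raise KeyError(
            f"unknown group {group_label!r}; have {sorted(decomp.groups)}"
        )
    strengths = decomp.component_strengths()
    return float(strengths[decomp.groups[group_label]].sum())
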