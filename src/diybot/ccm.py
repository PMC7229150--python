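"""Convergent cross mapping and its delayed (extended) variant.

CCM detects causality running from a driver Y to a response X when the
attractor reconstructed from X alone cross-maps Y with skill that grows
with library size.  Extended CCM scans imposed driver-response delays: a
skill peak at a negative delay marks true causality, a peak at zero or a
positive delay marks synchrony to a shared force (false positive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import kendalltau

from .state_space import DelayEmbedding, NeighborSpec, mixed_embed, simplex_project
from .timeseries import UniformTimeSeries

__all__ = [
    "CCMResult",
    "ExtendedCCMResult",
    "CausalClassification",
    "ccm",
    "extended_ccm",
    "classify_interaction",
    "STRONG_SKILL_THRESHOLD",
    "WEAK_SKILL_THRESHOLD",
]

#: skill above which a driver is called strong
STRONG_SKILL_THRESHOLD = 0.8
#: skill at or below which a driver is called absent
WEAK_SKILL_THRESHOLD = 0.5
#: minimum gain from smallest to largest library to call convergence
CONVERGENCE_MARGIN = 0.1
#: a curve "converging" to skill below this is noise, not causality
MIN_CONVERGED_SKILL = 0.2
#: skills within this of the peak count as tied when locating the peak delay
PEAK_TIE_TOL = 1e-3


@dataclass
class CCMResult:
    driver: str
    response: str
    E: int
    tau: int
    lib_sizes: np.ndarray
    skill: np.ndarray          # mean cross-map rho per library size
    skill_spread: np.ndarray   # SD across draws per library size
    n_draws: int
    seed: int
    converged: bool
    rho_max: float


@dataclass
class ExtendedCCMResult:
    driver: str
    response: str
    delays: np.ndarray
    skill_by_delay: np.ndarray
    peak_delay: int
    true_causal: bool


@dataclass
class CausalClassification:
    pair: tuple[str, str]
    a_drives_b: str            # strong | weak | absent
    b_drives_a: str
    synchrony_suspected: bool
    summary: str               # bidirectional | unidirectional | none


def _response_embedding(x: np.ndarray, E: int, tau: int, step: float,
                        channel: str) -> tuple[DelayEmbedding, np.ndarray]:
    """Lagged-back embedding of the response; row r reconstructs the state
    at time index r + (E-1) tau, where the cross-mapped value is read."""
    n = x.size
    ts = UniformTimeSeries(x, step=step, channels=[channel])
    emb = mixed_embed(ts, [(channel, -j * tau) for j in range(E)])
    map_times = emb.valid_time_index  # first feasible is (E-1) tau
    return emb, map_times


def ccm(
    x: UniformTimeSeries | np.ndarray,
    y: UniformTimeSeries | np.ndarray,
    E: int = 3,
    tau: int = 1,
    lib_sizes=None,
    n_draws: int = 50,
    sampling: str = "contiguous",
    seed: int = 0,
    theiler_window: int | None = None,
) -> CCMResult:
    """Cross-map the driver-candidate ``y`` from the response ``x``'s attractor.

    Tests "y causes x": embeds x with (E, tau), then for each library size
    draws ``n_draws`` libraries (``sampling``: "contiguous" segments,
    "random" rows, or "sequential" = the leading rows, deterministic) and
    predicts y at the matching times with the simplex kernel.  Convergence
    requires the mean skill to rise from the smallest to the largest
    library by at least ``CONVERGENCE_MARGIN`` with a positive Kendall
    trend across sizes.
    """
    xv, x_name = _as_values(x, "x")
    yv, y_name = _as_values(y, "y")
    if xv.size != yv.size:
        raise ValueError(f"series lengths differ: {xv.size} vs {yv.size}")
    step = x.step if isinstance(x, UniformTimeSeries) else 1.0
    emb, map_times = _response_embedding(xv, E, tau, step, x_name)
    target = yv[map_times]
    m = emb.m
    k = E + 1
    if lib_sizes is None:
        hi = m
        lo = max(k + 2, E + 2)
        lib_sizes = np.unique(np.linspace(lo, hi, 8).astype(int))
    lib_sizes = np.asarray(sorted(set(int(s) for s in lib_sizes)))
    if lib_sizes[0] < E + 2:
        raise ValueError(
            f"smallest library size {lib_sizes[0]} is below E + 2 = {E + 2}"
        )
    if lib_sizes[-1] > m:
        raise ValueError(
            f"largest library size {lib_sizes[-1]} exceeds the {m} embedded points"
        )
    tw = tau * E if theiler_window is None else theiler_window
    rng = np.random.default_rng(seed)
    mean_skill = np.empty(lib_sizes.size)
    spread = np.empty(lib_sizes.size)
    for li, L in enumerate(lib_sizes):
        draws = 1 if sampling == "sequential" else n_draws
        skills = np.empty(draws)
        for di in range(draws):
            if sampling == "sequential":
                rows = np.arange(L)
            elif sampling == "contiguous":
                start = rng.integers(0, m - L + 1)
                rows = np.arange(start, start + L)
            elif sampling == "random":
                rows = rng.choice(m, size=L, replace=False)
            else:
                raise ValueError(f"unknown sampling {sampling!r}")
            eff_tw = max(0, min(tw, (L - k - 2) // 2))
            res = simplex_project(
                emb, target, lib_rows=rows, pred_rows=None,
                spec=NeighborSpec(k=k, theiler_window=eff_tw),
            )
            skills[di] = res.skill
        mean_skill[li] = np.nanmean(skills)
        spread[li] = np.nanstd(skills)
    gain = mean_skill[-1] - mean_skill[0]
    if lib_sizes.size >= 3:
        trend = kendalltau(lib_sizes, mean_skill).statistic
    else:
        trend = np.sign(gain)
    converged = bool(
        gain >= CONVERGENCE_MARGIN
        and trend > 0
        and mean_skill[-1] >= MIN_CONVERGED_SKILL
    )
    return CCMResult(
        driver=y_name,
        response=x_name,
        E=E,
        tau=tau,
        lib_sizes=lib_sizes,
        skill=mean_skill,
        skill_spread=spread,
        n_draws=n_draws,
        seed=seed,
        converged=converged,
        rho_max=float(mean_skill[-1]),
    )


def _as_values(ts, fallback_name: str) -> tuple[np.ndarray, str]:
    if isinstance(ts, UniformTimeSeries):
        if ts.n_channels != 1:
            raise ValueError("ccm expects single-channel series")
        return ts.values[:, 0], ts.channels[0]
    arr = np.asarray(ts, dtype=float).ravel()
    return arr, fallback_name


def extended_ccm(
    x: UniformTimeSeries | np.ndarray,
    y: UniformTimeSeries | np.ndarray,
    E: int = 3,
    tau: int = 1,
    delays=range(-8, 9),
    lib_size: int | None = None,
    seed: int = 0,
    theiler_window: int | None = None,
) -> ExtendedCCMResult:
    """Cross-map y shifted by each delay d from x's attractor.

    Negative d asks the attractor to recover the driver's past (driver
    leads); the delay with peak skill localizes the interaction in time.
    Skills within ``PEAK_TIE_TOL`` of the maximum are tied and resolve to
    the smallest-magnitude delay (negative first on an exact +/- tie).
    """
    xv, x_name = _as_values(x, "x")
    yv, y_name = _as_values(y, "y")
    if xv.size != yv.size:
        raise ValueError(f"series lengths differ: {xv.size} vs {yv.size}")
    delays = np.asarray(list(delays), dtype=int)
    if delays.min() >= 0 or delays.max() <= 0:
        raise ValueError("delays must span negative and positive values")
    step = x.step if isinstance(x, UniformTimeSeries) else 1.0
    emb, map_times = _response_embedding(xv, E, tau, step, x_name)
    k = E + 1
    tw = tau * E if theiler_window is None else theiler_window
    skills = np.empty(delays.size)
    for i, d in enumerate(delays):
        shifted_times = map_times + d
        valid = (shifted_times >= 0) & (shifted_times < yv.size)
        rows = np.where(valid)[0]
        if rows.size < k + 2:
            raise ValueError(
                f"delay {d} leaves only {rows.size} valid points; "
                f"feasible range is +/-{map_times.size - k - 2}"
            )
        sub = DelayEmbedding(
            coordinates=emb.coordinates,
            points=emb.points[rows],
            source_length=emb.source_length,
            step=emb.step,
            valid_time_index=emb.valid_time_index[rows],
        )
        target = yv[shifted_times[rows]]
        if lib_size is not None and lib_size < rows.size:
            lib_rows = np.arange(lib_size)
        else:
            lib_rows = None
        eff_tw = max(0, min(tw, (rows.size - k - 2) // 2))
        res = simplex_project(
            sub, target, lib_rows=lib_rows,
            spec=NeighborSpec(k=k, theiler_window=eff_tw),
        )
        skills[i] = res.skill
    # delays whose skill is within PEAK_TIE_TOL of the maximum are tied:
    # prefer the smallest-magnitude delay (negative before positive on an
    # exact +/- tie), so estimation jitter between in-embedding lags cannot
    # manufacture a spurious lead or lag
    best = np.nanmax(skills)
    tied = delays[skills >= best - PEAK_TIE_TOL]
    peak = int(sorted(tied, key=lambda d: (abs(d), d))[0])
    return ExtendedCCMResult(
        driver=y_name,
        response=x_name,
        delays=delays,
        skill_by_delay=skills,
        peak_delay=peak,
        true_causal=bool(peak < 0),
    )


def _grade(res: CCMResult, ext: ExtendedCCMResult) -> tuple[str, bool]:
    """Apply the strong/weak/absent rules; returns (grade, synchrony)."""
    if res.rho_max > STRONG_SKILL_THRESHOLD and res.converged:
        grade = "strong"
    elif WEAK_SKILL_THRESHOLD < res.rho_max <= STRONG_SKILL_THRESHOLD:
        grade = "weak"
    else:
        grade = "absent"
    # skill without a negative-delay peak is the synchrony signature: the
    # apparent driver mirrors the response rather than causing it.  High
    # skill that never converged (near-ceiling from the smallest library,
    # as for an instantaneous copy) counts too.
    if not ext.true_causal and (
        grade != "absent" or res.rho_max > STRONG_SKILL_THRESHOLD
    ):
        return "absent", True
    return grade, False


def classify_interaction(
    ccm_ab: CCMResult,
    ccm_ba: CCMResult,
    ext_ab: ExtendedCCMResult,
    ext_ba: ExtendedCCMResult,
) -> CausalClassification:
    """Combine both directions into one interaction label.

    ``ccm_ab`` tests "A drives B" (B's attractor cross-maps A), and
    ``ext_ab`` is its delayed variant; likewise for the reverse direction.
    """
    if (ccm_ab.driver, ccm_ab.response) != (ccm_ba.response, ccm_ba.driver):
        raise ValueError(
            "mismatched pair metadata: "
            f"({ccm_ab.driver}->{ccm_ab.response}) vs "
            f"({ccm_ba.driver}->{ccm_ba.response})"
        )
    for res, ext in ((ccm_ab, ext_ab), (ccm_ba, ext_ba)):
        if (res.driver, res.response) != (ext.driver, ext.response):
            raise ValueError(
                "extended CCM metadata does not match its CCM direction: "
                f"({res.driver}->{res.response}) vs ({ext.driver}->{ext.response})"
            )
    a, b = ccm_ab.driver, ccm_ab.response
    ab, syn_ab = _grade(ccm_ab, ext_ab)
    ba, syn_ba = _grade(ccm_ba, ext_ba)
    n_causal = sum(1 for g in (ab, ba) if g != "absent")
    summary = {2: "bidirectional", 1: "unidirectional", 0: "none"}[n_causal]
    return CausalClassification(
        pair=(a, b),
        a_drives_b=ab,
        b_drives_a=ba,
        synchrony_suspected=bool(syn_ab or syn_ba),
        summary=summary,
    )
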