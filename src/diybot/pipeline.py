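"""End-to-end orchestration: sensors in, management recommendation out.

Fixed stage order: block aggregation -> SSA signal isolation ->
stationarity gate (nonlinear cross prediction) -> surrogate gate (IAAFT) ->
attractor reconstruction -> CCM / extended CCM -> sparse ODE discovery ->
equilibrium eigenvalues, Lyapunov correspondence, marginal impacts.

A failed gate halts model fitting and yields an ``indeterminate`` report
naming the gate: fitting an ODE to signals that are nonstationary or
indistinguishable from linear noise is precisely the failure mode the
gates exist to prevent.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .ccm import (
    CausalClassification,
    ccm,
    classify_interaction,
    extended_ccm,
)
from .ode import (
    FunctionLibrary,
    eigen_classify,
    estimate_derivatives,
    find_equilibria,
    integrate_model,
    marginal_impacts,
    sindy_fit,
)
from .ssa import aggregate_blocks, signal_strength, ssa_decompose, ssa_group, ssa_reconstruct
from .state_space import (
    NeighborSpec,
    delay_embed,
    max_lyapunov,
    mixed_embed,
    select_delay,
    select_dimension,
)
from .stationarity import nonlinear_cross_prediction, surrogate_test
from .timeseries import UniformTimeSeries, read_sensor_csv

__all__ = ["PipelineConfig", "DiybotReport", "run_diybot", "write_report",
           "read_sensor_csv"]

logger = logging.getLogger("diybot")

REPORT_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Every stage default, overridable and recorded in provenance."""

    input: str | None = None
    channels: tuple[str, str] = ("pH", "DO")
    block_duration: float = 7200.0       # seconds (two-hour blocks)

    # SSA
    ssa_window: int | None = None        # default n // 2
    ssa_wcorr_threshold: float = 0.5
    ssa_max_components: int = 20

    # stationarity gate
    n_segments: int = 4
    stationarity_factor: float = 1.4
    stationarity_error_floor: float = 0.5

    # surrogate gate
    n_surrogates: int = 99
    surrogate_level: float = 0.05
    surrogate_statistic: str = "prediction_error"

    # embedding
    E: int | None = None
    tau: int | None = None
    E_max: int = 6
    mixed_coordinates: list[tuple[str, int]] | None = None

    # CCM
    lib_sizes: list[int] | None = None
    n_draws: int = 20
    ccm_sampling: str = "contiguous"
    delay_grid: tuple[int, int] = (-8, 8)
    strong_threshold: float = 0.8
    weak_threshold: float = 0.5

    # sparse ODE discovery
    model_dim: int = 2                   # 2: (channel) states; 3: embedded coords
    sindy_degree: int = 2
    sindy_threshold: float = 0.05

    # Lyapunov
    lyap_max_periods: int = 20
    lyap_tolerance: float = 0.02         # absolute slope agreement floor

    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.weak_threshold < self.strong_threshold <= 1:
            raise ValueError(
                "thresholds must satisfy 0 < weak < strong <= 1, got "
                f"weak={self.weak_threshold}, strong={self.strong_threshold}"
            )
        if self.model_dim not in (2, 3):
            raise ValueError("model_dim must be 2 or 3")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class DiybotReport:
    """Machine-readable twin of the full analysis."""

    management_flag: str                 # self_correcting | intervention_advised | indeterminate
    halted_at: str | None
    stages: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "management_flag": self.management_flag,
            "halted_at": self.halted_at,
            "stages": _jsonable(self.stages),
            "provenance": _jsonable(self.provenance),
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, complex):
        return {"re": obj.real, "im": obj.imag}
    if dataclasses.is_dataclass(obj):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def run_diybot(config: PipelineConfig, ts: UniformTimeSeries | None = None) -> DiybotReport:
    """Execute the full logic flow; see module docstring for stage order.

    ``ts`` overrides ``config.input``; all randomness flows from
    ``config.seed``, so identical inputs give identical reports.
    """
    t_start = time.perf_counter()
    if ts is None:
        if config.input is None:
            raise ValueError("config.input is unset and no series was passed")
        ts = read_sensor_csv(config.input)
    ts = ts.select(list(config.channels))
    stages: dict = {}
    provenance = {
        "config": dataclasses.asdict(config),
        "config_hash": config.hash(),
        "seed": config.seed,
        "version": __version__,
    }

    def _report(flag: str, halted: str | None) -> DiybotReport:
        logger.info("pipeline done in %.2f s (flag=%s)", time.perf_counter() - t_start, flag)
        return DiybotReport(
            management_flag=flag, halted_at=halted,
            stages=stages, provenance=provenance,
        )

    # -- stage 1: aggregation ---------------------------------------------
    t0 = time.perf_counter()
    if config.block_duration > ts.step * (1 + 1e-9):
        blocks = aggregate_blocks(ts, config.block_duration)
    else:
        blocks = ts
    stages["aggregate"] = {
        "n_blocks": blocks.n,
        "block_duration_s": blocks.step,
        "input_samples": ts.n,
    }
    logger.info("aggregate: %d -> %d samples (%.2f s)", ts.n, blocks.n,
                time.perf_counter() - t0)

    # -- stage 2: SSA ------------------------------------------------------
    t0 = time.perf_counter()
    signal_cols = []
    ssa_summary = {}
    for ch in config.channels:
        decomp = ssa_group(
            ssa_decompose(blocks.single(ch), config.ssa_window),
            "wcorr",
            threshold=config.ssa_wcorr_threshold,
            max_components=config.ssa_max_components,
        )
        sig = np.zeros(blocks.n)
        strength = 0.0
        for label in decomp.groups:
            if label.startswith("signal"):
                sig += ssa_reconstruct(decomp, label).values[:, 0]
                strength += signal_strength(decomp, label)
        signal_cols.append(sig)
        ssa_summary[ch] = {
            "window_length": decomp.window_length,
            "signal_strength_pct": strength,
            "groups": {k: v for k, v in decomp.groups.items() if k != "noise"},
            "leading_singular_values": decomp.singular_values[:5],
        }
    signal_ts = UniformTimeSeries(
        np.column_stack(signal_cols), step=blocks.step,
        channels=list(config.channels), start_time=blocks.start_time,
    )
    stages["ssa"] = ssa_summary
    logger.info("ssa done (%.2f s)", time.perf_counter() - t0)

    # -- stage 3: stationarity gate ---------------------------------------
    t0 = time.perf_counter()
    stat_summary = {}
    all_stationary = True
    for ch in config.channels:
        res = nonlinear_cross_prediction(
            signal_ts.single(ch),
            n_segments=config.n_segments,
            threshold=config.stationarity_factor,
            error_floor=config.stationarity_error_floor,
        )
        stat_summary[ch] = {
            "stationary": res.stationary,
            "heterogeneity_score": res.heterogeneity_score,
            "error_matrix": res.error_matrix,
        }
        all_stationary &= res.stationary
    stages["stationarity"] = stat_summary
    logger.info("stationarity gate: %s (%.2f s)", all_stationary,
                time.perf_counter() - t0)
    if not all_stationary:
        return _report("indeterminate", "stationarity")

    # -- stage 4: surrogate gate ------------------------------------------
    t0 = time.perf_counter()
    surr_summary = {}
    all_reject = True
    for i, ch in enumerate(config.channels):
        res = surrogate_test(
            blocks.single(ch),
            statistic=config.surrogate_statistic,
            n_surrogates=config.n_surrogates,
            level=config.surrogate_level,
            seed=config.seed + 7919 * (i + 1),
        )
        surr_summary[ch] = {
            "statistic": res.statistic_name,
            "observed": res.observed_value,
            "rank_p": res.rank_p,
            "reject_linear_null": res.reject_linear_null,
        }
        all_reject &= res.reject_linear_null
    stages["surrogates"] = surr_summary
    logger.info("surrogate gate: %s (%.2f s)", all_reject, time.perf_counter() - t0)
    if not all_reject:
        return _report("indeterminate", "surrogates")

    # -- stage 5: embedding ------------------------------------------------
    t0 = time.perf_counter()
    ph, do = config.channels
    tau = config.tau if config.tau is not None else select_delay(signal_ts.single(do))
    if config.E is not None:
        E = config.E
    else:
        E = select_dimension(signal_ts.single(do), tau=tau, E_max=config.E_max)
        E = max(E, 2)
    coords = config.mixed_coordinates or [(do, 0), (do, tau), (ph, 0)]
    embedding = mixed_embed(signal_ts, coords)
    stages["embedding"] = {
        "tau": tau, "E": E, "coordinates": coords, "n_points": embedding.m,
    }
    logger.info("embedding: tau=%d E=%d (%.2f s)", tau, E, time.perf_counter() - t0)

    # -- stage 6: CCM ------------------------------------------------------
    t0 = time.perf_counter()
    x_ph = signal_ts.single(ph)
    x_do = signal_ts.single(do)
    dmin, dmax = config.delay_grid
    max_feasible = (embedding.m - E - 4) // 2
    delays = range(max(dmin, -max_feasible), min(dmax, max_feasible) + 1)
    common = dict(E=E, tau=tau, seed=config.seed)
    # "pH drives DO": DO's attractor cross-maps pH
    ccm_ph_do = ccm(x_do, x_ph, lib_sizes=config.lib_sizes,
                    n_draws=config.n_draws, sampling=config.ccm_sampling, **common)
    ccm_do_ph = ccm(x_ph, x_do, lib_sizes=config.lib_sizes,
                    n_draws=config.n_draws, sampling=config.ccm_sampling, **common)
    ext_ph_do = extended_ccm(x_do, x_ph, delays=delays, **common)
    ext_do_ph = extended_ccm(x_ph, x_do, delays=delays, **common)
    classification = classify_interaction(ccm_ph_do, ccm_do_ph, ext_ph_do, ext_do_ph)
    stages["ccm"] = {
        "classification": dataclasses.asdict(classification),
        "curves": {
            f"{r.driver}->{r.response}": {
                "lib_sizes": r.lib_sizes, "skill": r.skill,
                "rho_max": r.rho_max, "converged": r.converged,
            }
            for r in (ccm_ph_do, ccm_do_ph)
        },
        "extended": {
            f"{r.driver}->{r.response}": {
                "delays": r.delays, "skill": r.skill_by_delay,
                "peak_delay": r.peak_delay, "true_causal": r.true_causal,
            }
            for r in (ext_ph_do, ext_do_ph)
        },
    }
    logger.info("ccm: %s (%.2f s)", classification.summary, time.perf_counter() - t0)

    # -- stage 7: sparse ODE discovery ------------------------------------
    t0 = time.perf_counter()
    if config.model_dim == 2:
        state_names = [do, ph]
        states = np.column_stack([x_do.values[:, 0], x_ph.values[:, 0]])
    else:
        state_names = [f"{ch}_lag{lag}" if lag else ch for ch, lag in coords]
        states = embedding.points
    state_ts = UniformTimeSeries(states, step=1.0, channels=state_names)
    derivs = estimate_derivatives(state_ts)  # per block
    library = FunctionLibrary(state_names, degree=config.sindy_degree)
    model = sindy_fit(states, derivs, library, threshold=config.sindy_threshold)
    lo = states.min(axis=0)
    hi = states.max(axis=0)
    span = np.maximum(hi - lo, 1e-6)
    box = (lo - 0.5 * span, hi + 0.5 * span)
    equilibria = find_equilibria(model, box, seed=config.seed)
    stages["ode_model"] = {
        "state_names": state_names,
        "terms": library.term_names(),
        "coefficients": model.coefficients,
        "threshold": model.threshold,
        "residual_rms": model.residual_rms,
        "equations": model.equations(),
        "degenerate": model.degenerate,
        "n_equilibria": len(equilibria),
    }
    if model.degenerate or not equilibria:
        logger.info("ode discovery inconclusive (%.2f s)", time.perf_counter() - t0)
        return _report("indeterminate", "ode_discovery")
    # relevant equilibrium: the one the trajectory is heading toward
    eq = min(equilibria, key=lambda e: np.linalg.norm(e - states[-1]))
    analysis = eigen_classify(model, eq, tol=1e-4)
    stages["equilibrium"] = {
        "equilibrium": analysis.equilibrium,
        "eigenvalues": [complex(v) for v in analysis.eigenvalues],
        "classification": analysis.classification,
    }
    logger.info("ode: %s (%.2f s)", analysis.classification, time.perf_counter() - t0)

    # -- stage 8: Lyapunov correspondence + marginal impacts --------------
    t0 = time.perf_counter()
    model_traj = integrate_model(model, states[0], step=1.0, n_steps=states.shape[0])
    spec = NeighborSpec(k=1, theiler_window=tau * E)
    emp_embedding = mixed_embed(state_ts, [(state_names[0], j * tau) for j in range(E)])
    mod_embedding = mixed_embed(model_traj, [(state_names[0], j * tau) for j in range(E)])
    lyap_kwargs = dict(spec=spec, max_periods=min(config.lyap_max_periods,
                                                  emp_embedding.m // 4))
    lyap_emp = max_lyapunov(emp_embedding, **lyap_kwargs)
    lyap_mod = max_lyapunov(mod_embedding, **lyap_kwargs)
    tol = max(2.0 * float(np.hypot(lyap_emp.stderr, lyap_mod.stderr)),
              config.lyap_tolerance)
    corresponds = bool(abs(lyap_emp.slope - lyap_mod.slope) <= tol)
    impacts = {}
    for drv, rsp in ((state_names[1], state_names[0]), (state_names[0], state_names[1])):
        mi = marginal_impacts(model, model_traj, drv, rsp,
                              tol=1e-3 * max(1.0, float(np.abs(model.jacobian(eq)).max())))
        impacts[f"{drv}->{rsp}"] = {
            "initial": float(mi.values[0]),
            "final": float(mi.values[-1]),
            "decayed_to_zero_by": mi.decayed_to_zero_by,
        }
    stages["lyapunov"] = {
        "empirical_slope": lyap_emp.slope,
        "empirical_stderr": lyap_emp.stderr,
        "model_slope": lyap_mod.slope,
        "model_stderr": lyap_mod.stderr,
        "corresponds": corresponds,
        "tolerance": tol,
    }
    stages["marginal_impacts"] = impacts
    logger.info("lyapunov: emp=%.4f mod=%.4f corresponds=%s (%.2f s)",
                lyap_emp.slope, lyap_mod.slope, corresponds,
                time.perf_counter() - t0)

    # -- management flag ---------------------------------------------------
    is_sink = analysis.classification in ("spiral_sink", "node_sink")
    if is_sink and corresponds:
        flag = "self_correcting"
    elif not is_sink and corresponds:
        flag = "intervention_advised"
    else:
        flag = "indeterminate"
    return _report(flag, None)


def write_report(report: DiybotReport, directory: str | Path,
                 overwrite: bool = False) -> dict[str, Path]:
    """Write report.json, model.json, ccm_curves.csv and summary.txt."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    targets = {
        "report": directory / "report.json",
        "model": directory / "model.json",
        "ccm_curves": directory / "ccm_curves.csv",
        "summary": directory / "summary.txt",
    }
    existing = [p for p in targets.values() if p.exists()]
    if existing and not overwrite:
        raise FileExistsError(
            f"refusing to overwrite {existing[0]}; pass overwrite=True"
        )
    targets["report"].write_text(report.to_json() + "\n")

    model_stage = report.stages.get("ode_model")
    if model_stage is not None:
        targets["model"].write_text(
            json.dumps(_jsonable(model_stage), indent=2, sort_keys=True) + "\n"
        )
    else:
        targets.pop("model")

    ccm_stage = report.stages.get("ccm")
    if ccm_stage is not None:
        lines = ["direction,lib_size,skill"]
        for direction, curve in ccm_stage["curves"].items():
            for L, s in zip(curve["lib_sizes"], curve["skill"]):
                lines.append(f"{direction},{int(L)},{float(s):.6f}")
        targets["ccm_curves"].write_text("\n".join(lines) + "\n")
    else:
        targets.pop("ccm_curves")

    lines = [
        "DIYBOT analysis summary",
        "=======================",
        f"management flag: {report.management_flag}",
    ]
    if report.halted_at:
        lines.append(f"halted at gate: {report.halted_at}")
    if ccm_stage is not None:
        cls = ccm_stage["classification"]
        lines.append(f"causal interaction: {cls['summary']}")
        lines.append(
            f"  {cls['pair'][0]} drives {cls['pair'][1]}: {cls['a_drives_b']}; "
            f"{cls['pair'][1]} drives {cls['pair'][0]}: {cls['b_drives_a']}; "
            f"synchrony suspected: {cls['synchrony_suspected']}"
        )
    if model_stage is not None:
        lines.append("fitted equations:")
        lines.extend(f"  {eq}" for eq in model_stage["equations"])
    eq_stage = report.stages.get("equilibrium")
    if eq_stage is not None:
        lines.append(f"equilibrium classification: {eq_stage['classification']}")
    ly = report.stages.get("lyapunov")
    if ly is not None:
        lines.append(
            f"max Lyapunov: empirical {ly['empirical_slope']:.4f}, "
            f"model {ly['model_slope']:.4f}, corresponds: {ly['corresponds']}"
        )
    lines.append(f"config hash: {report.provenance['config_hash']}")
    targets["summary"].write_text("\n".join(lines) + "\n")
    return targets
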