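"""Synthetic sensor-like series with known dynamical structure.

Four generators cover the benchmarks the analysis stages need:

* a linear spiral-sink system (damped oscillatory approach to equilibrium),
* a two-channel sensor record with baseline harmonic oscillation and a
  damped post-shock response,
* unidirectionally/bidirectionally coupled logistic maps (causality
  benchmarks),
* a stationary Gaussian autoregressive null.

All generators are deterministic under a fixed seed and can dump their full
configuration to a sidecar JSON for provenance.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .timeseries import UniformTimeSeries

__all__ = [
    "SpiralSinkSystem",
    "SensorSimConfig",
    "CoupledMapConfig",
    "default_spiral_sink_matrix",
    "simulate_spiral_sink",
    "simulate_sensor_record",
    "simulate_coupled_logistic",
    "simulate_linear_stochastic",
    "write_provenance",
]


def default_spiral_sink_matrix() -> np.ndarray:
    """3x3 state matrix with eigenvalues {-0.5, -0.1 +/- 1j}.

    A rotating block paired with a fast real mode, conjugated by a fixed
    mixing matrix so that every observed channel carries all three modes.
    The eigenvalues are a documented stand-in (the study's fitted
    coefficients are not published); the dominant real part -0.1 sets the
    slow damped-oscillation envelope.
    """
    block = np.array(
        [
            [-0.1, 1.0, 0.0],
            [-1.0, -0.1, 0.0],
            [0.0, 0.0, -0.5],
        ]
    )
    mix = np.array(
        [
            [1.0, 0.2, 0.3],
            [-0.2, 1.0, 0.1],
            [0.1, -0.3, 1.0],
        ]
    )
    return mix @ block @ np.linalg.inv(mix)


@dataclass
class SpiralSinkSystem:
    """Linear system x' = A (x - x*) observed with additive sensor noise.

    ``step`` and the entries of ``state_matrix`` are expressed per hour.
    """

    state_matrix: np.ndarray = field(default_factory=default_spiral_sink_matrix)
    equilibrium: np.ndarray = field(
        default_factory=lambda: np.array([7.3, 178.0, 0.0])
    )
    initial_state: np.ndarray = field(
        default_factory=lambda: np.array([8.3, 190.0, 1.0])
    )
    step: float = 0.1
    n_steps: int = 1000
    noise_sd: float | np.ndarray = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.state_matrix = np.asarray(self.state_matrix, dtype=float)
        self.equilibrium = np.asarray(self.equilibrium, dtype=float)
        self.initial_state = np.asarray(self.initial_state, dtype=float)
        if self.state_matrix.shape != (3, 3):
            raise ValueError("state_matrix must be 3x3")
        if self.equilibrium.shape != (3,) or self.initial_state.shape != (3,):
            raise ValueError("equilibrium and initial_state must be 3-vectors")
        if not self.step > 0:
            raise ValueError(f"step must be > 0, got {self.step}")
        if self.n_steps < 2:
            raise ValueError(f"n_steps must be >= 2, got {self.n_steps}")
        eig = np.linalg.eigvals(self.state_matrix)
        worst = eig[np.argmax(eig.real)]
        if worst.real >= 0:
            raise ValueError(
                f"state_matrix is not a sink: eigenvalue {worst:.6g} has "
                "non-negative real part"
            )
        n_real = int(np.sum(np.abs(eig.imag) < 1e-12))
        if n_real != 1:
            raise ValueError(
                "state_matrix is not a spiral: expected exactly one real "
                f"eigenvalue and one conjugate pair, got eigenvalues {eig}"
            )

    @property
    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvals(self.state_matrix)


def _rk4_linear(A: np.ndarray, x_star: np.ndarray, x0: np.ndarray,
                step: float, n_steps: int) -> np.ndarray:
    """Fixed-step RK4 integration of x' = A (x - x*)."""
    out = np.empty((n_steps, x0.size))
    x = x0.astype(float).copy()
    out[0] = x
    for i in range(1, n_steps):
        d = x - x_star
        k1 = A @ d
        k2 = A @ (d + 0.5 * step * k1)
        k3 = A @ (d + 0.5 * step * k2)
        k4 = A @ (d + step * k3)
        x = x + (step / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        out[i] = x
    return out


def simulate_spiral_sink(system: SpiralSinkSystem) -> UniformTimeSeries:
    """Integrate the spiral-sink system; channels are named x1, x2, x3.

    The output step is ``system.step`` hours (stored in seconds).  With
    ``noise_sd = 0`` the trajectory is deterministic and matches the
    matrix-exponential closed form of the linear ODE.
    """
    traj = _rk4_linear(
        system.state_matrix,
        system.equilibrium,
        system.initial_state,
        system.step,
        system.n_steps,
    )
    noise_sd = np.broadcast_to(np.asarray(system.noise_sd, dtype=float), (3,))
    if np.any(noise_sd > 0):
        rng = np.random.default_rng(system.seed)
        traj = traj + rng.normal(0.0, 1.0, traj.shape) * noise_sd
    return UniformTimeSeries(
        values=traj,
        step=system.step * 3600.0,
        channels=["x1", "x2", "x3"],
    )


@dataclass
class SensorSimConfig:
    """Two-channel (pH, DO) sensor record emulator.

    Healthy operation oscillates harmonically around the baselines with
    minute-scale periods; at ``shock_time`` a contamination pulse displaces
    both channels, after which they relax as damped harmonic oscillators
    with an hours-scale period.  ``shock_time == duration`` disables the
    shock.  Units: periods of the fast baseline oscillation in minutes,
    shock periods / times / rates in hours, DO in micromolar.
    """

    baseline_ph: float = 7.3
    baseline_do: float = 178.0
    ph_period: float = 2.1        # minutes
    do_period: float = 2.9        # minutes
    osc_amplitude_ph: float = 0.2
    osc_amplitude_do: float = 4.0
    sample_rate: float = 100.0    # Hz
    shock_time: float = 0.0       # hours
    damping_rate: float = 0.1     # per hour, post-shock envelope
    shock_amplitude_ph: float = 0.5
    shock_amplitude_do: float = 20.0
    shock_period_ph: float = 50.0  # hours
    shock_period_do: float = 50.0  # hours
    duration: float = 1.0          # hours
    noise_sd_ph: float = 0.0
    noise_sd_do: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ph_period", "do_period", "shock_period_ph",
                     "shock_period_do", "sample_rate", "duration"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.shock_time <= self.duration:
            raise ValueError(
                f"shock_time must lie in [0, duration], got {self.shock_time}"
            )
        if self.damping_rate < 0:
            raise ValueError("damping_rate must be >= 0")


def simulate_sensor_record(config: SensorSimConfig) -> UniformTimeSeries:
    """Generate the pH/DO record described by ``config``.

    Pre-shock: baseline + fast sinusoid.  Post-shock: the fast oscillation
    and an added slow shock response share an exp(-damping_rate * t)
    envelope, so successive excursion peaks shrink while both channels
    relax back toward baseline.  The DO shock response lags pH by a
    quarter cycle (sine vs cosine).
    """
    n = int(round(config.duration * 3600.0 * config.sample_rate))
    if n < 2:
        raise ValueError("duration x sample_rate yields fewer than 2 samples")
    min_period_h = min(config.ph_period, config.do_period) / 60.0
    if config.duration < min_period_h:
        raise ValueError(
            f"duration {config.duration} h is shorter than one oscillation "
            f"period ({min_period_h:.4g} h)"
        )
    t_h = np.arange(n) / config.sample_rate / 3600.0  # hours
    t_min = t_h * 60.0

    fast_ph = config.osc_amplitude_ph * np.sin(2 * np.pi * t_min / config.ph_period)
    fast_do = config.osc_amplitude_do * np.sin(2 * np.pi * t_min / config.do_period)

    post = t_h >= config.shock_time
    no_shock = config.shock_time >= config.duration
    envelope = np.ones(n)
    slow_ph = np.zeros(n)
    slow_do = np.zeros(n)
    if not no_shock:
        dt = t_h[post] - config.shock_time
        envelope[post] = np.exp(-config.damping_rate * dt)
        slow_ph[post] = config.shock_amplitude_ph * np.cos(
            2 * np.pi * dt / config.shock_period_ph
        )
        slow_do[post] = config.shock_amplitude_do * np.sin(
            2 * np.pi * dt / config.shock_period_do
        )
    ph = config.baseline_ph + envelope * (fast_ph + slow_ph)
    do = config.baseline_do + envelope * (fast_do + slow_do)

    if config.noise_sd_ph > 0 or config.noise_sd_do > 0:
        rng = np.random.default_rng(config.seed)
        ph = ph + rng.normal(0.0, max(config.noise_sd_ph, 0.0), n)
        do = do + rng.normal(0.0, max(config.noise_sd_do, 0.0), n)

    return UniformTimeSeries(
        values=np.column_stack([ph, do]),
        step=1.0 / config.sample_rate,
        channels=["pH", "DO"],
    )


@dataclass
class CoupledMapConfig:
    """Coupled logistic maps, the canonical cross-mapping benchmark.

    x_{t+1} = x_t (r_x - r_x x_t - beta_xy y_t)
    y_{t+1} = y_t (r_y - r_y y_t - beta_yx x_t)

    ``beta_xy`` is the influence of y on x; ``beta_yx`` of x on y.
    """

    r_x: float = 3.8
    r_y: float = 3.5
    beta_xy: float = 0.0
    beta_yx: float = 0.1
    n: int = 1000
    burn_in: int = 100
    x0: float = 0.4
    y0: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.x0 < 1 and 0 < self.y0 < 1):
            raise ValueError("x0 and y0 must lie in (0, 1)")
        if not self.n > self.burn_in >= 0:
            raise ValueError("need n > burn_in >= 0")
        if self.beta_xy < 0 or self.beta_yx < 0:
            raise ValueError("coupling strengths must be >= 0")


def simulate_coupled_logistic(
    config: CoupledMapConfig,
) -> tuple[UniformTimeSeries, UniformTimeSeries]:
    """Iterate the coupled maps; burn-in is discarded.

    The maps are fully deterministic; ``seed`` only perturbs the initial
    condition by a tiny seeded jitter so that seed sweeps decorrelate
    trajectories without leaving (0, 1).
    """
    rng = np.random.default_rng(config.seed)
    jitter = rng.uniform(-1e-3, 1e-3, 2)
    x = float(np.clip(config.x0 + jitter[0], 1e-6, 1 - 1e-6))
    y = float(np.clip(config.y0 + jitter[1], 1e-6, 1 - 1e-6))
    total = config.n
    xs = np.empty(total)
    ys = np.empty(total)
    for t in range(total):
        xs[t], ys[t] = x, y
        x_next = x * (config.r_x - config.r_x * x - config.beta_xy * y)
        y_next = y * (config.r_y - config.r_y * y - config.beta_yx * x)
        if not (0 < x_next < 1 and 0 < y_next < 1):
            raise ValueError(
                f"trajectory escaped (0, 1) at step {t + 1}: "
                f"x={x_next:.6g}, y={y_next:.6g}"
            )
        x, y = x_next, y_next
    keep = slice(config.burn_in, total)
    ts_x = UniformTimeSeries(xs[keep], step=1.0, channels=["x"])
    ts_y = UniformTimeSeries(ys[keep], step=1.0, channels=["y"])
    return ts_x, ts_y


def simulate_linear_stochastic(
    ar_coefficients,
    noise_sd: float,
    n: int,
    seed: int = 0,
) -> UniformTimeSeries:
    """Gaussian AR(p) null series: x_t = sum_i a_i x_{t-i} + eps_t.

    Coefficients must define a stationary process (all characteristic
    roots outside the unit circle).
    """
    a = np.atleast_1d(np.asarray(ar_coefficients, dtype=float))
    if a.size == 0:
        raise ValueError("need at least one AR coefficient")
    # characteristic polynomial 1 - a1 z - ... - ap z^p; stationary iff
    # all roots |z| > 1
    roots = np.roots(np.concatenate(([1.0], -a))[::-1])
    if roots.size and np.min(np.abs(roots)) <= 1.0 + 1e-12:
        raise ValueError(
            f"non-stationary AR coefficients {a.tolist()}: characteristic "
            f"root of modulus {np.min(np.abs(roots)):.6g} <= 1"
        )
    if n < 2:
        raise ValueError("n must be >= 2")
    p = a.size
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
    x = np.zeros(n)
    for t in range(n):
        acc = eps[t]
        for i in range(min(p, t)):
            acc += a[i] * x[t - 1 - i]
        x[t] = acc
    return UniformTimeSeries(x, step=1.0, channels=["ar"])


def write_provenance(config, path: str | Path) -> Path:
    """Dump a generator's full configuration to a sidecar JSON."""
    path = Path(path)
    if dataclasses.is_dataclass(config):
        payload = dataclasses.asdict(config)
    else:
        payload = dict(config)
    payload = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v)
        for k, v in payload.items()
    }
    payload["_generator"] = type(config).__name__
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
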