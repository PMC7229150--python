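"""Sparse ODE discovery and stability diagnostics.

Sequentially thresholded least squares on a polynomial candidate library
recovers a sparse right-hand side dx/dt = Theta(x) Xi from states and
derivative estimates; the fitted model is then interrogated: equilibria by
multi-start Newton, eigenvalue classification of the Jacobian (spiral sink,
node sink, saddle, ...), marginal impacts as symbolic partial derivatives
evaluated along a trajectory, and regeneration of model attractors by RK4
integration for side-by-side comparison with the empirical ones.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import root

from .timeseries import UniformTimeSeries

__all__ = [
    "FunctionLibrary",
    "OdeModel",
    "EquilibriumAnalysis",
    "MarginalImpact",
    "estimate_derivatives",
    "sindy_fit",
    "integrate_model",
    "find_equilibria",
    "eigen_classify",
    "marginal_impacts",
]


@dataclass
class FunctionLibrary:
    """Monomial candidate terms up to a polynomial degree.

    Each term is an exponent tuple over the states, e.g. for states
    (u, v): () -> 1, (1, 0) -> u, (1, 1) -> u*v, (0, 2) -> v^2.  The
    constant term always comes first.
    """

    state_names: list[str]
    degree: int = 2
    exponents: list[tuple[int, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        d = len(self.state_names)
        if not self.exponents:
            self.exponents = [
                e
                for total in range(self.degree + 1)
                for e in sorted(
                    (e for e in itertools.product(range(total + 1), repeat=d)
                     if sum(e) == total),
                    reverse=True,
                )
            ]
        if self.exponents[0] != tuple([0] * d):
            raise ValueError("constant term must come first")
        if len(set(self.exponents)) != len(self.exponents):
            raise ValueError("duplicate library terms")

    @property
    def n_terms(self) -> int:
        return len(self.exponents)

    def term_names(self) -> list[str]:
        names = []
        for e in self.exponents:
            parts = []
            for s, p in zip(self.state_names, e):
                if p == 1:
                    parts.append(s)
                elif p > 1:
                    parts.append(f"{s}^{p}")
            names.append(" ".join(parts) if parts else "1")
        return names

    def evaluate(self, states: np.ndarray) -> np.ndarray:
        """Design matrix Theta: (m, d) states -> (m, p) monomial values."""
        states = np.atleast_2d(np.asarray(states, dtype=float))
        m, d = states.shape
        if d != len(self.state_names):
            raise ValueError(
                f"states have {d} columns; library expects {len(self.state_names)}"
            )
        theta = np.ones((m, self.n_terms))
        for j, e in enumerate(self.exponents):
            for i, p in enumerate(e):
                if p:
                    theta[:, j] *= states[:, i] ** p
        return theta

    def gradient(self, states: np.ndarray, wrt: int) -> np.ndarray:
        """d Theta / d x_wrt evaluated at states; shape (m, p)."""
        states = np.atleast_2d(np.asarray(states, dtype=float))
        m = states.shape[0]
        grad = np.zeros((m, self.n_terms))
        for j, e in enumerate(self.exponents):
            p = e[wrt]
            if p == 0:
                continue
            col = np.full(m, float(p))
            for i, q in enumerate(e):
                q_eff = q - 1 if i == wrt else q
                if q_eff:
                    col *= states[:, i] ** q_eff
            grad[:, j] = col
        return grad


@dataclass
class OdeModel:
    """Sparse right-hand side dx/dt = Theta(x) Xi."""

    library: FunctionLibrary
    coefficients: np.ndarray      # p x d (column per state equation)
    threshold: float
    residual_rms: np.ndarray      # per equation
    degenerate: bool = False      # True when an equation has no active terms

    @property
    def state_names(self) -> list[str]:
        return self.library.state_names

    def active_terms(self, equation: int) -> list[int]:
        return [int(i) for i in np.where(self.coefficients[:, equation] != 0)[0]]

    def rhs(self, x: np.ndarray) -> np.ndarray:
        """Evaluate dx/dt at one state or a batch of states."""
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        out = self.library.evaluate(np.atleast_2d(x)) @ self.coefficients
        return out[0] if single else out

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        """Analytic Jacobian of the library RHS at one state."""
        x = np.asarray(x, dtype=float)
        d = len(self.state_names)
        J = np.empty((d, d))
        for j in range(d):
            J[:, j] = (self.library.gradient(x, j) @ self.coefficients)[0]
        return J

    def equations(self) -> list[str]:
        """Human-readable rendering of each state equation."""
        names = self.library.term_names()
        lines = []
        for k, st in enumerate(self.state_names):
            terms = [
                f"{c:+.6g} {nm}" if nm != "1" else f"{c:+.6g}"
                for c, nm in zip(self.coefficients[:, k], names)
                if c != 0
            ]
            rhs = " ".join(terms) if terms else "0"
            lines.append(f"d{st}/dt = {rhs}")
        return lines


def estimate_derivatives(
    ts: UniformTimeSeries, method: str = "centered", smoother=None
) -> np.ndarray:
    """Finite-difference time derivatives of every channel.

    Centered differences on interior points, one-sided at the edges.
    ``smoother`` may pre-process the value matrix (e.g. an SSA signal
    reconstruction) before differencing.
    """
    if method != "centered":
        raise ValueError(f"unknown derivative method {method!r}")
    if ts.n < 5:
        raise ValueError(f"need at least 5 samples, got {ts.n}")
    vals = ts.values if smoother is None else np.asarray(smoother(ts.values))
    return np.gradient(vals, ts.step, axis=0)


def sindy_fit(
    states: np.ndarray,
    derivatives: np.ndarray,
    library: FunctionLibrary,
    threshold: float = 0.05,
    max_iter: int = 20,
    ridge: float = 0.0,
) -> OdeModel:
    """Sequentially thresholded least squares, per state equation.

    The design matrix is column-normalized before thresholding so the
    cutoff is scale-free; returned coefficients are on the original scale.
    Inactive terms are exactly zero; every surviving coefficient respects
    the threshold on the normalized scale.
    """
    states = np.asarray(states, dtype=float)
    derivatives = np.asarray(derivatives, dtype=float)
    if states.shape != derivatives.shape:
        raise ValueError(
            f"states {states.shape} and derivatives {derivatives.shape} differ"
        )
    m, d = states.shape
    theta = library.evaluate(states)
    p = theta.shape[1]
    if p >= m:
        raise ValueError(f"need more samples ({m}) than library terms ({p})")
    scale = np.linalg.norm(theta, axis=0)
    scale[scale == 0] = 1.0
    theta_n = theta / scale

    def solve(A: np.ndarray, b: np.ndarray, eq: int) -> np.ndarray:
        if ridge > 0:
            AtA = A.T @ A + ridge * np.eye(A.shape[1])
            cond = np.linalg.cond(AtA)
            if not np.isfinite(cond) or cond > 1e12:
                raise ValueError(
                    f"equation {eq}: active design matrix ill-conditioned "
                    f"(cond {cond:.3g})"
                )
            return np.linalg.solve(AtA, A.T @ b)
        sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
        if rank < A.shape[1]:
            raise ValueError(
                f"equation {eq}: active design matrix rank-deficient "
                f"(rank {rank} < {A.shape[1]}, cond "
                f"{np.linalg.cond(A):.3g})"
            )
        return sol

    xi = np.zeros((p, d))
    degenerate = False
    resid = np.empty(d)
    for k in range(d):
        b = derivatives[:, k]
        active = np.ones(p, dtype=bool)
        coef = solve(theta_n, b, k)
        for _ in range(max_iter):
            small = np.abs(coef) < threshold
            new_active = active.copy()
            new_active[np.where(active)[0][small[: active.sum()]]] = False
            # recompute on the active set
            coef_full = np.zeros(p)
            if new_active.any():
                sub = solve(theta_n[:, new_active], b, k)
                coef_full[new_active] = sub
            if new_active.sum() == active.sum() and np.array_equal(new_active, active):
                active = new_active
                coef = coef_full[new_active]
                break
            active = new_active
            coef = coef_full[new_active]
            if not active.any():
                break
        full = np.zeros(p)
        full[active] = coef
        # drop any below-threshold stragglers at the fixed point
        full[np.abs(full) < threshold] = 0.0
        xi[:, k] = full / scale
        resid[k] = float(np.sqrt(np.mean((theta @ xi[:, k] - b) ** 2)))
        if not np.any(full):
            degenerate = True
    return OdeModel(
        library=library,
        coefficients=xi,
        threshold=threshold,
        residual_rms=resid,
        degenerate=degenerate,
    )


def integrate_model(
    model: OdeModel,
    x0: np.ndarray,
    step: float,
    n_steps: int,
    norm_bound: float = 1e9,
) -> UniformTimeSeries:
    """Fixed-step RK4 integration of the fitted right-hand side.

    Halts with an error (reporting the step index) if the state norm
    exceeds ``norm_bound`` — a diverging fit, not a numerical issue.
    """
    x = np.asarray(x0, dtype=float).copy()
    d = len(model.state_names)
    if x.shape != (d,):
        raise ValueError(f"x0 must be a {d}-vector")
    out = np.empty((n_steps, d))
    out[0] = x
    for i in range(1, n_steps):
        k1 = model.rhs(x)
        k2 = model.rhs(x + 0.5 * step * k1)
        k3 = model.rhs(x + 0.5 * step * k2)
        k4 = model.rhs(x + step * k3)
        x = x + (step / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(x)) or np.linalg.norm(x) > norm_bound:
            raise RuntimeError(
                f"integration diverged at step {i} (|x| > {norm_bound:g})"
            )
        out[i] = x
    return UniformTimeSeries(out, step=step, channels=list(model.state_names))


def find_equilibria(
    model: OdeModel,
    search_box: tuple[np.ndarray, np.ndarray] | None = None,
    n_starts: int = 20,
    tol: float = 1e-8,
    seed: int = 0,
) -> list[np.ndarray]:
    """Multi-start Newton root finding on the RHS within a box.

    Roots closer than ``sqrt(tol)`` in infinity norm are merged; an empty
    list (no roots located) is a result, not an error.
    """
    d = len(model.state_names)
    if search_box is None:
        lo, hi = -np.ones(d) * 10.0, np.ones(d) * 10.0
    else:
        lo = np.asarray(search_box[0], dtype=float)
        hi = np.asarray(search_box[1], dtype=float)
    rng = np.random.default_rng(seed)
    starts = rng.uniform(lo, hi, size=(n_starts, d))
    starts[0] = 0.5 * (lo + hi)
    found: list[np.ndarray] = []
    merge_tol = max(np.sqrt(tol), 1e-6)
    for x0 in starts:
        sol = root(model.rhs, x0, jac=model.jacobian, method="hybr")
        if not sol.success:
            continue
        x = sol.x
        if np.linalg.norm(model.rhs(x)) >= tol:
            continue
        if np.any(x < lo - 1e-6) or np.any(x > hi + 1e-6):
            continue
        if any(np.max(np.abs(x - f)) < merge_tol * max(1.0, np.max(np.abs(f))) for f in found):
            continue
        found.append(x)
    return found


@dataclass
class EquilibriumAnalysis:
    equilibrium: np.ndarray
    jacobian: np.ndarray
    eigenvalues: np.ndarray
    classification: str  # spiral_sink | node_sink | saddle | source | center | other


def _classify_spectrum(eig: np.ndarray, imag_tol: float = 1e-9) -> str:
    re, im = eig.real, eig.imag
    has_pair = np.any(np.abs(im) > imag_tol)
    if np.all(re < -imag_tol):
        return "spiral_sink" if has_pair else "node_sink"
    if np.all(re > imag_tol):
        return "source"
    if np.any(re > imag_tol) and np.any(re < -imag_tol):
        return "saddle"
    if has_pair and np.all(np.abs(re) <= imag_tol):
        return "center"
    return "other"


def eigen_classify(model: OdeModel, equilibrium: np.ndarray,
                   tol: float = 1e-6) -> EquilibriumAnalysis:
    """Eigenvalues of the analytic Jacobian at an equilibrium, classified.

    A spiral sink is the signature of damped oscillatory self-correction:
    every real part negative with at least one conjugate complex pair.
    """
    equilibrium = np.asarray(equilibrium, dtype=float)
    res = np.linalg.norm(model.rhs(equilibrium))
    if res > tol:
        raise ValueError(
            f"point is not an equilibrium: |RHS| = {res:.3g} > tol {tol:g}"
        )
    J = model.jacobian(equilibrium)
    eig = np.linalg.eigvals(J)
    eig = eig[np.lexsort((eig.imag, eig.real))]
    return EquilibriumAnalysis(
        equilibrium=equilibrium,
        jacobian=J,
        eigenvalues=eig,
        classification=_classify_spectrum(eig),
    )


@dataclass
class MarginalImpact:
    driver: str
    response: str
    times: np.ndarray
    values: np.ndarray
    decayed_to_zero_by: float | None  # None = "not decayed"
    tol: float


def marginal_impacts(
    model: OdeModel,
    trajectory: UniformTimeSeries,
    driver: str,
    response: str,
    tol: float = 1e-3,
) -> MarginalImpact:
    """Partial derivative of the response equation w.r.t. the driver state,
    evaluated along a trajectory.

    Reports the impact series and the first time from which its magnitude
    stays below ``tol`` to the end of the trajectory ("decays to zero");
    ``decayed_to_zero_by`` is None when it never settles.
    """
    names = model.state_names
    for nm in (driver, response):
        if nm not in names:
            raise KeyError(f"unknown state {nm!r}; have {names}")
    j = names.index(driver)
    k = names.index(response)
    states = trajectory.select(names).values
    grad = model.library.gradient(states, j)  # m x p
    values = grad @ model.coefficients[:, k]
    below = np.abs(values) < tol
    decayed: float | None = None
    if below[-1]:
        # last index before which the magnitude still reached tol
        above = np.where(~below)[0]
        first = 0 if above.size == 0 else int(above[-1]) + 1
        decayed = float(first * trajectory.step)
    return MarginalImpact(
        driver=driver,
        response=response,
        times=trajectory.time(),
        values=values,
        decayed_to_zero_by=decayed,
        tol=tol,
    )
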