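"""Numerical integration of the four dynamical systems compared here.

* Lotka-Volterra abundances:      n_i' = n_i (r_i + (A n)_i)
* replicator frequencies:         x_i' = x_i ((A x)_i - x.Ax)
* coupled frequencies/total:      x_i' = x_i [(r_i - rbar) + N ((A x)_i - fbar)],
                                  N'   = N (rbar + N fbar)
* frequency-dependent abundances: n_i' = n_i (r_i + (A x)_i), x = n / sum(n)

The coupled system is the exact change of variables of the LV system to
(frequencies, total); when all growth rates are equal its frequency part
is a time-rescaled replicator flow, and ``check_equivalence`` measures
how far the LV frequencies stray from that prediction.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .core import (
    AbundanceState,
    CoupledState,
    DynamicalTerms,
    EcoGameSystem,
    FrequencyState,
    InteractionMatrix,
    LVGamesError,
    Trajectory,
)

__all__ = [
    "DEFAULT_RTOL",
    "DEFAULT_ATOL",
    "EXTINCTION_FLOOR",
    "ABUNDANCE_CEILING",
    "IntegrationError",
    "UnboundedDynamicsError",
    "dynamical_terms",
    "lv_derivative",
    "replicator_derivative",
    "integrate_lv",
    "integrate_replicator",
    "integrate_coupled",
    "integrate_lv_freqdep",
    "check_equivalence",
    "EquivalenceReport",
]

# Tight defaults: the neutral RPS orbits drift visibly under loose
# tolerances, and the closed-orbit / conserved-quantity checks need them.
DEFAULT_RTOL = 1e-10
DEFAULT_ATOL = 1e-12
EXTINCTION_FLOOR = 1e-9
ABUNDANCE_CEILING = 1e6
DEFAULT_METHOD = "DOP853"


class IntegrationError(LVGamesError):
    """Integration failed; ``time`` is the time of failure."""

    def __init__(self, message: str, time: float | None = None):
        super().__init__(message)
        self.time = time


class UnboundedDynamicsError(IntegrationError):
    """Abundances exceeded the ceiling: the system is diverging."""


def _state_array(state, cls) -> np.ndarray:
    if isinstance(state, cls):
        return np.asarray(state.n if cls is AbundanceState else state.x, float)
    return np.atleast_1d(np.asarray(state, float))


def dynamical_terms(A: InteractionMatrix | np.ndarray, x, r=None) -> DynamicalTerms:
    """Game fitnesses f_i = (A x)_i, mean fitness x.f and mean growth rate x.r."""
    Am = np.asarray(A, float)
    xv = _state_array(x, FrequencyState)
    f = Am @ xv
    f_bar = float(xv @ f)
    r_bar = float(xv @ np.asarray(r, float)) if r is not None else 0.0
    return DynamicalTerms(f=f, f_bar=f_bar, r_bar=r_bar)


def lv_derivative(sys: EcoGameSystem, state) -> np.ndarray:
    """Right-hand side of the Lotka-Volterra equations at an abundance state."""
    n = _state_array(state, AbundanceState)
    if n.shape[0] != sys.dim:
        raise LVGamesError("state dimension does not match the system")
    return n * (sys.rates + sys.matrix @ n)


def replicator_derivative(A: InteractionMatrix | np.ndarray, state) -> np.ndarray:
    """Replicator right-hand side x_i (f_i - fbar); sums to zero on the simplex."""
    Am = np.asarray(A, float)
    x = _state_array(state, FrequencyState)
    if x.shape[0] != Am.shape[0]:
        raise LVGamesError("state dimension does not match the matrix")
    terms = dynamical_terms(Am, x)
    return x * (terms.f - terms.f_bar)


def _freqdep_derivative(sys: EcoGameSystem, n: np.ndarray) -> np.ndarray:
    total = n.sum()
    if total <= 0:
        return np.zeros_like(n)
    return n * (sys.rates + sys.matrix @ (n / total))


def _solve(rhs, y0, t_end, tol, *, events=None, n_points, method=DEFAULT_METHOD):
    sol = solve_ivp(
        rhs,
        (0.0, float(t_end)),
        np.asarray(y0, float),
        method=method,
        rtol=tol,
        atol=DEFAULT_ATOL,
        dense_output=True,
        events=events,
    )
    if sol.status == -1:
        raise IntegrationError(f"integration failed: {sol.message}", time=float(sol.t[-1]))
    times = np.linspace(0.0, float(sol.t[-1]), n_points)
    return sol, times


def integrate_lv(
    sys: EcoGameSystem,
    n0,
    t_end: float,
    tol: float = DEFAULT_RTOL,
    *,
    floor: float = EXTINCTION_FLOOR,
    ceiling: float = ABUNDANCE_CEILING,
    n_points: int = 1001,
    method: str = DEFAULT_METHOD,
) -> Trajectory:
    """Integrate the Lotka-Volterra abundances.

    Abundances below ``floor`` are clamped to exactly 0 in the returned
    samples (never mid-step, which would distort near-boundary cycles).
    Crossing ``ceiling`` raises :class:`UnboundedDynamicsError` with the
    crossing time.
    """
    n0 = _state_array(n0, AbundanceState)
    if np.any(n0 < 0):
        raise LVGamesError("initial abundances must be nonnegative")
    if t_end <= 0:
        raise LVGamesError("t_end must be positive")

    def rhs(t, n):
        nn = np.maximum(n, 0.0)
        return nn * (sys.rates + sys.matrix @ nn)

    def hit_ceiling(t, n):
        return float(np.max(n) - ceiling)

    hit_ceiling.terminal = True
    hit_ceiling.direction = 1

    sol, times = _solve(rhs, n0, t_end, tol, events=hit_ceiling, n_points=n_points, method=method)
    if sol.status == 1:  # terminated by the ceiling event
        t_fail = float(sol.t_events[0][0])
        raise UnboundedDynamicsError(
            f"abundances exceeded {ceiling:g} at t={t_fail:.6g}: unbounded", time=t_fail)
    values = np.maximum(sol.sol(times).T, 0.0)
    values[values < floor] = 0.0
    return Trajectory(times, values, "lv", system=sys, dense=sol.sol,
                      node_times=sol.t, node_values=sol.y.T)


def _normalized_replicator_rhs(Am: np.ndarray):
    # Evaluating the field at x / sum(x) makes the simplex-sum exactly
    # stationary; the raw field is transversally unstable whenever the
    # mean payoff is negative.
    def rhs(t, x):
        s = x.sum()
        y = x / s if s > 0 else x
        f = Am @ y
        return y * (f - y @ f)

    return rhs


def integrate_replicator(
    A: InteractionMatrix | np.ndarray,
    x0,
    t_end: float,
    tol: float = DEFAULT_RTOL,
    *,
    n_points: int = 1001,
    method: str = DEFAULT_METHOD,
) -> Trajectory:
    """Integrate the replicator dynamics on the simplex."""
    Am = np.asarray(A, float)
    x0 = _state_array(x0, FrequencyState)
    if abs(x0.sum() - 1.0) > 1e-9:
        raise LVGamesError("initial frequencies must lie on the simplex")
    sol, times = _solve(_normalized_replicator_rhs(Am), x0, t_end, tol,
                        n_points=n_points, method=method)
    values = sol.sol(times).T
    defect = np.abs(values.sum(axis=1) - 1.0).max()
    if defect > 1e-9:
        raise IntegrationError(f"simplex defect {defect:.3g} exceeds 1e-9")
    values = np.clip(values, 0.0, None)
    values /= values.sum(axis=1, keepdims=True)
    sys = A if isinstance(A, EcoGameSystem) else None
    return Trajectory(times, values, "replicator", system=sys, dense=sol.sol)


def integrate_coupled(
    sys: EcoGameSystem,
    c0: CoupledState,
    t_end: float,
    tol: float = DEFAULT_RTOL,
    *,
    n_points: int = 1001,
    method: str = DEFAULT_METHOD,
) -> Trajectory:
    """Integrate the coupled (frequency, total-abundance) system.

    For two types this is exactly the textbook frequency equation
    x1' = N x1 x2 [(r1 - r2)/N + f1 - f2]; for m types the frequency part
    is x_i' = x_i [(r_i - rbar) + N (f_i - fbar)] with N' = N (rbar + N fbar).
    """
    if not isinstance(c0, CoupledState):
        c0 = CoupledState.from_abundances(c0)
    Am, rv = sys.matrix, sys.rates
    y0 = np.append(c0.x.x, c0.N)

    def rhs(t, y):
        x, N = y[:-1], y[-1]
        s = x.sum()
        xs = x / s if s > 0 else x
        f = Am @ xs
        f_bar = xs @ f
        r_bar = xs @ rv
        dx = xs * ((rv - r_bar) + N * (f - f_bar))
        dN = N * (r_bar + N * f_bar)
        return np.append(dx, dN)

    sol, times = _solve(rhs, y0, t_end, tol, n_points=n_points, method=method)
    values = sol.sol(times).T
    x_part = np.clip(values[:, :-1], 0.0, None)
    x_part /= x_part.sum(axis=1, keepdims=True)
    values = np.column_stack([x_part, values[:, -1]])
    return Trajectory(times, values, "coupled", system=sys, dense=sol.sol)


def integrate_lv_freqdep(
    sys: EcoGameSystem,
    n0,
    t_end: float,
    tol: float = DEFAULT_RTOL,
    *,
    n_points: int = 1001,
    method: str = DEFAULT_METHOD,
) -> Trajectory:
    """Integrate abundances whose interactions depend on frequencies, not densities."""
    n0 = _state_array(n0, AbundanceState)
    if n0.sum() <= 0:
        raise LVGamesError("total initial abundance must be positive")

    def rhs(t, n):
        return _freqdep_derivative(sys, np.maximum(n, 0.0))

    def total_collapse(t, n):
        return float(n.sum() - 1e-12)

    total_collapse.terminal = True
    total_collapse.direction = -1

    sol, times = _solve(rhs, n0, t_end, tol, events=total_collapse, n_points=n_points,
                        method=method)
    values = np.maximum(sol.sol(times).T, 0.0)
    return Trajectory(times, values, "lv_freqdep", system=sys, dense=sol.sol)


@dataclass(frozen=True)
class EquivalenceReport:
    """Outcome of comparing LV frequencies with the time-rescaled replicator flow."""

    max_orbit_deviation: float
    equivalent: bool
    threshold: float = 1e-6


def check_equivalence(
    sys: EcoGameSystem,
    n0,
    t_end: float,
    tol: float = DEFAULT_RTOL,
    *,
    n_points: int = 2001,
) -> EquivalenceReport:
    """Test whether the replicator equation reproduces the LV frequency dynamics.

    The LV system is integrated and its frequencies x_LV(t) recorded; the
    replicator flow for the same matrix is then integrated under the time
    change dtau/dt = N(t) (total abundance interpolated from the dense LV
    solution), i.e. as the non-autonomous system x' = N(t) x (f - fbar).
    The report carries the maximum pointwise deviation; the two flows are
    declared equivalent below 1e-6.  Equality of the intrinsic growth
    rates is exactly the condition under which this holds.
    """
    n0 = _state_array(n0, AbundanceState)
    lv = integrate_lv(sys, n0, t_end, tol, n_points=n_points, floor=0.0)
    total0 = n0.sum()
    if total0 <= 0:
        return EquivalenceReport(0.0, True)
    x0 = n0 / total0
    Am = sys.matrix
    dense = lv.dense

    def rhs(t, x):
        s = x.sum()
        y = x / s if s > 0 else x
        f = Am @ y
        N = float(np.maximum(dense(t), 0.0).sum())
        return N * y * (f - y @ f)

    sol, times = _solve(rhs, x0, lv.times[-1], tol, n_points=n_points)
    x_resc = sol.sol(lv.times).T
    x_resc = np.clip(x_resc, 0.0, None)
    x_resc /= x_resc.sum(axis=1, keepdims=True)
    x_lv = lv.frequencies()
    dev = float(np.nanmax(np.abs(x_lv - x_resc)))
    return EquivalenceReport(max_orbit_deviation=dev, equivalent=dev < 1e-6)
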