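"""Fixed points, linear stability, and invasion fitness for LV systems.

Fixed points are enumerated by support: for every subset S of types the
linear system r_i + sum_{j in S} a_ij n_j = 0 is solved on S and kept if
the solution is strictly positive on S.  Each equilibrium carries the
eigenvalues of the full Jacobian and a stability label.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .core import EcoGameSystem, LVGamesError
from .dynamics import lv_derivative

__all__ = ["Stability", "Equilibrium", "jacobian", "fixed_points", "invasion_fitness"]

log = logging.getLogger(__name__)

#: eigenvalue real-part tolerance separating stable / neutral / unstable;
#: chosen so that the purely-imaginary pair at the symmetric RPS interior
#: is labelled neutral under floating-point error
STABILITY_TOL = 1e-8

RESIDUAL_TOL = 1e-10
MAX_SUPPORT_DIM = 10


class Stability(Enum):
    STABLE = "STABLE"
    UNSTABLE = "UNSTABLE"
    SADDLE = "SADDLE"
    NEUTRAL = "NEUTRAL"


@dataclass(frozen=True)
class Equilibrium:
    """A steady state of the LV system with its linearization."""

    n: np.ndarray
    support: frozenset[int]
    eigenvalues: np.ndarray
    stability: Stability
    residual: float

    def __post_init__(self):
        n = np.atleast_1d(np.asarray(self.n, float))
        n.setflags(write=False)
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "support", frozenset(self.support))

    @property
    def is_stable(self) -> bool:
        return self.stability is Stability.STABLE

    @property
    def is_interior(self) -> bool:
        return len(self.support) == self.n.shape[0]


def jacobian(sys: EcoGameSystem, n) -> np.ndarray:
    """Jacobian of the LV vector field: J_ik = d_ik (r_i + (A n)_i) + n_i a_ik.

    At an interior equilibrium the diagonal growth term vanishes and the
    Jacobian reduces to diag(n) A.
    """
    n = np.atleast_1d(np.asarray(n, float))
    A, r = sys.matrix, sys.rates
    return np.diag(r + A @ n) + n[:, None] * A


def _stability_label(eigenvalues: np.ndarray, tol: float = STABILITY_TOL) -> Stability:
    re = eigenvalues.real
    if re.max() < -tol:
        return Stability.STABLE
    if abs(re.max()) <= tol:
        return Stability.NEUTRAL
    if re.min() < -tol:
        return Stability.SADDLE
    return Stability.UNSTABLE


def _make_equilibrium(sys: EcoGameSystem, n: np.ndarray, support) -> Equilibrium:
    eig = np.linalg.eigvals(jacobian(sys, n))
    residual = float(np.abs(lv_derivative(sys, n)).max())
    return Equilibrium(n=n, support=frozenset(support), eigenvalues=eig,
                       stability=_stability_label(eig), residual=residual)


def fixed_points(sys: EcoGameSystem, *, feasibility_tol: float = 1e-12) -> list[Equilibrium]:
    """All feasible fixed points of the LV system, one per viable support.

    The origin is always included.  Supports whose restricted interaction
    matrix is singular are skipped with a logged note.  Support
    enumeration is exponential and capped at 10 types.
    """
    m = sys.dim
    if m > MAX_SUPPORT_DIM:
        raise LVGamesError(f"support enumeration is 2^m; refusing m={m} > {MAX_SUPPORT_DIM}")
    A, r = sys.matrix, sys.rates
    out = [_make_equilibrium(sys, np.zeros(m), frozenset())]
    for size in range(1, m + 1):
        for support in itertools.combinations(range(m), size):
            idx = np.array(support)
            sub = A[np.ix_(idx, idx)]
            try:
                n_s = np.linalg.solve(sub, -r[idx])
            except np.linalg.LinAlgError:
                log.info("singular support system for support %s; skipped", support)
                continue
            if np.any(n_s <= feasibility_tol):
                continue
            n = np.zeros(m)
            n[idx] = n_s
            eq = _make_equilibrium(sys, n, support)
            if eq.residual > RESIDUAL_TOL:
                log.warning("discarding candidate on support %s with residual %.3g",
                            support, eq.residual)
                continue
            out.append(eq)
    return out


def invasion_fitness(sys: EcoGameSystem, resident_eq: Equilibrium, invader: int) -> float:
    """Per-capita growth rate of a rare invader at the resident equilibrium.

    Positive fitness means the invader grows deterministically from a low
    inoculum: r_inv + sum_j a_inv,j n_hat_j.
    """
    if invader in resident_eq.support:
        raise LVGamesError(f"type {invader} is already in the resident support")
    if not 0 <= invader < sys.dim:
        raise LVGamesError(f"invader index {invader} out of range")
    return float(sys.rates[invader] + sys.matrix[invader] @ resident_eq.n)
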