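"""Stepwise community assembly by sequential rare introductions.

Types are introduced one at a time at a low inoculum into a fully relaxed
resident community (mutations/migrations are rare, so ecological and
introduction timescales are strictly separated).  After each
introduction the community is relaxed until it reaches a fixed point or
settles onto a sustained oscillation; types falling below the extinction
floor are pruned.  ``can_assemble`` searches introduction orders for one
that builds a target community — e.g. a full cyclic-dominance triplet,
which cannot be assembled when growth rates are equal but can be when
one rate is sufficiently different.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .core import EcoGameSystem, LVGamesError
from .dynamics import UnboundedDynamicsError, integrate_lv, lv_derivative
from .equilibria import Equilibrium, _make_equilibrium, invasion_fitness

__all__ = [
    "AssemblyParams",
    "Regime",
    "RelaxResult",
    "AssemblyStep",
    "AssemblyRecord",
    "CanAssembleResult",
    "relax",
    "assemble",
    "can_assemble",
]

STEADY_TOL = 1e-8
STEADY_WINDOW = 5.0
#: a supported type must oscillate with at least this relative amplitude
#: for the window to count as a cycle
CYCLE_MIN_REL_AMPLITUDE = 1e-3


class Regime(Enum):
    FIXED_POINT = "FIXED_POINT"
    CYCLE = "CYCLE"
    EXTINCT = "EXTINCT"
    INDETERMINATE = "INDETERMINATE"


@dataclass(frozen=True)
class AssemblyParams:
    """Introduction and relaxation protocol parameters.

    inoculum: abundance at which a new type arrives (must exceed the
    extinction floor); relax_time: integration horizon per step, doubled
    once if neither a fixed point nor a cycle is detected; cycle_window:
    trailing window inspected for sustained oscillation.
    """

    inoculum: float = 1e-6
    extinction_floor: float = 1e-9
    relax_time: float = 500.0
    cycle_window: float = 100.0

    def __post_init__(self):
        if not self.inoculum > self.extinction_floor > 0:
            raise LVGamesError("need inoculum > extinction_floor > 0")
        if self.relax_time <= self.cycle_window:
            raise LVGamesError("relax_time must exceed cycle_window")


@dataclass(frozen=True)
class RelaxResult:
    """Relaxed community: representative state, support, and dynamical regime.

    For a cycle the state is the time average over the detection window
    and ``window_min``/``window_max`` bracket the oscillation.
    """

    state: np.ndarray
    support: frozenset[int]
    regime: Regime
    window_min: np.ndarray | None = None
    window_max: np.ndarray | None = None


@dataclass(frozen=True)
class AssemblyStep:
    introduced: int
    invasion_fitness: float | None  # None when the resident is cycling
    support: frozenset[int]
    regime: Regime


@dataclass
class AssemblyRecord:
    steps: list[AssemblyStep] = field(default_factory=list)
    final_state: np.ndarray | None = None
    final_support: frozenset[int] = frozenset()
    final_regime: Regime = Regime.EXTINCT


@dataclass(frozen=True)
class CanAssembleResult:
    possible: bool
    witness_order: tuple[int, ...] | None


def _prune(n: np.ndarray, floor: float) -> np.ndarray:
    out = n.copy()
    out[out < floor] = 0.0
    return out


def relax(sys: EcoGameSystem, n0, p: AssemblyParams | None = None) -> RelaxResult:
    """Integrate until the community settles, and report how it settled.

    A fixed point is declared when the derivative stays below 1e-8 (sup
    norm) over the trailing 5 time units; otherwise the trailing
    ``cycle_window`` is inspected: if every surviving type stays above the
    extinction floor and oscillates with non-decaying amplitude, the
    regime is a cycle.  One doubling of ``relax_time`` is attempted before
    giving up as indeterminate.
    """
    if p is None:
        p = AssemblyParams()
    n0 = np.atleast_1d(np.asarray(n0, float))
    if np.all(n0 <= 0):
        return RelaxResult(np.zeros(sys.dim), frozenset(), Regime.EXTINCT)

    T = p.relax_time
    for _attempt in range(2):
        traj = integrate_lv(sys, n0, T, floor=0.0, n_points=max(2001, int(T)))
        dense = traj.dense

        # fixed point: derivative small over the trailing window, checked at
        # the solver's own step nodes (dense-output derivatives wiggle at
        # ~10x the integration tolerance and would mask a true steady state)
        in_window = traj.node_times >= T - STEADY_WINDOW
        tail = np.maximum(traj.node_values[in_window], 0.0)
        deriv = np.abs([lv_derivative(sys, row) for row in tail]).max(axis=1)
        if deriv.max() < STEADY_TOL:
            state = _prune(np.maximum(dense(T), 0.0), p.extinction_floor)
            support = frozenset(np.flatnonzero(state > 0).tolist())
            regime = Regime.FIXED_POINT if support else Regime.EXTINCT
            return RelaxResult(state, support, regime)

        # cycle: sustained, non-decaying oscillation above the floor
        ts_win = np.linspace(T - p.cycle_window, T, 2001)
        Y = np.maximum(dense(ts_win), 0.0)
        lo, hi, mean = Y.min(axis=1), Y.max(axis=1), Y.mean(axis=1)
        alive = lo > p.extinction_floor
        dying = (~alive) & (hi > p.extinction_floor)
        if alive.any() and not dying.any():
            half = ts_win.size // 2
            amp1 = Y[:, :half].max(axis=1) - Y[:, :half].min(axis=1)
            amp2 = Y[:, half:].max(axis=1) - Y[:, half:].min(axis=1)
            rel_amp = np.where(mean > 0, (hi - lo) / np.maximum(mean, 1e-300), 0.0)
            oscillating = alive & (rel_amp > CYCLE_MIN_REL_AMPLITUDE)
            sustained = np.all(amp2[oscillating] > 0.5 * amp1[oscillating]) \
                if oscillating.any() else False
            if oscillating.any() and sustained:
                state = np.where(alive, mean, 0.0)
                return RelaxResult(state, frozenset(np.flatnonzero(alive).tolist()),
                                   Regime.CYCLE,
                                   window_min=np.where(alive, lo, 0.0),
                                   window_max=np.where(alive, hi, 0.0))
        T *= 2.0

    state = _prune(np.maximum(dense(traj.times[-1]), 0.0), p.extinction_floor)
    support = frozenset(np.flatnonzero(state > 0).tolist())
    return RelaxResult(state, support, Regime.INDETERMINATE)


def _resident_equilibrium(sys: EcoGameSystem, res: RelaxResult) -> Equilibrium:
    return _make_equilibrium(sys, res.state, res.support)


def assemble(sys: EcoGameSystem, order, p: AssemblyParams | None = None) -> AssemblyRecord:
    """Introduce types in ``order`` one at a time, relaxing fully in between.

    Invasion fitness is recorded against the pre-introduction community
    when it is at a fixed point (or empty), and as None against a cycle.
    A type whose single-species growth rate is nonpositive and that
    arrives into an empty community dies out immediately.
    """
    if p is None:
        p = AssemblyParams()
    order = tuple(int(i) for i in order)
    if len(set(order)) != len(order):
        raise LVGamesError("introduction order must not repeat types")
    if order and not all(0 <= i < sys.dim for i in order):
        raise LVGamesError("introduction order contains an out-of-range type index")

    record = AssemblyRecord()
    current = RelaxResult(np.zeros(sys.dim), frozenset(), Regime.EXTINCT)
    for idx in order:
        if idx in current.support:
            raise LVGamesError(f"type {idx} is already resident")
        if current.regime is Regime.CYCLE:
            fitness = None
        elif not current.support:
            fitness = float(sys.rates[idx])
        else:
            fitness = invasion_fitness(sys, _resident_equilibrium(sys, current), idx)
        if not current.support and sys.rates[idx] <= 0:
            # cannot establish alone: n' = r n + a_ii n^2 <= a_ii n^2 < 0
            step_res = RelaxResult(np.zeros(sys.dim), frozenset(), Regime.EXTINCT)
        else:
            n0 = current.state.copy()
            n0[idx] = p.inoculum
            step_res = relax(sys, n0, p)
        record.steps.append(AssemblyStep(idx, fitness, step_res.support, step_res.regime))
        current = step_res
    record.final_state = current.state
    record.final_support = current.support
    record.final_regime = current.regime
    return record


def can_assemble(sys: EcoGameSystem, target_support, p: AssemblyParams | None = None,
                 ) -> CanAssembleResult:
    """Exhaustively search introduction orders that build ``target_support``.

    Orders over every subset of the pool containing the target are tried
    (smallest subsets first); the first order whose final support covers
    the target is returned as witness.
    """
    if sys.dim > 8:
        raise LVGamesError("exhaustive order search is factorial; pool capped at 8")
    target = frozenset(int(i) for i in target_support)
    if not all(0 <= i < sys.dim for i in target):
        raise LVGamesError("target support contains an out-of-range type index")
    pool = range(sys.dim)
    extras = [i for i in pool if i not in target]
    for k in range(len(extras) + 1):
        for added in itertools.combinations(extras, k):
            members = tuple(sorted(target)) + added
            for order in itertools.permutations(members):
                try:
                    rec = assemble(sys, order, p)
                except UnboundedDynamicsError:
                    continue
                if target <= rec.final_support:
                    return CanAssembleResult(True, order)
    return CanAssembleResult(False, None)
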