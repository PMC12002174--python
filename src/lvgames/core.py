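"""Domain types for ecological game systems.

A model is an interaction matrix ``A`` (entry ``a_ij`` is the per-capita
effect of type *j* on the growth rate of type *i*; row = affected type,
column = acting type) together with a vector of intrinsic growth rates
``r`` (per-capita growth when rare and free of all interactions).  The
same matrix doubles as a game payoff matrix when read through the
replicator lens, which is exactly the identification this package is
about.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LVGamesError",
    "InteractionMatrix",
    "GrowthRateVector",
    "EcoGameSystem",
    "AbundanceState",
    "FrequencyState",
    "CoupledState",
    "DynamicalTerms",
    "HawkDoveParams",
    "RPSParams",
    "Trajectory",
    "hawk_dove_matrix",
    "rps_matrix",
    "example_system",
    "EXAMPLE_SYSTEMS",
    "sample_bounded_system",
    "canonical_game_order",
]

SIMPLEX_TOL = 1e-12

# orientation statement written into every serialized system file
MATRIX_ORIENTATION = "row=affected,column=acting"


class LVGamesError(Exception):
    """Base class for errors raised by lvgames."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise LVGamesError(f"{name} must contain only finite values")
    return arr


@dataclass(frozen=True)
class InteractionMatrix:
    """Square matrix of per-capita interaction coefficients.

    In Lotka-Volterra use the entries carry units 1/(time*abundance); in
    replicator use they are dimensionless payoffs.  Row = affected type,
    column = acting type.
    """

    entries: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self):
        entries = _as_float_array(self.entries, "interaction matrix")
        if entries.ndim != 2 or entries.shape[0] != entries.shape[1]:
            raise LVGamesError("interaction matrix must be square")
        labels = tuple(self.labels) or tuple(f"T{i + 1}" for i in range(entries.shape[0]))
        if len(labels) != entries.shape[0]:
            raise LVGamesError("label count must equal matrix dimension")
        entries.setflags(write=False)
        object.__setattr__(self, "entries", entries)
        object.__setattr__(self, "labels", labels)

    @property
    def dim(self) -> int:
        return self.entries.shape[0]

    def __array__(self, dtype=None, copy=None):
        return np.array(self.entries, dtype=dtype)


@dataclass(frozen=True)
class GrowthRateVector:
    """Intrinsic per-capita growth rates, units 1/time."""

    r: np.ndarray

    def __post_init__(self):
        r = np.atleast_1d(_as_float_array(self.r, "growth rates"))
        r.setflags(write=False)
        object.__setattr__(self, "r", r)

    @property
    def dim(self) -> int:
        return self.r.shape[0]

    def __array__(self, dtype=None, copy=None):
        return np.array(self.r, dtype=dtype)


@dataclass(frozen=True)
class EcoGameSystem:
    """An interaction matrix paired with growth rates: n_i' = n_i (r_i + sum_j a_ij n_j)."""

    A: InteractionMatrix
    r: GrowthRateVector

    def __post_init__(self):
        if self.A.dim != self.r.dim:
            raise LVGamesError("matrix and growth-rate dimensions disagree")

    @classmethod
    def from_arrays(cls, matrix, rates, labels=()) -> "EcoGameSystem":
        return cls(InteractionMatrix(np.asarray(matrix, float), tuple(labels)),
                   GrowthRateVector(np.asarray(rates, float)))

    @property
    def dim(self) -> int:
        return self.A.dim

    @property
    def matrix(self) -> np.ndarray:
        return self.A.entries

    @property
    def rates(self) -> np.ndarray:
        return self.r.r

    @property
    def labels(self) -> tuple[str, ...]:
        return self.A.labels


@dataclass(frozen=True)
class AbundanceState:
    """Nonnegative absolute abundances at a time point."""

    n: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        n = np.atleast_1d(_as_float_array(self.n, "abundances"))
        if np.any(n < 0):
            raise LVGamesError("abundances must be nonnegative")
        n.setflags(write=False)
        object.__setattr__(self, "n", n)

    @property
    def total(self) -> float:
        return float(self.n.sum())


@dataclass(frozen=True)
class FrequencyState:
    """A point on the probability simplex at a time point."""

    x: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        x = np.atleast_1d(_as_float_array(self.x, "frequencies"))
        if np.any(x < 0):
            raise LVGamesError("frequencies must be nonnegative")
        if abs(x.sum() - 1.0) > SIMPLEX_TOL:
            raise LVGamesError(f"frequencies must sum to 1 within {SIMPLEX_TOL}")
        x.setflags(write=False)
        object.__setattr__(self, "x", x)


@dataclass(frozen=True)
class CoupledState:
    """Frequencies plus total abundance N = sum_i n_i."""

    x: FrequencyState
    N: float

    def __post_init__(self):
        if not (self.N > 0 and np.isfinite(self.N)):
            raise LVGamesError("total abundance N must be positive and finite")

    @classmethod
    def from_abundances(cls, n, t: float = 0.0) -> "CoupledState":
        n = np.atleast_1d(np.asarray(n, float))
        total = n.sum()
        if total <= 0:
            raise LVGamesError("total abundance must be positive")
        return cls(FrequencyState(n / total, t=t), float(total))

    @property
    def abundances(self) -> np.ndarray:
        return self.x.x * self.N


@dataclass(frozen=True)
class DynamicalTerms:
    """Game fitnesses f_i = (A x)_i, mean fitness and mean growth rate."""

    f: np.ndarray
    f_bar: float
    r_bar: float

    def __post_init__(self):
        f = np.atleast_1d(_as_float_array(self.f, "fitnesses"))
        f.setflags(write=False)
        object.__setattr__(self, "f", f)
        if not (f.min() - 1e-12 <= self.f_bar <= f.max() + 1e-12):
            raise LVGamesError("mean fitness must lie within [min f, max f]")


@dataclass(frozen=True)
class HawkDoveParams:
    """Benefit b and cost of escalated conflict c, with c > b > 0."""

    b: float
    c: float

    def __post_init__(self):
        if not (self.c > self.b > 0):
            raise LVGamesError("Hawk-Dove requires c > b > 0")


@dataclass(frozen=True)
class RPSParams:
    """Single payoff scale alpha > 0 for the cyclic game: winning +alpha, losing -alpha,
    on top of a uniform self-limitation of -1."""

    alpha: float

    def __post_init__(self):
        if not self.alpha > 0:
            raise LVGamesError("RPS requires alpha > 0")


@dataclass
class Trajectory:
    """Time series of states produced by one of the integrators.

    ``values`` has one row per time point; columns follow the system's
    type order (plus a trailing total-abundance column for the coupled
    dynamics).  ``dynamics_kind`` is one of {"lv", "replicator",
    "coupled", "lv_freqdep"}.
    """

    times: np.ndarray
    values: np.ndarray
    dynamics_kind: str
    system: EcoGameSystem | None = None
    dense: object = field(default=None, repr=False, compare=False)
    #: raw solver step nodes (times, states); exact to the integration
    #: tolerance, unlike dense-output samples whose derivatives wiggle
    node_times: np.ndarray | None = field(default=None, repr=False, compare=False)
    node_values: np.ndarray | None = field(default=None, repr=False, compare=False)

    KINDS = ("lv", "replicator", "coupled", "lv_freqdep")

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.values = np.asarray(self.values, float)
        if self.dynamics_kind not in self.KINDS:
            raise LVGamesError(f"unknown dynamics kind {self.dynamics_kind!r}")
        if np.any(np.diff(self.times) <= 0):
            raise LVGamesError("trajectory times must be strictly increasing")
        if self.values.shape[0] != self.times.shape[0]:
            raise LVGamesError("times and values must align")

    @property
    def final(self) -> np.ndarray:
        return self.values[-1]

    def frequencies(self) -> np.ndarray:
        """Per-time-point relative abundances x_i = n_i / sum_j n_j."""
        if self.dynamics_kind == "replicator":
            return self.values
        if self.dynamics_kind == "coupled":
            return self.values[:, :-1]
        totals = self.values.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, self.values / totals, np.nan)


# ---------------------------------------------------------------------------
# named game matrices


def hawk_dove_matrix(p: HawkDoveParams | None = None, *, b: float | None = None,
                     c: float | None = None) -> InteractionMatrix:
    """Payoff matrix of the Hawk-Dove conflict game.

    Two Doves split the benefit b, a Dove meeting a Hawk retreats with 0
    while the Hawk takes b, and two Hawks fight for an expected payoff of
    (b - c)/2 < 0.
    """
    if p is None:
        p = HawkDoveParams(b=b, c=c)
    return InteractionMatrix(
        np.array([[(p.b - p.c) / 2.0, p.b], [0.0, p.b / 2.0]]),
        ("Hawk", "Dove"),
    )


def rps_matrix(p: RPSParams | float) -> InteractionMatrix:
    """Symmetric Rock-Paper-Scissors interaction matrix with bounded growth.

    Every type limits itself at rate -1; winning against another type
    adds +alpha and losing subtracts alpha, so e.g. the effect of Scissors
    on Rock is -1 + alpha (Rock beats Scissors).
    """
    if not isinstance(p, RPSParams):
        p = RPSParams(float(p))
    a = p.alpha
    m = np.array([
        [-1.0, -1.0 - a, -1.0 + a],
        [-1.0 + a, -1.0, -1.0 - a],
        [-1.0 - a, -1.0 + a, -1.0],
    ])
    return InteractionMatrix(m, ("R", "P", "S"))


# ---------------------------------------------------------------------------
# built-in example systems

_PD_MATRIX = np.array([[-3.0, -5.0], [1.0, -4.0]])
_PD_LABELS = ("cooperator", "defector")


def _pd(rates) -> EcoGameSystem:
    return EcoGameSystem.from_arrays(_PD_MATRIX, rates, _PD_LABELS)


def _rps(rates) -> EcoGameSystem:
    A = rps_matrix(1.3)
    return EcoGameSystem(A, GrowthRateVector(np.asarray(rates, float)))


#: Built-in parameter sets.  The generalized Prisoner's Dilemma matrix
#: (a11=-3, a12=-5, a21=1, a22=-4) is paired with four growth-rate regimes;
#: the two RPS systems use alpha=1.3 with equal rates and with Rock sped up.
EXAMPLE_SYSTEMS = {
    "pd_equal": lambda: _pd((1.0, 1.0)),
    "pd_mild_advantage": lambda: _pd((1.5, 1.0)),
    "pd_mixed_rates": lambda: _pd((1.0, -1.0)),
    "pd_declining": lambda: _pd((-0.5, -1.0)),
    "pd_coexistence": lambda: _pd((2.0, 1.0)),
    "rps_equal": lambda: _rps((1.0, 1.0, 1.0)),
    "rps_fast_rock": lambda: _rps((2.5, 1.0, 1.0)),
}


def example_system(name: str) -> EcoGameSystem:
    """Return one of the built-in example systems by name."""
    try:
        return EXAMPLE_SYSTEMS[name]()
    except KeyError:
        known = ", ".join(sorted(EXAMPLE_SYSTEMS))
        raise LVGamesError(f"unknown example system {name!r}; known: {known}") from None


# ---------------------------------------------------------------------------
# canonical ordering and random sampling


def canonical_game_order(A: InteractionMatrix) -> tuple[InteractionMatrix, tuple[int, ...], bool]:
    """Reorder a 2-type matrix so that a11 >= a22.

    Returns (reordered matrix, permutation applied, tie flag).  The
    permutation maps new index -> original index; ties keep user order
    and are flagged.
    """
    if A.dim != 2:
        raise LVGamesError("canonical game ordering is defined for 2-type matrices")
    a = A.entries
    if a[0, 0] == a[1, 1]:
        return A, (0, 1), True
    if a[0, 0] > a[1, 1]:
        return A, (0, 1), False
    perm = (1, 0)
    idx = np.array(perm)
    reordered = InteractionMatrix(a[np.ix_(idx, idx)], tuple(A.labels[i] for i in perm))
    return reordered, perm, False


def sample_bounded_system(
    seed: int,
    dim: int = 2,
    *,
    rate_regime: str = "positive",
    diag_range: tuple[float, float] = (-5.0, -0.5),
    offdiag_range: tuple[float, float] = (-5.0, 5.0),
    rate_range: tuple[float, float] = (0.2, 3.0),
    max_attempts: int = 10_000,
    rng: np.random.Generator | None = None,
) -> EcoGameSystem:
    """Draw a random bounded 2-type system, deterministically from ``seed``.

    Diagonal entries are drawn from ``diag_range`` (negative: each type is
    self-limiting), off-diagonals from ``offdiag_range``, rejecting draws
    with a12*a21 >= a11*a22 so every returned system is bounded.  The
    matrix is put in canonical order (a11 > a22).  ``rate_regime`` selects
    the sign pattern of the growth rates: "positive" (both in
    ``rate_range``), "mixed" (r1 > 0 > r2) or "negative" (0 > r1 > r2).
    """
    if dim != 2:
        raise LVGamesError("only 2-type sampling is supported")
    if rng is None:
        rng = np.random.default_rng(seed)
    lo, hi = rate_range
    if not 0 < lo < hi:
        raise LVGamesError("rate_range must be positive and increasing")
    for _ in range(max_attempts):
        diag = rng.uniform(*diag_range, size=2)
        off = rng.uniform(*offdiag_range, size=2)
        if off[0] * off[1] >= diag[0] * diag[1]:
            continue
        if diag[0] == diag[1]:  # measure zero, but keep the contract strict
            continue
        if diag[0] < diag[1]:
            diag = diag[::-1]
            off = off[::-1]
        if rate_regime == "positive":
            rates = rng.uniform(lo, hi, size=2)
        elif rate_regime == "mixed":
            rates = np.array([rng.uniform(lo, hi), -rng.uniform(lo, hi)])
        elif rate_regime == "negative":
            draw = -rng.uniform(lo, hi, size=2)
            rates = np.sort(draw)[::-1]
            if rates[0] == rates[1]:
                continue
        else:
            raise LVGamesError(f"unknown rate_regime {rate_regime!r}")
        A = np.array([[diag[0], off[0]], [off[1], diag[1]]])
        return EcoGameSystem.from_arrays(A, rates)
    raise LVGamesError(f"failed to sample a bounded system in {max_attempts} attempts")


def iter_bounded_systems(seed: int, count: int, **kwargs):
    """Yield ``count`` independent bounded systems from a single seeded stream."""
    rng = np.random.default_rng(seed)
    for _ in range(count):
        yield sample_bounded_system(0, rng=rng, **kwargs)
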