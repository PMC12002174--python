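"""Outcome classification of two-type systems with unequal growth rates.

Three lenses on the same interaction matrix:

* the classic game quadrants (signs of a21 - a11 and a12 - a22, under the
  canonical ordering a11 >= a22), valid only when growth rates are equal;
* the ecological interaction type (signs of the off-diagonals);
* the dynamical outcome of the full LV system, where unequal rates shift
  the quadrant boundaries from (a11, a22) to (a11 r2/r1, a22 r1/r2).

Each boundary inequality is exactly the condition that the rare type
grows at the other type's single-species equilibrium (mutual
invasibility), which is what assigns the dominance direction.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .core import EcoGameSystem, InteractionMatrix, LVGamesError, canonical_game_order

__all__ = [
    "OutcomeClass",
    "GameClass",
    "EcologicalInteractionClass",
    "RegionBoundaries",
    "OutcomeReport",
    "GameReport",
    "DegenerateClassificationError",
    "is_bounded",
    "can_diverge",
    "classify_game",
    "game_report",
    "classify_ecology",
    "classification_boundaries",
    "classify_outcome",
    "outcome_report",
    "critical_r1",
    "achievable_outcomes",
]

#: comparisons closer than this to a region boundary are non-generic
DEGENERACY_EPS = 1e-9


class OutcomeClass(Enum):
    DOMINANCE_1 = "DOMINANCE_1"
    DOMINANCE_2 = "DOMINANCE_2"
    COEXISTENCE = "COEXISTENCE"
    BISTABILITY = "BISTABILITY"
    EXTINCTION_BOTH = "EXTINCTION_BOTH"
    UNBOUNDED = "UNBOUNDED"


class GameClass(Enum):
    PRISONERS_DILEMMA = "PRISONERS_DILEMMA"
    HARMONY = "HARMONY"
    COEXISTENCE_GAME = "COEXISTENCE_GAME"
    COORDINATION = "COORDINATION"


class EcologicalInteractionClass(Enum):
    MUTUALISM = "MUTUALISM"
    COMPETITION = "COMPETITION"
    EXPLOITATION = "EXPLOITATION"
    NEUTRAL_EDGE = "NEUTRAL_EDGE"


class DegenerateClassificationError(LVGamesError):
    """The system sits on a classification boundary (measure-zero case)."""


@dataclass(frozen=True)
class RegionBoundaries:
    """Growth-rate-shifted region boundaries in the (a12, a21) plane.

    a21_threshold = a11 r2/r1 (horizontal line), a12_threshold = a22 r1/r2
    (vertical line); at r1 = r2 these reduce to (a11, a22).
    """

    a21_threshold: float
    a12_threshold: float


@dataclass(frozen=True)
class GameReport:
    game_class: GameClass | None
    permutation: tuple[int, ...]
    degenerate: bool
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class OutcomeReport:
    outcome: OutcomeClass
    degenerate: bool = False
    flags: tuple[str, ...] = ()
    boundaries: RegionBoundaries | None = None


def _matrix(A) -> np.ndarray:
    m = np.asarray(A.entries if isinstance(A, InteractionMatrix) else A, float)
    if m.shape != (2, 2):
        raise LVGamesError("classification is defined for 2-type matrices")
    return m


def is_bounded(sys: EcoGameSystem) -> bool:
    """Both self-limitation conditions (a11 < 0, a22 < 0) and a12 a21 < a11 a22."""
    if sys.dim != 2:
        raise LVGamesError("is_bounded is defined for 2-type systems")
    a = sys.matrix
    return bool(a[0, 0] < 0 and a[1, 1] < 0 and a[0, 1] * a[1, 0] < a[0, 0] * a[1, 1])


def can_diverge(A) -> bool:
    """True if some trajectory with positive abundances can blow up.

    Divergence requires a non-self-limiting type or a mutualism strong
    enough that a12 a21 >= a11 a22 with both off-diagonals positive;
    strong competition violates the product condition too but stays
    bounded.
    """
    a = _matrix(A)
    if a[0, 0] >= 0 or a[1, 1] >= 0:
        return True
    return bool(a[0, 1] > 0 and a[1, 0] > 0 and a[0, 1] * a[1, 0] >= a[0, 0] * a[1, 1])


def game_report(A: InteractionMatrix | np.ndarray) -> GameReport:
    """Classify the 2x2 game, recording the canonical permutation applied."""
    if not isinstance(A, InteractionMatrix):
        A = InteractionMatrix(_matrix(A))
    canon, perm, tie = canonical_game_order(A)
    a = canon.entries
    flags = []
    if tie:
        flags.append("DEGENERATE: a11 == a22, canonical ordering undefined")
    if a[1, 0] == a[0, 0]:
        flags.append("DEGENERATE: a21 == a11")
    if a[0, 1] == a[1, 1]:
        flags.append("DEGENERATE: a12 == a22")
    if flags:
        return GameReport(None, perm, True, tuple(flags))
    if a[1, 0] > a[0, 0]:
        cls = GameClass.PRISONERS_DILEMMA if a[0, 1] < a[1, 1] else GameClass.COEXISTENCE_GAME
    else:
        cls = GameClass.COORDINATION if a[0, 1] < a[1, 1] else GameClass.HARMONY
    return GameReport(cls, perm, False)


def classify_game(A: InteractionMatrix | np.ndarray) -> GameClass:
    """Game quadrant under canonical ordering; raises on boundary ties."""
    rep = game_report(A)
    if rep.degenerate:
        raise DegenerateClassificationError("; ".join(rep.flags))
    return rep.game_class


def classify_ecology(A: InteractionMatrix | np.ndarray) -> EcologicalInteractionClass:
    """Ecological interaction type from the signs of (a12, a21)."""
    a = _matrix(A)
    a12, a21 = a[0, 1], a[1, 0]
    if a12 == 0 or a21 == 0:
        return EcologicalInteractionClass.NEUTRAL_EDGE
    if a12 > 0 and a21 > 0:
        return EcologicalInteractionClass.MUTUALISM
    if a12 < 0 and a21 < 0:
        return EcologicalInteractionClass.COMPETITION
    return EcologicalInteractionClass.EXPLOITATION


def classification_boundaries(A, r) -> RegionBoundaries:
    """Region boundaries shifted by the growth-rate ratio (positive rates only)."""
    a = _matrix(A)
    r = np.atleast_1d(np.asarray(r, float))
    if r.shape[0] != 2:
        raise LVGamesError("two growth rates required")
    if r[0] <= 0 or r[1] <= 0:
        raise LVGamesError("boundary formulas are valid only for positive growth rates")
    return RegionBoundaries(a21_threshold=a[0, 0] * r[1] / r[0],
                            a12_threshold=a[1, 1] * r[0] / r[1])


def outcome_report(sys: EcoGameSystem, *, eps: float = DEGENERACY_EPS) -> OutcomeReport:
    """Dynamical outcome of a bounded 2-type system, with degeneracy flags.

    With both rates positive the verdict follows the two invasion
    inequalities a21 > a11 r2/r1 (type 2 invades type 1) and
    a12 > a22 r1/r2 (type 1 invades type 2): both -> coexistence, neither
    -> bistability, exactly one -> dominance of the successful invader.
    With one nonpositive rate only the positive-rate type persists alone,
    and the other type either invades it (coexistence) or not (dominance);
    with both rates nonpositive only extinction is possible.
    """
    if sys.dim != 2:
        raise LVGamesError("classify_outcome is defined for 2-type systems")
    a, r = sys.matrix, sys.rates
    flags: list[str] = []
    if can_diverge(a):
        return OutcomeReport(OutcomeClass.UNBOUNDED, False, (), None)

    r1, r2 = float(r[0]), float(r[1])
    if abs(r1) <= eps or abs(r2) <= eps:
        flags.append("DEGENERATE: growth rate within eps of 0")

    if r1 > eps and r2 > eps:
        b = classification_boundaries(a, r)
        g2 = a[1, 0] - b.a21_threshold  # invasion margin of type 2
        g1 = a[0, 1] - b.a12_threshold  # invasion margin of type 1
        for name, g in (("a21 - a11 r2/r1", g2), ("a12 - a22 r1/r2", g1)):
            if abs(g) <= eps:
                flags.append(f"DEGENERATE: {name} within eps of 0")
        if g2 > 0 and g1 > 0:
            out = OutcomeClass.COEXISTENCE
        elif g2 <= 0 and g1 <= 0:
            out = OutcomeClass.BISTABILITY
        elif g2 > 0:
            out = OutcomeClass.DOMINANCE_2
        else:
            out = OutcomeClass.DOMINANCE_1
        return OutcomeReport(out, bool(flags), tuple(flags), b)

    if r1 > eps:  # r1 > 0 >= r2
        phi2 = r2 + a[1, 0] * (-r1 / a[0, 0])  # invasion fitness of 2 at (n1_hat, 0)
        if abs(phi2) <= eps:
            flags.append("DEGENERATE: invasion fitness of type 2 within eps of 0")
        out = OutcomeClass.COEXISTENCE if phi2 > 0 else OutcomeClass.DOMINANCE_1
        return OutcomeReport(out, bool(flags), tuple(flags), None)

    if r2 > eps:  # r2 > 0 >= r1, mirror case
        phi1 = r1 + a[0, 1] * (-r2 / a[1, 1])
        if abs(phi1) <= eps:
            flags.append("DEGENERATE: invasion fitness of type 1 within eps of 0")
        out = OutcomeClass.COEXISTENCE if phi1 > 0 else OutcomeClass.DOMINANCE_2
        return OutcomeReport(out, bool(flags), tuple(flags), None)

    return OutcomeReport(OutcomeClass.EXTINCTION_BOTH, bool(flags), tuple(flags), None)


def classify_outcome(sys: EcoGameSystem, *, eps: float = DEGENERACY_EPS) -> OutcomeClass:
    """Dynamical outcome class of a 2-type system (see :func:`outcome_report`)."""
    return outcome_report(sys, eps=eps).outcome


def critical_r1(A, r2: float) -> float:
    """Smallest growth-rate advantage turning dominance of type 2 into coexistence.

    For a matrix in which type 1 cannot invade at equal rates (a12 < a22
    < 0), the invasion condition a12 > a22 r1/r2 flips at
    r1 = r2 a12/a22; above that ratio the two types coexist.
    """
    a = _matrix(A)
    problems = []
    if not a[1, 1] < 0:
        problems.append("a22 must be negative (type 2 self-limiting)")
    if not r2 > 0:
        problems.append("r2 must be positive")
    if not a[0, 1] < a[1, 1]:
        problems.append("a12 < a22 required (type 1 cannot invade at equal rates)")
    if problems:
        raise LVGamesError("; ".join(problems))
    return float(r2 * a[0, 1] / a[1, 1])


def achievable_outcomes(A) -> dict[OutcomeClass, tuple[float, float]]:
    """Every outcome reachable by tuning (r1, r2), with one witness rate pair.

    For positive rates the outcome depends only on the ratio rho = r1/r2
    through the two invasion margins; their sign changes at
    rho1 = a11/a21 (finite only for a21 < 0) and rho2 = a12/a22 (positive
    only for a12 < 0) carve (0, inf) into at most three outcome
    intervals.  Dominance of either type is always reachable through the
    mixed-sign rate regimes, and joint extinction through negative rates.
    Each witness is re-checked through :func:`classify_outcome`.
    """
    a = _matrix(A)
    if a[0, 0] >= 0 or a[1, 1] >= 0:
        raise LVGamesError("achievable_outcomes requires self-limiting types (a11, a22 < 0)")
    if a[0, 1] > 0 and a[1, 0] > 0 and a[0, 1] * a[1, 0] >= a[0, 0] * a[1, 1]:
        raise LVGamesError("mutualism too strong: unbounded for every choice of rates")

    rho1 = a[0, 0] / a[1, 0] if a[1, 0] < 0 else math.inf
    rho2 = a[0, 1] / a[1, 1] if a[0, 1] < 0 else 0.0

    witnesses: dict[OutcomeClass, tuple[float, float]] = {}
    witnesses[OutcomeClass.EXTINCTION_BOTH] = (-0.5, -1.0)

    n1_hat = -1.0 / a[0, 0]  # single-type equilibrium of 1 at r1 = 1
    witnesses[OutcomeClass.DOMINANCE_1] = (1.0, -(1.0 + abs(a[1, 0]) * n1_hat))
    n2_hat = -1.0 / a[1, 1]
    witnesses[OutcomeClass.DOMINANCE_2] = (-(1.0 + abs(a[0, 1]) * n2_hat), 1.0)

    if rho2 < rho1:  # coexistence interval (rho2, rho1)
        if math.isinf(rho1):
            rho = 1.0 if rho2 == 0.0 else 2.0 * rho2
        else:
            rho = 0.5 * (rho2 + rho1)
        witnesses[OutcomeClass.COEXISTENCE] = (rho, 1.0)
    if rho1 < rho2:  # bistability interval (rho1, rho2)
        witnesses[OutcomeClass.BISTABILITY] = (0.5 * (rho1 + rho2), 1.0)

    out = {}
    for cls, rates in witnesses.items():
        check = classify_outcome(EcoGameSystem.from_arrays(a, rates))
        if check is not cls:  # pragma: no cover - guards the derivation
            raise LVGamesError(
                f"internal witness check failed: expected {cls}, classifier says {check}")
        out[cls] = rates
    return out
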