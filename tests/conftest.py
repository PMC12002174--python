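import numpy as np
import pytest
from scipy.integrate import solve_ivp

from lvgames import example_system


@pytest.fixture
def pd_equal():
    return example_system("pd_equal")


@pytest.fixture
def pd_coexistence():
    return example_system("pd_coexistence")


@pytest.fixture
def rps_equal():
    return example_system("rps_equal")


@pytest.fixture
def rps_fast_rock():
    return example_system("rps_fast_rock")


def simulate_outcome(sys, *, t_max=1e7):
    """Independent long-run simulation verdict for a bounded 2-type system.

    Integrates from four starts (each boundary equilibrium plus a rare
    other type, and two generic interior starts) until every type is
    either vanishingly rare or per-capita settled, then reads off the
    surviving support.  Uses scipy directly so the verdict shares no code
    with the algebraic classifier it cross-checks.
    """
    A, r = sys.matrix, sys.rates
    delta = 1e-4
    n1_hat = -r[0] / A[0, 0]
    n2_hat = -r[1] / A[1, 1]
    starts = [(delta, n2_hat), (n1_hat, delta), (0.1, 0.1), (1.0, 1.0)]

    def rhs(t, n):
        nn = np.maximum(n, 0.0)
        return nn * (r + A @ nn)

    supports = []
    for n0 in starts:
        n = np.asarray(n0, float)
        t, chunk = 0.0, 200.0
        while t < t_max:
            sol = solve_ivp(rhs, (0.0, chunk), n, method="LSODA", rtol=1e-9, atol=1e-12)
            n = np.maximum(sol.y[:, -1], 0.0)
            t += chunk
            chunk *= 2.0
            percap = r + A @ n
            resolved = (n < 1e-7) | (np.abs(percap * n) < 1e-10) | (np.abs(percap) < 1e-7)
            if resolved.all():
                break
        supports.append(frozenset(np.flatnonzero(n > 1e-5).tolist()))
    distinct = set(supports)
    if distinct == {frozenset({0, 1})}:
        return "COEXISTENCE"
    if distinct == {frozenset({0})}:
        return "DOMINANCE_1"
    if distinct == {frozenset({1})}:
        return "DOMINANCE_2"
    if distinct == {frozenset({0}), frozenset({1})}:
        return "BISTABILITY"
    if distinct == {frozenset()}:
        return "EXTINCTION_BOTH"
    return f"AMBIGUOUS:{sorted(map(sorted, distinct))}"


def margin_ok(sys, margin=1e-3):
    """Exclude systems within ``margin`` of a classification threshold."""
    a, r = sys.matrix, sys.rates
    if abs(r[0]) <= margin or abs(r[1]) <= margin:
        return False
    if r[0] > 0 and r[1] > 0:
        g2 = a[1, 0] - a[0, 0] * r[1] / r[0]
        g1 = a[0, 1] - a[1, 1] * r[0] / r[1]
        return abs(g2) > margin and abs(g1) > margin
    if r[0] > 0:
        return abs(r[1] + a[1, 0] * (-r[0] / a[0, 0])) > margin
    if r[1] > 0:
        return abs(r[0] + a[0, 1] * (-r[1] / a[1, 1])) > margin
    return abs(r[0] - r[1]) > margin
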