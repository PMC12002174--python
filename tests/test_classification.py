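import numpy as np
import pytest

from lvgames import (
    DegenerateClassificationError,
    EcoGameSystem,
    EcologicalInteractionClass,
    GameClass,
    LVGamesError,
    OutcomeClass,
    achievable_outcomes,
    classification_boundaries,
    classify_ecology,
    classify_game,
    classify_outcome,
    critical_r1,
    example_system,
    game_report,
    integrate_lv,
    is_bounded,
    iter_bounded_systems,
    outcome_report,
)

PD = np.array([[-3.0, -5.0], [1.0, -4.0]])


class TestIsBounded:
    def test_pd_example_is_bounded(self, pd_equal):
        assert is_bounded(pd_equal)  # -5*1 = -5 < 12

    def test_strong_mutualism_is_not(self):
        s = EcoGameSystem.from_arrays([[-0.5, 1.0], [1.0, -0.5]], [1.0, 1.0])
        assert not is_bounded(s)

    def test_positive_self_interaction_is_never_bounded(self):
        s = EcoGameSystem.from_arrays([[0.1, -1.0], [-1.0, -2.0]], [1.0, 1.0])
        assert not is_bounded(s)


class TestClassifyGame:
    def test_pd_matrix(self):
        assert classify_game(PD) is GameClass.PRISONERS_DILEMMA

    def test_comparisons_are_against_a22_not_zero(self):
        # a12 = -3.5 is negative yet exceeds a22 = -4: harmony, not coordination
        assert classify_game([[-3.0, -3.5], [-4.0, -4.0]]) is GameClass.HARMONY

    @pytest.mark.parametrize("A,expected", [
        ([[-3.0, -3.0], [1.0, -4.0]], GameClass.COEXISTENCE_GAME),
        ([[-3.0, -5.0], [-4.5, -4.0]], GameClass.COORDINATION),
    ])
    def test_remaining_quadrants(self, A, expected):
        assert classify_game(A) is expected

    def test_boundary_tie_is_degenerate(self):
        with pytest.raises(DegenerateClassificationError):
            classify_game([[-3.0, -4.0], [-3.0, -4.0]])
        rep = game_report([[-3.0, -4.0], [-3.0, -4.0]])
        assert rep.degenerate and rep.game_class is None

    def test_permutation_recorded_for_reordered_input(self):
        rep = game_report([[-4.0, 1.0], [-5.0, -3.0]])
        assert rep.permutation == (1, 0)
        assert rep.game_class is GameClass.PRISONERS_DILEMMA


class TestClassifyEcology:
    @pytest.mark.parametrize("a12,a21,expected", [
        (-5.0, 1.0, EcologicalInteractionClass.EXPLOITATION),
        (0.2, 0.3, EcologicalInteractionClass.MUTUALISM),
        (-0.2, -0.3, EcologicalInteractionClass.COMPETITION),
        (0.0, -1.0, EcologicalInteractionClass.NEUTRAL_EDGE),
    ])
    def test_sign_quadrants(self, a12, a21, expected):
        assert classify_ecology([[-1.0, a12], [a21, -1.0]]) is expected


class TestBoundaries:
    def test_equal_rates_recover_diagonal_entries(self):
        b = classification_boundaries(PD, [1.0, 1.0])
        assert (b.a21_threshold, b.a12_threshold) == (-3.0, -4.0)

    def test_shifted_boundaries(self):
        b = classification_boundaries(PD, [1.5, 1.0])
        assert b.a21_threshold == pytest.approx(-2.0)
        assert b.a12_threshold == pytest.approx(-6.0)

    def test_critical_ratio_puts_the_example_on_the_boundary(self):
        b = classification_boundaries(PD, [1.25, 1.0])
        assert b.a12_threshold == pytest.approx(-5.0)  # exactly a12

    def test_nonpositive_rates_rejected(self):
        with pytest.raises(LVGamesError):
            classification_boundaries(PD, [1.0, -1.0])


class TestClassifyOutcome:
    @pytest.mark.parametrize("name,expected", [
        ("pd_equal", OutcomeClass.DOMINANCE_2),
        ("pd_coexistence", OutcomeClass.COEXISTENCE),
        ("pd_mixed_rates", OutcomeClass.DOMINANCE_1),
        ("pd_declining", OutcomeClass.EXTINCTION_BOTH),
    ])
    def test_example_systems(self, name, expected):
        assert classify_outcome(example_system(name)) is expected

    def test_unbounded_mutualism(self):
        s = EcoGameSystem.from_arrays([[-0.5, 1.0], [1.0, -0.5]], [1.0, 1.0])
        assert classify_outcome(s) is OutcomeClass.UNBOUNDED

    def test_threshold_proximity_flagged_degenerate(self):
        s = EcoGameSystem.from_arrays(PD, [1.25, 1.0])
        rep = outcome_report(s)
        assert rep.degenerate

    def test_reduction_to_game_quadrants_at_equal_rates(self):
        # at r1 = r2 the outcome must reproduce the game classification:
        # PD/harmony -> dominance, coexistence game -> coexistence,
        # coordination -> bistability
        mapping = {
            GameClass.PRISONERS_DILEMMA: OutcomeClass.DOMINANCE_2,
            GameClass.HARMONY: OutcomeClass.DOMINANCE_1,
            GameClass.COEXISTENCE_GAME: OutcomeClass.COEXISTENCE,
            GameClass.COORDINATION: OutcomeClass.BISTABILITY,
        }
        checked = 0
        for s in iter_bounded_systems(21, 100):
            s_eq = EcoGameSystem.from_arrays(s.matrix, [1.0, 1.0])
            try:
                game = classify_game(s_eq.matrix)
            except DegenerateClassificationError:
                continue
            assert classify_outcome(s_eq) is mapping[game]
            checked += 1
        assert checked >= 90


class TestCriticalR1:
    def test_worked_example_value(self):
        assert critical_r1(PD, 1.0) == pytest.approx(1.25)

    def test_collapses_to_equal_rates_when_a12_equals_a22(self):
        # precondition requires a12 < a22; the threshold tends to r2 as
        # a12 -> a22 from below
        assert critical_r1([[-3.0, -4.0 - 1e-12], [1.0, -4.0]], 1.0) == \
            pytest.approx(1.0, abs=1e-9)

    def test_threshold_separates_dominance_from_coexistence(self):
        A = [[-3.0, -6.0], [1.0, -4.0]]
        rc = critical_r1(A, 1.0)
        assert rc == pytest.approx(1.5)
        below = EcoGameSystem.from_arrays(A, [1.4, 1.0])
        above = EcoGameSystem.from_arrays(A, [1.6, 1.0])
        assert classify_outcome(below) is OutcomeClass.DOMINANCE_2
        assert classify_outcome(above) is OutcomeClass.COEXISTENCE
        # ODE cross-check on both sides of the threshold
        t_below = integrate_lv(below, [0.1, 0.1], 400.0)
        assert t_below.final[0] == 0.0
        t_above = integrate_lv(above, [0.1, 0.1], 400.0)
        assert t_above.final.min() > 1e-3

    def test_monotone_crossing_at_critical_r1(self):
        # for fixed a12 < a22 < 0 the outcome flips from dominance of 2 to
        # coexistence exactly once, at critical_r1; boundedness guarantees
        # the second (a21) threshold, if any, lies strictly above it, so the
        # full sweep reads DOMINANCE_2* COEXISTENCE+ DOMINANCE_1*
        checked = 0
        for s in iter_bounded_systems(33, 60):
            a = s.matrix.copy()
            if not a[0, 1] < a[1, 1]:
                continue
            rc = critical_r1(a, 1.0)
            seq = []
            for r1 in np.linspace(0.1, 4.0, 80):
                if abs(r1 - rc) < 1e-6:
                    continue
                seq.append((r1, classify_outcome(EcoGameSystem.from_arrays(a, [r1, 1.0]))))
            for r1, out in seq:
                if r1 < rc:
                    assert out is OutcomeClass.DOMINANCE_2, (a, r1, rc, out)
            above = [out for r1, out in seq if r1 > rc]
            if above:
                grouped = [above[0]] + [b for x, b in zip(above, above[1:]) if b is not x]
                assert grouped in (
                    [OutcomeClass.COEXISTENCE],
                    [OutcomeClass.COEXISTENCE, OutcomeClass.DOMINANCE_1],
                ) or (rc > 4.0), (a, rc, grouped)
                checked += 1
        assert checked >= 10


class TestAchievableOutcomes:
    def test_pd_matrix_reaches_everything_but_bistability(self):
        reach = achievable_outcomes(PD)
        assert set(reach) == {
            OutcomeClass.DOMINANCE_1,
            OutcomeClass.DOMINANCE_2,
            OutcomeClass.COEXISTENCE,
            OutcomeClass.EXTINCTION_BOTH,
        }

    def test_strong_competition_reaches_bistability(self):
        reach = achievable_outcomes([[-3.0, -5.0], [-4.0, -4.0]])
        assert OutcomeClass.BISTABILITY in reach
        r1, r2 = reach[OutcomeClass.BISTABILITY]
        # witness satisfies a21 < a11 r2/r1 < 0
        assert -4.0 < -3.0 * r2 / r1 < 0

    def test_extinction_always_reachable(self):
        for s in iter_bounded_systems(17, 25):
            assert OutcomeClass.EXTINCTION_BOTH in achievable_outcomes(s.matrix)

    def test_witnesses_confirmed_by_simulation(self):
        reach = achievable_outcomes(PD)
        for cls, rates in reach.items():
            s = EcoGameSystem.from_arrays(PD, rates)
            traj = integrate_lv(s, [0.1, 0.1], 600.0)
            survivors = frozenset(np.flatnonzero(traj.final > 1e-4).tolist())
            if cls is OutcomeClass.COEXISTENCE:
                assert survivors == {0, 1}
            elif cls is OutcomeClass.DOMINANCE_1:
                assert survivors == {0}
            elif cls is OutcomeClass.DOMINANCE_2:
                assert survivors == {1}
            elif cls is OutcomeClass.EXTINCTION_BOTH:
                assert survivors == frozenset()


class TestRegimeRestrictions:
    def test_mixed_rates_allow_only_coexistence_or_dominance_1(self):
        outs = {classify_outcome(s)
                for s in iter_bounded_systems(41, 100, rate_regime="mixed")}
        assert outs <= {OutcomeClass.COEXISTENCE, OutcomeClass.DOMINANCE_1}

    def test_negative_rates_force_extinction(self):
        outs = {classify_outcome(s)
                for s in iter_bounded_systems(43, 100, rate_regime="negative")}
        assert outs == {OutcomeClass.EXTINCTION_BOTH}
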