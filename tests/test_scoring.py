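"""Unit tests for differentials, link scores and consistency classes."""

import math

import pytest

from netcondense import (ConsistencyClass, DegenerateVarianceError, Direction,
                         InteractionType, TypedNetwork, classify_consistency,
                         differential, differential_welch, link_score,
                         score_network)
from netcondense.scoring import Basis, node_differentials

from conftest import edge, table_of

INT = InteractionType.INTERACTION
STIM = InteractionType.STIMULATION
INH = InteractionType.INHIBITION


class TestDifferential:
    @pytest.mark.parametrize("m1, m2, expected", [
        (5.37, 7.15, 1.78),       # FAS up-regulation, printed pair
        (7041.0, 9124.0, 2083.0),  # Trim28 startup, printed pair
        (4.56, 5.38, 0.82),       # CASP8, printed pair
        (3.2, 3.2, 0.0),
    ])
    def test_values(self, m1, m2, expected):
        assert differential(m1, m2) == pytest.approx(expected)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            differential(float("nan"), 1.0)
        with pytest.raises(ValueError):
            differential(1.0, float("inf"))


class TestWelchDifferential:
    @pytest.mark.parametrize("args, expected", [
        # hand arithmetic: 2 / sqrt(1/4 + 1/4)
        ((0, 2, 1, 1, 4, 4), 2.828427),
        # 2 / sqrt(4/4 + 9/9)
        ((1, 3, 4, 9, 4, 9), 1.414214),
        ((5, 5, 2, 3, 4, 6), 0.0),
    ])
    def test_values(self, args, expected):
        assert differential_welch(*args) == pytest.approx(expected, abs=1e-6)

    def test_matches_scipy_welch_t(self):
        """The standardised differential is exactly the Welch t statistic."""
        from scipy import stats
        import numpy as np
        rng = np.random.default_rng(7)
        a = rng.normal(5, 1, size=10)
        b = rng.normal(6, 2, size=16)
        t_ref = stats.ttest_ind(b, a, equal_var=False).statistic
        d = differential_welch(a.mean(), b.mean(), a.var(ddof=1), b.var(ddof=1),
                               len(a), len(b))
        assert d == pytest.approx(t_ref, rel=1e-12)

    def test_zero_pooled_variance_is_an_error(self):
        with pytest.raises(DegenerateVarianceError):
            differential_welch(1, 2, 0.0, 0.0, 4, 4)

    def test_variance_floor_opt_in(self):
        d = differential_welch(1, 2, 0.0, 0.0, 4, 4, variance_floor=1e-12)
        assert d == pytest.approx(1.0 / math.sqrt(1e-12))


class TestLinkScore:
    def test_stimulation_sums_differentials(self):
        # FAS -> CASP8 startup: D_FAS + D_CASP8 = 1.78 + 0.82
        assert link_score(STIM, 1.78, 0.82) == pytest.approx(2.60)

    def test_perfectly_anticorrelated_stimulation_scores_zero(self):
        assert link_score(STIM, 1.5, -1.5) == 0.0

    def test_inhibition_rewards_anticorrelation(self):
        # inhibitor up, target down: a startup of magnitude 2c
        assert link_score(INH, 2.0, -2.0) == pytest.approx(4.0)

    def test_interaction_is_symmetric(self):
        assert link_score(INT, 0.3, -1.7) == link_score(INT, -1.7, 0.3)


class TestConsistencyClassification:
    @pytest.mark.parametrize("etype, ds, dt, eps, expected", [
        (STIM, +2.0, +1.0, 0.0, ConsistencyClass.CONSISTENT),
        (STIM, -2.0, -1.0, 0.0, ConsistencyClass.CONSISTENT),
        (INH, +2.0, -1.0, 0.0, ConsistencyClass.CONSISTENT),
        (INH, -1.0, +2.0, 0.0, ConsistencyClass.CONSISTENT),
        (STIM, +2.0, -0.3, 0.0, ConsistencyClass.SOURCE_PRINCIPLE),
        (STIM, +2.0, 0.0, 0.0, ConsistencyClass.SOURCE_PRINCIPLE),
        (INH, +2.0, +0.5, 0.0, ConsistencyClass.SOURCE_PRINCIPLE),
        (STIM, -0.2, +2.0, 0.0, ConsistencyClass.TARGET_PRINCIPLE),
        (STIM, 0.0, +2.0, 0.0, ConsistencyClass.TARGET_PRINCIPLE),
        (STIM, 0.0, 0.0, 0.1, ConsistencyClass.NO_CHANGE),
        (INT, 0.05, -0.05, 0.1, ConsistencyClass.NO_CHANGE),
        # equal-magnitude disagreement: neither principle dominates
        (STIM, +1.0, -1.0, 0.0, ConsistencyClass.INCONSISTENT),
        (INH, +1.0, +1.0, 0.0, ConsistencyClass.INCONSISTENT),
    ])
    def test_gallery(self, etype, ds, dt, eps, expected):
        assert classify_consistency(etype, ds, dt, eps) == expected

    def test_dead_band_downgrades_small_changes(self):
        # below epsilon the target counts as unchanged -> source principle
        assert (classify_consistency(STIM, 2.0, 0.05, 0.1)
                == ConsistencyClass.SOURCE_PRINCIPLE)

    def test_negative_epsilon_rejected(self):
        with pytest.raises(ValueError):
            classify_consistency(STIM, 1.0, 1.0, -0.1)


class TestScoreNetwork:
    def test_two_node_stimulation(self):
        net = TypedNetwork(nodes={"A", "B"},
                           edges=[edge("A", "B", "stimulation", "e1")])
        table = table_of({"A": (1, 2), "B": (3, 5)})
        (link,) = score_network(net, table)
        assert link.score == pytest.approx(3.0)
        assert link.direction is Direction.STARTUP

    def test_inhibition_shutdown(self):
        net = TypedNetwork(nodes={"I", "T"},
                           edges=[edge("I", "T", "inhibition", "e1")])
        table = table_of({"I": (2, 1), "T": (1, 3)})
        (link,) = score_network(net, table)
        assert link.score == pytest.approx(-3.0)
        assert link.direction is Direction.SHUTDOWN

    def test_empty_network(self):
        net = TypedNetwork(nodes=set(), edges=[])
        assert score_network(net, table_of({})) == []

    def test_self_loop_uses_equal_differentials(self, toy_network, toy_table):
        by_id = {l.edge.edge_id: l for l in score_network(toy_network, toy_table)}
        loop = by_id["e5"]
        assert loop.d_source == loop.d_target
        assert loop.score == pytest.approx(1.0)

    def test_duplicate_edges_score_identically(self, toy_network, toy_table):
        by_id = {l.edge.edge_id: l for l in score_network(toy_network, toy_table)}
        assert by_id["e1"].score == by_id["e4"].score

    def test_unscored_edges_skipped_or_flagged(self, toy_network):
        partial = table_of({"A": (1, 2), "B": (3, 5)})
        links = score_network(toy_network, partial)
        assert {l.edge.edge_id for l in links} == {"e1", "e4"}
        links = score_network(toy_network, partial, include_unscored=True)
        assert len(links) == 5
        assert sum(not l.scored for l in links) == 3

    def test_welch_basis_when_table_has_variance(self):
        import pandas as pd
        from netcondense import MeasurementTable
        frame = pd.DataFrame({"m_e1": [1.0, 3.0], "m_e2": [2.0, 5.0],
                              "var_e1": [1.0, 1.0], "var_e2": [1.0, 1.0]},
                             index=["A", "B"])
        table = MeasurementTable(frame, n1=4, n2=4)
        net = TypedNetwork(nodes={"A", "B"},
                           edges=[edge("A", "B", "stimulation", "e1")])
        diffs = node_differentials(net, table)
        assert diffs["A"].basis is Basis.WELCH
        assert diffs["A"].d == pytest.approx(1.0 / math.sqrt(0.5))

    def test_degenerate_variance_names_the_node(self):
        import pandas as pd
        from netcondense import MeasurementTable
        frame = pd.DataFrame({"m_e1": [1.0], "m_e2": [2.0],
                              "var_e1": [0.0], "var_e2": [0.0]}, index=["Bad"])
        table = MeasurementTable(frame, n1=3, n2=3)
        net = TypedNetwork(nodes={"Bad"}, edges=[])
        with pytest.raises(DegenerateVarianceError, match="Bad"):
            node_differentials(net, table)
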