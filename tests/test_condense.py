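"""Unit tests for preprocessing, threshold resolution and condensation."""

import numpy as np
import pandas as pd
import pytest

from netcondense import (ScoredLink, StateError, ThresholdSpec,
                         condensation_series, condense, preprocess,
                         quantile_normalize, resolve_thresholds)
from netcondense.scoring import ConsistencyClass

from conftest import edge


def scored(links):
    """Build ScoredLinks on a path graph from a list of scores (None = unscored)."""
    out = []
    for i, s in enumerate(links):
        e = edge(f"N{i}", f"N{i + 1}", "stimulation", f"e{i}")
        if s is None:
            out.append(ScoredLink(e, None, None, None, None))
        else:
            out.append(ScoredLink(e, s / 2, s / 2, float(s),
                                  ConsistencyClass.CONSISTENT))
    return out


class TestPreprocess:
    def test_identical_columns_unchanged_by_quantile_normalisation(self):
        frame = pd.DataFrame({"a": [1.0, 5.0, 3.0], "b": [1.0, 5.0, 3.0]},
                             index=list("xyz"))
        out = quantile_normalize(frame)
        pd.testing.assert_frame_equal(out, frame)

    def test_rank_mean_substitution(self):
        frame = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]},
                             index=list("xyz"))
        out = quantile_normalize(frame)
        expected = [2.5, 3.5, 4.5]
        assert list(out["a"]) == expected
        assert list(out["b"]) == expected

    def test_ties_get_average_of_rank_means(self):
        frame = pd.DataFrame({"a": [1.0, 1.0, 9.0], "b": [2.0, 4.0, 6.0]},
                             index=list("xyz"))
        out = quantile_normalize(frame)
        # column a ties at ranks 1-2 -> average of the two smallest rank means
        rank_means = np.sort(frame.to_numpy(), axis=0).mean(axis=1)
        assert out.loc["x", "a"] == pytest.approx(rank_means[:2].mean())
        assert out.loc["y", "a"] == pytest.approx(rank_means[:2].mean())

    def test_log2(self):
        frame = pd.DataFrame({"a": [4.0], "b": [8.0]}, index=["x"])
        table = preprocess(frame, ["a"], ["b"], log_base="log2")
        assert table.row("x")["m_e1"] == 2.0
        assert table.row("x")["m_e2"] == 3.0

    def test_log_of_nonpositive_names_node(self):
        frame = pd.DataFrame({"a": [4.0, -1.0], "b": [8.0, 2.0]},
                             index=["ok", "bad"])
        with pytest.raises(ValueError, match="bad"):
            preprocess(frame, ["a"], ["b"], log_base="log2")

    def test_replicate_columns_produce_variances(self):
        rng = np.random.default_rng(3)
        frame = pd.DataFrame(rng.normal(8, 1, size=(5, 5)),
                             index=[f"g{i}" for i in range(5)],
                             columns=["a1", "a2", "b1", "b2", "b3"])
        table = preprocess(frame, ["a1", "a2"], ["b1", "b2", "b3"])
        assert table.has_variance and table.n1 == 2 and table.n2 == 3
        expected = frame[["b1", "b2", "b3"]].var(axis=1, ddof=1)
        assert table.data["var_e2"].to_numpy() == pytest.approx(expected.to_numpy())


class TestResolveThresholds:
    def test_quantiles_of_integer_scores(self):
        scores = list(range(1, 101))
        lower, upper = resolve_thresholds(scores, ThresholdSpec.quantile(0.03))
        # brute-force type-7 oracle: x_(k) + frac * (x_(k+1) - x_(k))
        xs = sorted(scores)
        h = 0.03 * (len(xs) - 1)
        expected_lower = xs[int(h)] + (h - int(h)) * (xs[int(h) + 1] - xs[int(h)])
        assert lower == pytest.approx(expected_lower)
        assert upper == pytest.approx(sorted(xs, reverse=True)[int(h)]
                                      - (h - int(h)))
        assert (lower, upper) == pytest.approx((3.97, 97.03))

    def test_absolute_passthrough(self):
        assert resolve_thresholds([], ThresholdSpec.absolute(-2, 2)) == (-2, 2)

    def test_zero_quantile_keeps_only_extremes(self):
        scores = [1.0, 2.0, 3.0]
        assert resolve_thresholds(scores, ThresholdSpec.quantile(0.0)) == (1.0, 3.0)

    def test_empty_scores_in_quantile_mode(self):
        with pytest.raises(StateError):
            resolve_thresholds([], ThresholdSpec.quantile(0.1))

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ThresholdSpec.quantile(0.6)
        with pytest.raises(ValueError):
            ThresholdSpec.absolute(1.0, 2.0)


class TestCondense:
    def test_keep_everything_spec(self):
        links = scored([-2, -1, 0, 1, 2])
        result = condense(links, ThresholdSpec.absolute(0.0, 0.0))
        assert result.kept == links
        assert result.removed_fraction == 0.0

    def test_all_zero_scores_removed(self):
        links = scored([0.0] * 5)
        result = condense(links, ThresholdSpec.absolute(-1.0, 1.0))
        assert result.kept == [] and result.retained_nodes == set()
        assert result.removed_fraction == 1.0

    def test_boundary_scores_are_kept(self):
        links = scored([-2.0, -1.0, 0.0, 1.0, 2.0])
        result = condense(links, ThresholdSpec.absolute(-2.0, 2.0))
        assert sorted(l.score for l in result.kept) == [-2.0, 2.0]

    def test_retained_nodes_are_exactly_kept_endpoints(self):
        links = scored([5.0, 0.0, 0.0, -5.0])
        result = condense(links, ThresholdSpec.absolute(-3.0, 3.0))
        expected = set()
        for l in result.kept:
            expected |= {l.edge.source, l.edge.target}
        assert result.retained_nodes == expected
        assert all(any(n in (l.edge.source, l.edge.target) for l in result.kept)
                   for n in result.retained_nodes)

    def test_unscored_links_always_removed_and_counted(self):
        links = scored([5.0, None, -5.0, None])
        result = condense(links, ThresholdSpec.absolute(0.0, 0.0))
        assert result.kept_count == 2
        assert result.unscored_removed == 2
        assert result.removed_count == 2

    def test_idempotent_at_resolved_cutoffs(self):
        rng = np.random.default_rng(5)
        links = scored(rng.normal(size=50).tolist())
        first = condense(links, ThresholdSpec.quantile(0.1))
        again = condense(first.kept,
                         ThresholdSpec.absolute(*first.thresholds_resolved))
        assert [l.edge.edge_id for l in again.kept] == \
               [l.edge.edge_id for l in first.kept]

    def test_three_percent_quantile_on_206_distinct_scores(self):
        """The case-study condensation: ~94% of 206 links removed."""
        rng = np.random.default_rng(11)
        links = scored(rng.normal(size=206).tolist())
        result = condense(links, ThresholdSpec.quantile(0.03))
        # type-7 cutoffs keep floor(1 + 205*0.03) = 7 links per tail
        assert result.removed_count == 192
        assert abs(result.removed_count - 0.94 * 206) <= 2

    def test_empty_input_with_quantile_spec(self):
        with pytest.raises(StateError):
            condense([], ThresholdSpec.quantile(0.1))


class TestCondensationSeries:
    def test_nested_kept_sets(self):
        rng = np.random.default_rng(9)
        links = scored(rng.normal(size=80).tolist())
        specs = [ThresholdSpec.absolute(-c, c) for c in (0.5, 1.0, 1.5, 2.0)]
        results = condensation_series(links, specs)
        for lenient, stringent in zip(results, results[1:]):
            lenient_ids = {l.edge.edge_id for l in lenient.kept}
            stringent_ids = {l.edge.edge_id for l in stringent.kept}
            assert stringent_ids <= lenient_ids

    def test_singleton_equals_condense(self):
        links = scored([1.0, -2.0, 3.0])
        spec = ThresholdSpec.absolute(-1.5, 1.5)
        (only,) = condensation_series(links, [spec])
        assert [l.edge.edge_id for l in only.kept] == \
               [l.edge.edge_id for l in condense(links, spec).kept]

    def test_empty_specs(self):
        assert condensation_series(scored([1.0]), []) == []
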