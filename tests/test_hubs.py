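import numpy as np
import pytest

from dynhubs import (
    InvalidInputError,
    TVCStack,
    bc_time_series,
    betweenness_centrality,
    binarize_stack,
    consensus_candidates,
    find_active_hubs,
    find_candidate_hubs,
    summarize_bc,
)
from dynhubs.hubs import AdjacencyStack, BCTimeSeries, weighted_betweenness_centrality

from _oracles import brute_force_bc


def stack_from_values(values):
    """TVCStack whose normalized slices are the given T x N x N values."""
    values = np.asarray(values, dtype=float)
    return TVCStack(raw=-values, normalized=values, t_total=values.shape[0])


def star_adjacency(n):
    a = np.zeros((n, n), dtype=np.uint8)
    a[0, 1:] = 1
    a[1:, 0] = 1
    return a


class TestBinarizeStack:
    def test_single_maximal_edge_retained(self):
        vals = np.zeros((1, 4, 4))
        vals[0, 0, 1] = vals[0, 1, 0] = 5.0
        adj = binarize_stack(
            stack_from_values(vals), density=0.17, values="normalized",
            smoothing_window=1,
        )
        expected = np.zeros((4, 4))
        expected[0, 1] = expected[1, 0] = 1
        assert np.array_equal(adj.adjacency[0], expected)

    def test_all_ties_at_cutoff_are_retained(self):
        vals = np.ones((1, 4, 4))
        vals[0, range(4), range(4)] = 0
        adj = binarize_stack(
            stack_from_values(vals), density=0.17, values="normalized",
            smoothing_window=1,
        )
        assert adj.adjacency[0].sum() == 12  # all 6 undirected edges

    def test_edge_count_meets_density_floor(self):
        rng = np.random.default_rng(5)
        t, n = 4, 90
        vals = rng.standard_normal((t, n, n))
        vals = 0.5 * (vals + vals.transpose(0, 2, 1))
        vals[:, range(n), range(n)] = 0
        adj = binarize_stack(
            stack_from_values(vals), density=0.15, values="normalized",
            smoothing_window=1,
        )
        floor = int(np.ceil(0.15 * n * (n - 1) / 2))
        for slice_ in adj.adjacency:
            assert slice_.sum() // 2 >= floor

    def test_invalid_density_rejected(self):
        with pytest.raises(InvalidInputError):
            binarize_stack(stack_from_values(np.zeros((1, 4, 4))), density=1.5)

    def test_unknown_value_mode_rejected(self):
        with pytest.raises(InvalidInputError):
            binarize_stack(stack_from_values(np.zeros((1, 4, 4))), values="bogus")


class TestBetweennessCentrality:
    def test_star_center_is_one_leaves_zero(self):
        bc = betweenness_centrality(star_adjacency(5))
        assert bc[0] == pytest.approx(1.0)
        assert np.all(bc[1:] == 0)

    def test_path_of_four_middle_node(self):
        a = np.zeros((4, 4), dtype=np.uint8)
        for i, j in [(0, 1), (1, 2), (2, 3)]:
            a[i, j] = a[j, i] = 1
        bc = betweenness_centrality(a)
        assert bc[1] == pytest.approx(2.0 / 3.0)
        assert bc[2] == pytest.approx(2.0 / 3.0)

    @pytest.mark.parametrize("n", [3, 5, 8])
    def test_complete_graph_is_all_zero(self, n):
        a = np.ones((n, n), dtype=np.uint8)
        a[range(n), range(n)] = 0
        assert np.all(betweenness_centrality(a) == 0)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            n = int(rng.integers(4, 8))
            a = (rng.random((n, n)) < 0.4).astype(np.uint8)
            a = np.triu(a, 1)
            a = a + a.T
            assert np.allclose(
                betweenness_centrality(a), brute_force_bc(a), atol=1e-12
            )

    def test_small_or_invalid_graphs_rejected(self):
        with pytest.raises(InvalidInputError):
            betweenness_centrality(np.zeros((2, 2), dtype=np.uint8))
        bad = np.zeros((4, 4), dtype=np.uint8)
        bad[0, 1] = 1  # asymmetric
        with pytest.raises(InvalidInputError):
            betweenness_centrality(bad)

    def test_weighted_star_center_dominates(self):
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 2.0
        bc = weighted_betweenness_centrality(w)
        assert bc[0] == pytest.approx(1.0)


class TestBcTimeSeries:
    def test_identical_slices_give_identical_columns(self):
        a = star_adjacency(5)
        stack = AdjacencyStack(adjacency=np.stack([a, a, a]), density=0.5)
        bc = bc_time_series(stack)
        assert np.array_equal(bc.values[:, 0], bc.values[:, 1])
        assert bc.values[0, 0] == pytest.approx(1.0)

    def test_empty_graphs_give_zeros(self):
        stack = AdjacencyStack(
            adjacency=np.zeros((3, 5, 5), dtype=np.uint8), density=0.1
        )
        assert np.all(bc_time_series(stack).values == 0)


class TestThresholds:
    @pytest.fixture
    def bcts(self):
        col = np.array([0.1, 0.1, 0.1, 0.7])
        return BCTimeSeries(values=np.column_stack([col, col]))

    def test_th1_mean_plus_sample_sd(self, bcts, table4):
        summary = summarize_bc(bcts, table4)
        assert summary.th1 == pytest.approx(0.55)
        assert summary.bc_global == pytest.approx(0.25)
        assert summary.bc_rsn["SMN"] == pytest.approx(0.1)
        assert summary.bc_rsn["DMN"] == pytest.approx(0.4)

    def test_summary_internal_consistency(self, bcts, table4):
        summary = summarize_bc(bcts, table4)
        assert summary.bc_global == pytest.approx(summary.bc_avg.mean(), abs=1e-12)
        for label in table4.rsn_labels:
            members = table4.members(label)
            assert summary.bc_rsn[label] == pytest.approx(
                summary.bc_avg[members].mean(), abs=1e-12
            )

    def test_candidates_strictly_above_th1(self, bcts, table4):
        summary = summarize_bc(bcts, table4)
        assert find_candidate_hubs(summary) == (3,)

    def test_uniform_bc_yields_no_candidates(self, table4):
        bcts = BCTimeSeries(values=np.full((4, 3), 0.2))
        summary = summarize_bc(bcts, table4)
        assert summary.th1 == pytest.approx(0.2)
        assert find_candidate_hubs(summary) == ()

    def test_stricter_multiplier_gives_subset(self, table4):
        rng = np.random.default_rng(3)
        bcts = BCTimeSeries(values=rng.random((4, 6)))
        summary = summarize_bc(bcts, table4)
        loose = set(find_candidate_hubs(summary, 1.0))
        strict = set(find_candidate_hubs(summary, 2.0))
        assert strict <= loose

    def test_th2_and_activity(self):
        series = np.array([[0.2, 0.2, 0.2, 0.8], [0.0, 0.0, 0.0, 0.0]])
        activity = find_active_hubs(BCTimeSeries(values=series), [0])
        assert activity.th2[0] == pytest.approx(0.65)
        assert np.array_equal(activity.activity[0], [0, 0, 0, 1])

    def test_constant_candidate_never_active(self):
        series = np.full((1, 5), 0.4)
        activity = find_active_hubs(BCTimeSeries(values=series), [0])
        assert activity.activity.sum() == 0

    def test_non_candidate_rows_stay_zero(self):
        series = np.array([[0.0, 0.9, 0.0], [0.1, 0.1, 0.1]])
        activity = find_active_hubs(BCTimeSeries(values=series), [1])
        assert activity.activity[0].sum() == 0


class TestConsensus:
    def test_majority_rule(self):
        sets = [(0, 1), (0, 2), (0,), (1,)]
        assert consensus_candidates(sets, 0.5) == (0,)

    def test_fraction_zero_keeps_any_occurrence(self):
        assert consensus_candidates([(0,), (1,)], 0.0) == (0, 1)
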