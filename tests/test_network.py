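"""Edge calling, network assembly, hub/coverage/neighborhood statistics."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from matrixrnai import (
    ConfigurationError,
    EdgeCriteria,
    InputError,
    ParameterError,
    PerturbationMatrix,
    assemble_network,
    call_edges,
    classify_nodes,
    edge_coverage,
    first_neighbors,
    influential_set,
    select_combination,
)
from matrixrnai.ddct import DdctStat
from matrixrnai.network import fold_to_log2_cutoff

from conftest import make_network, random_network


def matrix_from_cells(cells):
    """cells: {(kd, gene): (log2_ratio, p_value)} with full stats derived."""
    tfs = sorted({k for k, _ in cells} | {g for _, g in cells})
    stats = {
        (kd, g): DdctStat(
            knockdown=kd, measured_gene=g, mean_ddct=-l2, sd_ddct=abs(l2) / 4 or 0.1,
            p_value=p, n=4,
        )
        for (kd, g), (l2, p) in cells.items()
    }
    return PerturbationMatrix(tfs=tfs, cells=stats)


class TestCallEdges:
    def test_strong_downregulation_is_activating_edge(self):
        matrix = matrix_from_cells({("A", "B"): (-2.0, 0.01)})
        edges = call_edges(matrix)
        assert len(edges) == 1
        assert edges[0].source == "A" and edges[0].target == "B"
        assert edges[0].sign == "activating"

    @pytest.mark.parametrize(
        "log2, p, called",
        [
            (-2.0, 0.2, False),  # alpha gate
            (-1.0, 0.01, False),  # effect gate
            (1.5, 0.01, True),  # inclusive effect cutoff, inhibiting
            (1.5, 0.05, False),  # strict alpha cutoff
        ],
    )
    def test_gates(self, log2, p, called):
        edges = call_edges(matrix_from_cells({("A", "B"): (log2, p)}))
        assert bool(edges) is called
        if called:
            assert edges[0].sign == "inhibiting"

    def test_diagonal_excluded_by_default(self):
        matrix = matrix_from_cells({("A", "A"): (-3.0, 0.001), ("A", "B"): (-3.0, 0.001)})
        assert len(call_edges(matrix)) == 1
        crit = EdgeCriteria(exclude_self=False)
        assert len(call_edges(matrix, crit)) == 2

    def test_sd_multiple_mode(self):
        # |mean ddct| = 2.0, sd = 0.5 -> passes 3-SD rule; sd = 0.7 fails
        cells = {
            ("A", "B"): DdctStat("A", "B", mean_ddct=-2.0, sd_ddct=0.5, p_value=0.01, n=4),
            ("B", "A"): DdctStat("B", "A", mean_ddct=-2.0, sd_ddct=0.7, p_value=0.01, n=4),
        }
        matrix = PerturbationMatrix(tfs=["A", "B"], cells=cells)
        edges = call_edges(matrix, EdgeCriteria(mode="sd_multiple"))
        assert [(e.source, e.target) for e in edges] == [("A", "B")]

    def test_missing_statistics_raise_configuration_error(self):
        cells = {
            ("A", "B"): DdctStat("A", "B", mean_ddct=-2.0, sd_ddct=math.nan,
                                 p_value=math.nan, n=0)
        }
        matrix = PerturbationMatrix(tfs=["A", "B"], cells=cells)
        with pytest.raises(ConfigurationError, match="p-value"):
            call_edges(matrix)
        with pytest.raises(ConfigurationError, match="SD"):
            call_edges(matrix, EdgeCriteria(mode="sd_multiple", alpha=None))
        # ratio-only calling works once the alpha gate is dropped
        edges = call_edges(matrix, EdgeCriteria(alpha=None))
        assert len(edges) == 1

    def test_fold_flag_conversion(self):
        assert fold_to_log2_cutoff(2.83) == pytest.approx(1.5, abs=0.01)
        assert fold_to_log2_cutoff(0.5) == pytest.approx(1.0)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_tightening_criteria_is_monotone(self, seed):
        """Raising any cutoff or lowering alpha never adds an edge."""
        rng = np.random.default_rng(seed)
        cells = {}
        names = [f"T{i}" for i in range(6)]
        for kd in names:
            for g in names:
                if kd == g:
                    continue
                cells[(kd, g)] = (float(rng.normal(0, 2)), float(rng.uniform(0, 0.2)))
        matrix = matrix_from_cells(cells)
        base = {(e.source, e.target) for e in call_edges(matrix)}
        for crit in [
            EdgeCriteria(log2_cutoff=2.5),
            EdgeCriteria(alpha=0.01),
            EdgeCriteria(mode="sd_multiple", sd_multiplier=6.0),
        ]:
            tightened = {(e.source, e.target) for e in call_edges(matrix, crit)}
            if crit.mode == "log2_threshold":
                assert tightened <= base
        # sign partition is exhaustive and exclusive
        edges = call_edges(matrix)
        assert sum(e.sign == "activating" for e in edges) + sum(
            e.sign == "inhibiting" for e in edges
        ) == len(edges)


class TestAssembleAndDegrees:
    def test_zero_edge_network_keeps_all_nodes(self):
        net = make_network([], [f"T{i}" for i in range(18)])
        assert len(net.nodes) == 18
        assert all(d == 0 for d in net.out_degree.values())

    def test_hand_counted_degrees(self):
        net = make_network([("A", "B"), ("A", "C"), ("B", "A")], ["A", "B", "C"])
        assert net.out_degree == {"A": 2, "B": 1, "C": 0}
        assert net.in_degree == {"A": 1, "B": 1, "C": 1}

    def test_endpoint_outside_node_list_rejected(self):
        with pytest.raises(InputError, match="outside"):
            make_network([("A", "X")], ["A", "B"])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_degree_conservation(self, seed):
        """Sum of out-degrees = sum of in-degrees = edge count."""
        net = random_network(np.random.default_rng(seed))
        assert sum(net.out_degree.values()) == len(net.edges)
        assert sum(net.in_degree.values()) == len(net.edges)
        assert net.n_activating + net.n_inhibiting == len(net.edges)


class TestHubsAndCoverage:
    def test_influential_set_ordering_and_thresholds(self):
        pairs = [("H", t) for t in ["A", "B", "C", "D", "E"]] + [("G", "A")]
        net = make_network(pairs, ["H", "G", "A", "B", "C", "D", "E"])
        assert influential_set(net) == ["H"]
        assert influential_set(net, min_targets=0) == [
            "H", "G", "A", "B", "C", "D", "E",
        ]
        assert influential_set(net, min_targets=6) == []

    def test_full_set_covers_everything(self):
        rng = np.random.default_rng(2)
        net = random_network(rng)
        cov = edge_coverage(net, net.nodes)
        assert cov.fraction == 1.0

    def test_empty_network_coverage_is_missing(self):
        net = make_network([], ["A", "B"])
        assert edge_coverage(net, ["A"]).fraction is None

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_coverage_equals_outdegree_sum(self, seed):
        """coverage(S) = sum of out-degrees over S / total edges, always."""
        rng = np.random.default_rng(seed)
        net = random_network(rng)
        if not net.edges:
            return
        subset = [n for n in net.nodes if rng.random() < 0.5]
        cov = edge_coverage(net, subset)
        expected = sum(net.out_degree[n] for n in subset) / len(net.edges)
        assert cov.fraction == pytest.approx(expected)

    @pytest.mark.parametrize(
        "out_degree, cls", [(0, "low"), (4, "low"), (5, "mid"), (6, "mid"), (7, "high"), (11, "high")]
    )
    def test_degree_classes(self, out_degree, cls):
        targets = [f"T{i}" for i in range(out_degree)]
        net = make_network([("H", t) for t in targets], ["H"] + targets)
        table = classify_nodes(net).set_index("node")
        assert table.loc["H", "class"] == cls


class TestFirstNeighbors:
    def test_hand_trace(self):
        net = make_network([("A", "B"), ("B", "C")], ["A", "B", "C"])
        sub = first_neighbors(net, {"A"}, direction="out")
        assert sub.nodes == ["A", "B"]
        assert [(e.source, e.target) for e in sub.edges] == [("A", "B")]

    def test_all_seeds_gives_full_network(self):
        rng = np.random.default_rng(4)
        net = random_network(rng)
        sub = first_neighbors(net, net.nodes, direction="both")
        assert sub.nodes == net.nodes
        assert len(sub.edges) == len(net.edges)

    def test_empty_seed_set(self):
        net = make_network([("A", "B")], ["A", "B"])
        sub = first_neighbors(net, set())
        assert sub.nodes == [] and sub.edges == []

    def test_unknown_seed_rejected(self):
        net = make_network([("A", "B")], ["A", "B"])
        with pytest.raises(InputError, match="unknown seed"):
            first_neighbors(net, {"Z"})

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000), direction=st.sampled_from(["out", "in", "both"]))
    def test_idempotent(self, seed, direction):
        rng = np.random.default_rng(seed)
        net = random_network(rng)
        seeds = {n for n in net.nodes if rng.random() < 0.4}
        once = first_neighbors(net, seeds, direction=direction)
        twice = first_neighbors(once, seeds, direction=direction)
        assert twice.nodes == once.nodes
        assert [(e.source, e.target) for e in twice.edges] == [
            (e.source, e.target) for e in once.edges
        ]


class TestSelectCombination:
    def test_star_hub_found_by_both_strategies(self):
        leaves = [f"L{i}" for i in range(5)]
        net = make_network([("HUB", l) for l in leaves], ["HUB"] + leaves)
        for strategy in ("top_out_degree", "greedy_cover"):
            chosen, covered = select_combination(net, 1, strategy=strategy)
            assert chosen == ["HUB"] and covered == 5

    def test_k_equal_to_node_count(self):
        rng = np.random.default_rng(6)
        net = random_network(rng, n_nodes=6)
        chosen, covered = select_combination(net, len(net.nodes), "greedy_cover")
        assert sorted(chosen) == sorted(net.nodes)
        assert covered == len({e.target for e in net.edges})

    def test_k_out_of_range(self):
        net = make_network([("A", "B")], ["A", "B"])
        with pytest.raises(ParameterError):
            select_combination(net, 3)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_greedy_pair_against_exhaustive_search(self, seed):
        """Greedy 2-mix coverage is within the (1-1/e) guarantee of the
        exhaustive-optimum pair, and matches it when greedy happens to be
        optimal."""
        rng = np.random.default_rng(seed)
        net = random_network(rng, n_nodes=6, density=0.4)
        _, greedy_cov = select_combination(net, 2, "greedy_cover")
        best = max(
            len(net.targets_of(a) | net.targets_of(b))
            for a, b in itertools.combinations(net.nodes, 2)
        )
        assert greedy_cov <= best
        assert greedy_cov >= (1 - 1 / math.e) * best
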