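"""Reaction-graph construction, driver nodes, frequencies, thresholds."""
import math
from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from wcflux.errors import (
    DegenerateFitWarning,
    InvalidArgumentError,
    ParseError,
)
from wcflux.network import (
    DriverSet,
    abnormality_frequencies,
    adjacency_from_stoichiometry,
    annotate_pathways,
    class_subnetwork,
    find_driver_nodes,
    noise_threshold,
)
from wcflux.types import FluxProfile, StoichiometricMatrix


def _matrix(mets, rxns, coeff):
    return StoichiometricMatrix(tuple(mets), tuple(rxns), np.array(coeff))


def brute_force_max_matching(G: nx.Graph) -> int:
    """Exhaustive maximum-matching size, for small graphs only."""
    edges = list(G.edges())
    best = 0
    for k in range(len(edges), 0, -1):
        if k <= best:
            break
        for combo in combinations(edges, k):
            nodes = [n for e in combo for n in e]
            if len(nodes) == len(set(nodes)):
                best = max(best, k)
                break
    return best


class TestAdjacency:
    def test_single_reaction_gives_single_isolated_node(self):
        S = _matrix(["A", "B"], ["R1"], [[-1], [1]])
        G = adjacency_from_stoichiometry(S)
        assert G.number_of_nodes() == 1 and G.number_of_edges() == 0

    def test_metabolic_cycle_gives_triangle(self):
        # R1: A->B, R2: B->C, R3: C->A
        S = _matrix(
            ["A", "B", "C"],
            ["R1", "R2", "R3"],
            [[-1, 0, 1], [1, -1, 0], [0, 1, -1]],
        )
        G = adjacency_from_stoichiometry(S)
        assert set(G.edges()) == {("R1", "R2"), ("R1", "R3"), ("R2", "R3")}

    def test_matches_shared_metabolite_test_on_random_matrices(self, rng):
        for _ in range(25):
            m, n = int(rng.integers(2, 12)), int(rng.integers(2, 15))
            S = rng.choice(
                [-2, -1, 0, 0, 0, 1, 2], size=(m, n)
            )
            S[rng.integers(0, m, size=n), np.arange(n)] = 1  # no zero column
            rxns = [f"R{j}" for j in range(n)]
            sm = _matrix([f"M{i}" for i in range(m)], rxns, S)
            G = adjacency_from_stoichiometry(sm)
            for i, j in combinations(range(n), 2):
                share = bool(np.any((S[:, i] != 0) & (S[:, j] != 0)))
                assert G.has_edge(rxns[i], rxns[j]) == share

    def test_empty_matrix_rejected(self):
        with pytest.raises(InvalidArgumentError):
            adjacency_from_stoichiometry(
                _matrix(["A"], [], np.empty((1, 0)))
            )


class TestDriverNodes:
    def test_single_edge_perfectly_matched(self):
        G = nx.Graph([("a", "b")])
        d = find_driver_nodes(G)
        assert d.drivers == () and d.matching == (("a", "b"),)

    def test_three_node_path_has_one_driver(self):
        G = nx.path_graph(["a", "b", "c"])
        for strategy in ("maximum", "greedy_sorted"):
            d = find_driver_nodes(G, strategy)
            assert len(d.drivers) == 1

    def test_isolated_nodes_are_always_drivers(self):
        G = nx.Graph([("a", "b")])
        G.add_node("lonely")
        assert "lonely" in find_driver_nodes(G).drivers

    def test_maximum_matching_agrees_with_brute_force(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 8))
            G = nx.gnp_random_graph(
                n, 0.4, seed=int(rng.integers(0, 10_000))
            )
            G = nx.relabel_nodes(G, {i: f"R{i}" for i in range(n)})
            d = find_driver_nodes(G, "maximum")
            assert len(d.drivers) == n - 2 * brute_force_max_matching(G)

    def test_greedy_never_beats_maximum(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 10))
            G = nx.gnp_random_graph(
                n, 0.5, seed=int(rng.integers(0, 10_000))
            )
            G = nx.relabel_nodes(G, {i: f"R{i}" for i in range(n)})
            n_max = len(find_driver_nodes(G, "maximum").drivers)
            n_greedy = len(find_driver_nodes(G, "greedy_sorted").drivers)
            assert n_greedy >= n_max

    def test_transport_fraction_counts_tx_prefix(self):
        d = DriverSet(("TX_A", "TX_B", "R_C"), (), "maximum")
        assert d.transport_fraction == pytest.approx(2 / 3)
        assert math.isnan(DriverSet((), (), "maximum").transport_fraction)

    def test_unknown_strategy_rejected(self):
        with pytest.raises(InvalidArgumentError):
            find_driver_nodes(nx.Graph(), "fastest")


def _profiles(bit_rows, rids=("R1", "R2")):
    return [
        FluxProfile(f"S{i}", tuple(rids), np.array(b))
        for i, b in enumerate(bit_rows)
    ]


class TestAbnormalityFrequencies:
    def test_all_zero_profiles_give_zero_frequencies(self):
        freqs = abnormality_frequencies(_profiles([[0, 0], [0, 0]]))
        assert freqs["all"] == {"R1": 0.0, "R2": 0.0}

    def test_mean_of_bits(self):
        freqs = abnormality_frequencies(
            _profiles([[1, 0], [0, 0], [1, 1], [1, 0]])
        )
        assert freqs["all"]["R1"] == pytest.approx(0.75)
        assert freqs["all"]["R2"] == pytest.approx(0.25)

    def test_grouping_by_key(self):
        profiles = _profiles([[1, 0], [0, 0], [1, 1]])
        groups = {"S0": "ko", "S1": "wt", "S2": "ko"}
        freqs = abnormality_frequencies(profiles, groups)
        assert freqs["ko"]["R1"] == 1.0 and freqs["wt"]["R1"] == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidArgumentError):
            abnormality_frequencies([])


class TestNoiseThreshold:
    def test_closed_form_exponential_quantile(self):
        nt = noise_threshold([0.1] * 8, coverage=0.95)
        assert nt.rate == pytest.approx(10.0)
        assert nt.threshold == pytest.approx(-math.log(0.05) / 10.0)
        assert nt.threshold == pytest.approx(0.29957, abs=1e-5)

    def test_zero_coverage_gives_zero_threshold(self):
        assert noise_threshold([0.2, 0.4], coverage=0.0).threshold == 0.0

    def test_threshold_monotone_in_coverage_and_mean(self):
        t1 = noise_threshold([0.1], coverage=0.90).threshold
        t2 = noise_threshold([0.1], coverage=0.95).threshold
        t3 = noise_threshold([0.2], coverage=0.95).threshold
        assert t1 < t2 < t3

    def test_all_zero_frequencies_warn_and_return_zero(self):
        with pytest.warns(DegenerateFitWarning):
            nt = noise_threshold([0.0, 0.0])
        assert nt.threshold == 0.0


class TestClassSubnetwork:
    G = nx.path_graph(["R1", "R2", "R3"])

    def test_all_below_threshold_gives_empty_graph(self):
        H = class_subnetwork(self.G, {"R1": 0.1, "R2": 0.1, "R3": 0.1}, 0.5)
        assert H.number_of_nodes() == 0

    def test_single_selected_node(self):
        H = class_subnetwork(self.G, {"R1": 0.9, "R2": 0.1, "R3": 0.0}, 0.3)
        assert list(H.nodes()) == ["R1"]
        assert H.nodes["R1"]["frequency"] == pytest.approx(0.9)

    def test_induced_edges_match_adjacency(self):
        H = class_subnetwork(self.G, {"R1": 0.9, "R2": 0.8, "R3": 0.7}, 0.5)
        assert set(H.edges()) == {("R1", "R2"), ("R2", "R3")}


class TestAnnotatePathways:
    drivers = DriverSet(("R1", "R2"), (), "maximum")

    def test_empty_annotation_gives_na(self):
        out = annotate_pathways(self.drivers, {})
        assert out == {"R1": ["n/a"], "R2": ["n/a"]}

    def test_direct_annotation_passes_through(self):
        out = annotate_pathways(
            self.drivers, {"R1": ["Pyrimidine metabolism"]}
        )
        assert out["R1"] == ["Pyrimidine metabolism"]

    def test_unannotated_driver_inherits_sole_neighbour(self):
        G = nx.Graph([("R1", "R3"), ("R2", "R3")])
        out = annotate_pathways(
            self.drivers, {"R3": ["Glycolysis", "TCA cycle"]}, adjacency=G
        )
        assert out["R1"] == ["Glycolysis", "TCA cycle"]

    def test_malformed_annotation_rejected(self):
        with pytest.raises(ParseError):
            annotate_pathways(self.drivers, {"R1": "not-a-list"})
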