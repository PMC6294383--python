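"""Network construction, Newman-Girvan modularity, spin-glass detection."""
import itertools

import igraph as ig
import numpy as np
import pytest

from cooccurnet import (EdgeList, Network, Partition, build_edge_list,
                        build_network, detect_modules_sa, modularity_score)
from cooccurnet.errors import CoverageError, DegenerateNetworkError
from cooccurnet.synth import generate_planted_network
from cooccurnet.congruence import congruence_C


def set_partitions(items):
    """All set partitions (Bell-number enumeration) of a list."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [[first] + block] + smaller[i + 1:]
        yield [[first]] + smaller


def brute_force_max_q(net):
    best = None
    for blocks in set_partitions(list(net.nodes)):
        labels = {}
        for i, block in enumerate(blocks, start=1):
            for v in block:
                labels[v] = i
        p = Partition.from_labels(list(net.nodes), [labels[v] for v in net.nodes])
        q = modularity_score(net, p)
        if best is None or q > best[0]:
            best = (q, p)
    return best


def random_connected_net(rng, n, p=0.5):
    """Deterministic Erdos-Renyi-style connected graph from a numpy rng."""
    ids = [f"v{i}" for i in range(n)]
    while True:
        edges = [
            (ids[i], ids[j])
            for i in range(n)
            for j in range(i + 1, n)
            if rng.random() < p
        ]
        g = ig.Graph(n=n, edges=[(int(a[1:]), int(b[1:])) for a, b in edges])
        if g.is_connected() and len(edges) >= n - 1:
            return Network(nodes=tuple(ids), edges=tuple(edges))


def two_triangles(bridged):
    edges = [("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("e", "f"), ("d", "f")]
    if bridged:
        edges.append(("c", "d"))
    return Network(nodes=("a", "b", "c", "d", "e", "f"), edges=tuple(edges))


TRIANGLE_PART = Partition.from_labels(list("abcdef"), [1, 1, 1, 2, 2, 2])


class TestBuildNetwork:
    def test_simple_chain(self):
        e = EdgeList(pairs=(("A", "B"), ("B", "C")), co_counts=(1, 2))
        net = build_network(e)
        assert net.n_nodes == 3 and net.n_edges == 2

    def test_isolated_species_recorded(self):
        e = EdgeList(pairs=(("A", "B"),), co_counts=(1,))
        net = build_network(e, all_species=["A", "B", "C"])
        assert net.isolated == ("C",)
        assert "C" not in net.nodes

    def test_duplicate_edge_rejected(self):
        with pytest.raises(ValueError):
            Network(nodes=("A", "B"), edges=(("A", "B"), ("B", "A")))

    def test_empty_edge_list(self):
        with pytest.raises(DegenerateNetworkError):
            build_network(EdgeList(pairs=(), co_counts=()))

    def test_synthetic_counts_match_tally(self):
        net, truth = generate_planted_network(n_species=94 - 94 % 3 + 3, seed=5)
        # node/edge counts equal brute-force tally over the pair set
        nodes = {v for e in net.edges for v in e}
        assert set(net.nodes) == nodes
        assert net.n_edges == len({frozenset(e) for e in net.edges})


class TestModularityScore:
    def test_single_group_is_zero(self):
        net = two_triangles(bridged=True)
        p = Partition.from_labels(list("abcdef"), [1] * 6)
        assert modularity_score(net, p) == pytest.approx(0.0)

    def test_bridged_triangles_closed_form(self):
        # 7 edges; each triangle: 3 within, summed degree 7
        net = two_triangles(bridged=True)
        expect = 2 * (3 / 7 - (7 / 14) ** 2)
        assert modularity_score(net, TRIANGLE_PART) == pytest.approx(expect)
        assert expect == pytest.approx(0.357, abs=5e-4)

    def test_disconnected_triangles_half(self):
        net = two_triangles(bridged=False)
        assert modularity_score(net, TRIANGLE_PART) == pytest.approx(0.5)

    def test_brute_force_confirms_maxima(self):
        for bridged, expect in [(True, 2 * (3 / 7 - 0.25)), (False, 0.5)]:
            q, _ = brute_force_max_q(two_triangles(bridged))
            assert q == pytest.approx(expect)

    def test_agrees_with_igraph(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            net = random_connected_net(rng, 12, p=0.35)
            ids = list(net.nodes)
            g = net.to_igraph()
            membership = rng.integers(0, 3, size=12)
            p = Partition.from_labels(ids, [int(x) + 1 for x in membership])
            # igraph is the independent implementation of the same formula
            remap = {v: p.assignment[v] for v in ids}
            assert modularity_score(net, p) == pytest.approx(
                g.modularity([remap[v] - 1 for v in ids])
            )

    def test_label_permutation_invariance(self):
        net = two_triangles(bridged=True)
        swapped = Partition.from_labels(list("abcdef"), [2, 2, 2, 1, 1, 1])
        assert modularity_score(net, TRIANGLE_PART) == pytest.approx(
            modularity_score(net, swapped)
        )

    def test_missing_label_raises(self):
        net = two_triangles(bridged=True)
        p = Partition.from_labels(list("abcde"), [1, 1, 1, 2, 2])
        with pytest.raises(CoverageError):
            modularity_score(net, p)


class TestDetectModules:
    def test_two_cliques_with_bridge(self):
        nodes = [f"n{i}" for i in range(20)]
        edges = [
            (nodes[i], nodes[j])
            for block in (range(10), range(10, 20))
            for i, j in itertools.combinations(block, 2)
        ]
        edges.append((nodes[9], nodes[10]))
        net = Network(nodes=tuple(nodes), edges=tuple(edges))
        truth = Partition.from_labels(nodes, [1] * 10 + [2] * 10, "planted")
        for seed in range(3):
            res = detect_modules_sa(net, seed=seed)
            assert congruence_C(truth, res.partition).c == 1.0

    def test_planted_three_groups_recovered(self):
        net, truth = generate_planted_network(
            n_species=60, n_groups=3, p_in=0.9, p_out=0.05, seed=1
        )
        res = detect_modules_sa(net, seed=1, restarts=3)
        assert congruence_C(truth, res.partition).c == 1.0

    def test_deterministic_given_seed(self):
        net, _ = generate_planted_network(seed=2)
        a = detect_modules_sa(net, seed=42)
        b = detect_modules_sa(net, seed=42)
        assert a.partition.assignment == b.partition.assignment
        assert a.q == b.q

    def test_disconnected_components_all_labelled(self):
        nodes = [f"n{i}" for i in range(8)]
        edges = [
            (nodes[i], nodes[j])
            for block in (range(4), range(4, 8))
            for i, j in itertools.combinations(block, 2)
        ]
        net = Network(nodes=tuple(nodes), edges=tuple(edges))
        res = detect_modules_sa(net, seed=0)
        assert set(res.partition.species) == set(nodes)
        assert res.n_components == 2
        # the two cliques cannot share a label
        labs = res.partition.assignment
        assert {labs[n] for n in nodes[:4]} & {labs[n] for n in nodes[4:]} == set()

    def test_q_not_below_trivial_partition(self):
        net, _ = generate_planted_network(n_species=30, seed=7)
        res = detect_modules_sa(net, seed=7)
        assert res.q >= 0.0

    def test_matches_brute_force_on_small_graphs(self):
        rng = np.random.default_rng(99)
        for trial in range(4):
            n = int(rng.integers(5, 8))
            net = random_connected_net(rng, n)
            q_best, _ = brute_force_max_q(net)
            res = detect_modules_sa(net, seed=trial, restarts=5)
            assert res.q == pytest.approx(q_best, abs=1e-9)
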