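"""Alignment and median-joining networks, checked against brute oracles.

The oracle reimplements the same mathematical definition through different
primitives: link feasibility by graph connectivity over shorter edges
(networkx) instead of Kruskal + bottleneck distances, and exhaustive
quasi-median enumeration without caps.
"""

import itertools

import networkx as nx
import numpy as np
import pytest

from ribomine5s import (SimilarityOptions, align_small, alignment_stats,
                        cluster_by_threshold, mj_network, pairwise_identity)
from ribomine5s._util import random_seq
from ribomine5s.hapnet import Alignment


# ---------------------------------------------------------------------------
# independent oracle
# ---------------------------------------------------------------------------

def _dist(a, b):
    return sum(x != y for x, y in zip(a, b))


def _oracle_links(seqs, eps=0):
    """A pair is a feasible link iff its endpoints are disconnected using
    only strictly shorter edges (allowing epsilon slack)."""
    links = {}
    for i, j in itertools.combinations(range(len(seqs)), 2):
        d = _dist(seqs[i], seqs[j])
        g = nx.Graph()
        g.add_nodes_from(range(len(seqs)))
        for a, b in itertools.combinations(range(len(seqs)), 2):
            if _dist(seqs[a], seqs[b]) < d - eps:
                g.add_edge(a, b)
        if not nx.has_path(g, i, j):
            links[(i, j)] = d
    return links


def _oracle_cost(seqs, eps=0):
    return sum(_oracle_links(seqs, eps).values())


def _oracle_medians(u, v, w):
    cols = []
    for a, b, c in zip(u, v, w):
        if a == b or a == c:
            cols.append({a})
        elif b == c:
            cols.append({b})
        else:
            cols.append({a, b, c})
    return {"".join(p) for p in itertools.product(*cols)}


def _oracle_mj(rows, eps=0):
    """Greedy cost-reducing median joining, naively recomputed throughout."""
    current = sorted(set(rows.values()))
    medians = set()
    while True:
        links = _oracle_links(current, eps)
        cost = sum(links.values())
        best = None
        for i, j, k in itertools.combinations(range(len(current)), 3):
            pairs = [(min(x, y), max(x, y)) for x, y in
                     [(i, j), (i, k), (j, k)]]
            if not all(p in links for p in pairs):
                continue
            for m in _oracle_medians(current[i], current[j], current[k]):
                if m in current:
                    continue
                c = _oracle_cost(current + [m], eps)
                if c < cost and (best is None or (c, m) < best):
                    best = (c, m)
        if best is None:
            break
        medians.add(best[1])
        current.append(best[1])
        changed = True
        while changed:
            changed = False
            now = _oracle_cost(current, eps)
            for m in sorted(medians):
                trial = [s for s in current if s != m]
                if _oracle_cost(trial, eps) <= now:
                    current = trial
                    medians.discard(m)
                    changed = True
                    break
    links = _oracle_links(current, eps)
    edges = {frozenset((current[i], current[j])): w
             for (i, j), w in links.items()}
    return set(current), medians, edges


def _net_edges(net):
    return {frozenset((net.graph.nodes[u]["sequence"],
                       net.graph.nodes[v]["sequence"])): w
            for u, v, w in net.graph.edges.data("weight")}


# ---------------------------------------------------------------------------
# center-star alignment
# ---------------------------------------------------------------------------

class TestAlignSmall:
    def test_identical_sequences_align_gap_free(self):
        aln = align_small({"a": "ACGTACGT", "b": "ACGTACGT", "c": "ACGTACGT"})
        assert set(aln.rows.values()) == {"ACGTACGT"}

    def test_two_sequences_equal_optimal_pairwise(self):
        rng = np.random.default_rng(51)
        a, b = random_seq(rng, 60), random_seq(rng, 55)
        aln = align_small({"a": a, "b": b})
        opts = SimilarityOptions()
        from ribomine5s.igsfeat import _identity_from_rows

        induced = _identity_from_rows(aln.rows["a"], aln.rows["b"], opts)
        assert induced == pytest.approx(pairwise_identity(a, b, opts))

    def test_induced_identity_close_to_pairwise_optimum(self):
        rng = np.random.default_rng(52)
        base = random_seq(rng, 50)
        seqs = {}
        for i in range(4):
            chars = list(base)
            for p in rng.choice(50, size=3, replace=False):
                chars[p] = "ACGT"[rng.integers(4)]
            seqs[f"s{i}"] = "".join(chars)
        aln = align_small(seqs)
        opts = SimilarityOptions()
        from ribomine5s.igsfeat import _identity_from_rows

        for x, y in itertools.combinations(seqs, 2):
            induced = _identity_from_rows(aln.rows[x], aln.rows[y], opts)
            optimal = pairwise_identity(seqs[x], seqs[y], opts)
            assert induced <= optimal + 1e-9
            assert induced >= optimal - 5.0


class TestAlignmentStats:
    def test_identical_pair(self):
        aln = Alignment({"a": "A" * 100, "b": "A" * 100})
        assert alignment_stats(aln) == (100, 100, 100.0)

    def test_gap_column_not_identical(self):
        aln = Alignment({"a": "AC-T", "b": "ACGT"})
        length, ident, _ = alignment_stats(aln)
        assert (length, ident) == (4, 3)

    def test_random_alignment_matches_brute_force(self):
        rng = np.random.default_rng(53)
        rows = {f"r{i}": "".join(rng.choice(list("ACGT-"), size=50))
                for i in range(4)}
        aln = Alignment(rows)
        length, ident, mean_id = alignment_stats(aln)
        assert length == 50
        ident_oracle = sum(
            1 for c in zip(*rows.values())
            if len(set(c)) == 1 and c[0] != "-")
        assert ident == ident_oracle
        from ribomine5s.igsfeat import _identity_from_rows

        vals = [_identity_from_rows(a, b, SimilarityOptions())
                for a, b in itertools.combinations(rows.values(), 2)]
        assert mean_id == pytest.approx(sum(vals) / len(vals))


# ---------------------------------------------------------------------------
# median-joining network
# ---------------------------------------------------------------------------

class TestMJNetwork:
    def test_two_haplotypes_distance_one(self):
        net = mj_network(Alignment({"a": "AAAA", "b": "GAAA"}))
        assert net.graph.number_of_nodes() == 2
        assert list(net.graph.edges.data("weight")) == [("a", "b", 1)]

    def test_disjoint_triplet_gains_one_median(self):
        net = mj_network(Alignment({"x": "GAA", "y": "AGA", "z": "AAG"}))
        assert net.medians == ["m1"]
        m = net.graph.nodes["m1"]
        assert m["sequence"] == "AAA"
        assert sorted(w for _, _, w in net.graph.edges.data("weight")) \
            == [1, 1, 1]

    def test_identical_rows_collapse_with_multiplicity(self):
        net = mj_network(Alignment({"a": "ACGT", "b": "ACGT", "c": "ACGA"}))
        assert net.graph.nodes["a"]["multiplicity"] == 2

    def test_unique_mst_without_savings_is_returned_exactly(self):
        # chain with strictly increasing, non-tied distances
        rows = {"a": "AAAAAAAA", "b": "GAAAAAAA", "c": "GGGAAAAA"}
        net = mj_network(Alignment(rows))
        g = nx.Graph()
        for x, y in itertools.combinations(rows, 2):
            g.add_edge(x, y, weight=_dist(rows[x], rows[y]))
        mst = nx.minimum_spanning_tree(g)
        assert {frozenset(e) for e in net.graph.edges} == \
            {frozenset(e) for e in mst.edges}

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(2, 6))
        length = int(rng.integers(4, 11))
        rows = {f"h{i}": "".join(rng.choice(list("ACG"), size=length))
                for i in range(n)}
        net = mj_network(Alignment(rows))
        nodes, medians, edges = _oracle_mj(rows)
        assert {d["sequence"] for _, d in net.graph.nodes(data=True)} == nodes
        assert _net_edges(net) == edges
        # every observed haplotype is a node
        seqs = {d["sequence"] for _, d in net.graph.nodes(data=True)}
        assert set(rows.values()) <= seqs
        # construction never exceeds the initial spanning-network cost
        assert net.total_weight <= _oracle_cost(sorted(set(rows.values())))

    def test_input_order_permutation_gives_isomorphic_network(self):
        rng = np.random.default_rng(54)
        rows = {f"h{i}": "".join(rng.choice(list("ACG"), size=8))
                for i in range(5)}
        net1 = mj_network(Alignment(rows))
        perm = dict(reversed(list(rows.items())))
        net2 = mj_network(Alignment(perm))
        assert _net_edges(net1) == _net_edges(net2)

    def test_all_identical_is_single_node(self):
        net = mj_network(Alignment({"a": "ACGT", "b": "ACGT"}))
        assert net.graph.number_of_nodes() == 1


class TestClusters:
    def _toy_net(self):
        rng = np.random.default_rng(55)
        base = {}
        for g in range(3):  # three tight groups >=5 differences apart
            anchor = list("ACGTACGTACGTACGTACGT")
            for p in range(g * 7, g * 7 + 6):
                anchor[p] = "T" if anchor[p] != "T" else "A"
            base[f"g{g}a"] = "".join(anchor)
            mutated = list(anchor)
            mutated[-1 - g] = "C" if mutated[-1 - g] != "C" else "G"
            base[f"g{g}b"] = "".join(mutated)
        return mj_network(Alignment(base))

    def test_threshold_extremes(self):
        net = self._toy_net()
        weights = [w for _, _, w in net.graph.edges.data("weight")]
        _, sizes = cluster_by_threshold(net, max_edge=max(weights))
        assert len(sizes) == 1
        assignment, sizes0 = cluster_by_threshold(net, max_edge=0)
        observed = [n for n, d in net.graph.nodes(data=True)
                    if d["kind"] == "observed"]
        assert all(sizes0[assignment[n]] >= 1 for n in observed)

    def test_three_designed_clusters(self):
        net = self._toy_net()
        assignment, sizes = cluster_by_threshold(net, max_edge=2)
        observed = {n for n, d in net.graph.nodes(data=True)
                    if d["kind"] == "observed"}
        assert len(sizes) >= 3
        by_cluster = {}
        for n in observed:
            by_cluster.setdefault(assignment[n], set()).add(n)
        groups = [{f"g{g}a", f"g{g}b"} for g in range(3)]
        for grp in groups:
            assert any(grp <= members for members in by_cluster.values())

    def test_partition_property(self):
        net = self._toy_net()
        assignment, sizes = cluster_by_threshold(net, max_edge=3)
        observed = [n for n, d in net.graph.nodes(data=True)
                    if d["kind"] == "observed"]
        assert set(assignment) >= set(observed)
        assert sum(sizes.values()) == len(observed)
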