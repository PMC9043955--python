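"""Median-joining haplotype networks over aligned spacer sequences.

The median-joining (MJ) construction connects observed haplotypes through a
minimum-spanning network (the union of all minimum spanning trees, relaxed
by a tolerance epsilon) and augments it with inferred intermediate
("median") haplotypes: for triplets of mutually connected nodes the
quasi-median — column-wise majority, with fully ambiguous columns expanded
over the three observed states — is added whenever it lowers the total
network cost. Gaps count as a fifth character state: spacer evolution is
indel-rich and the indels carry most of the signal the networks display.

Also provides a deterministic center-star progressive aligner for small
sequence sets and the usual alignment summary statistics.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx

from ._util import aligned_rows
from .igsfeat import SimilarityOptions

__all__ = [
    "Alignment",
    "HaplotypeNetwork",
    "align_small",
    "alignment_stats",
    "mj_network",
    "cluster_by_threshold",
    "write_graphml",
    "write_dot",
]

log = logging.getLogger(__name__)

#: quasi-median expansion cap: beyond this many fully ambiguous columns the
#: candidate set is truncated deterministically (documented approximation)
MAX_AMBIGUOUS_COLUMNS = 8


@dataclass
class Alignment:
    rows: dict[str, str]

    def __post_init__(self) -> None:
        lens = {len(s) for s in self.rows.values()}
        if len(lens) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0


def align_small(
    seqs: dict[str, str],
    opts: SimilarityOptions | None = None,
) -> Alignment:
    """Center-star progressive alignment of 2-200 sequences.

    The center is the sequence maximizing the summed pairwise alignment
    score (ties by id); every other sequence is aligned to the center and
    the pairwise alignments are merged by the once-a-gap-always-a-gap rule.
    """
    opts = opts or SimilarityOptions()
    if not seqs:
        raise ValueError("no sequences")
    if len(seqs) > 200:
        raise ValueError("center-star aligner is for small sets (<=200)")
    ids = list(seqs)
    if len(ids) == 1:
        return Alignment({ids[0]: seqs[ids[0]]})
    aligner = opts.aligner()
    totals = {i: 0.0 for i in ids}
    for a, b in itertools.combinations(ids, 2):
        s = aligner.score(seqs[a], seqs[b])
        totals[a] += s
        totals[b] += s
    center = min(ids, key=lambda i: (-totals[i], i))
    L = len(seqs[center])
    pair_rows: dict[str, tuple[str, str]] = {}
    master = [0] * (L + 1)
    for i in ids:
        if i == center:
            continue
        ca, sa = aligned_rows(seqs[center], seqs[i], aligner)
        pair_rows[i] = (ca, sa)
        ins = [0] * (L + 1)
        p = 0
        for c in ca:
            if c == "-":
                ins[p] += 1
            else:
                p += 1
        for p in range(L + 1):
            master[p] = max(master[p], ins[p])
    center_row = []
    for p in range(L):
        center_row.append("-" * master[p])
        center_row.append(seqs[center][p])
    center_row.append("-" * master[L])
    rows = {center: "".join(center_row)}
    for i in ids:
        if i == center:
            continue
        ca, sa = pair_rows[i]
        out = []
        p = 0
        j = 0
        for p in range(L + 1):
            gap_chars = []
            while j < len(ca) and ca[j] == "-":
                gap_chars.append(sa[j])
                j += 1
            out.append("".join(gap_chars))
            out.append("-" * (master[p] - len(gap_chars)))
            if p < L:
                out.append(sa[j])
                j += 1
        rows[i] = "".join(out)
    return Alignment({i: rows[i] for i in ids})


def alignment_stats(aln: Alignment,
                    opts: SimilarityOptions | None = None
                    ) -> tuple[int, int, float]:
    """(alignment length, identical sites, mean pairwise identity %).

    An identical site is a column where every row carries the same non-gap
    base; mean pairwise identity averages over all unordered row pairs with
    the configured identity denominator.
    """
    opts = opts or SimilarityOptions()
    rows = list(aln.rows.values())
    if len(rows) < 2:
        raise ValueError("need at least two rows")
    identical = 0
    for col in zip(*rows):
        s = set(col)
        if len(s) == 1 and "-" not in s:
            identical += 1
    from .igsfeat import _identity_from_rows

    idents = [_identity_from_rows(a, b, opts)
              for a, b in itertools.combinations(rows, 2)]
    return aln.length, identical, sum(idents) / len(idents)


# ---------------------------------------------------------------------------
# median-joining network
# ---------------------------------------------------------------------------

def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _feasible_links(
    seqs: list[str], epsilon: int,
    cache: dict[tuple[str, str], int] | None = None,
) -> dict[tuple[int, int], int]:
    """Minimum-spanning-network links with tolerance epsilon.

    A pair is linked iff its distance is within epsilon of the bottleneck
    (minimax-path) distance, computed over an MST built by Kruskal with a
    deterministic tie order.
    """
    n = len(seqs)
    d = {}
    for i, j in itertools.combinations(range(n), 2):
        if cache is None:
            d[(i, j)] = _hamming(seqs[i], seqs[j])
        else:
            key = (seqs[i], seqs[j]) if seqs[i] <= seqs[j] \
                else (seqs[j], seqs[i])
            if key not in cache:
                cache[key] = _hamming(*key)
            d[(i, j)] = cache[key]
    # Kruskal MST
    uf = _UnionFind(range(n))
    mst = nx.Graph()
    mst.add_nodes_from(range(n))
    for (i, j), w in sorted(d.items(), key=lambda kv: (kv[1], kv[0])):
        if uf.find(i) != uf.find(j):
            uf.union(i, j)
            mst.add_edge(i, j, weight=w)
    # bottleneck distances by DFS from each node
    bottleneck = {}
    for src in range(n):
        stack = [(src, 0)]
        seen = {src}
        while stack:
            node, mx = stack.pop()
            for nb in mst.neighbors(node):
                if nb not in seen:
                    seen.add(nb)
                    b = max(mx, mst[node][nb]["weight"])
                    bottleneck[(min(src, nb), max(src, nb))] = b
                    stack.append((nb, b))
    return {ij: w for ij, w in d.items()
            if w <= bottleneck[ij] + epsilon}


def _quasi_medians(u: str, v: str, w: str) -> list[str]:
    """Column-majority consensus; fully ambiguous columns expand."""
    fixed: list[str] = []
    options: list[tuple[int, tuple[str, str, str]]] = []
    for pos, (a, b, c) in enumerate(zip(u, v, w)):
        if a == b or a == c:
            fixed.append(a)
        elif b == c:
            fixed.append(b)
        else:
            fixed.append("?")
            options.append((pos, (a, b, c)))
    if not options:
        return ["".join(fixed)]
    options = options[:MAX_AMBIGUOUS_COLUMNS]
    out = []
    for combo in itertools.product(*[states for _, states in options]):
        cand = list(fixed)
        for (pos, _), st in zip(options, combo):
            cand[pos] = st
        # any ambiguous column beyond the cap falls back to the first state
        for k in range(len(cand)):
            if cand[k] == "?":
                cand[k] = u[k]
        out.append("".join(cand))
    return sorted(set(out))


def _network_cost(
    seqs: list[str], epsilon: int,
    cache: dict[tuple[str, str], int] | None = None,
) -> int:
    return sum(_feasible_links(seqs, epsilon, cache).values())


@dataclass
class HaplotypeNetwork:
    graph: nx.Graph
    epsilon: int = 0
    observed: dict[str, int] = field(default_factory=dict)  # name -> multiplicity
    medians: list[str] = field(default_factory=list)

    @property
    def total_weight(self) -> int:
        return sum(w for _, _, w in self.graph.edges.data("weight"))


def mj_network(aln: Alignment, epsilon: int = 0) -> HaplotypeNetwork:
    """Median-joining network of the distinct haplotypes in an alignment.

    Iterates: (1) feasible links of the current node set; (2) for every
    mutually connected triplet, candidate quasi-medians; the candidate
    giving the largest cost reduction (ties by sequence) is added; (3)
    median nodes whose removal does not raise the cost are deleted; repeat
    to fixpoint. Distances count gap as a fifth state.
    """
    if not aln.rows:
        raise ValueError("empty alignment")
    groups: dict[str, list[str]] = {}
    for rid in sorted(aln.rows):
        groups.setdefault(aln.rows[rid], []).append(rid)
    observed = sorted(groups)  # sequences
    name_of = {s: min(groups[s]) for s in observed}
    mult_of = {s: len(groups[s]) for s in observed}

    current: list[str] = list(observed)
    medians: set[str] = set()
    cache: dict[tuple[str, str], int] = {}
    guard = 0
    while True:
        guard += 1
        if guard > 200:
            log.warning("hapnet: median-joining iteration cap reached")
            break
        links = _feasible_links(current, epsilon, cache)
        cost = sum(links.values())
        linked = set(links)
        best: tuple[int, str] | None = None
        for i, j, k in itertools.combinations(range(len(current)), 3):
            if (i, j) in linked and (i, k) in linked and (j, k) in linked:
                for m in _quasi_medians(current[i], current[j], current[k]):
                    if m in current:
                        continue
                    new_cost = _network_cost(current + [m], epsilon, cache)
                    if new_cost < cost and \
                            (best is None or (new_cost, m) < best):
                        best = (new_cost, m)
        if best is None:
            break
        medians.add(best[1])
        current.append(best[1])
        # prune obsolete medians
        changed = True
        while changed:
            changed = False
            cost_now = _network_cost(current, epsilon, cache)
            for m in sorted(medians):
                trial = [s for s in current if s != m]
                if _network_cost(trial, epsilon, cache) <= cost_now:
                    current = trial
                    medians.discard(m)
                    changed = True
                    break

    labels: dict[str, str] = {}
    mcount = 0
    med_list = sorted(m for m in current if m in medians)
    for s in current:
        if s in medians:
            mcount += 1
            labels[s] = f"m{med_list.index(s) + 1}"
        else:
            labels[s] = name_of[s]
    g = nx.Graph()
    for s in sorted(current, key=lambda s: labels[s]):
        g.add_node(labels[s], sequence=s,
                   kind="inferred" if s in medians else "observed",
                   multiplicity=mult_of.get(s, 0),
                   members=",".join(groups.get(s, [])))
    links = _feasible_links(current, epsilon, cache)
    for (i, j), w in sorted(links.items()):
        g.add_edge(labels[current[i]], labels[current[j]], weight=int(w))
    return HaplotypeNetwork(
        graph=g, epsilon=epsilon,
        observed={name_of[s]: mult_of[s] for s in observed},
        medians=[labels[m] for m in med_list],
    )


def cluster_by_threshold(
    net: HaplotypeNetwork, max_edge: int = 3,
) -> tuple[dict[str, str], dict[str, int]]:
    """Connected components after dropping edges heavier than ``max_edge``.

    Returns (node -> cluster label, cluster label -> observed-node count);
    a cluster is labeled by its smallest member name.
    """
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes(data=True))
    for u, v, w in net.graph.edges.data("weight"):
        if w <= max_edge:
            g.add_edge(u, v)
    assignment: dict[str, str] = {}
    sizes: dict[str, int] = {}
    for comp in nx.connected_components(g):
        label = min(comp)
        n_obs = sum(1 for n in comp
                    if net.graph.nodes[n]["kind"] == "observed")
        sizes[label] = n_obs
        for n in comp:
            assignment[n] = label
    return assignment, sizes


def write_graphml(net: HaplotypeNetwork, path) -> None:
    nx.write_graphml(net.graph, path)


def write_dot(net: HaplotypeNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("graph hapnet {\n")
        for n, data in net.graph.nodes(data=True):
            shape = "circle" if data["kind"] == "observed" else "point"
            fh.write(f'  "{n}" [shape={shape}];\n')
        for u, v, w in net.graph.edges.data("weight"):
            fh.write(f'  "{u}" -- "{v}" [label={w}];\n')
        fh.write("}\n")
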