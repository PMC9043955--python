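"""Assemble filtered reads and recover complete 5S repeat units.

A tandem array collapses in a k-mer (de Bruijn) graph to a cycle: the
conserved CDS and every stretch of spacer shared between ribotypes merge,
while ribotype-specific sites form bubbles. Three stages live here:

1. ``build_graph`` — strand-canonical k-mer counting (k odd, so no k-mer is
   its own reverse complement).
2. ``prune_and_assemble`` — coverage pruning and compaction into maximal
   unbranched contigs (unitigs); cyclic components are linearized with a
   canonical rotation.
3. unit recovery — ``extract_repeat_units`` locates CDS anchors (full or
   terminal fragments, indel-tolerant) on contigs and cuts out
   CDS+IGS units; ``assemble_units`` additionally *phases* bubble chains by
   threading reads through the unitig graph and enumerating read-supported
   CDS-to-CDS paths, which is what recovers every ribotype when several
   near-identical spacers share most of their sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib
import numpy as np

from ._util import canonical, revcomp
from .cdsfilter import make_probes
from .simarray import ReadLibrary

__all__ = [
    "AssemblyConfig",
    "KmerGraph",
    "Contig",
    "RepeatUnit",
    "build_graph",
    "prune_and_assemble",
    "extract_repeat_units",
    "assemble_units",
    "write_contigs_fasta",
    "write_units_fasta",
    "read_units_fasta",
    "write_graphml",
]

log = logging.getLogger(__name__)

_ACGT = "ACGT"


@dataclass
class AssemblyConfig:
    """k-mer assembly parameters.

    The real-data coverage threshold (100 reads) assumes deep libraries;
    synthetic runs use 5 (error-free) or 20 (error-bearing) — see the
    methods note for the noise bounds behind those choices.
    """

    k: int = 31
    min_kmer_coverage: int = 100
    max_contigs_reported: int = 12
    min_overlap_identity: float = 1.0
    max_cds_mismatches: int = 5
    max_unit_bases: int = 3000
    max_paths: int = 500
    min_pair_reads: int = 2
    strong_pair_reads: int = 8
    strong_span_margin: int = 50

    def __post_init__(self) -> None:
        if self.k % 2 == 0 or self.k < 15:
            raise ValueError("k must be odd and >= 15")
        if self.min_kmer_coverage < 1:
            raise ValueError("min_kmer_coverage must be >= 1")


@dataclass
class KmerGraph:
    """Node-centric de Bruijn graph over strand-canonical k-mers.

    Edges are implicit: two k-mers are adjacent iff they overlap by k-1
    bases; ``successors`` enumerates them on demand.
    """

    k: int
    counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.counts)

    def coverage(self, kmer: str) -> int:
        return self.counts.get(canonical(kmer), 0)

    def successors(self, kmer: str, nodes: set[str] | None = None) -> list[str]:
        ns = nodes if nodes is not None else self.counts
        out = []
        suf = kmer[1:]
        for b in _ACGT:
            t = suf + b
            if canonical(t) in ns:
                out.append(t)
        return out

    def predecessors(self, kmer: str, nodes: set[str] | None = None) -> list[str]:
        ns = nodes if nodes is not None else self.counts
        out = []
        pre = kmer[:-1]
        for b in _ACGT:
            t = b + pre
            if canonical(t) in ns:
                out.append(t)
        return out


@dataclass
class Contig:
    id: str
    seq: str
    mean_coverage: float
    circular: bool = False
    cyclic_length: int = 0  # number of distinct bases when circular


@dataclass
class RepeatUnit:
    """One repeat on the CDS-sense strand: unit_seq = cds_seq + igs_seq."""

    unit_seq: str
    cds_seq: str
    igs_seq: str
    source_contig: str
    mean_coverage: float
    igs_coords: tuple[int, int]

    def __post_init__(self) -> None:
        if self.unit_seq != self.cds_seq + self.igs_seq:
            raise ValueError("unit_seq must equal cds_seq + igs_seq")
        if not self.igs_seq:
            raise ValueError("unit has empty IGS")


def build_graph(reads: ReadLibrary, config: AssemblyConfig) -> KmerGraph:
    """Count canonical k-mers over all read windows; k-mers with N skipped."""
    k = config.k
    counts: dict[str, int] = {}
    for r in reads.reads:
        s = r.seq.upper()
        for i in range(len(s) - k + 1):
            km = s[i:i + k]
            if "N" in km:
                continue
            c = canonical(km)
            counts[c] = counts.get(c, 0) + 1
    if not counts:
        log.warning("unitasm: empty read set, empty graph")
    return KmerGraph(k=k, counts=counts)


# ---------------------------------------------------------------------------
# compaction
# ---------------------------------------------------------------------------

def _canonical_rotation(cyc: str) -> str:
    """Lexicographically minimal rotation over both strands of a cyclic seq."""
    best = None
    for s in (cyc, revcomp(cyc)):
        for i in range(len(s)):
            rot = s[i:] + s[:i]
            if best is None or rot < best:
                best = rot
    return best


def _compact(graph: KmerGraph, min_cov: int) -> list[Contig]:
    """Maximal unbranched paths over nodes with coverage >= min_cov."""
    k = graph.k
    ns = {c for c, cov in graph.counts.items() if cov >= min_cov}
    succ = lambda s: graph.successors(s, ns)
    pred = lambda s: graph.predecessors(s, ns)
    visited: set[str] = set()
    raw: list[tuple[str, float, bool]] = []

    def _walk(start: str) -> list[str]:
        path = [start]
        seen = {canonical(start)}
        cur = start
        while True:
            sc = succ(cur)
            if len(sc) != 1:
                break
            nxt = sc[0]
            if len(pred(nxt)) != 1:
                break
            cn = canonical(nxt)
            if cn in visited or cn in seen:
                break
            path.append(nxt)
            seen.add(cn)
            cur = nxt
        return path

    # linear unitigs: start anywhere the backwards extension is not unique
    for c in sorted(ns):
        if c in visited:
            continue
        for s in (c, revcomp(c)):
            ps = pred(s)
            if len(ps) != 1 or len(succ(ps[0])) != 1:
                path = _walk(s)
                visited.update(canonical(p) for p in path)
                seq = path[0] + "".join(p[-1] for p in path[1:])
                cov = float(np.mean([graph.counts[canonical(p)] for p in path]))
                raw.append((min(seq, revcomp(seq)), cov, False))
                break

    # leftovers are pure cycles
    for c in sorted(ns):
        if c in visited:
            continue
        path = [c]
        visited.add(c)
        cur = c
        while True:
            sc = succ(cur)
            if not sc:
                break
            nxt = sc[0]
            if canonical(nxt) == c:
                break
            path.append(nxt)
            visited.add(canonical(nxt))
            cur = nxt
        cyc = "".join(p[-1] for p in path)  # one base per node
        rot = _canonical_rotation(cyc)
        spelled = rot + rot[:k - 1]
        cov = float(np.mean([graph.counts[canonical(p)] for p in path]))
        raw.append((spelled, cov, True))

    raw.sort(key=lambda t: (-t[1], t[0]))
    contigs = []
    for i, (seq, cov, circ) in enumerate(raw):
        contigs.append(Contig(
            id=f"ctg{i + 1}", seq=seq, mean_coverage=cov, circular=circ,
            cyclic_length=len(seq) - (graph.k - 1) if circ else 0,
        ))
    return contigs


def prune_and_assemble(graph: KmerGraph, config: AssemblyConfig) -> list[Contig]:
    """Prune low-coverage k-mers, compact, rank by mean coverage.

    Returns at most ``max_contigs_reported`` contigs (highest coverage first;
    real 5S repeats dominate coverage by orders of magnitude, so a small cap
    suffices and mirrors keeping only the top contigs of a targeted assembly).
    """
    contigs = _compact(graph, config.min_kmer_coverage)
    return contigs[:config.max_contigs_reported]


# ---------------------------------------------------------------------------
# CDS anchoring
# ---------------------------------------------------------------------------

@dataclass
class _Anchor:
    start: int           # may be negative (CDS suffix at contig start)
    end: int             # may exceed len(seq) (CDS prefix at contig end)
    observed: str        # bases actually present on the contig
    cds_from: int        # first reference CDS position covered
    cds_to: int          # one-past-last reference CDS position covered
    distance: int


def _orient_by_probes(seq: str, probe_map: dict[str, int]) -> tuple[str, int, int]:
    """Return (oriented seq, fwd hits, rc hits) using exact CDS 20-mers."""
    plen = len(next(iter(probe_map)))
    fwd = sum(1 for i in range(len(seq) - plen + 1)
              if seq[i:i + plen] in probe_map)
    rc_seq = revcomp(seq)
    rev = sum(1 for i in range(len(rc_seq) - plen + 1)
              if rc_seq[i:i + plen] in probe_map)
    if rev > fwd:
        return rc_seq, fwd, rev
    return seq, fwd, rev


def _find_anchors(seq: str, cds: str, max_mm: int,
                  probe_map: dict[str, int], min_fragment: int = 20) -> list[_Anchor]:
    """CDS occurrences on an oriented contig, tolerant of small indels.

    Exact 20-mer seeds vote for candidate CDS start offsets; each candidate
    region is then verified by infix alignment (edlib), so pseudogenized
    copies with 1-2 bp CDS indels still anchor. Occurrences truncated at the
    contig boundary are reported as partial anchors.
    """
    plen = len(next(iter(probe_map)))
    L = len(cds)
    votes: dict[int, int] = {}
    for i in range(len(seq) - plen + 1):
        off = probe_map.get(seq[i:i + plen])
        if off is not None:
            start = i - off
            votes[start] = votes.get(start, 0) + 1
    # cluster candidate starts within +-4 (indel slack)
    anchors: list[_Anchor] = []
    taken: list[tuple[int, int]] = []
    for start in sorted(votes, key=lambda s: (-votes[s], s)):
        if any(abs(start - t) <= 4 for t, _ in taken):
            continue
        cds_from = max(0, -start)
        cds_to = min(L, len(seq) - start)
        if cds_to - cds_from < min_fragment:
            continue
        frag = cds[cds_from:cds_to]
        w0 = max(0, start + cds_from - 4)
        w1 = min(len(seq), start + cds_to + 4)
        res = edlib.align(frag, seq[w0:w1], mode="HW", task="locations",
                          k=max_mm)
        if res["editDistance"] < 0:
            continue
        loc = res["locations"][0]
        obs_s, obs_e = w0 + loc[0], w0 + loc[1] + 1
        anchors.append(_Anchor(
            start=obs_s - cds_from, end=obs_e + (L - cds_to),
            observed=seq[obs_s:obs_e], cds_from=cds_from, cds_to=cds_to,
            distance=res["editDistance"],
        ))
        taken.append((start, votes[start]))
    anchors.sort(key=lambda a: a.start)
    # drop overlapping duplicates (same occurrence seeded twice)
    dedup: list[_Anchor] = []
    for a in anchors:
        if dedup and a.start < dedup[-1].end - L // 2:
            continue
        dedup.append(a)
    return dedup


def extract_repeat_units(
    contigs: list[Contig],
    cds_reference: str,
    max_cds_mismatches: int = 5,
    probe_length: int = 20,
) -> list[RepeatUnit]:
    """Cut CDS+IGS units out of contigs between consecutive CDS anchors.

    Contigs are first oriented to the CDS sense; a contig with exact probe
    hits on both strands is flagged anomalous and skipped. Circular contigs
    are doubled so a unit can be read across the wrap point; the unit start
    is canonical (first base of the upstream CDS occurrence). Where only a
    terminal CDS fragment is present, the unit CDS is the reference overlaid
    with the observed fragment.
    """
    if not cds_reference:
        raise ValueError("empty CDS reference")
    cds = cds_reference.upper()
    probe_map = {}
    pset = make_probes(cds, probe_length)
    for i in range(len(cds) - probe_length + 1):
        probe_map.setdefault(cds[i:i + probe_length], i)
    units: list[RepeatUnit] = []
    n_short, n_anom = 0, 0
    for ctg in contigs:
        seq = ctg.seq
        limit = len(seq)
        if ctg.circular:
            core = seq[:ctg.cyclic_length]
            seq = core + seq  # two wraps and change
            limit = ctg.cyclic_length
        oriented, fwd, rev = _orient_by_probes(seq, probe_map)
        if fwd and rev:
            log.warning("unitasm: contig %s has CDS hits on both strands",
                        ctg.id)
            n_anom += 1
            continue
        if fwd == 0 and rev == 0:
            n_short += 1
            continue
        anchors = _find_anchors(oriented, cds, max_cds_mismatches, probe_map)
        if len(anchors) < 2:
            n_short += 1
            continue
        for a1, a2 in zip(anchors, anchors[1:]):
            if ctg.circular and not 0 <= a1.start < limit:
                continue  # wrap duplicate (the full anchor recurs in-range)
            igs = oriented[a1.end:a2.start]
            if not igs:
                continue
            obs_cds = (cds[:a1.cds_from] + a1.observed + cds[a1.cds_to:])
            unit = obs_cds + igs
            units.append(RepeatUnit(
                unit_seq=unit, cds_seq=obs_cds, igs_seq=igs,
                source_contig=ctg.id, mean_coverage=ctg.mean_coverage,
                igs_coords=(len(obs_cds), len(unit)),
            ))
    if n_short or n_anom:
        log.info("unitasm: %d contigs without an anchor pair, %d anomalous",
                 n_short, n_anom)
    return units


# ---------------------------------------------------------------------------
# read-threaded phasing
# ---------------------------------------------------------------------------

def _unitig_index(contigs: list[Contig], k: int) -> dict[str, tuple[int, int]]:
    idx: dict[str, tuple[int, int]] = {}
    for ui, ctg in enumerate(contigs):
        n = ctg.cyclic_length if ctg.circular else len(ctg.seq) - k + 1
        for i in range(n):
            idx[canonical(ctg.seq[i:i + k])] = (ui, i)
    return idx


def _spell(ctg: Contig, orient: str) -> str:
    return ctg.seq if orient == "+" else revcomp(ctg.seq)


def _successor_unitigs(
    contigs: list[Contig], idx: dict[str, tuple[int, int]],
    uid: int, orient: str, k: int,
) -> list[tuple[int, str]]:
    s = _spell(contigs[uid], orient)
    last = s[-k:]
    out = []
    for b in _ACGT:
        t = last[1:] + b
        hit = idx.get(canonical(t))
        if hit is None:
            continue
        vid, off = hit
        v = contigs[vid]
        if v.circular:
            continue  # a cycle is its own complete unit; no threading needed
        if v.seq[off:off + k] == t and off == 0:
            out.append((vid, "+"))
        elif revcomp(t) == v.seq[off:off + k] and off == len(v.seq) - k:
            out.append((vid, "-"))
    return sorted(set(out))


def _thread_reads(
    reads: ReadLibrary, contigs: list[Contig],
    idx: dict[str, tuple[int, int]], k: int,
) -> tuple[dict[frozenset, dict[int, int]], set[frozenset]]:
    """Map reads to unitig paths; collect gap-annotated co-occurrence.

    For every pair of unitigs visited by one read the signed gap between
    their spans within the read is recorded with a read count. The gap
    equals the genomic distance between the unitig spans, which lets the
    path enumeration distinguish genuine within-unit phasing evidence from
    a read that merely crosses the junction into the neighbouring repeat
    copy (where the same two unitigs can co-occur at a very different
    spacing).
    """
    pair_gaps: dict[frozenset, dict[int, int]] = {}
    edge_support: set[frozenset] = set()
    for r in reads.reads:
        s = r.seq.upper()
        spans: list[list[int]] = []  # [uid, first_pos, last_pos + k)
        for i in range(len(s) - k + 1):
            km = s[i:i + k]
            if "N" in km:
                continue
            hit = idx.get(canonical(km))
            if hit is None:
                continue
            if spans and spans[-1][0] == hit[0]:
                spans[-1][2] = i + k
            else:
                spans.append([hit[0], i, i + k])
        for (a, *_), (b, *_) in zip(spans, spans[1:]):
            edge_support.add(frozenset((a, b)))
        for x in range(len(spans)):
            for y in range(x + 1, len(spans)):
                ua, _, ea = spans[x]
                ub, sb, _ = spans[y]
                if ua == ub:
                    continue
                gap = sb - ea  # signed inter-span distance
                key = frozenset((ua, ub))
                pair_gaps.setdefault(key, {})
                pair_gaps[key][gap] = pair_gaps[key].get(gap, 0) + 1
    return pair_gaps, edge_support


def _cds_orientation(ctg: Contig, probe_map: dict[str, int]) -> str | None:
    _, fwd, rev = _orient_by_probes(ctg.seq, probe_map)
    if fwd == 0 and rev == 0:
        return None
    return "+" if fwd >= rev else "-"


def assemble_units(
    reads: ReadLibrary,
    cds_reference: str,
    config: AssemblyConfig,
    probe_length: int = 20,
) -> list[RepeatUnit]:
    """Full unit recovery: graph, compaction, read-threaded phasing.

    Cyclic paths through CDS-bearing unitigs are enumerated depth-first;
    wherever the graph branches, consecutive branch choices must co-occur in
    at least one read (bubble-chain phasing) and every junction crossed must
    be read-supported. Each accepted path is stitched and cut into units by
    the CDS-anchor extractor; units are deduplicated by sequence.
    """
    graph = build_graph(reads, config)
    contigs = _compact(graph, config.min_kmer_coverage)
    if not contigs:
        return []
    k = config.k
    cds = cds_reference.upper()
    probe_map: dict[str, int] = {}
    for i in range(len(cds) - probe_length + 1):
        probe_map.setdefault(cds[i:i + probe_length], i)
    idx = _unitig_index(contigs, k)
    pair_gaps, edge_support = _thread_reads(reads, contigs, idx, k)

    # candidate roots: unitigs carrying a meaningful share of CDS probes
    probe_hits: list[tuple[int, int, str]] = []
    for ui, ctg in enumerate(contigs):
        orient = _cds_orientation(ctg, probe_map)
        if orient is None:
            continue
        s = _spell(ctg, orient)
        plen = probe_length
        hits = sum(1 for i in range(len(s) - plen + 1)
                   if s[i:i + plen] in probe_map)
        probe_hits.append((hits, ui, orient))
    probe_hits.sort(key=lambda t: (-t[0], t[1]))
    if not probe_hits:
        return []

    pieces: list[tuple[str, float]] = []
    for hits, root, orient in probe_hits:
        if hits < 3 and pieces:
            break
        ctg = contigs[root]
        if ctg.circular:
            pieces.append((ctg.seq[:ctg.cyclic_length] + ctg.seq,
                           ctg.mean_coverage))
            continue
        span_limit = max(reads.read_length - 2 * k - 12, 0)
        strong_span = max(reads.read_length - 2 * k -
                          config.strong_span_margin, 0)
        paths = _enumerate_cycles(contigs, idx, (root, orient), k,
                                  pair_gaps, edge_support,
                                  config.max_unit_bases, config.max_paths,
                                  span_limit=span_limit,
                                  min_pair_reads=config.min_pair_reads,
                                  strong_span=strong_span,
                                  strong_pair_reads=config.strong_pair_reads)
        for p in paths:
            seq = _spell(contigs[p[0][0]], p[0][1])
            covs = [contigs[p[0][0]].mean_coverage]
            lens = [len(seq)]
            for uid, o in p[1:]:
                sp = _spell(contigs[uid], o)
                seq += sp[k - 1:]
                covs.append(contigs[uid].mean_coverage)
                lens.append(len(sp) - k + 1)
            if len(covs) > 1:  # path coverage without the shared root
                cov = float(np.average(covs[1:-1] or covs, weights=lens[1:-1] or lens))
            else:
                cov = covs[0]
            pieces.append((seq, cov))

    best: dict[str, RepeatUnit] = {}
    for pi, (seq, cov) in enumerate(pieces):
        fake = Contig(id=f"path{pi + 1}", seq=seq, mean_coverage=cov)
        for u in extract_repeat_units([fake], cds, config.max_cds_mismatches,
                                      probe_length):
            prev = best.get(u.unit_seq)
            if prev is None or u.mean_coverage > prev.mean_coverage:
                best[u.unit_seq] = u
    units = sorted(best.values(),
                   key=lambda u: (-u.mean_coverage, u.unit_seq))
    log.info("unitasm: %d distinct repeat units from %d path pieces",
             len(units), len(pieces))
    return units


def _enumerate_cycles(
    contigs: list[Contig],
    idx: dict[str, tuple[int, int]],
    root: tuple[int, str],
    k: int,
    pair_gaps: dict[frozenset, dict[int, int]],
    edge_support: set[frozenset],
    max_bases: int,
    max_paths: int,
    span_limit: int = 0,
    min_pair_reads: int = 2,
    strong_span: int = 0,
    strong_pair_reads: int = 8,
    gap_tolerance: int = 3,
    max_visits: int = 2,
) -> list[list[tuple[int, str]]]:
    """DFS for read-supported cyclic paths root -> ... -> root.

    Phasing rule: whenever the graph offers a choice, the chosen unitig must
    co-occur — at the gap the path implies, within ``gap_tolerance`` — in at
    least ``min_pair_reads`` reads with *every* earlier branch choice a read
    of the library could span (``span_limit`` stitched bases between the two
    unitig spans). Gap-consistent pairwise support rejects switch chimeras
    between coexisting haplotypes and ignores coincidental co-occurrence in
    reads that merely cross into the neighbouring repeat copy, while never
    demanding evidence a read could not physically provide.

    The requirement is two-tier: pairs a read spans with room to spare
    (gap <= ``strong_span``) must be seen in ``strong_pair_reads`` reads —
    single error reads can fake a short allele span, but genuine phasing at
    such gaps is covered by dozens of reads at any usable depth — while
    pairs close to the physical span limit only need ``min_pair_reads``.
    """
    results: list[list[tuple[int, str]]] = []
    succ_cache: dict[tuple[int, str], list[tuple[int, str]]] = {}

    def succs(node: tuple[int, str]) -> list[tuple[int, str]]:
        if node not in succ_cache:
            succ_cache[node] = _successor_unitigs(
                contigs, idx, node[0], node[1], k)
        return succ_cache[node]

    def dfs(cur, path, visits, choices, bases):
        # choices: list of (uid, span_start, span_end) for branch choices
        if len(results) >= max_paths:
            return
        sc = succs(cur)
        ambiguous = len(sc) > 1
        for nxt in sc:
            if frozenset((cur[0], nxt[0])) not in edge_support and cur[0] != nxt[0]:
                continue
            new_start = bases - (k - 1)
            if ambiguous:
                ok = True
                for uid, _, prev_end in choices:
                    if uid == nxt[0]:
                        continue
                    expected = new_start - prev_end
                    if expected > span_limit:
                        continue
                    gaps = pair_gaps.get(frozenset((uid, nxt[0])), {})
                    n = sum(cnt for g, cnt in gaps.items()
                            if abs(g - expected) <= gap_tolerance)
                    need = strong_pair_reads if expected <= strong_span \
                        else min_pair_reads
                    if n < need:
                        ok = False
                        break
                if not ok:
                    continue
            if nxt == root:
                results.append(path + [nxt])
                continue
            if visits.get(nxt[0], 0) >= max_visits:
                continue
            extra = len(contigs[nxt[0]].seq) - k + 1
            if bases + extra > max_bases:
                continue
            nv = dict(visits)
            nv[nxt[0]] = nv.get(nxt[0], 0) + 1
            nc = choices + [(nxt[0], new_start, new_start +
                             len(contigs[nxt[0]].seq))] if ambiguous else choices
            dfs(nxt, path + [nxt], nv, nc, bases + extra)

    # the root itself is a phased choice: cycles rooted on an allele-bearing
    # CDS fragment must not escape pair checks against that allele
    dfs(root, [root], {root[0]: 1},
        [(root[0], 0, len(contigs[root[0]].seq))],
        len(contigs[root[0]].seq))
    if len(results) >= max_paths:
        log.warning("unitasm: path enumeration capped at %d", max_paths)
    return results


# ---------------------------------------------------------------------------
# on-disk formats
# ---------------------------------------------------------------------------

def write_graphml(contigs: list[Contig], k: int, path) -> None:
    """Dump the compacted unitig graph (nodes = contigs, k-1 overlaps)."""
    import networkx as nx

    idx = _unitig_index(contigs, k)
    g = nx.DiGraph()
    for c in contigs:
        g.add_node(c.id, length=len(c.seq), coverage=c.mean_coverage,
                   circular=c.circular)
    for ui, ctg in enumerate(contigs):
        for orient in "+-":
            for vid, vo in _successor_unitigs(contigs, idx, ui, orient, k):
                g.add_edge(ctg.id, contigs[vid].id,
                           orientation=f"{orient}{vo}")
    nx.write_graphml(g, path)


def write_contigs_fasta(contigs: list[Contig], path) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            circ = " circular=1" if c.circular else ""
            fh.write(f">{c.id} coverage={c.mean_coverage:.2f}{circ}\n{c.seq}\n")


def write_units_fasta(units: list[RepeatUnit], path) -> None:
    with open(path, "w") as fh:
        for i, u in enumerate(units):
            fh.write(
                f">unit{i + 1} contig={u.source_contig} "
                f"coverage={u.mean_coverage:.2f} "
                f"igs={u.igs_coords[0]}:{u.igs_coords[1]}\n{u.unit_seq}\n"
            )


def read_units_fasta(path) -> list[RepeatUnit]:
    units: list[RepeatUnit] = []
    name, desc, seq = None, "", []
    with open(path) as fh:
        lines = list(fh) + [">"]
    for line in lines:
        line = line.rstrip("\n")
        if line.startswith(">"):
            if name is not None:
                fields = dict(kv.split("=", 1) for kv in desc.split()[1:]
                              if "=" in kv)
                a, b = (int(x) for x in fields["igs"].split(":"))
                s = "".join(seq)
                units.append(RepeatUnit(
                    unit_seq=s, cds_seq=s[:a], igs_seq=s[a:b],
                    source_contig=fields.get("contig", "?"),
                    mean_coverage=float(fields.get("coverage", 0.0)),
                    igs_coords=(a, b),
                ))
            name, desc, seq = line[1:].split()[0] if len(line) > 1 else "", line[1:], []
        else:
            seq.append(line.strip())
    return units
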