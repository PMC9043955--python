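"""Descriptive features of the 5S intergenic spacer.

Covers the spacer-level analyses: GC content and length, pairwise
similarity under an affine-gap global alignment (optionally masking long
indels, which repeatedly arise and vanish in spacer evolution and would
otherwise dominate the identity), detection of internal tandem duplications
by self-comparison (seed-and-extend), scanning for the external RNA
polymerase III promoter elements that flank the downstream CDS (TATA-like
box near -30, GC dinucleotide near -12/-14, conserved GA at -3, pyrimidine
at -1) plus the oligo-T terminator at the spacer 5' end, CDS divergence
counting, and typing of the four spacer structural variants (SV-A/B/C/D)
defined by two group-specific indels and a GC duplication.
"""

from __future__ import annotations

import importlib.resources
import itertools
import logging
from dataclasses import dataclass, field

import edlib
import yaml

from ._util import aligned_rows, make_aligner
from .unitasm import RepeatUnit

__all__ = [
    "SimilarityOptions",
    "DuplicationCall",
    "MotifEntry",
    "MotifCatalog",
    "MotifHit",
    "SVSignatureSet",
    "SVCall",
    "gc_content",
    "pairwise_identity",
    "similarity_range",
    "find_tandem_duplication",
    "scan_promoter_motifs",
    "default_motif_catalog",
    "cds_divergence",
    "classify_sv",
    "sv_label",
    "load_default_signatures",
]

log = logging.getLogger(__name__)

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass
class SimilarityOptions:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -0.5
    long_indel_threshold: int = 5
    mask_long_indels: bool = False
    identity_denominator: str = "alignment_length"

    def __post_init__(self) -> None:
        if self.long_indel_threshold < 1:
            raise ValueError("long_indel_threshold must be >= 1")
        if self.identity_denominator not in ("alignment_length",
                                             "ungapped_columns"):
            raise ValueError("unknown identity denominator")

    def aligner(self):
        return make_aligner(self.match, self.mismatch,
                            self.gap_open, self.gap_extend)


def gc_content(seq: str) -> float:
    """GC percentage of the unambiguous bases (N excluded both sides)."""
    s = seq.upper()
    if not s:
        raise ValueError("empty sequence")
    counts = {b: s.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return 100.0 * (counts["G"] + counts["C"]) / total


def _mask_long_gaps(rows: tuple[str, str], threshold: int) -> tuple[str, str]:
    """Remove alignment columns inside gap runs longer than ``threshold``."""
    a, b = rows
    keep = [True] * len(a)
    for row in (a, b):
        i = 0
        while i < len(row):
            if row[i] == "-":
                j = i
                while j < len(row) and row[j] == "-":
                    j += 1
                if j - i > threshold:
                    for t in range(i, j):
                        keep[t] = False
                i = j
            else:
                i += 1
    return ("".join(c for c, k in zip(a, keep) if k),
            "".join(c for c, k in zip(b, keep) if k))


def _identity_from_rows(a: str, b: str, opts: SimilarityOptions) -> float:
    if opts.mask_long_indels:
        a, b = _mask_long_gaps((a, b), opts.long_indel_threshold)
    cols = [(x, y) for x, y in zip(a, b) if not (x == "-" and y == "-")]
    if not cols:
        return 100.0
    matches = sum(1 for x, y in cols if x == y and x != "-")
    if opts.identity_denominator == "ungapped_columns":
        denom = sum(1 for x, y in cols if x != "-" and y != "-")
    else:
        denom = len(cols)
    return 100.0 * matches / denom if denom else 100.0


def pairwise_identity(a: str, b: str,
                      opts: SimilarityOptions | None = None) -> float:
    """Percent identity of the optimal global alignment of ``a`` and ``b``."""
    opts = opts or SimilarityOptions()
    if not a or not b:
        raise ValueError("empty sequence")
    # co-optimal alignments can differ in length; fixing the argument order
    # makes the reported identity symmetric and deterministic
    x, y = sorted((a.upper(), b.upper()))
    rx, ry = aligned_rows(x, y, opts.aligner())
    return _identity_from_rows(rx, ry, opts)


def similarity_range(
    seqs: list[str],
    opts: SimilarityOptions | None = None,
) -> tuple[float, float] | None:
    """(min %, max %) over all unordered pairs; None below two sequences."""
    if len(seqs) < 2:
        return None
    vals = [pairwise_identity(a, b, opts)
            for a, b in itertools.combinations(seqs, 2)]
    return (min(vals), max(vals))


# ---------------------------------------------------------------------------
# tandem duplications
# ---------------------------------------------------------------------------

@dataclass
class DuplicationCall:
    unit_length: int
    n_copies: int
    copy_spans: list[tuple[int, int]]
    snps_between_copies: int
    indels_between_copies: list[int]
    cds_derived_length: int
    igs_derived_length: int


def _xdrop(seq: str, start: int, diag: int, step: int, drop: int = 8) -> int:
    """Ungapped extension along seq[x] vs seq[x+diag]; returns best x."""
    n = len(seq)
    score, best_score, best_x = 0, 0, start
    x = start + step
    while 0 <= x and x + diag < n and x + diag >= 0:
        score += 1 if seq[x] == seq[x + diag] else -2
        if score > best_score:
            best_score, best_x = score, x
        if score < best_score - drop:
            break
        x += step
    return best_x


def _copy_divergence(copy1: str, copy2: str) -> tuple[int, list[int], int]:
    """(substitutions, indel lengths, matches) between adjacent copies."""
    ra, rb = aligned_rows(copy1, copy2, make_aligner())
    subs, matches = 0, 0
    indels: list[int] = []
    i = 0
    while i < len(ra):
        if ra[i] == "-" or rb[i] == "-":
            which = ra[i] == "-"
            j = i
            while j < len(ra) and ((ra[j] == "-") == which) and \
                    (ra[j] == "-" or rb[j] == "-"):
                j += 1
            indels.append(j - i)
            i = j
            continue
        if ra[i] == rb[i]:
            matches += 1
        else:
            subs += 1
        i += 1
    return subs, indels, matches


def find_tandem_duplication(
    unit_seq: str,
    min_unit: int = 30,
    max_divergence: float = 0.2,
    cds_length: int | None = None,
    seed_len: int = 15,
    max_gap: int = 5,
    max_diag_drift: int = 20,
) -> DuplicationCall | None:
    """Detect an internal tandem duplication by self-comparison.

    Exact ``seed_len``-mers shared at an offset of at least ``min_unit`` are
    clustered by diagonal (drift up to ``max_diag_drift`` absorbs indels
    between copies); each cluster is refined by ungapped X-drop extension.
    The repeat unit length is the offset between adjacent copy starts; the
    copies must be adjacent (inter-copy gap <= ``max_gap``) and diverge by at
    most ``max_divergence`` (substituted + indel bases per unit length).
    When ``cds_length`` is given the unit is split into the portion derived
    from the coding region ([0, cds_length) of the input) and the rest.
    """
    if min_unit < 10:
        raise ValueError("min_unit must be >= 10")
    seq = unit_seq.upper()
    n = len(seq)
    pos_by_kmer: dict[str, list[int]] = {}
    for i in range(n - seed_len + 1):
        pos_by_kmer.setdefault(seq[i:i + seed_len], []).append(i)
    seeds: list[tuple[int, int]] = []
    for ps in pos_by_kmer.values():
        if len(ps) < 2:
            continue
        for a, b in itertools.combinations(ps[:8], 2):
            if b - a >= min_unit:
                seeds.append((a, b))
    if not seeds:
        return None
    # cluster by diagonal
    seeds.sort(key=lambda s: (s[1] - s[0], s[0]))
    clusters: list[list[tuple[int, int]]] = []
    for s in seeds:
        d = s[1] - s[0]
        if clusters and d - (clusters[-1][-1][1] - clusters[-1][-1][0]) \
                <= max_diag_drift:
            clusters[-1].append(s)
        else:
            clusters.append([s])
    best_call: DuplicationCall | None = None
    best_score = -1.0
    for cl in clusters:
        i0, j0 = min(cl, key=lambda s: s[0])
        i1, j1 = max(cl, key=lambda s: s[0] + seed_len)
        u = j0 - i0
        if u < min_unit:
            continue
        p = _xdrop(seq, i0, u, -1)
        d_last = j1 - i1
        right = _xdrop(seq, i1 + seed_len - 1, d_last, +1)
        gap = (p + u) - (right + 1)
        if gap > max_gap:
            continue
        if len(seq) < p + u + u // 2:
            continue
        # parsimony boundary refinement: a chance match just outside the
        # true copy can pull the ungapped extension one base too far, so
        # pick the boundary shift minimizing the copies' divergence
        best_div = None
        for dp, de in itertools.product(range(-6, 7), repeat=2):
            if p + dp < 0 or p + dp + u + d_last + de > len(seq):
                continue
            c1 = seq[p + dp:p + dp + u]
            c2 = seq[p + dp + u:p + u + d_last + de]
            if len(c2) < u // 2:
                continue
            subs, indels, matches = _copy_divergence(c1, c2)
            key = (subs + sum(indels), abs(dp) + abs(de), dp, de)
            if best_div is None or key < best_div[0]:
                best_div = (key, dp, de, subs, indels, matches)
        if best_div is None:
            continue
        _, dp, de, subs, indels, matches = best_div
        p += dp
        copy1 = seq[p:p + u]
        copy2 = seq[p + u:p + u - dp + d_last + de]
        if (subs + sum(indels)) / u > max_divergence:
            continue
        spans = [(p, p + u), (p + u, p + u + len(copy2))]
        # greedily take further adjacent copies
        end = spans[-1][1]
        while end + u // 2 <= n:
            window = seq[end:min(n, end + u + max_diag_drift)]
            res = edlib.align(copy1, window, mode="SHW", task="locations")
            if res["editDistance"] < 0 or \
                    res["editDistance"] / u > max_divergence:
                break
            stop = res["locations"][0][1] + 1
            spans.append((end, end + stop))
            end += stop
        score = matches * len(spans)
        if score > best_score:
            best_score = score
            cds_len = min(max(cds_length - p, 0), u) if cds_length else 0
            best_call = DuplicationCall(
                unit_length=u, n_copies=len(spans), copy_spans=spans,
                snps_between_copies=subs, indels_between_copies=indels,
                cds_derived_length=cds_len, igs_derived_length=u - cds_len,
            )
    return best_call


# ---------------------------------------------------------------------------
# promoter / terminator motifs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifEntry:
    name: str
    pattern: str          # IUPAC codes allowed
    expected_offset: int  # negative: upstream of the downstream CDS start
    window: int = 5
    max_mismatches: int = 0


@dataclass
class MotifCatalog:
    entries: list[MotifEntry]


def default_motif_catalog() -> MotifCatalog:
    """External Pol III promoter elements and the oligo-T terminator.

    Upstream offsets are counted so that -1 is the spacer base immediately
    5' of the next CDS; the terminator is searched from the spacer 5' end.
    """
    return MotifCatalog(entries=[
        MotifEntry("TATA_box", "TTTAATA", -30, window=5, max_mismatches=1),
        MotifEntry("GC_minus12", "GC", -12, window=2, max_mismatches=0),
        MotifEntry("GC_minus14", "GC", -14, window=2, max_mismatches=0),
        MotifEntry("GA_minus3", "GA", -3, window=2, max_mismatches=0),
        MotifEntry("pyrimidine_minus1", "Y", -1, window=0, max_mismatches=0),
        MotifEntry("terminator_oligoT", "TTTTT", 0, window=15,
                   max_mismatches=0),
    ])


@dataclass
class MotifHit:
    name: str
    found: bool
    offset: int | None
    mismatches: int | None
    reason: str = ""


def _pattern_mismatches(window: str, pattern: str) -> int:
    mm = 0
    for b, p in zip(window, pattern):
        if b not in _IUPAC.get(p, ""):
            mm += 1
    return mm


def scan_promoter_motifs(
    unit: RepeatUnit | str,
    catalog: MotifCatalog | None = None,
) -> list[MotifHit]:
    """Scan one spacer for every catalog entry.

    Entries with a negative expected offset are searched within
    expected_offset +- window, counting back from the spacer 3' end (the
    base at -1 abuts the downstream CDS); entries with offset >= 0 are
    searched forward from the spacer 5' end. The reported hit is the one
    with the fewest mismatches, closest to the expected offset.
    """
    igs = unit.igs_seq if isinstance(unit, RepeatUnit) else unit
    igs = igs.upper()
    cat = catalog or default_motif_catalog()
    L = len(igs)
    report: list[MotifHit] = []
    for e in cat.entries:
        plen = len(e.pattern)
        if e.expected_offset < 0 and L < -e.expected_offset:
            report.append(MotifHit(e.name, False, None, None,
                                   "IGS shorter than expected offset"))
            continue
        candidates: list[tuple[int, int, int]] = []  # (mm, |delta|, offset)
        for off in range(e.expected_offset - e.window,
                         e.expected_offset + e.window + 1):
            start = L + off if off < 0 else off
            if start < 0 or start + plen > L:
                continue
            if off < 0 and start + plen > L:
                continue
            mm = _pattern_mismatches(igs[start:start + plen], e.pattern)
            if mm <= e.max_mismatches:
                candidates.append((mm, abs(off - e.expected_offset), off))
        if candidates:
            mm, _, off = min(candidates)
            report.append(MotifHit(e.name, True, off, mm))
        else:
            report.append(MotifHit(e.name, False, None, None,
                                   "no match within window"))
    return report


def cds_divergence(cds_seq: str, consensus: str) -> tuple[int, list[int]]:
    """(substitution count, indel lengths) of a CDS against the consensus."""
    from .ribotypes import _cds_mutations  # shared alignment bookkeeping

    muts, identity = _cds_mutations(cds_seq.upper(), consensus.upper())
    if identity < 0.5:
        raise ValueError("sequence too diverged to be a 5S CDS (<50% id)")
    subs = sum(1 for m in muts if m.kind == "substitution")
    indels = [len(m.ref) or len(m.alt) for m in muts
              if m.kind in ("insertion", "deletion")]
    return subs, indels


# ---------------------------------------------------------------------------
# structural variants of sect. Petota spacers
# ---------------------------------------------------------------------------

@dataclass
class SVSignatureSet:
    """Signature segments as column ranges on a master reference spacer.

    The master carries all three segments (both group-specific indels and
    the GC duplication); presence in a query is read off a global alignment.
    """

    segments: dict[str, tuple[int, int]]
    master: str
    presence_threshold: float = 0.5

    def __post_init__(self) -> None:
        spans = sorted(self.segments.values())
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            if a2 < b1:
                raise ValueError("signature segments overlap")


@dataclass
class SVCall:
    presence: dict[str, bool]
    label: str


def sv_label(presence: dict[str, bool]) -> str:
    """Decision table over {indel_I, indel_II, GC_DUP} presence."""
    i1 = presence.get("indel_I", False)
    i2 = presence.get("indel_II", False)
    gc = presence.get("GC_DUP", False)
    if i1 and i2:
        return "A"
    if i1 and not i2:
        return "B"
    if not i1 and i2 and not gc:
        return "C"
    if not i1 and i2 and gc:
        return "D"
    return "unclassified"


def load_default_signatures() -> tuple[SVSignatureSet, dict[str, str]]:
    """Packaged synthetic reference alignment + signature column ranges.

    The shipped reference is synthetic (real signature coordinates are not
    machine-readable from published figures); users supply their own
    alignment and YAML for real data.
    """
    pkg = importlib.resources.files("ribomine5s") / "data"
    cfg = yaml.safe_load((pkg / "sv_signatures.yaml").read_text())
    rows: dict[str, str] = {}
    name = None
    for line in (pkg / cfg["reference"]).read_text().splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            rows[name] = ""
        elif name:
            rows[name] += line.strip()
    master = rows[cfg["master_row"]]
    segs = {k: (int(v[0]), int(v[1])) for k, v in cfg["segments"].items()}
    return SVSignatureSet(segments=segs, master=master), rows


def classify_sv(
    igs_seq: str,
    signatures: SVSignatureSet | None = None,
) -> SVCall:
    """Type one spacer as SV-A/B/C/D (or unclassified) by segment presence.

    The query is globally aligned to the master reference; a signature
    segment is present iff at least ``presence_threshold`` of its columns
    align to query bases. Queries under 40% identity to the master are
    rejected as not comparable.
    """
    sigs = signatures or load_default_signatures()[0]
    query = igs_seq.upper().replace("-", "")
    qa, ma = aligned_rows(query, sigs.master, make_aligner())
    matches = sum(1 for x, y in zip(qa, ma) if x == y and x != "-")
    if matches / len(qa) < 0.40:
        raise ValueError("not a Petota-like IGS (alignment identity < 40%)")
    covered = [False] * len(sigs.master)
    mpos = 0
    for x, y in zip(qa, ma):
        if y != "-":
            covered[mpos] = x != "-"
            mpos += 1
    presence = {}
    for name, (a, b) in sigs.segments.items():
        frac = sum(covered[a:b]) / max(b - a, 1)
        presence[name] = frac >= sigs.presence_threshold
    return SVCall(presence=presence, label=sv_label(presence))
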