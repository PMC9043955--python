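"""Ribotype calling: deduplication, pseudogene exclusion, abundance classes.

A *ribotype* is a distinct IGS sequence variant; any difference — one
substitution or an indel — separates two ribotypes. A repeat whose CDS
carries an indel or several substitutions relative to the intact-unit
consensus is treated as a pseudogene and kept in a side list rather than
the catalog. The relative genomic content of each ribotype is estimated by
mapping the complete read library back onto the catalog references
(mismatch-only placement over head-to-tail doubled units, so
junction-spanning reads still map) and classifying each ribotype as
major (>=10% of IGS copies), minor (5-10%) or rare (<5%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import aligned_rows, make_aligner, onehot, revcomp
from .simarray import ReadLibrary
from .unitasm import RepeatUnit

__all__ = [
    "IntegrityConfig",
    "ClassificationConfig",
    "Ribotype",
    "RibotypeCatalog",
    "AbundanceTable",
    "Mutation",
    "NonCdsUnitError",
    "check_cds_integrity",
    "dedup_ribotypes",
    "estimate_abundance",
    "classify",
]

log = logging.getLogger(__name__)


class NonCdsUnitError(ValueError):
    """The putative CDS does not resemble the consensus at all (<50% id)."""


@dataclass
class IntegrityConfig:
    """Operationalizes the pseudogene rule: any CDS indel, or >= several SNP."""

    pseudo_snp_threshold: int = 3
    any_indel_is_pseudogene: bool = True

    def __post_init__(self) -> None:
        if self.pseudo_snp_threshold < 1:
            raise ValueError("pseudo_snp_threshold must be >= 1")


@dataclass
class ClassificationConfig:
    major_min: float = 0.10
    minor_min: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.minor_min < self.major_min < 1.0:
            raise ValueError("need 0 < minor_min < major_min < 1")


@dataclass(frozen=True)
class Mutation:
    kind: str      # "substitution" | "insertion" | "deletion"
    position: int  # 0-based consensus coordinate
    ref: str
    alt: str


@dataclass
class Ribotype:
    id: str
    igs_seq: str
    representative_unit: RepeatUnit
    pseudogene: bool = False
    relative_content: float = 0.0
    abundance_class: str = "unset"


@dataclass
class RibotypeCatalog:
    ribotypes: list[Ribotype]
    pseudogenes: list[tuple[RepeatUnit, list[Mutation]]]
    cds_consensus: str

    def __len__(self) -> int:
        return len(self.ribotypes)


@dataclass
class AbundanceTable:
    rows: pd.DataFrame  # ribotype_id, assigned_weight, relative_content, abundance_class
    assigned_weight: float
    unassigned_weight: float
    cumulative_major_minor: float = float("nan")
    class_counts: dict[str, int] = field(default_factory=dict)


def _cds_mutations(cds: str, consensus: str) -> tuple[list[Mutation], float]:
    """Global alignment of an observed CDS against the consensus.

    Returns the mutation list and the fraction of identical columns.
    """
    aligner = make_aligner()
    qa, ca = aligned_rows(cds, consensus, aligner)
    muts: list[Mutation] = []
    cons_pos = 0
    matches = 0
    i = 0
    n = len(qa)
    while i < n:
        q, c = qa[i], ca[i]
        if q == "-" or c == "-":
            kind = "deletion" if q == "-" else "insertion"
            run_q, run_c = [], []
            start = cons_pos
            while i < n and (qa[i] == "-" or ca[i] == "-") and \
                    (("-" if qa[i] == "-" else "") == ("-" if q == "-" else "")):
                run_q.append(qa[i])
                run_c.append(ca[i])
                if ca[i] != "-":
                    cons_pos += 1
                i += 1
            muts.append(Mutation(
                kind, start,
                ref="".join(b for b in run_c if b != "-"),
                alt="".join(b for b in run_q if b != "-"),
            ))
            continue
        if q == c:
            matches += 1
        else:
            muts.append(Mutation("substitution", cons_pos, c, q))
        cons_pos += 1
        i += 1
    return muts, matches / n if n else 0.0


def check_cds_integrity(
    unit: RepeatUnit,
    cds_consensus: str,
    config: IntegrityConfig | None = None,
) -> tuple[bool, list[Mutation]]:
    """Pseudogene flag for one unit: True iff the CDS carries an indel
    (when ``any_indel_is_pseudogene``) or at least ``pseudo_snp_threshold``
    substitutions versus the consensus."""
    cfg = config or IntegrityConfig()
    if not cds_consensus:
        raise ValueError("empty CDS consensus")
    muts, identity = _cds_mutations(unit.cds_seq, cds_consensus)
    if identity < 0.5:
        raise NonCdsUnitError(
            f"unit from {unit.source_contig}: CDS identity "
            f"{identity:.0%} < 50%, not a 5S coding sequence"
        )
    n_sub = sum(1 for m in muts if m.kind == "substitution")
    has_indel = any(m.kind in ("insertion", "deletion") for m in muts)
    flag = (cfg.any_indel_is_pseudogene and has_indel) or \
        n_sub >= cfg.pseudo_snp_threshold
    return flag, muts


def _majority_consensus(seqs: list[str]) -> str:
    """Column-majority string over equal-length sequences, ties alphabetical."""
    arr = np.array([list(s) for s in seqs])
    out = []
    for col in arr.T:
        vals, counts = np.unique(col, return_counts=True)
        best = max(zip(counts, [-ord(v[0]) for v in vals], vals))
        out.append(best[2])
    return "".join(out)


def _consensus_over(units: list[RepeatUnit]) -> str:
    lengths = [len(u.cds_seq) for u in units]
    mode = max(set(lengths), key=lambda L: (lengths.count(L), -L))
    return _majority_consensus([u.cds_seq for u in units
                                if len(u.cds_seq) == mode])


def dedup_ribotypes(
    units: list[RepeatUnit],
    config: IntegrityConfig | None = None,
) -> RibotypeCatalog:
    """Collapse units into ribotypes; pseudogenes go to the side list.

    The CDS consensus is the column-majority over intact units (two passes:
    a provisional consensus over all units selects the intact set, then the
    consensus is recomputed over it). One ribotype per distinct IGS sequence;
    ordering is by descending representative coverage, then sequence.
    """
    cfg = config or IntegrityConfig()
    if not units:
        log.warning("ribotypes: no repeat units, empty catalog")
        return RibotypeCatalog([], [], "")
    consensus = _consensus_over(units)
    intact = [u for u in units
              if not check_cds_integrity(u, consensus, cfg)[0]]
    if intact:
        consensus = _consensus_over(intact)
    ribos: dict[str, RepeatUnit] = {}
    pseudos: list[tuple[RepeatUnit, list[Mutation]]] = []
    for u in units:
        flag, muts = check_cds_integrity(u, consensus, cfg)
        if flag:
            pseudos.append((u, muts))
            continue
        prev = ribos.get(u.igs_seq)
        if prev is None or u.mean_coverage > prev.mean_coverage:
            ribos[u.igs_seq] = u
    ordered = sorted(ribos.values(),
                     key=lambda u: (-u.mean_coverage, u.igs_seq))
    catalog = [
        Ribotype(id=f"RT{i + 1}", igs_seq=u.igs_seq, representative_unit=u)
        for i, u in enumerate(ordered)
    ]
    if not catalog:
        log.warning("ribotypes: zero intact units, empty catalog")
    return RibotypeCatalog(catalog, pseudos, consensus)


# ---------------------------------------------------------------------------
# read map-back
# ---------------------------------------------------------------------------

def _reference_windows(unit: RepeatUnit, read_len: int):
    """One-hot window matrix over the doubled unit, both strands, plus the
    IGS overlap (bp) of every window."""
    doubled = unit.unit_seq + unit.unit_seq
    L = len(unit.unit_seq)
    s, e = unit.igs_coords
    mask = np.zeros(2 * L, dtype=np.int32)
    mask[s:e] = 1
    mask[L + s:L + e] = 1
    mats, overlaps = [], []
    for target, m in ((doubled, mask), (revcomp(doubled), mask[::-1])):
        if len(target) < read_len:
            continue
        oh = onehot(target)
        win = np.lib.stride_tricks.sliding_window_view(oh, (read_len, 4))
        mats.append(win.reshape(win.shape[0], -1).astype(np.float32))
        csum = np.concatenate([[0], np.cumsum(m)])
        overlaps.append(csum[read_len:] - csum[:-read_len])
    if not mats:
        return None, None
    return np.vstack(mats), np.concatenate(overlaps)


def estimate_abundance(
    catalog: RibotypeCatalog,
    reads: ReadLibrary,
    max_mismatches: int = 2,
    min_igs_overlap: int = 20,
    chunk: int = 512,
) -> AbundanceTable:
    """Relative genomic content per ribotype by read map-back.

    Every read is placed against every doubled reference on both strands by
    mismatch count (no gaps); a read's unit weight is split equally among the
    references achieving the minimum mismatch count, and only placements
    overlapping the IGS by at least ``min_igs_overlap`` bp contribute — a
    CDS-only read carries no ribotype information.
    """
    if not catalog.ribotypes:
        raise ValueError("empty catalog")
    weights = {rt.id: 0.0 for rt in catalog.ribotypes}
    unassigned = 0.0
    by_len: dict[int, list] = {}
    for r in reads.reads:
        by_len.setdefault(len(r.seq), []).append(r)
    for rlen, group in sorted(by_len.items()):
        Ws, ovs, ref_ids = [], [], []
        for rt in catalog.ribotypes:
            W, ov = _reference_windows(rt.representative_unit, rlen)
            if W is None:
                continue
            Ws.append(W)
            ovs.append(ov)
            ref_ids.extend([rt.id] * W.shape[0])
        if not Ws:
            unassigned += len(group)
            continue
        W = np.vstack(Ws).T          # (4*rlen, n_rows)
        overlap = np.concatenate(ovs)
        ref_arr = np.array(ref_ids)
        for lo in range(0, len(group), chunk):
            sub = group[lo:lo + chunk]
            R = np.stack([onehot(r.seq).reshape(-1) for r in sub])
            matches = R @ W
            mm = rlen - matches
            best = mm.min(axis=1)
            for i in range(len(sub)):
                if best[i] > max_mismatches + 0.5:
                    unassigned += 1.0
                    continue
                ok = (mm[i] <= best[i] + 0.5) & (overlap >= min_igs_overlap)
                hit_refs = np.unique(ref_arr[ok])
                if hit_refs.size == 0:
                    unassigned += 1.0
                    continue
                w = 1.0 / hit_refs.size
                for rid in hit_refs:
                    weights[rid] += w
    total = sum(weights.values())
    if total <= 0:
        log.warning("ribotypes: no read overlaps the IGS; contents are 0")
        contents = {rid: 0.0 for rid in weights}
    else:
        contents = {rid: w / total for rid, w in weights.items()}
    for rt in catalog.ribotypes:
        rt.relative_content = contents[rt.id]
    rows = pd.DataFrame({
        "ribotype_id": [rt.id for rt in catalog.ribotypes],
        "assigned_weight": [weights[rt.id] for rt in catalog.ribotypes],
        "relative_content": [contents[rt.id] for rt in catalog.ribotypes],
        "abundance_class": ["unset"] * len(catalog.ribotypes),
    })
    return AbundanceTable(rows=rows, assigned_weight=total,
                          unassigned_weight=unassigned)


def classify(
    table: AbundanceTable,
    config: ClassificationConfig | None = None,
    catalog: RibotypeCatalog | None = None,
) -> AbundanceTable:
    """Assign major/minor/rare classes and the cumulative major+minor share."""
    cfg = config or ClassificationConfig()

    def _cls(c: float) -> str:
        if c >= cfg.major_min:
            return "major"
        if c >= cfg.minor_min:
            return "minor"
        return "rare"

    table.rows["abundance_class"] = table.rows["relative_content"].map(_cls)
    counts = table.rows["abundance_class"].value_counts().to_dict()
    table.class_counts = {k: int(counts.get(k, 0))
                          for k in ("major", "minor", "rare")}
    mm = table.rows["abundance_class"].isin(["major", "minor"])
    table.cumulative_major_minor = float(
        table.rows.loc[mm, "relative_content"].sum())
    if catalog is not None:
        cls_by_id = dict(zip(table.rows["ribotype_id"],
                             table.rows["abundance_class"]))
        for rt in catalog.ribotypes:
            rt.abundance_class = cls_by_id.get(rt.id, "unset")
    return table
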