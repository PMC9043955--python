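"""Synthetic 5S rDNA tandem arrays and short-read libraries with known truth.

A 5S rDNA locus is a head-to-tail array of repeat units, each a conserved
~120-bp coding sequence (CDS) followed by a fast-evolving intergenic spacer
(IGS, typically 190-220 bp). Within one genome the IGS occurs as a mixture of
sequence variants ("ribotypes") at very different copy numbers. This module
builds such arrays with fully known ground truth — ribotype sequences, true
proportions, per-copy layout, pseudogenized copies — and samples error-bearing
short reads from them, so that every downstream stage of the pipeline can be
exercised without any external data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import edlib
import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import random_seq, revcomp, spawn_rng

__all__ = [
    "SimulationConfig",
    "DuplicationSpec",
    "TruthSet",
    "Read",
    "ReadLibrary",
    "SimulatedArray",
    "RibotypeCollisionError",
    "generate_ribotype_set",
    "build_tandem_array",
    "simulate_reads",
    "write_fastq",
    "read_fastq",
    "write_truth",
    "read_truth",
    "write_config",
    "read_config",
]

#: attempts to re-draw a ribotype whose mutations collided with an existing one
RETRY_LIMIT = 20


class RibotypeCollisionError(RuntimeError):
    """Raised when distinct ribotypes cannot be generated within RETRY_LIMIT."""


@dataclass(frozen=True)
class DuplicationSpec:
    """An internal tandem duplication planted into the last derived ribotype.

    ``copy_snps`` substitutions and one ``copy_indel_bp``-long deletion
    distinguish each extra copy from the first, mirroring naturally diverged
    duplication copies. The indel is placed in the copy interior (>=15 bp from
    either copy boundary) so the duplication boundaries stay well defined.
    """

    unit_bp: int
    copies: int = 2
    copy_snps: int = 0
    copy_indel_bp: int = 0

    def __post_init__(self) -> None:
        if self.unit_bp <= 0 or self.copies < 2:
            raise ValueError("duplication needs unit_bp > 0 and copies >= 2")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic locus + library.

    Lengths in bp, fractions in [0, 1]. ``proportions`` defaults to equal
    shares. ``min_pairwise_distance`` is the smallest edit distance allowed
    between any two generated ribotypes (1 = merely distinct).
    """

    seed: int = 0
    cds_length: int = 120
    igs_length: int = 210
    igs_gc: float = 0.50
    cds_gc: float = 0.55
    n_ribotypes: int = 3
    proportions: list[float] | None = None
    snps_per_ribotype: int = 4
    indel_spec: list[tuple[int, str]] = field(default_factory=list)
    duplication_spec: DuplicationSpec | None = None
    pseudogene_fraction: float = 0.0
    array_copies: int = 20
    flank_length: int = 500
    background_read_fraction: float = 0.0
    min_pairwise_distance: int = 1
    # library parameters (ReadLibrary carries the realized values)
    read_length: int = 250
    coverage: float = 100.0
    error_rate: float = 0.0
    layout: str = "single"
    insert_size: int = 600

    def __post_init__(self) -> None:
        if self.proportions is None:
            self.proportions = [1.0 / self.n_ribotypes] * self.n_ribotypes
        if len(self.proportions) != self.n_ribotypes:
            raise ValueError("proportions length must equal n_ribotypes")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
        for name in ("cds_length", "igs_length", "array_copies", "read_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("igs_gc", "cds_gc", "pseudogene_fraction",
                     "background_read_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be within [0, 1]")
        if any(p < 0 or p > 1 for p in self.proportions):
            raise ValueError("proportions must be within [0, 1]")
        if self.layout not in ("single", "paired"):
            raise ValueError("layout must be 'single' or 'paired'")
        if isinstance(self.duplication_spec, (tuple, list)):
            self.duplication_spec = DuplicationSpec(*self.duplication_spec)
        self.indel_spec = [tuple(x) for x in self.indel_spec]


@dataclass
class TruthSet:
    """Simulation ground truth carried alongside every synthetic dataset."""

    ribotype_sequences: dict[str, str]
    true_proportions: dict[str, float]
    array_layout: list[tuple[int, str, bool]]
    seed: int
    cds: str = ""

    def __post_init__(self) -> None:
        if abs(sum(self.true_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("true proportions must sum to 1")
        for _, rid, _ in self.array_layout:
            if rid not in self.ribotype_sequences:
                raise ValueError(f"layout ribotype {rid} missing from sequences")


@dataclass
class Read:
    id: str
    seq: str
    qual: str | None = None
    source_pos: int | None = None
    source_strand: str | None = None
    mate: int | None = None


@dataclass
class ReadLibrary:
    reads: list[Read]
    layout: str = "single"
    read_length: int = 0
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.layout == "paired":
            n1 = sum(1 for r in self.reads if r.mate == 1)
            n2 = sum(1 for r in self.reads if r.mate == 2)
            if n1 != n2:
                raise ValueError("paired library has unequal mate counts")

    def __len__(self) -> int:
        return len(self.reads)


@dataclass
class SimulatedArray:
    """A built tandem array plus the coordinates tests need as oracles."""

    sequence: str
    truth: TruthSet
    cds_intervals: list[tuple[int, int]]
    unit_intervals: list[tuple[int, int]]

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# ribotype generation
# ---------------------------------------------------------------------------

def _apply_snps(seq: str, n: int, rng: np.random.Generator,
                forbidden: set[int] | None = None) -> str:
    chars = list(seq)
    allowed = [i for i in range(len(chars)) if not forbidden or i not in forbidden]
    pos = rng.choice(len(allowed), size=n, replace=False)
    for p in pos:
        i = allowed[int(p)]
        alts = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alts[int(rng.integers(0, 3))]
    return "".join(chars)


def _apply_indel(seq: str, length: int, kind: str,
                 rng: np.random.Generator) -> str:
    if kind == "deletion":
        if length >= len(seq):
            raise ValueError("deletion longer than sequence")
        p = int(rng.integers(0, len(seq) - length + 1))
        return seq[:p] + seq[p + length:]
    if kind == "insertion":
        p = int(rng.integers(0, len(seq) + 1))
        return seq[:p] + random_seq(rng, length) + seq[p:]
    raise ValueError(f"unknown indel kind {kind!r}")


def _apply_duplication(seq: str, spec: DuplicationSpec,
                       rng: np.random.Generator) -> str:
    u = spec.unit_bp
    if u > len(seq):
        raise ValueError("duplication unit longer than the spacer")
    s = int(rng.integers(0, len(seq) - u + 1))
    unit = seq[s:s + u]
    margin = 15  # keep copy boundaries and the indel cleanly anchored
    extra = []
    for _ in range(spec.copies - 1):
        copy = unit
        forbidden: set[int] = set(range(margin)) | \
            set(range(max(u - margin, 0), u))
        if spec.copy_indel_bp:
            lo, hi = margin, u - spec.copy_indel_bp - margin
            if hi < lo:
                raise ValueError("copy indel does not fit in duplication unit")
            p = int(rng.integers(lo, hi + 1))
            forbidden |= set(range(p - 10, p + spec.copy_indel_bp + 10))
        if spec.copy_snps:
            # isolated substitutions (pairwise >= 10 bp apart) keep the
            # planted divergence identifiable by alignment
            base_allowed = [i for i in range(u) if i not in forbidden]
            pos: list[int] = []
            for _ in range(200):
                pos = []
                avail = list(base_allowed)
                while avail and len(pos) < spec.copy_snps:
                    i = int(avail[int(rng.integers(0, len(avail)))])
                    pos.append(i)
                    avail = [a for a in avail if abs(a - i) >= 10]
                if len(pos) == spec.copy_snps:
                    break
            else:
                raise ValueError("cannot place isolated copy SNPs")
            chars = list(copy)
            for i in pos:
                alts = [b for b in "ACGT" if b != chars[i]]
                chars[i] = alts[int(rng.integers(0, 3))]
            copy = "".join(chars)
        if spec.copy_indel_bp:
            copy = copy[:p] + copy[p + spec.copy_indel_bp:]
        extra.append(copy)
    return seq[:s + u] + "".join(extra) + seq[s + u:]


def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b)["editDistance"]


def generate_ribotype_set(
    config: SimulationConfig,
) -> tuple[str, dict[str, str], TruthSet]:
    """Generate an ancestral IGS and derived ribotypes.

    Ribotype ``R1`` is the ancestor itself; each further ribotype differs from
    the ancestor by ``snps_per_ribotype`` substitutions, by its entry of
    ``indel_spec`` (assigned in order), and — for the last ribotype — by
    ``duplication_spec`` when given. Returns (ancestral IGS, id->IGS map,
    TruthSet with an empty array layout).
    """
    if config.n_ribotypes < 1:
        raise ValueError("n_ribotypes must be >= 1")
    rng = spawn_rng(config.seed, 0)
    cds = random_seq(spawn_rng(config.seed, 1), config.cds_length, config.cds_gc)
    ancestor = random_seq(rng, config.igs_length, config.igs_gc)
    ids = [f"R{i + 1}" for i in range(config.n_ribotypes)]
    ribotypes: dict[str, str] = {ids[0]: ancestor}
    for i in range(1, config.n_ribotypes):
        for attempt in range(RETRY_LIMIT + 1):
            seq = ancestor
            if config.snps_per_ribotype:
                seq = _apply_snps(seq, config.snps_per_ribotype, rng)
            if i - 1 < len(config.indel_spec):
                length, kind = config.indel_spec[i - 1]
                seq = _apply_indel(seq, length, kind, rng)
            if config.duplication_spec and i == config.n_ribotypes - 1:
                seq = _apply_duplication(seq, config.duplication_spec, rng)
            dmin = min(_edit_distance(seq, s) for s in ribotypes.values())
            if dmin >= max(1, config.min_pairwise_distance):
                break
        else:
            raise RibotypeCollisionError(
                f"could not derive a distinct ribotype after {RETRY_LIMIT} tries"
            )
        ribotypes[ids[i]] = seq
    truth = TruthSet(
        ribotype_sequences=dict(ribotypes),
        true_proportions=dict(zip(ids, config.proportions)),
        array_layout=[],
        seed=config.seed,
        cds=cds,
    )
    return ancestor, dict(ribotypes), truth


# ---------------------------------------------------------------------------
# array construction
# ---------------------------------------------------------------------------

def _largest_remainder_counts(props: list[float], total: int) -> list[int]:
    raw = [p * total for p in props]
    counts = [int(np.floor(x)) for x in raw]
    rem = total - sum(counts)
    order = sorted(range(len(props)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:rem]:
        counts[i] += 1
    return counts


def _pseudogenize_cds(cds: str, rng: np.random.Generator) -> str:
    """Damage a CDS copy: one random 1-2 bp indel, or three substitutions."""
    if rng.random() < 0.5:
        length = int(rng.integers(1, 3))
        kind = "deletion" if rng.random() < 0.5 else "insertion"
        return _apply_indel(cds, length, kind, rng)
    return _apply_snps(cds, 3, rng)


def build_tandem_array(
    ribotypes: dict[str, str],
    truth: TruthSet,
    config: SimulationConfig,
) -> SimulatedArray:
    """Lay ribotype copies head-to-tail between single-copy flanks.

    Copy counts follow ``true_proportions`` by largest-remainder rounding; the
    copy order is a seeded shuffle (real arrays interleave variants, and the
    order must not matter downstream). A ``pseudogene_fraction`` of copies gets
    a damaged CDS. Fills ``truth.array_layout`` and returns the built array
    with per-copy coordinates.
    """
    ids = list(truth.true_proportions)
    props = [truth.true_proportions[i] for i in ids]
    counts = _largest_remainder_counts(props, config.array_copies)
    for rid, c in zip(ids, counts):
        if c == 0:
            raise ValueError(
                f"ribotype {rid}: proportion rounds to 0 copies at "
                f"array_copies={config.array_copies}"
            )
    rng = spawn_rng(config.seed, 2)
    order: list[str] = [rid for rid, c in zip(ids, counts) for _ in range(c)]
    rng.shuffle(order)
    n_pseudo = int(round(config.pseudogene_fraction * config.array_copies))
    pseudo_idx = set(
        int(i) for i in rng.choice(config.array_copies, size=n_pseudo,
                                   replace=False)
    )
    flank = random_seq(rng, config.flank_length) if config.flank_length else ""
    parts = [flank]
    cds_intervals: list[tuple[int, int]] = []
    unit_intervals: list[tuple[int, int]] = []
    layout: list[tuple[int, str, bool]] = []
    pos = len(flank)
    for idx, rid in enumerate(order):
        is_pseudo = idx in pseudo_idx
        cds = _pseudogenize_cds(truth.cds, rng) if is_pseudo else truth.cds
        igs = ribotypes[rid]
        parts.append(cds + igs)
        cds_intervals.append((pos, pos + len(cds)))
        unit_intervals.append((pos, pos + len(cds) + len(igs)))
        pos += len(cds) + len(igs)
        layout.append((idx, rid, is_pseudo))
    parts.append(flank)
    truth.array_layout = layout
    return SimulatedArray("".join(parts), truth, cds_intervals, unit_intervals)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _add_errors(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    mask = rng.random(len(seq)) < error_rate
    if not mask.any():
        return seq
    chars = list(seq)
    for i in np.flatnonzero(mask):
        alts = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alts[int(rng.integers(0, 3))]
    return "".join(chars)


def _draw_read(source: str, pos: int, length: int, strand: str,
               rng: np.random.Generator, error_rate: float) -> str:
    seq = source[pos:pos + length]
    if strand == "-":
        seq = revcomp(seq)
    return _add_errors(seq, rng, error_rate)


def simulate_reads(array: SimulatedArray | str,
                   config: SimulationConfig) -> ReadLibrary:
    """Sample uniform, strand-symmetric reads at the configured coverage.

    Single-end read count is ``round(coverage * array_length / read_length)``;
    a ``background_read_fraction`` of that total is replaced by reads from a
    seeded non-rDNA background sequence (filter-specificity control).
    Substitution errors only; constant base quality.
    """
    genome = array.sequence if isinstance(array, SimulatedArray) else array
    rl = config.read_length
    if rl > len(genome):
        raise ValueError("read_length exceeds array length")
    if config.coverage <= 0:
        raise ValueError("coverage must be > 0")
    rng = spawn_rng(config.seed, 3)
    n_total = int(round(config.coverage * len(genome) / rl))
    n_bg = int(round(config.background_read_fraction * n_total))
    n_arr = n_total - n_bg
    reads: list[Read] = []
    if config.layout == "paired":
        if config.insert_size < rl:
            raise ValueError("paired insert size smaller than read length")
        if config.insert_size > len(genome):
            raise ValueError("insert size exceeds array length")
        n_pairs = max(n_arr // 2, 0)
        for i in range(n_pairs):
            start = int(rng.integers(0, len(genome) - config.insert_size + 1))
            frag = genome[start:start + config.insert_size]
            flip = bool(rng.integers(0, 2))
            fwd = _add_errors(frag[:rl], rng, config.error_rate)
            rev = _add_errors(revcomp(frag[-rl:]), rng, config.error_rate)
            m1, m2 = (rev, fwd) if flip else (fwd, rev)
            reads.append(Read(f"sim_{i}", m1, source_pos=start,
                              source_strand="-" if flip else "+", mate=1))
            reads.append(Read(f"sim_{i}", m2, source_pos=start,
                              source_strand="+" if flip else "-", mate=2))
    else:
        for i in range(n_arr):
            pos = int(rng.integers(0, len(genome) - rl + 1))
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            seq = _draw_read(genome, pos, rl, strand, rng, config.error_rate)
            reads.append(Read(f"sim_{i}", seq, source_pos=pos,
                              source_strand=strand))
    if n_bg:
        bg = random_seq(spawn_rng(config.seed, 4), max(1000, 4 * rl))
        for i in range(n_bg):
            pos = int(rng.integers(0, len(bg) - rl + 1))
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            seq = _draw_read(bg, pos, rl, strand, rng, config.error_rate)
            reads.append(Read(f"bg_{i}", seq, source_pos=None,
                              source_strand=strand))
    return ReadLibrary(reads, layout=config.layout, read_length=rl,
                       error_rate=config.error_rate)


# ---------------------------------------------------------------------------
# on-disk formats
# ---------------------------------------------------------------------------

def write_fastq(library: ReadLibrary, path, quality: int = 35) -> None:
    """Sanger Phred+33 FASTQ; read provenance kept in the description."""
    records = []
    for r in library.reads:
        desc = []
        if r.source_pos is not None:
            desc.append(f"pos={r.source_pos}")
        if r.source_strand is not None:
            desc.append(f"strand={r.source_strand}")
        if r.mate is not None:
            desc.append(f"mate={r.mate}")
        rec = SeqRecord(Seq(r.seq), id=r.id, description=" ".join(desc))
        rec.letter_annotations["phred_quality"] = (
            [ord(c) - 33 for c in r.qual] if r.qual
            else [quality] * len(r.seq)
        )
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


def read_fastq(path, layout: str = "single") -> ReadLibrary:
    reads = []
    rl = 0
    for rec in SeqIO.parse(str(path), "fastq"):
        fields = dict(
            kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv
        )
        qual = "".join(
            chr(q + 33) for q in rec.letter_annotations["phred_quality"]
        )
        reads.append(Read(
            rec.id, str(rec.seq), qual=qual,
            source_pos=int(fields["pos"]) if "pos" in fields else None,
            source_strand=fields.get("strand"),
            mate=int(fields["mate"]) if "mate" in fields else None,
        ))
        rl = max(rl, len(rec.seq))
    return ReadLibrary(reads, layout=layout, read_length=rl)


def write_truth(truth: TruthSet, path) -> None:
    pseudo_counts = {rid: 0 for rid in truth.ribotype_sequences}
    for _, rid, flag in truth.array_layout:
        if flag:
            pseudo_counts[rid] += 1
    with open(path, "w") as fh:
        fh.write(f"#seed={truth.seed}\n")
        fh.write(f"#cds={truth.cds}\n")
        layout = ",".join(
            f"{i}:{rid}:{int(flag)}" for i, rid, flag in truth.array_layout
        )
        fh.write(f"#layout={layout}\n")
        fh.write("ribotype_id\tsequence\tproportion\tpseudogene\n")
        for rid, seq in truth.ribotype_sequences.items():
            fh.write(
                f"{rid}\t{seq}\t{truth.true_proportions[rid]!r}"
                f"\t{pseudo_counts[rid]}\n"
            )


def read_truth(path) -> TruthSet:
    seed, cds, layout = 0, "", []
    seqs: dict[str, str] = {}
    props: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#seed="):
                seed = int(line[6:])
            elif line.startswith("#cds="):
                cds = line[5:]
            elif line.startswith("#layout="):
                body = line[8:]
                if body:
                    for item in body.split(","):
                        i, rid, flag = item.split(":")
                        layout.append((int(i), rid, bool(int(flag))))
            elif line and not line.startswith("ribotype_id"):
                rid, seq, prop, _ = line.split("\t")
                seqs[rid] = seq
                props[rid] = float(prop)
    return TruthSet(seqs, props, layout, seed, cds)


def write_array_fasta(array: SimulatedArray, path, name: str = "array") -> None:
    with open(path, "w") as fh:
        SeqIO.write(
            [SeqRecord(Seq(array.sequence), id=name,
                       description=f"seed={array.truth.seed}")],
            fh, "fasta",
        )


def write_config(config: SimulationConfig, path) -> None:
    data = dataclasses.asdict(config)
    if config.duplication_spec is not None:
        data["duplication_spec"] = dataclasses.asdict(config.duplication_spec)
    data["indel_spec"] = [list(x) for x in config.indel_spec]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def read_config(path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data.get("duplication_spec"):
        data["duplication_spec"] = DuplicationSpec(**data["duplication_spec"])
    return SimulationConfig(**data)
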