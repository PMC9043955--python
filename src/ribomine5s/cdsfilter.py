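"""Select 5S rDNA-bearing reads by exact 20-mer matching against the CDS.

The conserved 5S coding sequence is tiled into every overlapping probe of
``probe_length`` (default 20 bp) on both strands; a read is kept iff any of
its windows equals a probe exactly. This reproduces, in-process, the kind of
exact-match pre-filter applied to SRA libraries before targeted assembly.
Sequencing errors inside a matched window lose that window, but because the
probes tile the whole CDS a read overlapping the CDS by more than the probe
length nearly always retains an error-free window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from ._util import revcomp
from .simarray import Read, ReadLibrary

__all__ = ["ProbeSet", "FilterStats", "make_probes", "filter_reads"]

log = logging.getLogger(__name__)


@dataclass
class ProbeSet:
    """All overlapping CDS k-mers plus their reverse complements."""

    probe_length: int
    probes: frozenset[str]
    source_cds: str

    def __post_init__(self) -> None:
        if any(len(p) != self.probe_length for p in self.probes):
            raise ValueError("probe length mismatch in probe set")


@dataclass
class FilterStats:
    kept: int = 0
    discarded: int = 0
    too_short: int = 0
    pairs_kept: int = 0


def make_probes(cds: str, probe_length: int = 20) -> ProbeSet:
    """Tile ``cds`` into probes of ``probe_length``, closed under strand."""
    cds = cds.upper()
    if probe_length > len(cds):
        raise ValueError(
            f"probe_length {probe_length} exceeds CDS length {len(cds)}"
        )
    for i, b in enumerate(cds):
        if b not in "ACGT":
            raise ValueError(f"ambiguous base {b!r} at CDS position {i}")
    fwd = {cds[i:i + probe_length]
           for i in range(len(cds) - probe_length + 1)}
    probes = frozenset(fwd | {revcomp(p) for p in fwd})
    return ProbeSet(probe_length, probes, cds)


def _read_matches(seq: str, probes: ProbeSet) -> bool:
    k = probes.probe_length
    s = seq.upper()
    return any(s[i:i + k] in probes.probes for i in range(len(s) - k + 1))


def filter_reads(
    library: ReadLibrary,
    probes: ProbeSet,
    stats: FilterStats | None = None,
) -> ReadLibrary:
    """Keep reads (or pairs, if either mate hits) with an exact probe match.

    Order is preserved. Reads shorter than the probe length are discarded and
    counted separately. Kept/discarded counts are logged and written into
    ``stats`` when one is supplied.
    """
    if not probes.probes:
        raise ValueError("empty probe set")
    st = stats if stats is not None else FilterStats()
    kept: list[Read] = []
    if library.layout == "paired":
        by_pair: dict[str, list[Read]] = {}
        order: list[str] = []
        for r in library.reads:
            if r.id not in by_pair:
                by_pair[r.id] = []
                order.append(r.id)
            by_pair[r.id].append(r)
        for rid in order:
            mates = by_pair[rid]
            if all(len(m.seq) < probes.probe_length for m in mates):
                st.too_short += 1
                st.discarded += len(mates)
                continue
            if any(_read_matches(m.seq, probes) for m in mates):
                kept.extend(mates)
                st.kept += len(mates)
                st.pairs_kept += 1
            else:
                st.discarded += len(mates)
    else:
        for r in library.reads:
            if len(r.seq) < probes.probe_length:
                st.too_short += 1
                st.discarded += 1
                continue
            if _read_matches(r.seq, probes):
                kept.append(r)
                st.kept += 1
            else:
                st.discarded += 1
    log.info(
        "cdsfilter: kept %d, discarded %d (%d shorter than probe)",
        st.kept, st.discarded, st.too_short,
    )
    return ReadLibrary(kept, layout=library.layout,
                       read_length=library.read_length,
                       error_rate=library.error_rate)
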