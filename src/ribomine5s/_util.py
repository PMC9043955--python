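"""Shared sequence helpers used across the pipeline modules."""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTNacgtn-", "TGCANtgcan-")

DNA = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N,-} (case preserved)."""
    return seq.translate(_COMP)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def encode(seq: str) -> np.ndarray:
    """Encode A,C,G,T as 0..3; anything else (N) as 4."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        out[arr == b] = i
    return out


def onehot(seq: str) -> np.ndarray:
    """(len, 4) float32 one-hot; N rows are all-zero (mismatch everywhere)."""
    e = encode(seq)
    oh = np.zeros((len(seq), 4), dtype=np.float32)
    valid = e < 4
    oh[np.arange(len(seq))[valid], e[valid]] = 1.0
    return oh


def hamming_scan(text: str, pattern: str) -> np.ndarray:
    """Mismatch count of `pattern` against every window of `text`.

    Returns an array of length len(text) - len(pattern) + 1 (empty if the
    pattern is longer than the text). N in either sequence counts as mismatch.
    """
    m, n = len(pattern), len(text)
    if n < m:
        return np.zeros(0, dtype=np.int64)
    t = encode(text)
    p = encode(pattern)
    windows = np.lib.stride_tricks.sliding_window_view(t, m)
    eq = (windows == p[None, :]) & (p[None, :] < 4) & (windows < 4)
    return m - eq.sum(axis=1)


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """Random sequence with *exact* GC composition (rounded), shuffled.

    Drawing bases i.i.d. would let realized GC wander by several percent at
    typical spacer lengths; fixing the composition keeps the generator's GC
    parameter meaningful.
    """
    n_gc = int(round(gc * length))
    n_at = length - n_gc
    gcs = rng.integers(0, 2, size=n_gc)
    ats = rng.integers(0, 2, size=n_at)
    bases = ["GC"[i] for i in gcs] + ["AT"[i] for i in ats]
    rng.shuffle(bases)
    return "".join(bases)


def make_aligner(match: float = 1.0, mismatch: float = -1.0,
                 gap_open: float = -2.0, gap_extend: float = -0.5,
                 mode: str = "global"):
    """Affine-gap pairwise aligner (Needleman-Wunsch scoring by default)."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def aligned_rows(a: str, b: str, aligner) -> tuple[str, str]:
    """Gapped strings of the best (first-enumerated, deterministic) alignment."""
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def spawn_rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic child RNG for a (seed, stage-key) pair."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))
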