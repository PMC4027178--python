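"""Vectorised byte-level kernels shared by the tally and simulation code.

Sequences are represented as ``uint8`` arrays with A=0, C=1, G=2, T=3 and
N (or any other character) = 4.  With this encoding the reverse complement
of a valid base ``b`` is ``3 - b``, and GC membership is ``b in {1, 2}``.
"""

from __future__ import annotations

import numpy as np

A, C, G, T, N = 0, 1, 2, 3, 4

_ENCODE = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

TTAGGG = _ENCODE[np.frombuffer(b"TTAGGG", dtype=np.uint8)]
CCCTAA = _ENCODE[np.frombuffer(b"CCCTAA", dtype=np.uint8)]


def seq_to_index(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 index array."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def index_to_seq(idx: np.ndarray) -> str:
    """Decode a uint8 index array back to an uppercase string."""
    return _DECODE[idx].tobytes().decode("ascii")


def revcomp_index(idx: np.ndarray) -> np.ndarray:
    """Reverse complement an index array (N stays N)."""
    out = np.where(idx < 4, 3 - idx, idx).astype(np.uint8)
    return out[::-1]


def motif_position_counts(reads: np.ndarray, motif_idx: np.ndarray) -> np.ndarray:
    """Per-read count of all match positions of a motif.

    ``reads`` is an (n_reads, read_length) uint8 array.  For motifs that
    cannot overlap themselves (TTAGGG/CCCTAA) this equals the greedy
    non-overlapping count used on the string path.
    """
    n, length = reads.shape
    k = len(motif_idx)
    w = length - k + 1
    if w <= 0:
        return np.zeros(n, dtype=np.int64)
    match = reads[:, 0:w] == motif_idx[0]
    for i in range(1, k):
        match &= reads[:, i : i + w] == motif_idx[i]
    return match.sum(axis=1)


def telomere_repeat_counts(reads: np.ndarray) -> np.ndarray:
    """Strand-symmetric telomere repeat count per read (vectorised)."""
    return np.maximum(
        motif_position_counts(reads, TTAGGG),
        motif_position_counts(reads, CCCTAA),
    )


def gc_base_counts(reads: np.ndarray) -> np.ndarray:
    """Per-read number of G+C bases."""
    return (((reads == C) | (reads == G))).sum(axis=1)
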