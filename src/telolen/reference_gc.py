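"""Genome-side GC profile: cumulative reference length per GC band.

The telomere-length estimator normalises the telomeric read count by the
number of reads whose GC content falls in a narrow band around the
telomeric composition (50%).  The matching genome-side constant is the
cumulative length of reference sequence at that same composition, L_gc.
This module measures it by tiling the reference with non-overlapping
windows of read length (default 100 bp), binning each window's GC
fraction on the same 0.02 grid used for reads, and summing window lengths
per bin.  Windows containing any N are excluded; trailing partial windows
are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pysam

from . import _kernels
from .tally import GC_BIN_WIDTH, N_GC_BINS, band_bin_range

__all__ = ["GCProfile", "profile_reference", "length_at_band", "write_profile", "read_profile"]


@dataclass
class GCProfile:
    """Cumulative genome length (bp) in each GC bin of width 0.02."""

    window: int
    band_lengths: np.ndarray  # int64, length N_GC_BINS
    total_effective_length: int
    n_excluded_windows: int

    def __post_init__(self) -> None:
        self.band_lengths = np.asarray(self.band_lengths, dtype=np.int64)
        if self.band_lengths.shape != (N_GC_BINS,):
            raise ValueError(f"band_lengths must have {N_GC_BINS} bins")
        if int(self.band_lengths.sum()) != self.total_effective_length:
            raise ValueError("band_lengths must sum to total_effective_length")


def _iter_index_sequences(
    source: str | Path | Iterable,
) -> Iterable[np.ndarray]:
    """Yield sequences as uint8 index arrays from a FASTA path or an
    iterable of strings / index arrays."""
    if isinstance(source, (str, Path)):
        with pysam.FastxFile(str(source)) as fh:
            for rec in fh:
                yield _kernels.seq_to_index(rec.sequence or "")
    else:
        for seq in source:
            if isinstance(seq, np.ndarray):
                yield np.asarray(seq, dtype=np.uint8)
            else:
                yield _kernels.seq_to_index(seq)


def profile_reference(source, window: int = 100) -> GCProfile:
    """Build a :class:`GCProfile` from reference sequences.

    ``source`` may be a FASTA path (gzip allowed) or an iterable of
    sequences (strings or uint8 index arrays).  Each sequence is tiled
    independently with non-overlapping windows of ``window`` bp.
    """
    if window < 6:
        raise ValueError("window must be >= 6 bp")
    hist = np.zeros(N_GC_BINS, dtype=np.int64)
    excluded = 0
    any_seq = False
    for idx in _iter_index_sequences(source):
        any_seq = True
        n_win = len(idx) // window
        if n_win == 0:
            continue
        tiles = idx[: n_win * window].reshape(n_win, window)
        has_n = (tiles >= 4).any(axis=1)
        excluded += int(has_n.sum())
        kept = tiles[~has_n]
        if kept.size == 0:
            continue
        gc = _kernels.gc_base_counts(kept)
        bins = np.minimum((gc * N_GC_BINS) // window, N_GC_BINS - 1)
        hist += np.bincount(bins, minlength=N_GC_BINS)
    if not any_seq:
        raise ValueError("reference contains no sequences")
    hist *= window
    return GCProfile(
        window=window,
        band_lengths=hist,
        total_effective_length=int(hist.sum()),
        n_excluded_windows=excluded,
    )


def length_at_band(profile: GCProfile, band_lo: float, band_hi: float) -> int:
    """Cumulative length (bp) of windows with GC in [band_lo, band_hi).

    Bounds must lie on the 0.02 bin grid; the band is half-open, matching
    the read-side band query exactly.
    """
    bins = band_bin_range(band_lo, band_hi)
    return int(profile.band_lengths[bins.start : bins.stop].sum())


def write_profile(profile: GCProfile, path: str | Path) -> None:
    """Write the profile as TSV with a metadata header line."""
    with open(path, "w") as fh:
        fh.write(
            f"#window={profile.window}\texcluded_windows={profile.n_excluded_windows}\n"
        )
        fh.write("bin_lo\tbin_hi\tcumulative_bp\n")
        for i in range(N_GC_BINS):
            fh.write(
                f"{i * GC_BIN_WIDTH:.2f}\t{(i + 1) * GC_BIN_WIDTH:.2f}\t"
                f"{int(profile.band_lengths[i])}\n"
            )


def read_profile(path: str | Path) -> GCProfile:
    """Inverse of :func:`write_profile`."""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#window="):
            raise ValueError(f"{path}: not a GC profile file")
        meta = dict(
            item.split("=", 1) for item in header.lstrip("#").strip().split("\t")
        )
        fh.readline()  # column header
        lengths = np.zeros(N_GC_BINS, dtype=np.int64)
        for line in fh:
            lo, _hi, bp = line.rstrip("\n").split("\t")
            i = round(float(lo) / GC_BIN_WIDTH)
            lengths[i] = int(bp)
    return GCProfile(
        window=int(meta["window"]),
        band_lengths=lengths,
        total_effective_length=int(lengths.sum()),
        n_excluded_windows=int(meta["excluded_windows"]),
    )
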