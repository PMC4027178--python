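"""Streaming reads into per-read-group accumulators.

A :class:`ReadGroupTally` keeps, for one read group (typically one
sequencing lane), the full per-read telomere-repeat-count histogram and a
GC-content histogram on a fixed grid of 50 bins of width 0.02.  Storing
the whole repeat histogram means the telomeric read count ``t_k`` is a
tail sum that can be recomputed for any threshold ``k`` without rescanning
the reads, and the GC histogram supports arbitrary band queries on the
0.02 grid (the default band being 48-52%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pysam

from . import _kernels
from .motif import (
    TELOMERE_MOTIF,
    TELOMERE_MOTIF_RC,
    count_occurrences,
    reverse_complement,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SequenceRead",
    "ReadGroupTally",
    "passes_filters",
    "tally_read",
    "tally_read_arrays",
    "merge_tallies",
    "repeat_spectrum",
    "stream_reads",
    "write_tallies",
    "read_tallies",
]

#: GC histogram geometry: 50 half-open bins of width 0.02 covering [0, 1].
N_GC_BINS = 50
GC_BIN_WIDTH = 0.02
#: Default repeat-histogram cap: floor(150 / 6) = 25, so no read up to
#: 150 bp can overflow it; larger counts are bucketed at the cap.
DEFAULT_CAP = 25

ALL_FLAGS = frozenset(
    {"paired", "unmapped", "secondary", "supplementary", "duplicate", "qc_fail"}
)
#: Flags that disqualify a read from tallying by default.  Unmapped reads
#: are deliberately NOT here: telomeric reads usually fail to align.
DEFAULT_DROP_FLAGS = frozenset({"secondary", "supplementary", "duplicate", "qc_fail"})

UNKNOWN_READ_GROUP = "unknown"


@dataclass
class SequenceRead:
    """One sequencing read: payload plus the flag subset we filter on."""

    name: str
    bases: str
    read_group: str = ""
    flags: frozenset = frozenset()

    def __post_init__(self) -> None:
        unknown = set(self.flags) - ALL_FLAGS
        if unknown:
            raise ValueError(f"unknown read flags: {sorted(unknown)}")
        self.flags = frozenset(self.flags)


def gc_bin_index(gc_bases: int, length: int) -> int:
    """Histogram bin of a read with ``gc_bases`` G+C out of ``length``.

    Computed in integer arithmetic as floor((gc/length)/0.02), so bin
    edges are exact; a read of 100% GC is clamped into the top bin.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    return min((gc_bases * N_GC_BINS) // length, N_GC_BINS - 1)


def band_bin_range(band_lo: float, band_hi: float) -> range:
    """Bins whose intervals tile the half-open band [band_lo, band_hi).

    Both bounds must sit on the 0.02 grid; off-grid bounds raise.
    """
    lo_i = band_lo * N_GC_BINS
    hi_i = band_hi * N_GC_BINS
    if abs(lo_i - round(lo_i)) > 1e-9 or abs(hi_i - round(hi_i)) > 1e-9:
        raise ValueError(
            f"band bounds must lie on the {GC_BIN_WIDTH} grid, "
            f"got [{band_lo}, {band_hi})"
        )
    lo_i, hi_i = round(lo_i), round(hi_i)
    if not (0 <= lo_i < hi_i <= N_GC_BINS):
        raise ValueError(f"band [{band_lo}, {band_hi}) out of order or range")
    return range(lo_i, hi_i)


@dataclass
class ReadGroupTally:
    """Per-read-group histograms of telomere repeat counts and GC content."""

    read_group: str
    cap: int = DEFAULT_CAP
    total_reads: int = 0
    repeat_hist: np.ndarray = field(default=None)  # type: ignore[assignment]
    gc_hist: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.cap < 1:
            raise ValueError("cap must be >= 1")
        if self.repeat_hist is None:
            self.repeat_hist = np.zeros(self.cap + 1, dtype=np.int64)
        else:
            self.repeat_hist = np.asarray(self.repeat_hist, dtype=np.int64)
        if self.gc_hist is None:
            self.gc_hist = np.zeros(N_GC_BINS, dtype=np.int64)
        else:
            self.gc_hist = np.asarray(self.gc_hist, dtype=np.int64)
        if self.repeat_hist.shape != (self.cap + 1,):
            raise ValueError("repeat_hist length must be cap + 1")
        if self.gc_hist.shape != (N_GC_BINS,):
            raise ValueError(f"gc_hist must have {N_GC_BINS} bins")


def passes_filters(
    read: SequenceRead, drop_flags: frozenset = DEFAULT_DROP_FLAGS
) -> bool:
    """True if the read should be tallied.

    Secondary/supplementary records describe the same molecule twice and
    duplicates/QC failures are library artefacts; unmapped reads pass —
    they are where most of the telomeric signal lives.
    """
    return not (read.flags & drop_flags)


def tally_read(tally: ReadGroupTally, read: SequenceRead) -> ReadGroupTally:
    """Add one read to the tally (in place; the tally is also returned).

    Zero-length reads are skipped with a warning rather than raising, so a
    single malformed record cannot abort a whole-file scan.
    """
    s = read.bases.upper()
    if not s:
        logger.warning("skipping zero-length read %r", read.name)
        return tally
    r = max(s.count(TELOMERE_MOTIF), s.count(TELOMERE_MOTIF_RC))
    gc = s.count("G") + s.count("C")
    tally.repeat_hist[min(r, tally.cap)] += 1
    tally.gc_hist[gc_bin_index(gc, len(s))] += 1
    tally.total_reads += 1
    return tally


def tally_read_arrays(tally: ReadGroupTally, reads: np.ndarray) -> ReadGroupTally:
    """Vectorised equivalent of :func:`tally_read` for a batch of
    equal-length reads encoded as a (n_reads, read_length) uint8 index
    array (see :mod:`telolen._kernels`)."""
    if reads.size == 0:
        return tally
    n, length = reads.shape
    rep = np.minimum(_kernels.telomere_repeat_counts(reads), tally.cap)
    gc = _kernels.gc_base_counts(reads)
    bins = np.minimum((gc * N_GC_BINS) // length, N_GC_BINS - 1)
    tally.repeat_hist += np.bincount(rep, minlength=tally.cap + 1)
    tally.gc_hist += np.bincount(bins, minlength=N_GC_BINS)
    tally.total_reads += n
    return tally


def merge_tallies(a: ReadGroupTally, b: ReadGroupTally) -> ReadGroupTally:
    """Elementwise sum of two tallies (associative and commutative)."""
    if a.cap != b.cap:
        raise ValueError(f"cannot merge tallies with caps {a.cap} != {b.cap}")
    read_group = a.read_group if a.read_group == b.read_group else "pooled"
    return ReadGroupTally(
        read_group=read_group,
        cap=a.cap,
        total_reads=a.total_reads + b.total_reads,
        repeat_hist=a.repeat_hist + b.repeat_hist,
        gc_hist=a.gc_hist + b.gc_hist,
    )


def repeat_spectrum(
    reads: Iterable[SequenceRead],
    motifs: Sequence[str],
    cap: int = DEFAULT_CAP,
) -> pd.DataFrame:
    """Per-motif frequency table of per-read occurrence counts.

    For each motif the count per read is strand-symmetric — the maximum of
    the motif's and its reverse complement's occurrence counts — mirroring
    the telomere repeat count.  Rows are motifs, columns repeat counts
    0..cap; each row sums to the number of reads processed.
    """
    motif_list = sorted(set(m.upper() for m in motifs))
    if not motif_list:
        raise ValueError("motifs must be non-empty")
    pairs = {m: reverse_complement(m) for m in motif_list}
    table = {m: np.zeros(cap + 1, dtype=np.int64) for m in motif_list}
    for read in reads:
        s = read.bases
        for m, rc in pairs.items():
            c = max(count_occurrences(s, m), count_occurrences(s, rc))
            table[m][min(c, cap)] += 1
    return pd.DataFrame.from_dict(table, orient="index", columns=range(cap + 1))


_SAM_FLAG_BITS = (
    (0x1, "paired"),
    (0x4, "unmapped"),
    (0x100, "secondary"),
    (0x200, "qc_fail"),
    (0x400, "duplicate"),
    (0x800, "supplementary"),
)


def _flags_from_sam(flag: int) -> frozenset:
    return frozenset(name for bit, name in _SAM_FLAG_BITS if flag & bit)


def stream_reads(
    path: str | Path, read_group: str | None = None
) -> Iterator[SequenceRead]:
    """Yield every record of a SAM/BAM or FASTQ file as a SequenceRead.

    Mapped and unmapped records are both yielded, in file order.  For
    SAM/BAM the read group comes from the RG tag ("unknown" if absent);
    FASTQ carries no read groups, so ``read_group`` (default: the file
    stem) labels the whole file.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    suffixes = p.name.lower()
    if suffixes.endswith((".sam", ".bam")):
        mode = "rb" if suffixes.endswith(".bam") else "r"
        with pysam.AlignmentFile(str(p), mode, check_sq=False) as fh:
            for rec in fh.fetch(until_eof=True):
                rg = rec.get_tag("RG") if rec.has_tag("RG") else UNKNOWN_READ_GROUP
                yield SequenceRead(
                    name=rec.query_name or "",
                    bases=rec.query_sequence or "",
                    read_group=str(rg),
                    flags=_flags_from_sam(rec.flag),
                )
    elif suffixes.endswith(
        (".fastq", ".fq", ".fastq.gz", ".fq.gz", ".fasta", ".fa")
    ):
        label = read_group if read_group is not None else p.name.split(".")[0]
        with pysam.FastxFile(str(p)) as fh:
            for rec in fh:
                yield SequenceRead(
                    name=rec.name,
                    bases=rec.sequence or "",
                    read_group=label,
                    flags=frozenset({"paired"}) if rec.name.endswith(("/1", "/2")) else frozenset(),
                )
    else:
        raise ValueError(f"unrecognised read file format: {p.name}")


def _gc_bin_lo(i: int) -> str:
    return f"{i * GC_BIN_WIDTH:.2f}"


def write_tallies(tallies: Sequence[ReadGroupTally], path: str | Path) -> None:
    """Serialise tallies to TSV, one row per read group, bit-exact counts."""
    if not tallies:
        raise ValueError("no tallies to write")
    cap = tallies[0].cap
    rows = []
    for t in tallies:
        if t.cap != cap:
            raise ValueError("tallies must share a cap to be written together")
        row: dict[str, object] = {"read_group": t.read_group, "total": t.total_reads}
        for i in range(N_GC_BINS):
            row[f"gc_bin_{_gc_bin_lo(i)}"] = int(t.gc_hist[i])
        for r in range(cap + 1):
            row[f"tel_{r}"] = int(t.repeat_hist[r])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_tallies(path: str | Path) -> list[ReadGroupTally]:
    """Inverse of :func:`write_tallies`."""
    df = pd.read_csv(path, sep="\t")
    tel_cols = sorted(
        (c for c in df.columns if c.startswith("tel_")),
        key=lambda c: int(c.split("_")[1]),
    )
    gc_cols = [f"gc_bin_{_gc_bin_lo(i)}" for i in range(N_GC_BINS)]
    cap = int(tel_cols[-1].split("_")[1])
    out = []
    for _, row in df.iterrows():
        out.append(
            ReadGroupTally(
                read_group=str(row["read_group"]),
                cap=cap,
                total_reads=int(row["total"]),
                repeat_hist=row[tel_cols].to_numpy(dtype=np.int64),
                gc_hist=row[gc_cols].to_numpy(dtype=np.int64),
            )
        )
    return out
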