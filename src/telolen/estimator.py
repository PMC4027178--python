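"""Telomere length estimation from read-group tallies.

The estimator converts counts into a physical length:

    l = (t_k / n_gc) * (L_gc / n_ends)

where ``t_k`` is the number of reads carrying at least ``k`` telomere
repeats, ``n_gc`` the number of reads whose GC content falls in the
normalisation band (default 48-52%, the composition of TTAGGG-dense
sequence), ``L_gc`` the cumulative reference length at that same band
(see :mod:`telolen.reference_gc`), and ``n_ends`` the number of telomere
ends the total telomeric content is spread over (46 = 23 x 2 for a human
haploid reference complement; 2 for a single synthetic chromosome).

``t_k / n_gc`` is the per-band-read telomeric read fraction; scaling by
``L_gc`` converts it to total telomeric base pairs under the assumption
that reads at a given GC composition sample the genome regions of that
composition uniformly — which is exactly why the band normalisation is
used instead of the raw read total: library GC bias cancels between
numerator and denominator within the band.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .tally import ReadGroupTally, band_bin_range, merge_tallies

__all__ = [
    "EstimatorParams",
    "TelomereEstimate",
    "EstimateUndefinedError",
    "telomeric_read_count",
    "gc_band_read_count",
    "estimate_length",
    "sweep_k",
    "aggregate_sample",
    "estimates_to_frame",
    "write_report",
]

#: Human telomere end count: 23 chromosomes x 2 ends, matching a haploid
#: reference genome length in L_gc.
HUMAN_N_ENDS = 46


class EstimateUndefinedError(ValueError):
    """Raised when no reads fall in the GC band, leaving l undefined."""


@dataclass(frozen=True)
class EstimatorParams:
    """Parameters of the length estimator.

    l_gc must be supplied (from a GCProfile or as a known constant for the
    reference in use); there is no packaged default constant.
    """

    l_gc: float
    k: int = 7
    band_lo: float = 0.48
    band_hi: float = 0.52
    n_ends: int = HUMAN_N_ENDS

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n_ends < 1:
            raise ValueError("n_ends must be >= 1")
        if not self.l_gc > 0:
            raise ValueError("l_gc must be positive")
        band_bin_range(self.band_lo, self.band_hi)  # validates the band


@dataclass(frozen=True)
class TelomereEstimate:
    """One length estimate with the counts and parameters that produced it."""

    read_group: str
    length_bp: float
    t_k: int
    n_gc: int
    total_reads: int
    params: EstimatorParams

    @property
    def length_kb(self) -> float:
        return self.length_bp / 1000.0


def telomeric_read_count(tally: ReadGroupTally, k: int) -> int:
    """t_k: number of reads with at least k telomere repeats (tail sum)."""
    if not 0 <= k <= tally.cap:
        raise ValueError(f"k must be in [0, {tally.cap}], got {k}")
    return int(tally.repeat_hist[k:].sum())


def gc_band_read_count(
    tally: ReadGroupTally, band_lo: float, band_hi: float
) -> int:
    """Number of reads with GC fraction in the half-open band [lo, hi).

    A read with GC exactly equal to band_hi falls in the next bin and is
    excluded — the same convention the reference profile uses, so the
    read-side and genome-side band definitions match.
    """
    bins = band_bin_range(band_lo, band_hi)
    return int(tally.gc_hist[bins.start : bins.stop].sum())


def estimate_length(
    tally: ReadGroupTally, params: EstimatorParams
) -> TelomereEstimate:
    """Estimate mean telomere length for one read group.

    Raises :class:`EstimateUndefinedError` when the GC band holds no reads
    (possible at extremely low coverage); never returns a silent zero.
    """
    t_k = telomeric_read_count(tally, params.k)
    n_gc = gc_band_read_count(tally, params.band_lo, params.band_hi)
    if n_gc == 0:
        raise EstimateUndefinedError(
            f"read group {tally.read_group!r}: no reads in GC band "
            f"[{params.band_lo}, {params.band_hi}); estimate undefined"
        )
    length_bp = (t_k / n_gc) * (params.l_gc / params.n_ends)
    return TelomereEstimate(
        read_group=tally.read_group,
        length_bp=length_bp,
        t_k=t_k,
        n_gc=n_gc,
        total_reads=tally.total_reads,
        params=params,
    )


def sweep_k(
    tally: ReadGroupTally,
    params: EstimatorParams,
    k_range: Iterable[int],
) -> list[TelomereEstimate]:
    """Estimates at several thresholds from one tally, without rescanning.

    Because t_k is a tail sum the lengths are non-increasing in k; the
    sweep is how threshold choices (e.g. k > 3 for off-target exome reads
    versus the default k = 7) are compared.
    """
    return [estimate_length(tally, replace(params, k=k)) for k in k_range]


def aggregate_sample(
    tallies: Sequence[ReadGroupTally], params: EstimatorParams
) -> TelomereEstimate:
    """Pooled estimate for a sample: merge tallies, then estimate.

    This is read-count-weighted pooling — identical to tallying the
    concatenated read stream — not a mean of per-group estimates.
    """
    if not tallies:
        raise ValueError("aggregate_sample requires at least one tally")
    merged = tallies[0]
    for t in tallies[1:]:
        merged = merge_tallies(merged, t)
    return estimate_length(merged, params)


def estimates_to_frame(
    estimates: Sequence[TelomereEstimate], sample: str = "sample"
) -> pd.DataFrame:
    """Report table: one row per estimate, lengths in kb, NA-safe.

    The schema is stable even for an empty estimate list, so an empty but
    valid input still yields a well-formed (zero-row) report.
    """
    columns = [
        "sample",
        "read_group",
        "total_reads",
        "gc_band_reads",
        "tel_reads",
        "k",
        "band_lo",
        "band_hi",
        "L_gc",
        "n_ends",
        "length_kb",
    ]
    rows = []
    for e in estimates:
        rows.append(
            {
                "sample": sample,
                "read_group": e.read_group,
                "total_reads": e.total_reads,
                "gc_band_reads": e.n_gc,
                "tel_reads": e.t_k,
                "k": e.params.k,
                "band_lo": e.params.band_lo,
                "band_hi": e.params.band_hi,
                "L_gc": e.params.l_gc,
                "n_ends": e.params.n_ends,
                "length_kb": e.length_kb,
            }
        )
    return pd.DataFrame(rows, columns=columns)


def write_report(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a report TSV; undefined lengths are printed as NA, never 0."""
    frame.to_csv(path, sep="\t", index=False, na_rep="NA")
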