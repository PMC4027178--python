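"""Synthetic telomere-bearing genomes and paired-end read simulation.

The validation strategy is parameter recovery: build a chromosome whose
telomere length is known by construction, sequence it in silico across a
range of coverages, and check that the estimator returns the truth.  The
synthetic chromosome has an i.i.d. random core (default 5 Mb at 50% GC)
flanked by perfect telomere tracts — CCCTAA repeats on the left (p-arm)
end and TTAGGG repeats on the right (q-arm) end, default 30 kb each,
mirroring the construction of a reference chromosome with its ends
replaced by telomere repeats.

Reads are 100 bp paired ends drawn from normally distributed fragments
with uniform start positions and i.i.d. uniform substitution errors
(default 1%).  No indels or quality-dependent errors are modelled: motif
counting at these scales is substitution-dominated, and the recovery
surface is insensitive to error-model detail at ~1% error.

The coverage titration reproduces the benchmark design at reduced scale:
coverages 0.2X to 10X in 0.2X steps, several replicates per coverage,
estimating each run with k = 7, the 48-52% GC band, n_ends = 2 (one
chromosome, two telomeres) and L_gc profiled from the same genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .estimator import (
    EstimateUndefinedError,
    EstimatorParams,
    estimate_length,
)
from .reference_gc import length_at_band, profile_reference
from .stats import variance_f_test
from .tally import DEFAULT_CAP, ReadGroupTally, SequenceRead, tally_read_arrays

logger = logging.getLogger(__name__)

__all__ = [
    "SimulatedGenome",
    "TruthManifest",
    "ReadSimConfig",
    "build_genome",
    "simulate_read_arrays",
    "simulate_reads",
    "write_fastq",
    "write_sam",
    "tally_simulated",
    "coverage_titration",
    "titration_summary",
    "standard_coverages",
    "standard_titration",
]

#: Pairs simulated per vectorised batch.  Fixed (not a tuning knob) so a
#: given seed always yields the identical read stream.
_CHUNK_PAIRS = 1 << 16

#: Default titration design: 0.2X..10X in 0.2X steps, 5 replicates each.
DEFAULT_CORE_LENGTH = 5_000_000
DEFAULT_TELOMERE_LENGTH = 30_000
DEFAULT_REPLICATES = 5
#: Coverage below which estimate variance inflates markedly.
LOW_COVERAGE_SPLIT = 2.5


@dataclass
class SimulatedGenome:
    """Synthetic chromosome: random core flanked by telomere tracts."""

    index: np.ndarray  # uint8 base indices, A=0 C=1 G=2 T=3
    core_length: int
    telomere_length: int
    core_gc: float
    seed: int

    def __len__(self) -> int:
        return len(self.index)

    @property
    def sequence(self) -> str:
        return _kernels.index_to_seq(self.index)


@dataclass(frozen=True)
class TruthManifest:
    """Ground truth of a simulated genome, for recovery tests."""

    telomere_length: int
    genome_length: int
    core_length: int
    core_gc: float
    seed: int
    n_ends: int = 2


@dataclass(frozen=True)
class ReadSimConfig:
    """Paired-end simulation parameters.

    Fragment geometry defaults (350 +/- 50 bp inserts, 100 bp reads)
    follow a typical Illumina paired-end library.
    """

    coverage: float
    read_length: int = 100
    fragment_mean: float = 350.0
    fragment_sd: float = 50.0
    error_rate: float = 0.01
    seed: int = 0
    read_group: str = "sim"

    def __post_init__(self) -> None:
        if not self.coverage > 0:
            raise ValueError("coverage must be positive")
        if self.read_length < 6:
            raise ValueError("read_length must be >= 6")
        if self.fragment_mean < 2 * self.read_length:
            raise ValueError("fragment_mean must be >= 2 * read_length")
        if self.fragment_sd < 0:
            raise ValueError("fragment_sd must be >= 0")
        if not 0 <= self.error_rate < 0.1:
            raise ValueError("error_rate must be in [0, 0.1)")


def build_genome(
    core_length: int = DEFAULT_CORE_LENGTH,
    telomere_length: int = DEFAULT_TELOMERE_LENGTH,
    core_gc: float = 0.5,
    seed: int = 0,
) -> tuple[SimulatedGenome, TruthManifest]:
    """Build a telomere-bearing synthetic chromosome.

    The core is i.i.d. with per-base G/C probability ``core_gc`` (split
    evenly G vs C and A vs T).  The first ``telomere_length`` bases are
    perfect CCCTAA repeats and the last ``telomere_length`` bases perfect
    TTAGGG repeats, phased so each chromosome end starts on a motif
    boundary.  The core must be at least 10x the tract length so that
    telomeric reads contaminate the GC normaliser only negligibly.
    """
    if telomere_length < 6:
        raise ValueError("telomere_length must be >= 6")
    if core_length < 10 * telomere_length:
        raise ValueError("core_length must be >= 10 * telomere_length")
    if not 0 < core_gc < 1:
        raise ValueError("core_gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    # base order A, C, G, T
    p = np.array(
        [(1 - core_gc) / 2, core_gc / 2, core_gc / 2, (1 - core_gc) / 2]
    )
    core = np.searchsorted(np.cumsum(p)[:-1], rng.random(core_length), side="right")
    core = core.astype(np.uint8)
    reps = -(-telomere_length // 6)  # ceil
    left = np.tile(_kernels.CCCTAA, reps)[:telomere_length]
    right = np.tile(_kernels.TTAGGG, reps)[-telomere_length:]
    index = np.concatenate([left, core, right])
    genome = SimulatedGenome(
        index=index,
        core_length=core_length,
        telomere_length=telomere_length,
        core_gc=core_gc,
        seed=seed,
    )
    truth = TruthManifest(
        telomere_length=telomere_length,
        genome_length=len(index),
        core_length=core_length,
        core_gc=core_gc,
        seed=seed,
    )
    return genome, truth


def n_read_pairs(genome_length: int, config: ReadSimConfig) -> int:
    """Number of pairs giving the configured fold coverage exactly."""
    return int(round(config.coverage * genome_length / (2 * config.read_length)))


def _inject_errors(reads: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    """Apply i.i.d. substitutions in place: each error replaces the base
    with one of the three alternatives uniformly."""
    if rate <= 0 or reads.size == 0:
        return
    n_err = rng.binomial(reads.size, rate)
    if n_err == 0:
        return
    flat = reads.reshape(-1)
    pos = rng.integers(0, flat.size, n_err)
    shift = rng.integers(1, 4, n_err).astype(np.uint8)
    flat[pos] = (flat[pos] + shift) % 4


def simulate_read_arrays(
    genome: SimulatedGenome, config: ReadSimConfig
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Yield batches of (read1, read2) uint8 index arrays.

    Fragments have normally distributed lengths truncated to
    [2*read_length, genome_length] and uniform start positions over all
    placements where the fragment fits.  Read 1 is the first read_length
    bases of the fragment; read 2 the reverse complement of the last
    read_length bases.  Deterministic given ``config.seed``.
    """
    g = genome.index
    n_total = n_read_pairs(len(g), config)
    rl = config.read_length
    rng = np.random.default_rng(config.seed)
    offs = np.arange(rl, dtype=np.int64)
    done = 0
    while done < n_total:
        m = min(_CHUNK_PAIRS, n_total - done)
        lens = np.rint(rng.normal(config.fragment_mean, config.fragment_sd, m))
        lens = np.clip(lens, 2 * rl, len(g)).astype(np.int64)
        starts = (rng.random(m) * (len(g) - lens + 1)).astype(np.int64)
        r1 = g[starts[:, None] + offs]
        r2 = (3 - g[(starts + lens - 1)[:, None] - offs]).astype(np.uint8)
        _inject_errors(r1, config.error_rate, rng)
        _inject_errors(r2, config.error_rate, rng)
        yield r1, r2
        done += m


def simulate_reads(
    genome: SimulatedGenome, config: ReadSimConfig
) -> Iterator[tuple[SequenceRead, SequenceRead]]:
    """Yield simulated read pairs as :class:`SequenceRead` objects.

    Thin per-read wrapper over :func:`simulate_read_arrays`; the same
    seed produces the same reads on either interface.
    """
    pair_idx = 0
    flags = frozenset({"paired", "unmapped"})
    for r1, r2 in simulate_read_arrays(genome, config):
        for i in range(r1.shape[0]):
            name = f"{config.read_group}:{pair_idx}"
            yield (
                SequenceRead(
                    name=name,
                    bases=_kernels.index_to_seq(r1[i]),
                    read_group=config.read_group,
                    flags=flags,
                ),
                SequenceRead(
                    name=name,
                    bases=_kernels.index_to_seq(r2[i]),
                    read_group=config.read_group,
                    flags=flags,
                ),
            )
            pair_idx += 1


def write_fastq(
    genome: SimulatedGenome, config: ReadSimConfig, path: str | Path
) -> int:
    """Write interleaved paired FASTQ (/1 and /2 name suffixes).

    The header comment of every record carries the simulation seed, so a
    file is reproducible from its own content.  Returns the pair count.
    """
    n = 0
    with open(path, "w") as fh:
        for r1, r2 in simulate_reads(genome, config):
            qual = "I" * len(r1.bases)
            fh.write(f"@{r1.name}/1 seed={config.seed}\n{r1.bases}\n+\n{qual}\n")
            fh.write(f"@{r2.name}/2 seed={config.seed}\n{r2.bases}\n+\n{qual}\n")
            n += 1
    return n


def write_sam(
    genome: SimulatedGenome, config: ReadSimConfig, path: str | Path
) -> int:
    """Write unaligned SAM with an @RG header line.  Returns pair count.

    Flags are 77/141: paired, both mates unmapped, first/second in pair.
    """
    n = 0
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@RG\tID:{config.read_group}\tSM:sim\n")
        fh.write(f"@CO\ttelolen simulation seed={config.seed}\n")
        for r1, r2 in simulate_reads(genome, config):
            for read, flag in ((r1, 77), (r2, 141)):
                qual = "I" * len(read.bases)
                fh.write(
                    f"{read.name}\t{flag}\t*\t0\t0\t*\t*\t0\t0\t"
                    f"{read.bases}\t{qual}\tRG:Z:{config.read_group}\n"
                )
            n += 1
    return n


def tally_simulated(
    genome: SimulatedGenome, config: ReadSimConfig, cap: int = DEFAULT_CAP
) -> ReadGroupTally:
    """Simulate one run and tally it without materialising reads."""
    tally = ReadGroupTally(read_group=config.read_group, cap=cap)
    for r1, r2 in simulate_read_arrays(genome, config):
        tally_read_arrays(tally, r1)
        tally_read_arrays(tally, r2)
    return tally


def _run_seed(master_seed: int, run_index: int) -> int:
    """Stable per-run seed below 2**31 derived from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), int(run_index)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def standard_coverages() -> list[float]:
    """The titration grid: 0.2X to 10X in 0.2X increments (50 values)."""
    return [round(0.2 * i, 1) for i in range(1, 51)]


def coverage_titration(
    genome: SimulatedGenome,
    coverages: Sequence[float],
    replicates: int,
    config_base: ReadSimConfig | None = None,
    params: EstimatorParams | None = None,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Run the estimator across a coverage grid with replicate runs.

    Each (coverage, replicate) run gets an independent seed derived from
    ``master_seed``.  If ``params`` is None, the estimator is configured
    for the synthetic genome itself: k=7, band 48-52%, n_ends=2 and L_gc
    from a GC profile of the same genome at the read-length window.
    Runs whose GC band holds no reads get estimate_kb = NaN, never 0.
    """
    if config_base is None:
        config_base = ReadSimConfig(coverage=1.0)
    if params is None:
        profile = profile_reference([genome.index], window=config_base.read_length)
        params = EstimatorParams(
            l_gc=length_at_band(profile, 0.48, 0.52),
            k=7,
            band_lo=0.48,
            band_hi=0.52,
            n_ends=2,
        )
    rows = []
    run_index = 0
    for cov in coverages:
        for rep in range(replicates):
            seed = _run_seed(master_seed, run_index)
            run_index += 1
            cfg = replace(
                config_base,
                coverage=cov,
                seed=seed,
                read_group=f"cov{cov:g}_rep{rep}",
            )
            tally = tally_simulated(genome, cfg)
            row = {
                "coverage": cov,
                "replicate": rep,
                "seed": seed,
                "total_reads": tally.total_reads,
            }
            try:
                est = estimate_length(tally, params)
                row.update(
                    tel_reads=est.t_k,
                    gc_band_reads=est.n_gc,
                    estimate_kb=est.length_kb,
                )
            except EstimateUndefinedError:
                logger.warning(
                    "run %s: no GC-band reads, estimate recorded as missing",
                    cfg.read_group,
                )
                row.update(tel_reads=np.nan, gc_band_reads=0, estimate_kb=np.nan)
            rows.append(row)
    columns = [
        "coverage",
        "replicate",
        "seed",
        "total_reads",
        "tel_reads",
        "gc_band_reads",
        "estimate_kb",
    ]
    return pd.DataFrame(rows, columns=columns)


def titration_summary(
    table: pd.DataFrame, split: float = LOW_COVERAGE_SPLIT
) -> dict:
    """Mean/SD of estimates over all runs and the high-coverage subset,
    plus the low-vs-high variance F-test.

    Keys absent when undefined (e.g. no runs above the split) rather than
    filled with placeholders; ``n_missing`` counts runs without an
    estimate.
    """
    est = table["estimate_kb"]
    valid = table.loc[est.notna()]
    vals = valid["estimate_kb"].to_numpy(dtype=float)
    out: dict = {
        "n_runs": int(len(table)),
        "n_missing": int(est.isna().sum()),
        "mean_all_kb": float(vals.mean()) if vals.size else float("nan"),
        "sd_all_kb": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
    }
    high = valid.loc[valid["coverage"] > split, "estimate_kb"].to_numpy(dtype=float)
    low = valid.loc[valid["coverage"] <= split, "estimate_kb"].to_numpy(dtype=float)
    out["n_high"] = int(high.size)
    out["n_low"] = int(low.size)
    if high.size >= 2:
        out["mean_high_kb"] = float(high.mean())
        out["sd_high_kb"] = float(high.std(ddof=1))
    if high.size >= 2 and low.size >= 2:
        f, p = variance_f_test(low, high)
        out["f_low_vs_high"] = f
        out["p_low_vs_high"] = p
    return out


def standard_titration(
    master_seed: int = 0,
    core_length: int = DEFAULT_CORE_LENGTH,
    telomere_length: int = DEFAULT_TELOMERE_LENGTH,
    replicates: int = DEFAULT_REPLICATES,
    error_rate: float = 0.01,
    coverages: Sequence[float] | None = None,
) -> tuple[pd.DataFrame, TruthManifest]:
    """The full reference validation: build the default genome and run the
    default coverage titration on it.  One call, fully seeded."""
    genome, truth = build_genome(
        core_length=core_length,
        telomere_length=telomere_length,
        core_gc=0.5,
        seed=_run_seed(master_seed, 1_000_000),
    )
    table = coverage_titration(
        genome,
        coverages=list(coverages) if coverages is not None else standard_coverages(),
        replicates=replicates,
        config_base=ReadSimConfig(coverage=1.0, error_rate=error_rate),
        master_seed=master_seed,
    )
    return table, truth
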