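"""Synthetic genomes, read simulation and the coverage titration."""

import numpy as np
import pytest

from telolen import _kernels
from telolen.estimator import EstimatorParams
from telolen.motif import reverse_complement, telomere_repeat_count
from telolen.reference_gc import length_at_band, profile_reference
from telolen.simulate import (
    ReadSimConfig,
    build_genome,
    coverage_titration,
    n_read_pairs,
    simulate_read_arrays,
    simulate_reads,
    standard_coverages,
    tally_simulated,
    write_fastq,
    write_sam,
)
from telolen.tally import ReadGroupTally, stream_reads, tally_read


@pytest.fixture(scope="module")
def small_genome():
    genome, truth = build_genome(
        core_length=200_000, telomere_length=5_000, core_gc=0.5, seed=11
    )
    return genome, truth


class TestBuildGenome:
    def test_lengths_add_up(self, small_genome):
        genome, truth = small_genome
        assert len(genome) == 200_000 + 2 * 5_000
        assert truth.genome_length == len(genome)

    def test_telomere_tracts_by_construction(self, small_genome):
        genome, _ = small_genome
        seq = genome.sequence
        assert seq[:12] == "CCCTAACCCTAA"
        assert seq[-12:] == "TTAGGGTTAGGG"
        assert telomere_repeat_count(seq[:5000]) == 5000 // 6
        assert telomere_repeat_count(seq[-5000:]) == 5000 // 6

    def test_core_gc_matches_binomial_oracle(self, small_genome):
        genome, _ = small_genome
        core = genome.index[5000:-5000]
        gc = int(((core == 1) | (core == 2)).sum())
        n = core.size
        se = np.sqrt(0.25 * n)
        assert abs(gc - 0.5 * n) < 3 * se

    def test_determinism(self):
        g1, _ = build_genome(100_000, 2_000, 0.5, seed=5)
        g2, _ = build_genome(100_000, 2_000, 0.5, seed=5)
        np.testing.assert_array_equal(g1.index, g2.index)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            build_genome(core_length=50_000, telomere_length=10_000)
        with pytest.raises(ValueError):
            build_genome(core_length=100_000, telomere_length=1_000, core_gc=1.5)


class TestReadSimConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            ReadSimConfig(coverage=0)
        with pytest.raises(ValueError):
            ReadSimConfig(coverage=1, fragment_mean=150, read_length=100)
        with pytest.raises(ValueError):
            ReadSimConfig(coverage=1, error_rate=0.5)


class TestSimulateReads:
    def test_pair_count_exact(self, small_genome):
        genome, _ = small_genome
        cfg = ReadSimConfig(coverage=0.5, seed=1)
        expected = int(round(0.5 * len(genome) / 200))
        assert n_read_pairs(len(genome), cfg) == expected
        total = sum(r1.shape[0] for r1, _ in simulate_read_arrays(genome, cfg))
        assert total == expected

    def test_error_free_reads_are_genome_substrings(self, small_genome):
        genome, _ = small_genome
        seq = genome.sequence
        rc = reverse_complement(seq)
        cfg = ReadSimConfig(coverage=0.01, error_rate=0.0, seed=2)
        pairs = list(simulate_reads(genome, cfg))
        assert pairs
        for r1, r2 in pairs[:50]:
            assert r1.bases in seq
            assert r2.bases in rc

    def test_substitution_rate_matches_binomial_oracle(self, small_genome):
        """Compare >=1e5 simulated bases against the genome positions they
        came from; mismatch fraction ~ Binomial(n, 0.01)."""
        genome, _ = small_genome
        rate = 0.01
        cfg = ReadSimConfig(coverage=1.0, error_rate=rate, seed=3)
        cfg0 = ReadSimConfig(coverage=1.0, error_rate=0.0, seed=3)
        mismatches = 0
        n = 0
        for (e1, e2), (c1, c2) in zip(
            simulate_read_arrays(genome, cfg), simulate_read_arrays(genome, cfg0)
        ):
            # same seed, same fragments; only the error step differs
            mismatches += int((e1 != c1).sum()) + int((e2 != c2).sum())
            n += e1.size + e2.size
        assert n >= 1e5
        se = np.sqrt(rate * (1 - rate) * n)
        assert abs(mismatches - rate * n) < 3 * se

    def test_fastq_deterministic_and_streamable(self, small_genome, tmp_path):
        genome, _ = small_genome
        cfg = ReadSimConfig(coverage=0.01, seed=4, read_group="lane7")
        p1, p2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
        n1 = write_fastq(genome, cfg, p1)
        write_fastq(genome, cfg, p2)
        assert p1.read_bytes() == p2.read_bytes()
        reads = list(stream_reads(p1))
        assert len(reads) == 2 * n1

    def test_sam_output_round_trips_through_tally(self, small_genome, tmp_path):
        genome, _ = small_genome
        cfg = ReadSimConfig(coverage=0.01, seed=5, read_group="rg1")
        path = tmp_path / "sim.sam"
        n_pairs = write_sam(genome, cfg, path)
        reads = list(stream_reads(path))
        assert len(reads) == 2 * n_pairs
        assert {r.read_group for r in reads} == {"rg1"}
        assert all("unmapped" in r.flags and "paired" in r.flags for r in reads)

    def test_array_and_read_paths_agree(self, small_genome):
        genome, _ = small_genome
        cfg = ReadSimConfig(coverage=0.02, seed=6)
        via_arrays = tally_simulated(genome, cfg)
        via_reads = ReadGroupTally(cfg.read_group)
        for r1, r2 in simulate_reads(genome, cfg):
            tally_read(via_reads, r1)
            tally_read(via_reads, r2)
        np.testing.assert_array_equal(via_arrays.repeat_hist, via_reads.repeat_hist)
        np.testing.assert_array_equal(via_arrays.gc_hist, via_reads.gc_hist)


class TestCoverageTitration:
    def test_single_run_recovers_truth_error_free(self):
        # 30 kb tracts: junction and fragment-edge losses are <1% of the
        # tract, so a single 10X error-free run recovers truth within 5%
        genome, truth = build_genome(
            core_length=300_000, telomere_length=30_000, core_gc=0.5, seed=21
        )
        table = coverage_titration(
            genome,
            coverages=[10.0],
            replicates=1,
            config_base=ReadSimConfig(coverage=1.0, error_rate=0.0),
            master_seed=9,
        )
        est = table.loc[0, "estimate_kb"]
        assert est == pytest.approx(truth.telomere_length / 1000, rel=0.05)

    def test_replicate_sd_shrinks_with_coverage(self, small_genome):
        """Telomeric read counting is Poisson-like, so the SD of estimates
        shrinks roughly as coverage^(-1/2)."""
        genome, _ = small_genome
        table = coverage_titration(
            genome,
            coverages=[0.5, 8.0],
            replicates=8,
            config_base=ReadSimConfig(coverage=1.0, error_rate=0.0),
            master_seed=10,
        )
        sd_low = table.loc[table.coverage == 0.5, "estimate_kb"].std(ddof=1)
        sd_high = table.loc[table.coverage == 8.0, "estimate_kb"].std(ddof=1)
        expected_ratio = np.sqrt(8.0 / 0.5)
        assert sd_low > sd_high
        assert expected_ratio / 3 < sd_low / sd_high < expected_ratio * 3

    def test_empty_coverage_list(self, small_genome):
        genome, _ = small_genome
        table = coverage_titration(genome, [], 3, master_seed=0)
        assert len(table) == 0

    def test_deterministic_given_master_seed(self, small_genome):
        genome, _ = small_genome
        t1 = coverage_titration(genome, [0.3], 2, master_seed=42)
        t2 = coverage_titration(genome, [0.3], 2, master_seed=42)
        assert t1.equals(t2)

    def test_estimates_never_fabricated_when_band_empty(self):
        """At vanishing coverage a run can miss the GC band entirely; the
        table records NaN, never zero."""
        genome, _ = build_genome(60_000, 1_000, core_gc=0.5, seed=1)
        # GC band far from core composition: no reads will land there
        params = EstimatorParams(l_gc=1.0, k=7, band_lo=0.90, band_hi=0.94, n_ends=2)
        table = coverage_titration(
            genome, [0.01], 2, params=params, master_seed=3
        )
        assert table["estimate_kb"].isna().all()
        assert not (table["estimate_kb"] == 0).any()


def test_standard_coverages_grid():
    grid = standard_coverages()
    assert len(grid) == 50
    assert grid[0] == pytest.approx(0.2)
    assert grid[-1] == pytest.approx(10.0)
    steps = np.diff(grid)
    assert np.allclose(steps, 0.2)
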