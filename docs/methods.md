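# Methods

## Model

`telolen` estimates mean telomere length from the abundance of
motif-dense reads in shotgun sequencing data. A read is classified
telomeric when it contains at least *k* non-overlapping copies of the
telomere hexamer, counted strand-symmetrically as
`max(count(TTAGGG), count(CCCTAA))`. On uniform random sequence the
probability of even a handful of hexamer hits per 100 bp read is
negligible (per-register hit rate 4⁻⁶), so read counts beyond the default
threshold *k* = 7 essentially only arise from genuine telomeric (or
telomere-like interstitial) sequence; the 54 control hexamers — the
permutations of the letters of TTAGGG that are not cyclic rotations of it
— provide the matching empirical background spectrum at identical base
composition.

The telomeric read count *t<sub>k</sub>* is converted to a length by

    l = (t_k / n_gc) · (L_gc / n_ends)

*t<sub>k</sub>/n<sub>gc</sub>* is the telomeric read abundance per read
of telomere-like GC composition (48–52% by default; TTAGGG-dense sequence
is exactly 50% GC). Under the assumption that reads of a given GC
composition sample the genomic regions of that composition uniformly,
multiplying by *L<sub>gc</sub>* — the total reference length at that
composition — yields total telomeric base pairs, and dividing by the
number of telomere ends gives a per-end mean. Normalising inside a GC
band instead of by total read count is the point of the method: PCR
amplification bias makes read density GC-dependent, and restricting both
numerator (implicitly, telomeric reads are ~50% GC) and denominator to
the same band cancels that bias to first order.

The formula is written here with explicit count ratios:
*s* = *n<sub>gc</sub>*-normalisation and *c* = *L<sub>gc</sub>/n<sub>ends</sub>*
are the only dimensional reading under which *l* is a length and the
simulator recovers known truth; this reading is verified by the
parameter-recovery tests rather than assumed.

## Counting conventions

- Occurrences are counted non-overlapping, left to right. TTAGGG and
  CCCTAA cannot overlap themselves, so for the telomere motifs this is
  identical to counting all match positions; the convention only matters
  for self-overlapping control hexamers, where it is fixed for
  determinism.
- `N` never matches a motif; it counts toward length in the GC-fraction
  denominator. Lowercase input is uppercased.
- GC histograms (reads and reference windows alike) use 50 half-open bins
  of width 0.02 computed in exact integer arithmetic
  (`bin = (gc_count · 50) // length`); band queries are half-open
  `[lo, hi)` on that grid, applied identically to reads and windows so
  the two sides of the normalisation use the same band definition. A read
  with GC exactly at the upper band edge is excluded.
- Read filtering drops secondary, supplementary, duplicate-flagged and
  QC-fail records (one count per sequenced molecule) and keeps unmapped
  reads, which carry most of the telomeric signal. Duplicate handling is
  configurable (`--keep-dups`).
- The repeat histogram is capped at 25 (= ⌊150/6⌋); no read up to 150 bp
  can exceed it. The full histogram is stored, so any threshold *k* and
  any GC band on the grid can be queried after a single pass over the
  reads — including the lower *k* > 3 threshold appropriate for the
  off-target fraction of exome captures.

## Reference GC profile

*L<sub>gc</sub>* is measured by tiling each reference sequence with
non-overlapping windows equal to the read length (default 100 bp, so the
genome-side GC distribution lives on the same length scale as the
read-side one), excluding any window containing an N, and accumulating
window length per GC bin. Trailing partial windows are dropped. No
packaged constant is claimed for any particular reference build; users
either profile their FASTA (`telolen gcprofile`) or pass a known
`--lgc` value directly.

## Statistics

- **Replicate CV** — sample SD (n−1) over mean of per-lane estimates of
  one sample; scale-invariant.
- **Variance F-test** — F = var(a)/var(b) with (n−1, n−1) degrees of
  freedom, two-sided p (doubled tail, capped at 1). Used to test variance
  inflation of low-coverage estimates.
- **Bootstrap correlation difference** — for two measures y1, y2 against
  a common x: Δρ = ρ(x,y1) − ρ(x,y2), with a SD from paired case
  resampling (whole rows (xᵢ, y1ᵢ, y2ᵢ), preserving the dependence
  between the two correlations) and a two-sided normal reference for
  Δρ/SD. Pearson by default, Spearman optional, B = 1000, explicit seed.
  This is a standard, assumption-light construction chosen where the
  design space (pairs vs residual bootstrap, reference distribution) was
  open.

## Simulator

The validation strategy is parameter recovery on synthetic data, because
no real sample has ground-truth telomere length at base-pair accuracy.

**Genome.** A single chromosome: an i.i.d. random core (per-base G/C
probability `core_gc`, split evenly G/C and A/T) flanked by perfect
telomere tracts — CCCTAA repeats on the left end, TTAGGG on the right,
following reference-strand orientation for p/q arms (the estimator is
strand-symmetric, so this affects realism only). Defaults: 5 Mb core at
50% GC, 30 kb per tract. The core must be ≥ 10× the tract so that
telomeric reads contaminate the GC band only marginally — and since the
profile of the same genome includes the tract windows, that contamination
enters numerator-side and genome-side alike and cancels in the ratio.

**Reads.** Paired 100 bp ends of fragments with normal(350, 50) lengths
truncated to [2·read length, genome length] and uniform starts wherever
the fragment fits; i.i.d. substitution errors (default 1%) to a uniformly
chosen different base. The fragment geometry is a typical Illumina
paired-end library of the 100 bp era. No indels, no quality-dependent
error profile, no GC amplification bias: motif counting at ~1% error is
substitution-dominated (a full telomeric read still carries ≈ 14 intact
motifs against a threshold of 7), and the simulator's i.i.d. sampling is
exactly the uniformity assumption the estimator makes. Passing recovery
tests therefore demonstrates the *formula* and the *counting machinery*
are right; they do not probe real-library GC bias (which the GC band is
designed to absorb) or subtelomeric degenerate repeats.

**Known bias.** Estimates sit slightly below truth, for two reasons that
both scale inversely with tract length: reads straddling the
tract-to-core junction with fewer than *k* complete motifs are lost
(≈ 6·k bp per end), and coverage dips within roughly a fragment length of
each chromosome end because only fragments fully inside the genome are
drawn. At 30 kb tracts the combined deficit is ~1–2% (observed ≈ 29.8 kb
recovered against 30 kb truth); at a 3 kb tract it grows to ~8%. The
direction is always downward — estimates never exceed truth beyond
sampling noise.

**Titration.** The benchmark sweep runs 50 coverages (0.2X–10X in 0.2X
steps) × 5 replicates = 250 runs, each with an independent seed derived
from the master seed via `SeedSequence([master_seed, run_index])`,
estimating with k = 7, the 48–52% band, n_ends = 2 and L_gc profiled from
the simulated genome itself. The 5 Mb core keeps the full titration at
about one minute on one CPU while leaving per-run GC-band counts in the
thousands even at 0.2X; the estimator is scale-free in genome length once
L_gc is matched, so the core size affects only the (negligible) GC-band
counting noise. A run whose GC band happens to hold no reads is recorded
as missing, never as zero. Estimate variability across runs is dominated
by Poisson-like noise in *t<sub>k</sub>* (mean ≈ 600 × coverage reads),
roughly doubled because telomeric reads arrive in correlated mate pairs;
variance therefore scales as 1/coverage, which is what the low- versus
high-coverage F-test quantifies.

## Numerical and degenerate-input choices

- Estimates with an empty GC band raise a dedicated error in the API and
  print `NA` in reports — never a silent 0 or infinity.
- All histogram counts are int64; bin assignment is integer-exact.
- Simulation is chunked (65 536 pairs per batch) with a fixed chunk size,
  so a given seed yields a byte-identical read stream regardless of how
  the output is consumed; FASTQ/SAM emission and in-memory tallying share
  one generator.
- Zero-length reads are skipped with a warning; merging tallies with
  mismatched histogram geometry is an error.

## Limitations

- Interstitial telomere-like repeats inflate estimates on real genomes;
  no correction is applied.
- The per-end mean assumes all ends equivalent (no per-chromosome or
  allele-specific resolution) and `n_ends` must match the ploidy
  convention of L_gc (46 with a haploid human reference).
- The simulator's uniform-substitution error model and bias-free sampling
  make its recovery results a necessary, not sufficient, condition for
  accuracy on real libraries.
- CRAM input and base-quality-aware filtering are out of scope.
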