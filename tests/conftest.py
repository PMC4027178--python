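import numpy as np
import pytest

from telolen.tally import ReadGroupTally, SequenceRead, tally_read


def random_dna(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(20140307)


@pytest.fixture
def small_tally():
    """A tally of a handful of hand-constructed reads."""
    t = ReadGroupTally(read_group="L1")
    reads = [
        SequenceRead("tel1", "TTAGGG" * 16, "L1"),
        SequenceRead("tel2", "CCCTAA" * 16, "L1"),
        SequenceRead("at", "AT" * 50, "L1"),
        SequenceRead("gc", "GC" * 50, "L1"),
        SequenceRead("mixed", "ACGT" * 25, "L1"),
    ]
    for r in reads:
        tally_read(t, r)
    return t


def make_sam(path, records, read_groups=("L1",)):
    """Write a minimal SAM file with unmapped records.

    records: iterable of (name, bases, flag, rg) tuples.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for rg in read_groups:
            fh.write(f"@RG\tID:{rg}\tSM:test\n")
        for name, bases, flag, rg in records:
            qual = "I" * len(bases) if bases else "*"
            seq = bases if bases else "*"
            tag = f"\tRG:Z:{rg}" if rg else ""
            fh.write(f"{name}\t{flag}\t*\t0\t0\t*\t*\t0\t0\t{seq}\t{qual}{tag}\n")
    return path
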