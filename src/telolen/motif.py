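"""Sequence-level primitives for telomere repeat analysis.

The human telomere is a tandem array of the hexamer TTAGGG (reverse
complement CCCTAA).  Everything in this module is a pure function on
strings: motif occurrence counting, GC fraction, and enumeration of the
control hexamers (permutations of TTAGGG that are not cyclic rotations of
it) used to characterise the background repeat spectrum.

Conventions fixed here and relied on throughout the package:

* occurrences are counted non-overlapping, left to right.  TTAGGG and
  CCCTAA cannot overlap themselves, so for the telomere motifs this is
  identical to counting every match position;
* ``N`` never matches a motif but does count toward sequence length in
  the GC fraction denominator;
* lowercase input is accepted and uppercased on entry.
"""

from __future__ import annotations

from itertools import permutations

__all__ = [
    "TELOMERE_MOTIF",
    "TELOMERE_MOTIF_RC",
    "reverse_complement",
    "count_occurrences",
    "telomere_repeat_count",
    "gc_fraction",
    "control_hexamers",
]

#: Canonical human telomere repeat unit (reference / G-strand).
TELOMERE_MOTIF = "TTAGGG"
#: Reverse complement of the telomere repeat (C-strand).
TELOMERE_MOTIF_RC = "CCCTAA"

HEXAMER_LENGTH = 6

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANTGCAN")
_MOTIF_ALPHABET = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (uppercased; N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1].upper()


def _validated_motif(motif: str) -> str:
    m = motif.upper()
    if len(m) != HEXAMER_LENGTH:
        raise ValueError(
            f"motif must be exactly {HEXAMER_LENGTH} bases, got {len(m)!r}"
        )
    if not set(m) <= _MOTIF_ALPHABET:
        raise ValueError(f"motif must be over A/C/G/T, got {motif!r}")
    return m


def count_occurrences(seq: str, motif: str) -> int:
    """Count non-overlapping occurrences of ``motif`` in ``seq``.

    Matching is case-insensitive and left-to-right greedy; characters are
    never reused between matches.  Positions containing ``N`` never match
    (the motif alphabet excludes N).
    """
    m = _validated_motif(motif)
    return seq.upper().count(m)


def telomere_repeat_count(seq: str) -> int:
    """Strand-symmetric telomere repeat count of a read.

    Returns ``max(count(TTAGGG), count(CCCTAA))``.  A genuinely telomeric
    read carries repeats of essentially one strand, so the maximum tracks
    the true repeat load while staying invariant under reverse
    complementation of the read.
    """
    s = seq.upper()
    return max(s.count(TELOMERE_MOTIF), s.count(TELOMERE_MOTIF_RC))


def gc_fraction(seq: str) -> float:
    """Fraction of G+C bases; N counts in the denominator only.

    Raises ``ValueError`` on an empty sequence (the fraction is undefined).
    """
    if not seq:
        raise ValueError("gc_fraction is undefined for an empty sequence")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def gc_count(seq: str) -> int:
    """Number of G+C bases (integer numerator of :func:`gc_fraction`)."""
    s = seq.upper()
    return s.count("G") + s.count("C")


def control_hexamers() -> frozenset[str]:
    """All permutations of the letters of TTAGGG that are not cyclic
    rotations of TTAGGG.

    The letter multiset {T,T,A,G,G,G} has 6!/(2!*3!) = 60 distinct
    arrangements; the 6 cyclic rotations of TTAGGG match the same tandem
    repeat and are excluded, leaving 54 control motifs.  These share the
    exact base composition (50% GC) of the telomere motif, making them
    the natural negative controls for the read repeat spectrum.
    """
    rotations = {
        TELOMERE_MOTIF[i:] + TELOMERE_MOTIF[:i] for i in range(HEXAMER_LENGTH)
    }
    return frozenset("".join(p) for p in permutations(TELOMERE_MOTIF)) - frozenset(
        rotations
    )
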