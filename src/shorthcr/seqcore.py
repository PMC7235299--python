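"""Nucleotide sequence primitives.

All sequences are plain Python strings over the DNA alphabet {A, C, G, T},
read 5'->3'.  RNA input is accepted (U is mapped to T on normalization)
because probes hybridize mRNA targets but every designed oligo is DNA.
IUPAC ambiguity codes are rejected: a designed oligo must be concrete.
Coordinates are 0-based, half-open, on the sense strand throughout the
package.
"""

from __future__ import annotations

__all__ = [
    "AlphabetError",
    "EmptySequenceError",
    "normalize",
    "reverse_complement",
    "gc_fraction",
    "gc_imbalance",
    "max_complementary_run",
    "longest_homopolymer",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


class AlphabetError(ValueError):
    """Sequence contains a character outside {A, C, G, T} after normalization."""


class EmptySequenceError(ValueError):
    """Operation requires a non-empty sequence."""


def normalize(seq: str) -> str:
    """Uppercase, strip whitespace, map U->T, and validate the alphabet.

    Raises
    ------
    AlphabetError
        If any character other than A/C/G/T/U remains after cleanup.
    """
    s = "".join(seq.split()).upper().replace("U", "T")
    bad = set(s) - _VALID
    if bad:
        raise AlphabetError(
            f"invalid nucleotide(s) {sorted(bad)!r}; only A/C/G/T (or U) allowed"
        )
    return s


def _require_nonempty(s: str) -> str:
    s = normalize(s)
    if not s:
        raise EmptySequenceError("empty sequence")
    return s


def reverse_complement(s: str) -> str:
    """Watson-Crick reverse complement, 5'->3'."""
    s = _require_nonempty(s)
    return s.translate(_COMPLEMENT)[::-1]


def gc_fraction(s: str) -> float:
    """Fraction of G+C bases, in [0, 1]."""
    s = _require_nonempty(s)
    return (s.count("G") + s.count("C")) / len(s)


def gc_imbalance(s: str) -> int:
    """Absolute difference between the G and C counts, |#G - #C|.

    For a hairpin stem strand this is the quantity whose magnitude
    predicts initiator-independent HCR leakage: stems with a similar
    number of G and C leak, stems with an imbalance of 4-5 are stable.
    """
    s = _require_nonempty(s)
    return abs(s.count("G") - s.count("C"))


def longest_homopolymer(s: str) -> int:
    """Length of the longest run of a single base."""
    s = _require_nonempty(s)
    best = run = 1
    for a, b in zip(s, s[1:]):
        run = run + 1 if a == b else 1
        if run > best:
            best = run
    return best


def max_complementary_run(s1: str, s2: str) -> int:
    """Longest contiguous substring of ``s1`` whose reverse complement occurs in ``s2``.

    Equivalent to the longest common substring of reverse_complement(s1)
    and s2, computed by dynamic programming.  Used for orthogonality and
    off-target screens in place of a full homology search.
    """
    a = reverse_complement(s1)
    b = _require_nonempty(s2)
    # classic O(len(a)*len(b)) LCS-substring DP, one rolling row
    prev = [0] * (len(b) + 1)
    best = 0
    for ca in a:
        cur = [0] * (len(b) + 1)
        for j, cb in enumerate(b, start=1):
            if ca == cb:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best
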