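"""Nucleotide-alphabet utilities shared across the package.

Internally everything is carried in an upper-case DNA alphabet (U is folded
into T on input); miRNA sequences are presented back to the user in RNA.
"""

from __future__ import annotations

from Bio import Align

DNA_BASES = "ACGT"
_COMPLEMENT_DNA = str.maketrans("ACGTN", "TGCAN")

__all__ = [
    "normalize_dna",
    "normalize_rna",
    "complement_base",
    "reverse_complement",
    "mature_sequence_differences",
    "AlphabetError",
]


class AlphabetError(ValueError):
    """Raised when a sequence contains characters outside {A, C, G, T/U, N}."""


def _validate(seq: str) -> None:
    bad = set(seq) - set("ACGTN")
    if bad:
        raise AlphabetError(f"invalid nucleotide characters: {sorted(bad)!r}")


def normalize_dna(seq: str) -> str:
    """Upper-case, fold U into T, and validate the alphabet."""
    s = seq.upper().replace("U", "T")
    _validate(s)
    return s


def normalize_rna(seq: str) -> str:
    """Upper-case, fold T into U, and validate the alphabet."""
    s = normalize_dna(seq)
    return s.replace("T", "U")


def complement_base(base: str, alphabet: str = "DNA") -> str:
    """Watson-Crick complement of a single base, in DNA or RNA output."""
    if len(base) != 1:
        raise ValueError("complement_base expects a single base")
    b = normalize_dna(base).translate(_COMPLEMENT_DNA)
    return b.replace("T", "U") if alphabet == "RNA" else b


def reverse_complement(seq: str, output_alphabet: str = "DNA") -> str:
    """Reverse complement with U/T treated as equivalent on input.

    output_alphabet selects whether the result is written with T (DNA)
    or U (RNA).
    """
    if output_alphabet not in ("DNA", "RNA"):
        raise ValueError("output_alphabet must be 'DNA' or 'RNA'")
    rc = normalize_dna(seq).translate(_COMPLEMENT_DNA)[::-1]
    return rc.replace("T", "U") if output_alphabet == "RNA" else rc


def mature_sequence_differences(seq_a: str, seq_b: str) -> int:
    """Number of nucleotide differences between two mature miRNA sequences.

    Computed as the global-alignment edit distance (unit costs), so
    orthologues of unequal length -- e.g. a 3'-end extension -- are compared
    sensibly rather than truncated.
    """
    a, b = normalize_dna(seq_a), normalize_dna(seq_b)
    if a == b:
        return 0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 0
    aligner.mismatch_score = -1
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return int(-aligner.score(a, b))
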