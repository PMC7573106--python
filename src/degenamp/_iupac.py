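"""IUPAC nucleotide ambiguity-code tables (DNA only)."""

from __future__ import annotations

# Code -> sorted tuple of concrete bases (A < C < G < T).
IUPAC_SETS: dict[str, tuple[str, ...]] = {
    "A": ("A",),
    "C": ("C",),
    "G": ("G",),
    "T": ("T",),
    "R": ("A", "G"),
    "Y": ("C", "T"),
    "S": ("C", "G"),
    "W": ("A", "T"),
    "K": ("G", "T"),
    "M": ("A", "C"),
    "B": ("C", "G", "T"),
    "D": ("A", "G", "T"),
    "H": ("A", "C", "T"),
    "V": ("A", "C", "G"),
    "N": ("A", "C", "G", "T"),
}

IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
    "S": "S", "W": "W", "N": "N",
}

BASE_ORDER = "ACGT"


class InvalidAlphabetError(ValueError):
    """A sequence contains a character outside the IUPAC DNA alphabet."""


def validate_iupac(sequence: str) -> str:
    """Uppercase and validate an IUPAC DNA string.

    Raises :class:`InvalidAlphabetError` naming the first offending
    1-based position.  ``U`` is rejected (DNA only).
    """
    seq = sequence.upper()
    for i, ch in enumerate(seq):
        if ch not in IUPAC_SETS:
            raise InvalidAlphabetError(
                f"invalid IUPAC character {ch!r} at position {i + 1}"
            )
    return seq


def reverse_complement(sequence: str) -> str:
    """Reverse complement of an IUPAC string, code-level (R<->Y etc.)."""
    seq = validate_iupac(sequence)
    return "".join(IUPAC_COMPLEMENT[ch] for ch in reversed(seq))
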