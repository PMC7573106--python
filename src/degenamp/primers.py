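"""Degenerate-primer algebra.

A degenerate PCR primer is written with IUPAC ambiguity codes and stands
for a mixture of concrete oligonucleotides ("variants").  Its degeneracy
is the number of variants, i.e. the product over positions of each
code's base-set size.  Variant enumeration is deterministic (per
position A < C < G < T, rightmost position varying fastest) so variant
identifiers are stable across runs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.SeqUtils import MeltingTemp as _mt

from ._iupac import (
    BASE_ORDER,
    IUPAC_SETS,
    InvalidAlphabetError,
    reverse_complement,
    validate_iupac,
)

__all__ = [
    "DegeneratePrimer",
    "OligoVariant",
    "ThermoParams",
    "degeneracy",
    "expand",
    "reverse_complement",
    "melting_range",
    "InvalidAlphabetError",
    "read_primer_fasta",
    "write_variant_fasta",
]


@dataclass(frozen=True)
class DegeneratePrimer:
    """An IUPAC-encoded primer, written 5'->3'."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = validate_iupac(self.sequence)
        if len(seq) < 1:
            raise ValueError("primer sequence must be non-empty")
        object.__setattr__(self, "sequence", seq)

    @property
    def degeneracy(self) -> int:
        return degeneracy(self)

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "DegeneratePrimer":
        return DegeneratePrimer(
            name=f"{self.name}-rc", sequence=reverse_complement(self.sequence)
        )


@dataclass(frozen=True)
class OligoVariant:
    """One concrete A/C/G/T oligo from a degenerate primer's mixture."""

    parent: str
    index: int  # 1-based ordinal in the deterministic enumeration
    sequence: str

    @property
    def id(self) -> str:
        return f"{self.parent}-{self.index:02d}"


def _as_primer(primer: "DegeneratePrimer | str") -> DegeneratePrimer:
    if isinstance(primer, DegeneratePrimer):
        return primer
    return DegeneratePrimer(name="primer", sequence=primer)


def degeneracy(primer: "DegeneratePrimer | str") -> int:
    """Number of concrete variants the primer encodes."""
    p = _as_primer(primer)
    return math.prod(len(IUPAC_SETS[ch]) for ch in p.sequence)


def expand(primer: "DegeneratePrimer | str") -> list[OligoVariant]:
    """Enumerate all concrete variants in deterministic order.

    Per-position alternatives are ordered A < C < G < T and the
    rightmost position varies fastest; ids are assigned in that order.
    """
    p = _as_primer(primer)
    sets = [IUPAC_SETS[ch] for ch in p.sequence]
    return [
        OligoVariant(parent=p.name, index=i, sequence="".join(combo))
        for i, combo in enumerate(itertools.product(*sets), start=1)
    ]


def variant_index(primer: "DegeneratePrimer | str", concrete: str) -> int:
    """1-based enumeration index of a concrete sequence within the primer.

    Mixed-radix positional computation; raises ``ValueError`` if the
    concrete sequence is not contained in the primer's IUPAC sets.
    """
    p = _as_primer(primer)
    if len(concrete) != len(p.sequence):
        raise ValueError("length mismatch")
    idx = 0
    for code, base in zip(p.sequence, concrete):
        options = IUPAC_SETS[code]
        try:
            digit = options.index(base)
        except ValueError:
            raise ValueError(
                f"base {base!r} not allowed by code {code!r}"
            ) from None
        idx = idx * len(options) + digit
    return idx + 1


@dataclass(frozen=True)
class ThermoParams:
    """Nearest-neighbor melting-temperature settings.

    Uses the unified SantaLucia (2004) DNA/DNA parameter set with a
    sodium-concentration entropy correction.  The defaults (50 mM Na+,
    250 nM oligo) are ordinary PCR-adjacent conditions; predicted Tm is
    model-dependent and should be read as a relative, not absolute,
    quantity.
    """

    na_mM: float = 50.0
    oligo_nM: float = 250.0
    min_length: int = 8


def melting_range(
    primer: "DegeneratePrimer | str",
    thermo: ThermoParams | None = None,
) -> tuple[float, float]:
    """(min, max) nearest-neighbor Tm over the primer's variants, in C."""
    p = _as_primer(primer)
    thermo = thermo or ThermoParams()
    if len(p.sequence) < thermo.min_length:
        raise ValueError(
            f"primer length {len(p.sequence)} below model minimum "
            f"{thermo.min_length}"
        )
    tms = [
        _mt.Tm_NN(
            v.sequence,
            nn_table=_mt.DNA_NN4,
            Na=thermo.na_mM,
            dnac1=thermo.oligo_nM,
            dnac2=0,
            saltcorr=5,
        )
        for v in expand(p)
    ]
    return (min(tms), max(tms))


def read_primer_fasta(path) -> list[DegeneratePrimer]:
    """Read primers from a FASTA whose headers are primer names."""
    from Bio import SeqIO

    return [
        DegeneratePrimer(name=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_variant_fasta(primer: "DegeneratePrimer | str", path) -> None:
    """Write the expanded variants as FASTA with ids ``<parent>-NN``."""
    p = _as_primer(primer)
    with open(path, "w") as fh:
        for v in expand(p):
            fh.write(f">{v.id}\n{v.sequence}\n")
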