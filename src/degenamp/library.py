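"""Taxonomy-annotated sequence libraries.

A :class:`ReferenceLibrary` holds nucleotide records with an optional
seven-rank lineage (domain..species) and a role describing where the
record came from: a curated reference gene, a paralog decoy, a Sanger
clone, or a high-throughput amplicon.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Iterator

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
ROLES = ("reference_gene", "paralog", "clone", "amplicon")

_NT_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class TargetSequence:
    id: str
    sequence: str
    lineage: tuple[str, ...] = ()
    role: str = "reference_gene"

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(seq) - _NT_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid characters {sorted(bad)}"
            )
        if self.role not in ROLES:
            raise ValueError(f"record {self.id!r}: unknown role {self.role!r}")
        if self.lineage and len(self.lineage) != len(RANKS):
            raise ValueError(
                f"record {self.id!r}: lineage must have {len(RANKS)} ranks"
            )
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "lineage", tuple(self.lineage))


class ReferenceLibrary:
    """An ordered collection of :class:`TargetSequence` with unique ids."""

    def __init__(self, records: Iterable[TargetSequence] = ()):
        self._records: dict[str, TargetSequence] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: TargetSequence) -> None:
        if rec.id in self._records:
            raise ValueError(f"duplicate record id {rec.id!r}")
        self._records[rec.id] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[TargetSequence]:
        return iter(self._records.values())

    def __getitem__(self, rec_id: str) -> TargetSequence:
        return self._records[rec_id]

    def __contains__(self, rec_id: str) -> bool:
        return rec_id in self._records

    @property
    def ids(self) -> list[str]:
        return list(self._records)

    def subset_role(self, role: str) -> "ReferenceLibrary":
        return ReferenceLibrary(r for r in self if r.role == role)

    # ------------------------------------------------------------------ IO

    @classmethod
    def from_fasta(
        cls,
        fasta_path,
        taxonomy_csv=None,
        role: str = "reference_gene",
    ) -> "ReferenceLibrary":
        """Load records from FASTA plus an optional taxonomy CSV.

        The CSV must have columns ``id, domain, phylum, class, order,
        family, genus, species``; missing ranks are empty strings.
        """
        from Bio import SeqIO

        taxonomy = read_taxonomy_csv(taxonomy_csv) if taxonomy_csv else {}
        lib = cls()
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            lib.add(
                TargetSequence(
                    id=rec.id,
                    sequence=str(rec.seq),
                    lineage=taxonomy.get(rec.id, ()),
                    role=role,
                )
            )
        return lib

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for rec in self:
                fh.write(f">{rec.id}\n{rec.sequence}\n")

    def taxonomy(self) -> dict[str, tuple[str, ...]]:
        return {r.id: r.lineage for r in self if r.lineage}

    def write_taxonomy_csv(self, path) -> None:
        write_taxonomy_csv(self.taxonomy(), path)


def read_taxonomy_csv(path) -> dict[str, tuple[str, ...]]:
    taxonomy: dict[str, tuple[str, ...]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = {"id", *RANKS} - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"taxonomy CSV missing columns: {sorted(missing)}")
        for row in reader:
            taxonomy[row["id"]] = tuple(row[r].strip() for r in RANKS)
    return taxonomy


def write_taxonomy_csv(taxonomy: dict[str, tuple[str, ...]], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(("id",) + RANKS)
        for rec_id, lineage in taxonomy.items():
            row = list(lineage) + [""] * (len(RANKS) - len(lineage))
            writer.writerow([rec_id] + row)
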