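"""Mismatch-constrained in-silico PCR and primer audit statistics.

The matcher scans every window of a template for the primer (or, in
reverse orientation, its reverse complement), counting a position as a
match iff the template base is contained in the primer position's IUPAC
set.  Mismatches falling within a protected window at the primer's 3'
end disqualify the site outright, reflecting the disproportionate
effect of 3'-proximal mismatches on polymerase extension.

On top of the matcher sit the audit statistics used to judge a
degenerate primer against a reference gene library:

* efficiency - fraction of reference genes with at least one site;
* specificity - fraction of paralog decoys hit at each mismatch level;
* redundancy - variants of the mixture that exactly match nothing;
* per-variant occurrence - which variants actually appear in observed
  clone/amplicon sequences, against the 100/degeneracy equal-use line;
* rule-driven degeneracy reduction and equimolar subset selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._iupac import IUPAC_SETS, reverse_complement, validate_iupac
from ._util import round_half_up
from .library import ReferenceLibrary, TargetSequence
from .primers import DegeneratePrimer, degeneracy, expand, variant_index

__all__ = [
    "MatchPolicy",
    "BindingSite",
    "Amplicon",
    "find_binding_sites",
    "efficiency",
    "specificity_screen",
    "redundancy",
    "occurrence_tally",
    "equal_distribution_threshold",
    "conservation_profile",
    "apply_edits",
    "reduce_degeneracy",
    "select_equimolar_subset",
    "predict_amplicons",
    "primer_audit",
    "AuditReport",
]

_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_N_BIT = 16


@dataclass(frozen=True)
class MatchPolicy:
    """Mismatch tolerance for primer-template matching.

    ``protected_3prime_len`` bases at the primer 3' end (terminal base
    included) admit no mismatch at all.  ``n_policy`` controls how a
    template 'N' scores: ``"primer_n_only"`` (default) counts it as a
    mismatch unless the primer position is N; ``"always_match"`` lets it
    match any primer position.
    """

    max_mismatches: int = 2
    protected_3prime_len: int = 5
    n_policy: str = "primer_n_only"

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if self.n_policy not in ("primer_n_only", "always_match"):
            raise ValueError(f"unknown n_policy {self.n_policy!r}")


EXACT_POLICY = MatchPolicy(max_mismatches=0, protected_3prime_len=0)


@dataclass(frozen=True)
class BindingSite:
    """A located primer footprint on a template's sense strand.

    ``start``/``end`` are 0-based half-open sense-strand coordinates.
    ``mismatch_offsets`` are distances from the primer's 3' end
    (0 = terminal base).
    """

    target_id: str
    strand: str
    start: int
    end: int
    mismatch_count: int
    mismatch_offsets: tuple[int, ...]
    best_variant_id: str


@dataclass(frozen=True)
class Amplicon:
    start: int
    end: int
    length: int
    sequence: str
    forward_site: BindingSite
    reverse_site: BindingSite


def _encode_target(seq: str, n_policy: str) -> np.ndarray:
    table = np.zeros(256, dtype=np.uint8)
    for base, bit in _BASE_BIT.items():
        table[ord(base)] = bit
    table[ord("N")] = 31 if n_policy == "always_match" else _N_BIT
    codes = table[np.frombuffer(seq.encode(), dtype=np.uint8)]
    return codes


def _primer_masks(pattern: str) -> np.ndarray:
    masks = np.empty(len(pattern), dtype=np.uint8)
    for j, code in enumerate(pattern):
        bits = 0
        for base in IUPAC_SETS[code]:
            bits |= _BASE_BIT[base]
        if code == "N":
            bits |= _N_BIT
        masks[j] = bits
    return masks


def find_binding_sites(
    primer: DegeneratePrimer | str,
    target: TargetSequence,
    policy: MatchPolicy = MatchPolicy(),
    orientation: str = "forward",
) -> list[BindingSite]:
    """All windows of ``target`` the primer may bind under ``policy``.

    In reverse orientation the primer is matched as its reverse
    complement against the sense strand; 3'-protection then applies at
    the left end of the footprint (where the primer's 3' terminus sits).
    Sites are sorted by start coordinate.
    """
    pseq = primer.sequence if isinstance(primer, DegeneratePrimer) else validate_iupac(primer)
    if orientation == "forward":
        pattern, strand = pseq, "+"
    elif orientation == "reverse":
        pattern, strand = reverse_complement(pseq), "-"
    else:
        raise ValueError(f"unknown orientation {orientation!r}")

    k = len(pattern)
    tseq = target.sequence
    if k > len(tseq):
        return []
    protected = policy.protected_3prime_len
    if protected > k:
        raise ValueError("protected_3prime_len exceeds primer length")

    codes = _encode_target(tseq, policy.n_policy)
    masks = _primer_masks(pattern)
    W = len(tseq) - k + 1
    counts = np.zeros(W, dtype=np.int32)
    viol = np.zeros(W, dtype=bool)
    for j in range(k):
        mm = (codes[j : j + W] & masks[j]) == 0
        counts += mm
        offset3 = (k - 1 - j) if strand == "+" else j
        if offset3 < protected:
            viol |= mm
    hits = np.nonzero((counts <= policy.max_mismatches) & ~viol)[0]

    sites = []
    for start in hits.tolist():
        window = tseq[start : start + k]
        offsets = []
        for j, (code, base) in enumerate(zip(pattern, window)):
            matched = base in IUPAC_SETS[code] or (
                base == "N"
                and (code == "N" or policy.n_policy == "always_match")
            )
            if not matched:
                offsets.append((k - 1 - j) if strand == "+" else j)
        sites.append(
            BindingSite(
                target_id=target.id,
                strand=strand,
                start=start,
                end=start + k,
                mismatch_count=len(offsets),
                mismatch_offsets=tuple(sorted(offsets)),
                best_variant_id=_best_variant_id(primer, pseq, window, strand),
            )
        )
    return sites


def _best_variant_id(
    primer: DegeneratePrimer | str, pseq: str, window: str, strand: str
) -> str:
    """Id of the concrete variant closest to the observed footprint."""
    observed = window if strand == "+" else reverse_complement(window)
    concrete = []
    for code, base in zip(pseq, observed):
        options = IUPAC_SETS[code]
        concrete.append(base if base in options else options[0])
    name = primer.name if isinstance(primer, DegeneratePrimer) else "primer"
    idx = variant_index(pseq, "".join(concrete))
    return f"{name}-{idx:02d}"


# --------------------------------------------------------------------------
# Audit statistics


@dataclass
class EfficiencyResult:
    fraction: float
    n_matched: int
    n_total: int
    per_clade: dict[str, float]


def efficiency(
    primer: DegeneratePrimer | str,
    library: ReferenceLibrary | Iterable[TargetSequence],
    policy: MatchPolicy = MatchPolicy(),
    rank_index: int = 1,
) -> EfficiencyResult:
    """Fraction of reference-gene records with >= 1 binding site.

    Both orientations are searched (the footprint may sit on either
    strand of a deposited gene record).  ``rank_index`` selects the
    lineage rank (default phylum) for the per-clade breakdown.
    """
    records = [r for r in library if r.role == "reference_gene"]
    if not records:
        raise ValueError("empty reference library")
    clade_hits: dict[str, list[int]] = {}
    n_matched = 0
    for rec in records:
        hit = bool(
            find_binding_sites(primer, rec, policy, "forward")
            or find_binding_sites(primer, rec, policy, "reverse")
        )
        n_matched += hit
        if rec.lineage:
            clade = rec.lineage[rank_index]
            clade_hits.setdefault(clade, []).append(hit)
    per_clade = {
        clade: sum(hits) / len(hits) for clade, hits in sorted(clade_hits.items())
    }
    return EfficiencyResult(
        fraction=n_matched / len(records),
        n_matched=n_matched,
        n_total=len(records),
        per_clade=per_clade,
    )


@dataclass
class SpecificityResult:
    """Paralogs hit at each mismatch level 0..max_mismatches."""

    counts: dict[int, int]
    fractions: dict[int, float]
    n_total: int


def specificity_screen(
    primer: DegeneratePrimer | str,
    paralogs: ReferenceLibrary | Iterable[TargetSequence],
    policy: MatchPolicy = MatchPolicy(),
) -> SpecificityResult:
    """How many paralog decoys the primer would bind, per mismatch level."""
    records = [r for r in paralogs if r.role == "paralog"]
    if not records:
        raise ValueError("empty paralog set")
    counts: dict[int, int] = {}
    for level in range(policy.max_mismatches + 1):
        level_policy = MatchPolicy(
            max_mismatches=level,
            protected_3prime_len=policy.protected_3prime_len,
            n_policy=policy.n_policy,
        )
        n = sum(
            bool(
                find_binding_sites(primer, rec, level_policy, "forward")
                or find_binding_sites(primer, rec, level_policy, "reverse")
            )
            for rec in records
        )
        counts[level] = n
    fractions = {lvl: n / len(records) for lvl, n in counts.items()}
    return SpecificityResult(counts=counts, fractions=fractions, n_total=len(records))


def _library_kmers(library: Iterable[TargetSequence], k: int) -> set[str]:
    kmers: set[str] = set()
    for rec in library:
        seq = rec.sequence
        rc = reverse_complement(seq.replace("N", "N"))
        for s in (seq, rc):
            for i in range(len(s) - k + 1):
                kmers.add(s[i : i + k])
    return kmers


@dataclass
class RedundancyResult:
    count: int
    percent: float
    unmatched_variant_ids: list[str]


def redundancy(
    primer: DegeneratePrimer | str,
    library: ReferenceLibrary | Iterable[TargetSequence],
) -> RedundancyResult:
    """Variants of the mixture with zero exact matches in the library.

    Exact matching only (either strand); the percent is reported to one
    decimal, as 100 * count / degeneracy.
    """
    records = list(library)
    if not records:
        raise ValueError("empty library")
    variants = expand(primer)
    k = len(variants[0].sequence)
    kmers = _library_kmers(records, k)
    unmatched = [v for v in variants if v.sequence not in kmers]
    d = len(variants)
    return RedundancyResult(
        count=len(unmatched),
        percent=round_half_up(100.0 * len(unmatched) / d, 1),
        unmatched_variant_ids=[v.id for v in unmatched],
    )


def equal_distribution_threshold(deg: int) -> float:
    """Percent occurrence each variant would have under equal use."""
    if deg < 1:
        raise ValueError("degeneracy must be >= 1")
    return round_half_up(100.0 / deg, 2)


def occurrence_tally(
    primer: DegeneratePrimer | str,
    observed: ReferenceLibrary | Iterable[TargetSequence],
) -> "OccurrenceTable":
    """Exact per-variant footprint counts over observed sequences.

    Each observed sequence contributes at most one footprint (the
    leftmost exact variant match on either strand).  Percents are over
    sequences with a detected footprint; ``below_threshold`` flags
    variants under the 100/degeneracy equal-distribution line.
    """
    variants = expand(primer)
    k = len(variants[0].sequence)
    by_seq: dict[str, int] = {}
    for v in variants:
        by_seq.setdefault(v.sequence, v.index)
        by_seq.setdefault(reverse_complement(v.sequence), v.index)

    counts = {v.index: 0 for v in variants}
    n_with_footprint = 0
    for rec in observed:
        seq = rec.sequence
        found = None
        for i in range(len(seq) - k + 1):
            idx = by_seq.get(seq[i : i + k])
            if idx is not None:
                found = idx
                break
        if found is not None:
            counts[found] += 1
            n_with_footprint += 1

    threshold = equal_distribution_threshold(len(variants))
    rows = []
    for v in variants:
        pct = (
            round_half_up(100.0 * counts[v.index] / n_with_footprint, 2)
            if n_with_footprint
            else 0.0
        )
        rows.append(
            OccurrenceRow(
                variant_id=v.id,
                sequence=v.sequence,
                count=counts[v.index],
                percent=pct,
                below_threshold=pct < threshold,
            )
        )
    return OccurrenceTable(rows=rows, n_with_footprint=n_with_footprint,
                           threshold=threshold)


@dataclass(frozen=True)
class OccurrenceRow:
    variant_id: str
    sequence: str
    count: int
    percent: float
    below_threshold: bool


@dataclass
class OccurrenceTable:
    rows: list[OccurrenceRow]
    n_with_footprint: int
    threshold: float

    def percents(self) -> dict[str, float]:
        return {r.variant_id: r.percent for r in self.rows}

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("variant_id\tsequence\tcount\tpercent\tbelow_threshold\n")
            for r in self.rows:
                fh.write(
                    f"{r.variant_id}\t{r.sequence}\t{r.count}\t"
                    f"{r.percent}\t{str(r.below_threshold).lower()}\n"
                )


def conservation_profile(aligned: Sequence[str]) -> list[dict]:
    """Per-column mean pairwise identity over equal-length sequences.

    Identity of a column is the fraction of unordered sequence pairs
    sharing the same base.  Categories: ``full`` at 100%, ``mid`` in
    [30, 100), ``low`` below 30 (percent scale).
    """
    seqs = [s.upper() for s in aligned]
    if len(seqs) < 2:
        raise ValueError("need >= 2 sequences")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences must have equal lengths")
    n = len(seqs)
    pairs = n * (n - 1) / 2
    profile = []
    for col in range(L):
        bases = [s[col] for s in seqs]
        same = 0
        for b in set(bases):
            c = bases.count(b)
            same += c * (c - 1) / 2
        pct = 100.0 * same / pairs
        category = "full" if pct >= 100.0 else ("mid" if pct >= 30.0 else "low")
        profile.append(
            {"column": col, "mean_pairwise_identity": round_half_up(pct, 1),
             "category": category}
        )
    return profile


@dataclass
class EditReport:
    primer: DegeneratePrimer
    degeneracy_before: int
    degeneracy_after: int


def apply_edits(
    primer: DegeneratePrimer | str, edits: Mapping[int, str]
) -> EditReport:
    """Replace IUPAC codes at 1-based positions (counted from the 5' end)."""
    p = primer if isinstance(primer, DegeneratePrimer) else DegeneratePrimer("primer", primer)
    seq = list(p.sequence)
    for pos, code in edits.items():
        if not 1 <= pos <= len(seq):
            raise ValueError(f"edit position {pos} out of range 1..{len(seq)}")
        code = validate_iupac(code)
        if len(code) != 1:
            raise ValueError("each edit must be a single IUPAC code")
        seq[pos - 1] = code
    edited = DegeneratePrimer(name=p.name, sequence="".join(seq))
    return EditReport(
        primer=edited,
        degeneracy_before=degeneracy(p),
        degeneracy_after=degeneracy(edited),
    )


_SET_TO_CODE = {frozenset(v): k for k, v in IUPAC_SETS.items()}


@dataclass
class ReductionReport:
    primer: DegeneratePrimer
    degeneracy_before: int
    degeneracy_after: int
    removed_variant_ids: list[str]
    base_frequencies: list[dict[str, float]]


def reduce_degeneracy(
    primer: DegeneratePrimer | str,
    library: ReferenceLibrary | Iterable[TargetSequence],
    min_base_freq: float = 0.05,
) -> ReductionReport:
    """Drop mixture members not observed in nature.

    Exact primer footprints are located in the library (either strand);
    at every position the IUPAC set is restricted to bases whose
    frequency among footprints is >= ``min_base_freq``.  A position is
    never emptied: if no base passes, the modal base is kept.
    """
    p = primer if isinstance(primer, DegeneratePrimer) else DegeneratePrimer("primer", primer)
    variants = expand(p)
    k = len(p.sequence)
    by_seq = {}
    for v in variants:
        by_seq.setdefault(v.sequence, v.sequence)
        by_seq.setdefault(reverse_complement(v.sequence), v.sequence)

    footprints = []
    for rec in library:
        seq = rec.sequence
        for i in range(len(seq) - k + 1):
            hit = by_seq.get(seq[i : i + k])
            if hit is not None:
                footprints.append(hit)
                break
    if not footprints:
        raise ValueError("no primer footprints found in library")

    new_codes = []
    freqs_out = []
    n = len(footprints)
    for pos, code in enumerate(p.sequence):
        options = IUPAC_SETS[code]
        freqs = {b: sum(f[pos] == b for f in footprints) / n for b in options}
        keep = frozenset(b for b in options if freqs[b] >= min_base_freq)
        if not keep:
            keep = frozenset([max(options, key=lambda b: (freqs[b], -options.index(b)))])
        new_codes.append(_SET_TO_CODE[keep])
        freqs_out.append(freqs)

    reduced = DegeneratePrimer(name=p.name, sequence="".join(new_codes))
    kept_seqs = {v.sequence for v in expand(reduced)}
    removed = [v.id for v in variants if v.sequence not in kept_seqs]
    return ReductionReport(
        primer=reduced,
        degeneracy_before=degeneracy(p),
        degeneracy_after=degeneracy(reduced),
        removed_variant_ids=removed,
        base_frequencies=freqs_out,
    )


@dataclass
class SubsetResult:
    kept_variant_ids: list[str]
    dropped_variant_ids: list[str]
    count: int


def select_equimolar_subset(
    primer: DegeneratePrimer | str,
    occurrence_tables: Sequence[Mapping[str, float]],
    floor: float,
) -> SubsetResult:
    """Drop variants underrepresented in *every* occurrence table.

    ``occurrence_tables`` map variant id -> percent occurrence (e.g.
    over references, clones, and amplicons); a variant is removed from
    the equimolar mixture only if its percent is below ``floor`` in all
    provided tables.
    """
    variants = expand(primer)
    ids = [v.id for v in variants]
    if not occurrence_tables:
        raise ValueError("need at least one occurrence table")
    for t in occurrence_tables:
        missing = set(ids) - set(t)
        if missing:
            raise ValueError(f"occurrence table missing variants: {sorted(missing)}")
    dropped = [
        vid for vid in ids if all(t[vid] < floor for t in occurrence_tables)
    ]
    kept = [vid for vid in ids if vid not in set(dropped)]
    return SubsetResult(kept_variant_ids=kept, dropped_variant_ids=dropped,
                        count=len(kept))


def predict_amplicons(
    fwd_primer: DegeneratePrimer | str,
    rev_primer: DegeneratePrimer | str,
    target: TargetSequence,
    policy: MatchPolicy = MatchPolicy(),
    size_range: tuple[int, int] = (200, 2000),
) -> list[Amplicon]:
    """Pair forward sites with downstream reverse sites into products."""
    fwd_sites = find_binding_sites(fwd_primer, target, policy, "forward")
    rev_sites = find_binding_sites(rev_primer, target, policy, "reverse")
    lo, hi = size_range
    products = []
    for f in fwd_sites:
        for r in rev_sites:
            if r.start < f.end:
                continue
            length = r.end - f.start
            if lo <= length <= hi:
                products.append(
                    Amplicon(
                        start=f.start,
                        end=r.end,
                        length=length,
                        sequence=target.sequence[f.start : r.end],
                        forward_site=f,
                        reverse_site=r,
                    )
                )
    return products


@dataclass
class AuditReport:
    """Bundle of the audit statistics for one primer vs one library set."""

    primer: DegeneratePrimer
    efficiency: EfficiencyResult | None = None
    specificity: SpecificityResult | None = None
    redundancy: RedundancyResult | None = None
    occurrence: OccurrenceTable | None = None

    def to_dict(self) -> dict:
        out: dict = {
            "primer": {"name": self.primer.name, "sequence": self.primer.sequence,
                       "degeneracy": degeneracy(self.primer)},
        }
        if self.efficiency:
            out["efficiency"] = {
                "fraction": self.efficiency.fraction,
                "n_matched": self.efficiency.n_matched,
                "n_total": self.efficiency.n_total,
                "per_clade": self.efficiency.per_clade,
            }
        if self.specificity:
            out["specificity"] = {
                "counts": self.specificity.counts,
                "fractions": self.specificity.fractions,
                "n_total": self.specificity.n_total,
            }
        if self.redundancy:
            out["redundancy"] = {
                "count": self.redundancy.count,
                "percent": self.redundancy.percent,
            }
        if self.occurrence:
            out["occurrence"] = {
                "threshold": self.occurrence.threshold,
                "n_with_footprint": self.occurrence.n_with_footprint,
                "variants": [r.__dict__ for r in self.occurrence.rows],
            }
        return out

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_tsv(self, path) -> None:
        """Flat key/value rendering of the report (stable row order)."""

        def _flatten(prefix, obj, rows):
            if isinstance(obj, dict):
                for key, value in obj.items():
                    _flatten(f"{prefix}.{key}" if prefix else str(key),
                             value, rows)
            elif isinstance(obj, list):
                for i, value in enumerate(obj):
                    _flatten(f"{prefix}[{i}]", value, rows)
            else:
                rows.append((prefix, obj))

        rows: list[tuple[str, object]] = []
        _flatten("", self.to_dict(), rows)
        with open(path, "w") as fh:
            fh.write("key\tvalue\n")
            for key, value in rows:
                fh.write(f"{key}\t{value}\n")


def primer_audit(
    primer: DegeneratePrimer | str,
    reference_library: ReferenceLibrary | None = None,
    paralog_library: ReferenceLibrary | None = None,
    observed: ReferenceLibrary | None = None,
    policy: MatchPolicy = MatchPolicy(),
) -> AuditReport:
    """Run every applicable audit statistic and bundle the results."""
    p = primer if isinstance(primer, DegeneratePrimer) else DegeneratePrimer("primer", primer)
    report = AuditReport(primer=p)
    if reference_library is not None:
        report.efficiency = efficiency(p, reference_library, policy)
        report.redundancy = redundancy(p, reference_library)
    if paralog_library is not None:
        report.specificity = specificity_screen(p, paralog_library, policy)
    if observed is not None:
        report.occurrence = occurrence_tally(p, observed)
    return report
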