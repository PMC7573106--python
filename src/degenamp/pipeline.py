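"""Amplicon read processing: raw reads to an OTU count table.

Stages follow the usual functional-gene amplicon recipe: 5' adaptor /
primer stripping and fixed-length trimming, exact dereplication with
singleton removal, chimera flagging with a two-parent single-crossover
model, greedy centroid clustering at an identity cutoff (nucleotide or
translated-peptide space), and global mapping of reads back onto the
centroids to produce per-sample OTU counts.

Identity is defined as matches / global-alignment columns with end gaps
penalized, so results are reproducible without any particular
clustering tool's word-filter heuristics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import pandas as pd

from ._iupac import IUPAC_SETS

__all__ = [
    "Read",
    "UniqueSeq",
    "OTU",
    "OTUTable",
    "PipelineConfig",
    "PipelineResult",
    "global_identity",
    "trim_and_filter",
    "dereplicate",
    "detect_chimeras",
    "cluster_greedy",
    "map_reads",
    "run_pipeline",
    "read_fastx",
    "write_fastq",
]


@dataclass(frozen=True)
class Read:
    id: str
    sequence: str
    quality: tuple[int, ...] | None = None
    sample: str = "sample1"

    def __post_init__(self) -> None:
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(f"read {self.id!r}: quality/sequence length mismatch")


@dataclass
class UniqueSeq:
    sequence: str
    abundance: int
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.abundance != len(self.members):
            raise ValueError("abundance must equal number of member reads")


@dataclass
class OTU:
    id: str
    centroid: UniqueSeq
    members: list[UniqueSeq] = field(default_factory=list)

    @property
    def abundance(self) -> int:
        return sum(m.abundance for m in self.members)


@dataclass
class OTUTable:
    counts: pd.DataFrame  # rows = OTU ids, columns = samples
    otus: list[OTU]
    unmapped: dict[str, int]

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="otu_id")

    def relative_abundance(self) -> pd.DataFrame:
        return self.counts / self.counts.sum(axis=0)


_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def global_identity(a: str, b: str) -> float:
    """Matches / global-alignment columns, end gaps penalized."""
    if a == b:
        return 1.0
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, task="path", mode="NW")
    cols = sum(int(n) for n, _ in _CIGAR_RE.findall(res["cigar"]))
    return (cols - res["editDistance"]) / cols


# ------------------------------------------------------------------ trimming


def _strip_adaptor(seq: str, adaptors: Sequence[str], search_window: int) -> str:
    for adaptor in adaptors:
        pos = seq.find(adaptor.upper(), 0, search_window + len(adaptor))
        if pos >= 0:
            return seq[pos + len(adaptor) :]
    return seq


def _strip_primer_prefix(seq: str, primer_seq: str, max_mismatches: int = 4) -> str:
    # sequencing errors can hit the primer footprint, so the prefix is
    # stripped on an approximate IUPAC match rather than an exact one
    if len(seq) >= len(primer_seq):
        mismatches = sum(
            b not in IUPAC_SETS[c] for c, b in zip(primer_seq, seq)
        )
        if mismatches <= max_mismatches:
            return seq[len(primer_seq) :]
    return seq


def _quality_truncate(read: Read, min_mean_q: float, window: int) -> str:
    if read.quality is None:
        return read.sequence
    q = read.quality
    for i in range(0, max(1, len(q) - window + 1)):
        if sum(q[i : i + window]) / min(window, len(q) - i) < min_mean_q:
            return read.sequence[:i]
    return read.sequence


def trim_and_filter(
    reads: Iterable[Read],
    target_len: int = 201,
    adaptors: Sequence[str] = (),
    primer=None,
    min_mean_quality: float | None = None,
    quality_window: int = 4,
    adaptor_search_window: int = 5,
) -> list[Read]:
    """Strip 5' adaptor (and primer footprint), truncate to ``target_len``.

    Reads shorter than ``target_len`` after trimming, or truncated by
    the sliding-window quality rule, are discarded rather than padded.
    """
    primer_seq = getattr(primer, "sequence", primer)
    out = []
    for read in reads:
        seq = read.sequence
        if min_mean_quality is not None:
            seq = _quality_truncate(read, min_mean_quality, quality_window)
        if adaptors:
            seq = _strip_adaptor(seq, adaptors, adaptor_search_window)
        if primer_seq:
            seq = _strip_primer_prefix(seq, primer_seq)
        if len(seq) >= target_len:
            out.append(
                Read(id=read.id, sequence=seq[:target_len], quality=None,
                     sample=read.sample)
            )
    return out


# -------------------------------------------------------------- dereplication


def dereplicate(reads: Iterable[Read], min_abundance: int = 2) -> list[UniqueSeq]:
    """Exact-sequence grouping; groups below ``min_abundance`` dropped.

    Output is deterministically ordered by (abundance desc, sequence
    asc).  With the default ``min_abundance=2`` singletons are removed.
    """
    groups: dict[str, list[str]] = {}
    for read in reads:
        groups.setdefault(read.sequence, []).append(read.id)
    uniques = [
        UniqueSeq(sequence=seq, abundance=len(ids), members=tuple(ids))
        for seq, ids in groups.items()
        if len(ids) >= min_abundance
    ]
    uniques.sort(key=lambda u: (-u.abundance, u.sequence))
    return uniques


# ------------------------------------------------------------------ chimeras


def _match_profile(q: str, p: str) -> list[int]:
    return [1 if a == b else 0 for a, b in zip(q, p)]


def detect_chimeras(
    uniques: Sequence[UniqueSeq],
    parents: Sequence[UniqueSeq] | Sequence[str] | None = None,
    mode: str = "denovo",
    min_divergence: float = 0.02,
    model_min: float = 0.98,
    abundance_skew: float = 2.0,
    max_candidate_parents: int = 20,
) -> list[bool]:
    """Flag uniques explainable as a two-parent single crossover.

    A query is flagged iff some crossover of two candidate parents
    attains identity to the query at least ``min_divergence`` above the
    best single parent's identity, and the crossover model itself is at
    least ``model_min`` identical to the query.  In de-novo mode the
    uniques are examined in decreasing abundance and only uniques
    already accepted as non-chimeric, at ``abundance_skew`` times the
    query's abundance, are eligible parents (a chimera arises after its
    parents, so it should be rarer than both).  Sequences must be
    pre-trimmed to one length.
    """
    if mode not in ("denovo", "reference"):
        raise ValueError(f"unknown mode {mode!r}")
    flags = [False] * len(uniques)
    if mode == "reference":
        if not parents:
            raise ValueError("reference mode requires a parent set")
        pool = [getattr(p, "sequence", p) for p in parents]
        for i, q in enumerate(uniques):
            candidates = [
                s for s in pool
                if s != q.sequence and len(s) == len(q.sequence)
            ]
            flags[i] = _is_chimeric(
                q.sequence, candidates, min_divergence, model_min,
                max_candidate_parents,
            )
        return flags

    order = sorted(
        range(len(uniques)),
        key=lambda i: (-uniques[i].abundance, uniques[i].sequence),
    )
    accepted: list[UniqueSeq] = []
    for i in order:
        q = uniques[i]
        candidates = [
            u.sequence
            for u in accepted
            if u.abundance >= abundance_skew * q.abundance
            and len(u.sequence) == len(q.sequence)
        ]
        flags[i] = _is_chimeric(
            q.sequence, candidates, min_divergence, model_min,
            max_candidate_parents,
        )
        if not flags[i]:
            accepted.append(q)
    return flags


def _is_chimeric(
    query: str,
    parents: list[str],
    min_divergence: float,
    model_min: float,
    max_candidates: int,
) -> bool:
    L = len(query)
    if L == 0 or len(parents) < 2:
        return False
    scored = sorted(
        parents, key=lambda p: -sum(_match_profile(query, p))
    )[:max_candidates]
    profiles = [_match_profile(query, p) for p in scored]
    best_single = max(sum(pr) for pr in profiles) / L
    if best_single == 1.0:
        return False

    import numpy as np

    prefix = [np.concatenate([[0], np.cumsum(pr)]) for pr in profiles]
    best_model = 0.0
    for ia in range(len(profiles)):
        for ib in range(len(profiles)):
            if ia == ib:
                continue
            # left part from parent A, right part from parent B
            combined = prefix[ia] + (prefix[ib][-1] - prefix[ib])
            best_model = max(best_model, combined.max() / L)
    return bool(
        best_model >= model_min and best_model >= best_single + min_divergence
    )


# ----------------------------------------------------------------- clustering


def _translate_frame0(seq: str, table: int = 11) -> str:
    from Bio.Seq import Seq

    trimmed = seq[: len(seq) // 3 * 3]
    return str(Seq(trimmed).translate(table=table))


def cluster_greedy(
    uniques: Sequence[UniqueSeq],
    identity: float = 0.90,
    on: str = "nucleotide",
    translation_table: int = 11,
) -> list[OTU]:
    """Greedy centroid clustering in abundance order.

    Uniques are visited sorted by (abundance desc, length desc,
    sequence asc); each joins the first existing centroid at or above
    the identity cutoff, else founds a new OTU.  ``on="peptide"``
    clusters frame-0 translations instead of nucleotides.
    """
    if on not in ("nucleotide", "peptide"):
        raise ValueError(f"unknown clustering space {on!r}")
    ordered = sorted(
        uniques, key=lambda u: (-u.abundance, -len(u.sequence), u.sequence)
    )
    space = {
        u.sequence: (
            u.sequence if on == "nucleotide"
            else _translate_frame0(u.sequence, translation_table)
        )
        for u in ordered
    }
    otus: list[OTU] = []
    for u in ordered:
        placed = False
        for otu in otus:
            if global_identity(space[u.sequence], space[otu.centroid.sequence]) >= identity:
                otu.members.append(u)
                placed = True
                break
        if not placed:
            otus.append(
                OTU(id=f"OTU_{len(otus) + 1:03d}", centroid=u, members=[u])
            )
    return otus


def map_reads(
    reads: Iterable[Read],
    otus: Sequence[OTU],
    identity: float = 0.90,
) -> OTUTable:
    """Assign each read to its highest-identity centroid at the cutoff.

    Ties go to the earlier centroid in OTU order; reads below the
    cutoff to every centroid are tallied per sample as unmapped.
    """
    samples: list[str] = []
    counts: dict[tuple[str, str], int] = {}
    unmapped: dict[str, int] = {}
    cache: dict[str, str | None] = {}
    for read in reads:
        if read.sample not in samples:
            samples.append(read.sample)
            unmapped.setdefault(read.sample, 0)
        assigned = cache.get(read.sequence, "?")
        if assigned == "?":
            best_id, best_ident = None, identity
            for otu in otus:
                ident = global_identity(read.sequence, otu.centroid.sequence)
                if ident > best_ident or (best_id is None and ident >= identity):
                    best_id, best_ident = otu.id, ident
            assigned = best_id
            cache[read.sequence] = assigned
        if assigned is None:
            unmapped[read.sample] += 1
        else:
            counts[(assigned, read.sample)] = counts.get((assigned, read.sample), 0) + 1

    table = pd.DataFrame(
        0, index=[o.id for o in otus], columns=samples, dtype=int
    )
    for (otu_id, sample), n in counts.items():
        table.loc[otu_id, sample] = n
    return OTUTable(counts=table, otus=list(otus), unmapped=unmapped)


# ------------------------------------------------------------------- pipeline


@dataclass
class PipelineConfig:
    """End-to-end settings; the four clustering variants map to
    ``chimera_filter`` on/off crossed with the clustering space."""

    target_len: int = 201
    adaptors: tuple[str, ...] = ()
    primer: object = None
    min_mean_quality: float | None = None
    min_abundance: int = 2
    chimera_filter: bool = True
    chimera_mode: str = "denovo"
    cluster_identity: float = 0.90
    cluster_on: str = "nucleotide"
    map_identity: float = 0.90


@dataclass
class PipelineResult:
    table: OTUTable
    uniques: list[UniqueSeq]
    chimera_flags: list[bool]
    stage_counts: dict[str, int]


def run_pipeline(reads: Sequence[Read], config: PipelineConfig | None = None) -> PipelineResult:
    """Reads -> trimmed -> uniques -> (chimera filter) -> OTUs -> table."""
    config = config or PipelineConfig()
    stage_counts = {"input_reads": len(reads)}
    trimmed = trim_and_filter(
        reads,
        target_len=config.target_len,
        adaptors=config.adaptors,
        primer=config.primer,
        min_mean_quality=config.min_mean_quality,
    )
    stage_counts["trimmed_reads"] = len(trimmed)
    uniques = dereplicate(trimmed, min_abundance=config.min_abundance)
    stage_counts["unique_seqs"] = len(uniques)
    if config.chimera_filter and uniques:
        flags = detect_chimeras(uniques, mode=config.chimera_mode)
        kept = [u for u, f in zip(uniques, flags) if not f]
    else:
        flags = [False] * len(uniques)
        kept = list(uniques)
    stage_counts["non_chimeric"] = len(kept)
    otus = cluster_greedy(
        kept, identity=config.cluster_identity, on=config.cluster_on
    )
    stage_counts["otus"] = len(otus)
    table = map_reads(trimmed, otus, identity=config.map_identity)
    stage_counts["mapped_reads"] = int(table.counts.to_numpy().sum())
    return PipelineResult(
        table=table, uniques=uniques, chimera_flags=flags,
        stage_counts=stage_counts,
    )


# ------------------------------------------------------------------------- IO


def read_fastx(path, sample: str | None = None) -> list[Read]:
    """Read FASTQ or FASTA (gzip allowed) into :class:`Read` objects."""
    import gzip

    from Bio import SeqIO

    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    stem = path[:-3] if path.endswith(".gz") else path
    fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
    sample = sample or "sample1"
    reads = []
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, fmt):
            qual = rec.letter_annotations.get("phred_quality")
            reads.append(
                Read(
                    id=rec.id,
                    sequence=str(rec.seq).upper(),
                    quality=tuple(qual) if qual else None,
                    sample=sample,
                )
            )
    return reads


def write_fastq(reads: Iterable[Read], path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            qual = read.quality or (40,) * len(read.sequence)
            fh.write(
                f"@{read.id}\n{read.sequence}\n+\n"
                + "".join(chr(q + 33) for q in qual)
                + "\n"
            )
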