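"""Synthetic fixtures: reference libraries, paralog decoys, mock runs.

The generators emulate the study conditions every other module is
audited under: a clade-structured reference gene library with planted
forward/reverse primer-binding sites whose variant usage is
controllable, a paralog decoy set carrying the conserved ferredoxin
triple-cysteine motif with near-miss binding sites, and mock-community
amplicon runs with a specified composition, substitution error rate,
chimera rate, and 5' sequencing adaptors.

Every generator is deterministic under (config, seed).  The planted
primer footprints and the start codon of the classified region are
excluded from mutation, and substitutions inside the classified coding
region never create an in-frame stop codon, so error-free simulations
survive the translation filters by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._iupac import IUPAC_SETS, reverse_complement
from .library import RANKS, ReferenceLibrary, TargetSequence
from .pipeline import Read
from .primers import DegeneratePrimer, expand

__all__ = [
    "FORWARD_PRIMER",
    "REVERSE_PRIMER_96",
    "REVERSE_PRIMER_32",
    "ADAPTOR_FWD",
    "ADAPTOR_REV",
    "MOCK_PRESETS",
    "SimulationConfig",
    "make_reference_library",
    "make_paralog_library",
    "simulate_amplicon_run",
    "mock_composition",
]

# The broad-range hgcAB primer set: published forward primer, the
# original 96-fold degenerate reverse primer, and the redesigned
# 32-fold reverse primer.
FORWARD_PRIMER = DegeneratePrimer("uni-F", "AAYGTCTGGTGYGCNGCVGG")
REVERSE_PRIMER_96 = DegeneratePrimer("uni-R", "CABGCNCCRCAYTCCATRCA")
REVERSE_PRIMER_32 = DegeneratePrimer("uni-32R", "CAGGCNCCGCAYTCSATRCA")

# 5' sequencing adaptors prepended to the gene-specific primers.
ADAPTOR_FWD = "TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG"
ADAPTOR_REV = "GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG"

# Mock-community compositions as printed (three spiked methylators,
# percentages of the mix): combo1 = 41/50/9, combo2 = 59/7/35.
MOCK_PRESETS: dict[str, tuple[float, float, float]] = {
    "combo1": (0.41, 0.50, 0.09),
    "combo2": (0.59, 0.07, 0.35),
}

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generators.

    Divergences are per-site substitution probabilities applied outside
    the planted primer footprints.  ``variant_usage`` maps reverse
    primer variant index -> probability (default: uniform over all
    variants); ``composition`` maps reference record id -> read
    proportion for amplicon runs.
    """

    seed: int = 0
    n_clades: int = 3
    taxa_per_clade: int = 4
    within_divergence: float = 0.02
    between_divergence: float = 0.20
    fwd_primer: DegeneratePrimer = FORWARD_PRIMER
    rev_primer: DegeneratePrimer = REVERSE_PRIMER_32
    variant_usage: dict[int, float] | None = None
    fwd_variant_usage: dict[int, float] | None = None
    amplicon_length: int = 950
    coding_length: int = 240
    flank_length: int = 50
    composition: dict[str, float] | None = None
    n_reads: int = 1000
    read_length: int = 300
    error_rate: float = 0.0
    chimera_rate: float = 0.0
    adaptor: str = ADAPTOR_FWD
    sample_name: str = "sample1"
    n_outgroups: int = 2
    outgroup_divergence: float = 0.40

    def __post_init__(self) -> None:
        for name in ("within_divergence", "between_divergence",
                     "error_rate", "chimera_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.coding_length % 3 or self.coding_length < 204:
            raise ValueError(
                "coding_length must be a multiple of 3 and >= 204 "
                "(201 nt classified region plus the start codon margin)"
            )
        spacer = (
            self.amplicon_length
            - len(self.fwd_primer)
            - len(self.rev_primer)
            - self.coding_length
        )
        if spacer < 0:
            raise ValueError(
                "amplicon_length too short for primers + coding region "
                "(footprints would be destroyed)"
            )
        if self.composition is not None:
            total = sum(self.composition.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"composition must sum to 1, got {total}")


def _draw_variant(rng, variants, usage: dict[int, float] | None):
    if usage is None:
        idx = rng.integers(0, len(variants))
        return variants[int(idx)]
    indices = sorted(usage)
    probs = np.array([usage[i] for i in indices], dtype=float)
    probs = probs / probs.sum()
    chosen = rng.choice(len(indices), p=probs)
    return next(v for v in variants if v.index == indices[int(chosen)])


def _random_seq(rng, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _random_codons(rng, n_codons: int) -> str:
    out = []
    while len(out) < n_codons:
        codon = _random_seq(rng, 3)
        if codon not in _STOPS:
            out.append(codon)
    return "".join(out)


def _mutate(rng, seq: str, rate: float) -> str:
    if rate == 0.0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits.tolist():
        alternatives = [b for b in _BASES if b != chars[i]]
        chars[i] = alternatives[int(rng.integers(0, 3))]
    return "".join(chars)


def _mutate_coding(rng, seq: str, rate: float) -> str:
    """Mutate a frame-0 coding segment without creating stop codons or
    touching the start codon."""
    if rate == 0.0:
        return seq
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    for ci in range(1, len(codons)):
        original = codons[ci]
        mutated = _mutate(rng, original, rate)
        codons[ci] = original if mutated in _STOPS else mutated
    return "".join(codons)


@dataclass
class SyntheticLibrary:
    """A generated reference library plus its ground truth."""

    library: ReferenceLibrary
    truth: pd.DataFrame  # id, lineage ranks, variant ids, coordinates
    config: SimulationConfig

    @property
    def fwd_start(self) -> int:
        return int(self.truth.iloc[0]["fwd_start"])

    def amplicon_region(self, rec_id: str) -> str:
        row = self.truth.set_index("id").loc[rec_id]
        rec = self.library[rec_id]
        return rec.sequence[int(row["fwd_start"]) : int(row["rev_end"])]


def make_reference_library(config: SimulationConfig) -> SyntheticLibrary:
    """Clade-structured gene library with planted primer footprints.

    A random root gene is diverged into ``n_clades`` clade ancestors at
    the between-clade rate, then into taxa at the within-clade rate.
    Forward and reverse primer footprints are planted at fixed
    coordinates, drawing concrete variants from the configured usage
    distributions; the classified coding region begins with ATG
    immediately after the forward footprint.
    """
    rng = np.random.default_rng(config.seed)
    fwd_variants = expand(config.fwd_primer)
    rev_variants = expand(config.rev_primer)

    spacer_len = (
        config.amplicon_length
        - len(config.fwd_primer)
        - len(config.rev_primer)
        - config.coding_length
    )
    root = {
        "left": _random_seq(rng, config.flank_length),
        "coding": "ATG" + _random_codons(rng, config.coding_length // 3 - 1),
        "spacer": _random_seq(rng, spacer_len),
        "right": _random_seq(rng, config.flank_length),
    }

    lib = ReferenceLibrary()
    rows = []
    for c in range(config.n_clades):
        ancestor = {
            "left": _mutate(rng, root["left"], config.between_divergence),
            "coding": _mutate_coding(rng, root["coding"], config.between_divergence),
            "spacer": _mutate(rng, root["spacer"], config.between_divergence),
            "right": _mutate(rng, root["right"], config.between_divergence),
        }
        for t in range(config.taxa_per_clade):
            taxon = {
                k: (
                    _mutate_coding(rng, v, config.within_divergence)
                    if k == "coding"
                    else _mutate(rng, v, config.within_divergence)
                )
                for k, v in ancestor.items()
            }
            fv = _draw_variant(rng, fwd_variants, config.fwd_variant_usage)
            rv = _draw_variant(rng, rev_variants, config.variant_usage)
            fwd_start = config.flank_length
            seq = (
                taxon["left"]
                + fv.sequence
                + taxon["coding"]
                + taxon["spacer"]
                + reverse_complement(rv.sequence)
                + taxon["right"]
            )
            rev_end = fwd_start + config.amplicon_length
            rec_id = f"ref_c{c}_t{t}"
            lineage = (
                "Bacteria",
                f"Phylum_{c}",
                f"Class_{c}",
                f"Order_{c}",
                f"Family_{c}",
                f"Genus_{c}",
                f"Species_{c}_{t}",
            )
            lib.add(
                TargetSequence(
                    id=rec_id, sequence=seq, lineage=lineage,
                    role="reference_gene",
                )
            )
            rows.append(
                {
                    "id": rec_id,
                    **dict(zip(RANKS, lineage)),
                    "fwd_variant_id": fv.id,
                    "rev_variant_id": rv.id,
                    "fwd_start": fwd_start,
                    "fwd_end": fwd_start + len(fv.sequence),
                    "rev_start": rev_end - len(rv.sequence),
                    "rev_end": rev_end,
                    "seed": config.seed,
                }
            )
    # deeply diverged outgroup genes (paralog stand-ins used to root the
    # reference tree); drawn from a common outgroup ancestor so the
    # outgroup clade is monophyletic by construction
    out_ancestor = {
        "left": _mutate(rng, root["left"], config.outgroup_divergence),
        "coding": _mutate_coding(rng, root["coding"], config.outgroup_divergence),
        "spacer": _mutate(rng, root["spacer"], config.outgroup_divergence),
        "right": _mutate(rng, root["right"], config.outgroup_divergence),
    }
    for g in range(config.n_outgroups):
        taxon = {
            k: (
                _mutate_coding(rng, v, config.within_divergence)
                if k == "coding"
                else _mutate(rng, v, config.within_divergence)
            )
            for k, v in out_ancestor.items()
        }
        fv = _draw_variant(rng, fwd_variants, config.fwd_variant_usage)
        rv = _draw_variant(rng, rev_variants, config.variant_usage)
        fwd_start = config.flank_length
        seq = (
            taxon["left"]
            + fv.sequence
            + taxon["coding"]
            + taxon["spacer"]
            + reverse_complement(rv.sequence)
            + taxon["right"]
        )
        rec_id = f"outgroup_{g}"
        lineage = (
            "Bacteria", "Paralog_phylum", "Paralog_class", "Paralog_order",
            "Paralog_family", "Paralog_genus", f"Paralog_species_{g}",
        )
        lib.add(
            TargetSequence(
                id=rec_id, sequence=seq, lineage=lineage, role="reference_gene",
            )
        )
        rows.append(
            {
                "id": rec_id,
                **dict(zip(RANKS, lineage)),
                "fwd_variant_id": fv.id,
                "rev_variant_id": rv.id,
                "fwd_start": fwd_start,
                "fwd_end": fwd_start + len(fv.sequence),
                "rev_start": fwd_start + config.amplicon_length - len(rv.sequence),
                "rev_end": fwd_start + config.amplicon_length,
                "seed": config.seed,
            }
        )
    return SyntheticLibrary(library=lib, truth=pd.DataFrame(rows), config=config)


def build_package_from_synthetic(
    synthetic: SyntheticLibrary,
    label: str = "201",
    region_length: int = 201,
    name: str | None = None,
):
    """Reference package over the classified coding region of a
    synthetic library (NJ tree rooted on the generated outgroups)."""
    from .refpkg import RegionSpec, build_refpkg

    cfg = synthetic.config
    if region_length % 3 or region_length > cfg.coding_length:
        raise ValueError(
            f"region_length must be a codon multiple <= {cfg.coding_length}"
        )
    coords = synthetic.truth.set_index("id")
    alignment = {}
    for rec in synthetic.library:
        start = int(coords.loc[rec.id, "fwd_end"])
        alignment[rec.id] = rec.sequence[start : start + cfg.coding_length]
    anchor = synthetic.truth.iloc[0]["id"]
    region = RegionSpec(label=label, anchor_id=anchor,
                        anchor_interval=(1, region_length))
    outgroups = [r.id for r in synthetic.library if r.id.startswith("outgroup_")]
    return build_refpkg(
        name=name or f"synthetic_{label}",
        region=region,
        nt_alignment=alignment,
        taxonomy={r.id: r.lineage for r in synthetic.library},
        outgroup_ids=outgroups,
        seed=cfg.seed,
    )


def make_paralog_library(
    n: int,
    motif: str = "TGYNNNNNNTGYNNNNNNTGY",
    seed: int = 0,
    rev_primer: DegeneratePrimer = REVERSE_PRIMER_32,
    near_miss_fraction: float = 0.0,
    length: int = 600,
    protected_3prime_len: int = 5,
) -> tuple[ReferenceLibrary, pd.DataFrame]:
    """Decoy ferredoxin-like sequences with near-miss primer sites.

    Every decoy carries an instantiation of the conserved
    triple-cysteine (CXXCXXC) motif and a corrupted reverse-primer
    footprint.  Ordinary decoys get three mismatches, one inside the
    primer's protected 3' window, so even mismatch-tolerant matching
    never fires; a ``near_miss_fraction`` of decoys instead get exactly
    two mismatches outside the protected window, which a two-mismatch
    screen does hit but an exact screen never does.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    variants = expand(rev_primer)
    k = len(rev_primer.sequence)
    n_near = int(round(near_miss_fraction * n))

    lib = ReferenceLibrary()
    rows = []
    for i in range(n):
        near_miss = i < n_near
        seq = list(_random_seq(rng, length))
        # instantiate the IUPAC motif
        motif_seq = "".join(
            IUPAC_SETS[c][int(rng.integers(0, len(IUPAC_SETS[c])))] for c in motif
        )
        mpos = int(rng.integers(0, length - len(motif_seq) - k - 10))
        seq[mpos : mpos + len(motif_seq)] = motif_seq

        variant = variants[int(rng.integers(0, len(variants)))]
        site = list(variant.sequence)  # primer 5'->3' coordinates
        # mismatch positions expressed as offsets from the primer 3' end;
        # fully degenerate (N) primer positions admit no mismatching base
        mutable = np.array(
            [
                off
                for off in range(k)
                if len(IUPAC_SETS[rev_primer.sequence[k - 1 - off]]) < 4
            ]
        )
        outside_pool = mutable[mutable >= protected_3prime_len]
        protected_pool = mutable[mutable < protected_3prime_len]
        if near_miss:
            offsets = rng.choice(outside_pool, size=2, replace=False)
        else:
            protected_offset = protected_pool[
                int(rng.integers(0, len(protected_pool)))
            ]
            outside = rng.choice(outside_pool, size=2, replace=False)
            offsets = np.concatenate([[protected_offset], outside])
        for off in offsets.tolist():
            j = k - 1 - int(off)  # primer position from the 5' end
            allowed = IUPAC_SETS[rev_primer.sequence[j]]
            forbidden = [b for b in _BASES if b not in allowed]
            site[j] = forbidden[int(rng.integers(0, len(forbidden)))]
        footprint = reverse_complement("".join(site))
        spos = int(rng.integers(mpos + len(motif_seq), length - k + 1))
        seq[spos : spos + k] = footprint

        rec_id = f"paralog_{i:03d}"
        lib.add(
            TargetSequence(
                id=rec_id,
                sequence="".join(seq),
                lineage=("Bacteria", "Paralog_phylum", "", "", "", "", ""),
                role="paralog",
            )
        )
        rows.append({"id": rec_id, "near_miss": near_miss,
                     "source_variant": variant.id, "site_start": spos})
    return lib, pd.DataFrame(rows)


def _integer_counts(composition: dict[str, float], n_reads: int) -> dict[str, int]:
    """Largest-remainder apportionment of n_reads over the composition."""
    items = sorted(composition.items())
    raw = {k: v * n_reads for k, v in items}
    counts = {k: int(math.floor(x)) for k, x in raw.items()}
    remainder = n_reads - sum(counts.values())
    by_frac = sorted(items, key=lambda kv: -(raw[kv[0]] - counts[kv[0]]))
    for k, _ in by_frac[:remainder]:
        counts[k] += 1
    return counts


def mock_composition(
    synthetic: SyntheticLibrary, preset: str = "combo1"
) -> dict[str, float]:
    """Map a printed three-organism preset onto one taxon per clade.

    The printed percentages are normalized to sum to one (one preset
    totals 101% as printed, a rounding artifact of its source).
    """
    if preset not in MOCK_PRESETS:
        raise ValueError(f"unknown preset {preset!r}")
    props = MOCK_PRESETS[preset]
    if synthetic.config.n_clades < 3:
        raise ValueError("mock presets need >= 3 clades")
    taxa = [f"ref_c{c}_t0" for c in range(3)]
    total = sum(props)
    return {t: p / total for t, p in zip(taxa, props)}


@dataclass
class AmpliconRun:
    reads: list[Read]
    truth: pd.DataFrame
    config: SimulationConfig


def simulate_amplicon_run(
    synthetic: SyntheticLibrary, config: SimulationConfig | None = None
) -> AmpliconRun:
    """Mock amplicon sequencing of a synthetic library.

    Templates are drawn with deterministic (largest-remainder) integer
    counts matching the composition; each forward read is the 5'
    adaptor plus the amplicon region, truncated to the read length,
    with i.i.d. substitution errors on the template portion.  A
    ``chimera_rate`` fraction of reads are two-parent single-crossover
    recombinants between templates of different taxa.
    """
    config = config or synthetic.config
    composition = config.composition or mock_composition(synthetic)
    missing = set(composition) - set(synthetic.library.ids)
    if missing:
        raise ValueError(f"composition taxa not in library: {sorted(missing)}")

    rng = np.random.default_rng(config.seed + 1)
    counts = _integer_counts(composition, config.n_reads)
    templates = {k: synthetic.amplicon_region(k) for k in composition}
    taxa = sorted(composition)

    reads, rows = [], []
    read_no = 0
    for taxon in taxa:
        for _ in range(counts[taxon]):
            read_no += 1
            read_id = f"read_{read_no:06d}"
            is_chimera = bool(rng.random() < config.chimera_rate) and len(taxa) > 1
            if is_chimera:
                other = taxa[int(rng.integers(0, len(taxa)))]
                while other == taxon:
                    other = taxa[int(rng.integers(0, len(taxa)))]
                template = templates[taxon]
                partner = templates[other]
                # crossover inside the 201 nt window kept after trimming,
                # with margins so both parents contribute a segment long
                # enough to constitute a real recombinant
                lo = len(config.fwd_primer) + 30
                hi = min(len(template), len(partner),
                         len(config.fwd_primer) + 171)
                x = int(rng.integers(lo, hi))
                amplicon = template[:x] + partner[x : len(template)]
                source2 = other
            else:
                amplicon = templates[taxon]
                source2 = ""
            body = amplicon[: max(0, config.read_length - len(config.adaptor))]
            n_errors = 0
            if config.error_rate > 0:
                mutated = _mutate(rng, body, config.error_rate)
                n_errors = sum(a != b for a, b in zip(body, mutated))
                body = mutated
            seq = (config.adaptor + body)[: config.read_length]
            reads.append(
                Read(
                    id=read_id,
                    sequence=seq,
                    quality=tuple([40] * len(seq)),
                    sample=config.sample_name,
                )
            )
            rows.append(
                {
                    "read_id": read_id,
                    "source_id": taxon,
                    "source2_id": source2,
                    "is_chimera": is_chimera,
                    "n_errors": n_errors,
                    "seed": config.seed,
                }
            )
    return AmpliconRun(reads=reads, truth=pd.DataFrame(rows), config=config)
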