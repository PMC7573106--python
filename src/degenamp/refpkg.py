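"""Reference packages for placement-based classification.

A reference package bundles everything needed to classify a query gene
fragment: a region-trimmed nucleotide alignment, its translation, a
profile model over the peptide alignment, a rooted reference tree with
branch lengths in substitutions/site, a seven-rank taxonomy table, and
the ids of outgroup (paralog) leaves used for rooting.  Two region
labels are conventional for the mercury-methylation marker: the short
"201" amplicon region and the longer "654" clone region; the label is
a name, the region itself is defined by the anchor interval.

External maximum-likelihood trees (newick) are imported as-is; a
neighbor-joining builder is provided so packages can be constructed
without any external tool.
"""

from __future__ import annotations

import io
import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .library import RANKS, read_taxonomy_csv, write_taxonomy_csv

__all__ = [
    "RegionSpec",
    "ProfileModel",
    "ReferencePackage",
    "trim_to_region",
    "translate_alignment",
    "build_profile",
    "load_tree",
    "build_nj_tree",
    "peptide_distance_matrix",
    "collapse_by_identity",
    "build_refpkg",
    "save_refpkg",
    "load_refpkg",
    "RefpkgError",
]

FORMAT_VERSION = "1.0"


class RefpkgError(ValueError):
    """A reference package component is missing or inconsistent."""


@dataclass(frozen=True)
class RegionSpec:
    """A gene region named by an anchor record and 1-based inclusive
    nucleotide coordinates on that anchor's ungapped sequence."""

    label: str
    anchor_id: str
    anchor_interval: tuple[int, int]

    def __post_init__(self) -> None:
        start, end = self.anchor_interval
        if not (1 <= start <= end):
            raise ValueError(f"bad anchor interval {self.anchor_interval}")

    @property
    def length(self) -> int:
        return self.anchor_interval[1] - self.anchor_interval[0] + 1


def trim_to_region(alignment: Mapping[str, str], region: RegionSpec) -> dict[str, str]:
    """Keep the alignment columns holding the anchor's region positions.

    The anchor row is read left to right; columns where the anchor has
    an ungapped base numbered within ``anchor_interval`` (1-based,
    inclusive) are retained for every row.
    """
    if region.anchor_id not in alignment:
        raise RefpkgError(f"anchor {region.anchor_id!r} not in alignment")
    anchor = alignment[region.anchor_id]
    start, end = region.anchor_interval
    cols = []
    pos = 0
    for col, ch in enumerate(anchor):
        if ch not in "-.":
            pos += 1
            if start <= pos <= end:
                cols.append(col)
    if pos < end:
        raise RefpkgError(
            f"anchor interval {region.anchor_interval} exceeds anchor "
            f"ungapped length {pos}"
        )
    return {rid: "".join(row[c] for c in cols) for rid, row in alignment.items()}


def translate_alignment(
    nt_alignment: Mapping[str, str], table: int = 11
) -> dict[str, str]:
    """Codon-wise translation of a frame-0 nucleotide alignment.

    Gap codons ('---') become '-'; stop codons become '*' and are the
    caller's concern.  Column count must be a multiple of three.
    """
    from Bio.Seq import Seq

    out = {}
    for rid, row in nt_alignment.items():
        if len(row) % 3:
            raise RefpkgError(f"row {rid!r} length {len(row)} not codon-aligned")
        pep = []
        for i in range(0, len(row), 3):
            codon = row[i : i + 3]
            if codon == "---":
                pep.append("-")
            elif "-" in codon:
                raise RefpkgError(f"row {rid!r}: partial gap codon {codon!r}")
            else:
                pep.append(str(Seq(codon).translate(table=table)))
        out[rid] = "".join(pep)
    return out


class ProfileModel:
    """A position-specific profile over a peptide alignment.

    Thin wrapper around a plan7 profile HMM: builds from an alignment,
    scores query peptides with an E-value-style inclusion statistic,
    and aligns queries into the profile's match-column coordinates.
    """

    def __init__(self, hmm):
        self._hmm = hmm

    @classmethod
    def from_alignment(cls, aa_alignment: Mapping[str, str], name: str = "ref"):
        import pyhmmer
        from pyhmmer.easel import Alphabet, TextMSA, TextSequence
        from pyhmmer.plan7 import Background, Builder

        if len(aa_alignment) < 2:
            raise RefpkgError("profile needs >= 2 aligned peptides")
        abc = Alphabet.amino()
        seqs = [
            TextSequence(name=rid.encode(), sequence=row)
            for rid, row in aa_alignment.items()
        ]
        msa = TextMSA(name=name.encode(), sequences=seqs).digitize(abc)
        hmm, _, _ = Builder(abc).build_msa(msa, Background(abc))
        return cls(hmm)

    @property
    def length(self) -> int:
        return self._hmm.M

    @property
    def name(self) -> str:
        return self._hmm.name.decode()

    def search(
        self, peptides: Mapping[str, str], z: float = 1000.0
    ) -> dict[str, float]:
        """Inclusion statistic (E-value at database size ``z``) per query.

        Queries producing no reportable hit get ``inf``.
        """
        import pyhmmer.hmmer as H
        from pyhmmer.easel import Alphabet, TextSequence

        abc = Alphabet.amino()
        seqs = [
            TextSequence(name=rid.encode(), sequence=pep).digitize(abc)
            for rid, pep in peptides.items()
        ]
        scores = {rid: float("inf") for rid in peptides}
        if seqs:
            for hits in H.hmmsearch([self._hmm], seqs, Z=z):
                for hit in hits:
                    name = hit.name
                    if isinstance(name, bytes):
                        name = name.decode()
                    scores[name] = hit.evalue
        return scores

    def align(self, peptides: Mapping[str, str]) -> dict[str, str]:
        """Align queries to the profile; returns match-column strings."""
        import pyhmmer.hmmer as H
        from pyhmmer.easel import Alphabet, TextSequence

        if not peptides:
            return {}
        abc = Alphabet.amino()
        seqs = [
            TextSequence(name=rid.encode(), sequence=pep).digitize(abc)
            for rid, pep in peptides.items()
        ]
        msa = H.hmmalign(self._hmm, seqs, trim=True)
        return {
            (name.decode() if isinstance(name, bytes) else name): aligned.upper()
            for name, aligned in zip(msa.names, msa.alignment)
        }

    def write(self, path) -> None:
        with open(path, "wb") as fh:
            self._hmm.write(fh, binary=False)

    @classmethod
    def read(cls, path):
        from pyhmmer.plan7 import HMMFile

        with HMMFile(str(path)) as hf:
            return cls(hf.read())


def build_profile(aa_alignment: Mapping[str, str], name: str = "ref") -> ProfileModel:
    return ProfileModel.from_alignment(aa_alignment, name=name)


# ----------------------------------------------------------------------- tree


def load_tree(source) -> TreeNode:
    """Parse a newick tree (path or string) with branch lengths."""
    if isinstance(source, TreeNode):
        return source
    if isinstance(source, str) and source.lstrip().startswith("("):
        return TreeNode.read(io.StringIO(source))
    return TreeNode.read(str(source))


def root_tree(tree: TreeNode, outgroup_ids: Iterable[str] = ()) -> TreeNode:
    """Root on the outgroup clade, or at the midpoint if none given."""
    outgroups = sorted(set(outgroup_ids))
    if outgroups:
        tips = {t.name for t in tree.tips()}
        missing = set(outgroups) - tips
        if missing:
            raise RefpkgError(f"outgroups not in tree: {sorted(missing)}")
        if set(outgroups) == tips:
            raise RefpkgError("outgroup set cannot cover every leaf")
        if len(outgroups) == 1:
            return tree.root_at(outgroups[0], above=True, reset=True)
        return tree.root_by_outgroup(outgroups)
    return tree.root_at_midpoint(reset=True)


def peptide_distance_matrix(aa_alignment: Mapping[str, str]) -> DistanceMatrix:
    """Pairwise p-distance over alignment columns where both rows have
    residues."""
    ids = list(aa_alignment)
    arr = np.array([list(aa_alignment[i]) for i in ids])
    n = len(ids)
    dm = np.zeros((n, n))
    valid = (arr != "-") & (arr != ".")
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            total = int(both.sum())
            diff = int(((arr[i] != arr[j]) & both).sum())
            dm[i, j] = dm[j, i] = diff / total if total else 1.0
    return DistanceMatrix(dm, ids=ids)


def build_nj_tree(distances: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree from a distance matrix (fallback for when
    no externally inferred tree is supplied)."""
    return nj(distances)


# ------------------------------------------------------------------- package


@dataclass
class ReferencePackage:
    name: str
    region: RegionSpec
    nt_alignment: dict[str, str]
    aa_alignment: dict[str, str]
    profile: ProfileModel
    tree: TreeNode
    taxonomy: dict[str, tuple[str, ...]]
    outgroup_ids: frozenset[str] = frozenset()
    seed: int | None = None

    def validate(self) -> None:
        leaves = {t.name for t in self.tree.tips()}
        aln_ids = set(self.aa_alignment)
        tax_ids = set(self.taxonomy)
        if leaves != aln_ids:
            raise RefpkgError(
                f"tree leaves != alignment ids; only-tree="
                f"{sorted(leaves - aln_ids)} only-alignment="
                f"{sorted(aln_ids - leaves)}"
            )
        if leaves != tax_ids:
            raise RefpkgError(
                f"tree leaves != taxonomy ids; only-tree="
                f"{sorted(leaves - tax_ids)} only-taxonomy="
                f"{sorted(tax_ids - leaves)}"
            )
        if not set(self.outgroup_ids) <= leaves:
            raise RefpkgError(
                f"outgroup ids not in tree: "
                f"{sorted(set(self.outgroup_ids) - leaves)}"
            )
        lengths = {len(r) for r in self.aa_alignment.values()}
        if len(lengths) > 1:
            raise RefpkgError(f"ragged peptide alignment: lengths {sorted(lengths)}")

    @property
    def reference_ids(self) -> list[str]:
        return [i for i in self.aa_alignment if i not in self.outgroup_ids]


def build_refpkg(
    name: str,
    region: RegionSpec,
    nt_alignment: Mapping[str, str],
    taxonomy: Mapping[str, tuple[str, ...]],
    tree=None,
    outgroup_ids: Iterable[str] = (),
    seed: int | None = None,
) -> ReferencePackage:
    """Assemble and validate a package from a codon-aligned region.

    If no newick ``tree`` is supplied a neighbor-joining tree is built
    from peptide p-distances and rooted on the outgroups (midpoint if
    none).
    """
    trimmed = trim_to_region(dict(nt_alignment), region)
    aa = translate_alignment(trimmed)
    profile = build_profile(aa, name=name)
    if tree is None:
        tree = build_nj_tree(peptide_distance_matrix(aa))
    else:
        tree = load_tree(tree)
    tree = root_tree(tree, outgroup_ids)
    pkg = ReferencePackage(
        name=name,
        region=region,
        nt_alignment=trimmed,
        aa_alignment=aa,
        profile=profile,
        tree=tree,
        taxonomy={k: tuple(v) for k, v in taxonomy.items()},
        outgroup_ids=frozenset(outgroup_ids),
        seed=seed,
    )
    pkg.validate()
    return pkg


def collapse_by_identity(
    package: ReferencePackage, cutoff: float
) -> tuple[TreeNode, dict]:
    """Collapse reference leaves above a peptide identity cutoff.

    Complete-linkage clustering over pairwise peptide identity; each
    cluster is represented by its lexicographically first leaf and the
    tree is sheared down to the representatives.  Returns the collapsed
    tree plus a report with node counts and the cluster membership.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    ids = list(package.aa_alignment)
    if len(ids) < 2:
        return package.tree, {"nodes_before": len(ids), "nodes_after": len(ids),
                              "clusters": {i: [i] for i in ids}}
    dm = peptide_distance_matrix(package.aa_alignment)
    condensed = squareform(dm.data, checks=False)
    labels = fcluster(linkage(condensed, method="complete"),
                      t=1.0 - cutoff, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for rid, lab in zip(ids, labels):
        clusters.setdefault(int(lab), []).append(rid)
    reps = {min(members): sorted(members) for members in clusters.values()}
    collapsed = package.tree.copy().shear(sorted(reps))
    report = {
        "cutoff": cutoff,
        "nodes_before": len(ids),
        "nodes_after": len(reps),
        "clusters": reps,
    }
    return collapsed, report


# ------------------------------------------------------------------------- IO

_FILES = {
    "nt_alignment": "refs_nt.fasta",
    "aa_alignment": "refs_aa.fasta",
    "profile": "profile.hmm",
    "tree": "tree.nwk",
    "taxonomy": "taxonomy.csv",
}


def _write_fasta(alignment: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for rid, row in alignment.items():
            fh.write(f">{rid}\n{row}\n")


def _read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def save_refpkg(package: ReferencePackage, path) -> None:
    """Write the package as a directory of plain-text components."""
    package.validate()
    os.makedirs(path, exist_ok=True)
    manifest = {
        "format_version": FORMAT_VERSION,
        "name": package.name,
        "region": {
            "label": package.region.label,
            "anchor_id": package.region.anchor_id,
            "anchor_interval": list(package.region.anchor_interval),
        },
        "seed": package.seed,
        "outgroup_ids": sorted(package.outgroup_ids),
        "files": dict(_FILES),
    }
    with open(os.path.join(path, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    _write_fasta(package.nt_alignment, os.path.join(path, _FILES["nt_alignment"]))
    _write_fasta(package.aa_alignment, os.path.join(path, _FILES["aa_alignment"]))
    package.profile.write(os.path.join(path, _FILES["profile"]))
    package.tree.write(os.path.join(path, _FILES["tree"]))
    write_taxonomy_csv(package.taxonomy, os.path.join(path, _FILES["taxonomy"]))


def load_refpkg(path) -> ReferencePackage:
    """Load and validate a saved package, naming any broken component."""
    manifest_path = os.path.join(path, "manifest.json")
    if not os.path.exists(manifest_path):
        raise RefpkgError(f"missing component: {manifest_path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    files = manifest.get("files", _FILES)
    for key, fname in files.items():
        if not os.path.exists(os.path.join(path, fname)):
            raise RefpkgError(f"missing component: {os.path.join(path, fname)}")
    region = RegionSpec(
        label=manifest["region"]["label"],
        anchor_id=manifest["region"]["anchor_id"],
        anchor_interval=tuple(manifest["region"]["anchor_interval"]),
    )
    pkg = ReferencePackage(
        name=manifest["name"],
        region=region,
        nt_alignment=_read_fasta(os.path.join(path, files["nt_alignment"])),
        aa_alignment=_read_fasta(os.path.join(path, files["aa_alignment"])),
        profile=ProfileModel.read(os.path.join(path, files["profile"])),
        tree=load_tree(os.path.join(path, files["tree"])),
        taxonomy=read_taxonomy_csv(os.path.join(path, files["taxonomy"])),
        outgroup_ids=frozenset(manifest.get("outgroup_ids", ())),
        seed=manifest.get("seed"),
    )
    try:
        pkg.validate()
    except RefpkgError as exc:
        raise RefpkgError(f"{path}: {exc}") from exc
    return pkg
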