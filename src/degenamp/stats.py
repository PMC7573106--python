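"""Community summaries over classified OTU tables.

Relative abundance by rank, analytic/resampled rarefaction, a
mock-community sequencing error rate (global alignment of each read to
its best-matching expected template), weighted UniFrac on the reference
tree, and classical principal coordinates analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .library import RANKS
from .pipeline import Read, global_identity

__all__ = [
    "aggregate_rank",
    "rarefaction",
    "seq_error_rate",
    "ErrorRateReport",
    "weighted_unifrac",
    "pcoa",
    "PCoAResult",
    "plot_rarefaction",
    "plot_pcoa",
]


def aggregate_rank(
    classifications: pd.DataFrame,
    counts: pd.DataFrame,
    rank: str,
) -> pd.DataFrame:
    """Per-sample relative abundance with lineages truncated at ``rank``.

    ``classifications`` is the classifier output (query_id = OTU id,
    semicolon-joined lineage); ``counts`` is the OTU x sample count
    matrix.  Queries without a call at the rank fall into the
    ``unclassified`` category (paralog calls into ``paralog``); columns
    are normalized to sum to one.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    depth = RANKS.index(rank) + 1
    calls = classifications.set_index("query_id")

    def category(otu_id: str) -> str:
        if otu_id not in calls.index:
            return "unclassified"
        row = calls.loc[otu_id]
        if row["status"] == "paralog":
            return "paralog"
        lineage = tuple(str(row["lineage"]).split(";")) if row["lineage"] else ()
        if row["status"] != "classified" or len(lineage) < depth:
            return "unclassified"
        return lineage[depth - 1]

    grouped = counts.groupby([category(i) for i in counts.index]).sum()
    totals = grouped.sum(axis=0)
    if (totals == 0).any():
        empty = list(totals.index[totals == 0])
        raise ValueError(f"samples with zero counts: {empty}")
    return grouped / totals


def rarefaction(
    otu_counts: Sequence[int],
    depths: Sequence[int],
    mode: str = "analytic",
    reps: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Expected OTU richness at each subsampling depth.

    Analytic mode uses the hypergeometric expectation
    ``E[S_d] = sum_i (1 - C(N - n_i, d) / C(N, d))``; resample mode
    averages seeded subsamples without replacement.
    """
    counts = np.asarray([c for c in otu_counts if c > 0], dtype=int)
    n_total = int(counts.sum())
    depths = list(depths)
    if any(d > n_total for d in depths):
        raise ValueError(f"depth exceeds total count {n_total}")
    if any(d < 0 for d in depths):
        raise ValueError("depths must be non-negative")

    rows = []
    if mode == "analytic":
        for d in depths:
            # log C(N-n_i, d) - log C(N, d), with C(m, d)=0 when m < d
            expected = 0.0
            for n_i in counts:
                m = n_total - n_i
                if m < d:
                    p_absent = 0.0
                else:
                    p_absent = np.exp(
                        _log_comb(m, d) - _log_comb(n_total, d)
                    )
                expected += 1.0 - p_absent
            rows.append({"depth": d, "richness": expected})
    elif mode == "resample":
        rng = np.random.default_rng(seed)
        pool = np.repeat(np.arange(len(counts)), counts)
        for d in depths:
            richness = [
                len(np.unique(rng.choice(pool, size=d, replace=False)))
                for _ in range(reps)
            ]
            rows.append(
                {"depth": d, "richness": float(np.mean(richness)),
                 "sd": float(np.std(richness, ddof=1)) if reps > 1 else 0.0}
            )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(rows)


def _log_comb(n: int, k: int) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


@dataclass
class ErrorRateReport:
    total_errors: int
    mismatches: int
    indels: int
    aligned_bases: int
    overall_percent: float
    per_read: pd.DataFrame


def seq_error_rate(
    reads: Iterable[Read | str],
    mock_references: Sequence[str],
    ) -> ErrorRateReport:
    """Sequencing error rate of a mock-community run.

    Each read is globally aligned to its best-identity expected
    template; errors are mismatches plus indels, and the overall
    percent is 100 * total errors / total read bases.
    """
    refs = [getattr(r, "sequence", r) for r in mock_references]
    if not refs:
        raise ValueError("empty mock reference set")
    import re

    import edlib

    cigar_re = re.compile(r"(\d+)([=XIDM])")
    rows = []
    for read in reads:
        seq = getattr(read, "sequence", read)
        rid = getattr(read, "id", "")
        best = None
        for ref in refs:
            res = edlib.align(seq, ref, task="path", mode="NW")
            if best is None or res["editDistance"] < best["editDistance"]:
                best = res
        ops = {"=": 0, "X": 0, "I": 0, "D": 0}
        for n, op in cigar_re.findall(best["cigar"]):
            ops[op] = ops.get(op, 0) + int(n)
        rows.append(
            {
                "read_id": rid,
                "mismatches": ops["X"],
                "insertions": ops["I"],
                "deletions": ops["D"],
                "aligned_bases": len(seq),
            }
        )
    per_read = pd.DataFrame(rows)
    mismatches = int(per_read["mismatches"].sum())
    indels = int(per_read["insertions"].sum() + per_read["deletions"].sum())
    aligned = int(per_read["aligned_bases"].sum())
    total = mismatches + indels
    return ErrorRateReport(
        total_errors=total,
        mismatches=mismatches,
        indels=indels,
        aligned_bases=aligned,
        overall_percent=100.0 * total / aligned if aligned else 0.0,
        per_read=per_read,
    )


def weighted_unifrac(
    profiles: Mapping[str, Mapping[str, float]],
    tree,
    normalized: bool = True,
) -> pd.DataFrame:
    """Weighted UniFrac distances between leaf-mass profiles.

    ``profiles`` maps sample -> {leaf name -> mass}; masses are
    normalized per sample.  The raw distance is
    ``sum_e b_e * |A_e - B_e|`` where ``X_e`` is the fraction of
    community X descending through edge e; the normalized variant
    divides by ``sum_e b_e * (A_e + B_e)``.
    """
    leaf_names = {t.name for t in tree.tips()}
    masses = {}
    for sample, profile in profiles.items():
        missing = set(profile) - leaf_names
        if missing:
            raise ValueError(
                f"sample {sample!r}: categories with no tree leaf: "
                f"{sorted(missing)}"
            )
        total = sum(profile.values())
        if total <= 0:
            raise ValueError(f"sample {sample!r}: empty profile")
        masses[sample] = {k: v / total for k, v in profile.items()}

    # fraction of each community under each edge (edge = child node)
    edges = []
    for node in tree.postorder(include_self=False):
        if node.length is None:
            continue
        tips_below = (
            (node.name,) if node.is_tip()
            else tuple(t.name for t in node.tips())
        )
        edges.append((node.length, tips_below))

    samples = list(profiles)
    mat = np.zeros((len(samples), len(samples)))
    frac = {
        s: [sum(masses[s].get(t, 0.0) for t in tips) for _, tips in edges]
        for s in samples
    }
    lengths = np.array([b for b, _ in edges])
    for i, a in enumerate(samples):
        for j in range(i + 1, len(samples)):
            b = samples[j]
            fa = np.array(frac[a])
            fb = np.array(frac[b])
            raw = float(np.sum(lengths * np.abs(fa - fb)))
            if normalized:
                denom = float(np.sum(lengths * (fa + fb)))
                d = raw / denom if denom else 0.0
            else:
                d = raw
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=samples, columns=samples)


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # samples x retained axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    percent_variance: np.ndarray  # over positive eigenvalues
    negative_eigenvalues: np.ndarray


def pcoa(distance_matrix: pd.DataFrame | np.ndarray, ids=None) -> PCoAResult:
    """Classical (Torgerson) scaling of a distance matrix.

    Double-centers -0.5 * D^2, eigendecomposes, orders axes by
    eigenvalue and drops non-positive axes (negative eigenvalues are
    reported, not corrected).
    """
    if isinstance(distance_matrix, pd.DataFrame):
        ids = list(distance_matrix.index)
        d = distance_matrix.to_numpy(dtype=float)
    else:
        d = np.asarray(distance_matrix, dtype=float)
        ids = list(ids) if ids is not None else [str(i) for i in range(len(d))]
    if d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")

    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    positive = evals > 1e-10
    coords = evecs[:, positive] * np.sqrt(evals[positive])
    axes = [f"PC{i + 1}" for i in range(int(positive.sum()))]
    pos_sum = evals[positive].sum()
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=ids, columns=axes),
        eigenvalues=evals,
        percent_variance=100.0 * evals[positive] / pos_sum if pos_sum else
        np.array([]),
        negative_eigenvalues=evals[evals < -1e-10],
    )


# ------------------------------------------------------------ plotting


def plot_rarefaction(curves: Mapping[str, pd.DataFrame], path) -> None:
    """Write rarefaction curves (one per sample) as a vector graphic."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for label, curve in curves.items():
        ax.plot(curve["depth"], curve["richness"], marker="o", label=label)
    ax.set_xlabel("subsampling depth (reads)")
    ax.set_ylabel("expected OTU richness")
    if len(curves) > 1:
        ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_pcoa(result: PCoAResult, path) -> None:
    """Write the first two principal coordinates as a vector graphic."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = result.coordinates
    y = coords["PC2"] if "PC2" in coords else coords["PC1"] * 0
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.scatter(coords["PC1"], y)
    for sample in coords.index:
        ax.annotate(sample, (coords.loc[sample, "PC1"], y.loc[sample]),
                    fontsize=8, xytext=(3, 3), textcoords="offset points")
    pv = result.percent_variance
    ax.set_xlabel(f"PC1 ({pv[0]:.1f}%)" if len(pv) else "PC1")
    ax.set_ylabel(f"PC2 ({pv[1]:.1f}%)" if len(pv) > 1 else "PC2")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
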