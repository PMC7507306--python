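"""Greedy centroid clustering by global sequence identity.

Mirrors the USEARCH-style greedy scheme: sequences are visited in
length-descending (then lexicographic-id) order; each either joins the
first (or best) existing centroid it matches at the identity threshold,
or founds a new cluster. The thresholds of interest are 0.70 (form
assignment) and 0.90 (representative selection).

Identity is defined as matching columns over alignment columns of the
optimal global alignment (BLOSUM62, gap open 10 / extend 0.5), with
terminal gap columns excluded; ``iddef="shorter"`` divides matches by the
shorter sequence length instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .records import ProteinRecord


@dataclass(frozen=True)
class ClusterConfig:
    threshold: float = 0.90
    assignment_rule: Literal["first-hit", "best-hit"] = "first-hit"
    ordering: Literal["input", "length-descending"] = "length-descending"
    iddef: Literal["aligned_columns", "shorter"] = "aligned_columns"

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")


@dataclass
class Cluster:
    centroid_id: str
    member_ids: list[str] = field(default_factory=list)
    threshold: float = 0.0
    identities: dict[str, float] = field(default_factory=dict)  # member -> identity to centroid


_ALIGNER: Align.PairwiseAligner | None = None


def _global_aligner() -> Align.PairwiseAligner:
    global _ALIGNER
    if _ALIGNER is None:
        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.mode = "global"
        aligner.open_gap_score = -10.0
        aligner.extend_gap_score = -0.5
        _ALIGNER = aligner
    return _ALIGNER


def global_identity(a: str, b: str, iddef: str = "aligned_columns") -> float:
    """Pairwise identity from the optimal global alignment.

    Symmetric, in [0, 1], and 1.0 iff the sequences are identical.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if a == b:
        return 1.0
    aln = _global_aligner().align(a, b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    n = len(row_a)
    # exclude terminal gap columns: first/last column where both rows are residues
    first = 0
    while first < n and (row_a[first] == "-" or row_b[first] == "-"):
        first += 1
    last = n - 1
    while last >= 0 and (row_a[last] == "-" or row_b[last] == "-"):
        last -= 1
    if last < first:  # no overlapping residues at all
        return 0.0
    matches = sum(1 for i in range(first, last + 1) if row_a[i] == row_b[i] and row_a[i] != "-")
    if iddef == "shorter":
        denom = min(len(a), len(b))
    else:
        denom = last - first + 1
    return matches / denom


def greedy_cluster(
    records: Sequence[ProteinRecord], config: ClusterConfig = ClusterConfig()
) -> list[Cluster]:
    """Greedy centroid clustering at ``config.threshold``.

    Every member has identity >= threshold to its centroid, and every
    centroid has identity < threshold to all earlier centroids.
    Deterministic given the config.
    """
    if config.ordering == "length-descending":
        ordered = sorted(records, key=lambda r: (-len(r), r.id))
    else:
        ordered = list(records)

    clusters: list[Cluster] = []
    centroids: list[ProteinRecord] = []
    for rec in ordered:
        hit: tuple[int, float] | None = None
        for idx, cen in enumerate(centroids):
            ident = global_identity(rec.sequence, cen.sequence, config.iddef)
            if ident >= config.threshold:
                if config.assignment_rule == "first-hit":
                    hit = (idx, ident)
                    break
                if hit is None or ident > hit[1]:
                    hit = (idx, ident)
        if hit is None:
            cluster = Cluster(centroid_id=rec.id, threshold=config.threshold)
            cluster.member_ids.append(rec.id)
            cluster.identities[rec.id] = 1.0
            clusters.append(cluster)
            centroids.append(rec)
        else:
            idx, ident = hit
            clusters[idx].member_ids.append(rec.id)
            clusters[idx].identities[rec.id] = ident
    return clusters


def select_representatives(
    clusters: Sequence[Cluster], records: Sequence[ProteinRecord]
) -> list[ProteinRecord]:
    """One representative per cluster: its centroid record."""
    by_id = {r.id: r for r in records}
    reps = []
    for cluster in clusters:
        if cluster.centroid_id not in by_id:
            raise KeyError(f"centroid {cluster.centroid_id!r} missing from records")
        reps.append(by_id[cluster.centroid_id])
    return reps


def write_cluster_table(clusters: Sequence[Cluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tcentroid_id\tmember_id\tidentity_to_centroid\n")
        for i, cluster in enumerate(clusters):
            for member in cluster.member_ids:
                fh.write(f"{i}\t{cluster.centroid_id}\t{member}\t"
                         f"{cluster.identities[member]:.4f}\n")
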