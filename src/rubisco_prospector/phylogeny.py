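"""Centroid alignment, trimming, distance trees and form-label propagation.

The form-assignment stage aligns 70%-identity cluster centroids, trims the
alignment to well-occupied columns (> 95% non-gap), builds a
neighbor-joining tree on p-distances, propagates curated form labels to
clades, and removes form-IV (non-carboxylating) sequences. The multiple
alignment is a center-star progressive alignment built from pairwise
global alignments; externally produced alignments (aligned FASTA) and
trees (newick) can be supplied instead at any point.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .clustering import _global_aligner, global_identity
from .records import FormLabel, ProteinRecord

logger = logging.getLogger(__name__)

GAP = "-"


@dataclass
class MultipleAlignment:
    """Equal-length gapped rows keyed by record id."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must have equal length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows must all have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rid, row in zip(self.ids, self.rows):
                fh.write(f">{rid}\n{row}\n")

    @classmethod
    def read_fasta(cls, path: str | Path) -> "MultipleAlignment":
        ids, rows = [], []
        current: list[str] | None = None
        with open(path) as fh:
            for line in fh:
                line = line.rstrip()
                if line.startswith(">"):
                    ids.append(line[1:].split()[0])
                    current = []
                    rows.append(current)
                elif line and current is not None:
                    current.append(line)
        return cls(ids=ids, rows=["".join(r).upper() for r in rows])


def star_align(records: Sequence[ProteinRecord]) -> MultipleAlignment:
    """Center-star progressive multiple alignment.

    The center is the record with maximal summed pairwise identity to all
    others; every other sequence is globally aligned to the center and the
    pairwise alignments are merged column-wise (a gap inserted into the
    center, once introduced, persists).
    """
    if len(records) < 2:
        raise ValueError("star_align needs >= 2 records; pass single records through unchanged")

    n = len(records)
    sums = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            ident = global_identity(records[i].sequence, records[j].sequence)
            sums[i] += ident
            sums[j] += ident
    center_idx = int(max(range(n), key=lambda i: (sums[i], -i)))
    center = records[center_idx]

    # master columns: index into the center sequence, or None for a gap column
    master: list[int | None] = list(range(len(center.sequence)))
    merged: dict[str, list[str]] = {}

    aligner = _global_aligner()
    for rec in records:
        if rec.id == center.id:
            continue
        aln = aligner.align(center.sequence, rec.sequence)[0]
        row_c, row_s = str(aln[0]), str(aln[1])

        new_master: list[int | None] = []
        new_rows: dict[str, list[str]] = {rid: [] for rid in merged}
        srow: list[str] = []
        mi = 0

        def copy_master_column() -> None:
            nonlocal mi
            new_master.append(master[mi])
            for rid in merged:
                new_rows[rid].append(merged[rid][mi])
            srow.append(GAP)
            mi += 1

        for ch_c, ch_s in zip(row_c, row_s):
            if ch_c != GAP:
                while master[mi] is None:  # earlier-introduced center gaps
                    copy_master_column()
                new_master.append(master[mi])
                for rid in merged:
                    new_rows[rid].append(merged[rid][mi])
                srow.append(ch_s)
                mi += 1
            else:  # insertion relative to the center
                new_master.append(None)
                for rid in merged:
                    new_rows[rid].append(GAP)
                srow.append(ch_s)
        while mi < len(master):
            copy_master_column()

        master = new_master
        merged = {rid: new_rows[rid] for rid in merged}
        merged[rec.id] = srow

    center_row = "".join(center.sequence[c] if c is not None else GAP for c in master)
    ids, rows = [], []
    for rec in records:
        ids.append(rec.id)
        rows.append(center_row if rec.id == center.id else "".join(merged[rec.id]))
    return MultipleAlignment(ids=ids, rows=rows)


def trim_alignment(msa: MultipleAlignment, min_occupancy: float = 0.95) -> MultipleAlignment:
    """Keep columns whose non-gap fraction strictly exceeds ``min_occupancy``."""
    n_rows = len(msa.rows)
    keep = [
        c
        for c in range(msa.n_columns)
        if sum(1 for row in msa.rows if row[c] != GAP) / n_rows > min_occupancy
    ]
    if not keep:
        raise ValueError("trimming removed every column; lower min_occupancy")
    return MultipleAlignment(
        ids=list(msa.ids),
        rows=["".join(row[c] for c in keep) for row in msa.rows],
    )


def distance_matrix(msa: MultipleAlignment) -> DistanceMatrix:
    """p-distance over pairwise-complete columns of a (trimmed) alignment."""
    n = len(msa.ids)
    data = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = diffs = 0
            for a, b in zip(msa.rows[i], msa.rows[j]):
                if a != GAP and b != GAP:
                    comparable += 1
                    if a != b:
                        diffs += 1
            if comparable == 0:
                raise ValueError(
                    f"no comparable columns between {msa.ids[i]!r} and {msa.ids[j]!r}"
                )
            data[i, j] = data[j, i] = diffs / comparable
    return DistanceMatrix(data, ids=msa.ids)


def nj_tree(distances: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree; exact on additive distances.

    Negative branch lengths (possible on non-additive input) are clamped
    to zero with a warning.
    """
    if distances.shape[0] < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    tree = nj(distances)
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            logger.warning("clamping negative branch length %.4g at %s", node.length, node.name)
            node.length = 0.0
    return tree


def read_tree_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def _bipartition_sides(tree: TreeNode) -> set[frozenset[str]]:
    all_tips = frozenset(t.name for t in tree.tips())
    sides: set[frozenset[str]] = set()
    for node in tree.traverse(include_self=False):
        side = frozenset([node.name]) if node.is_tip() else frozenset(
            t.name for t in node.tips()
        )
        if 0 < len(side) < len(all_tips):
            sides.add(side)
            sides.add(all_tips - side)
    return sides


def propagate_forms(
    tree: TreeNode, curated_labels: Mapping[str, FormLabel]
) -> dict[str, FormLabel]:
    """Assign each leaf a form from curated leaves in its smallest informative clade.

    A clade is one side of an internal-edge bipartition of the unrooted
    tree (hence the assignment is invariant to rerooting). Curated leaves
    keep their labels. Each uncurated leaf takes the unanimous label of
    the smallest side containing it and at least one curated leaf;
    conflicting labels — or ties between equally small sides that
    disagree — yield ``unknown``.
    """
    tips = [t.name for t in tree.tips()]
    curated_in_tree = {t for t in tips if t in curated_labels}
    if not curated_in_tree:
        raise ValueError("no curated leaf present in the tree")

    sides = _bipartition_sides(tree)
    labels: dict[str, FormLabel] = {}
    for tip in tips:
        if tip in curated_labels:
            labels[tip] = FormLabel(curated_labels[tip])
            continue
        informative = [s for s in sides if tip in s and s & curated_in_tree]
        if not informative:
            labels[tip] = FormLabel.unknown
            continue
        min_size = min(len(s) for s in informative)
        verdicts = set()
        for side in (s for s in informative if len(s) == min_size):
            forms = {FormLabel(curated_labels[c]) for c in side & curated_in_tree}
            verdicts.add(forms.pop() if len(forms) == 1 else FormLabel.unknown)
        labels[tip] = verdicts.pop() if len(verdicts) == 1 else FormLabel.unknown
    return labels


def inherit_cluster_labels(
    clusters: Sequence, centroid_labels: Mapping[str, FormLabel]
) -> dict[str, FormLabel]:
    """Attach each centroid's form label to every member of its cluster."""
    out: dict[str, FormLabel] = {}
    for cluster in clusters:
        label = centroid_labels[cluster.centroid_id]
        for member in cluster.member_ids:
            out[member] = label
    return out


def drop_form_iv(
    records: Sequence[ProteinRecord], labels: Mapping[str, FormLabel]
) -> list[ProteinRecord]:
    """Remove records labeled form IV (rubisco-like, non-carboxylating)."""
    retained = [r for r in records if FormLabel(labels[r.id]) is not FormLabel.IV]
    if records and not retained:
        warnings.warn("all records were labeled form IV; nothing retained")
    return retained
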