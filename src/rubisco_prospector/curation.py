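"""Curation filters producing the non-redundant carboxylase candidate set.

The funnel applies, in fixed order: an open-interval length filter
(300 < l < 700 residues by default), an ambiguity filter (canonical
residues only), a local-alignment coverage filter against a bait sequence
(>= 50% of the bait aligned), and exact-sequence deduplication. The fixed
order makes per-record removal reasons deterministic.

Local alignment is exact Smith-Waterman-style dynamic programming
(BLOSUM62, gap open 11 / extend 1) rather than a heuristic database
search, which keeps the coverage semantics while staying deterministic
and dependency-free.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .records import CANONICAL_AA, ProteinRecord


@dataclass(frozen=True)
class CurationConfig:
    """Parameters of the curation funnel.

    min_length / max_length are exclusive bounds in residues; min_coverage
    is the fraction of the bait sequence that must be spanned by the best
    local alignment.
    """

    min_length: int = 300
    max_length: int = 700
    min_coverage: float = 0.5
    allowed_alphabet: frozenset[str] = CANONICAL_AA
    gap_open: float = 11.0
    gap_extend: float = 1.0
    substitution_matrix: str = "BLOSUM62"

    def __post_init__(self) -> None:
        if not 0 < self.min_length < self.max_length:
            raise ValueError("require 0 < min_length < max_length")
        if not 0 <= self.min_coverage <= 1:
            raise ValueError("min_coverage must be in [0, 1]")


@dataclass
class CurationReport:
    """Counts removed per stage plus per-record removal reasons."""

    input_count: int = 0
    retained_count: int = 0
    removed_by_stage: Counter = field(default_factory=Counter)
    reasons: dict[str, tuple[str, str]] = field(default_factory=dict)  # id -> (stage, reason)

    @property
    def removed_count(self) -> int:
        return sum(self.removed_by_stage.values())

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id\tstage_removed\treason\n")
            for rid, (stage, reason) in self.reasons.items():
                fh.write(f"{rid}\t{stage}\t{reason}\n")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "input": self.input_count,
            "retained": self.retained_count,
            "removed_by_stage": dict(self.removed_by_stage),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


class LocalAlignment(NamedTuple):
    """Best local alignment: score plus half-open spans on each sequence."""

    score: float
    query_span: tuple[int, int]
    reference_span: tuple[int, int]


def _local_aligner(config: CurationConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(config.substitution_matrix)
    aligner.mode = "local"
    aligner.open_gap_score = -config.gap_open
    aligner.extend_gap_score = -config.gap_extend
    return aligner


def local_align(
    query: str, reference: str, config: CurationConfig | None = None
) -> LocalAlignment:
    """Maximal-scoring local alignment of query against reference.

    Returns a zero-score empty alignment when no positive-scoring residue
    pair exists. Raises ``KeyError`` naming the offending residue if a
    residue is missing from the substitution matrix.
    """
    if not query or not reference:
        raise ValueError("sequences must be non-empty")
    config = config or CurationConfig()
    aligner = _local_aligner(config)
    alphabet = set(str(aligner.substitution_matrix.alphabet))
    for seq, name in ((query, "query"), (reference, "reference")):
        bad = sorted(set(seq) - alphabet)
        if bad:
            raise KeyError(
                f"residue(s) {', '.join(bad)} in {name} absent from "
                f"{config.substitution_matrix}"
            )
    score = aligner.score(query, reference)
    if score <= 0:
        return LocalAlignment(0.0, (0, 0), (0, 0))
    best = aligner.align(query, reference)[0]
    qblocks, rblocks = best.aligned
    qspan = (int(qblocks[0][0]), int(qblocks[-1][1]))
    rspan = (int(rblocks[0][0]), int(rblocks[-1][1]))
    return LocalAlignment(float(best.score), qspan, rspan)


def alignment_coverage(
    record: ProteinRecord, reference: ProteinRecord, config: CurationConfig | None = None
) -> float:
    """Fraction of the reference spanned by the best local alignment."""
    aln = local_align(record.sequence, reference.sequence, config)
    start, end = aln.reference_span
    return (end - start) / len(reference)


def filter_by_length(
    records: Sequence[ProteinRecord], config: CurationConfig = CurationConfig()
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Keep records with min_length < l < max_length (strict bounds)."""
    retained, removed = [], []
    for rec in records:
        (retained if config.min_length < len(rec) < config.max_length else removed).append(rec)
    return retained, removed


def filter_ambiguous(
    records: Sequence[ProteinRecord], config: CurationConfig = CurationConfig()
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Keep records whose residues are all in the allowed alphabet."""
    retained, removed = [], []
    for rec in records:
        (retained if set(rec.sequence) <= config.allowed_alphabet else removed).append(rec)
    return retained, removed


def filter_by_coverage(
    records: Sequence[ProteinRecord],
    reference: ProteinRecord,
    config: CurationConfig = CurationConfig(),
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Keep records covering >= min_coverage of the bait by local alignment."""
    retained, removed = [], []
    for rec in records:
        cov = alignment_coverage(rec, reference, config)
        (retained if cov >= config.min_coverage else removed).append(rec)
    return retained, removed


def deduplicate(records: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """Collapse exact sequence duplicates, first-seen id kept.

    Later ids with an identical sequence are recorded in the survivor's
    ``synonyms``; survivor order follows the input.
    """
    by_seq: dict[str, ProteinRecord] = {}
    out: list[ProteinRecord] = []
    for rec in records:
        survivor = by_seq.get(rec.sequence)
        if survivor is None:
            kept = ProteinRecord(rec.id, rec.sequence, rec.source, list(rec.synonyms))
            by_seq[rec.sequence] = kept
            out.append(kept)
        else:
            survivor.synonyms.append(rec.id)
    return out


def curate(
    records: Sequence[ProteinRecord],
    reference: ProteinRecord,
    config: CurationConfig = CurationConfig(),
) -> tuple[list[ProteinRecord], CurationReport]:
    """Run the full funnel: length -> ambiguity -> coverage -> deduplicate."""
    report = CurationReport(input_count=len(records))

    current, dropped = filter_by_length(records, config)
    for rec in dropped:
        report.removed_by_stage["length"] += 1
        report.reasons[rec.id] = ("length", f"length {len(rec)} outside "
                                  f"({config.min_length}, {config.max_length})")

    current, dropped = filter_ambiguous(current, config)
    for rec in dropped:
        bad = "".join(sorted(set(rec.sequence) - config.allowed_alphabet))
        report.removed_by_stage["ambiguity"] += 1
        report.reasons[rec.id] = ("ambiguity", f"non-canonical residue(s) {bad}")

    current, dropped = filter_by_coverage(current, reference, config)
    for rec in dropped:
        report.removed_by_stage["coverage"] += 1
        report.reasons[rec.id] = ("coverage", f"< {config.min_coverage:.0%} of bait aligned")

    # Only synonyms added by THIS dedup pass count as removals (records may
    # already carry synonyms from an earlier curation round).
    prior_syn_count = {rec.id: len(rec.synonyms) for rec in current}
    deduped = deduplicate(current)
    for rec in deduped:
        for syn in rec.synonyms[prior_syn_count[rec.id]:]:
            report.removed_by_stage["duplicate"] += 1
            report.reasons[syn] = ("duplicate", f"identical to {rec.id}")

    report.retained_count = len(deduped)
    return deduped, report
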