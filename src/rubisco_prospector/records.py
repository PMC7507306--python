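"""Protein sequence records and FASTA I/O.

The unit flowing through curation, clustering and phylogeny is a
:class:`ProteinRecord`: an identifier, an uppercase amino-acid sequence, a
free-text provenance tag and the list of ids collapsed into it during
deduplication.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


class FastaError(ValueError):
    """Raised for malformed FASTA input or duplicate identifiers."""


class FormLabel(str, Enum):
    """Structural/phylogenetic class of a rubisco sequence.

    Form IV marks the non-carboxylating rubisco-like proteins; ``unknown``
    marks clades with ambiguous affiliation.
    """

    Ia = "Ia"
    Ib = "Ib"
    Ic = "Ic"
    Id = "Id"
    Ie = "Ie"
    II = "II"
    II_III = "II/III"
    IIIa = "IIIa"
    IIIb = "IIIb"
    IIIc = "IIIc"
    III_like = "III-like"
    IV = "IV"
    unknown = "unknown"


KNOWN_FORMS: tuple[FormLabel, ...] = tuple(
    f for f in FormLabel if f is not FormLabel.unknown
)


@dataclass
class ProteinRecord:
    """One protein sequence with provenance.

    The sequence is normalized on construction: uppercased, with a single
    terminal stop character (``*``) stripped.
    """

    id: str
    sequence: str
    source: str = ""
    synonyms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if not seq:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        self.sequence = seq

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file into records, preserving order.

    Raises :class:`FastaError` if the file does not start with a header
    line, if any entry has an empty sequence, or if ids repeat.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaError(
                        f"{path}: line {lineno}: expected a '>' header, got {line.strip()[:30]!r}"
                    )
                break
        else:
            return []

    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    for entry in SeqIO.parse(str(path), "fasta"):
        if not str(entry.seq):
            raise FastaError(f"{path}: entry {entry.id!r} has an empty sequence")
        seen[entry.id] = seen.get(entry.id, 0) + 1
        records.append(ProteinRecord(id=entry.id, sequence=str(entry.seq), source=str(path)))
    dupes = sorted(i for i, n in seen.items() if n > 1)
    if dupes:
        raise FastaError(f"{path}: duplicate ids: {', '.join(dupes)}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records to FASTA (60-column wrapped)."""
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")
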