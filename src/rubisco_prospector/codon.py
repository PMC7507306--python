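"""GC- and CAI-constrained reverse translation for gene synthesis.

Proteins selected for synthesis are reverse-translated into coding
sequences for an expression host under two constraints: GC content at
most ``gc_max`` (default 60%) and codon adaptation index (CAI) at least
``cai_min`` (default 60%).

CAI follows Sharp & Li (1987): the geometric mean of per-codon relative
adaptiveness values w, excluding codons with no synonymous choice (ATG,
TGG) and stop codons. w(codon) = usage(codon) / max usage within its
synonymous family; zero-usage codons receive a pseudo-weight of 0.01.

The optimizer is deterministic: start every position at its family's
maximal-w codon, then while GC exceeds the cap repeatedly apply the
synonymous swap that lowers GC at the smallest CAI loss (ties broken by
codon lexicographic order, then position).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from Bio.Data import CodonTable
from Bio.Seq import Seq

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_STANDARD.forward_table))
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)

# amino acid -> sorted tuple of codons
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    FAMILIES.setdefault(_STANDARD.forward_table[_codon], ())
for _codon in SENSE_CODONS:
    aa = _STANDARD.forward_table[_codon]
    FAMILIES[aa] = tuple(sorted(FAMILIES[aa] + (_codon,)))

#: codons excluded from the CAI geometric mean (single-codon families)
CAI_EXCLUDED: frozenset[str] = frozenset({"ATG", "TGG"})

_PSEUDO_W = 0.01


class CodonDesignError(ValueError):
    """Raised when the (gc_max, cai_min) constraint pair is infeasible."""


@dataclass(frozen=True)
class CodonUsageTable:
    """Per-codon usage counts (or frequencies) for the 61 sense codons."""

    counts: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = [c for c in SENSE_CODONS if c not in self.counts]
        if missing:
            raise ValueError(f"usage table missing sense codons: {missing[:5]} ...")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("usage counts must be non-negative")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CodonUsageTable":
        counts: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.lower().startswith("codon"):
                    continue
                codon, value = line.split("\t")[:2]
                counts[codon.upper().replace("U", "T")] = float(value)
        return cls(counts)


def relative_adaptiveness(usage: CodonUsageTable) -> dict[str, float]:
    """w(codon) = usage / max usage in its synonymous family, in (0, 1]."""
    w: dict[str, float] = {}
    for aa, codons in FAMILIES.items():
        family_max = max(usage.counts[c] for c in codons)
        if family_max <= 0:
            raise ValueError(f"all-zero usage counts for amino acid {aa!r}")
        for c in codons:
            w[c] = usage.counts[c] / family_max if usage.counts[c] > 0 else _PSEUDO_W
    return w


def gc_content(nt_sequence: str) -> float:
    """(#G + #C) / length of an ACGT string."""
    seq = nt_sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT character(s): {sorted(bad)}")
    return (seq.count("G") + seq.count("C")) / len(seq)


def _codons_of(nt_sequence: str) -> list[str]:
    if len(nt_sequence) % 3 != 0:
        raise ValueError("nucleotide length must be divisible by 3")
    return [nt_sequence[i : i + 3] for i in range(0, len(nt_sequence), 3)]


def cai(nt_sequence: str, usage: CodonUsageTable) -> float:
    """Geometric mean of w over codons, excluding ATG/TGG and stops.

    A terminal stop codon is tolerated (and excluded); an internal stop is
    an error.
    """
    codons = _codons_of(nt_sequence.upper())
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    internal_stops = [c for c in codons if c in STOP_CODONS]
    if internal_stops:
        raise ValueError(f"internal stop codon(s): {internal_stops}")
    w = relative_adaptiveness(usage)
    scored = [w[c] for c in codons if c not in CAI_EXCLUDED]
    if not scored:
        raise ValueError("CAI undefined: sequence contains only excluded codons")
    return math.exp(sum(math.log(x) for x in scored) / len(scored))


def translate(nt_sequence: str) -> str:
    return str(Seq(nt_sequence).translate())


@dataclass(frozen=True)
class OptimizedGene:
    protein_id: str
    nt_sequence: str
    cai: float
    gc: float


def reverse_translate(
    protein: str,
    usage: CodonUsageTable,
    gc_max: float = 0.60,
    cai_min: float = 0.60,
    protein_id: str = "",
) -> OptimizedGene:
    """Reverse-translate a protein under GC and CAI constraints.

    Deterministic; raises :class:`CodonDesignError` reporting the best
    achievable (gc, cai) point when the constraints cannot both be met.
    """
    protein = protein.upper()
    unknown = sorted(set(protein) - set(FAMILIES))
    if unknown:
        raise ValueError(f"cannot reverse-translate residue(s): {unknown}")
    w = relative_adaptiveness(usage)

    def _gc_count(codon: str) -> int:
        return codon.count("G") + codon.count("C")

    # start at the maximal-w codon of each family (ties: lexicographic)
    chosen = [
        min(FAMILIES[aa], key=lambda c: (-w[c], c))
        for aa in protein
    ]

    gc_counts = sum(_gc_count(c) for c in chosen)
    total_nt = 3 * len(chosen)

    while gc_counts / total_nt > gc_max:
        best: tuple[float, str, int] | None = None  # (cai loss, codon, position)
        for pos, cur in enumerate(chosen):
            for alt in FAMILIES[protein[pos]]:
                if _gc_count(alt) < _gc_count(cur):
                    loss = math.log(w[cur]) - math.log(w[alt])
                    key = (loss, alt, pos)
                    if best is None or key < best:
                        best = key
        if best is None:
            break  # no GC-lowering swap exists anywhere
        _, alt, pos = best
        gc_counts += _gc_count(alt) - _gc_count(chosen[pos])
        chosen[pos] = alt

    nt = "".join(chosen)
    achieved_gc = gc_content(nt)
    achieved_cai = cai(nt, usage)
    if achieved_gc > gc_max or achieved_cai < cai_min:
        raise CodonDesignError(
            f"constraints gc<={gc_max:.2f}, cai>={cai_min:.2f} infeasible for this "
            f"protein/usage; best achievable point on the repair path: "
            f"gc={achieved_gc:.3f}, cai={achieved_cai:.3f}"
        )
    return OptimizedGene(protein_id=protein_id, nt_sequence=nt, cai=achieved_cai, gc=achieved_gc)


def toy_usage_table(bias: str = "at") -> CodonUsageTable:
    """Synthetic usage table for tests and demonstrations only.

    Not a real organism's codon usage. ``bias="at"`` ranks synonymous
    codons by ascending GC (maximal-w codons are AT-rich), ``bias="gc"``
    by descending GC; counts fall geometrically with rank.
    """
    if bias not in {"at", "gc"}:
        raise ValueError("bias must be 'at' or 'gc'")
    counts: dict[str, float] = {}
    for codons in FAMILIES.values():
        sign = 1 if bias == "at" else -1
        ranked = sorted(codons, key=lambda c: (sign * (c.count("G") + c.count("C")), c))
        for rank, codon in enumerate(ranked):
            counts[codon] = 100.0 / (2 ** rank)
    return CodonUsageTable(counts)
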