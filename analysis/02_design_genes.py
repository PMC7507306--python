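"""Reverse-translate the selected representatives for gene synthesis.

Reads the representatives chosen in step 01 and designs coding sequences
under the synthesis constraints (GC <= 60%, CAI >= 60%) against the
package's synthetic demonstration usage table. Real designs would swap in
the expression host's measured codon-usage table (TSV: codon, count).
Writes results/02_genes/.
"""

from pathlib import Path

import pandas as pd

from rubisco_prospector.codon import CodonDesignError, reverse_translate, toy_usage_table
from rubisco_prospector.records import read_fasta

IN = Path("results/01_sequences/representatives.fasta")
OUT = Path("results/02_genes")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    reps = read_fasta(IN)
    usage = toy_usage_table()
    rows, designed = [], []
    for rep in reps:
        try:
            gene = reverse_translate(rep.sequence, usage, gc_max=0.60, cai_min=0.60,
                                     protein_id=rep.id)
        except CodonDesignError as exc:
            rows.append({"id": rep.id, "status": "infeasible", "detail": str(exc)})
            continue
        designed.append(gene)
        rows.append({"id": rep.id, "status": "ok", "gc": round(gene.gc, 4),
                     "cai": round(gene.cai, 4), "length_nt": len(gene.nt_sequence)})
    with open(OUT / "genes.fasta", "w") as fh:
        for gene in designed:
            fh.write(f">{gene.protein_id} cai={gene.cai:.3f} gc={gene.gc:.3f}\n")
            fh.write(gene.nt_sequence + "\n")
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "design_table.tsv", sep="\t", index=False)
    ok = table[table.status == "ok"]
    print(f"designed {len(ok)}/{len(reps)} genes; "
          f"GC range {ok.gc.min():.3f}-{ok.gc.max():.3f}, "
          f"CAI range {ok.cai.min():.3f}-{ok.cai.max():.3f}")


if __name__ == "__main__":
    main()
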