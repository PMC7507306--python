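"""Benchmark kinetic constants for reference rubiscos.

Published carboxylation constants (25 C, radiometric assays) for the
fastest bacterial form-II/form-II/III screen hits, the cyanobacterial and
plant benchmarks, and the R. rubrum internal reference. These serve as
ground-truth inputs for the synthetic generators, as expectations for the
batch QC of the plate screen, and as parameter sets for curve-comparison
analyses. kcat in s^-1, KM for CO2 in uM, S_C/O dimensionless.
"""

from __future__ import annotations

from .stats import KineticRecord

TABLE_KINETICS: tuple[KineticRecord, ...] = (
    KineticRecord("Gallionella sp.", 22.2, 276.0, 10.0, oligomer="L2", form="II"),
    KineticRecord("Zetaproteobacterium", 18.2, 261.0, 12.5, oligomer="L2", form="II"),
    KineticRecord("Hydrogenovibrio marinus", 15.6, 162.0, 20.7, oligomer="L2", form="II"),
    KineticRecord("Sulfurivirga caldicuralii", 14.3, 143.0, 13.5, oligomer="L4", form="II"),
    KineticRecord("Unknown organism", 11.8, 130.0, 4.8, oligomer="L6", form="II"),
    KineticRecord("S. elongatus", 11.7, 200.0, 42.7, oligomer="L8S8", form="I"),
    KineticRecord("Zetaproteobacteria_53_45", 11.0, 284.0, 13.9, oligomer="L2", form="II"),
    KineticRecord("Acidithiobacillus ferrooxidans", 9.6, 239.0, 16.4, oligomer="L6", form="II"),
    KineticRecord("R. rubrum", 6.6, 109.0, 12.5, oligomer="L2", form="II"),
)

#: median plant rubisco benchmark (screen-wide comparisons, 25 C)
PLANT_MEDIAN = KineticRecord("Plant (median)", 3.3, 14.0, 94.0, oligomer="L8S8", form="I")
#: median C3 plant rubisco (MM-curve comparisons)
PLANT_C3 = KineticRecord("Plant (C3 median)", 3.1, 14.0, form="I")
#: median C4 plant rubisco
PLANT_C4 = KineticRecord("Plant (C4 median)", 4.2, 20.0, form="I")

#: internal reference included in every screen batch
R_RUBRUM_KCAT_PER_S = 6.6
R_RUBRUM_KCAT_SE = 0.3

GALLIONELLA = TABLE_KINETICS[0]
S_ELONGATUS = TABLE_KINETICS[5]

#: screen-wide summary statistics of the active variants
SCREEN_MEDIAN_KCAT_PER_S = 5.6
SCREEN_N_ASSAYED = 143
SCREEN_N_ACTIVE = 105


def by_name(name: str) -> KineticRecord:
    for rec in TABLE_KINETICS + (PLANT_MEDIAN, PLANT_C3, PLANT_C4):
        if rec.variant_id == name:
            return rec
    raise KeyError(name)
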