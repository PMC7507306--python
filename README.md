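# rubisco-prospector

A desk-scale implementation of a prospecting pipeline for fast-carboxylating
rubiscos: mine candidate protein sequences, curate and cluster them, assign
structural forms on a tree, design synthesizable genes, and analyze the two
kinetic assays used to rank variants — the spectrophotometric CABP-titration
screen and the radiometric Michaelis–Menten / CO₂:O₂-specificity assays.

It is written for computational biologists and enzymologists who want to run,
test or extend each stage of such a screen on their own data, with every stage
backed by a synthetic-data generator that knows its own ground truth.

## The science in brief

**Sequence funnel.** Candidate sequences are filtered by length
(300 < l < 700 residues), by ambiguous residues, and by local-alignment
coverage of a bait rubisco (≥ 50 % of *R. rubrum*'s large subunit), then
deduplicated. Greedy centroid clustering at 70 % global identity feeds form
assignment: cluster centroids are aligned (center-star), the alignment trimmed
to columns > 95 % occupied, a neighbor-joining tree built on p-distances, and
curated form labels propagated to clades; form-IV (non-carboxylating) clades
are dropped. Re-clustering at 90 % identity yields the diversity-spanning
representatives.

**Gene design.** Representatives are reverse-translated under two constraints:
GC ≤ 60 % and codon adaptation index (CAI, Sharp–Li geometric mean of relative
adaptiveness w) ≥ 60 %, via a deterministic greedy repair that starts from the
maximal-w codons and swaps in GC-lowering synonyms at minimal CAI cost.

**Plate kinetics.** In the coupled assay each carboxylation produces two
3-phosphoglycerate, each oxidizing one NADH, so the A340 slope divided by the
effective extinction coefficient gives twice the carboxylation rate. CABP
binds active sites stoichiometrically, so rate declines linearly with [CABP]:
the x-intercept of the titration line is the active-site concentration [E],
the y-intercept is V_max, and k_cat = V_max/[E]. Variants with
k_cat ≥ 0.5 s⁻¹ are called active; an *R. rubrum* reference
(k_cat = 6.6 s⁻¹) rides along in every batch as QC.

**Radiometric kinetics.** ¹⁴C counts convert to rates through a specific
activity calibrated by exhausting 5.2 nmol RuBP; rates across a CO₂ series
(dissolved CO₂ = HCO₃⁻·10^(pKa′−pH), pKa′ = 6.10) are fit to
v = k_cat·S/(K_M+S). The specificity factor is
S_C/O = (v_c/v_o)·[O₂]/[CO₂], with v_c/v_o read off the labeled
glycerate:glycolate peak ratio.

**Statistics.** Q10 temperature adjustment (Q10 = 2.2), carboxylation
efficiency k_cat/K_M, Michaelis–Menten curve crossover
C* = (k_cat,a·K_M,b − k_cat,b·K_M,a)/(k_cat,b − k_cat,a), pairwise kinetic
similarity (larger/smaller rate ratio) against sequence identity, and rate
summaries.

## Layout

- `src/rubisco_prospector/` — the library: `curation`, `clustering`,
  `phylogeny`, `codon`, `plate`, `radiometric`, `stats`, `synthetic`,
  `pipeline`, plus `reference_data` (benchmark kinetic constants).
- `analysis/01…05_*.py` — numbered drivers running each stage on synthetic
  data and writing tables under `results/`.
- `tests/` — unit, property and acceptance tests.

## Worked example

```
$ python analysis/04_radiometric_kinetics.py
dissolved gases at equilibrium: CO2 166.7 uM, O2 1253.7 uM
Gallionella sp.: kcat 22.1 +/- 0.12 /s (truth 22.2), KM 274 +/- 3.4 uM (truth 276.0), S_C/O 9.96 (truth 10.0)
S. elongatus: kcat 11.8 +/- 0.06 /s (truth 11.7), KM 202 +/- 2.8 uM (truth 200.0), S_C/O 43.25 (truth 42.7)
Gallionella sp. vs S. elongatus: Gallionella sp. is faster at every CO2 concentration
Gallionella sp. vs Plant (C3 median): curves cross at 28.5 uM CO2 (Plant (C3 median) faster below, Gallionella sp. above)
```

Poisson-count simulations parameterized by the fastest screen hit
(*Gallionella* sp., 22.2 s⁻¹, K_M 276 µM) and the cyanobacterial benchmark
are refit from raw counts; both recover their truths within one standard
error. The gas mixture of the specificity assay dissolves to 166.7 µM CO₂ and
1253.7 µM O₂, under which binomially partitioned turnovers return
S_C/O = 9.96 against a planted 10.0. The curve comparison shows the fast
bacterial enzyme outrunning the cyanobacterial one at every CO₂ level, while
the plant median wins only below ≈ 28.5 µM CO₂.

The full chain (`analysis/01…05`) mines and classifies a synthetic family set,
designs genes for its representatives, simulates the plate screen for nine
benchmark variants (all recovered within ~1 % with r² > 0.999 titration
lines), and tabulates the cross-variant statistics.

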