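# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of rubisco-prospector. It states no empirical result that
the test suite and `scripts/acceptance.py` do not themselves compute.

## Sequence curation

Records are normalized on construction (uppercase, one terminal `*` stripped).
The funnel applies four filters in a fixed order — length, ambiguity,
coverage, deduplication — so that each removed record carries exactly one
(first-triggered) reason and the report is deterministic. Bounds are strict
open intervals: a 300- or 700-residue sequence is removed.

*Ambiguity* is read strictly: any character outside the 20 canonical residues
(B, J, Z, X, U, O, `*`, `-`, …) disqualifies a sequence; the alphabet is
configurable.

*Coverage* uses an exact Smith–Waterman-style local alignment (Biopython's
`PairwiseAligner`, BLOSUM62, gap open 11 / extend 1 — the defaults of common
heuristic protein search tools) rather than a database-search heuristic; this
keeps the semantics (fraction of the bait spanned by the best local alignment)
while being deterministic and self-contained. The denominator is the bait
(reference) length, since candidates are aligned *against* the bait; the
alternative (query-length denominator) would keep long fusions that merely
contain a rubisco domain, which is exactly what the filter is meant to remove.
Coverage is measured as the extent of the reference span (last aligned column
minus first), so internal gaps count toward coverage; for the near-full-length
homologs this filter targets, span and aligned-column counts coincide.

*Non-redundancy* is exact string identity after normalization. Thresholded
collapse is deliberately left to the clustering stage; collapsing at < 100 %
identity here would silently change downstream cluster counts.

Idempotence and input-order independence of the retained sequence multiset are
property-tested.

## Identity and clustering

Global identity = matching columns / alignment columns of the optimal global
alignment (BLOSUM62, gap open 10 / extend 0.5), with terminal gap columns
excluded so that a fragment is not penalized for length; an alternative
`iddef="shorter"` (matches / shorter sequence length) is available. In the
≥ 70 % regime the two definitions rarely disagree.

Greedy clustering visits sequences length-descending (ties: lexicographic id)
and assigns each to the first existing centroid at ≥ T identity (best-hit
optional), else founds a new cluster. This reproduces the behavior of
USEARCH-style greedy clustering deterministically. Every member is ≥ T to its
centroid and centroids are mutually < T (in creation order); consequently
re-clustering the representative set at the same T yields only singletons. All
pairs are compared by exact dynamic programming — appropriate up to a few
thousand sequences; no k-mer prefilter is implemented.

Exact cluster counts from any particular published screen depend on the
original tool's identity definition and input order and are treated as
descriptive, not as recovery targets; what is tested is perfect partition
recovery on synthetic families whose between-family identity < T <
within-family identity.

## Alignment, tree and form propagation

The multiple alignment is center-star: the center maximizes summed pairwise
identity, every other sequence is globally aligned to it, and pairwise
alignments are merged under "once a gap, always a gap". Center-star is within
a factor-2 of optimal SP score and exactly reduces to the pairwise alignment
for two sequences; externally produced alignments (aligned FASTA) can be read
in instead when a production aligner is preferred.

Trimming keeps columns whose non-gap occupancy is strictly greater than the
threshold (default 0.95): with 20 rows, a column with one gap (occupancy
exactly 0.95) is removed. The occupancy is computed per column across rows.

Distances are p-distances over pairwise-complete columns (positions gapped in
either row ignored); a pair with no comparable columns is an error naming the
pair. Trees are neighbor-joining (scikit-bio), which is exact on additive
distances — property-tested by regenerating distances from random trees of up
to 8 taxa. Negative branch lengths, which NJ can produce on non-additive
input, are clamped to zero with a warning. Maximum-likelihood inference and
bootstrap support are out of scope; externally produced newick trees can be
supplied.

Form propagation treats a clade as one side of an internal-edge bipartition of
the unrooted tree, which makes the assignment invariant to rerooting and leaf
order. Each uncurated leaf takes the unanimous label of the smallest side
containing it and at least one curated leaf; conflicts — including ties
between equally small sides that disagree — resolve to `unknown`. Curated
leaves always keep their labels. Form-IV (rubisco-like, non-carboxylating)
records are then dropped; `unknown` is retained, erring toward keeping
candidates.

## Codon design

CAI follows Sharp & Li (1987): the geometric mean of relative adaptiveness
w = f(codon)/max f(synonym), excluding the single-codon families (ATG, TGG)
and stops; a terminal stop is tolerated and excluded; zero-usage codons get a
pseudo-weight of 0.01 to keep the geometric mean defined.

The optimizer starts every position at its family's maximal-w codon (ties:
lexicographic) and, while GC exceeds the cap, applies the synonymous swap with
ΔGC < 0 and the smallest CAI loss (ties: codon lexicographic order, then
position). The repair is monotone — GC never increases — and deterministic.
When the loop stalls above the GC cap, or the final CAI lands below the
floor, a `CodonDesignError` reports the best achieved (GC, CAI) point rather
than returning a violating design. Poly-glycine illustrates genuine
infeasibility: all four Gly codons are GGN, so GC cannot fall below 2/3.

The shipped usage table (`toy_usage_table`) is synthetic — counts fall
geometrically with a codon's GC rank — and exists for tests and
demonstrations; real designs require the expression host's measured table
(TSV: codon, count). Restriction-site avoidance and mRNA structure are not
modeled.

## Plate kinetics

Model: CABP is a tight-binding stoichiometric inhibitor, so the carboxylation
rate at inhibitor concentration c is k_cat·max([E]−c, 0); NADH is consumed at
twice that rate (two 3PG per carboxylation, one NADH per 3PG); A340 =
ε_eff·[NADH]. ε_eff (absorbance per molar) is a **required** configuration
value with no default because it folds in the plate's path length; the
synthetic generator's default of 1800 A·M⁻¹ corresponds to NADH's
6220 M⁻¹cm⁻¹ over a ≈ 0.29 cm well path, a typical 100 µl 96-well geometry.

Slope fitting is ordinary least squares over a window of 30–330 s by default —
skipping 30 s of mixing dead time and using a 300 s initial-rate stretch; the
window is configurable and residuals beyond 5σ are logged as artifacts.
Positive slopes beyond 2× their standard error are warned about and the rate
clamped to zero.

The titration line averages replicate rates at equal CABP (notably the
duplicate zeros) and excludes, in one pass, points with CABP above the
estimated [E] and rate below 5 % of the uninhibited rate: such
saturated-inhibition points (e.g. 90 nM CABP against 50 nM sites) lie off the
linear regime and would bias the intercepts. [E] outside (0, 2·max CABP] or a
non-negative slope flags the variant as not quantifiable instead of reporting
a number. The activity call k_cat ≥ 0.5 s⁻¹ is inclusive at the boundary and
applied per active site. Batch QC flags a batch when the internal reference's
k_cat strays more than 25 % (default) from expectation and reports the running
mean ± SE across batches.

At zero noise the pipeline inverts the generator exactly; at the study's
acquisition settings (2-s cadence, 15 min, σ_A340 = 0.002) the mean recovered
k_cat over 50 seeds is within 5 % of truth (acceptance test).

## Radiometric kinetics and specificity

The apparent pKa of the CO₂/HCO₃⁻ equilibrium defaults to 6.10, chosen so the
assay's printed 4 mM → ≈ 50 µM and 55 mM → ≈ 700 µM correspondences hold at
pH 8.0; it is configurable. Henry coefficients default to 0.0334 (CO₂) and
0.00126 (O₂) M·atm⁻¹ at 25 °C.

CPM → rate: nmol fixed = CPM / specific activity; per-site rate = nmol fixed /
(time × nmol sites). The Michaelis–Menten fit is unweighted nonlinear least
squares initialized from a Hanes–Woolf linearization (falling back to
1.5·max v and the median S when the linearization is degenerate); standard
errors come from the local covariance. Replicates enter individually.

S_C/O bookkeeping: with [1-³H]RuBP, each oxygenation yields one labeled
glycolate and each carboxylation one labeled glycerate, so v_c/v_o is the
glycerate:glycolate count ratio and S_C/O = (v_c/v_o)·[O₂]/[CO₂]. This 1:1
label-partition assumption is isolated in `specificity_from_peaks` so an
alternative stoichiometric correction can be substituted. Counting is taken as
Poisson (no quench/efficiency correction); the reported SE propagates the two
counts.

## Statistics

Q10 adjustment is the exact closed form k·Q10^(ΔT/10) with Q10 = 2.2; its
round trip is an identity. (Published temperature-corrected values rounded
from different bases may differ from the closed form; no agreement is forced.)
Kinetic similarity uses the arithmetic mean of larger/smaller rate ratios
(geometric mean behind a flag); "high identity" means global identity > 0.80
under the clustering module's definition. Quantiles are linear-interpolation
(type 7). The crossover formula is returned only when finite and positive;
otherwise the everywhere-faster enzyme is named by comparing low-S
efficiencies (and saturation rates on ties).

## Synthetic generators

All randomness flows through NumPy's PCG64 `default_rng`; identical seeds give
identical bytes. Sequence evolution is substitution-only at disjoint random
sites, so identity arithmetic is exact: per-member mutation fractions of
(1−w)/2 within families and (1−b)/2 between family ancestors put realized
pairwise identities within ±0.05 of the requested w (within) and b (between).
What this does **not** emulate: indels, rate heterogeneity, selection, or
real phylogenetic depth — so passing recovery tests demonstrates correctness
of the clustering/labeling machinery, not robustness to real evolutionary
noise.

Plate traces are exactly linear with homoscedastic Gaussian absorbance noise
(no drift, lag or substrate depletion curvature); the generator refuses
parameter combinations that would exhaust NADH inside the trace. Radiometric
counts are Poisson around the MM expectation; specificity counts are a
binomial partition of turnovers with carboxylation probability
S_C/O·[CO₂]/(S_C/O·[CO₂]+[O₂]). Because the generators implement the same
forward models the estimators invert, zero-noise recovery is exact by
construction and is used as a consistency check, not as evidence about real
instruments.

## Problem sizes

Default runs are sized for a desk machine: tens of sequences of 150–400
residues through the alignment-heavy stages (all-pairs exact DP is quadratic),
50-seed recovery loops for the stochastic acceptance checks, and 10⁵ turnovers
for specificity simulations. The analysis drivers finish in seconds; the full
test suite in well under a minute.

## Known limitations

- No database search: the pipeline starts from user-supplied FASTA; E-value
  screening is out of scope.
- Center-star + NJ are deliberate stand-ins for production MSA/ML tools at
  desk scale; both stages accept external alignments and trees.
- The greedy codon repair is near-optimal for the one-dimensional GC
  constraint but is not guaranteed to find the global CAI optimum subject to
  GC; infeasibility reports are with respect to its repair path.
- Oxygenation side-flux in the plate assay is not modeled (the protocol
  suppresses O₂); background NADH oxidation subtraction is supported but off
  by default, consistent with handling background via the activity threshold.
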