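# Methods

## Grantham distances, GV and GD

The pairwise distance is `D(a,b) = ρ·√(α·Δc² + β·Δp² + γ·Δv²)` over
side-chain composition `c`, polarity `p` and volume `v` (Å³), with the
classical coefficients α = 1.833, β = 0.1018, γ = 0.000399 and scale
ρ = 50.723 (mean pairwise distance ≈ 100). These constants reproduce the
unrounded anchors D(T,S) = 57.75 and D(V,I) = 29.61 used throughout the
conservation analysis. The packaged integer matrix
(`data/grantham_matrix_1974.tsv`) is the formula rounded to integers; tests
additionally pin ~20 widely cited published integer entries at ±1, the
slack needed because the original table's own rounding differs by one unit
for a few pairs (e.g. R–S prints 110 where the formula gives 109.2).

Grantham Variation (GV) applies the same formula to the property *ranges*
observed in an alignment column (duplicates ignored); Grantham Deviation
(GD) measures a mutant residue's distance outside those ranges, zero inside.
Columns are mapped to 1-based ungapped reference coordinates; alignment
columns where the reference is gapped (insertions) are dropped. Gap
characters carry no properties, so they are excluded from a column's residue
set and counted separately; a column with fewer than two ungapped residues
is flagged unscorable (GV = NaN) rather than scored 0. The "highly
conserved" rule is GV < 61.3 (configurable). The GV-vs-family-frequency
correlation includes *every* reference position, with zero-filled counts for
positions never reported mutated; Spearman uses midranks for ties. Whether
the original analysis scored gapped columns from the reduced residue set,
and whether it zero-filled unmutated positions, is not documented — both
conventions here are package decisions, stated and kept.

## Kinetic model and the RAI / GSIR-T derivation

Activity is `A(G, ATP) = kcat · G^nH/(S0.5^nH + G^nH) · ATP/(ATP + KM_ATP)`.
Hill fits use nonlinear least squares (trust-region reflective through
`scipy.optimize.curve_fit`) initialized at `S0.5 = x at half-max`,
`nH = 1.5`, `vmax = max rate`, with `nH` bounded to [0.5, 4]; rates are
per-enzyme turnovers so the fitted plateau is `kcat` times the fixed-ATP
Michaelis factor. A titration whose maximum rate does not exceed the
detection limit (caller-supplied, e.g. twice the blank SD; default 0) is
flagged `no_activity` and contributes zero activity downstream. IC₅₀ fits
use a four-parameter logistic with the top plateau pinned to the dose-0
rate; a curve whose two highest doses stay above 90 % of that plateau is
censored "IC₅₀ > max dose".

The literature formulas behind the published RAI and GSIR-T columns are not
reproduced in full anywhere accessible, so the package fixes one explicit,
documented model and exposes every constant in `BetaCellModelConfig`:

* operating point 5 mM glucose, 2.5 mM ATP (ATP KM measured at S0.5 is
  used where available, the 50 mM-glucose value as fallback);
* `RAI = A_var/A_wt` at that point, censored "<0.01" below the floor;
* `GSIR-T` solves `½·κ·A_wt(G) + ½·A_var(G) = A_wt(5 mM)` for the smallest
  positive root (κ = 1: no wild-type-allele compensation), by bracket
  expansion from [0.1, 50] mM (doubling to 500 mM) and bisection to
  10⁻⁶ mM, reported at 0.1 mM precision and censored "≥7.1" at the cap.

Under this model the published per-variant values are *not* reproduced
numerically (e.g. the activating variant R63S computes RAI 2.77 where 4.17
is printed; the model census censors C252R and F419L at the cap where 6.2
and 6.6 are printed) — the model family upstream is under-specified, and no
constant here was tuned to the printed numbers. What the model does
reproduce, and what the tests assert, is the *ordering*: Spearman ρ = 0.98
against the printed RAI over the 14 fully parameterized proteins and
ρ = 0.92 against printed GSIR-T over all 20 rows (censored values tied at
7.1). The sign identity RAI > 1 ⇔ GSIR-T < 5 mM holds by construction
(activating variants lower the secretion threshold), and bisection agrees
with a 10⁻³ mM grid scan on random parameter draws to within one reporting
step.

## Threshold calibration

`threshold = center ± k·spread` on the neutral-class scores, direction per
predictor orientation (EVmutation/SIFT/I-Mutant: lower is deleterious;
PoPMuSiC ΔΔG/SNAP2/PolyPhen-2: higher). Defaults: k = 2, center = median
(mean for SNAP2, matching how its published boundary was derived), spread =
sample SD with n−1 denominator; a robust 1.4826·MAD spread is available but
not default. The SD estimator is a package decision — the source statistic
is stated only as "SD". Scores exactly at the boundary are not called
deleterious (strict inequality). The CI of the center is a seeded
nonparametric bootstrap (percentile method, 10⁴ resamples); the method is
unstated upstream and chosen here. Binary predictors (PhD-SNP, SNPs&GO)
cannot be recalibrated and are rejected.

## Evaluation conventions

Expected calls per class: disease classes (MODY, PHHI, PNDM; GSIR-T low/high
bins; Hill bins below 1.5) expect "deleterious", normal classes expect a
neutral call. Sensitivity is the percent of class members matching their
expected call; the false-positive ratio is the percent of disease-associated
variants called neutral. Bin boundaries 4.0/5.5 mM and 1.2/1.5 are inclusive
in the middle bin — printed bin labels do not state inclusivity, so this is
a package convention. Records without a score for the predictor under test
are excluded from every denominator and counted. Ternary coordinates rescale
each of (−EVmutation, ΔΔG, SNAP2) to [0,1] on its *observed* range over the
analyzed set (recorded in the run manifest) and close the triple to sum 1;
an all-benign triple maps to the barycenter. Region boundaries
(EV < −7.5 ∧ SNAP2 > 70; −4 ≤ EV ≤ −2 ∧ SNAP2 < −50) are strict except the
EV window of the benign region, which is closed as written.

## Synthetic data: what it emulates and what it does not

The generator produces the three input kinds with full ground truth and a
one-seed/named-stream design (`SeedSequence(seed, spawn_key=stream)`), so
outputs are byte-stable and adding a generator never shifts existing draws.

* **Assays**: model curves on a 9-point glucose grid (0.5–150 mM, 3
  replicates) at 5 mM ATP with Normal(0, 0.02·kcat) noise truncated at zero —
  matching the few-percent replicate SE of the published wild-type row.
* **Scores**: class-conditional Normals. The *neutral* class is anchored to
  published statistics — EVmutation (−2.39, 1.96), PoPMuSiC ΔΔG (0.58,
  0.42), SNAP2 (−58, 32.25), each SD derived as (threshold − center)/2 from
  the printed center/threshold pair. Disease-class parameters (MODY
  EVmutation (−6.5, 1.8), etc.) are plausible placeholders chosen once to
  mimic the reported qualitative behaviour (MODY deep in the deleterious
  tails, PHHI overlapping neutral) and are **not** literature-derived. Class
  sizes default to the real catalogue's composition (499/16/53).
* **Alignments**: exactly `round(L·fraction)` invariant columns; variable
  columns draw from small residue pools of physicochemically similar amino
  acids; specific residue sets (e.g. {T,S}) can be planted at chosen
  positions. Family counts are negative-binomial with log-mean decreasing
  in GV.

Real data differ in ways the generator does not emulate: predictor scores
are position-correlated along the protein and correlated across methods
(scores here are independent given the class), real alignments have gaps
and phylogenetic structure, and the real variant catalogue is ascertained
through clinical sequencing. Passing round-trip tests therefore shows the
*estimators* are correct and calibrated under the stated conditions, not
that the thresholds transfer to other proteins.

The package ships no real GCK protein sequence; where a 465-residue
reference is needed (enumeration, simulated alignments) a synthetic random
sequence of that length is generated and labelled as such. Published
wild-type and variant kinetic constants are embedded as packaged data
(`data/table1_kinetics.tsv`) and treated as inputs.

## Problem sizes and numerics

Default analysis sizes — 568 variants, 15 fitted titrations, a 465 × 12
alignment, 10⁴ bootstrap resamples — run the whole chain in seconds and were
chosen as the scale of the real study. Degenerate inputs fail loudly:
empty columns, constant correlation vectors, binary predictors in
calibration, identity substitutions, duplicate table rows. Percentiles use
linear interpolation; reported percentages are rounded to one decimal
(metrics) or whole percent (pass rates) while internal values keep full
precision.
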