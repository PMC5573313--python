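# gckvar

Interpretation of nonsynonymous glucokinase (GCK) variants by combining
enzyme-kinetics modeling, evidence-based recalibration of variant-effect
predictor thresholds, and evolutionary conservation profiling.

GCK is the pancreatic beta-cell glucose sensor; heterozygous inactivating
missense variants cause GCK-MODY (mild fasting hyperglycemia) and activating
ones cause persistent hyperinsulinemic hypoglycemia of infancy (PHHI).
Whether a newly found substitution is disease-associated is usually guessed
from predictor scores (SIFT, PolyPhen-2, SNAP2, PoPMuSiC ΔΔG, EVmutation, …)
with arbitrary default cutoffs. This package implements a pipeline that
anchors those predictions in measurable biology:

1. **Kinetics → physiology** (`gckvar.kinetics`). Glucose titrations are fit
   with the Hill model `v = kcat·G^nH/(S0.5^nH + G^nH)` and ATP titrations
   with a Michaelis factor. From fitted constants a variant's **relative
   activity index** `RAI = A_var(5 mM G, 2.5 mM ATP)/A_wt(…)` and its
   **GSIR-T** — the glucose level at which a heterozygous beta-cell
   (½ wild-type + ½ variant enzyme) regains the wild-type reference rate —
   are derived. Wild type sits at RAI 1.00 / GSIR-T 5.0 mM; inactivating
   variants push GSIR-T up (values ≥ 7.1 mM are censored, null alleles print
   "<0.01" / "≥7.1").
2. **Evidence-based thresholds** (`gckvar.calibration`). A predictor's
   decision boundary is placed at the *neutral* (normoglycemic) score
   distribution's center ± 2·SD in the deleterious direction, with a
   bootstrap CI of the center — reproducing the calibrated boundaries
   −6.31 (EVmutation, median −2.39), +1.42 kcal/mol (PoPMuSiC ΔΔG, median
   0.58) and +6.5 (SNAP2, mean −58).
3. **Multi-class evaluation** (`gckvar.evaluation`). Per-class sensitivity
   and the disease false-positive ratio against phenotype, GSIR-T bins
   (<4 / 4–5.5 / >5.5 mM) and Hill-coefficient bins (<1.2 / 1.2–1.5 / >1.5);
   predictor agreement counts; saturating enumeration of all 19·465 = 8835
   substitutions; ternary score composition; and the two-region
   EVmutation × SNAP2 classifier (highly pathogenic: EV < −7.5 ∧ SNAP2 > 70;
   benign: −4 ≤ EV ≤ −2 ∧ SNAP2 < −50).
4. **Conservation** (`gckvar.grantham`). Grantham distances
   `D = ρ√(α·Δc² + β·Δp² + γ·Δv²)`, per-column Grantham Variation/Deviation
   over a 12-species ortholog alignment, the GV < 61.3 conservation rule,
   and the correlation of GV with per-residue disease-family counts.
5. **Synthetic ground truth** (`gckvar.synthetic`). Every input kind —
   assays, score tables, alignments, family counts — can be generated with
   known ground truth, so each analysis stage is testable as a round trip.

## Worked example

```bash
python analysis/01_simulate.py --seed 0   # synthetic inputs under results/synthetic/
python analysis/02_fit_kinetics.py --seed 0
python analysis/03_calibrate.py --seed 0
python analysis/04_evaluate.py --seed 0
python analysis/05_conserve.py --seed 0
```

prints, among other lines:

```
Spearman vs published: RAI 0.985, GSIR-T 0.949
wild-type recovery: S0.5 8.81 mM (true 8.82), nH 1.70 (true 1.72), kcat 44.1 /s (true 43.8)
evmutation: center -2.15 (95% CI -2.76 to -1.06), SD 2.05 -> call deleterious below -6.25
  MODY: 59% of 499 pass the threshold
  PHHI: 0% of 16 pass the threshold
301 invariant residues (65%) of 465; 446 conserved (GV < 61.3)
benchmark column at position 332: GV = 57.75
GV vs family frequency: Pearson -0.290 (p=1.8e-10), Spearman -0.319 (p=1.8e-12), n=465
```

Reading: Hill fits on 2%-noise titrations recover the wild-type constants
and rank the 15 fitted variants almost exactly as the published RAI/GSIR-T
columns do; the threshold calibrated from only 53 synthetic neutral variants
lands near the population value −6.31 and passes MODY-like but no PHHI-like
variants; the planted {T,S} benchmark column scores GV 57.75; and conserved
(low-GV) positions carry more disease families, a negative rank correlation.

A library-level run of the same stages is `gckvar.io.run_pipeline(RunConfig(...))`,
which writes a manifest with input/output hashes and is byte-reproducible
per config.

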