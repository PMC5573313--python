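#!/usr/bin/env python
"""Evaluate the calibrated predictors per class and map the score landscape.

Reads the synthetic variant table and the calibrated thresholds, then:
  * per-class sensitivity and disease false-positive ratio per predictor
    (results/class_metrics.tsv);
  * saturating enumeration of all 19*465 substitutions of the synthetic
    reference, with score summaries per predictor (results/score_summary.tsv);
  * pairwise score correlations (results/score_correlations.tsv);
  * ternary coordinates and EVmutation x SNAP2 region classes per variant
    (results/ternary.tsv, results/regions.tsv).
"""

import argparse
from pathlib import Path

import pandas as pd

from gckvar.calibration import ThresholdResult, apply_threshold
from gckvar.evaluation import (
    class_metrics,
    enumerate_substitutions,
    harmonize_and_ternary,
    region_classify,
    score_correlations,
    score_summary,
)
from gckvar.io import parse_variant_table, write_tsv
from gckvar.synthetic import gen_reference_sequence

OUT = Path("results")


def main(seed: int) -> None:
    records = parse_variant_table(OUT / "synthetic" / "variants.tsv")
    thr_df = pd.read_csv(OUT / "thresholds.tsv", sep="\t", comment="#")

    mrows = []
    for _, t in thr_df.iterrows():
        thr = ThresholdResult(predictor=t["predictor"], center=t["center"],
                              spread=t["spread"], k=t["k"], threshold=t["threshold"],
                              direction=t["direction"], n=t["n"])
        calls = {r.name: apply_threshold(r.scores.get(thr.predictor), thr)
                 for r in records if thr.predictor in r.scores}
        cm = class_metrics(records, calls, "phenotype")
        for _, row in cm.per_class.iterrows():
            mrows.append({"predictor": thr.predictor, "class": row["class"],
                          "n": row["n"], "sensitivity_pct": round(row["sensitivity_pct"], 1)})
        mrows.append({"predictor": thr.predictor, "class": "disease_false_positive",
                      "n": cm.n_disease,
                      "sensitivity_pct": round(cm.false_positive_ratio, 1)})
        print(f"{thr.predictor}: FP ratio "
              f"{cm.false_positive_ratio:.1f}% over {cm.n_disease} disease variants")
    write_tsv(pd.DataFrame(mrows), OUT / "class_metrics.tsv")

    seq = gen_reference_sequence(465, seed=seed)
    enumerated = enumerate_substitutions(seq)
    print(f"saturating enumeration: {len(enumerated)} substitutions of a 465-mer")
    srows = []
    for name in ("evmutation", "popmusic_ddg", "snap2"):
        scores = [r.scores[name] for r in records if name in r.scores]
        srows.append({"predictor": name, **score_summary(scores)})
    write_tsv(pd.DataFrame(srows), OUT / "score_summary.tsv")

    crows = []
    for a, b in (("snap2", "evmutation"), ("popmusic_ddg", "evmutation"),
                 ("snap2", "popmusic_ddg")):
        out = score_correlations(records, a, b)
        crows.append({"pair": f"{a}~{b}", **out})
        print(f"{a} ~ {b}: Pearson {out['pearson']:.3f}, "
              f"Spearman {out['spearman']:.3f} (n={out['n']})")
    write_tsv(pd.DataFrame(crows), OUT / "score_correlations.tsv")

    triple = [r for r in records
              if {"evmutation", "popmusic_ddg", "snap2"} <= set(r.scores)]
    ranges = {
        name: (min(r.scores[name] for r in triple), max(r.scores[name] for r in triple))
        for name in ("evmutation", "popmusic_ddg", "snap2")
    }
    trows, rrows = [], []
    for r in triple:
        t1, t2, t3 = harmonize_and_ternary(
            r.scores["evmutation"], r.scores["popmusic_ddg"], r.scores["snap2"],
            ranges["evmutation"], ranges["popmusic_ddg"], ranges["snap2"],
        )
        trows.append({"variant": r.hgvs_p, "phenotype": r.phenotype,
                      "t_ev": t1, "t_ddg": t2, "t_snap2": t3})
        rrows.append({"variant": r.hgvs_p, "phenotype": r.phenotype,
                      "region": region_classify(r.scores["evmutation"], r.scores["snap2"])})
    write_tsv(pd.DataFrame(trows), OUT / "ternary.tsv")
    regions = pd.DataFrame(rrows)
    write_tsv(regions, OUT / "regions.tsv")
    print("region counts:", regions["region"].value_counts().to_dict())


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    main(ap.parse_args().seed)
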