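#!/usr/bin/env python
"""Calibrate evidence-based thresholds from the synthetic neutral variants.

Reads results/synthetic/variants.tsv, takes the normoglycemic class, and
places each continuous predictor's decision boundary at center +/- 2 SD in
the deleterious direction, with a bootstrap CI of the center.  Writes
results/thresholds.tsv and prints the per-class pass rates at the new
boundaries.
"""

import argparse
import dataclasses
from pathlib import Path

import pandas as pd

from gckvar.calibration import DEFAULT_PREDICTORS, apply_threshold, evidence_threshold, pass_rate
from gckvar.io import parse_variant_table, write_tsv

OUT = Path("results")
PREDICTORS = ("evmutation", "popmusic_ddg", "snap2")


def main(seed: int) -> None:
    records = parse_variant_table(OUT / "synthetic" / "variants.tsv")
    neutral = [r for r in records if r.phenotype == "normoglycemic"]
    print(f"{len(neutral)} neutral variants calibrate {len(PREDICTORS)} predictors")

    rows = []
    for name in PREDICTORS:
        scores = [r.scores[name] for r in neutral if name in r.scores]
        thr = evidence_threshold(scores, DEFAULT_PREDICTORS[name], k=2, ci_seed=seed)
        rows.append(dataclasses.asdict(thr))
        print(f"{name}: center {thr.center:.2f} (95% CI {thr.ci_low:.2f} to "
              f"{thr.ci_high:.2f}), SD {thr.spread:.2f} -> call deleterious "
              f"{thr.direction} {thr.threshold:.2f}")
        for cls in ("MODY", "PHHI", "normoglycemic"):
            scored = [r for r in records if r.phenotype == cls and name in r.scores]
            calls = [apply_threshold(r.scores[name], thr) for r in scored]
            rate = pass_rate(calls, [cls] * len(calls), cls)
            print(f"  {cls}: {rate}% of {len(scored)} pass the threshold")
    write_tsv(pd.DataFrame(rows), OUT / "thresholds.tsv")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    main(ap.parse_args().seed)
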