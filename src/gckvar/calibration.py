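"""Evidence-based decision thresholds for continuous predictor scores.

The idea: instead of the arbitrary cutoffs shipped with variant-effect
predictors, place the decision boundary at the center of the *neutral*
(normoglycemic) score distribution plus or minus ``k`` standard deviations in
the deleterious direction — a score must clear the bulk of the benign
distribution before a variant is called deleterious.  With k = 2 this yields
the calibrated thresholds −6.31 for EVmutation (median −2.39, scores more
negative = more damaging), +1.42 kcal/mol for the PoPMuSiC ΔΔG (median 0.58)
and +6.5 for SNAP2 (mean −58).

Binary predictors (PhD-SNP, SNPs&GO) admit no such calibration and are
rejected.  Scores exactly at the threshold are *not* called deleterious
(strict inequality).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "PredictorSpec",
    "ThresholdResult",
    "DEFAULT_PREDICTORS",
    "evidence_threshold",
    "center_ci",
    "apply_threshold",
    "pass_rate",
]

Orientation = Literal["higher_is_deleterious", "lower_is_deleterious"]


@dataclass(frozen=True)
class PredictorSpec:
    """Conventions of one prediction method."""

    name: str
    orientation: Orientation | None = None
    output_type: Literal["continuous", "binary"] = "continuous"
    default_threshold: float | None = None
    center_stat: Literal["median", "mean"] = "median"

    def __post_init__(self) -> None:
        if self.output_type == "binary" and self.default_threshold is not None:
            raise ValueError(f"{self.name}: binary predictors take no threshold")
        if self.output_type == "continuous" and self.orientation is None:
            raise ValueError(f"{self.name}: continuous predictors need an orientation")


#: Score conventions of the nine methods whose outputs the pipeline ingests.
#: SNAP2 is calibrated on the mean, the others on the median.
DEFAULT_PREDICTORS: dict[str, PredictorSpec] = {
    "sift": PredictorSpec("sift", "lower_is_deleterious", default_threshold=0.05),
    "polyphen2": PredictorSpec("polyphen2", "higher_is_deleterious", default_threshold=0.5),
    "phd_snp": PredictorSpec("phd_snp", output_type="binary"),
    "popmusic_ddg": PredictorSpec("popmusic_ddg", "higher_is_deleterious", default_threshold=0.0),
    "snap2": PredictorSpec("snap2", "higher_is_deleterious", default_threshold=0.0,
                           center_stat="mean"),
    "snpsgo": PredictorSpec("snpsgo", output_type="binary"),
    "snpsgo_go": PredictorSpec("snpsgo_go", output_type="binary"),
    "imutant3": PredictorSpec("imutant3", "lower_is_deleterious", default_threshold=0.0),
    "agvgd_gv": PredictorSpec("agvgd_gv", "lower_is_deleterious", default_threshold=61.3),
    "agvgd_gd": PredictorSpec("agvgd_gd", "higher_is_deleterious", default_threshold=0.0),
    "evmutation": PredictorSpec("evmutation", "lower_is_deleterious", default_threshold=0.0),
}


@dataclass
class ThresholdResult:
    """A calibrated decision boundary for one predictor."""

    predictor: str
    center: float
    spread: float
    k: float
    threshold: float
    direction: Literal["below", "above"]  # call deleterious strictly below/above
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    n: int = 0


def _center(scores: np.ndarray, stat: str) -> float:
    if stat == "median":
        return float(np.median(scores))
    if stat == "mean":
        return float(np.mean(scores))
    raise ValueError(f"unknown center statistic {stat!r}")


def evidence_threshold(
    neutral_scores: Sequence[float],
    spec: PredictorSpec,
    k: float = 2.0,
    center_stat: str | None = None,
    spread_stat: Literal["sd", "mad"] = "sd",
    ci_seed: int | None = None,
) -> ThresholdResult:
    """Calibrate ``center ± k·spread`` from neutral-variant scores.

    ``spread`` is the sample SD (n−1 denominator) by default; ``"mad"``
    selects the robust 1.4826·MAD alternative.  A bootstrap CI of the
    center is attached when ``ci_seed`` is given.
    """
    if spec.output_type != "continuous":
        raise ValueError(f"{spec.name}: cannot calibrate a {spec.output_type} predictor")
    scores = np.asarray(list(neutral_scores), dtype=float)
    if scores.size < 3:
        raise ValueError(f"{spec.name}: need >= 3 neutral scores, got {scores.size}")
    if not np.all(np.isfinite(scores)):
        raise ValueError(f"{spec.name}: neutral scores contain non-finite values")
    stat = center_stat or spec.center_stat
    center = _center(scores, stat)
    if spread_stat == "sd":
        spread = float(np.std(scores, ddof=1))
    elif spread_stat == "mad":
        spread = float(1.4826 * np.median(np.abs(scores - np.median(scores))))
    else:
        raise ValueError(f"unknown spread statistic {spread_stat!r}")

    if spec.orientation == "lower_is_deleterious":
        threshold, direction = center - k * spread, "below"
    else:
        threshold, direction = center + k * spread, "above"

    ci_low = ci_high = float("nan")
    if ci_seed is not None and scores.size >= 5:
        ci_low, ci_high = center_ci(scores, center_stat=stat, seed=ci_seed)
    return ThresholdResult(
        predictor=spec.name, center=center, spread=spread, k=k,
        threshold=threshold, direction=direction,
        ci_low=ci_low, ci_high=ci_high, n=int(scores.size),
    )


def center_ci(
    scores: Sequence[float],
    center_stat: str = "median",
    level: float = 0.95,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Nonparametric bootstrap percentile CI of the center statistic."""
    x = np.asarray(list(scores), dtype=float)
    if x.size < 5:
        raise ValueError("need >= 5 scores for a bootstrap CI")
    if np.ptp(x) == 0:
        return float(x[0]), float(x[0])
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    boot = x[idx]
    stats = np.median(boot, axis=1) if center_stat == "median" else np.mean(boot, axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def apply_threshold(score: float | None, threshold: ThresholdResult) -> str:
    """Call one score against a calibrated threshold.

    Returns ``"deleterious"`` only for scores strictly past the threshold in
    the deleterious direction; anything else — including a score exactly at
    the threshold or a missing score — is ``"not_called"``.
    """
    if score is None or (isinstance(score, float) and math.isnan(score)):
        return "not_called"
    if threshold.direction == "below":
        return "deleterious" if score < threshold.threshold else "not_called"
    return "deleterious" if score > threshold.threshold else "not_called"


def pass_rate(
    calls: Sequence[str], labels: Sequence[str], target_label: str
) -> float:
    """Percent of ``target_label`` variants called deleterious.

    The denominator counts target-class variants with a call (missing-score
    records carry no call and must be filtered upstream).  Reported rounded
    to the nearest integer percent.
    """
    calls = list(calls)
    labels = list(labels)
    if len(calls) != len(labels):
        raise ValueError("calls and labels must have equal length")
    in_class = [c for c, l in zip(calls, labels) if l == target_label]
    if not in_class:
        raise ValueError(f"no scored variants with label {target_label!r}")
    hits = sum(c == "deleterious" for c in in_class)
    return round(100.0 * hits / len(in_class))
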