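"""Multi-class evaluation of predictor calls against phenotype and kinetics.

Variants are grouped three ways — by clinical phenotype (MODY / PHHI /
normoglycemic), by GSIR-T bin (activating < 4 mM, normal 4–5.5 mM,
deactivating > 5.5 mM) and by Hill-coefficient bin (< 1.2 lost
cooperativity, 1.2–1.5 intermediate, > 1.5 normal).  For each grouping a
predictor's per-class sensitivity is the percent of class members whose call
matches the class's expected direction (deleterious for disease classes,
neutral for normal classes), and the false-positive ratio is the percent of
disease-associated variants called neutral.

The module also provides predictor-agreement counts, saturating enumeration
of all 19·L substitutions of a protein sequence, descriptive score
summaries, pairwise score correlations, the min–max/ternary transformation
of the (EVmutation, PoPMuSiC, SNAP2) score triple, and the two-region
classifier of the EVmutation × SNAP2 plane (putatively highly pathogenic:
EV < −7.5 and SNAP2 > 70; putatively benign: −4 ≤ EV ≤ −2 and SNAP2 < −50).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .grantham import STANDARD_RESIDUES
from .kinetics import CensoredValue

__all__ = [
    "PHENOTYPES",
    "VariantRecord",
    "ClassMetrics",
    "bin_gsirt",
    "bin_hill",
    "class_metrics",
    "agreement_count",
    "enumerate_substitutions",
    "score_summary",
    "score_correlations",
    "harmonize_and_ternary",
    "region_classify",
]

PHENOTYPES = frozenset({"MODY", "PHHI", "PNDM", "normoglycemic", "unknown", "experimental"})

AA_ORDER = sorted(STANDARD_RESIDUES)


@dataclass
class VariantRecord:
    """One amino-acid substitution with its annotations."""

    ref_aa: str
    position: int
    alt_aa: str
    phenotype: str = "unknown"
    scores: dict = field(default_factory=dict)
    family_count: int = 0
    gsirt: CensoredValue | None = None
    n_h: float | None = None

    def __post_init__(self) -> None:
        if self.ref_aa not in STANDARD_RESIDUES or self.alt_aa not in STANDARD_RESIDUES:
            raise ValueError(f"non-standard residue in {self.ref_aa}{self.position}{self.alt_aa}")
        if self.ref_aa == self.alt_aa:
            raise ValueError(f"ref and alt residues identical at position {self.position}")
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        if self.family_count < 0:
            raise ValueError("family_count must be >= 0")

    @property
    def name(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"

    @property
    def hgvs_p(self) -> str:
        return f"p.{self.name}"


def bin_gsirt(gsirt: float | CensoredValue) -> str:
    """GSIR-T class: ``low`` (<4 mM), ``normal`` (4–5.5 mM incl.), ``high`` (>5.5 mM).

    A high-censored value (">=7.1") is ``high``.
    """
    if isinstance(gsirt, CensoredValue):
        if gsirt.censor == "ge":
            return "high"
        gsirt = gsirt.value
    if not math.isfinite(gsirt) or gsirt < 0:
        raise ValueError(f"invalid GSIR-T value: {gsirt!r}")
    if gsirt < 4.0:
        return "low"
    if gsirt <= 5.5:
        return "normal"
    return "high"


def bin_hill(n_h: float) -> str:
    """Hill-coefficient class: ``<1.2``, ``1.2-1.5`` (inclusive), ``>1.5`` (normal)."""
    if not math.isfinite(n_h) or n_h <= 0:
        raise ValueError(f"invalid Hill coefficient: {n_h!r}")
    if n_h < 1.2:
        return "<1.2"
    if n_h <= 1.5:
        return "1.2-1.5"
    return ">1.5"


# Which call each class is expected to receive, per grouping.
EXPECTED_CALL = {
    "phenotype": {
        "MODY": "deleterious", "PHHI": "deleterious", "PNDM": "deleterious",
        "normoglycemic": "neutral",
    },
    "gsirt": {"low": "deleterious", "high": "deleterious", "normal": "neutral"},
    "hill": {"<1.2": "deleterious", "1.2-1.5": "deleterious", ">1.5": "neutral"},
}

# Classes counted as disease-associated in the false-positive ratio.
DISEASE_CLASSES = {
    "phenotype": {"MODY", "PHHI", "PNDM"},
    "gsirt": {"low", "high"},
    "hill": {"<1.2", "1.2-1.5"},
}


@dataclass
class ClassMetrics:
    """Per-class sensitivities and the disease false-positive ratio."""

    grouping: str
    per_class: pd.DataFrame  # columns: class, n, sensitivity_pct
    false_positive_ratio: float
    n_disease: int
    n_missing: int


def _record_class(rec: VariantRecord, grouping: str) -> str | None:
    if grouping == "phenotype":
        return rec.phenotype if rec.phenotype in EXPECTED_CALL["phenotype"] else None
    if grouping == "gsirt":
        return bin_gsirt(rec.gsirt) if rec.gsirt is not None else None
    if grouping == "hill":
        return bin_hill(rec.n_h) if rec.n_h is not None else None
    raise ValueError(f"unknown grouping {grouping!r}")


def class_metrics(
    records: Sequence[VariantRecord],
    calls: Mapping[str, str],
    grouping: str,
    expected_call: Mapping[str, str] | None = None,
) -> ClassMetrics:
    """Per-class sensitivity and the disease false-positive ratio.

    ``calls`` maps variant name to ``"deleterious"`` or a neutral-direction
    call (anything else, e.g. ``"neutral"`` / ``"not_called"``); variants
    without an entry (missing score) are excluded from all denominators and
    counted in ``n_missing``.
    """
    expected = expected_call or EXPECTED_CALL[grouping]
    disease = DISEASE_CLASSES[grouping]
    by_class: dict[str, list[bool]] = {}
    fp_num = fp_den = 0
    n_missing = 0
    for rec in records:
        cls = _record_class(rec, grouping)
        if cls is None:
            continue
        call = calls.get(rec.name)
        if call is None:
            n_missing += 1
            continue
        is_del = call == "deleterious"
        want_del = expected[cls] == "deleterious"
        by_class.setdefault(cls, []).append(is_del == want_del)
        if cls in disease:
            fp_den += 1
            fp_num += not is_del
    rows = [
        {"class": cls, "n": len(oks), "sensitivity_pct": 100.0 * sum(oks) / len(oks)}
        for cls, oks in sorted(by_class.items())
    ]
    fpr = 100.0 * fp_num / fp_den if fp_den else float("nan")
    return ClassMetrics(
        grouping=grouping,
        per_class=pd.DataFrame(rows, columns=["class", "n", "sensitivity_pct"]),
        false_positive_ratio=fpr,
        n_disease=fp_den,
        n_missing=n_missing,
    )


def agreement_count(calls: Mapping[str, str | None]) -> tuple[int, int]:
    """(number of methods calling an effect, number of methods with a call)."""
    with_call = {m: c for m, c in calls.items() if c is not None}
    if not with_call:
        raise ValueError("no method produced a call for this record")
    n_effect = sum(c == "deleterious" for c in with_call.values())
    return n_effect, len(with_call)


def enumerate_substitutions(sequence: str) -> list[VariantRecord]:
    """All 19·L single substitutions of ``sequence``, phenotype unknown.

    Deterministic order: by position, then alphabetically by the substituted
    residue.
    """
    records: list[VariantRecord] = []
    for i, ref in enumerate(sequence, start=1):
        if ref not in STANDARD_RESIDUES:
            raise ValueError(f"non-standard residue {ref!r} at position {i}")
        for alt in AA_ORDER:
            if alt != ref:
                records.append(VariantRecord(ref_aa=ref, position=i, alt_aa=alt))
    return records


def score_summary(scores: Iterable[float]) -> dict[str, float]:
    """Descriptive statistics (quartiles by linear interpolation)."""
    x = np.asarray([s for s in scores if s is not None], dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no finite scores to summarize")
    return {
        "n": int(x.size),
        "mean": float(np.mean(x)),
        "se": float(np.std(x, ddof=1) / math.sqrt(x.size)) if x.size > 1 else 0.0,
        "min": float(np.min(x)),
        "max": float(np.max(x)),
        "median": float(np.median(x)),
        "q25": float(np.percentile(x, 25)),
        "q75": float(np.percentile(x, 75)),
    }


def score_correlations(
    records: Sequence[VariantRecord], predictor_a: str, predictor_b: str
) -> dict[str, float]:
    """Pairwise-complete Pearson and Spearman correlation of two score columns."""
    pairs = [
        (r.scores[predictor_a], r.scores[predictor_b])
        for r in records
        if predictor_a in r.scores and predictor_b in r.scores
        and np.isfinite(r.scores[predictor_a]) and np.isfinite(r.scores[predictor_b])
    ]
    if len(pairs) < 3:
        raise ValueError("need >= 3 complete score pairs")
    a, b = map(np.asarray, zip(*pairs))
    return {
        "pearson": float(stats.pearsonr(a, b).statistic),
        "spearman": float(stats.spearmanr(a, b).statistic),
        "n": len(pairs),
    }


def harmonize_and_ternary(
    ev_score: float,
    popmusic_score: float,
    snap2_score: float,
    ev_range: tuple[float, float],
    popmusic_range: tuple[float, float],
    snap2_range: tuple[float, float],
) -> tuple[float, float, float]:
    """Ternary composition of the three harmonized, min–max rescaled scores.

    Orientation is harmonized so higher = more deleterious (EVmutation is
    negated), each score is rescaled to [0, 1] on its *observed* range, and
    the triple is closed to sum 1.  An all-zero triple (every score at its
    most benign extreme) maps to the barycenter (1/3, 1/3, 1/3).
    """
    def rescale(value: float, lo: float, hi: float) -> float:
        if not (hi > lo):
            raise ValueError("degenerate score range")
        return (value - lo) / (hi - lo)

    # harmonize: negate EVmutation (and its range) so higher = deleterious
    t1 = rescale(-ev_score, -ev_range[1], -ev_range[0])
    t2 = rescale(popmusic_score, *popmusic_range)
    t3 = rescale(snap2_score, *snap2_range)
    total = t1 + t2 + t3
    if total == 0.0:
        return (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)
    return (t1 / total, t2 / total, t3 / total)


def region_classify(ev_score: float | None, snap2_score: float | None) -> str:
    """Two-region classification of the EVmutation × SNAP2 score plane.

    ``putatively_highly_pathogenic`` iff EV < −7.5 and SNAP2 > 70;
    ``putatively_benign`` iff −4 ≤ EV ≤ −2 and SNAP2 < −50; boundary values
    fall in ``other``; a missing score gives ``unclassified``.
    """
    if ev_score is None or snap2_score is None:
        return "unclassified"
    if isinstance(ev_score, float) and math.isnan(ev_score):
        return "unclassified"
    if isinstance(snap2_score, float) and math.isnan(snap2_score):
        return "unclassified"
    if ev_score < -7.5 and snap2_score > 70:
        return "putatively_highly_pathogenic"
    if -4.0 <= ev_score <= -2.0 and snap2_score < -50:
        return "putatively_benign"
    return "other"
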