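"""Synthetic inputs with known ground truth for every pipeline stage.

Three kinds of inputs are generated, each matching the file dialects the rest
of the package consumes:

* kinetic assays — Hill/Michaelis model curves plus Gaussian noise scaled to
  vmax, truncated at zero;
* variant score tables — class-conditional predictor scores.  The neutral
  (normoglycemic) class defaults are anchored to the published summary
  statistics of the real score distributions: EVmutation Normal(−2.39, 1.96),
  PoPMuSiC ΔΔG Normal(0.58, 0.42), SNAP2 Normal(−58, 32.25), where each SD is
  derived from the printed center and calibrated threshold as
  (threshold − center)/k with k = 2.  Disease-class defaults are plausible
  placeholders (documented in the methods note), not literature-derived;
* protein alignments — 12 sequences with an exact planted fraction of
  invariant columns, optional per-column residue pools, and a truth table;
  plus per-residue disease-family counts negatively coupled to GV.

Randomness: one global seed is expanded into named child streams
(``_rng(seed, stream)``) so adding a generator never shifts the draws of an
existing one.  The same seed always yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .evaluation import AA_ORDER, VariantRecord
from .kinetics import KineticAssay, KineticParams, activity

__all__ = [
    "ScoreDistributionSpec",
    "NEUTRAL_SCORE_DEFAULTS",
    "DISEASE_SCORE_DEFAULTS",
    "DEFAULT_CLASS_SIZES",
    "AssayDesign",
    "gen_assay",
    "gen_variant_table",
    "gen_alignment",
    "gen_family_counts",
    "gen_reference_sequence",
]

_STREAMS = {"assay": 0, "scores": 1, "alignment": 2, "families": 3, "sequence": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=(_STREAMS[stream],)))


@dataclass(frozen=True)
class ScoreDistributionSpec:
    """Distribution of one predictor's scores within one phenotype class."""

    family: str = "normal"  # normal | lognormal
    location: float = 0.0
    scale: float = 1.0
    lower: float = -np.inf
    upper: float = np.inf
    missingness: float = 0.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if not (0 <= self.missingness < 1):
            raise ValueError("missingness must lie in [0, 1)")
        if self.family not in {"normal", "lognormal"}:
            raise ValueError(f"unknown distribution family {self.family!r}")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "normal":
            x = rng.normal(self.location, self.scale, size=n)
        else:
            x = rng.lognormal(self.location, self.scale, size=n)
        return np.clip(x, self.lower, self.upper)


# Neutral-class defaults anchored to published center/threshold pairs
# (SD = (threshold - center)/2).
NEUTRAL_SCORE_DEFAULTS: dict[str, ScoreDistributionSpec] = {
    "evmutation": ScoreDistributionSpec("normal", -2.39, 1.96),
    "popmusic_ddg": ScoreDistributionSpec("normal", 0.58, 0.42),
    "snap2": ScoreDistributionSpec("normal", -58.0, 32.25, lower=-100.0, upper=100.0),
}

# Disease-class placeholders: inactivating (MODY-like) variants sit deep in
# the deleterious tail of each score, activating (PHHI-like) variants overlap
# the neutral range — mirroring the observed inability of the predictors to
# separate activating from benign substitutions.
DISEASE_SCORE_DEFAULTS: dict[str, dict[str, ScoreDistributionSpec]] = {
    "MODY": {
        "evmutation": ScoreDistributionSpec("normal", -6.5, 1.8),
        "popmusic_ddg": ScoreDistributionSpec("normal", 1.6, 0.8),
        "snap2": ScoreDistributionSpec("normal", 40.0, 30.0, lower=-100.0, upper=100.0),
    },
    "PHHI": {
        "evmutation": ScoreDistributionSpec("normal", -3.5, 1.5),
        "popmusic_ddg": ScoreDistributionSpec("normal", 0.9, 0.5),
        "snap2": ScoreDistributionSpec("normal", -20.0, 35.0, lower=-100.0, upper=100.0),
    },
}

#: Class composition of the real variant catalogue: 499 MODY- and 16
#: PHHI-associated substitutions plus 53 normoglycemic ones.
DEFAULT_CLASS_SIZES: dict[str, int] = {"MODY": 499, "PHHI": 16, "normoglycemic": 53}


@dataclass(frozen=True)
class AssayDesign:
    """Measurement grid for one generated titration."""

    kind: str = "glucose_titration"
    x: tuple[float, ...] = (0.5, 1, 2, 5, 10, 20, 50, 100, 150)
    atp_mM: float = 5.0
    glucose_mM: float | None = None
    replicates: int = 3


def gen_assay(
    params: KineticParams,
    design: AssayDesign | None = None,
    noise_sigma: float = 0.02,
    seed: int = 0,
) -> KineticAssay:
    """Simulate a titration: model rates plus Normal(0, sigma·vmax) noise.

    ``noise_sigma`` is relative to ``kcat``; negative draws are truncated at
    zero.  With ``noise_sigma = 0`` the rates lie exactly on the model curve.
    """
    design = design or AssayDesign()
    rng = _rng(seed, "assay")
    x = np.tile(np.asarray(design.x, dtype=float), design.replicates)
    if design.kind == "glucose_titration":
        ideal = np.array([activity(params, g, design.atp_mM) for g in x])
    elif design.kind == "atp_titration":
        if design.glucose_mM is None:
            raise ValueError("atp_titration design needs a fixed glucose_mM")
        ideal = np.array([activity(params, design.glucose_mM, a) for a in x])
    else:
        raise ValueError(f"cannot generate assay kind {design.kind!r}")
    vmax = params.kcat or 1.0
    noisy = ideal + rng.normal(0.0, noise_sigma * vmax, size=ideal.shape) if noise_sigma else ideal
    noisy = np.clip(noisy, 0.0, None)
    return KineticAssay(
        assay_kind=design.kind,
        x=x,
        rate=noisy,
        variant=params.name,
        glucose_mM=design.glucose_mM,
        atp_mM=design.atp_mM if design.kind == "glucose_titration" else None,
        replicate=np.repeat(np.arange(design.replicates), len(design.x)),
    )


def gen_reference_sequence(length: int = 465, seed: int = 0) -> str:
    """A synthetic reference protein sequence of the given length.

    Stands in for the 465-residue glucokinase isoform-1 sequence in tests and
    simulations; it is a random sequence, not the real protein.
    """
    rng = _rng(seed, "sequence")
    return "".join(rng.choice(AA_ORDER, size=length))


def gen_variant_table(
    n_per_class: Mapping[str, int] | None = None,
    neutral_spec: Mapping[str, ScoreDistributionSpec] | None = None,
    disease_spec: Mapping[str, Mapping[str, ScoreDistributionSpec]] | None = None,
    sequence: str | None = None,
    seed: int = 0,
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Class-labelled variant records with class-conditional scores.

    Returns the records and a ground-truth manifest (one row per
    class × predictor with the generating distribution).  Positions and
    substituted residues are drawn uniformly over ``sequence`` (a synthetic
    465-mer by default); variants are unique within the table.
    """
    n_per_class = dict(n_per_class or DEFAULT_CLASS_SIZES)
    neutral = dict(neutral_spec or NEUTRAL_SCORE_DEFAULTS)
    disease = {k: dict(v) for k, v in (disease_spec or DISEASE_SCORE_DEFAULTS).items()}
    rng = _rng(seed, "scores")
    sequence = sequence or gen_reference_sequence(seed=seed)
    L = len(sequence)

    specs_by_class: dict[str, Mapping[str, ScoreDistributionSpec]] = {}
    for cls in n_per_class:
        if cls == "normoglycemic":
            specs_by_class[cls] = neutral
        else:
            specs_by_class[cls] = disease.get(cls, neutral)

    # sample distinct (position, alt) pairs across the whole table
    total = sum(n_per_class.values())
    if total > 19 * L:
        raise ValueError("more variants requested than distinct substitutions exist")
    flat = rng.choice(19 * L, size=total, replace=False)
    records: list[VariantRecord] = []
    manifest_rows = []
    i = 0
    for cls, n in n_per_class.items():
        spec = specs_by_class[cls]
        drawn = {name: dist.draw(rng, n) for name, dist in spec.items()}
        miss = {name: rng.random(n) < dist.missingness for name, dist in spec.items()}
        for name, dist in spec.items():
            manifest_rows.append({
                "class": cls, "predictor": name, "family": dist.family,
                "location": dist.location, "scale": dist.scale,
                "missingness": dist.missingness, "n": n,
            })
        for j in range(n):
            code = int(flat[i]); i += 1
            pos = code // 19 + 1
            ref = sequence[pos - 1]
            alts = [a for a in AA_ORDER if a != ref]
            alt = alts[code % 19]
            scores = {
                name: float(drawn[name][j])
                for name in spec
                if not miss[name][j]
            }
            records.append(VariantRecord(ref_aa=ref, position=pos, alt_aa=alt,
                                         phenotype=cls, scores=scores))
    return records, pd.DataFrame(manifest_rows)


def gen_alignment(
    L: int,
    n_species: int = 12,
    invariant_fraction: float = 0.65,
    residue_pools: Sequence[Sequence[str]] = ("TS", "VI", "ILMV", "DE", "KRQ", "FYW", "AST"),
    planted: Mapping[int, Sequence[str]] | None = None,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """An ungapped protein alignment with a planted conservation structure.

    Exactly ``round(L * invariant_fraction)`` columns are invariant; the
    remaining columns draw every sequence's residue from a randomly chosen
    pool (guaranteeing >= 2 distinct residues per variable column).
    ``planted`` forces specific 1-based positions to realize exactly a given
    residue set, e.g. ``{332: "TS"}`` to plant a known-GV column.  Returns
    ``(records, truth)`` where records are (id, sequence) pairs and truth
    lists each column's residue set and invariance flag.
    """
    if not (0.0 <= invariant_fraction <= 1.0):
        raise ValueError("invariant_fraction must lie in [0, 1]")
    if n_species < 2:
        raise ValueError("need at least 2 species")
    pools = [tuple(dict.fromkeys(p)) for p in residue_pools]
    if any(len(p) < 2 for p in pools):
        raise ValueError("every residue pool needs >= 2 distinct residues")
    planted = {int(k): tuple(dict.fromkeys(v)) for k, v in (planted or {}).items()}
    for pos, resset in planted.items():
        if not (1 <= pos <= L):
            raise ValueError(f"planted position {pos} outside 1..{L}")
        if not resset:
            raise ValueError("planted residue set must be non-empty")

    rng = _rng(seed, "alignment")
    n_invariant = round(L * invariant_fraction)
    # planted multi-residue columns must be variable; planted singletons invariant
    forced_variable = {p for p, s in planted.items() if len(s) > 1}
    forced_invariant = {p for p, s in planted.items() if len(s) == 1}
    free = [p for p in range(1, L + 1) if p not in planted]
    n_free_invariant = n_invariant - len(forced_invariant)
    if not (0 <= n_free_invariant <= len(free)):
        raise ValueError("invariant_fraction incompatible with planted columns")
    invariant_pos = set(rng.choice(free, size=n_free_invariant, replace=False).tolist())
    invariant_pos |= forced_invariant

    cols: list[tuple[str, ...]] = []
    truth_rows = []
    for pos in range(1, L + 1):
        if pos in planted:
            resset = planted[pos]
            if len(resset) == 1:
                col = resset * n_species
            else:
                # each residue appears at least once, remainder drawn from the set
                base = list(resset)
                extra = rng.choice(list(resset), size=n_species - len(resset)).tolist()
                col = tuple(base + extra)
        elif pos in invariant_pos:
            col = (str(rng.choice(AA_ORDER)),) * n_species
        else:
            pool = pools[int(rng.integers(len(pools)))]
            base = list(rng.choice(pool, size=2, replace=False))
            extra = rng.choice(pool, size=n_species - 2).tolist()
            col = tuple(base + extra)
        cols.append(col)
        truth_rows.append({
            "position": pos,
            "residue_set": "".join(sorted(set(col))),
            "invariant": len(set(col)) == 1,
        })

    ids = ["ref"] + [f"species_{i}" for i in range(1, n_species)]
    seqs = ["".join(col[i] for col in cols) for i in range(n_species)]
    return list(zip(ids, seqs)), pd.DataFrame(truth_rows)


def gen_family_counts(
    gv_values: Sequence[float],
    coupling: float = 1.5,
    mean_at_zero_gv: float = 3.0,
    gv_scale: float = 60.0,
    dispersion: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Per-residue disease-family counts negatively coupled to GV.

    Counts are negative-binomial with log-mean
    ``log(mean_at_zero_gv) − coupling · gv/gv_scale`` and shape
    ``dispersion`` — conserved positions (low GV) accumulate more affected
    families.  ``coupling = 0`` decouples the two.
    """
    g = np.nan_to_num(np.asarray(gv_values, dtype=float), nan=0.0)
    if coupling < 0:
        raise ValueError("coupling must be >= 0 (negative association is implied)")
    rng = _rng(seed, "families")
    mu = mean_at_zero_gv * np.exp(-coupling * g / gv_scale)
    p = dispersion / (dispersion + mu)
    return rng.negative_binomial(dispersion, p)
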