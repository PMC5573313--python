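"""Grantham physicochemical distances and alignment conservation profiling.

The Grantham distance between two amino acids combines three side-chain
properties — composition ``c`` (atomic weight ratio of non-carbon elements),
polarity ``p`` and molecular volume ``v`` (A^3) — as

    D(a, b) = rho * sqrt(alpha*(dc)^2 + beta*(dp)^2 + gamma*(dv)^2)

with the 1974 coefficients alpha = 1.833, beta = 0.1018, gamma = 0.000399 and
the scale rho = 50.723 chosen so the mean pairwise distance is 100.

Two column-level scores extend the pairwise distance to a multiple sequence
alignment, following the Align-GVGD convention:

* Grantham Variation (GV): the distance formula applied to the *ranges* of
  c, p, v over the residues observed in a column.  GV = 0 for an invariant
  column; a column with high GV tolerates physicochemically diverse residues.
* Grantham Deviation (GD): the distance from a mutant residue's properties to
  the observed [min, max] property intervals (0 when the mutant falls inside
  all three ranges).

A GV below 61.3 is treated as "highly conserved" by default, the rule used to
relate glucokinase conservation to the frequency of disease-associated
families.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GRANTHAM_PROPERTIES",
    "GranthamTable",
    "AlignmentColumn",
    "grantham_distance",
    "gv",
    "gd",
    "map_alignment",
    "conservation_profile",
    "conservation_frequency_corr",
    "reference_integer_matrix",
]

#: Side-chain composition, polarity and volume for the 20 standard residues
#: (Grantham 1974 property values).
GRANTHAM_PROPERTIES: dict[str, tuple[float, float, float]] = {
    #      c      p      v
    "A": (0.00,  8.1,  31.0),
    "R": (0.65, 10.5, 124.0),
    "N": (1.33, 11.6,  56.0),
    "D": (1.38, 13.0,  54.0),
    "C": (2.75,  5.5,  55.0),
    "Q": (0.89, 10.5,  85.0),
    "E": (0.92, 12.3,  83.0),
    "G": (0.74,  9.0,   3.0),
    "H": (0.58, 10.4,  96.0),
    "I": (0.00,  5.2, 111.0),
    "L": (0.00,  4.9, 111.0),
    "K": (0.33, 11.3, 119.0),
    "M": (0.00,  5.7, 105.0),
    "F": (0.00,  5.2, 132.0),
    "P": (0.39,  8.0,  32.5),
    "S": (1.42,  9.2,  32.0),
    "T": (0.71,  8.6,  61.0),
    "W": (0.13,  5.4, 170.0),
    "Y": (0.20,  6.2, 136.0),
    "V": (0.00,  5.9,  84.0),
}

STANDARD_RESIDUES = frozenset(GRANTHAM_PROPERTIES)


class UnknownResidueError(ValueError):
    """A residue code outside the 20-letter standard alphabet."""


@dataclass(frozen=True)
class GranthamTable:
    """Property table plus the formula coefficients.

    All coefficients must be positive; the default table carries the 1974
    values, which reproduce the unrounded anchors D(T,S) = 57.75 and
    D(V,I) = 29.61.
    """

    properties: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(GRANTHAM_PROPERTIES)
    )
    alpha: float = 1.833
    beta: float = 0.1018
    gamma: float = 0.000399
    rho: float = 50.723

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0 and self.gamma > 0 and self.rho > 0):
            raise ValueError("Grantham coefficients alpha, beta, gamma, rho must be > 0")
        missing = STANDARD_RESIDUES - set(self.properties)
        if missing:
            raise ValueError(f"property table missing residues: {sorted(missing)}")

    def props(self, residue: str) -> tuple[float, float, float]:
        try:
            return self.properties[residue]
        except KeyError:
            raise UnknownResidueError(f"unknown residue code: {residue!r}") from None


_DEFAULT_TABLE = GranthamTable()


def _combine(table: GranthamTable, dc: float, dp: float, dv: float) -> float:
    return table.rho * math.sqrt(
        table.alpha * dc * dc + table.beta * dp * dp + table.gamma * dv * dv
    )


def grantham_distance(a: str, b: str, table: GranthamTable | None = None) -> float:
    """Unrounded Grantham distance between residues ``a`` and ``b``.

    Symmetric, non-negative and zero iff ``a == b`` (property triples are
    unique among the 20 residues).
    """
    table = table or _DEFAULT_TABLE
    ca, pa, va = table.props(a)
    cb, pb, vb = table.props(b)
    return _combine(table, ca - cb, pa - pb, va - vb)


def gv(residues: Iterable[str], table: GranthamTable | None = None) -> float:
    """Grantham Variation of an alignment column.

    ``residues`` is the multiset observed in the column; duplicates are
    ignored (the score depends only on property ranges).  Returns 0 for an
    invariant column and reduces to :func:`grantham_distance` for a
    two-residue column.
    """
    table = table or _DEFAULT_TABLE
    observed = set(residues)
    if not observed:
        raise ValueError("cannot score an empty residue set")
    triples = [table.props(r) for r in observed]
    cs, ps, vs = zip(*triples)
    return _combine(table, max(cs) - min(cs), max(ps) - min(ps), max(vs) - min(vs))


def gd(residues: Iterable[str], mutant: str, table: GranthamTable | None = None) -> float:
    """Grantham Deviation of ``mutant`` from the residues observed in a column.

    Zero iff each of the mutant's three properties lies within the observed
    [min, max] range; for a single-residue column this equals the pairwise
    distance to that residue.
    """
    table = table or _DEFAULT_TABLE
    observed = set(residues)
    if not observed:
        raise ValueError("cannot score an empty residue set")
    cm, pm, vm = table.props(mutant)
    triples = [table.props(r) for r in observed]
    cs, ps, vs = zip(*triples)

    def dev(x: float, lo: float, hi: float) -> float:
        if x < lo:
            return lo - x
        if x > hi:
            return x - hi
        return 0.0

    return _combine(
        table,
        dev(cm, min(cs), max(cs)),
        dev(pm, min(ps), max(ps)),
        dev(vm, min(vs), max(vs)),
    )


@dataclass(frozen=True)
class AlignmentColumn:
    """Residues observed at one reference position of the alignment.

    ``ref_position`` is 1-based in the ungapped reference sequence; gap
    characters are excluded from ``residues`` and counted in ``n_gaps``.
    """

    ref_position: int
    residues: tuple[str, ...]
    n_gaps: int = 0

    def __post_init__(self) -> None:
        if self.ref_position < 1:
            raise ValueError("ref_position must be >= 1")
        bad = set(self.residues) - STANDARD_RESIDUES
        if bad:
            raise UnknownResidueError(f"non-standard residues in column: {sorted(bad)}")

    @property
    def n_species(self) -> int:
        return len(self.residues) + self.n_gaps

    @property
    def invariant(self) -> bool:
        return len(set(self.residues)) == 1

    @property
    def scorable(self) -> bool:
        # A single ungapped sequence carries no variation information.
        return len(self.residues) >= 2


GAP_CHARS = frozenset("-.")


def map_alignment(alignment, ref_id: str) -> list[AlignmentColumn]:
    """Project an alignment onto the ungapped reference coordinate system.

    ``alignment`` is anything iterable over records with ``.id`` and string
    sequence (``str(record.seq)`` or the record itself if a ``(id, seq)``
    pair) — Bio.Align.MultipleSeqAlignment and lists of SeqRecord both work.
    Returns one :class:`AlignmentColumn` per non-gap reference position,
    numbered 1..L.  Alignment columns where the reference has a gap are
    dropped (insertions relative to the reference).
    """
    seqs: dict[str, str] = {}
    for rec in alignment:
        if isinstance(rec, tuple):
            name, seq = rec
        else:
            name, seq = rec.id, str(rec.seq)
        seqs[name] = seq.upper()
    if ref_id not in seqs:
        raise KeyError(f"reference id {ref_id!r} not present in alignment")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: sequence lengths {sorted(lengths)}")
    ref = seqs[ref_id]
    allowed = STANDARD_RESIDUES | GAP_CHARS
    for name, s in seqs.items():
        bad = set(s) - allowed
        if bad:
            raise UnknownResidueError(
                f"sequence {name!r} contains non-IUPAC characters: {sorted(bad)}"
            )

    columns: list[AlignmentColumn] = []
    pos = 0
    for j, ref_char in enumerate(ref):
        if ref_char in GAP_CHARS:
            continue
        pos += 1
        residues = []
        n_gaps = 0
        for s in seqs.values():
            ch = s[j]
            if ch in GAP_CHARS:
                n_gaps += 1
            else:
                residues.append(ch)
        columns.append(AlignmentColumn(ref_position=pos, residues=tuple(residues), n_gaps=n_gaps))
    return columns


def conservation_profile(
    columns: Sequence[AlignmentColumn],
    gv_threshold: float = 61.3,
    table: GranthamTable | None = None,
) -> pd.DataFrame:
    """Per-position GV, invariance and conservation flags.

    Returns a DataFrame indexed 0..L-1 with columns ``position`` (1-based),
    ``residues_observed``, ``n_species``, ``n_gaps``, ``gv``, ``invariant``,
    ``conserved`` and ``scorable``.  Columns with fewer than two ungapped
    residues are flagged unscorable (``gv`` is NaN, flags False) rather than
    scored zero.  ``conserved`` is ``gv < gv_threshold``.
    """
    rows = []
    for col in sorted(columns, key=lambda c: c.ref_position):
        if col.scorable:
            g = gv(col.residues, table)
            invariant = col.invariant
            conserved = g < gv_threshold
        else:
            g, invariant, conserved = float("nan"), False, False
        rows.append(
            {
                "position": col.ref_position,
                "residues_observed": "".join(sorted(set(col.residues))),
                "n_species": col.n_species,
                "n_gaps": col.n_gaps,
                "gv": g,
                "invariant": invariant,
                "conserved": conserved,
                "scorable": col.scorable,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        expected = list(range(1, len(df) + 1))
        if list(df["position"]) != expected:
            raise ValueError("columns do not cover contiguous reference positions 1..L")
    return df


def conservation_frequency_corr(
    gv_values: Sequence[float], family_counts: Sequence[float]
) -> dict[str, float]:
    """Correlate per-position GV with per-position disease-family counts.

    Positions never reported mutated enter with a count of zero, so the
    vectors cover the whole reference length.  Returns Pearson r and
    Spearman rho (midrank ties) with two-sided p-values and n.
    """
    g = np.asarray(gv_values, dtype=float)
    f = np.asarray(family_counts, dtype=float)
    if g.shape != f.shape:
        raise ValueError("gv_values and family_counts must have equal length")
    mask = np.isfinite(g) & np.isfinite(f)
    g, f = g[mask], f[mask]
    if g.size < 3:
        raise ValueError("need at least 3 positions with finite values")
    if np.ptp(g) == 0 or np.ptp(f) == 0:
        raise ValueError("correlation undefined for a constant vector")
    pr, pp = stats.pearsonr(g, f)
    sr, sp = stats.spearmanr(g, f)
    return {
        "pearson_r": float(pr),
        "pearson_p": float(pp),
        "spearman_rho": float(sr),
        "spearman_p": float(sp),
        "n": int(g.size),
    }


def reference_integer_matrix() -> pd.DataFrame:
    """The packaged integer Grantham distance matrix (20 x 20, symmetric)."""
    with resources.files("gckvar.data").joinpath("grantham_matrix_1974.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", index_col=0)
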