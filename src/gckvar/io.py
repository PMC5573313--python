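"""File formats, configuration and the end-to-end pipeline driver.

All tabular interchange is tab-separated UTF-8 with ``#`` comment headers;
alignments are aligned FASTA with ``-`` gaps; configuration is YAML.  Score
columns may contain typographic minus signs (U+2212) as found in published
supplementary tables; they are normalized to ASCII on input.  Residue
numbering is 1-based on the reference isoform throughout.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import calibration, evaluation, grantham, synthetic
from .evaluation import VariantRecord
from .kinetics import (
    BetaCellModelConfig,
    CensoredValue,
    KineticParams,
    compute_rai,
    gsir_threshold,
)

__all__ = [
    "SCORE_COLUMNS",
    "RunConfig",
    "parse_variant_table",
    "write_variant_table",
    "read_alignment",
    "write_alignment",
    "load_published_kinetics",
    "published_kinetic_params",
    "write_tsv",
    "run_pipeline",
]

log = logging.getLogger("gckvar")

SCORE_COLUMNS = [
    "sift", "polyphen2", "phd_snp", "popmusic_ddg", "snap2",
    "snpsgo", "snpsgo_go", "imutant3", "agvgd_gv", "agvgd_gd", "evmutation",
]

_HGVS_RE = re.compile(r"^(?:p\.)?([A-Z])(\d+)([A-Z])$")


def _normalize_minus(value):
    if isinstance(value, str):
        return value.replace("−", "-").strip()
    return value


def parse_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read a variant TSV into records.

    Accepts either an HGVS-style ``variant`` column (``p.V33A`` or ``V33A``),
    the triplet columns ``ref_aa``/``position``/``alt_aa``, or both — in
    which case they are cross-validated.  Sparse scores stay missing.
    Duplicate variants, unknown residue codes and notation/column mismatches
    raise with the offending line.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    df = df.map(_normalize_minus)
    records: list[VariantRecord] = []
    seen: dict[str, int] = {}
    for idx, row in df.iterrows():
        line = idx + 2  # 1-based, after header
        ref = pos = alt = None
        if "variant" in df.columns and isinstance(row.get("variant"), str):
            m = _HGVS_RE.match(row["variant"])
            if not m:
                raise ValueError(f"line {line}: cannot parse variant {row['variant']!r}")
            ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        if {"ref_aa", "position", "alt_aa"} <= set(df.columns) and isinstance(
            row.get("ref_aa"), str
        ):
            ref2, pos2, alt2 = row["ref_aa"], int(row["position"]), row["alt_aa"]
            if ref is not None and (ref, pos, alt) != (ref2, pos2, alt2):
                raise ValueError(
                    f"line {line}: variant notation {ref}{pos}{alt} disagrees with "
                    f"columns {ref2}{pos2}{alt2}"
                )
            ref, pos, alt = ref2, pos2, alt2
        if ref is None:
            raise ValueError(f"line {line}: no variant identification columns")

        scores = {}
        for col in SCORE_COLUMNS:
            if col in df.columns:
                raw = row[col]
                if isinstance(raw, str) and raw != "":
                    scores[col] = float(raw)

        gsirt = None
        if "gsirt" in df.columns and isinstance(row.get("gsirt"), str) and row["gsirt"]:
            censor = row.get("gsirt_censor")
            censor = censor if isinstance(censor, str) and censor else None
            gsirt = CensoredValue(float(row["gsirt"]), censor=censor)
        n_h = None
        if "hill" in df.columns and isinstance(row.get("hill"), str) and row["hill"]:
            n_h = float(row["hill"])
        fams = 0
        if "families" in df.columns and isinstance(row.get("families"), str) and row["families"]:
            fams = int(float(row["families"]))
        phenotype = row.get("phenotype") or "unknown"

        try:
            rec = VariantRecord(
                ref_aa=ref, position=pos, alt_aa=alt, phenotype=phenotype,
                scores=scores, family_count=fams, gsirt=gsirt, n_h=n_h,
            )
        except ValueError as exc:
            raise ValueError(f"line {line}: {exc}") from None
        if rec.name in seen:
            raise ValueError(
                f"line {line}: duplicate variant {rec.name} (first at line {seen[rec.name]})"
            )
        seen[rec.name] = line
        records.append(rec)
    return records


def _record_row(rec: VariantRecord) -> dict:
    row = {
        "variant": rec.hgvs_p,
        "position": rec.position,
        "ref_aa": rec.ref_aa,
        "alt_aa": rec.alt_aa,
        "phenotype": rec.phenotype,
        "families": rec.family_count,
    }
    for col in SCORE_COLUMNS:
        row[col] = rec.scores.get(col, "")
    row["gsirt"] = rec.gsirt.value if rec.gsirt is not None else ""
    row["gsirt_censor"] = (rec.gsirt.censor or "") if rec.gsirt is not None else ""
    row["hill"] = rec.n_h if rec.n_h is not None else ""
    return row


def write_variant_table(
    records: Sequence[VariantRecord], path: str | Path, header_comment: str = ""
) -> None:
    """Write records in the canonical column order (round-trips with the parser)."""
    df = pd.DataFrame([_record_row(r) for r in records])
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_alignment(path: str | Path):
    """Aligned FASTA -> Bio.Align.MultipleSeqAlignment."""
    return AlignIO.read(str(path), "fasta")


def write_alignment(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    """(id, sequence) pairs -> aligned FASTA."""
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records]
    SeqIO.write(seqs, str(path), "fasta")


def write_tsv(df: pd.DataFrame, path: str | Path, config_hash: str = "") -> None:
    """Write a result table, stamping the config hash in a comment header."""
    with open(path, "w", encoding="utf-8") as fh:
        if config_hash:
            fh.write(f"# config_sha256={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def load_published_kinetics() -> pd.DataFrame:
    """The packaged table of published kinetic constants (wild type + 19 variants)."""
    with resources.files("gckvar.data").joinpath("table1_kinetics.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def published_kinetic_params() -> dict[str, KineticParams]:
    """Published constants as :class:`KineticParams`, keyed by variant name.

    The ATP KM fed to the activity model is the one measured at S0.5; where
    only the 50 mM-glucose value was reported it is used as a fallback
    (``km_source`` column).
    """
    out: dict[str, KineticParams] = {}
    for _, row in load_published_kinetics().iterrows():
        km = row["km_atp_at_s05"] if row["km_source"] == "s05" else row["km_atp_at_50mM"]
        out[row["variant"]] = KineticParams(
            name=row["variant"],
            s05=None if pd.isna(row["s05_5mM_atp"]) else float(row["s05_5mM_atp"]),
            n_h=None if pd.isna(row["n_h"]) else float(row["n_h"]),
            kcat=None if pd.isna(row["kcat"]) else float(row["kcat"]),
            km_atp=None if pd.isna(km) else float(km),
            stability_pct=None if pd.isna(row["stability_pct"]) else float(row["stability_pct"]),
            no_activity=bool(row["no_activity"]),
        )
    return out


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; round-trips through YAML."""

    out_dir: str = "results/run"
    seed: int = 0
    variant_table: str | None = None      # TSV; None -> simulate
    alignment: str | None = None          # aligned FASTA; None -> simulate
    family_counts: str | None = None      # TSV position/families; None -> simulate
    n_per_class: dict = field(default_factory=lambda: dict(synthetic.DEFAULT_CLASS_SIZES))
    calibrate_predictors: tuple[str, ...] = ("evmutation", "popmusic_ddg", "snap2")
    k: float = 2.0
    gv_threshold: float = 61.3
    ref_length: int = 465
    n_species: int = 12
    invariant_fraction: float = 301 / 465
    beta_cell: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if "calibrate_predictors" in raw:
            raw["calibrate_predictors"] = tuple(raw["calibrate_predictors"])
        return cls(**raw)

    def sha256(self) -> str:
        # out_dir and log level do not affect the computation
        d = dataclasses.asdict(self)
        d.pop("out_dir"), d.pop("log_level")
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Run every feasible stage and write a manifest; deterministic per config.

    Stage order follows the analysis: kinetics (RAI/GSIR-T from the published
    constants) -> threshold calibration -> per-class evaluation ->
    conservation profiling.  Missing inputs are simulated from the config's
    seed; infeasible stages are skipped with a log entry.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.sha256()
    manifest: dict = {"config": dataclasses.asdict(config), "config_sha256": chash,
                      "inputs": {}, "stages": []}

    # --- stage 0: inputs (load or simulate) ---------------------------------
    if config.variant_table:
        records = parse_variant_table(config.variant_table)
        manifest["inputs"]["variant_table"] = _hash_file(Path(config.variant_table))
    else:
        records, truth = synthetic.gen_variant_table(
            n_per_class=config.n_per_class, seed=config.seed
        )
        write_tsv(truth, out / "score_truth.tsv", chash)
        write_variant_table(records, out / "variants.tsv", f"config_sha256={chash}")
    manifest["stages"].append("inputs")

    # --- stage 1: kinetics -> RAI / GSIR-T ----------------------------------
    params = published_kinetic_params()
    wt = params["WT"]
    cfg = BetaCellModelConfig(**config.beta_cell)
    krows = []
    for name, p in params.items():
        rai = compute_rai(p, wt, cfg)
        gs = gsir_threshold(p, wt, cfg)
        krows.append({
            "variant": name, "rai": rai.value, "rai_censor": rai.censor or "",
            "gsirt": gs.value, "gsirt_censor": gs.censor or "",
        })
    write_tsv(pd.DataFrame(krows), out / "kinetics_derived.tsv", chash)
    manifest["stages"].append("kinetics")

    # --- stage 2: calibration ------------------------------------------------
    neutral = [r for r in records if r.phenotype == "normoglycemic"]
    thresholds: dict[str, calibration.ThresholdResult] = {}
    trows = []
    for name in config.calibrate_predictors:
        spec = calibration.DEFAULT_PREDICTORS[name]
        scores = [r.scores[name] for r in neutral if name in r.scores]
        if len(scores) < 3:
            log.warning("calibration skipped for %s: %d neutral scores", name, len(scores))
            continue
        thr = calibration.evidence_threshold(scores, spec, k=config.k, ci_seed=config.seed)
        thresholds[name] = thr
        trows.append(dataclasses.asdict(thr))
    if trows:
        write_tsv(pd.DataFrame(trows), out / "thresholds.tsv", chash)
        manifest["stages"].append("calibration")

    # --- stage 3: evaluation -------------------------------------------------
    mrows = []
    for name, thr in thresholds.items():
        calls = {
            r.name: calibration.apply_threshold(r.scores.get(name, float("nan")), thr)
            for r in records if name in r.scores
        }
        cm = evaluation.class_metrics(records, calls, "phenotype")
        for _, row in cm.per_class.iterrows():
            mrows.append({"predictor": name, "grouping": "phenotype",
                          "class": row["class"], "n": row["n"],
                          "sensitivity_pct": round(row["sensitivity_pct"], 1)})
        mrows.append({"predictor": name, "grouping": "phenotype", "class": "disease_fp",
                      "n": cm.n_disease,
                      "sensitivity_pct": round(cm.false_positive_ratio, 1)})
    if mrows:
        write_tsv(pd.DataFrame(mrows), out / "class_metrics.tsv", chash)
        manifest["stages"].append("evaluation")

    # --- stage 4: conservation ----------------------------------------------
    if config.alignment:
        aln = read_alignment(config.alignment)
        columns = grantham.map_alignment(aln, ref_id=aln[0].id)
        manifest["inputs"]["alignment"] = _hash_file(Path(config.alignment))
    else:
        aln_records, _ = synthetic.gen_alignment(
            L=config.ref_length, n_species=config.n_species,
            invariant_fraction=config.invariant_fraction, seed=config.seed,
        )
        write_alignment(aln_records, out / "alignment.fasta")
        columns = grantham.map_alignment(aln_records, ref_id="ref")
    profile = grantham.conservation_profile(columns, gv_threshold=config.gv_threshold)
    write_tsv(profile, out / "conservation_profile.tsv", chash)
    if config.family_counts:
        fam = pd.read_csv(config.family_counts, sep="\t", comment="#")
        counts = fam.set_index("position").reindex(profile["position"])["families"]
        counts = counts.fillna(0).to_numpy()
        manifest["inputs"]["family_counts"] = _hash_file(Path(config.family_counts))
    else:
        counts = synthetic.gen_family_counts(profile["gv"].to_numpy(), seed=config.seed)
        write_tsv(pd.DataFrame({"position": profile["position"], "families": counts}),
                  out / "family_counts.tsv", chash)
    corr = grantham.conservation_frequency_corr(profile["gv"].to_numpy(), counts)
    write_tsv(pd.DataFrame([corr]), out / "conservation_corr.tsv", chash)
    manifest["stages"].append("conservation")

    manifest["outputs"] = {
        p.name: _hash_file(p) for p in sorted(out.iterdir()) if p.suffix in {".tsv", ".fasta"}
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
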