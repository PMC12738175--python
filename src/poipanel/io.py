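"""Readers and writers for the formats the pipeline touches.

TSV (tab-delimited, UTF-8, ``NA``/``na``/``.`` for missing), VCF v4.2
(SNV + indel subset via pysam), BED (0-based half-open) and JSON summaries.
Also exposes the packaged variant/patient/CNV reference tables used by the
golden-table tests.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, is_dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .types import PatientProfile, VARIANT_TYPES

__all__ = [
    "load_fixture",
    "load_cooccurrence",
    "check_fixture_integrity",
    "read_vcf",
    "write_vcf",
    "read_patients_tsv",
    "read_bed",
    "read_coverage_tsv",
    "write_summary_json",
    "read_summary_json",
    "FIXTURE_NAMES",
]

NA_VALUES = ["NA", "na", "."]
FIXTURE_NAMES = ("table1", "table2", "table3", "table4")

_FIXTURE_SCHEMAS = {
    "table1": {
        "n_patients": int,
        "gene": str,
        "variant_type": str,
        "aa_change": str,
        "gnomad_nfe_af": float,
        "eur_af_1kg": float,
        "sift": float,
        "polyphen": float,
        "cadd_phred": float,
        "mutation_taster": str,
        "grantham": float,
        "acmg_criteria": str,
        "classification": str,
    },
    "table3": {
        "patient_id": str,
        "gene": str,
        "chrom": str,
        "variant_type": str,
        "aa_change": str,
        "classification": str,
    },
    "table4": {
        "patient_id": str,
        "region": str,
        "chrom": str,
        "gene": str,
        "change": str,
        "length_bp": int,
        "co_occurring": str,
        "cadd_sv_phred": float,
        "strvctvre": float,
        "mvp": float,
    },
}
_FIXTURE_SCHEMAS["table2"] = _FIXTURE_SCHEMAS["table1"]


def _read_tsv(source, **kwargs) -> pd.DataFrame:
    return pd.read_csv(
        source,
        sep="\t",
        na_values=NA_VALUES,
        keep_default_na=False,
        **kwargs,
    )


def _fixture_path(name: str):
    return resources.files("poipanel").joinpath("data", f"{name}.tsv")


def load_fixture(name: str) -> pd.DataFrame:
    """Load one packaged reference table as a validated DataFrame.

    ``table1``/``table2`` carry variant records with predictor scores, the
    raw ACMG criteria string and the published classification; ``table3``
    maps monogenic patients to their variants; ``table4`` holds CNV regions
    with structural-variant scores.
    """
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
    path = _fixture_path(name)
    if not path.is_file():
        raise FileNotFoundError(f"packaged fixture missing: {path}")
    with path.open("r", encoding="utf-8") as handle:
        df = _read_tsv(handle)
    schema = _FIXTURE_SCHEMAS[name]
    missing = set(schema) - set(df.columns)
    if missing:
        raise ValueError(f"fixture {name}: missing columns {sorted(missing)}")
    for idx, row in df.iterrows():
        if "variant_type" in df.columns and row["variant_type"] not in VARIANT_TYPES:
            raise ValueError(
                f"fixture {name} row {idx}: bad variant_type {row['variant_type']!r}"
            )
        for col in ("gnomad_nfe_af", "eur_af_1kg"):
            if col in df.columns and pd.notna(row[col]) and row[col] < 0:
                raise ValueError(f"fixture {name} row {idx}: negative {col}")
    return df


def load_cooccurrence() -> pd.DataFrame:
    """Within-gene co-carrier adjustments for distinct-patient counting."""
    with _fixture_path("cooccurrence").open("r", encoding="utf-8") as handle:
        return _read_tsv(handle)


def check_fixture_integrity() -> dict:
    """Cross-table consistency of the packaged variant tables.

    Returns the summary counts; raises if a (gene, aa_change) key is
    duplicated across tables.
    """
    t1 = load_fixture("table1")
    t2 = load_fixture("table2")
    keys1 = set(zip(t1["gene"], t1["aa_change"]))
    keys2 = set(zip(t2["gene"], t2["aa_change"]))
    shared = keys1 & keys2
    if shared:
        raise ValueError(f"variant keys duplicated across tables: {sorted(shared)}")
    if len(keys1) != len(t1) or len(keys2) != len(t2):
        raise ValueError("duplicate variant key within a table")
    combined = pd.concat([t1, t2], ignore_index=True)
    return {
        "unique_variants": len(keys1 | keys2),
        "n_genes": combined["gene"].nunique(),
        "table1_rows": len(t1),
        "table2_rows": len(t2),
    }


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path) -> pd.DataFrame:
    """Read a VCF into per-sample, per-ALT call rows.

    One row per ALT allele per sample whose genotype carries that allele
    (hom-ref and no-call genotypes are dropped).  ``pos`` is converted to
    0-based.  Coverage comes from FORMAT/DP (falling back to INFO/DP),
    quality from QUAL.  Unparseable records are skipped with a warning.
    """
    rows = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            try:
                alts = rec.alts or ()
                for sample in samples:
                    call = rec.samples[sample]
                    gt = call.get("GT")
                    if gt is None or all(a in (None, 0) for a in gt):
                        continue
                    dp = call.get("DP")
                    if dp is None:
                        dp = rec.info.get("DP")
                    for alt_index, alt in enumerate(alts, start=1):
                        if alt_index not in gt:
                            continue
                        rows.append(
                            {
                                "sample_id": sample,
                                "chrom": rec.chrom,
                                "pos": rec.pos - 1,
                                "ref": rec.ref,
                                "alt": alt,
                                "gt": "/".join(
                                    "." if a is None else str(a) for a in gt
                                ),
                                "coverage": dp,
                                "quality": rec.qual,
                            }
                        )
            except Exception:  # malformed record: skip, keep count
                n_skipped += 1
    if n_skipped:
        warnings.warn(f"read_vcf: skipped {n_skipped} unparseable record(s)")
    df = pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "chrom",
            "pos",
            "ref",
            "alt",
            "gt",
            "coverage",
            "quality",
        ],
    )
    df.attrs["n_skipped"] = n_skipped
    return df


def write_vcf(calls: pd.DataFrame, path) -> None:
    """Write call rows (as produced by :func:`read_vcf`) back to VCF v4.2.

    Supports the same SNV/indel subset: one ALT per row, per-sample GT and
    DP.  Rows for the same (chrom, pos, ref, alt) site are merged into one
    record with per-sample genotype columns.
    """
    calls = calls.copy()
    samples = sorted(calls["sample_id"].unique())
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    for chrom in dict.fromkeys(calls["chrom"]):
        header.contigs.add(str(chrom))
    for sample in samples:
        header.add_sample(sample)
    site_cols = ["chrom", "pos", "ref", "alt"]
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for (chrom, pos, ref, alt), group in calls.groupby(site_cols, sort=True):
            rec = out.new_record(
                contig=str(chrom), start=int(pos), alleles=(str(ref), str(alt))
            )
            qual = group["quality"].dropna()
            if len(qual):
                rec.qual = float(qual.iloc[0])
            by_sample = group.set_index("sample_id")
            for sample in samples:
                if sample in by_sample.index:
                    row = by_sample.loc[sample]
                    gt = tuple(
                        None if a == "." else int(a) for a in str(row["gt"]).split("/")
                    )
                    rec.samples[sample]["GT"] = gt
                    if pd.notna(row["coverage"]):
                        rec.samples[sample]["DP"] = int(row["coverage"])
                else:
                    rec.samples[sample]["GT"] = (None, None)
            out.write(rec)


# ---------------------------------------------------------------------------
# Patient / panel / coverage tables


def read_patients_tsv(path) -> list[PatientProfile]:
    """Read patient profiles; ``exclusion_flags`` is a semicolon-separated list."""
    df = _read_tsv(path)
    profiles = []
    for _, row in df.iterrows():
        flags = row.get("exclusion_flags")
        if pd.isna(flags) or not str(flags).strip():
            flag_set: frozenset[str] = frozenset()
        else:
            flag_set = frozenset(
                token.strip() for token in str(flags).split(";") if token.strip()
            )
        profiles.append(
            PatientProfile(
                patient_id=str(row["patient_id"]),
                age=float(row["age"]),
                amh=None if pd.isna(row.get("amh")) else float(row["amh"]),
                fsh=None if pd.isna(row.get("fsh")) else float(row["fsh"]),
                e2=None if pd.isna(row.get("e2")) else float(row["e2"]),
                afc=None if pd.isna(row.get("afc")) else int(row["afc"]),
                fi=None if pd.isna(row.get("fi")) else float(row["fi"]),
                vi=None if pd.isna(row.get("vi")) else float(row["vi"]),
                vfi=None if pd.isna(row.get("vfi")) else float(row["vfi"]),
                exclusion_flags=flag_set,
            )
        )
    ids = [p.patient_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient_id in profiles table")
    return profiles


def read_bed(path, gc_sidecar=None) -> pd.DataFrame:
    """Read an amplicon panel BED (0-based half-open, identity on coordinates).

    Columns: chrom, start, end, amplicon_id.  An optional TSV sidecar with
    ``amplicon_id`` and ``gc_fraction`` columns is merged in.
    """
    panel = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "amplicon_id"],
        dtype={"chrom": str, "start": int, "end": int, "amplicon_id": str},
    )
    if (panel["start"] >= panel["end"]).any():
        raise ValueError("BED intervals must satisfy start < end")
    if gc_sidecar is not None:
        gc = _read_tsv(gc_sidecar)
        panel = panel.merge(gc[["amplicon_id", "gc_fraction"]], on="amplicon_id")
    return panel


def read_coverage_tsv(path) -> pd.DataFrame:
    """Read an amplicon x sample read-count matrix (first column amplicon_id)."""
    df = _read_tsv(path)
    return df.set_index(df.columns[0])


# ---------------------------------------------------------------------------
# JSON summaries


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_summary_json(summary, path) -> None:
    """Write a cohort summary (dataclass or dict) as JSON with sorted keys."""
    payload = _jsonable(summary)
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def read_summary_json(path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
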