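"""Cohort-level aggregation: diagnostic yield, variant spectrum, per-gene
carrier counts, monogenic/polygenic partition and CNV prevalence."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .acmg import patient_classification
from .cnv import tier_sv_scores
from .types import SVScoreSet, classification_rank

__all__ = [
    "CohortSummary",
    "summarize_variants",
    "gene_patient_counts",
    "partition_patients",
    "summarize_cnv",
    "build_cohort_summary",
]


@dataclass
class CohortSummary:
    """Headline statistics of one analyzed cohort.

    Invariants: ``n_mutated + n_negative == n_patients``; variant-type
    counts sum to ``unique_variants``; ``monogenic`` plus the polygenic
    counts sum to ``n_mutated``.  Percentages are always recomputed from the
    counts, never stored.
    """

    n_patients: int = 0
    n_mutated: int = 0
    n_negative: int = 0
    n_lp_p_patients: int = 0
    n_vus_only_patients: int = 0
    unique_variants: int = 0
    variants_by_type: dict = field(default_factory=dict)
    genes: dict = field(default_factory=dict)
    classification_counts: dict = field(default_factory=dict)
    monogenic: int = 0
    polygenic: dict = field(default_factory=dict)
    cnv_patient_count: int = 0
    cnv_tier_counts: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_mutated + self.n_negative != self.n_patients:
            raise ValueError("n_mutated + n_negative != n_patients")
        if self.variants_by_type and sum(self.variants_by_type.values()) != self.unique_variants:
            raise ValueError("variant type counts do not sum to unique_variants")
        if (self.monogenic or self.polygenic) and (
            self.monogenic + sum(self.polygenic.values()) != self.n_mutated
        ):
            raise ValueError("monogenic + polygenic != n_mutated")


def _percent(count: int, total: int) -> float:
    return round(100.0 * count / total, 1) if total else 0.0


def summarize_variants(classified: pd.DataFrame) -> dict:
    """Type / gene / classification counts over unique variants.

    Expects one row per unique variant with ``gene``, ``variant_type`` and a
    classification column (``computed_classification`` if present, else
    ``classification``).  Percentages are rounded to one decimal.
    """
    if classified.empty:
        return {
            "unique_variants": 0,
            "n_genes": 0,
            "variants_by_type": {},
            "variants_by_type_pct": {},
            "classification_counts": {},
        }
    cls_col = (
        "computed_classification"
        if "computed_classification" in classified.columns
        else "classification"
    )
    n = len(classified)
    by_type = classified["variant_type"].value_counts().to_dict()
    return {
        "unique_variants": n,
        "n_genes": int(classified["gene"].nunique()),
        "variants_by_type": {k: int(v) for k, v in by_type.items()},
        "variants_by_type_pct": {k: _percent(v, n) for k, v in by_type.items()},
        "classification_counts": {
            k: int(v) for k, v in classified[cls_col].value_counts().to_dict().items()
        },
    }


def gene_patient_counts(
    variants: pd.DataFrame, cooccurrence: pd.DataFrame | None = None
) -> pd.Series:
    """Distinct patients per gene from per-variant carrier counts.

    Carriers of two variants of the same gene would be double-counted by a
    straight sum, so known within-gene co-occurrences are supplied as
    adjustment records (gene, variant_a, variant_b, n_patients) and
    subtracted.  Referencing an unknown variant is fatal.
    """
    counts = variants.groupby("gene")["n_patients"].sum()
    if cooccurrence is not None:
        known = set(zip(variants["gene"], variants["aa_change"]))
        for _, row in cooccurrence.iterrows():
            for variant in (row["variant_a"], row["variant_b"]):
                if (row["gene"], variant) not in known:
                    raise ValueError(
                        f"co-occurrence adjustment references unknown variant "
                        f"{row['gene']}:{variant}"
                    )
            counts.loc[row["gene"]] -= row["n_patients"]
    return counts.astype(int)


def partition_patients(patient_variants: pd.DataFrame) -> dict:
    """Monogenic/polygenic partition and per-patient best classification.

    Expects one row per (patient_id, variant) with ``gene`` and
    ``classification``.  Monogenic means variants in exactly one gene;
    polygenic patients are keyed by their distinct-gene count.
    """
    if patient_variants.empty:
        return {
            "n_patients": 0,
            "monogenic": 0,
            "polygenic": {},
            "patient_classifications": {},
            "classification_patient_counts": {},
        }
    per_patient = patient_variants.groupby("patient_id")
    gene_counts = per_patient["gene"].nunique()
    best = per_patient["classification"].agg(patient_classification)
    polygenic = (
        gene_counts[gene_counts >= 2].value_counts().sort_index().to_dict()
    )
    return {
        "n_patients": int(gene_counts.size),
        "monogenic": int((gene_counts == 1).sum()),
        "polygenic": {int(k): int(v) for k, v in polygenic.items()},
        "patient_classifications": best.to_dict(),
        "classification_patient_counts": {
            k: int(v) for k, v in best.value_counts().to_dict().items()
        },
    }


def summarize_cnv(segments: pd.DataFrame) -> dict:
    """Distinct patients with >= 1 CNV, plus MVP-band tier counts.

    Expects one row per (patient, region) with ``patient_id`` and an ``mvp``
    column (may be missing/NaN for regions whose scores are reported on a
    lead row only); tiers are counted over rows with a reported MVP.
    """
    if segments.empty:
        return {"cnv_patient_count": 0, "tier_counts": {}}
    tiers = []
    if "mvp" in segments.columns:
        for mvp in segments["mvp"]:
            if pd.notna(mvp):
                tiers.append(tier_sv_scores(SVScoreSet(mvp=float(mvp))))
    tier_counts = pd.Series(tiers, dtype=object).value_counts().to_dict()
    return {
        "cnv_patient_count": int(segments["patient_id"].nunique()),
        "tier_counts": {k: int(v) for k, v in tier_counts.items()},
    }


def build_cohort_summary(
    n_patients: int,
    classified_variants: pd.DataFrame,
    patient_variants: pd.DataFrame,
    cnv_segments: pd.DataFrame | None = None,
    cooccurrence: pd.DataFrame | None = None,
) -> CohortSummary:
    """Assemble the full cohort summary and check its partition identities."""
    spectrum = summarize_variants(classified_variants)
    partition = partition_patients(patient_variants)
    cnv = summarize_cnv(cnv_segments if cnv_segments is not None else pd.DataFrame())

    n_mutated = partition["n_patients"]
    by_class = partition["classification_patient_counts"]
    n_lp_p = sum(
        v for k, v in by_class.items() if classification_rank(k) > classification_rank("VUS")
    )
    n_vus_only = by_class.get("VUS", 0)

    genes = {}
    if not classified_variants.empty and "n_patients" in classified_variants.columns:
        variant_counts = classified_variants.groupby("gene").size()
        carrier_counts = gene_patient_counts(classified_variants, cooccurrence)
        genes = {
            gene: {
                "variants": int(variant_counts[gene]),
                "patients": int(carrier_counts[gene]),
            }
            for gene in variant_counts.index
        }

    summary = CohortSummary(
        n_patients=n_patients,
        n_mutated=n_mutated,
        n_negative=n_patients - n_mutated,
        n_lp_p_patients=n_lp_p,
        n_vus_only_patients=n_vus_only,
        unique_variants=spectrum["unique_variants"],
        variants_by_type=spectrum["variants_by_type"],
        genes=genes,
        classification_counts=spectrum["classification_counts"],
        monogenic=partition["monogenic"],
        polygenic=partition["polygenic"],
        cnv_patient_count=cnv["cnv_patient_count"],
        cnv_tier_counts=cnv["tier_counts"],
    )
    summary.validate()
    return summary
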