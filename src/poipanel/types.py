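"""Domain types shared across the pipeline.

Plain dataclasses with eager validation: every record checks its own
invariants at construction time, so malformed inputs fail at the boundary
rather than deep inside an analysis.  Missing values are explicit ``None``
(scalar records) or ``NaN`` (DataFrame columns) — never silently zero.

Coordinate convention: all genomic intervals are stored 0-based half-open
(BED-style).  VCF positions are converted on ingestion; human-readable
output uses 1-based inclusive coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "PatientProfile",
    "VariantRecord",
    "PredictionProfile",
    "RunMetrics",
    "AmpliconCoverage",
    "SVScoreSet",
    "QpcrMeasurement",
    "CNVSegment",
    "SampleNoise",
    "VARIANT_TYPES",
    "CLASSIFICATIONS",
    "SEVERITY",
    "classification_rank",
]

#: Closed vocabulary for protein-level consequence classes.
VARIANT_TYPES = frozenset(
    {
        "missense",
        "nonsense",
        "frameshift",
        "inframe_deletion",
        "inframe_insertion",
        "duplication",
    }
)

#: ACMG five-tier classification labels, most to least severe.
CLASSIFICATIONS = ("P", "LP", "VUS", "LB", "B")

#: Total severity order: P > LP > VUS > LB > B.
SEVERITY = {label: rank for rank, label in enumerate(reversed(CLASSIFICATIONS))}


def classification_rank(label: str) -> int:
    """Rank of a classification on the severity order (higher = more severe)."""
    try:
        return SEVERITY[label]
    except KeyError:
        raise ValueError(f"unknown classification label: {label!r}") from None


def _require_non_negative(name: str, value: float | int | None) -> None:
    if value is not None and value < 0:
        raise ValueError(f"{name} must be non-negative, got {value}")


@dataclass
class PatientProfile:
    """Hormonal/ultrasound measurements for one woman.

    Units: age in years; AMH in ng/ml; FSH in mU/L; E2 in pg/ml; AFC is a
    follicle count; FI/VI/VFI are dimensionless Doppler indices.  VFI is
    carried for completeness but does not enter the ovarian-age equation.
    """

    patient_id: str
    age: float
    amh: float | None = None
    fsh: float | None = None
    e2: float | None = None
    afc: int | None = None
    fi: float | None = None
    vi: float | None = None
    vfi: float | None = None
    exclusion_flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if not math.isfinite(self.age):
            raise ValueError("age must be finite")
        if self.age <= 0:
            raise ValueError(f"age must be positive, got {self.age}")
        for name in ("amh", "fsh", "e2", "afc", "fi", "vi", "vfi"):
            _require_non_negative(name, getattr(self, name))
        self.exclusion_flags = frozenset(self.exclusion_flags)


@dataclass
class VariantRecord:
    """One small variant on the panel, keyed by (gene, aa_change).

    Population allele frequencies are stored as PERCENTAGES (0.07048 means
    0.07048%), matching how retained rare variants relate to the 1% filter
    and to their assigned PM2 codes.  Genomic coordinates are optional:
    published variant tables print protein-level changes only.
    """

    gene: str
    aa_change: str
    variant_type: str
    chrom: str | None = None
    transcript: str | None = None
    gnomad_nfe_af: float | None = None
    eur_af_1kg: float | None = None
    coverage: int | None = None
    quality: float | None = None
    n_patients: int = 1

    def __post_init__(self) -> None:
        if not self.gene or not self.aa_change:
            raise ValueError("gene and aa_change are required")
        if self.variant_type not in VARIANT_TYPES:
            raise ValueError(
                f"variant_type {self.variant_type!r} not in {sorted(VARIANT_TYPES)}"
            )
        for name in ("gnomad_nfe_af", "eur_af_1kg", "coverage", "quality"):
            _require_non_negative(name, getattr(self, name))
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene, self.aa_change)


@dataclass
class PredictionProfile:
    """Precomputed in-silico predictor scores for one variant.

    SIFT and PolyPhen-2 live in [0, 1] (SIFT <= 0.05 is conventionally
    deleterious, PolyPhen near 1 is damaging); CADD is Phred-scaled;
    MutationTaster is a categorical benign/deleterious call; Grantham is the
    physicochemical distance in [0, 215].
    """

    sift: float | None = None
    polyphen: float | None = None
    cadd_phred: float | None = None
    mutation_taster: str | None = None
    grantham: float | None = None

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("sift", 0.0, 1.0),
            ("polyphen", 0.0, 1.0),
            ("grantham", 0.0, 215.0),
        ):
            value = getattr(self, name)
            if value is not None and not (lo <= value <= hi):
                raise ValueError(f"{name} must be in [{lo}, {hi}], got {value}")
        _require_non_negative("cadd_phred", self.cadd_phred)
        if self.mutation_taster is not None and self.mutation_taster not in {"B", "D"}:
            raise ValueError(
                f"mutation_taster must be 'B', 'D' or None, got {self.mutation_taster!r}"
            )


@dataclass
class RunMetrics:
    """Per-run sequencing coverage metrics used by run-level QC."""

    sample_id: str
    reads: int
    mean_depth: float
    uniformity: float

    def __post_init__(self) -> None:
        _require_non_negative("reads", self.reads)
        _require_non_negative("mean_depth", self.mean_depth)
        if not (0.0 <= self.uniformity <= 100.0):
            raise ValueError(f"uniformity must be in [0, 100], got {self.uniformity}")


@dataclass
class AmpliconCoverage:
    """Read count of one amplicon in one sample (coordinates 0-based half-open)."""

    sample_id: str
    amplicon_id: str
    chrom: str
    start: int
    end: int
    gc_fraction: float
    read_count: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"start must be < end, got [{self.start}, {self.end})")
        if not (0.0 <= self.gc_fraction <= 1.0):
            raise ValueError(f"gc_fraction must be in [0, 1], got {self.gc_fraction}")
        _require_non_negative("read_count", self.read_count)


@dataclass
class SVScoreSet:
    """Structural-variant pathogenicity predictor scores for one CNV region.

    CADD-SV is Phred-scaled in [0, 48] (0 potentially benign, 48 potentially
    pathogenic); StrVCTVRE and the X-CNV meta-voting prediction (MVP) are
    probabilities in [0, 1].  All are consumed as annotations, never
    recomputed.
    """

    cadd_sv_phred: float | None = None
    strvctvre: float | None = None
    mvp: float | None = None

    def __post_init__(self) -> None:
        if self.cadd_sv_phred is not None and not (0.0 <= self.cadd_sv_phred <= 48.0):
            raise ValueError(f"cadd_sv_phred must be in [0, 48], got {self.cadd_sv_phred}")
        for name in ("strvctvre", "mvp"):
            value = getattr(self, name)
            if value is not None and not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass
class QpcrMeasurement:
    """Ct values for one comparative-Ct (2^-ddCt) relative quantification.

    Reference gene is typically GAPDH; the calibrator is a normal-ploidy
    control sample.
    """

    sample_id: str
    target_ct: float
    reference_ct: float
    calibrator_target_ct: float
    calibrator_reference_ct: float

    def __post_init__(self) -> None:
        for name in (
            "target_ct",
            "reference_ct",
            "calibrator_target_ct",
            "calibrator_reference_ct",
        ):
            value = getattr(self, name)
            if value is None or not math.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {value}")


@dataclass
class CNVSegment:
    """A called copy-number interval (coordinates 0-based half-open).

    ``confidence`` is a log10 likelihood-ratio sum of the called ploidy
    against diploid; ``focal`` means shorter than 3 Mb.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    ploidy: int
    confidence: float
    n_amplicons: int = 0
    scores: SVScoreSet | None = None
    tier: str | None = None
    focal: bool | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"start must be < end, got [{self.start}, {self.end})")
        if self.ploidy < 0:
            raise ValueError("ploidy must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def change(self) -> str:
        if self.ploidy > 2:
            return "gain"
        if self.ploidy < 2:
            return "loss"
        return "neutral"


@dataclass
class SampleNoise:
    """Per-sample coverage-noise summary (MAPD) gating CNV calling."""

    sample_id: str
    mapd: float
    eligible: bool

    def __post_init__(self) -> None:
        _require_non_negative("mapd", self.mapd)
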