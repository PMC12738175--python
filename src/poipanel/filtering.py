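"""The variant filter cascade: run QC, call QC, control subtraction,
population allele-frequency filtering.

Stages run in a fixed order (run-level QC is applied per sample before the
per-variant stages).  Each stage records input / excluded / retained counts
so the report conserves counts, and the final retained *set* is invariant
to input order.  Allele frequencies are percentages; a variant with no
reported frequency in either population source is treated as rare and
retained (absence from the databases is itself evidence of rarity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .types import RunMetrics

__all__ = [
    "FilterConfig",
    "CascadeReport",
    "run_qc",
    "call_qc",
    "subtract_controls",
    "population_af_filter",
    "run_cascade",
]

KEY_COLS = ["gene", "aa_change"]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the cascade (AF thresholds in percent)."""

    min_coverage: int = 200
    min_quality: float = 30.0
    min_run_reads: int = 200_000
    min_run_depth: float = 200.0
    min_run_uniformity: float = 90.0
    max_population_af: float = 1.0
    control_cohort_size: int = 200
    #: exclude when EITHER population source exceeds the threshold; set to
    #: ``"both"`` to require both sources to exceed it.
    af_join: str = "either"

    def __post_init__(self) -> None:
        for name in (
            "min_coverage",
            "min_quality",
            "min_run_reads",
            "min_run_depth",
            "min_run_uniformity",
            "max_population_af",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.af_join not in {"either", "both"}:
            raise ValueError("af_join must be 'either' or 'both'")


@dataclass
class CascadeReport:
    """Per-stage accounting plus the final retained variant table."""

    stages: list[dict] = field(default_factory=list)
    retained: pd.DataFrame | None = None
    notes: list[str] = field(default_factory=list)

    def add_stage(self, name: str, n_in: int, n_excluded: int) -> None:
        self.stages.append(
            {
                "stage": name,
                "input": int(n_in),
                "excluded": int(n_excluded),
                "retained": int(n_in - n_excluded),
            }
        )

    def conserves_counts(self) -> bool:
        return all(s["input"] == s["excluded"] + s["retained"] for s in self.stages)


def run_qc(metrics: RunMetrics, cfg: FilterConfig | None = None) -> tuple[bool, list[str]]:
    """Run-level QC: fail when reads, mean depth or uniformity fall below
    their minima (strict < comparisons, so boundary values pass)."""
    cfg = cfg or FilterConfig()
    reasons = []
    if metrics.reads < cfg.min_run_reads:
        reasons.append("reads")
    if metrics.mean_depth < cfg.min_run_depth:
        reasons.append("mean_depth")
    if metrics.uniformity < cfg.min_run_uniformity:
        reasons.append("uniformity")
    return (not reasons), reasons


def call_qc(variant, cfg: FilterConfig | None = None) -> tuple[bool, str | None]:
    """Per-call QC: pass iff coverage >= 200 and quality >= 30 (inclusive).

    ``variant`` is any object/row with ``coverage`` and ``quality``
    attributes or keys; a missing value fails with reason ``missing_qc``.
    """
    cfg = cfg or FilterConfig()
    coverage = _get(variant, "coverage")
    quality = _get(variant, "quality")
    if coverage is None or quality is None or pd.isna(coverage) or pd.isna(quality):
        return False, "missing_qc"
    if coverage < cfg.min_coverage or quality < cfg.min_quality:
        return False, "qc_threshold"
    return True, None


def _get(obj, name):
    if isinstance(obj, (dict, pd.Series)):
        return obj.get(name)
    return getattr(obj, name, None)


def subtract_controls(
    case_variants: pd.DataFrame, control_keys: set[tuple[str, str]]
) -> pd.DataFrame:
    """Drop case variants whose (gene, aa_change) key occurs in controls."""
    for key in control_keys:
        if not (isinstance(key, tuple) and len(key) == 2):
            raise ValueError(
                "control keys must be (gene, aa_change) tuples matching the case keying"
            )
    keys = list(zip(case_variants["gene"], case_variants["aa_change"]))
    mask = [key not in control_keys for key in keys]
    return case_variants.loc[mask]


def population_af_filter(
    variants: pd.DataFrame, cfg: FilterConfig | None = None
) -> pd.Series:
    """Boolean retained mask from the population-frequency rule.

    Excluded when a reported frequency (percent) exceeds the threshold in
    either source (or in both, under ``af_join='both'``); variants missing
    from both sources are retained.
    """
    cfg = cfg or FilterConfig()
    gnomad = pd.to_numeric(variants.get("gnomad_nfe_af"), errors="coerce")
    eur = pd.to_numeric(variants.get("eur_af_1kg"), errors="coerce")
    if (gnomad.dropna() < 0).any() or (eur.dropna() < 0).any():
        raise ValueError("negative allele frequency")
    over_gnomad = gnomad > cfg.max_population_af
    over_eur = eur > cfg.max_population_af
    if cfg.af_join == "either":
        excluded = over_gnomad | over_eur
    else:
        excluded = over_gnomad & over_eur
    return ~excluded


def run_cascade(
    cohort_variants: pd.DataFrame,
    control_keys: set[tuple[str, str]],
    cfg: FilterConfig | None = None,
) -> CascadeReport:
    """Apply call QC -> control subtraction -> population AF filter in order.

    The stage order is pinned for reproducible per-stage counts (the final
    retained set does not depend on it).  A table that carries neither a
    ``coverage`` nor a ``quality`` column is taken to be upstream-QC'd and
    passes the call-QC stage unchanged (noted in the report); missing values
    in *present* columns still fail per variant.
    """
    cfg = cfg or FilterConfig()
    report = CascadeReport()
    report.notes.append(f"af_join={cfg.af_join}")
    current = cohort_variants.copy()

    has_qc_cols = "coverage" in current.columns or "quality" in current.columns
    n_in = len(current)
    if has_qc_cols:
        mask = current.apply(lambda row: call_qc(row, cfg)[0], axis=1)
        mask = mask.astype(bool) if len(mask) else pd.Series([], dtype=bool)
        current = current.loc[mask]
    else:
        report.notes.append("call_qc: no coverage/quality columns; upstream QC assumed")
    report.add_stage("call_qc", n_in, n_in - len(current))

    n_in = len(current)
    current = subtract_controls(current, control_keys)
    report.add_stage("control_subtraction", n_in, n_in - len(current))

    n_in = len(current)
    if n_in:
        current = current.loc[population_af_filter(current, cfg)]
    report.add_stage("population_af", n_in, n_in - len(current))

    report.retained = current.reset_index(drop=True)
    return report
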