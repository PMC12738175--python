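"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a case/control targeted-sequencing study of
premature ovarian insufficiency: hormonal profiles that satisfy the
eligibility predicates by construction (rejection sampling against the
ovarian-age equation), per-patient variant sets over a 72-gene panel with
known truth labels (rare case-only / shared-with-controls / common), and
GC-biased amplicon coverage with planted copy-number changes.

Default rates reproduce the published cohort marginals: with per-patient
gene counts Poisson-distributed, a total plant rate of -ln(0.4) = 0.916
gives 60% of patients carrying at least one variant, and splitting it as
0.261 pathogenic-class / 0.655 VUS-class gives 23% of patients with an
LP/P variant and 37% with only VUS; the same Poisson gives a
monogenic:polygenic split of 0.611 among mutated patients (printed: 37 of
60).  Hormone marginals are not published; truncated lognormal/uniform
shapes are used, and nothing downstream depends on them beyond the
eligibility predicates.

Everything is driven by one integer seed; equal configurations give
byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .ovage import OvAgeModel, compute_ovage
from .types import PatientProfile

__all__ = [
    "SimConfig",
    "CNVPlant",
    "SimCohort",
    "SimCoverage",
    "DEFAULT_PANEL_GENES",
    "generate_profiles",
    "generate_variants",
    "plant_exact",
    "build_panel",
    "generate_coverage",
    "write_outputs",
]

#: 72-gene target panel used by the default configuration: the 41 genes of
#: the packaged variant tables, the CNV-only gene INHBB, and 30 further
#: genes recurrently implicated in primary ovarian insufficiency.
DEFAULT_PANEL_GENES = (
    "DNAH5", "LAMC1", "HSD17B4", "HK3", "PCDH11X", "AR", "NOTCH2", "ADAMTS19",
    "FANCM", "FANCC", "GDF9", "SPIDR", "POU5F1", "SF1", "SOHLH1", "AMHR2",
    "TP63", "NANOS3", "MRPS22", "FOXL2", "ADAMTS1", "POF1B", "BNC1", "CDKN1B",
    "WT1", "MSH4", "WDR62", "BRSK1", "FANCG", "SOHLH2", "SYCE1", "AGTR2",
    "FOXO1", "FOXO3", "BBS9", "DUSP22", "LARS2", "NUPR1", "POLR3H", "SALL4",
    "DMC1", "INHBB", "FMR1", "BMP15", "NOBOX", "FIGLA", "FSHR", "ESR1",
    "ESR2", "STAG3", "HFM1", "MCM8", "MCM9", "NR5A1", "EIF2B2", "POLG",
    "INHA", "GJA4", "DIAPH2", "DACH2", "PGRMC1", "AIRE", "GALT", "NLRP7",
    "PADI6", "TWNK", "CLPP", "HARS2", "ERCC6", "MEIOB", "PSMC3IP", "KHDRBS1",
)

_CHROMS = [str(c) for c in range(1, 23)] + ["X"]

# criteria strings planted per truth class; every pathogenic-class string
# combines to LP or P, every vus-class string to VUS, every benign-class
# string to LB or B under the combining rules
_PATHOGENIC_CRITERIA = (
    "PM1, PM2, PM6",
    "PS1, PM2, PM1, PP3",
    "PM2, PM1, PP2, PP3",
)
_TRUNCATING_CRITERIA = "PVS1, PM2, PM1"
_VUS_CRITERIA = ("PM2", "PM2, PM1", "PM2, PP3", "PM2, PM1, PP2")
_BENIGN_CRITERIA = ("BS1, BP4", "BP4, BP6", "BS1, BS2")


@dataclass(frozen=True)
class CNVPlant:
    """One planted copy-number change (bp coordinates, 0-based half-open)."""

    chrom: str
    start: int
    end: int
    ploidy: int
    carrier_fraction: float = 0.1


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the generator; the seed drives every random draw."""

    seed: int = 0
    n_cases: int = 100
    n_controls: int = 200
    panel_genes: tuple[str, ...] = DEFAULT_PANEL_GENES
    # per-patient Poisson plant rates by truth class
    plant_rates: dict = field(
        default_factory=lambda: {
            "pathogenic": 0.261,
            "vus": 0.655,
            "benign_common": 2.0,
        }
    )
    shared_rate: float = 1.0  # shared-with-controls plants per case patient
    af_missing_fraction: float = 0.7  # rare variants absent from the databases
    # coverage model
    amplicons_per_gene: int = 21
    amplicon_length: int = 150
    mean_depth: float = 500.0
    coverage_sigma: float = 0.1  # lognormal sdlog of multiplicative noise
    gc_coef: float = 0.5  # slope of the linear GC-bias factor
    n_coverage_controls: int = 20
    cnv_plants: tuple[CNVPlant, ...] = ()
    max_rejection_draws: int = 10_000

    def __post_init__(self) -> None:
        if any(rate < 0 for rate in self.plant_rates.values()):
            raise ValueError("plant rates must be >= 0")
        if self.shared_rate < 0:
            raise ValueError("shared_rate must be >= 0")


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def _gene_locus(gene_index: int) -> tuple[str, int]:
    chrom = _CHROMS[gene_index % len(_CHROMS)]
    start = 1_000_000 + (gene_index // len(_CHROMS)) * 5_000_000
    return chrom, start


# ---------------------------------------------------------------------------
# Profiles


def _draw_case(rng: np.random.Generator, model: OvAgeModel, cfg: SimConfig) -> dict:
    for _ in range(cfg.max_rejection_draws):
        profile = dict(
            amh=float(rng.uniform(0.01, 0.95)),
            fsh=float(40.0 + rng.exponential(25.0)),
            e2=float(rng.uniform(5.0, 19.5)),
            afc=int(rng.poisson(1.5)),
            fi=float(rng.uniform(5.0, 20.0)),
            vi=float(rng.uniform(0.0, 6.0)),
            vfi=float(rng.uniform(0.0, 3.0)),
        )
        ovage = compute_ovage(PatientProfile(patient_id="draw", age=30.0, **profile), model)
        age = float(rng.uniform(22.0, 39.0))
        if ovage - age > 10.0:
            return {"age": age, "ovage": ovage, **profile}
    raise RuntimeError("case rejection sampling exceeded the draw budget")


def _draw_control(rng: np.random.Generator, model: OvAgeModel, cfg: SimConfig) -> dict:
    for _ in range(cfg.max_rejection_draws):
        profile = dict(
            amh=float(min(rng.lognormal(math.log(2.0), 0.5), 8.0)),
            fsh=float(rng.uniform(4.0, 12.0)),
            e2=float(rng.uniform(30.0, 150.0)),
            afc=int(5 + rng.poisson(8.0)),
            fi=float(rng.uniform(8.0, 18.0)),
            vi=float(rng.uniform(0.0, 5.0)),
            vfi=float(rng.uniform(0.0, 3.0)),
        )
        ovage = compute_ovage(PatientProfile(patient_id="draw", age=30.0, **profile), model)
        age = float(rng.uniform(20.0, 45.0))
        if abs(ovage - age) <= 2.0 and age > 18.0:
            return {"age": age, "ovage": ovage, **profile}
    raise RuntimeError("control rejection sampling exceeded the draw budget")


def generate_profiles(cfg: SimConfig, model: OvAgeModel | None = None) -> pd.DataFrame:
    """Case and control hormonal profiles satisfying eligibility by construction.

    Cases meet FSH > 40, E2 < 20, AMH < 1 and ovarian age more than 10 years
    ahead of chronological age; controls have |gap| <= 2.  Profiles carry no
    exclusion flags.  Returns one row per patient with a ``status`` column.
    """
    model = model or OvAgeModel()
    rng = _rng(cfg, 1)
    rows = []
    for i in range(cfg.n_cases):
        rows.append(
            {"patient_id": f"CASE_{i + 1:04d}", "status": "case", **_draw_case(rng, model, cfg)}
        )
    for i in range(cfg.n_controls):
        rows.append(
            {
                "patient_id": f"CTRL_{i + 1:04d}",
                "status": "control",
                **_draw_control(rng, model, cfg),
            }
        )
    df = pd.DataFrame(rows)
    df["exclusion_flags"] = ""
    return df


# ---------------------------------------------------------------------------
# Variants


@dataclass
class SimCohort:
    """Synthetic variant call set plus ground truth."""

    profiles: pd.DataFrame
    case_variants: pd.DataFrame
    control_keys: set
    truth: pd.DataFrame


def _draw_af(rng: np.random.Generator, truth_class: str, cfg: SimConfig) -> float | None:
    """Population AF in percent for one planted variant (None = not reported)."""
    if truth_class == "common":
        return float(rng.uniform(1.5, 15.0))
    if rng.random() < cfg.af_missing_fraction:
        return None
    return float(min(np.exp(rng.normal(math.log(0.005), 1.0)), 0.9))


def _draw_predictors(rng: np.random.Generator, truth_class: str) -> dict:
    if truth_class == "pathogenic":
        return {
            "sift": round(float(rng.uniform(0.0, 0.05)), 3),
            "polyphen": round(float(rng.uniform(0.85, 1.0)), 3),
            "cadd_phred": round(float(rng.uniform(20.0, 35.0)), 2),
            "mutation_taster": "D",
            "grantham": round(float(rng.uniform(80.0, 215.0)), 0),
        }
    if truth_class == "common":
        return {
            "sift": round(float(rng.uniform(0.2, 1.0)), 3),
            "polyphen": round(float(rng.uniform(0.0, 0.15)), 3),
            "cadd_phred": round(float(rng.uniform(0.0, 10.0)), 2),
            "mutation_taster": "B",
            "grantham": round(float(rng.uniform(5.0, 100.0)), 0),
        }
    return {
        "sift": round(float(rng.uniform(0.0, 0.6)), 3),
        "polyphen": round(float(rng.uniform(0.0, 1.0)), 3),
        "cadd_phred": round(float(rng.uniform(10.0, 25.0)), 2),
        "mutation_taster": "B",
        "grantham": round(float(rng.uniform(5.0, 180.0)), 0),
    }


_AA = "ARNDCQEGHILKMFPSTWYV"


def _plant_variant(
    rng: np.random.Generator,
    cfg: SimConfig,
    patient_id: str,
    truth_class: str,
) -> dict:
    gene_index = int(rng.integers(len(cfg.panel_genes)))
    gene = cfg.panel_genes[gene_index]
    chrom, locus = _gene_locus(gene_index)
    pos = locus + int(rng.integers(0, 50_000))
    ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
    aa_pos = int(rng.integers(10, 900))
    if truth_class == "pathogenic" and rng.random() < 0.2:
        variant_type = "nonsense" if rng.random() < 0.5 else "frameshift"
        aa_change = (
            f"{rng.choice(list(_AA))}{aa_pos}*"
            if variant_type == "nonsense"
            else f"{rng.choice(list(_AA))}{aa_pos}Tfs*{int(rng.integers(2, 20))}"
        )
        criteria = _TRUNCATING_CRITERIA
    else:
        variant_type = "missense"
        aa_from, aa_to = rng.choice(list(_AA), size=2, replace=False)
        aa_change = f"{aa_from}{aa_pos}{aa_to}"
        criteria = {
            "pathogenic": _PATHOGENIC_CRITERIA,
            "vus": _VUS_CRITERIA,
            "shared": _VUS_CRITERIA,
            "common": _BENIGN_CRITERIA,
        }[truth_class]
        criteria = str(rng.choice(criteria))
    af = _draw_af(rng, truth_class, cfg)
    return {
        "patient_id": patient_id,
        "gene": gene,
        "aa_change": aa_change,
        "variant_type": variant_type,
        "chrom": chrom,
        "pos": pos,
        "ref": str(ref),
        "alt": str(alt),
        "gt": "0/1",
        "coverage": int(200 + rng.poisson(400)),
        "quality": round(float(rng.uniform(40.0, 95.0)), 1),
        "gnomad_nfe_af": af,
        "eur_af_1kg": None,
        "acmg_criteria": criteria,
        "truth_class": truth_class,
        **_draw_predictors(rng, truth_class),
    }


def generate_variants(cfg: SimConfig, profiles: pd.DataFrame) -> SimCohort:
    """Plant per-patient variants with known truth classes.

    Classes: ``pathogenic`` and ``vus`` are rare case-only (survive the
    cascade), ``shared`` variants also enter the control key set (removed by
    control subtraction), ``common`` variants carry population frequencies
    above 1% (removed by the frequency filter).
    """
    rng = _rng(cfg, 2)
    cases = profiles.loc[profiles["status"] == "case", "patient_id"]
    counts_by_patient = {
        patient_id: [
            ("pathogenic", int(rng.poisson(cfg.plant_rates.get("pathogenic", 0.0)))),
            ("vus", int(rng.poisson(cfg.plant_rates.get("vus", 0.0)))),
            ("common", int(rng.poisson(cfg.plant_rates.get("benign_common", 0.0)))),
            ("shared", int(rng.poisson(cfg.shared_rate))),
        ]
        for patient_id in cases
    }
    return _plant_cohort(cfg, profiles, counts_by_patient, rng)


def plant_exact(
    cfg: SimConfig,
    profiles: pd.DataFrame,
    n_rare: int,
    n_shared: int,
    n_common: int,
) -> SimCohort:
    """Plant exact per-patient class counts (for constructed-cohort tests).

    ``n_rare`` variants are planted as the VUS-like rare case-only class.
    """
    rng = _rng(cfg, 2)
    cases = profiles.loc[profiles["status"] == "case", "patient_id"]
    counts_by_patient = {
        patient_id: [("vus", n_rare), ("common", n_common), ("shared", n_shared)]
        for patient_id in cases
    }
    return _plant_cohort(cfg, profiles, counts_by_patient, rng)


def _plant_cohort(
    cfg: SimConfig,
    profiles: pd.DataFrame,
    counts_by_patient: dict,
    rng: np.random.Generator,
) -> SimCohort:
    rows = []
    control_keys: set[tuple[str, str]] = set()
    class_of_key: dict[tuple[str, str], str] = {}
    for patient_id, plants in counts_by_patient.items():
        for truth_class, count in plants:
            for _ in range(count):
                # redraw on key collision across truth classes so the
                # (gene, aa_change) key determines the class unambiguously
                for _ in range(100):
                    row = _plant_variant(rng, cfg, patient_id, truth_class)
                    key = (row["gene"], row["aa_change"])
                    if class_of_key.get(key, truth_class) == truth_class:
                        break
                class_of_key[key] = truth_class
                rows.append(row)
                if truth_class == "shared":
                    control_keys.add(key)
    columns = [
        "patient_id", "gene", "aa_change", "variant_type", "chrom", "pos",
        "ref", "alt", "gt", "coverage", "quality", "gnomad_nfe_af",
        "eur_af_1kg", "sift", "polyphen", "cadd_phred", "mutation_taster",
        "grantham", "acmg_criteria", "truth_class",
    ]
    case_variants = pd.DataFrame(rows, columns=columns)
    truth = case_variants[["patient_id", "gene", "aa_change", "truth_class"]].copy()
    return SimCohort(
        profiles=profiles,
        case_variants=case_variants,
        control_keys=control_keys,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Coverage


@dataclass
class SimCoverage:
    """Synthetic amplicon panel and read-count matrices with CNV truth."""

    panel: pd.DataFrame
    control_matrix: pd.DataFrame
    case_matrix: pd.DataFrame
    truth: pd.DataFrame


def build_panel(cfg: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Amplicon definitions (0-based half-open) with GC fractions."""
    rng = rng if rng is not None else _rng(cfg, 3)
    rows = []
    for gene_index, gene in enumerate(cfg.panel_genes):
        chrom, locus = _gene_locus(gene_index)
        for k in range(cfg.amplicons_per_gene):
            start = locus + k * (cfg.amplicon_length + 50)
            rows.append(
                {
                    "amplicon_id": f"{gene}_amp{k + 1:03d}",
                    "chrom": chrom,
                    "start": start,
                    "end": start + cfg.amplicon_length,
                    "gene": gene,
                    "gc_fraction": round(float(rng.uniform(0.30, 0.75)), 4),
                }
            )
    return pd.DataFrame(rows)


def generate_coverage(cfg: SimConfig, case_ids=None) -> SimCoverage:
    """Amplicon read counts for controls (diploid) and cases (with plants).

    Coverage model: per-amplicon efficiency (lognormal, shared across
    samples) x a linear GC-bias factor 1 + gc_coef * (gc - 0.5) x ploidy/2
    x per-observation lognormal noise with natural-log sdlog
    ``coverage_sigma``.
    """
    rng = _rng(cfg, 3)
    panel = build_panel(cfg, rng)
    n_amp = len(panel)
    efficiency = rng.lognormal(0.0, 0.3, size=n_amp)
    gc_factor = 1.0 + cfg.gc_coef * (panel["gc_fraction"].to_numpy() - 0.5)
    base = cfg.mean_depth * efficiency * gc_factor

    def draw_sample(ploidy_vector: np.ndarray) -> np.ndarray:
        noise = rng.lognormal(0.0, cfg.coverage_sigma, size=n_amp)
        return np.rint(base * (ploidy_vector / 2.0) * noise).astype(int)

    diploid = np.full(n_amp, 2.0)
    controls = {
        f"COVCTRL_{i + 1:03d}": draw_sample(diploid)
        for i in range(cfg.n_coverage_controls)
    }
    if case_ids is None:
        case_ids = [f"CASE_{i + 1:04d}" for i in range(cfg.n_cases)]
    truth_rows = []
    case_cols = {}
    for sample_id in case_ids:
        ploidy = diploid.copy()
        for plant in cfg.cnv_plants:
            if rng.random() >= plant.carrier_fraction:
                continue
            mask = (
                (panel["chrom"] == plant.chrom)
                & (panel["start"] < plant.end)
                & (panel["end"] > plant.start)
            ).to_numpy()
            ploidy[mask] = plant.ploidy
            truth_rows.append(
                {
                    "sample_id": sample_id,
                    "chrom": plant.chrom,
                    "start": plant.start,
                    "end": plant.end,
                    "ploidy": plant.ploidy,
                    "n_amplicons": int(mask.sum()),
                }
            )
        case_cols[sample_id] = draw_sample(ploidy)
    index = panel["amplicon_id"]
    return SimCoverage(
        panel=panel,
        control_matrix=pd.DataFrame(controls, index=index),
        case_matrix=pd.DataFrame(case_cols, index=index),
        truth=pd.DataFrame(
            truth_rows,
            columns=["sample_id", "chrom", "start", "end", "ploidy", "n_amplicons"],
        ),
    )


# ---------------------------------------------------------------------------
# File emission


def write_outputs(cfg: SimConfig, outdir) -> dict:
    """Generate a full cohort and write the standard files.

    Emits profiles.tsv, case.vcf, controls.tsv, annotations.tsv,
    coverage.tsv, panel.bed and truth.json under ``outdir``; returns the
    paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    profiles = generate_profiles(cfg)
    cohort = generate_variants(cfg, profiles)
    coverage = generate_coverage(cfg)

    paths = {name: outdir / name for name in (
        "profiles.tsv", "case.vcf", "controls.tsv", "annotations.tsv",
        "coverage.tsv", "panel.bed", "panel_gc.tsv", "coverage_controls.txt",
        "truth.json",
    )}
    profiles.to_csv(paths["profiles.tsv"], sep="\t", index=False, na_rep="NA")
    calls = cohort.case_variants.rename(columns={"patient_id": "sample_id"})
    pio.write_vcf(calls, paths["case.vcf"])
    pd.DataFrame(sorted(cohort.control_keys), columns=["gene", "aa_change"]).to_csv(
        paths["controls.tsv"], sep="\t", index=False
    )
    cohort.case_variants.drop(columns=["truth_class"]).to_csv(
        paths["annotations.tsv"], sep="\t", index=False, na_rep="NA"
    )
    matrix = pd.concat([coverage.control_matrix, coverage.case_matrix], axis=1)
    matrix.to_csv(paths["coverage.tsv"], sep="\t", na_rep="NA")
    coverage.panel[["chrom", "start", "end", "amplicon_id"]].to_csv(
        paths["panel.bed"], sep="\t", index=False, header=False
    )
    coverage.panel[["amplicon_id", "gc_fraction"]].to_csv(
        paths["panel_gc.tsv"], sep="\t", index=False
    )
    paths["coverage_controls.txt"].write_text(
        "\n".join(coverage.control_matrix.columns) + "\n"
    )
    truth = {
        "variants": cohort.truth.to_dict(orient="records"),
        "cnv": coverage.truth.to_dict(orient="records"),
    }
    paths["truth.json"].write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return {name: str(path) for name, path in paths.items()}


def scaled_config(cfg: SimConfig, fraction: float) -> SimConfig:
    """A smaller copy of a configuration (for quick tests)."""
    return replace(
        cfg,
        n_cases=max(1, int(cfg.n_cases * fraction)),
        n_controls=max(1, int(cfg.n_controls * fraction)),
    )
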