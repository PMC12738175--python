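"""ACMG/AMP evidence parsing, combination and patient-level roll-up.

The combining table maps a set of evidence codes (PVS1, PS1-4, PM1-6,
PP1-5 on the pathogenic side; BA1, BS1-4, BP1-7 on the benign side) to one
of five classes: pathogenic (P), likely pathogenic (LP), uncertain (VUS),
likely benign (LB), benign (B).

Two conflict policies are supported when evidence from both sides is
present:

``strict``
    The guideline-faithful default for new data: contradictory evidence
    (a benign-side rule firing while pathogenic-side codes are present, or
    vice versa) yields VUS.

``paper_concordant``
    Benign-dominant: benign-side rules are evaluated first and win even
    when pathogenic codes co-occur; explicit per-variant overrides are
    applied last and logged.  This mode reproduces published curated call
    sets in which strong-benign evidence (e.g. BS1 with supporting BP
    codes) was allowed to dominate residual pathogenic-side codes.

Evidence-strength modulation (e.g. PVS1_Moderate) is not supported: only
unmodulated codes occur in the consumed tables.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .types import PredictionProfile, VariantRecord, classification_rank

__all__ = [
    "VOCABULARY",
    "CriteriaSet",
    "ConflictPolicy",
    "PAPER_CONCORDANT_OVERRIDES",
    "parse_criteria",
    "format_criteria",
    "combine",
    "classify_all",
    "assign_computational_criteria",
    "patient_classification",
]

#: Closed 28-code vocabulary of unmodulated ACMG/AMP evidence codes.
VOCABULARY = frozenset(
    ["PVS1"]
    + [f"PS{i}" for i in range(1, 5)]
    + [f"PM{i}" for i in range(1, 7)]
    + [f"PP{i}" for i in range(1, 6)]
    + ["BA1"]
    + [f"BS{i}" for i in range(1, 5)]
    + [f"BP{i}" for i in range(1, 8)]
)

#: Canonical code order used by :func:`format_criteria`.
_CANONICAL_ORDER = (
    ["PVS1"]
    + [f"PS{i}" for i in range(1, 5)]
    + [f"PM{i}" for i in range(1, 7)]
    + [f"PP{i}" for i in range(1, 6)]
    + ["BA1"]
    + [f"BS{i}" for i in range(1, 5)]
    + [f"BP{i}" for i in range(1, 8)]
)
_ORDER_INDEX = {code: i for i, code in enumerate(_CANONICAL_ORDER)}

#: Curated per-variant overrides shipped with the package.  A single entry:
#: a PS3 (functional) code in the source table combines to LP by the rules,
#: but the curators' final call was VUS; the override records that outcome
#: rather than inventing a criterion-discounting rule.
PAPER_CONCORDANT_OVERRIDES: dict[tuple[str, str], str] = {
    ("CDKN1B", "P117S"): "VUS",
}


@dataclass(frozen=True)
class CriteriaSet:
    """Parsed evidence codes plus the verbatim source string and warnings."""

    codes: frozenset[str]
    raw: str = ""
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class ConflictPolicy:
    """Conflict-resolution mode plus an optional per-variant override map."""

    mode: str = "strict"
    overrides: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in {"strict", "paper_concordant"}:
            raise ValueError(f"unknown policy mode {self.mode!r}")
        for key, label in self.overrides.items():
            classification_rank(label)  # validates the label


_TOKEN_SPLIT = re.compile(r"[,;\s]+")


def parse_criteria(raw: str) -> CriteriaSet:
    """Parse a comma/space-separated criteria string into a code set.

    Tokens are uppercased; duplicates are collapsed with a warning;
    tokens outside the closed vocabulary are dropped with a warning.
    Always returns a (possibly empty) set — parsing never fails.
    """
    codes: list[str] = []
    warn: list[str] = []
    for token in _TOKEN_SPLIT.split(str(raw).strip()):
        if not token:
            continue
        code = token.upper()
        if code not in VOCABULARY:
            warn.append(f"malformed token dropped: {token!r}")
        elif code in codes:
            warn.append(f"duplicate code collapsed: {code}")
        else:
            codes.append(code)
    return CriteriaSet(codes=frozenset(codes), raw=str(raw), warnings=tuple(warn))


def format_criteria(criteria: CriteriaSet) -> str:
    """Render codes in canonical order; ``parse o format`` is idempotent."""
    return ", ".join(sorted(criteria.codes, key=_ORDER_INDEX.__getitem__))


def _counts(codes: frozenset[str]) -> tuple[int, int, int, int, int, int, int]:
    pvs = int("PVS1" in codes)
    ps = sum(1 for c in codes if c.startswith("PS"))
    pm = sum(1 for c in codes if c.startswith("PM"))
    pp = sum(1 for c in codes if c.startswith("PP"))
    ba = int("BA1" in codes)
    bs = sum(1 for c in codes if c.startswith("BS"))
    bp = sum(1 for c in codes if c.startswith("BP"))
    return pvs, ps, pm, pp, ba, bs, bp


def _pathogenic_rule(pvs: int, ps: int, pm: int, pp: int) -> str | None:
    if (
        (pvs >= 1 and (ps >= 1 or pm >= 2 or (pm == 1 and pp >= 1) or pp >= 2))
        or ps >= 2
        or (ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2) or (pm == 1 and pp >= 4)))
    ):
        return "P"
    if (
        (pvs >= 1 and pm >= 1)
        or (ps == 1 and pm >= 1)
        or (ps == 1 and pp >= 2)
        or pm >= 3
        or (pm == 2 and pp >= 2)
        or (pm == 1 and pp >= 4)
    ):
        return "LP"
    return None


def _benign_rule(ba: int, bs: int, bp: int) -> str | None:
    if ba or bs >= 2:
        return "B"
    if (bs >= 1 and bp >= 1) or bp >= 2:
        return "LB"
    return None


def combine(criteria: CriteriaSet | frozenset | set, mode: str = "strict") -> str:
    """Combine an evidence-code set into a five-tier classification.

    ``strict`` returns VUS whenever a rule on one side fires while codes
    from the other side are present (contradictory evidence).
    ``paper_concordant`` lets benign-side rules dominate.
    """
    codes = criteria.codes if isinstance(criteria, CriteriaSet) else frozenset(criteria)
    unknown = codes - VOCABULARY
    if unknown:
        raise ValueError(f"codes outside vocabulary: {sorted(unknown)}")
    pvs, ps, pm, pp, ba, bs, bp = _counts(codes)
    pathogenic = _pathogenic_rule(pvs, ps, pm, pp)
    benign = _benign_rule(ba, bs, bp)
    has_path_codes = (pvs + ps + pm + pp) > 0
    has_benign_codes = (ba + bs + bp) > 0

    if mode == "paper_concordant":
        if benign is not None:
            return benign
        if pathogenic is not None:
            return pathogenic
        return "VUS"
    if mode != "strict":
        raise ValueError(f"unknown combine mode {mode!r}")
    if (benign is not None and has_path_codes) or (
        pathogenic is not None and has_benign_codes
    ):
        return "VUS"
    if pathogenic is not None:
        return pathogenic
    if benign is not None:
        return benign
    return "VUS"


def classify_all(
    variants: pd.DataFrame, policy: ConflictPolicy | None = None
) -> pd.DataFrame:
    """Classify every variant row of a table with an ``acmg_criteria`` column.

    Returns a copy with ``codes`` (canonical string), ``parse_warnings``,
    ``computed_classification`` and ``override_applied`` columns.  Overrides
    are keyed by (gene, aa_change) and applied after rule combination.
    """
    policy = policy or ConflictPolicy()
    out = variants.copy()
    codes_col, warn_col, cls_col, override_col = [], [], [], []
    for _, row in out.iterrows():
        criteria = parse_criteria(row["acmg_criteria"])
        label = combine(criteria, mode=policy.mode)
        key = (row["gene"], row["aa_change"])
        overridden = False
        if policy.mode == "paper_concordant" and key in policy.overrides:
            label = policy.overrides[key]
            overridden = True
        codes_col.append(format_criteria(criteria))
        warn_col.append("; ".join(criteria.warnings))
        cls_col.append(label)
        override_col.append(overridden)
    out["codes"] = codes_col
    out["parse_warnings"] = warn_col
    out["computed_classification"] = cls_col
    out["override_applied"] = override_col
    return out


# Per-predictor deleterious / benign call thresholds used by the heuristic
# evidence assigner (synthetic data only; curated tables keep their printed
# criteria strings).
def _predictor_votes(pred: PredictionProfile) -> tuple[int, int, int]:
    deleterious = benign = available = 0
    if pred.sift is not None:
        available += 1
        deleterious += pred.sift <= 0.05
        benign += pred.sift > 0.05
    if pred.polyphen is not None:
        available += 1
        deleterious += pred.polyphen >= 0.85
        benign += pred.polyphen <= 0.15
    if pred.cadd_phred is not None:
        available += 1
        deleterious += pred.cadd_phred >= 20.0
        benign += pred.cadd_phred < 10.0
    if pred.mutation_taster is not None:
        available += 1
        deleterious += pred.mutation_taster == "D"
        benign += pred.mutation_taster == "B"
    return deleterious, benign, available


def assign_computational_criteria(
    pred: PredictionProfile, variant: VariantRecord
) -> frozenset[str]:
    """Heuristic evidence codes from predictor scores and variant anatomy.

    PP3/BP4 from a strict majority of the available predictors; PM2 from
    rarity (both population frequencies missing, or every reported one
    below 0.01%); PM4 for in-frame length changes; PVS1 for truncations.
    Intended for synthetic cohorts — curated criteria strings are never
    overwritten by this function.
    """
    codes: set[str] = set()
    deleterious, benign, available = _predictor_votes(pred)
    if available:
        if deleterious * 2 > available:
            codes.add("PP3")
        elif benign * 2 > available:
            codes.add("BP4")
    afs = [
        af for af in (variant.gnomad_nfe_af, variant.eur_af_1kg) if af is not None
    ]
    if all(af < 0.01 for af in afs):  # vacuously true when both are missing
        codes.add("PM2")
    if variant.variant_type in {"inframe_deletion", "inframe_insertion", "duplication"}:
        codes.add("PM4")
    if variant.variant_type in {"nonsense", "frameshift"}:
        codes.add("PVS1")
    return frozenset(codes)


def patient_classification(classifications) -> str:
    """Best (most severe) classification among a patient's variants.

    An empty list means the patient carries no qualifying variant and is
    reported as ``negative``.
    """
    labels = list(classifications)
    if not labels:
        return "negative"
    return max(labels, key=classification_rank)
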