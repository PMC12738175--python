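"""Ovarian-age (OvAge) computation and case/control eligibility.

OvAge is a composite "ovarian age" in years, a linear combination of AMH,
FSH, antral follicle count (AFC) and Doppler flow indices with two
interaction terms (AMH x AFC and FSH x AFC).  The coefficients were fitted
once by a generalized linear model on a large reference database and are
used here as fixed constants; refitting is out of scope.

Eligibility mirrors the recruitment rules of a premature-ovarian-
insufficiency case/control design: cases show a menopausal hormone picture
(FSH > 40 mU/L, E2 < 20 pg/ml, AMH < 1 ng/ml) and an ovarian age more than
10 years ahead of chronological age; controls have ovarian age within
+/-2 years of chronological age.  Any named exclusion condition (pregnancy,
endometriosis, chemotherapy, ...) makes a woman ineligible for either arm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .types import PatientProfile

__all__ = ["OvAgeModel", "EligibilityRules", "compute_ovage", "classify_eligibility"]


@dataclass(frozen=True)
class OvAgeModel:
    """Coefficients of the ovarian-age equation (years as output unit)."""

    intercept: float = 48.05
    coef_amh: float = -3.14
    coef_fsh: float = 0.07
    coef_afc: float = -0.77
    coef_fi: float = -0.11
    coef_vi: float = 0.25
    coef_amh_afc: float = 0.10
    coef_fsh_afc: float = 0.02


@dataclass(frozen=True)
class EligibilityRules:
    """Thresholds of the case/control predicates.

    Strictness follows the printed comparison symbols: case thresholds are
    strict (>, <), the control gap is inclusive (|gap| <= 2).  The
    onset-before-40 criterion is applied at recruitment, upstream of this
    computation, so it is surfaced as a flag rather than a hard gate.
    """

    case_fsh_min: float = 40.0  # mU/L, strict >
    case_e2_max: float = 20.0  # pg/ml, strict <
    case_amh_max: float = 1.0  # ng/ml, strict <
    case_ovage_gap_min: float = 10.0  # years, strict >
    control_ovage_gap_abs_max: float = 2.0  # years, inclusive
    age_max: float = 40.0  # years, informational onset flag


_REQUIRED = ("amh", "fsh", "afc", "fi", "vi")


def compute_ovage(profile: PatientProfile, model: OvAgeModel | None = None) -> float:
    """Evaluate the ovarian-age equation for one profile.

    Raises ``ValueError`` naming the first missing or non-finite required
    input (AMH, FSH, AFC, FI, VI).
    """
    model = model or OvAgeModel()
    for name in _REQUIRED:
        value = getattr(profile, name)
        if value is None or not math.isfinite(value):
            raise ValueError(f"compute_ovage: required input {name!r} is missing")
    return (
        model.intercept
        + model.coef_amh * profile.amh
        + model.coef_fsh * profile.fsh
        + model.coef_afc * profile.afc
        + model.coef_fi * profile.fi
        + model.coef_vi * profile.vi
        + model.coef_amh_afc * profile.amh * profile.afc
        + model.coef_fsh_afc * profile.fsh * profile.afc
    )


def classify_eligibility(
    profile: PatientProfile,
    ovage: float,
    rules: EligibilityRules | None = None,
) -> tuple[str, list[str]]:
    """Classify one profile as ``case``, ``control`` or ``ineligible``.

    Returns ``(status, reasons)``; for ineligible profiles every failed rule
    is named.  The gap predicates (> 10 vs |gap| <= 2) are disjoint, so no
    profile can satisfy both arms.  The function is total: it never raises
    on eligible inputs and reports missing measurements as failed rules.
    """
    rules = rules or EligibilityRules()
    reasons: list[str] = []
    gap = ovage - profile.age

    if profile.exclusion_flags:
        reasons.append("exclusion_flags:" + ";".join(sorted(profile.exclusion_flags)))

    case_failures = []
    if profile.fsh is None or not profile.fsh > rules.case_fsh_min:
        case_failures.append("fsh")
    if profile.e2 is None or not profile.e2 < rules.case_e2_max:
        case_failures.append("e2")
    if profile.amh is None or not profile.amh < rules.case_amh_max:
        case_failures.append("amh")
    if not gap > rules.case_ovage_gap_min:
        case_failures.append("ovage_gap")

    control_ok = abs(gap) <= rules.control_ovage_gap_abs_max

    if not reasons:  # no exclusion condition
        if not case_failures:
            return "case", []
        if control_ok:
            return "control", []
    reasons.extend(case_failures)
    if not control_ok:
        reasons.append("control_gap")
    return "ineligible", reasons


def onset_flag(profile: PatientProfile, rules: EligibilityRules | None = None) -> bool:
    """True if chronological age is below the onset criterion (informational)."""
    rules = rules or EligibilityRules()
    return profile.age < rules.age_max
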