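"""Patient identification and exclusion cascade for visit registries.

A *visit table* is a :class:`pandas.DataFrame` with one row per visit and
the columns listed in :data:`VISIT_COLUMNS`.  Diagnosis-code columns hold
semicolon-separated code strings (possibly empty).  All operations return
new frames; inputs are never mutated.

Cohort membership is patient-level: a patient qualifies through a single
visit (psychiatric ICD-10 code, psychological ICPC-2 code, or a flagged
service type) and then *all* of the patient's visits are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

from psnet.errors import SpecificationError

#: Canonical column order of a visit table.
VISIT_COLUMNS = (
    "patient_id",
    "professional_id",
    "visit_date",
    "municipality",
    "occupation_code",
    "service_type",
    "icd10_codes",
    "icpc2_codes",
    "mh_service_flag",
)

#: Recognized service-type categories.
SERVICE_TYPES = (
    "general_care",
    "mh_substance",
    "routine",
    "other",
    "home_care",
    "occupational_health",
    "undefined",
)

#: Diagnosis subgroups and their ICD-10 three-character code ranges.
SUBGROUP_RANGES = {
    "substance": ("F10", "F19"),
    "psychosis": ("F20", "F29"),
    "depressive": ("F30", "F39"),
}

#: Fine occupation codes mapped to the three analysis classes.  Editable:
#: pass a modified copy to the network module to change the mapping.
DEFAULT_OCCUPATION_MAP = {
    "physician": "physician",
    "gp": "physician",
    "specialist_physician": "physician",
    "registered_nurse": "nurse",
    "practical_nurse": "nurse",
    "public_health_nurse": "nurse",
    "community_health_nurse": "nurse",
    "radiographer": "nurse",
    "midwife": "nurse",
    "psychologist": "other",
    "physiotherapist": "other",
    "occupational_therapist": "other",
    "therapist": "other",
    "social_worker": "other",
}

#: Occupations removed from the cohort (not involved in direct care).
DEFAULT_EXCLUDED_OCCUPATIONS = ("secretary", "manager", "pharmacist", "optician")


@dataclass(frozen=True)
class CohortDefinition:
    """Rules identifying mental-health/substance-use patients and subgroups.

    ICD-10 chapter F is included minus the exclusion ranges (defaults:
    dementia F00-F03, mental retardation F70-F79, specific developmental
    disorders F80-F83); ICPC-2 chapter P minus the exclusion codes
    (defaults P70, P85, P24); visits whose service type is flagged as
    mental-health/substance-abuse related qualify regardless of codes.

    Note: the "depressive" subgroup range is the full F30-F39 block even
    though F30-F31 are manic/bipolar codes; the label follows the block.
    """

    icd10_include_prefix: str = "F"
    icd10_exclude_ranges: tuple[tuple[str, str], ...] = (
        ("F00", "F03"),
        ("F70", "F79"),
        ("F80", "F83"),
    )
    icpc2_include_prefix: str = "P"
    icpc2_exclude_codes: tuple[str, ...] = ("P70", "P85", "P24")
    use_service_flag: bool = True
    subgroup: str | None = None

    def __post_init__(self) -> None:
        for lo, hi in self.icd10_exclude_ranges:
            if lo[0] != hi[0]:
                raise SpecificationError(
                    f"exclusion range {lo}-{hi} spans two code chapters"
                )
            if lo > hi:
                raise SpecificationError(f"exclusion range {lo}-{hi} has lower > upper")
        if self.subgroup is not None and self.subgroup not in (
            *SUBGROUP_RANGES,
            "all",
        ):
            raise SpecificationError(f"unknown subgroup {self.subgroup!r}")

    def with_subgroup(self, subgroup: str) -> "CohortDefinition":
        return replace(self, subgroup=subgroup)


@dataclass
class FilterStep:
    name: str
    n_patients: int
    n_visits: int


@dataclass
class FilterReport:
    """Ordered accounting of the exclusion cascade."""

    steps: list[FilterStep] = field(default_factory=list)

    def add(self, name: str, visits: pd.DataFrame) -> None:
        self.steps.append(
            FilterStep(name, int(visits["patient_id"].nunique()), int(len(visits)))
        )

    def extend(self, other: "FilterReport") -> None:
        self.steps.extend(other.steps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.name, s.n_patients, s.n_visits) for s in self.steps],
            columns=["step", "n_patients", "n_visits"],
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# code matching helpers


def _split_codes(cell) -> list[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return []
    return [c.strip().upper() for c in str(cell).split(";") if c.strip()]


def _prefix3(code: str) -> str:
    """Three-character category of a diagnosis code ('F32.1' -> 'F32')."""
    return code.replace(".", "")[:3]


def icd10_qualifies(code: str, defn: CohortDefinition) -> bool:
    code = code.strip().upper()
    if not code.startswith(defn.icd10_include_prefix):
        return False
    p = _prefix3(code)
    return not any(lo <= p <= hi for lo, hi in defn.icd10_exclude_ranges)


def icpc2_qualifies(code: str, defn: CohortDefinition) -> bool:
    code = code.strip().upper()
    if not code.startswith(defn.icpc2_include_prefix):
        return False
    return _prefix3(code) not in defn.icpc2_exclude_codes


def code_in_range(code: str, lo: str, hi: str) -> bool:
    p = _prefix3(code.strip().upper())
    return p[:1] == lo[:1] and lo <= p <= hi


# ---------------------------------------------------------------------------
# operations


def _visit_qualifies_mask(visits: pd.DataFrame, defn: CohortDefinition) -> pd.Series:
    icd = visits["icd10_codes"].map(
        lambda s: any(icd10_qualifies(c, defn) for c in _split_codes(s))
    )
    icpc = visits["icpc2_codes"].map(
        lambda s: any(icpc2_qualifies(c, defn) for c in _split_codes(s))
    )
    mask = icd | icpc
    if defn.use_service_flag:
        mask |= visits["mh_service_flag"].astype(bool)
    return mask


def identify_mh_patients(
    visits: pd.DataFrame, defn: CohortDefinition | None = None
) -> set:
    """Patients with at least one qualifying visit.

    A visit qualifies if any ICD-10 code is in chapter F minus the
    exclusion ranges, any ICPC-2 code is in chapter P minus the exclusion
    list, or the visit's service type is flagged as mental-health related.
    """
    defn = defn or CohortDefinition()
    mask = _visit_qualifies_mask(visits, defn)
    return set(visits.loc[mask, "patient_id"].unique())


def restrict_to_patients(visits: pd.DataFrame, patients: Iterable) -> pd.DataFrame:
    """All visits of the given patients (cohort membership is patient-level)."""
    patients = set(patients)
    return visits[visits["patient_id"].isin(patients)].copy()


def apply_visit_exclusions(
    visits: pd.DataFrame,
    excluded_occupations: Sequence[str] = DEFAULT_EXCLUDED_OCCUPATIONS,
    excluded_settings: Sequence[str] = ("home_care",),
) -> tuple[pd.DataFrame, FilterReport]:
    """Row-level exclusion cascade, applied in a fixed, audited order.

    Steps: home-care (excluded settings); undefined service type;
    occupational-health visits; rows missing professional id, occupation
    or service type; visits to excluded occupations.
    """
    report = FilterReport()
    out = visits
    report.add("input", out)

    out = out[~out["service_type"].isin(set(excluded_settings))]
    report.add("remove_home_care", out)

    out = out[out["service_type"] != "undefined"]
    report.add("remove_undefined_service_type", out)

    out = out[out["service_type"] != "occupational_health"]
    report.add("remove_occupational_health", out)

    complete = (
        out["professional_id"].notna()
        & (out["professional_id"].astype(str) != "")
        & out["occupation_code"].notna()
        & (out["occupation_code"].astype(str) != "")
        & out["service_type"].notna()
        & (out["service_type"].astype(str) != "")
    )
    out = out[complete]
    report.add("remove_missing_professional_info", out)

    out = out[~out["occupation_code"].isin(set(excluded_occupations))]
    report.add("remove_excluded_occupations", out)

    return out.copy(), report


def apply_patient_exclusions(
    visits: pd.DataFrame,
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop single-visit patients, then single-professional patients.

    Deliberately one sequential pass (no fixed-point iteration): a patient
    left with one visit only *after* the single-professional rule is not
    re-dropped.
    """
    report = FilterReport()
    report.add("input", visits)

    counts = visits.groupby("patient_id")["professional_id"].size()
    multi_visit = counts[counts > 1].index
    out = visits[visits["patient_id"].isin(multi_visit)]
    report.add("remove_single_visit_patients", out)

    nprof = out.groupby("patient_id")["professional_id"].nunique()
    multi_prof = nprof[nprof > 1].index
    out = out[out["patient_id"].isin(multi_prof)]
    report.add("remove_single_professional_patients", out)

    return out.copy(), report


def extract_subgroup(visits: pd.DataFrame, defn: CohortDefinition) -> pd.DataFrame:
    """All visits of patients with >=1 visit carrying a subgroup ICD code.

    Patients may belong to several subgroups; ``subgroup='all'`` returns
    the table unchanged.
    """
    if defn.subgroup is None:
        raise SpecificationError("CohortDefinition.subgroup must be set")
    if defn.subgroup == "all":
        return visits.copy()
    try:
        lo, hi = SUBGROUP_RANGES[defn.subgroup]
    except KeyError:  # pragma: no cover - blocked by CohortDefinition validation
        raise SpecificationError(f"unknown subgroup {defn.subgroup!r}") from None
    mask = visits["icd10_codes"].map(
        lambda s: any(code_in_range(c, lo, hi) for c in _split_codes(s))
    )
    members = set(visits.loc[mask, "patient_id"].unique())
    return restrict_to_patients(visits, members)


def filter_cohort(
    visits: pd.DataFrame, defn: CohortDefinition | None = None
) -> tuple[pd.DataFrame, FilterReport]:
    """Full cascade: identify patients, visit exclusions, patient exclusions."""
    defn = defn or CohortDefinition()
    report = FilterReport()
    report.add("initial", visits)

    patients = identify_mh_patients(visits, defn)
    cohort = restrict_to_patients(visits, patients)
    report.add("identify_mh_patients", cohort)

    cohort, visit_report = apply_visit_exclusions(cohort)
    report.steps.extend(visit_report.steps[1:])  # drop duplicate "input" row

    cohort, patient_report = apply_patient_exclusions(cohort)
    report.steps.extend(patient_report.steps[1:])
    return cohort, report
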