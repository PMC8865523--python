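"""Patients, per-modality dose summaries, and dosimetric subgroup rules.

A patient carries demographics (sex, age at treatment, smoking status),
anthracycline exposure, a longitudinal anatomy profile (CTV and heart
cranio-caudal extents plus two anatomical marker coordinates), and one mean
organ-dose summary per treatment modality (photon and proton plans on the
same anatomy).  Proton doses are in GyE (RBE 1.1); photon doses in Gy.

Subgroup rules implemented here:

* ``overlap`` — fraction of the heart's cranio-caudal extent covered by the
  CTV; ``ge40`` when >= 40% (inclusive).
* ``lmsca`` — whether the CTV extends below the origin of the left main
  stem coronary artery (a proton-referral criterion).
* ``t7`` — whether the CTV extends below the inferior endplate of the 7th
  thoracic vertebra.
* ``axilla`` — axillary involvement flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DataValidationError, SchemaError

MODALITIES = ("photon", "proton")
SMOKING_STATUSES = ("never", "current", "former", "unknown")

#: Weights for the combined heart-valve dose metric (aortic, mitral,
#: tricuspid), reflecting each valve's contribution to valvular-disease risk.
VALVE_WEIGHTS = {"aortic_valve": 0.553, "mitral_valve": 0.368, "tricuspid_valve": 0.079}

#: Sanity cap on a mean organ dose (Gy); prescription doses in this setting
#: are ~20-40 Gy, so a mean organ dose beyond this indicates bad input.
DEFAULT_DOSE_CAP = 60.0

_DOSE_FIELDS = (
    "whole_heart",
    "left_ventricle",
    "aortic_valve",
    "mitral_valve",
    "tricuspid_valve",
    "carotid_arteries",
    "lungs",
    "breast",
    "esophagus",
    "normal_tissue",
)


@dataclass
class DoseSummary:
    """Mean doses (Gy / GyE) to organs at risk for one plan."""

    modality: str
    whole_heart: float | None = None
    left_ventricle: float | None = None
    aortic_valve: float | None = None
    mitral_valve: float | None = None
    tricuspid_valve: float | None = None
    carotid_arteries: float | None = None
    lungs: float | None = None
    breast: float | None = None
    esophagus: float | None = None
    normal_tissue: float | None = None
    extras: dict[str, float] = field(default_factory=dict)
    dose_cap: float = DEFAULT_DOSE_CAP

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise DataValidationError(f"unknown modality {self.modality!r}")
        for name, value in self.items():
            if value < 0:
                raise DataValidationError(f"{self.modality} dose {name}={value} is negative")
            if value > self.dose_cap:
                raise DataValidationError(
                    f"{self.modality} dose {name}={value} exceeds sanity cap {self.dose_cap} Gy"
                )

    def items(self):
        for name in _DOSE_FIELDS:
            value = getattr(self, name)
            if value is not None:
                yield name, float(value)
        yield from self.extras.items()

    def get(self, metric: str) -> float | None:
        """Dose for a named metric; ``sum_valve`` is computed on the fly."""
        if metric == "sum_valve":
            try:
                return sum_valve_dose(self)
            except DataValidationError:
                return None
        if metric in _DOSE_FIELDS:
            value = getattr(self, metric)
            return None if value is None else float(value)
        return self.extras.get(metric)


def sum_valve_dose(doses: DoseSummary) -> float:
    """Weighted mean heart-valve dose (aortic/mitral/tricuspid)."""
    total = 0.0
    for valve, weight in VALVE_WEIGHTS.items():
        value = getattr(doses, valve)
        if value is None:
            raise DataValidationError(f"cannot compute sum_valve: {valve} dose missing")
        total += weight * value
    return total


@dataclass
class AnatomyProfile:
    """Longitudinal (cranio-caudal) anatomy on one patient axis.

    Coordinates are in cm on an arbitrary-origin axis with superior =
    larger value; only differences are used.
    """

    ctv_sup_z: float
    ctv_inf_z: float
    heart_sup_z: float
    heart_inf_z: float
    lmsca_origin_z: float
    t7_inferior_z: float
    axilla_involved: bool

    def __post_init__(self) -> None:
        if not self.ctv_sup_z > self.ctv_inf_z:
            raise DataValidationError(
                f"CTV extent degenerate: sup {self.ctv_sup_z} <= inf {self.ctv_inf_z}"
            )
        if not self.heart_sup_z > self.heart_inf_z:
            raise DataValidationError(
                f"heart extent degenerate: sup {self.heart_sup_z} <= inf {self.heart_inf_z}"
            )


def heart_overlap_fraction(anatomy: AnatomyProfile, denominator: str = "heart") -> float:
    """Fraction of the heart's longitudinal extent covered by the CTV.

    Intersection of the CTV and heart intervals divided by the heart's
    cranio-caudal length, clipped to [0, 1].  With the default denominator,
    ">=40% overlap" reads "at least 40% of the heart lies in the treated
    longitudinal band"; ``denominator='ctv'`` normalizes by the CTV length
    instead.
    """
    if denominator == "heart":
        denom = anatomy.heart_sup_z - anatomy.heart_inf_z
    elif denominator == "ctv":
        denom = anatomy.ctv_sup_z - anatomy.ctv_inf_z
    else:
        raise DataValidationError(f"unknown overlap denominator {denominator!r}")
    if denom <= 0:
        raise DataValidationError(f"{denominator} extent has zero length")
    lo = max(anatomy.ctv_inf_z, anatomy.heart_inf_z)
    hi = min(anatomy.ctv_sup_z, anatomy.heart_sup_z)
    return float(np.clip((hi - lo) / denom, 0.0, 1.0))


@dataclass(frozen=True)
class SubgroupLabels:
    overlap: str  # lt40 | ge40
    lmsca: str    # above_only | below
    t7: str       # above | below
    axilla: str   # yes | no

    def as_dict(self) -> dict[str, str]:
        return {"overlap": self.overlap, "lmsca": self.lmsca, "t7": self.t7, "axilla": self.axilla}


@dataclass
class PatientRecord:
    id: str
    sex: str
    age_at_treatment: float
    smoking: str
    anthracycline_dose: float  # mg/m2 doxorubicin-equivalent
    anatomy: AnatomyProfile | None = None
    doses: dict[str, DoseSummary] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise DataValidationError(f"patient {self.id}: unknown sex {self.sex!r}")
        if self.age_at_treatment < 0:
            raise DataValidationError(f"patient {self.id}: negative age")
        if self.smoking not in SMOKING_STATUSES:
            raise DataValidationError(f"patient {self.id}: unknown smoking status {self.smoking!r}")
        if self.anthracycline_dose < 0:
            raise DataValidationError(f"patient {self.id}: negative anthracycline dose")
        for modality, summary in self.doses.items():
            if summary.modality != modality:
                raise DataValidationError(
                    f"patient {self.id}: dose summary modality {summary.modality!r} "
                    f"stored under key {modality!r}"
                )


def classify_subgroups(patient: PatientRecord, overlap_threshold: float = 0.40) -> SubgroupLabels:
    """Assign the four dosimetric subgroup labels from anatomy alone.

    The overlap threshold is inclusive (exactly 40% -> ``ge40``); a CTV
    whose inferior edge sits exactly at the LMSCA origin (or T7 endplate)
    counts as "at and above", not below.
    """
    anatomy = patient.anatomy
    if anatomy is None:
        raise DataValidationError(f"patient {patient.id}: no anatomy profile")
    frac = heart_overlap_fraction(anatomy)
    return SubgroupLabels(
        overlap="ge40" if frac >= overlap_threshold else "lt40",
        lmsca="below" if anatomy.ctv_inf_z < anatomy.lmsca_origin_z else "above_only",
        t7="below" if anatomy.ctv_inf_z < anatomy.t7_inferior_z else "above",
        axilla="yes" if anatomy.axilla_involved else "no",
    )


# -- cohort CSV IO --------------------------------------------------------

_COL_TO_DOSE = {
    "mhd": "whole_heart",
    "mlvd": "left_ventricle",
    "av": "aortic_valve",
    "mv": "mitral_valve",
    "tv": "tricuspid_valve",
    "carotid": "carotid_arteries",
    "mld": "lungs",
    "mbd": "breast",
    "esoph": "esophagus",
    "normal_tissue": "normal_tissue",
}

_COHORT_COLUMNS = (
    "id", "sex", "age", "smoking", "anthracycline_mg_m2", "modality",
    *_COL_TO_DOSE, "ctv_sup", "ctv_inf", "heart_sup", "heart_inf",
    "lmsca_z", "t7_z", "axilla",
)


def write_cohort(cohort: list[PatientRecord], path) -> None:
    """Write one row per (patient, modality) in the cohort CSV schema."""
    rows = []
    for p in cohort:
        for modality in sorted(p.doses):
            d = p.doses[modality]
            row = {
                "id": p.id, "sex": p.sex, "age": p.age_at_treatment,
                "smoking": p.smoking, "anthracycline_mg_m2": p.anthracycline_dose,
                "modality": modality,
            }
            for col, attr in _COL_TO_DOSE.items():
                row[col] = getattr(d, attr)
            a = p.anatomy
            row.update(
                ctv_sup=a.ctv_sup_z if a else None,
                ctv_inf=a.ctv_inf_z if a else None,
                heart_sup=a.heart_sup_z if a else None,
                heart_inf=a.heart_inf_z if a else None,
                lmsca_z=a.lmsca_origin_z if a else None,
                t7_z=a.t7_inferior_z if a else None,
                axilla=(int(a.axilla_involved) if a else None),
            )
            rows.append(row)
    pd.DataFrame(rows, columns=_COHORT_COLUMNS).to_csv(path, index=False)


def read_cohort(path) -> list[PatientRecord]:
    """Read a cohort CSV (one row per patient-modality) back into records."""
    df = pd.read_csv(path)
    missing = {"id", "sex", "age", "smoking", "anthracycline_mg_m2", "modality"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {sorted(missing)}")
    if df["modality"].isna().any():
        raise SchemaError(f"{path}: row with missing modality")
    dup = df.duplicated(subset=["id", "modality"])
    if dup.any():
        bad = df.loc[dup, ["id", "modality"]].iloc[0]
        raise DataValidationError(
            f"{path}: duplicate rows for patient {bad['id']!r} modality {bad['modality']!r}"
        )

    def _opt(value):
        return None if pd.isna(value) else float(value)

    patients: list[PatientRecord] = []
    for pid, grp in df.groupby("id", sort=False):
        first = grp.iloc[0]
        anatomy = None
        if not pd.isna(first.get("heart_sup")):
            anatomy = AnatomyProfile(
                ctv_sup_z=float(first["ctv_sup"]), ctv_inf_z=float(first["ctv_inf"]),
                heart_sup_z=float(first["heart_sup"]), heart_inf_z=float(first["heart_inf"]),
                lmsca_origin_z=float(first["lmsca_z"]), t7_inferior_z=float(first["t7_z"]),
                axilla_involved=bool(int(first["axilla"])),
            )
        doses = {}
        for _, row in grp.iterrows():
            modality = str(row["modality"])
            kwargs = {attr: _opt(row.get(col)) for col, attr in _COL_TO_DOSE.items()}
            doses[modality] = DoseSummary(modality=modality, **kwargs)
        patients.append(PatientRecord(
            id=str(pid), sex=str(first["sex"]), age_at_treatment=float(first["age"]),
            smoking=str(first["smoking"]), anthracycline_dose=float(first["anthracycline_mg_m2"]),
            anatomy=anatomy, doses=doses,
        ))
    return patients
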