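"""Competing-risks life table and 30-year absolute mortality risk (AMR30).

The projection runs a discrete annual life table over the ``horizon`` years
after treatment.  In year ``t`` (t = 1..H) the attained age is
``age_at_treatment + t - 1`` (start-of-year lookup; an ``age_offset`` flag
switches to mid-year).  Each modeled endpoint ``c`` contributes an annual
hazard

    h_c(t) = background(sex, c, age) * smoking * chemo * radiation

where the chemo and radiation multipliers enter only in the corresponding
model layers, and a residual ``all other causes`` hazard competes.  Within
a year, survival is exponential in the total hazard and the probability of
death is apportioned to causes proportionally to their hazards:

    q_c(t)  = h_c(t) / H_tot(t) * (1 - exp(-H_tot(t)))
    S(t)    = exp(-sum_{u<=t} H_tot(u))
    AMR_c   = sum_t S(t-1) * q_c(t)

which is exact for piecewise-constant competing hazards.  Cause-specific
AMRs plus the other-cause AMR sum to ``1 - S(H)`` identically, so the
decomposition conserves total mortality.

Three nested model layers decompose each risk: ``background`` (no
treatment), ``chemo`` (background + chemotherapy), and ``full`` (background
+ chemotherapy + radiation, per modality).  Smoking multiplies all layers:
it is a host factor, not a treatment layer.

Each disease group (CVD as one group of five cardiovascular causes; each
second cancer on its own) is projected in its own life table in which only
that group's hazards carry the treatment multipliers, while every other
modeled cause competes at its background (smoking-adjusted) level.  This
keeps the layered decomposition clean — adding a cardiac treatment effect
cannot change the reported lung-cancer risk through competing-risk
leakage — and the CVD total is the sum of the five cardiovascular
cause-specific AMRs from the joint CVD table, which equals the group's
cumulative incidence exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    AnatomyProfile,
    DoseSummary,
    PatientRecord,
    classify_subgroups,
)
from .dose_response import (
    DoseResponseConfig,
    chemo_rate_factor,
    radiation_rate_factor,
    smoking_rate_factor,
)
from .errors import DataValidationError, RateLookupError
from .rate_tables import ALL_OTHER, CVD_ENDPOINTS, ENDPOINTS, RateTable

LAYERS = ("background", "chemo", "full")
COMBINATION_MODES = ("multiplicative", "additive_err")

#: Default age-band edges for direct age/sex standardization.
DEFAULT_AGE_EDGES = (0.0, 25.0, 35.0, 45.0, 55.0, 65.0, float("inf"))


@dataclass
class HazardSchedule:
    """Annual cause-specific hazards over the projection horizon."""

    endpoints: tuple[str, ...]
    hazards: np.ndarray  # shape (horizon, n_endpoints)
    other: np.ndarray    # shape (horizon,)

    def __post_init__(self) -> None:
        self.hazards = np.asarray(self.hazards, dtype=float)
        self.other = np.asarray(self.other, dtype=float)
        if self.hazards.ndim != 2 or self.hazards.shape[1] != len(self.endpoints):
            raise DataValidationError("hazard matrix shape does not match endpoints")
        if self.other.shape != (self.hazards.shape[0],):
            raise DataValidationError("other-cause hazard length mismatch")
        if np.any(self.hazards < 0) or np.any(self.other < 0):
            raise DataValidationError("negative hazard in schedule")

    @property
    def horizon(self) -> int:
        return self.hazards.shape[0]


def build_hazard_schedule(
    patient: PatientRecord,
    modality: str | None,
    rates: RateTable,
    cfg: DoseResponseConfig,
    layer: str,
    horizon: int = 30,
    age_offset: float = 0.0,
    combination: str = "multiplicative",
    treated_endpoints: Sequence[str] | None = None,
) -> HazardSchedule:
    """Per-endpoint annual hazards for one patient, modality and model layer.

    ``layer='background'`` ignores treatment entirely (modality may be
    None); ``'chemo'`` adds the anthracycline rate ratios; ``'full'`` adds
    the radiation factors for the given modality's dose summary.
    ``treated_endpoints`` restricts which endpoints carry the treatment
    multipliers (default: all); untreated endpoints keep their background
    (smoking-adjusted) hazards and still compete.  The residual competing
    hazard is the table's ``all_other_causes`` series (or all-cause minus
    the modeled endpoints' background, floored at 0, when only an
    ``all_causes`` series is present).
    """
    if layer not in LAYERS:
        raise DataValidationError(f"unknown layer {layer!r}")
    if combination not in COMBINATION_MODES:
        raise DataValidationError(f"unknown combination mode {combination!r}")
    ages = patient.age_at_treatment + np.arange(horizon, dtype=float) + age_offset
    doses = None
    if layer == "full":
        if modality is None or modality not in patient.doses:
            raise DataValidationError(
                f"patient {patient.id}: modality {modality!r} dose summary missing"
            )
        doses = patient.doses[modality]

    latency = cfg.latency_years
    rad_active = (np.arange(1, horizon + 1) > latency).astype(float)
    treated = set(ENDPOINTS if treated_endpoints is None else treated_endpoints)

    cols = []
    background = {}
    for endpoint in ENDPOINTS:
        bg = rates.hazard_vector(patient.sex, endpoint, ages)
        background[endpoint] = bg
        factor = smoking_rate_factor(cfg, endpoint, patient.smoking)
        if layer == "background" or endpoint not in treated:
            cols.append(bg * factor)
            continue
        chemo = chemo_rate_factor(cfg, endpoint, patient.anthracycline_dose)
        if layer == "chemo":
            cols.append(bg * factor * chemo)
            continue
        rad = radiation_rate_factor(cfg, endpoint, doses, patient.age_at_treatment,
                                    sex=patient.sex)
        # radiation excess switched off during an optional latency period
        rad_t = 1.0 + (rad - 1.0) * rad_active
        if combination == "multiplicative":
            treat = chemo * rad_t
        else:  # additive on the excess-relative-risk scale
            treat = np.maximum(chemo + rad_t - 1.0, 0.0)
        cols.append(bg * factor * treat)
    hazards = np.column_stack(cols)

    if rates.has(patient.sex, ALL_OTHER):
        other = rates.hazard_vector(patient.sex, ALL_OTHER, ages)
    elif rates.has(patient.sex, "all_causes"):
        total = rates.hazard_vector(patient.sex, "all_causes", ages)
        other = np.maximum(total - sum(background.values()), 0.0)
    else:
        raise RateLookupError(
            f"rate table {rates.name!r} has neither {ALL_OTHER!r} nor 'all_causes' "
            f"for sex {patient.sex!r}"
        )
    return HazardSchedule(endpoints=ENDPOINTS, hazards=hazards, other=other)


def cumulative_incidence(schedule: HazardSchedule,
                         horizon: int | None = None) -> tuple[dict[str, float], float]:
    """Cause-specific cumulative incidence over the horizon.

    Returns ``(amr_by_endpoint, amr_other)``.  Years with zero total hazard
    contribute zero to every cause.
    """
    h = schedule.horizon if horizon is None else int(horizon)
    if h > schedule.horizon:
        raise DataValidationError(f"horizon {h} exceeds schedule length {schedule.horizon}")
    hz = schedule.hazards[:h]
    other = schedule.other[:h]
    h_tot = hz.sum(axis=1) + other
    surv_end = np.exp(-np.cumsum(h_tot))
    surv_start = np.concatenate([[1.0], surv_end[:-1]])
    p_death = 1.0 - np.exp(-h_tot)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(h_tot > 0, 1.0 / np.where(h_tot > 0, h_tot, 1.0), 0.0)
    weight = surv_start * p_death * share  # S(t-1) * (1-exp(-H)) / H
    amr = {ep: float(np.sum(weight * hz[:, i])) for i, ep in enumerate(schedule.endpoints)}
    return amr, float(np.sum(weight * other))


def cumulative_mortality(schedule: HazardSchedule, cause: str,
                         horizon: int | None = None) -> float:
    """Cumulative probability of dying of ``cause`` within the horizon,
    accounting for all competing hazards in the schedule."""
    amr, other = cumulative_incidence(schedule, horizon)
    if cause == ALL_OTHER:
        return other
    if cause == "cvd":
        return sum(amr[ep] for ep in CVD_ENDPOINTS)
    if cause not in amr:
        raise DataValidationError(f"cause {cause!r} not in schedule")
    return amr[cause]


# -- per-patient decomposition -------------------------------------------

#: Disease groups reported downstream; "cvd" aggregates five endpoints.
REPORT_DISEASES = ("cvd", "lung_cancer", "breast_cancer", "esophageal_cancer")


@dataclass(frozen=True)
class EndpointRisk:
    """AMR30 for one endpoint under the three nested model layers."""

    background: float
    chemo: float
    full: dict[str, float]  # modality -> AMR30

    @property
    def excess_chemo(self) -> float:
        return self.chemo - self.background

    def excess_rt(self, modality: str) -> float:
        return self.full[modality] - self.chemo


@dataclass
class RiskDecomposition:
    patient_id: str
    horizon: int
    risks: dict[str, EndpointRisk]  # endpoint (incl. "cvd") -> risks
    flags: tuple[str, ...] = ()

    def to_records(self) -> list[dict]:
        rows = []
        for endpoint, r in self.risks.items():
            row = {
                "patient_id": self.patient_id,
                "endpoint": endpoint,
                "amr30_background": r.background,
                "amr30_chemo": r.chemo,
                "excess_chemo": r.excess_chemo,
            }
            for modality, value in r.full.items():
                row[f"amr30_full_{modality}"] = value
                row[f"excess_rt_{modality}"] = value - r.chemo
            rows.append(row)
        return rows


def decompose_patient(
    patient: PatientRecord,
    rates: RateTable,
    cfg: DoseResponseConfig,
    horizon: int = 30,
    modalities: Sequence[str] = ("photon", "proton"),
    age_offset: float = 0.0,
    combination: str = "multiplicative",
) -> RiskDecomposition:
    """Layered AMR30 per endpoint for one patient under both modalities.

    Background and chemo layers are shared across modalities (the paired
    design isolates radiation effects).  Each disease group is projected
    in its own life table: the group's hazards carry the treatment
    multipliers of the layer while every other modeled cause competes at
    background level, and each risk is the cause-specific cumulative
    incidence from that table.
    """
    for m in modalities:
        if m not in patient.doses:
            raise DataValidationError(f"patient {patient.id}: modality {m!r} doses missing")

    groups: dict[str, tuple[str, ...]] = {
        "cvd": tuple(CVD_ENDPOINTS),
        "lung_cancer": ("lung_cancer",),
        "breast_cancer": ("breast_cancer",),
        "esophageal_cancer": ("esophageal_cancer",),
    }

    def _amrs(layer: str, modality: str | None, members: tuple[str, ...]) -> dict[str, float]:
        schedule = build_hazard_schedule(
            patient, modality, rates, cfg, layer, horizon=horizon,
            age_offset=age_offset, combination=combination,
            treated_endpoints=members,
        )
        amr, _ = cumulative_incidence(schedule)
        return amr

    risks: dict[str, EndpointRisk] = {}
    for group, members in groups.items():
        bg = _amrs("background", None, members)
        ch = _amrs("chemo", None, members)
        full = {m: _amrs("full", m, members) for m in modalities}
        for ep in members:
            risks[ep] = EndpointRisk(
                background=bg[ep], chemo=ch[ep],
                full={m: full[m][ep] for m in modalities},
            )
        risks[group] = EndpointRisk(
            background=sum(bg[ep] for ep in members),
            chemo=sum(ch[ep] for ep in members),
            full={m: sum(full[m][ep] for ep in members) for m in modalities},
        ) if group == "cvd" else risks[members[0]]
    flags = ("smoking_unknown_treated_as_never",) if patient.smoking == "unknown" else ()
    return RiskDecomposition(patient_id=patient.id, horizon=horizon, risks=risks, flags=flags)


def scenario_risk(
    age: float,
    sex: str,
    smoking: str,
    doses: DoseSummary | Mapping[str, DoseSummary],
    anthracycline: float,
    rates: RateTable,
    cfg: DoseResponseConfig,
    horizon: int = 30,
    **kwargs,
) -> RiskDecomposition:
    """Layered AMR30 for a hypothetical individual.

    ``doses`` may be a single summary (applied to both modalities) or a
    mapping modality -> summary; used to build smoking-scenario panels.
    """
    from dataclasses import replace

    if isinstance(doses, DoseSummary):
        dose_map = {m: replace(doses, modality=m) for m in ("photon", "proton")}
    else:
        dose_map = dict(doses)
    patient = PatientRecord(
        id="scenario", sex=sex, age_at_treatment=age, smoking=smoking,
        anthracycline_dose=anthracycline, anatomy=None, doses=dose_map,
    )
    return decompose_patient(patient, rates, cfg, horizon=horizon,
                             modalities=tuple(dose_map), **kwargs)


# -- direct age/sex standardization --------------------------------------


@dataclass(frozen=True)
class StandardizedMean:
    value: float
    flagged: bool
    missing_strata: tuple = ()


def age_sex_stratum(patient: PatientRecord,
                    age_edges: Sequence[float] = DEFAULT_AGE_EDGES) -> tuple[str, str]:
    edges = np.asarray(age_edges, dtype=float)
    i = int(np.searchsorted(edges, patient.age_at_treatment, side="right") - 1)
    hi = edges[i + 1]
    label = f"[{edges[i]:g},{hi:g})" if np.isfinite(hi) else f"[{edges[i]:g},inf)"
    return (label, patient.sex)


def standardize(values: pd.Series, strata: pd.Series,
                standard: pd.Series | None = None,
                renormalize: bool = False) -> StandardizedMean:
    """Directly standardized mean: sum_s w_s * mean(values in stratum s).

    ``standard`` gives the weight per stratum (must sum to 1); by default
    the observed stratum distribution of ``values`` itself, in which case
    the standardized mean equals the crude mean.  A stratum with positive
    weight but no observations flags the result (or, with ``renormalize``,
    is dropped and the remaining weights rescaled).
    """
    if len(values) == 0:
        raise DataValidationError("cannot standardize an empty series")
    strata = strata.loc[values.index]
    if standard is None:
        standard = strata.value_counts(normalize=True)
    total = float(standard.sum())
    if not np.isclose(total, 1.0, atol=1e-9):
        raise DataValidationError(f"standard weights sum to {total}, not 1")
    means = values.groupby(strata).mean()
    missing = [s for s, w in standard.items() if w > 0 and s not in means.index]
    if missing and not renormalize:
        present = standard.reindex(means.index, fill_value=0.0)
        value = float((means * present).sum() + 0.0)
        # keep the un-renormalized weighted sum over present strata
        return StandardizedMean(value=value, flagged=True, missing_strata=tuple(missing))
    weights = standard[standard.index.isin(means.index)]
    if renormalize and missing:
        weights = weights / weights.sum()
    value = float((means * weights.reindex(means.index, fill_value=0.0)).sum())
    return StandardizedMean(value=value, flagged=False, missing_strata=tuple(missing))


# -- cohort-level prediction and reporting -------------------------------

#: Patient groups reported per disease, mirroring the standardized
#: disease x subgroup x region x modality summary table.
REPORT_GROUPS = {
    "cvd": ("all", "lt40", "ge40", "lmsca_above_only", "lmsca_below"),
    "lung_cancer": ("all", "no_axilla", "axilla"),
    "breast_cancer": ("all_women", "no_axilla_women", "axilla_women"),
    "esophageal_cancer": ("all",),
}


def _group_members(cohort: Sequence[PatientRecord], group: str,
                   overlap_threshold: float) -> list[str]:
    out = []
    for p in cohort:
        labels = classify_subgroups(p, overlap_threshold) if p.anatomy else None
        ok = {
            "all": True,
            "all_women": p.sex == "female",
            "lt40": labels is not None and labels.overlap == "lt40",
            "ge40": labels is not None and labels.overlap == "ge40",
            "lmsca_above_only": labels is not None and labels.lmsca == "above_only",
            "lmsca_below": labels is not None and labels.lmsca == "below",
            "axilla": labels is not None and labels.axilla == "yes",
            "no_axilla": labels is not None and labels.axilla == "no",
            "axilla_women": labels is not None and labels.axilla == "yes" and p.sex == "female",
            "no_axilla_women": labels is not None and labels.axilla == "no" and p.sex == "female",
        }[group]
        if ok:
            out.append(p.id)
    return out


@dataclass
class CohortPrediction:
    decomposition: pd.DataFrame  # long: one row per patient x region x endpoint
    report: pd.DataFrame         # disease x group x region x modality summary (%)
    metadata: dict


def predict_cohort(
    cohort: Sequence[PatientRecord],
    rates_by_region: Mapping[str, RateTable],
    cfg: DoseResponseConfig,
    horizon: int = 30,
    overlap_threshold: float = 0.40,
    age_edges: Sequence[float] = DEFAULT_AGE_EDGES,
    standard: pd.Series | None = None,
    combination: str = "multiplicative",
    age_offset: float = 0.0,
) -> CohortPrediction:
    """Run the full pipeline: per-patient decompositions in every region,
    then the standardized disease x subgroup x region x modality report.

    The default standard population is the full input cohort's age/sex
    stratum distribution, so the "all patients" rows are crude means.
    """
    strata = pd.Series({p.id: age_sex_stratum(p, age_edges) for p in cohort})
    default_standard = standard is None
    if standard is None:
        standard = strata.value_counts(normalize=True)

    rows = []
    for region, rates in rates_by_region.items():
        for p in cohort:
            decomp = decompose_patient(
                p, rates, cfg, horizon=horizon,
                combination=combination, age_offset=age_offset,
            )
            for rec in decomp.to_records():
                rec["region"] = region
                rec["flags"] = ";".join(decomp.flags)
                rows.append(rec)
    decomposition = pd.DataFrame(rows)

    report_rows = []
    for disease, groups in REPORT_GROUPS.items():
        for group in groups:
            member_ids = _group_members(cohort, group, overlap_threshold)
            if not member_ids:
                continue
            for region in rates_by_region:
                sub = decomposition[
                    (decomposition["region"] == region)
                    & (decomposition["endpoint"] == disease)
                    & (decomposition["patient_id"].isin(member_ids))
                ].set_index("patient_id")
                for modality in ("photon", "proton"):
                    col = f"amr30_full_{modality}"
                    std = standardize(sub[col], strata, standard=standard)
                    report_rows.append({
                        "disease": disease, "patient_group": group, "region": region,
                        "modality": modality,
                        "amr30_pct": 100.0 * std.value,
                        "amr30_min_pct": 100.0 * sub[col].min(),
                        "amr30_max_pct": 100.0 * sub[col].max(),
                        "n": len(sub),
                        "standardization_flagged": std.flagged,
                    })
    report = pd.DataFrame(report_rows)

    metadata = {
        "horizon_years": horizon,
        "combination_mode": combination,
        "overlap_threshold": overlap_threshold,
        "age_offset": age_offset,
        "standard_population": ("input cohort age/sex distribution"
                                if default_standard else "caller-supplied"),
        "age_band_edges": [e for e in age_edges],
        "config_hash": hashlib.sha256(
            json.dumps(cfg.model_dump(), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "n_patients": len(cohort),
        "regions": list(rates_by_region),
    }
    return CohortPrediction(decomposition=decomposition, report=report, metadata=metadata)
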