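"""Treatment-exposure rate multipliers driven by a coefficient config.

Three multiplier families act on an endpoint's background mortality rate:

* radiation: ``1 + ERR(age_at_treatment) * D`` where ``D`` is the mean dose
  (Gy) to the endpoint's driving organ/substructure and ERR is the excess
  relative risk per Gy, optionally replaced inside age-at-treatment bands
  (linear no-threshold, no latency by default);
* chemotherapy: a rate ratio per anthracycline dose band (mg/m2
  doxorubicin-equivalent), modelled for cardiovascular endpoints only;
* smoking: a current-smoker vs never-smoker rate ratio, modelled for
  cardiovascular endpoints and lung cancer.

All coefficients live in a validated JSON/YAML config, not in code, because
they come from published epidemiological follow-up studies and sites may
substitute their preferred literature values.  The bundled
:func:`placeholder_config` carries synthetic placeholder values of
literature-typical magnitude for testing and demonstration.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import pydantic
from pydantic import BaseModel, Field

from .cohort import DoseSummary
from .errors import DataValidationError, SchemaError
from .rate_tables import ENDPOINTS

#: Default driving dose metric per endpoint.
DEFAULT_DOSE_METRICS = {
    "coronary_heart_disease": "whole_heart",
    "heart_failure": "left_ventricle",
    "valvular_heart_disease": "sum_valve",
    "other_cardiac": "whole_heart",
    "stroke": "carotid_arteries",
    "lung_cancer": "lungs",
    "breast_cancer": "breast",
    "esophageal_cancer": "esophagus",
}

KNOWN_METRICS = ("whole_heart", "left_ventricle", "sum_valve", "carotid_arteries",
                 "lungs", "breast", "esophagus", "normal_tissue")


class AgeBandERR(BaseModel):
    """Replacement ERR per Gy inside an age-at-treatment band [lo, hi)."""

    age_lo: float = Field(ge=0)
    age_hi: Optional[float] = None  # None = open-ended
    err_per_gy: float


class ChemoBand(BaseModel):
    """Rate ratio for an anthracycline dose band [lo, hi) in mg/m2."""

    dose_lo: float = Field(ge=0)
    dose_hi: Optional[float] = None
    rate_ratio: float = Field(gt=0)


class EndpointConfig(BaseModel):
    dose_metric: str
    err_per_gy: float = 0.0
    age_modifiers: list[AgeBandERR] = Field(default_factory=list)
    chemo_rr: list[ChemoBand] = Field(default_factory=list)
    smoking_rr: float = Field(default=1.0, gt=0)
    former_smoking_rr: Optional[float] = Field(default=None, gt=0)
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None


class DoseResponseConfig(BaseModel):
    """Per-endpoint coefficient sets, validated on load."""

    endpoints: dict[str, EndpointConfig]
    latency_years: float = Field(default=0.0, ge=0)
    dose_cap: float = Field(default=60.0, gt=0)

    @pydantic.model_validator(mode="after")
    def _check(self) -> "DoseResponseConfig":
        missing = set(ENDPOINTS) - set(self.endpoints)
        if missing:
            raise ValueError(f"config missing endpoint(s): {sorted(missing)}")
        for name, ep in self.endpoints.items():
            if ep.dose_metric not in KNOWN_METRICS:
                raise ValueError(
                    f"endpoint {name!r}: unknown dose metric {ep.dose_metric!r} "
                    f"(known: {KNOWN_METRICS})"
                )
            errs = [ep.err_per_gy] + [m.err_per_gy for m in ep.age_modifiers]
            for err in errs:
                if 1.0 + err * self.dose_cap <= 0:
                    raise ValueError(
                        f"endpoint {name!r}: ERR {err}/Gy drives the rate factor below 0 "
                        f"within the sanity dose range [0, {self.dose_cap}] Gy"
                    )
            bands = sorted(ep.age_modifiers, key=lambda m: m.age_lo)
            for a, b in zip(bands, bands[1:]):
                hi = a.age_hi if a.age_hi is not None else float("inf")
                if hi > b.age_lo:
                    raise ValueError(
                        f"endpoint {name!r}: overlapping age modifier bands at age {b.age_lo}"
                    )
            cb = sorted(ep.chemo_rr, key=lambda m: m.dose_lo)
            for a, b in zip(cb, cb[1:]):
                hi = a.dose_hi if a.dose_hi is not None else float("inf")
                if hi > b.dose_lo:
                    raise ValueError(
                        f"endpoint {name!r}: overlapping chemo dose bands at {b.dose_lo} mg/m2"
                    )
        return self


def load_config(path) -> DoseResponseConfig:
    """Load and validate a dose-response config from JSON or YAML."""
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            payload = yaml.safe_load(text)
        else:
            payload = json.loads(text)
    except Exception as exc:
        raise SchemaError(f"{path}: cannot parse: {exc}") from exc
    try:
        return DoseResponseConfig.model_validate(payload)
    except pydantic.ValidationError as exc:
        raise SchemaError(f"{path}: invalid dose-response config: {exc}") from exc


def save_config(cfg: DoseResponseConfig, path) -> None:
    Path(path).write_text(json.dumps(cfg.model_dump(), indent=2, sort_keys=True) + "\n")


def err_at_age(ep: EndpointConfig, age_at_treatment: float) -> float:
    """ERR per Gy applicable at an age at treatment (band replacement)."""
    for band in ep.age_modifiers:
        hi = band.age_hi if band.age_hi is not None else float("inf")
        if band.age_lo <= age_at_treatment < hi:
            return band.err_per_gy
    return ep.err_per_gy


def radiation_rate_factor(cfg: DoseResponseConfig, endpoint: str, doses: DoseSummary,
                          age_at_treatment: float, sex: str | None = None) -> float:
    """``1 + ERR(age) * D`` for the endpoint's configured dose metric.

    A male patient with no breast dose gets factor 1 for breast cancer
    (the structure was not contoured; its dose is effectively 0).
    """
    ep = _endpoint(cfg, endpoint)
    dose = doses.get(ep.dose_metric)
    if dose is None:
        if endpoint == "breast_cancer" and sex == "male":
            dose = 0.0
        else:
            raise DataValidationError(
                f"endpoint {endpoint!r}: dose metric {ep.dose_metric!r} missing from "
                f"{doses.modality} dose summary"
            )
    factor = 1.0 + err_at_age(ep, age_at_treatment) * dose
    if factor < 0:
        raise DataValidationError(
            f"endpoint {endpoint!r}: radiation rate factor {factor} < 0 at dose {dose} Gy"
        )
    return factor


def chemo_rate_factor(cfg: DoseResponseConfig, endpoint: str,
                      anthracycline_dose: float) -> float:
    """Anthracycline rate ratio for the dose band; 1 when unexposed or the
    endpoint has no configured chemotherapy effect."""
    if anthracycline_dose < 0:
        raise DataValidationError("negative anthracycline dose")
    ep = _endpoint(cfg, endpoint)
    if anthracycline_dose == 0 or not ep.chemo_rr:
        return 1.0
    for band in ep.chemo_rr:
        hi = band.dose_hi if band.dose_hi is not None else float("inf")
        if band.dose_lo <= anthracycline_dose < hi:
            return band.rate_ratio
    return 1.0  # exposed but outside all configured bands


def smoking_rate_factor(cfg: DoseResponseConfig, endpoint: str, smoking_status: str) -> float:
    """Smoking rate ratio vs never-smoker baseline.

    Former smokers use the current-smoker ratio unless the config supplies
    a separate one; unknown status is treated as never (callers flag it).
    """
    ep = _endpoint(cfg, endpoint)
    if smoking_status in ("never", "unknown"):
        return 1.0
    if smoking_status == "former" and ep.former_smoking_rr is not None:
        return ep.former_smoking_rr
    if smoking_status in ("current", "former"):
        return ep.smoking_rr
    raise DataValidationError(f"unknown smoking status {smoking_status!r}")


def _endpoint(cfg: DoseResponseConfig, endpoint: str) -> EndpointConfig:
    try:
        return cfg.endpoints[endpoint]
    except KeyError:
        raise DataValidationError(f"endpoint {endpoint!r} not in dose-response config") from None


def placeholder_config() -> DoseResponseConfig:
    """A complete config with synthetic placeholder coefficients.

    The values below are NOT the coefficients any particular follow-up
    study reports; they are placeholders of literature-typical magnitude so
    the pipeline can be exercised end-to-end.  A production run should load
    a config populated from the user's preferred published dose-response
    studies.  "Other cardiac" deliberately carries ERR 0 (background only)
    because no published dose-response relationship exists for that group.
    """
    ep = {
        "coronary_heart_disease": EndpointConfig(
            dose_metric="whole_heart", err_per_gy=0.074,
            chemo_rr=[ChemoBand(dose_lo=0, dose_hi=None, rate_ratio=1.3)],
            smoking_rr=2.5,
        ),
        "heart_failure": EndpointConfig(
            dose_metric="left_ventricle", err_per_gy=0.10,
            chemo_rr=[
                ChemoBand(dose_lo=0, dose_hi=250, rate_ratio=2.0),
                ChemoBand(dose_lo=250, dose_hi=None, rate_ratio=3.0),
            ],
            smoking_rr=1.5,
        ),
        "valvular_heart_disease": EndpointConfig(
            dose_metric="sum_valve", err_per_gy=0.036,
        ),
        "other_cardiac": EndpointConfig(
            dose_metric="whole_heart", err_per_gy=0.0,
        ),
        "stroke": EndpointConfig(
            dose_metric="carotid_arteries", err_per_gy=0.02, smoking_rr=2.0,
        ),
        "lung_cancer": EndpointConfig(
            dose_metric="lungs", err_per_gy=0.10, smoking_rr=14.0,
        ),
        "breast_cancer": EndpointConfig(
            dose_metric="breast", err_per_gy=0.10,
            age_modifiers=[
                AgeBandERR(age_lo=0, age_hi=25, err_per_gy=0.30),
                AgeBandERR(age_lo=25, age_hi=None, err_per_gy=0.10),
            ],
        ),
        "esophageal_cancer": EndpointConfig(
            dose_metric="esophagus", err_per_gy=0.10,
        ),
    }
    return DoseResponseConfig(endpoints=ep)
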