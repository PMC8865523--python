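"""Synthetic cohorts and mortality-rate tables with the structure the
analysis assumes.

The cohort generator emulates a supradiaphragmatic-lymphoma proton-therapy
cohort: ~80 patients, ~62% female, age median ~30.5 (18-79), smoking
49/31/20% never / current-former / unknown, anthracycline median ~340
(170-420) mg/m2, and paired photon/proton mean organ doses whose
subgroup-conditional means and ranges follow the published dosimetric
pattern (protons spare the left ventricle, valves, lungs, breast and
normal tissue on average, but raise carotid dose; cardiac sparing
concentrates in patients whose CTV overlaps >=40% of the heart
longitudinally).  Within a patient, photon and proton doses for the same
organ are correlated (default rho = 0.7) because both plans share one
anatomy.

Anatomy is generated on a per-patient cranio-caudal axis: the >=40%-overlap
subgroup is drawn Bernoulli(0.29) and the CTV inferior edge placed to
realise the drawn overlap fraction; the LMSCA-origin and T7 marker
coordinates are placed (closed form plus small jitter) so the marginal
below-LMSCA and below-T7 proportions come out near 82% and 59% while
remaining geometrically consistent with the overlap fraction.

The rate generator produces Gompertz-like cause-specific rate tables
(rate = r0 * exp(slope * age), tabulated in 5-year bands) for four regions
whose cardiovascular scaling orders the synthetic 30-year background CVD
risk Eastern Europe > United States > Western Europe > Japan.  Levels are
plausible, not calibrated to any real national series.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import AnatomyProfile, DoseSummary, PatientRecord, write_cohort
from .dose_response import placeholder_config, save_config
from .errors import DataValidationError
from .rate_tables import ALL_OTHER, ENDPOINTS, RateTable, write_rate_tables

# (photon (mean, lo, hi), proton (mean, lo, hi)) in Gy, per metric and stratum
DEFAULT_DOSE_MODEL = {
    "whole_heart": {"by": "overlap",
                    "lt40": ((6.7, 0.6, 13.5), (7.1, 1.0, 14.3)),
                    "ge40": ((16.5, 9.6, 26.1), (13.3, 7.5, 20.7))},
    "left_ventricle": {"by": "overlap",
                       "lt40": ((3.0, 0.2, 9.1), (2.1, 0.0, 10.0)),
                       "ge40": ((11.2, 2.9, 23.9), (5.7, 0.1, 14.4))},
    "sum_valve": {"by": "overlap",
                  "lt40": ((11.2, 0.4, 24.1), (9.5, 0.1, 29.2)),
                  "ge40": ((21.0, 9.1, 28.3), (15.9, 6.8, 27.2))},
    "carotid_arteries": {"by": None, "all": ((25.1, 2.8, 30.2), (27.1, 7.9, 31.6))},
    "lungs": {"by": "axilla",
              "no": ((7.1, 3.7, 14.1), (5.2, 2.4, 9.6)),
              "yes": ((9.5, 6.5, 14.6), (6.6, 3.7, 10.1))},
    "breast": {"by": "axilla",
               "no": ((2.0, 0.4, 6.5), (1.5, 0.2, 4.2)),
               "yes": ((3.7, 0.7, 8.7), (1.9, 0.5, 4.6))},
    "esophagus": {"by": None, "all": ((16.4, 5.4, 24.4), (15.2, 0.3, 24.5))},
    "normal_tissue": {"by": None, "all": ((4.7, 1.6, 8.6), (2.3, 0.7, 6.2))},
}


@dataclass
class CohortSimSpec:
    """Generating parameters for a synthetic paired-modality cohort."""

    seed: int
    n_patients: int = 80
    p_female: float = 0.625
    age_median: float = 30.5
    age_log_sigma: float = 0.35
    age_range: tuple[float, float] = (18.0, 79.0)
    smoking_probs: tuple[float, float, float] = (0.49, 0.31, 0.20)  # never/current/unknown
    p_ge40: float = 0.29
    p_lmsca_below: float = 0.82
    p_t7_below: float = 0.59
    p_axilla: float = 0.36
    anthracycline: tuple[float, float, float] = (170.0, 340.0, 420.0)  # lo, mode, hi
    dose_model: dict = field(default_factory=lambda: DEFAULT_DOSE_MODEL)
    dose_scale: float = 1.0
    rho: float = 0.7
    valve_jitter_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise DataValidationError("seed is mandatory for reproducibility")
        probs = [self.p_female, self.p_ge40, self.p_lmsca_below, self.p_t7_below,
                 self.p_axilla, *self.smoking_probs]
        if any(not 0 <= p <= 1 for p in probs):
            raise DataValidationError("proportions must lie in [0, 1]")
        if not np.isclose(sum(self.smoking_probs), 1.0):
            raise DataValidationError("smoking probabilities must sum to 1")
        if not -1 < self.rho < 1:
            raise DataValidationError("rho must lie in (-1, 1)")
        if self.dose_scale < 0:
            raise DataValidationError("dose_scale must be >= 0")
        if self.p_lmsca_below < self.p_ge40 * 0 or self.p_t7_below < 0:
            raise DataValidationError("infeasible subgroup proportions")


def _marker_fraction_threshold(p_below: float, p_ge40: float) -> float:
    """Overlap-fraction threshold c with P(f > c) = p_below under the
    mixture f | ge40 ~ U[0.4, 1), f | lt40 ~ U[0, 0.4)."""
    if p_below >= p_ge40:
        # threshold falls in the lt40 branch
        if p_ge40 >= 1.0:
            return 0.4
        return 0.4 * (1.0 - (p_below - p_ge40) / (1.0 - p_ge40))
    if p_ge40 <= 0:
        return 0.4
    return 1.0 - 0.6 * p_below / p_ge40


def _correlated_pair(rng: np.random.Generator, rho: float) -> tuple[float, float]:
    z1 = rng.standard_normal()
    z2 = rho * z1 + np.sqrt(1.0 - rho * rho) * rng.standard_normal()
    return z1, z2


def _draw_dose_pair(rng, model_row, rho, scale):
    (mp, lop, hip), (mq, loq, hiq) = model_row
    z1, z2 = _correlated_pair(rng, rho)
    photon = float(np.clip(mp + z1 * (hip - lop) / 4.0, lop, hip)) * scale
    proton = float(np.clip(mq + z2 * (hiq - loq) / 4.0, loq, hiq)) * scale
    return photon, proton


def simulate_cohort(spec: CohortSimSpec) -> tuple[list[PatientRecord], dict]:
    """Generate a paired-modality cohort and its truth sidecar.

    The sidecar records every generating parameter plus the derived marker
    thresholds, so downstream recovery checks can compare against truth.
    """
    rng = np.random.default_rng(spec.seed)
    c_lmsca = _marker_fraction_threshold(spec.p_lmsca_below, spec.p_ge40)
    c_t7 = _marker_fraction_threshold(spec.p_t7_below, spec.p_ge40)

    patients: list[PatientRecord] = []
    for i in range(spec.n_patients):
        sex = "female" if rng.random() < spec.p_female else "male"
        lo, hi = spec.age_range
        for _ in range(1000):
            age = float(rng.lognormal(np.log(spec.age_median), spec.age_log_sigma))
            if lo <= age <= hi:
                break
        else:
            raise DataValidationError("age rejection sampling failed; widen age_range")
        smoking = str(rng.choice(["never", "current", "unknown"], p=spec.smoking_probs))
        anthra = float(rng.triangular(*spec.anthracycline))

        # anatomy on a randomly translated axis (origin-free convention)
        offset = float(rng.uniform(-50.0, 50.0))
        heart_len = float(rng.uniform(12.0, 15.0))
        heart_inf = offset
        heart_sup = offset + heart_len
        ge40 = rng.random() < spec.p_ge40
        frac = float(rng.uniform(0.4, 1.0)) if ge40 else float(rng.uniform(0.0, 0.4))
        ctv_inf = heart_sup - frac * heart_len
        ctv_sup = heart_sup + float(rng.uniform(2.0, 12.0))
        lmsca_z = heart_sup - c_lmsca * heart_len + float(rng.normal(0.0, 0.3))
        t7_z = heart_sup - c_t7 * heart_len + float(rng.normal(0.0, 0.3))
        axilla = bool(rng.random() < spec.p_axilla)
        anatomy = AnatomyProfile(
            ctv_sup_z=ctv_sup, ctv_inf_z=ctv_inf, heart_sup_z=heart_sup,
            heart_inf_z=heart_inf, lmsca_origin_z=lmsca_z, t7_inferior_z=t7_z,
            axilla_involved=axilla,
        )

        strata = {"overlap": "ge40" if ge40 else "lt40", "axilla": "yes" if axilla else "no"}
        values: dict[str, tuple[float, float]] = {}
        for metric, model in spec.dose_model.items():
            if metric == "breast" and sex != "female":
                continue
            key = "all" if model["by"] is None else strata[model["by"]]
            values[metric] = _draw_dose_pair(rng, model[key], spec.rho, spec.dose_scale)

        doses = {}
        for im, modality in enumerate(("photon", "proton")):
            sv = values["sum_valve"][im]
            valve = {}
            for v in ("aortic_valve", "mitral_valve", "tricuspid_valve"):
                noise = float(rng.normal(0.0, spec.valve_jitter_sd)) * spec.dose_scale
                valve[v] = max(0.0, sv + noise)
            doses[modality] = DoseSummary(
                modality=modality,
                whole_heart=values["whole_heart"][im],
                left_ventricle=values["left_ventricle"][im],
                carotid_arteries=values["carotid_arteries"][im],
                lungs=values["lungs"][im],
                breast=values["breast"][im] if "breast" in values else None,
                esophagus=values["esophagus"][im],
                normal_tissue=values["normal_tissue"][im],
                **valve,
            )
        patients.append(PatientRecord(
            id=f"P{i + 1:03d}", sex=sex, age_at_treatment=age, smoking=smoking,
            anthracycline_dose=anthra, anatomy=anatomy, doses=doses,
        ))

    truth = {
        "generator": "lymphrisk.synthetic.simulate_cohort",
        "spec": _spec_dict(spec),
        "derived": {"lmsca_fraction_threshold": c_lmsca, "t7_fraction_threshold": c_t7},
        "intended_orderings": {
            "modality": "proton <= photon on average for left_ventricle, sum_valve, "
                        "lungs, breast, normal_tissue; proton >= photon for carotids",
            "subgroup": "photon-proton cardiac dose gap larger in ge40 than lt40",
        },
    }
    return patients, truth


def _spec_dict(spec) -> dict:
    d = asdict(spec)
    return json.loads(json.dumps(d, default=list))


def simulate_cohort_files(spec: CohortSimSpec, out_dir) -> dict[str, Path]:
    """Write ``cohort.csv`` and ``cohort_truth.json``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort, truth = simulate_cohort(spec)
    cohort_path = out / "cohort.csv"
    truth_path = out / "cohort_truth.json"
    write_cohort(cohort, cohort_path)
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return {"cohort": cohort_path, "truth": truth_path}


# -- rate tables ----------------------------------------------------------

#: (rate per 100k person-years at age 0, Gompertz slope per year).  Levels
#: chosen so that, for smoking-affected causes, the tables read as
#: never-smoker-like baselines (smoking rate ratios then act on top).
DEFAULT_GOMPERTZ = {
    "coronary_heart_disease": (0.50, 0.100),
    "heart_failure": (0.04, 0.110),
    "valvular_heart_disease": (0.02, 0.100),
    "other_cardiac": (0.08, 0.100),
    "stroke": (0.05, 0.110),
    "lung_cancer": (0.10, 0.090),
    "breast_cancer": (2.00, 0.050),
    "esophageal_cancer": (0.06, 0.080),
    ALL_OTHER: (12.0, 0.078),
}

#: female-to-male rate multiplier per cause (male breast handled separately)
DEFAULT_FEMALE_MULT = {
    "coronary_heart_disease": 0.5, "heart_failure": 0.6,
    "valvular_heart_disease": 0.9, "other_cardiac": 0.8, "stroke": 0.8,
    "lung_cancer": 0.8, "breast_cancer": 1.0, "esophageal_cancer": 0.4,
    ALL_OTHER: 0.7,
}

_CAUSE_GROUP = {
    **{c: "cvd" for c in ("coronary_heart_disease", "heart_failure",
                          "valvular_heart_disease", "other_cardiac", "stroke")},
    **{c: "cancer" for c in ("lung_cancer", "breast_cancer", "esophageal_cancer")},
    ALL_OTHER: "other",
}

#: CVD scaling orders background CVD risk EE > US > WE > Japan.
DEFAULT_REGION_MULT = {
    "eastern_europe": {"cvd": 1.7, "cancer": 1.10, "other": 1.30},
    "united_states": {"cvd": 1.0, "cancer": 1.00, "other": 1.00},
    "western_europe": {"cvd": 0.55, "cancer": 0.95, "other": 0.90},
    "japan": {"cvd": 0.40, "cancer": 0.90, "other": 0.80},
}


@dataclass
class RateSimSpec:
    """Gompertz-like generating parameters for regional rate tables."""

    regions: tuple[str, ...] = tuple(DEFAULT_REGION_MULT)
    gompertz: dict = field(default_factory=lambda: dict(DEFAULT_GOMPERTZ))
    female_mult: dict = field(default_factory=lambda: dict(DEFAULT_FEMALE_MULT))
    region_mult: dict = field(default_factory=lambda: dict(DEFAULT_REGION_MULT))
    band_width: int = 5
    max_age: int = 85
    seed: int = 0

    def __post_init__(self) -> None:
        for cause, (r0, slope) in self.gompertz.items():
            if r0 <= 0:
                raise DataValidationError(f"cause {cause!r}: baseline rate must be > 0")
            if slope < 0:
                raise DataValidationError(
                    f"cause {cause!r}: Gompertz slope {slope} < 0 (non-increasing hazard)"
                )
        if self.band_width <= 0 or self.max_age <= 0:
            raise DataValidationError("band_width and max_age must be positive")


def simulate_rate_tables(spec: RateSimSpec) -> dict[str, RateTable]:
    """Banded cause/sex/region rates: ``rate(band) = r0 * exp(slope * mid)``
    evaluated at the band midpoint, scaled per sex and region."""
    edges = np.arange(0, spec.max_age + spec.band_width, spec.band_width, dtype=float)
    tables = {}
    for region in spec.regions:
        mult = spec.region_mult[region]
        rows = []
        for sex in ("male", "female"):
            for cause, (r0, slope) in spec.gompertz.items():
                base = r0 * (spec.female_mult.get(cause, 1.0) if sex == "female" else 1.0)
                if cause == "breast_cancer" and sex == "male":
                    base = r0 * 0.01
                scale = mult[_CAUSE_GROUP.get(cause, "other")]
                for lo in edges[:-1]:
                    mid = lo + spec.band_width / 2.0
                    rows.append((sex, cause, lo, lo + spec.band_width,
                                 base * scale * np.exp(slope * mid)))
                mid = spec.max_age + spec.band_width / 2.0
                rows.append((sex, cause, float(spec.max_age), np.inf,
                             base * scale * np.exp(slope * mid)))
        tables[region] = RateTable(region, pd.DataFrame(
            rows, columns=["sex", "cause", "age_lo", "age_hi", "rate_per_100k"]))
    return tables


# -- fixture bundle -------------------------------------------------------

FIXTURE_SEED = 220315


def make_fixture_bundle(out_dir) -> dict[str, Path]:
    """Write a small deterministic bundle: a 12-patient cohort, 2-region
    rate tables, and the placeholder dose-response config.

    Regeneration is byte-identical (fixed seed, sorted JSON keys).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = CohortSimSpec(seed=FIXTURE_SEED, n_patients=12)
    paths = simulate_cohort_files(spec, out)
    rate_spec = RateSimSpec(regions=("united_states", "japan"))
    rates_path = out / "rates.csv"
    write_rate_tables(simulate_rate_tables(rate_spec), rates_path)
    config_path = out / "dose_response.json"
    save_config(placeholder_config(), config_path)
    paths.update({"rates": rates_path, "config": config_path})
    return paths
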