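"""Paired photon/proton dose comparisons and between-subgroup tests.

Each patient has a photon and a proton plan on the same anatomy, so dose
comparisons are paired: the per-patient difference (proton - photon) for an
organ metric is tested against zero with a one-sample t test, and
between-subgroup differences of those paired differences are tested with
an ordinary least-squares regression of the difference on a subgroup
indicator (homoskedastic inference via the t distribution, which for a
binary indicator is algebraically the pooled-variance two-sample t test).
No multiple-testing adjustment is applied across organ metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import PatientRecord, classify_subgroups
from .errors import DataValidationError

#: p-value sentinel for a zero-variance, nonzero-mean paired difference.
P_SENTINEL = 1e-16

#: Organ metrics with paired comparisons in the default dose table.
DEFAULT_METRICS = ("whole_heart", "left_ventricle", "sum_valve", "carotid_arteries",
                   "lungs", "breast", "esophagus", "normal_tissue")


@dataclass
class PairedDoseComparison:
    metric: str
    patient_ids: tuple[str, ...]
    differences: np.ndarray  # proton - photon, Gy
    mean_difference: float
    range: tuple[float, float]
    p_value: float


@dataclass
class SubgroupComparison:
    metric: str
    grouping: str
    levels: tuple[str, str]
    estimate: float  # mean difference (level2 - level1) of the paired differences
    p_value: float
    n_per_level: tuple[int, int]


def _paired_differences(cohort: Sequence[PatientRecord], metric: str,
                        modalities: tuple[str, str] = ("photon", "proton")):
    ids, diffs = [], []
    for p in cohort:
        a = p.doses.get(modalities[0])
        b = p.doses.get(modalities[1])
        if a is None or b is None:
            continue
        va, vb = a.get(metric), b.get(metric)
        if va is None or vb is None:
            continue
        ids.append(p.id)
        diffs.append(vb - va)
    return ids, np.asarray(diffs, dtype=float)


def paired_difference_test(cohort: Sequence[PatientRecord], metric: str,
                           modalities: tuple[str, str] = ("photon", "proton"),
                           ) -> PairedDoseComparison:
    """Two-sided one-sample t test of per-patient (proton - photon) doses."""
    ids, diffs = _paired_differences(cohort, metric, modalities)
    if len(diffs) < 2:
        raise DataValidationError(
            f"metric {metric!r}: need >=2 patients with both modalities, got {len(diffs)}"
        )
    mean = float(diffs.mean())
    if np.allclose(diffs.std(ddof=1), 0.0):
        p = 1.0 if np.isclose(mean, 0.0) else P_SENTINEL
    else:
        p = float(stats.ttest_1samp(diffs, 0.0).pvalue)
    return PairedDoseComparison(
        metric=metric, patient_ids=tuple(ids), differences=diffs,
        mean_difference=mean, range=(float(diffs.min()), float(diffs.max())),
        p_value=p,
    )


def _group_label(patient: PatientRecord, grouping: str,
                 overlap_threshold: float) -> str:
    if grouping == "sex":
        return patient.sex
    labels = classify_subgroups(patient, overlap_threshold)
    return getattr(labels, grouping)


def subgroup_difference_test(cohort: Sequence[PatientRecord], metric: str,
                             grouping: str,
                             overlap_threshold: float = 0.40,
                             modalities: tuple[str, str] = ("photon", "proton"),
                             ) -> SubgroupComparison:
    """OLS of the paired dose difference on a binary subgroup indicator.

    ``grouping`` is one of ``overlap``, ``lmsca``, ``t7``, ``axilla`` or
    ``sex``.  Returns the indicator's estimate and its two-sided t-test
    p-value under homoskedastic (pooled-variance) inference.
    """
    ids, diffs = _paired_differences(cohort, metric, modalities)
    by_id = {p.id: p for p in cohort}
    labels = np.array([_group_label(by_id[i], grouping, overlap_threshold) for i in ids])
    levels = tuple(sorted(set(labels)))
    if len(levels) != 2:
        raise DataValidationError(
            f"grouping {grouping!r} has {len(levels)} level(s) {levels}; need exactly 2"
        )
    indicator = (labels == levels[1]).astype(float)
    X = sm.add_constant(indicator)
    fit = sm.OLS(diffs, X).fit()
    return SubgroupComparison(
        metric=metric, grouping=grouping, levels=levels,
        estimate=float(fit.params[1]), p_value=float(fit.pvalues[1]),
        n_per_level=(int((indicator == 0).sum()), int((indicator == 1).sum())),
    )


def dose_comparison_table(cohort: Sequence[PatientRecord],
                          metrics: Sequence[str] = DEFAULT_METRICS,
                          overlap_threshold: float = 0.40) -> pd.DataFrame:
    """Metric x subgroup dose summary: modality averages, ranges, paired p,
    and the between-subgroup p for the metric's natural grouping."""
    grouping_for = {
        "whole_heart": "overlap", "left_ventricle": "overlap", "sum_valve": "overlap",
        "lungs": "axilla", "breast": "axilla",
    }
    rows = []
    for metric in metrics:
        grouping = grouping_for.get(metric)
        subsets = {"all": list(cohort)}
        subgroup_p = np.nan
        if grouping is not None:
            for p in cohort:
                label = _group_label(p, grouping, overlap_threshold)
                subsets.setdefault(f"{grouping}={label}", []).append(p)
            try:
                subgroup_p = subgroup_difference_test(
                    cohort, metric, grouping, overlap_threshold).p_value
            except DataValidationError:
                subgroup_p = np.nan
        for name, subset in subsets.items():
            try:
                cmp = paired_difference_test(subset, metric)
            except DataValidationError:
                continue
            photon = np.array([p.doses["photon"].get(metric) for p in subset
                               if p.doses["photon"].get(metric) is not None], dtype=float)
            proton = np.array([p.doses["proton"].get(metric) for p in subset
                               if p.doses["proton"].get(metric) is not None], dtype=float)
            rows.append({
                "metric": metric, "patient_group": name, "n": len(cmp.differences),
                "photon_mean": photon.mean(), "photon_min": photon.min(),
                "photon_max": photon.max(),
                "proton_mean": proton.mean(), "proton_min": proton.min(),
                "proton_max": proton.max(),
                "difference_mean": cmp.mean_difference,
                "difference_min": cmp.range[0], "difference_max": cmp.range[1],
                "p_paired": cmp.p_value,
                "p_between_subgroups": subgroup_p if name == "all" else np.nan,
            })
    return pd.DataFrame(rows)
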