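# Methods

## The projection model

The package projects, for each patient, the probability of dying of each
modeled endpoint within a fixed horizon (default 30 years) after
treatment, under competing risks. Modeled endpoints are five
cardiovascular causes — coronary heart disease, heart failure, valvular
heart disease, "other cardiac" (pericardial disease, arrhythmias), and
stroke — reported jointly as CVD, plus lung, breast and esophageal cancer
reported singly. A residual "all other causes" hazard competes throughout.

The life table is discrete and annual. In projection year *t*
(*t* = 1..H) the attained age is `age_at_treatment + t − 1` (start-of-year
lookup; an `age_offset` flag switches to mid-year, which changes nothing
at 5-year band resolution). Within a year, survival is exponential in the
total hazard `H(t)` and the probability of death `1 − exp(−H(t))` is
apportioned to causes proportionally to their hazards. This choice (over
`1 − Π(1 − q_c)` product forms) is exact for piecewise-constant competing
hazards: for constant `h_c, h_o` it reproduces the closed form
`h_c/(h_c+h_o)·(1 − e^{−H(h_c+h_o)})` to machine precision, and it makes
the conservation identity Σ_c AMR_c = 1 − S(H) hold exactly rather than
approximately. Years with zero total hazard contribute zero to every
cause without a division.

### Hazard construction

Each endpoint's annual hazard is the background cause-, sex- and
age-specific rate multiplied by up to three factors:

* **Smoking** — a current-vs-never rate ratio, applied in *every* layer:
  smoking is a host characteristic, not a treatment, so it scales
  background and treatment-related rates alike (full multiplicative
  transport). Former smokers use the current-smoker ratio unless the
  config provides a separate one; unknown status is treated as
  never-smoking and flagged in the output.
* **Chemotherapy** — an anthracycline rate ratio, banded by mg/m²
  doxorubicin-equivalent dose, configured for cardiovascular endpoints
  only (no published dose–response supports a chemotherapy excess for the
  second cancers modeled here).
* **Radiation** — the linear no-threshold factor `1 + ERR·D` in the mean
  dose to the endpoint's driving structure, with optional replacement ERRs
  inside age-at-treatment bands (young women carry a higher breast-cancer
  ERR per Gy). No latency is imposed by default; a configurable latency
  offset (years with no radiation excess) exists for sensitivity use.

Chemotherapy and radiation combine multiplicatively by default,
`RR_chemo · (1 + ERR·D)`, consistent with both effects acting
multiplicatively on background rates; an additive mode on the
excess-relative-risk scale (`RR_chemo + ERR·D`, floored at 0) is available
behind the `combination` flag and recorded in output metadata.

### Layered decomposition and disease-group life tables

Risks are computed in three nested layers — background, background +
chemotherapy, and background + chemotherapy + radiation per modality —
and differenced to give absolute excess risks. The paired design reuses
one background/chemo layer per patient so modality differences isolate
radiation effects exactly.

Each reported disease group is projected in its own life table: the five
cardiovascular causes jointly (their apportioned cumulative incidences
sum exactly to the CVD group total), and each second cancer alone. Only
the group's hazards carry the treatment multipliers of the layer; all
other modeled causes compete at their background (smoking-adjusted)
level. The alternative — inflating every endpoint simultaneously in one
table — lets a cardiac treatment effect *reduce* the reported lung-cancer
risk purely through competing-risk leakage, which breaks the additive
reading of the layer decomposition. With group-wise tables the layer
ordering background ≤ +chemo ≤ +chemo+RT provably holds for every
reported disease group whenever all rate factors are ≥ 1. Within the CVD
group, an individual member cause whose own factor is 1 (e.g. stroke
under chemotherapy) can still be slightly suppressed by inflated
siblings; this is an inherent property of joint apportionment, so
ordering guarantees are stated at the reported-group level.

The residual competing hazard is the rate table's `all_other_causes`
series when present, otherwise `all_causes` minus the modeled endpoints'
background rates, floored at zero to avoid double counting.

## Rate tables

Background rates follow the layout of national mortality tabulations: one
row per (country, sex, cause, age band) in deaths per 100 000
person-years, with half-open `[lo, hi)` bands partitioning `[0, ∞)`.
Lookup is piecewise-constant; no smoothing is applied because the source
tabulations carry no sub-band information. One table is used per region
at all future attained ages — no secular-trend projection. Regional
tables are cell-wise means of member-country tables, equally weighted by
default with optional population weights; tables with mismatched band
structures are first expanded to 1-year bands by piecewise-constant fill,
which is lossless under the model.

## Standardization

Subgroup summaries are directly standardized for age and sex:
`Σ_s w_s · mean(AMR in stratum s)` with default strata from age bands
(0, 25, 35, 45, 55, 65, ∞) × sex and default weights from the full input
cohort's stratum distribution — so the "all patients" row equals the
crude mean. A stratum with positive standard weight but no members flags
the row rather than silently renormalizing (renormalization available by
flag). Reported ranges are per-patient minima and maxima of the crude
risks.

## Dosimetric statistics

Paired photon/proton comparisons use the one-sample t test on per-patient
(proton − photon) differences; a zero-variance nonzero-mean difference
reports the sentinel p < 1e-15. Between-subgroup comparisons regress the
paired difference on a binary subgroup indicator with homoskedastic OLS
inference — algebraically the pooled-variance two-sample t test, which
the test suite verifies numerically. Welch-style inference is not the
default because the regression formulation implies a common error
variance. No multiple-testing adjustment is applied across organ metrics.

## Subgroup definitions

* **Heart overlap** — length of the intersection of the CTV and heart
  cranio-caudal extents divided by the *heart's* length, clipped to
  [0, 1]; "≥40%" is inclusive. The heart denominator makes the category
  read "at least 40% of the heart lies in the treated longitudinal band",
  matching the cardiac-dose rationale; a CTV denominator is available by
  flag. Coordinates live on an arbitrary-origin per-patient axis
  (superior = larger); only differences are used.
* **LMSCA / T7** — the CTV extends "below" the marker when its inferior
  edge is strictly below the marker coordinate; an edge exactly at the
  marker counts as "at and above only".
* **Axilla** — a recorded involvement flag.

## Synthetic data generator

The generator exists so every pipeline stage is testable without
external data downloads. Its defaults emulate the study conditions:
80 patients, 62.5% female, log-normal ages with median 30.5 truncated to
18–79, smoking 49/31/20% never / current-former / unknown, anthracycline
triangular on (170, 340, 420) mg/m², subgroup prevalences 29% (≥40%
overlap), 82% (below LMSCA), 59% (below T7), 36% (axilla). Paired organ
doses are clipped normals per metric with subgroup-conditional means and
ranges following the published dosimetric pattern (cardiac metrics
conditioned on overlap group, lung/breast on axillary involvement), with
within-patient photon–proton correlation ρ = 0.7 because both plans share
one anatomy. Valve doses are generated around a common per-modality
`SumValve` level with small independent jitter.

Anatomy is generated so labels and geometry stay consistent: the overlap
fraction is drawn uniformly within the assigned overlap category, the CTV
inferior edge placed accordingly, and the LMSCA/T7 marker coordinates
placed at the closed-form fraction threshold that makes the marginal
below-marker proportions come out at their targets, plus N(0, 0.3 cm)
jitter.

Rate tables are Gompertz-like, `rate(a) = r₀·e^{θa}` per cause and sex,
tabulated at band midpoints in 5-year bands to 85+. Baselines are chosen
at plausible magnitudes — for smoking-affected causes they read as
never-smoker-like baselines so configured smoking rate ratios act on top
without double counting — and regional multipliers order the synthetic
background CVD risk Eastern Europe > United States > Western Europe >
Japan. A slope of exactly zero (constant hazard) is allowed; negative
slopes are rejected.

What the generator does *not* emulate: real national rate levels or
trends, dose–volume histogram shapes, correlations between anatomy and
dose beyond the subgroup conditioning, and proton RBE uncertainty.
Passing tests therefore demonstrate the correctness and internal
consistency of the risk machinery under realistic structure, not the
clinical accuracy of any particular risk estimate.

## Coefficients

Dose–response and rate-ratio coefficients are configuration, not code.
The bundled `placeholder_config()` carries synthetic placeholder values
of literature-typical magnitude (e.g. ERR 0.074/Gy of mean heart dose for
coronary disease, a 14-fold never-vs-current smoker ratio for lung
cancer), documented as such; "other cardiac" deliberately carries ERR 0
(background only) because no published dose–response relationship exists
for that group — inventing one would masquerade as an evidence-based
choice. A production analysis should load a config populated from the
user's preferred published studies.

## Numerical choices and problem sizes

Tolerances: the life table matches constant-hazard closed forms to 1e-12
relative; conservation holds to 1e-12 absolute; a monthly product-form
discretization agrees within 0.5% for hazards ≤ 0.2/yr. Doses are capped
at a configurable 60 Gy sanity limit; configs whose ERR could drive a
rate factor negative within that range are rejected at load. Test and
acceptance runs use cohorts of 12–800 patients and 20 replicates at
n = 200 for the end-to-end recovery checks — sizes chosen so the full
suite completes in well under a minute while keeping binomial tolerances
tight enough to detect structural errors.

## Known limitations

Mortality only (no incidence, which would be several-fold higher for CVD
and breast cancer); no time-since-exposure waning of treatment effects;
no calendar-period trends in background rates; no bootstrap confidence
intervals over patients; no proton-specific RBE uncertainty; smoking
enters only as a rate ratio, with no other cardiovascular risk factors
(diabetes, lipids) modeled.
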