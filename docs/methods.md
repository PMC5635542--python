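# Methods

## Cohort model and inclusion rules

The unit of analysis is a prospectively observed carrier: age at first planned
surveillance colonoscopy (inclusion), calendar year of inclusion, age at last
observation, optional age at death (death, when present, *is* the last
observation), an age-sorted list of cancers coded by 3-digit ICD-9 (153/154 =
colorectal; everything else extra-colonic), and — for CRC cases — the integer
months from the last cancer-free colonoscopy to diagnosis.

Three exclusion rules define the analysis cohort:

1. **pre-cutoff calendar year** — inclusion before 1997 (configurable), the
   point from which all non-Finnish centres recommended ≤2-yearly intervals;
2. **prevalent cancer** — any cancer at or before the inclusion age. The
   boundary is inclusive: a cancer exactly at the first-colonoscopy age is
   prevalent (ages compare with a 1e-9 tolerance; files store 2 decimals);
3. **insufficient follow-up** — under 1 year of prospective observation.

A record violating several rules is reported once, under the first rule in
that order: the calendar rule is a scope filter and is applied before the
clinical ones. The filter is idempotent and the exclusion report partitions
the input exactly. The calendar cutoff applies to both series uniformly.

## Person-years and annual incidence rates

Observation time is allocated to half-open 5-year bands [25,30) … [70,75);
an event at exactly 30.0 belongs to [30,35). Each carrier contributes from
max(25, inclusion age) to the first cancer or censoring, split *fractionally*
across bands — integer-rounding person-years would add discretisation bias,
and the fractional split is validated against a day-stepping allocator in the
tests. Carriers whose whole window precedes 25 contribute nothing.

Under the default censoring policy the first cancer of **any** class ends
incidence follow-up, and the analysed class scores an event only when it is
(part of) that first cancer; synchronous cancers at one age count once. The
alternative `censor_policy="class"` follows carriers through other-class
cancers to the first cancer of the analysed class. The default treats
"first cancer" literally as first of any class, which is the conservative
reading; the class policy is retained because extra-colonic follow-up past an
earlier CRC is a defensible alternative, and the choice is exposed as an
argument rather than hidden.

AIR = cancers / person-years per band, with SE_AIR = √c / PY — the Poisson
convention for a count over fixed person-time. Bands with zero exposure are
flagged undefined, warned about, and treated as rate 0 downstream.

## The cumulative-incidence recursion

One step per integer year of age from 25 to 70, Q(24) = 0, using the band
rate for each year the band covers; the first curve value Q(25) therefore
equals the first band's AIR. Ages not covered by an exposed band contribute
rate 0, so with follow-up ending at exactly 70 the value at 70 is the
45-risk-year product 1 − Π_b (1 − AIR_b)^5 over the nine bands [25,70) —
the recursion and this closed form agree to 1e-12 by construction, which the
property tests assert for random rate vectors.

**Standard errors.** SE_Q propagates on the hazard scale in two steps:
per band H = −ln(1−AIR), SE_H = SE_AIR/(1−AIR); then, because band estimates
are independent (disjoint person-time) while one band's estimate is *shared*
by each of its five recursion years,

    Var(cumH at age a) = Σ_b (years of b used through a · SE_H,b)²,
    SE_Q(a) = (1 − Q(a)) · √Var(cumH at a).

An alternative per-year delta recursion — Var Q(a) = (1−AIR_a)² Var Q(a−1) +
(1−Q(a−1))² Var AIR_a with every year treated as independent — is kept as
`seq_method="recursion"` for comparison, but it ignores the within-band
sharing and understates Var Q by a factor approaching the band width (≈5),
i.e. SE by ≈√5. The calibration experiment the acceptance suite re-runs
(constant hazard 0.01, full 25→70 follow-up, n=500, 200 replicates) measures
95%-CI coverage ≈0.96 for the hazard-scale default and ≈0.65 for the
per-year recursion, which is why the hazard scale is the default. Confidence
intervals are symmetric normal, Q ± 1.96·SE_Q, clipped to [0,1] — consistent
with the symmetric published intervals. When Q reaches 1 the state is
absorbing and SE_Q is set to 0.

## Interval cancers

Months since last cancer-free colonoscopy are rounded half-up to integers and
binned as <6, 7–11, 12–17, …, 42–47, 48–120; month 6 belongs to the first bin,
making the published label set exhaustive over [0,120]. The interval-cancer
rate is the proportion of CRCs with months **strictly below** the planned
interval — strict comparison reproduces both published rates exactly
(29/51 = 56.9% at 36 months; 25/50 = 50% at 24 months); a CRC at exactly the
planned month is counted as detected at the planned exam, not before it. The
histogram route to the rate requires the threshold to fall on a bin boundary
(24 and 36 do); otherwise raw months are required. Means and SDs of months
use the n−1 denominator; the SD of a single observation is NaN.

## Survival

Crude survival runs from the first cancer of the analysed class to death
(any cause — causes of death are deliberately ignored) or last observation;
carriers who never develop the class cancer are excluded from crude-survival
analyses. The product-limit fit is lifelines' Kaplan–Meier with the standard
tie convention (events precede censorings at equal times); Greenwood variance
is evaluated on the risk-set table; the 95% CI uses the log(−log) transform,
which keeps bounds inside [0,1] in the high-survival regime (85–95%) these
cohorts occupy. Curve evaluation is right-continuous; evaluation beyond the
last observed time returns the last value with an explicit extrapolation
warning. The Mantel–Cox test sums hypergeometric O−E contributions over pooled
event times; it is written in-package so the result can expose per-group
observed/expected counts, and is cross-checked against lifelines' statistic
in the tests.

## Synthetic cohort generator

The generator emulates the structure the analyses assume, per series:

| parameter | default | rationale |
|---|---|---|
| enrollment age | truncated normal, mean 35.5, SD 11.7 on [18,70] | reported cohort mean (SD) |
| sex | P(female) = 0.54 | reported sex balance |
| follow-up | uniform on [1, 15.8] years (mean 8.4) | reported mean follow-up with realistic spread |
| CRC annual hazard | 0.005→0.025 rising by 5-year band | gives ≈50% cumulative risk by 70, the carrier regime |
| extra-colonic hazard | 0.002→0.024 rising | slightly rarer, later onset |
| colonoscopy interval | 36 months (Finnish-style) or 24, jitter SD 4 months, floor 3 months | high but imperfect adherence |
| prevalent fraction | 10% also at risk from age 18 | gives the inclusion filter work |
| post-cancer death hazard | 0.012 / year | ≈89% 10-year survival, the observed range |
| calendar year | uniform 1997–2012 | post-cutoff era |

Cancer times are per-year Bernoulli draws at the band's annual rate with a
uniform within-year offset — exactly the discrete-hazard convention the AIR
estimator assumes, so parameter recovery is an identity in expectation. Event
ages round *down* to the 2-decimal file grid so they never cross the censoring
age. When a CRC occurs, the months field is computed from the last simulated
colonoscopy strictly before diagnosis (the enrollment exam always exists).
Post-cancer deaths are exponential, truncated at censoring; a death becomes
the last observation, later events are dropped, and a prevalent case's death
is clamped at enrollment (enrolled carriers are alive at inclusion). All
randomness flows from `numpy.random.default_rng(seed)` in a fixed draw order,
so a seed fully determines the cohort.

**What the generator does not emulate.** No adenoma→carcinoma natural history
(cancers arise directly from hazards), no colonoscopy sensitivity/miss-rate
model, no late-cycle clustering of interval cancers: simulated CRC onset is
uniform over the surveillance cycle, so simulated months-to-CRC means
(~15–18) sit well below the published ~31–33 and simulated interval-cancer
rates are higher than the published 50–57%. Passing tests therefore validate
the estimators' arithmetic and calibration, not the realism of interval-cancer
timing. Published per-bin counts are shipped as fixtures precisely so the
interval analysis can also be checked against real summary data.

## Numerical choices and degenerate inputs

- Ages stored to 2 decimals; age equality uses a 1e-9 tolerance; the cohort
  CSV round-trips bit-identically at that precision.
- AIR = 1 makes the hazard transform undefined; `hazard_transform` rejects it,
  and the recursion treats Q = 1 as absorbing with zero variance.
- Zero-exposure bands: rate undefined → warned, treated as 0.
- Empty inputs error loudly where a statistic is undefined (interval-cancer
  rate with no CRCs, KM with no subjects, log-rank with no events) rather than
  returning 0.
- Rounding for report output: percentages to 1 decimal, ratios to 2 decimals,
  round-half-even.
- Report generation is pure; identical inputs yield byte-identical bundles.

## Problem sizes

The simulation-backed checks run at the sizes that make their targets sharp
at desk scale: single-cohort recovery at n = 2000 (SE of Q(70) ≈ 1pp),
CI-coverage calibration at n = 500 over 200 replicates, log-rank type-I
calibration over 200 null replicates of 60 + 60 subjects, and the two-series
analysis study at 505 + 439 carriers, the published cohort sizes.

## Known limitations

- No competing-risk (Aalen–Johansen) correction: the estimator deliberately
  ignores mortality from other causes, matching the methodology it implements;
  Q is interpretable as risk in the absence of competing death.
- Band independence in the SE propagation neglects the (weak) negative
  dependence induced by carriers flowing through successive bands; the
  measured coverage (≈0.96 nominal 95%) shows the effect is minor at these
  sizes.
- The generator's hazards are a stand-in for an unknown natural history; only
  their order of magnitude is anchored to published cumulative risks.
- Interval-cancer timing in the generator is uniform within the surveillance
  cycle (see above), so generator-based interval statistics are structural,
  not quantitative, mirrors of the published ones.
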