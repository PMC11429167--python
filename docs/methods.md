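# Methods

## The estimation problem

A skeletochronological sample gives, per individual: sex, life stage,
age as an integer LAG count (years) and snout–vent length (SVL, mm).
From these the package estimates annual adult survival, adult life
expectancy, age at maturity/longevity, sexual size dimorphism, and a
per-sex growth curve, with rank-based tests for sex differences. All
estimators are cross-sectional: they assume the sample is a snapshot of
a stationary age distribution, not a cohort followed through time.

## Survival and life expectancy

Robson–Chapman: `S = T/(R + T − 1)`, `T = Σ w(a)·N_a`, `R = Σ N_a`.
Its model is constant annual survival across age classes and sampling
independent of age, under which the stationary age distribution is
geometric. Three age codings for `w` are provided:

* `raw_age` (default) — `w(a) = a`. This is what reproduces the
  published estimates for the study sample (male T = 67, R = 10,
  S = 67/76 → 0.88; female T = 105, R = 17 → 0.87); it treats the
  pre-maturity years as survived classes and therefore **overestimates**
  adult survival relative to the coded form.
* `coded_from_zero` — `w(a) = a − min(a)`, the standard
  Robson–Chapman coding. On simulated geometric samples it is nearly
  unbiased (|bias| < 0.01 at n = 500; see the recovery harness), so the
  simulator tests use it.
* `coded_from_one` — `w(a) = a − min(a) + 1`, for comparison with
  studies that code the youngest class as 1.

The estimate is undefined when `R + T − 1 = 0` (a single individual at
coded age 0); this raises rather than returning a sentinel.

Seber life expectancy `ESP = 0.5 + 1/(1 − S)` is reported twice: from
full-precision S, and from S rounded to 2 dp (`esp_rounded`). The
distinction matters because the published female ESP of 8.19 arises
only from the pre-rounded S = 0.87 (full precision gives 8.06). The
published male ESP of 9.17 is not reproducible from the male counts
under any rounding/coding combination tried (raw S = 67/76 gives 8.94;
S = 0.88 gives 8.83); the pipeline reports the recomputed values.
`ESP − 0.5` equals the mean of a geometric lifetime with success
probability `1 − S`, which a Monte-Carlo test verifies.

## Sexual size dimorphism

The index is the ratio of the larger sex's mean SVL to the smaller
sex's, with a sign convention of negative-when-males-larger. Two
variants: `ratio_plus_one` adds 1 to the ratio (the convention needed
to reproduce the published −2.081 from means 62.75/58.04) and
`lovich_gibbons` subtracts 1 (the conventional index). The two always
differ by exactly 2 in magnitude. Equal means return 0 with
`larger_sex="equal"`.

## Growth

Modified von Bertalanffy:
`SVL(t) = SVL_max − (SVL_max − SVL_met)·e^{−k(t − t_met)}`, implemented
in the anchored form `SVL_met + (SVL_max − SVL_met)(1 − e^{−k(t−t_met)})`
so the metamorphosis anchor is float-exact. Only `(SVL_max, k)` are
free; `SVL_met = 12.7 mm` and `t_met = 0.3 yr` (the published
population means) are fixed, shared by both sexes, since per-sex
metamorph sizes are unavailable. Fitting is bounded nonlinear least
squares (`scipy.optimize.least_squares`, `xtol = 1e−8`,
`k ∈ (0, 10]`, `SVL_max > SVL_met`), initialized at
`SVL_max₀ = 1.1 × max observed SVL`, `k₀ = 0.2/yr`; at least three
distinct ages are required. Standard errors come from the Jacobian at
the optimum. All life stages with a measured age and SVL enter the
per-sex fits (juveniles of unknown sex enter neither).

Note that the fitted asymptote need not exceed the sample maximum SVL:
on the study reconstruction the male optimum is SVL_max ≈ 68.7 mm
against an observed 71.69 mm, because the least-squares curve balances
the large age-5 individual against the older, smaller ones. The fit
sanity checks therefore compare SVL_max against the adult mean, not the
maximum.

## Rank statistics

Midranks everywhere (tied values share the mean of their occupied
ranks). Mann–Whitney U is reported in the min(U₁, U₂) convention with
both one-sided U's retained; the default p-value is the tie-corrected
normal approximation with continuity correction, with exact
enumeration available for small tie-free samples. Spearman's ρ is the
product-moment correlation of midranks; its companion statistic
`S = (1 − ρ)·n(n² − 1)/6` equals Σd² in the tie-free case; p uses the
t approximation with n − 2 df and the optional 95% CI the Fisher z
transform with SE `1/√(n − 3)`. The Shapiro–Wilk gate
(`scipy.stats.shapiro`) decides `normal = (p ≥ α)`; the pipeline runs
the nonparametric branch unconditionally and records the gate decision
per group. Descriptives use the sample SD (n − 1); a single value gets
SD 0 by convention.

## The synthetic-data generator

`generate_population` draws exactly the data-generating process the
estimators assume: adult ages from the truncated geometric stable-age
pmf `P(a) ∝ S^{a − maturity}` on `[maturity_age, max_age]` (sampled
directly rather than by cohort projection — it is the exact stationary
law and O(n)); SVL as the sex-specific growth-curve value plus
homoscedastic Gaussian noise, resampled if ≤ 0; metamorph SVLs
Gaussian around the metamorph mean at age 0. Defaults mirror the study
population: S = 0.87, maturity 3 yr, max age 12 yr, metamorph size
12.7 ± 1.297 mm, 14 metamorphs, 17 adults per sex. Growth truths
default to male (75 mm, 0.35/yr) and female (72 mm, 0.30/yr): the
asymptotes bracket the observed adult sizes and the male curve is
steeper, matching the qualitative ordering reported for the study
population (no fitted values were published). An explicit seed is
required; one seed reproduces the dataset byte-for-byte.

What the generator does **not** emulate: sex-specific survival
differences (available via config override but off by default),
age-dependent survival, heteroscedastic or skewed size residuals,
sampling bias with respect to age or size, and LAG-reading error
(double lines, endosteal resorption). Passing recovery tests therefore
show the estimators are correct **under their own model**, not that
the model is right for any field population.

Recovery tests run at sizes where sampling noise is small relative to
the tolerances: survival recovery uses n = 5000 (single draw, ±0.02)
or 50 replicates of n = 500 (|bias| < 0.02); growth recovery n = 200
with σ = 2 mm (±2 mm on SVL_max, ±0.05 on k); the k-ordering check 100
replicates at n = 200. With the study's own longevity cap
(max_age = 12) the truncated geometric departs enough from the full
geometric to bias the coded estimator by about −0.06 at S = 0.8, so
recovery runs use max_age = 40 where truncation is negligible; the
truncation bias is a property of the estimator, not a bug.

## The published-table reconstruction

Individual records are rebuilt from the per-age-class summary table:
n = 1 classes are the printed value; n = 2 classes the printed min and
max (both necessarily attained); n = 3 classes add `3·mean − min − max`.
The five females aged 6 cannot be reconstructed this way and are stored
at their class mean with an `approximate` flag, excluded from any
exact-SVL assertion. Consequences: the fixture female SVL mean is 58.18
vs the printed 58.04, so the dimorphism index recomputed from fixture
individuals is −2.079 rather than −2.081 (the acceptance path uses the
printed means, as the index is defined on them); and the published
SVL-based U of 59 is not checkable. Known internal inconsistencies of
the source table are preserved as metadata but never asserted: the
female age-5 mean (56.92) and juvenile mean (23.07) are inconsistent
with their own min–max, the printed male age SD 2.90 appears truncated
from 2.9078, and the printed female mean age 6.12 conflicts with the
counts (105/17 = 6.18).

## Numerical and design choices

* Rounding is a display concern: reports carry full precision plus
  2-dp renderings for S/ESP/means and 3-dp for SDI.
* Pipeline stages run independently; a failed stage (e.g. demography on
  an adult-free dataset) is recorded in `stages` and the rest proceed.
* Report JSON is validated against the shipped schema
  (`schemas/report.schema.json`) by a small structural checker.
* No multiple-testing correction is applied anywhere (none is part of
  the protocol being implemented).
* CSV interchange: comma-separated UTF-8 with header
  `id,sex,life_stage,age_years,svl_mm[,approximate]`; sex codes M/F/U,
  stage codes NM/J/SA/A; SVL written at caliper precision (2 dp).

## Limitations

No capture–mark–recapture modelling: constant survival is assumed, not
tested. Ages are error-free integers by assumption; uncertainty in LAG
counts propagates nowhere. The growth comparison between sexes is the
qualitative ordering of k only — no formal curve-comparison test is
implemented, since the reference analysis reports none.
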