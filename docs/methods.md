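# Methods

## The measurement model

A Humphrey 24-2 exam samples retinal sensitivity (dB, instrument range
0–40) at 54 locations on a 6° grid offset 3° from the meridians; two
locations fall on the physiologic blind spot and are excluded from all
derived quantities, leaving 52 analyzable points. Coordinates are kept in a
canonical per-eye frame with temporal = +x, so the blind spot is at
(15, ±3) for both eyes and fellow eyes pool without bookkeeping; the
left-eye mirror is applied only when reading or writing chart-frame files.

**Total deviation** at a location is measured sensitivity minus the
age-corrected normal sensitivity there. **Mean deviation** is the weighted
mean of total deviations, the weight at each location being the inverse of
its normal-population variance — central locations, which retest most
consistently in healthy eyes, dominate. MD is therefore invariant to
rescaling all weights, bounded by the extreme TDs, and monotone in every
TD; the tests assert all three.

Vendors do not publish their normative surfaces or weight tables, so the
`NormativeModel` is pluggable. The shipped default is parametric:

- normal sensitivity `N(ecc, age) = c0 − c1·ecc − c2·(age − 20)` with
  c0 = 34 dB, c1 = 0.25 dB/deg, c2 = 0.07 dB/yr;
- weights `w = 1/(s0 + s1·ecc)²` with s0 = 1.5 dB, s1 = 0.05 dB/deg.

These are this package's own defaults chosen to reproduce the qualitative
structure (hill of vision, central weighting, mild age slope), not any
vendor's numbers; every analysis accepts a replacement model.

**Reliability.** An exam is accepted when false positives < 15 % and both
fixation losses and false negatives < 30 %. The thresholds are applied as
strict inequalities ("less than"), so boundary values fail; a missing index
fails the exam by default (configurable).

## Pointwise change analysis

Matched points pair a location's TD at baseline and a follow-up visit for
the same patient/eye/location, both eyes pooled, reliable exams only.
Points are categorized by *baseline TD* into half-open 5-dB bins
[lower, upper) from −35 to +10 dB; the half-open convention makes boundary
assignment unique (exactly −10 goes to (−10, −5)). Binning uses the
deviation rather than raw sensitivity because the clinically meaningful
depth scale is negative and age-independent.

Per bin we report n, mean baseline TD, mean change, sample SD (n−1), and a
normal-approximation 95 % CI (mean ± 1.96·SD/√n) treating points as
independent. Points within a patient are correlated, so an optional
patient-level bootstrap CI (resampling patients with replacement) is
provided; the normal CI stays the default because the per-bin tables are
descriptive and the independence convention keeps them comparable across
bins. Bins with fewer than 10 observations are retained in raw output but
flagged unreported.

**Regression to the mean.** Because bins condition on a noisy baseline,
symmetric test-retest error alone displaces per-bin change estimates toward
the cohort point mean: deep bins upward, supranormal bins downward. The
simulation suite measures this displacement under a no-change cohort and
asserts the sign pattern; any real per-bin "improvement" must be read
against it.

**Effect sizes** are standardized mean change, mean/SD of the change
distribution, reported rounded to 2 decimals half-away-from-zero (matching
clinical-table convention; banker's rounding would disagree on ties).

## Feasibility analytics

Eligibility for a simulated medically managed population is a worse-eye
baseline MD inside [−7, −2] dB (closed bounds; the literature says
"between" without specifying closure and no conclusion here depends on the
boundary), with a per-eye mode available. A location is a **qualifying
(deep) point** when its baseline TD is at or beyond −10 dB (≤ −10;
a strict-< flag exists). The feasibility table counts participants with
≥ k deep points across both eyes (k = 1..5) per MD stratum, plus the
median (IQR, linear-interpolation quantiles) among those with ≥ 1.

MD strata are reconciled to the disjoint partition [−2, ∞), [−7, −2),
(−∞, −7) — clinical labels like "MD ≤ −7" overlap at the boundary, and
disjointness is required for the strata to partition the cohort.

**Responders.** A point responds when its change from baseline is ≥ 7 dB
(the change regulators accept as clinically meaningful). Participants are
cross-tabulated by responder-point count {0, 1, …, 5, > 5}; percentages
are of the visit's analyzable N.

## The synthetic cohort generator

The generator emulates the statistical structure of perimetry in an
IIH weight-loss trial; it is the ground-truth source for every validation
experiment.

**What it models.** Each patient draws a log-normal severity `S_p` (dB);
each eye multiplies it by an independent factor in [0.8, 1.2] (the disease
is bilateral, so the two eyes share the patient factor). The true defect at
a location is

```
D = −S_p · m_eye · (w_ecc · ecc/27.2 + w_bs · adj + w_loc · U)
```

with `adj` flagging the six locations ringing the blind spot and
U ~ Uniform(0, 1) as local texture — loss grows with eccentricity and
concentrates around the blind spot, and defects are loss-only. Measured
sensitivity is `clip(N(loc, age) + D·(1 − recovery) + ε, 0, 40)` with
ε ~ Normal(0, σ(D)), σ(D) = σ0 + σ1·|D|: damaged locations retest far more
variably. Recovery is a per-arm, per-visit fraction of defect depth.
Dropout removes whole visits; a configured fraction of exams draws
reliability indices that fail the filter. Random streams are split per
purpose so changing one parameter does not reshuffle unrelated draws, and
a seed reproduces the cohort bit for bit.

**Defaults and why** (frozen after a one-time calibration against the
study conditions the generator emulates; 30 replicates per candidate):

| parameter | default | rationale |
|---|---|---|
| n_patients / visits | 60, (0, 12, 24) mo | two-arm weight-trial cohort size and schedule |
| age | 32 ± 7.8 yr | trial demographic |
| arm_ratio / acetazolamide rate | 0.5 / 0.17 in the community arm | 1:1 randomization; observed co-medication fraction |
| severity_mu, severity_sigma | 1.85, 0.75 (log scale) | worse-eye MD ≈ −3.8 ± 3.0 dB, matching a mildly affected cohort (target −3.6 ± 3.7) with a severe tail |
| w_ecc, w_bs, w_loc | 0.55, 0.25, 0.20 | peripheral-dominant topography with a distinct peri-blind-spot component |
| σ0, σ1 | 1.0 dB, 0.30 dB/dB | jointly constrained: the null-cohort shallow-bin displacement must stay < 1 dB (bounds σ0) while deep-bin change SDs must grow steeply with depth (sets σ1) |
| recovery | bariatric {12: 0.55, 24: 0.60}; cwi {12: 0.50, 24: 0.60} | deep-range ([−25, −10)) mean change ≈ 8.6 dB at 12 mo and ≈ 9.4 dB at 24 mo, the scale seen in treated IIH |
| dropout | {12: 0.09, 24: 0.24} | attrition typical of a 24-month trial |
| unreliable_prob | 0.05 | occasional unreliable exams |

Presets: `null` (zero severity and recovery — pure noise), `mild_medical`
(narrower severity spread; most worse-eye MDs inside the trial window) and
`iihwt_like` (the defaults above).

**What it does not model**, hence what passing tests do not show about real
data: SITA staircase psychophysics (noise is Gaussian, not
response-probability based), between-patient recovery heterogeneity (all
patients in an arm recover the same fraction, so deep-bin change SDs run
≈ 4 dB where real cohorts show ≈ 7 dB), learning and fatigue effects,
cataract or media opacity, spatial correlation of noise beyond the shared
defect field, and any link between papilledema grade and field loss.

## Numerical conventions and edge cases

- Sample SDs use the n−1 denominator; a single-point group is flagged
  degenerate rather than reporting SD 0.
- Report rounding is half-away-from-zero at serialization only; internal
  statistics are full precision, and rerunning a pipeline with the same
  seed and configuration reproduces every CSV byte for byte.
- Missing single-location values are excluded pairwise; an exam with no
  analyzable values raises an "empty exam" error rather than propagating
  NaN.
- The injected-improvement harness (`inject_uniform_change`) synthesizes a
  follow-up visit as baseline + δ on points selected by *measured* baseline
  TD plus fresh noise, holding age fixed so the normative surface cancels
  exactly; this makes the expected binned change equal δ and turns CI
  coverage into a sharp test of the estimator (≥ 93 % of 200 replicates
  must cover, against a nominal 95 %).

## Problem sizes

The test and acceptance runs use the generator's native scale: 60-patient
cohorts (≈ 330 exams, ≈ 5000 matched points per visit), 200 replicates for
coverage and null-centering checks, 10–30 replicates for sign-pattern and
floor assertions. The full suite runs in well under a minute on one core.

## Known limitations

- The default normative surface is linear in eccentricity and age; real
  normative data curve near fixation and accelerate after age 60.
- The generator's noise is unbounded Gaussian before clipping; real
  frequency-of-seeing curves flatten below ~15–19 dB, making deep points
  even noisier than modeled.
- Feasibility strata default to the worse-eye unit; published tables built
  on overlapping strata or per-eye counting will not match a disjoint
  worse-eye partition row for row (a per-eye mode is provided).
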