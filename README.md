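# vfpoint

Pointwise analysis of Humphrey 24-2 visual fields for longitudinal cohorts,
built for the question a trialist in idiopathic intracranial hypertension
(IIH) has to answer before choosing a perimetric endpoint: **is there enough
signal at the level of individual test locations to beat the global mean
deviation (MD)?**

IIH causes diffuse, peripherally accentuated field loss that is usually
mild in the patients eligible for a medical treatment trial (baseline MD
between −2 and −7 dB). Pointwise endpoints — e.g. "k locations improving by
≥ 7 dB" — only work if enough locations start deep enough to have room to
improve, and if their test-retest variability does not swamp the change.
`vfpoint` implements the full feasibility audit:

- **Geometry** (`vfpoint.geometry`) — the 54-point 24-2 pattern in a
  canonical per-eye frame (temporal = +x), blind-spot identification, and
  chart-frame mirroring for left eyes.
- **Metrics** (`vfpoint.metrics`) — total deviation
  TD = sensitivity − age-normal, mean deviation
  MD = Σ wᵢ TDᵢ / Σ wᵢ with inverse-variance weights (central locations
  weigh more), and the standard reliability filter (false positives < 15 %,
  fixation losses and false negatives < 30 %). The normative surface is
  pluggable.
- **Pointwise statistics** (`vfpoint.pointwise`) — baseline-TD binning in
  5-dB half-open intervals, per-bin longitudinal change (n, mean, SD,
  normal 95 % CI, with an optional patient-level bootstrap), range-subset
  summaries by trial arm, standardized effect sizes (mean/SD of change),
  and per-location cohort maps by MD stratum.
- **Feasibility** (`vfpoint.feasibility`) — MD-window eligibility
  (worse-eye or per-eye), counts of "deep" points (baseline TD ≤ −10 dB,
  either eye), and responder tables (participants by number of points
  improved ≥ 7 dB).
- **Synthetic cohorts** (`vfpoint.simulate`) — a seeded generator of
  two-eye, 0/12/24-month cohorts with eccentricity- and
  blind-spot-weighted loss, depth-dependent test-retest noise,
  arm-specific recovery, dropout and unreliable exams, emitting ground
  truth for every validation experiment.
- **Pipeline + CLI** (`vfpoint.pipeline`, `vfpoint.cli`) — one command that
  writes every report table as tidy CSV.

## Worked example

```python
import dataclasses
from vfpoint import NormativeModel, generate, preset
from vfpoint.pointwise import match_points, change_by_bin, range_subset_stats, effect_size

model = NormativeModel()
cfg = dataclasses.replace(preset("iihwt_like"), seed=1)
cohort, truth = generate(cfg, model)
rel = cohort.reliable()                       # 330 exams, 310 reliable
pts = match_points(rel, model, 12, reliable_only=False)
print(change_by_bin(pts))
```

gives (reported bins only, ≥ 10 observations):

```
       bin  n_points  mean_baseline_db  mean_change_db  sd_change_db
(-30, -25)        87            -27.78           10.03          7.31
(-25, -20)        35            -22.07           11.36          5.58
(-20, -15)        72            -17.22           10.80          3.73
(-15, -10)       328            -12.01            7.22          3.09
 (-10, -5)      1195             -6.91            3.98          2.37
   (-5, 0)      3244             -2.46            1.07          1.94
    (0, 5)       387              0.72           -1.63          1.68
```

Read it the way a trialist would: the vast majority of matched points sit in
the shallow [−10, 0) bins, where the mean 12-month change is ~1–4 dB — far
below a 7-dB responder criterion — while the deep bins that do show 7–11 dB
of improvement hold only a few hundred points. Note the sign flip in the
(0, 5) bin: points that started *above* normal drift back down. That is
regression to the mean, not worsening — binning conditions on a noisy
baseline, so extreme bins drift toward the cohort mean even with no true
change.

The deep range pooled:

```python
r = range_subset_stats(pts, -25, -10).iloc[0]
effect_size(r["mean_change_db"], r["sd_change_db"])
# n=435, mean=8.14 dB, SD=3.81 dB -> effect size 2.13
```

The command-line equivalent writes every table at once:

```bash
vfpoint all --input iihwt_like --seed 1 --out results/
```

producing `table2_binchange_{12,24}.csv`, `table3_rangesubset.csv`,
`table4_restricted_counts.csv`, `table5_effectsizes.csv`,
`table6_feasibility.csv`, `table7_responders.csv`,
`fig1_map_<stratum>.csv`, a run log with attrition counts, and the resolved
configuration.

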