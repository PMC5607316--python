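# dielbias

Sampling-time bias analysis and correction for manually measured soil CO₂
efflux (Rs).

Soil respiration follows a diel cycle driven mainly by soil temperature, but
manual chamber surveys are usually made at one fixed, convenient time of day
— typically mid-day. A monitoring series built that way carries a systematic
bias relative to the daily mean flux, and so does any seasonal or annual
budget upscaled from it. `dielbias` is for field ecologists and carbon-flux
scientists who run occasional 24-hr chamber campaigns alongside routine
surveys and want to (a) find the hours of day that best represent the daily
mean, and (b) correct measurements taken at other hours.

## The statistics

For a 24-hr campaign with hourly fluxes x₁…xₙ and daily mean m, the relative
difference at hour i is

    RD_i = (x_i − m) / m

Across N campaigns, the per-hour mean relative difference MRD_i and its
sample standard deviation SDMRD_i quantify the systematic bias and the
precision of the bias at hour i. Hours are ranked by ascending MRD; the most
representative hour has MRD closest to zero with the lowest SDMRD (the hour
holding the middle rank — 12 or 13 of 24 — under the rank rule). A flux
measured at a non-ideal hour is corrected to its daily-mean equivalent by

    Rs_hat = Rs_i / (1 + MRD_i)

Corrected and uncorrected seasonal/annual means are compared with JZS
Bayes-factor t-tests (Cauchy prior on the standardized effect, scale √2/2),
and flux–driver relationships with Bayesian linear regressions. A bundled
Q10 diel-cycle simulator (sinusoidal soil temperature through a Q10
response, lognormal chamber noise) provides ground truth for validation.

## Worked example

Simulate eight 24-hr campaigns plus a year of monthly mid-day monitoring,
estimate the stability profile, and compare budgets:

```sh
dielbias --seed 7 simulate --out-campaigns campaigns.csv \
    --out-monitoring monitoring.csv --out-truth truth.csv
dielbias stability --input campaigns.csv --treatment trench \
    --season all --output stability.csv
head -4 stability.csv
```

```
# tool=dielbias version=0.1.0 seed=None
season_scope,hour,mrd,sdmrd,rank,n_campaigns
all,0,-0.2813693205327358,0.031099541347029396,4,8
all,1,-0.28459118209235396,0.02870938989705605,3,8
```

Hour 0 sits 28% below the daily mean on average across the 8 campaigns
(MRD = −0.28), with an across-campaign spread of 3 percentage points
(SDMRD = 0.031), and holds rank 4 of 24. In Python, the selection rules:

```python
from dielbias import *
obs, _ = read_flux_csv("campaigns.csv")
prof = build_stability_profile(
    [relative_difference(c) for c in assemble_campaigns(obs)], "trench")
rep = optimal_interval(prof, run_threshold=0.05)
```

prints (via the fields of `rep` and `prof`):

```
best hour 19: MRD=+0.030, SDMRD=0.052
middle-rank hours: [8, 20]
midday MRD: +0.314 +0.374
```

With the simulator's default afternoon temperature peak, 19:00 is the hour
closest to the daily mean, the two middle-rank hours (8:00 and 20:00) flank
the two mean-crossings of the sinusoid, and mid-day sampling runs 31–37%
hot. Building a correction table from the profile and applying it to the
mid-day monitoring series:

```sh
dielbias budget --monitoring monitoring.csv --table table.csv \
    --output budget.csv
```

```
treatment,scope,variant,mean,sd,n,diff_pct
trench,HY2015,corrected,1.19,0.12,36,-25.1
trench,HY2015,uncorrected,1.58,0.15,36,-25.1
```

The uncorrected annual mean (1.58 µmol CO₂ m⁻² s⁻¹, hydrological year
HY2015) overstates the corrected estimate by 25% — the sampling-time bias
the correction removes. (The table CSV here is the stability output
reshaped to `treatment,season,hour,mrd`; see `dielbias correct --help`.)

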