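# mobisym

Can short-term changes in how a person moves predict whether they will
report influenza-like or cold symptoms in the next days? `mobisym` is a
tested, reusable implementation of that analysis for smartphone location
streams paired with daily symptom diaries. It is aimed at digital-
epidemiology and mobile-sensing researchers who want the full chain —
place identification, mobility metrics, windowed sample construction,
balanced classification — as composable, scikit-learn-style components,
plus a synthetic cohort generator so everything is testable without any
private location data.

## The analysis

**Places and stops.** Raw points `[user, lat, lon, source, accuracy, time]`
are speed-annotated (moving iff ≥ 5 km/h versus the previous point),
filtered to stationary points with accuracy < 50 m, and clustered
incrementally in time order: a point joins the nearest cluster whose
current centroid is within 200 m, else it seeds a new one. Runs of
same-cluster points lasting ≥ 10 min become stops `[place, tᵃ, tᵈ, C]`;
*home* is the place with the most dwell time between 7 pm and 7 am.

**Daily mobility metrics.** Per user-day: total distance over the merged
stop + moving-point sequence D_T and its per-leg spread; total / std / max
displacement between consecutive stops; the dwell-time-weighted radius of
gyration

&nbsp;&nbsp;&nbsp;&nbsp;G = √( 1/T · Σᵢ Tᵢ · d(Cᵢ, C̄)² );

maximum displacement from home; visit counts N_dif, N_sig (top-10
significant places), N_unq; moving-point count; and the normalised visit
entropy Div = −Σⱼ vⱼ log vⱼ / log k ∈ [0, 1]. Rolling window statistics
(mean, std, max, min, first-to-last difference) summarise each metric over
a short history.

**Prediction task.** A sample anchored at (user, day t) uses features from
[t−t_hist, t] and the binary label "any of the eight symptoms reported at
t+t_hor" (t_hist, t_hor ∈ {0, 1, 2}); samples require complete mobility
coverage of the window and a diary entry at the label day. Classes are
balanced by random under-sampling; logistic regression, random forest and
gradient-boosted trees are tuned (RFE feature selection + small grids) by
10-fold CV maximising precision, and evaluated with precision, recall, F1,
AUCROC and a row-normalised confusion matrix. Pipeline-level
cross-validation groups folds by user so a model cannot score by merely
recognising a user's geography (see `docs/methods.md`).

**Synthetic cohorts.** The generator builds home-anchored daily routines
with GPS/network accuracy mixtures, day-level gaps in both streams, and
Poisson illness episodes whose prodrome and symptomatic days contract
mobility by an effect size δ (fewer anchor visits, shorter excursions);
δ = 0 decouples mobility from symptoms entirely.

## Worked example

```python
from mobisym import SimulationConfig, simulate_cohort
from mobisym.pipeline import balanced_samples, cohort_cv_reports, featurize

config = SimulationConfig(n_users=50, n_days=60, seed=1, effect_size=0.6)
locations, symptoms, episodes = simulate_cohort(config)

daily = featurize(locations)            # one row per user-day, 12 metrics
samples = balanced_samples(daily, symptoms, t_hist=1, t_hor=1, seed=1)
reports = cohort_cv_reports(config, t_hist=1, t_hor=1, seed=1,
                            daily=daily, symptoms=symptoms)
for family, rep in reports.items():
    print(family, round(rep.aucroc, 3), round(rep.precision, 3))
```

prints (grouped 10-fold out-of-fold metrics on the balanced set):

```
lr 0.958 0.9
rf 0.963 0.9
gbt 0.948 0.895
```

With a 60 % mobility contraction around illness episodes, every family
recovers the signal far above chance — one day of history predicts symptom
presence one day ahead with AUCROC ≈ 0.95. Re-running with
`effect_size=0.0` yields AUCROC ≈ 0.5 for every family: when mobility and
symptoms are decoupled the pipeline correctly reports chance performance.

The same chain is scriptable from a shell:

```bash
mobisym simulate --out data --seed 1 --effect-size 0.6
mobisym features --locations data/locations.csv --out work
mobisym samples --features work/daily_features.csv \
    --symptoms data/symptoms.csv --t-hist 1 --seed 1 --out work
mobisym train --samples work/samples_thor1.csv --seed 1 --out work
```

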