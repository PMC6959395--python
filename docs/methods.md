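# Methods

`mobisym` implements an end-to-end analysis that asks whether short-term
changes in a person's mobility, measured passively from smartphone location
points, predict the presence of influenza-like/cold symptoms in the next
days. This note records the models, the parameter choices and their
rationale, what the bundled simulator does and does not emulate, and the
numerical conventions.

## Place identification

Raw location points `[user, lat, lon, source, accuracy, time]` are reduced
to *stops* at *places* in four steps.

1. **Speed annotation.** Each point's speed is the great-circle distance to
   the user's previous point divided by the elapsed time. A point is
   *moving* when its speed is ≥ 5 km/h (stationary is strict-less). The
   first point of a user has no predecessor and is treated as stationary; a
   zero time gap with nonzero displacement is treated as moving (infinite
   speed).
2. **Accuracy filter.** Only stationary points with reported accuracy
   strictly below 50 m are clustering candidates. Moving points are kept for
   the travel-distance metrics regardless of their accuracy (the filter
   exists to protect place centroids, not path length; a switch also filters
   moving points).
3. **Incremental clustering.** Candidates are consumed in time order. A
   point joins the nearest existing cluster whose *current* centroid lies
   within 200 m, else it seeds a new cluster; centroids are running means of
   member coordinates. The pass is order-dependent by construction, and at
   insertion time every point is within 200 m of its cluster's then-current
   centroid. When several centroids qualify, the nearest wins —
   deterministic and locally optimal. Place ids are assigned per user in
   creation order (uniqueness is per-user; the pipeline never compares place
   ids across users).
4. **Stop construction.** Maximal runs of consecutive same-cluster points
   become stops spanning first to last timestamp. A run is ended by a moving
   point (the user demonstrably left and returned) and by a silent gap
   longer than `max_point_gap_min` (default 120 min; without this rule a
   home dwell on the evening before and the morning after a day-long
   recording gap would merge into one stop *bridging* the gap day,
   fabricating mobility rows for days with no data and defeating the
   sample-availability constraints). Points dropped by the accuracy filter
   do not break runs. Runs shorter than `min_stop_min` (default 10 min — the
   dwell time below which a cluster crossing is noise rather than a visit)
   are discarded.

**Home labelling.** Home is the place where the user spends the largest
total dwell time inside the nightly 7 pm–7 am window (intersection with
[19:00, 24:00) ∪ [00:00, 07:00) per local day; the window wraps midnight).
An alternative rule — most night-touching visits — is selectable
(`home_rule="frequency"`); the dwell rule is the default because a single
long overnight stay is stronger evidence of home than several short evening
errands. Ties break by larger member count, then smaller place id. A user
with no night-time stop gets no home label and the home-displacement metric
is reported missing for them. Local time is one configurable timezone per
dataset (default: timestamps as stored, i.e. UTC for the simulator); no
per-point timezone lookup is attempted.

## Mobility metrics

Twelve base metrics are computed per user per calendar day. Stops crossing
local midnight are split at 00:00 so dwell is attributed to the day it
falls in. Distances are haversine kilometres on a sphere of radius
6371.0 km (sub-0.5 % error versus the ellipsoid at city scale — irrelevant
here).

| metric | definition |
|---|---|
| `d_t` | total distance over the merged, time-ordered sequence of stop centroids and moving points |
| `sigma_d_t` | sample std (n−1) of the consecutive-leg distances of that sequence |
| `dis_t` | total displacement: sum of legs between consecutive stop centroids |
| `sigma_dis` | sample std of those stop-to-stop legs |
| `dis_m` | maximum stop-to-stop leg |
| `g` | radius of gyration: √(Σᵢ Tᵢ·d(Cᵢ, C̄)² / T), dwell-time weights Tᵢ, every visit contributing separately |
| `dis_h` | maximum distance of any visited stop from home |
| `n_dif` | number of visits (stops); two stops at one place count twice |
| `n_sig` | visits at *significant* places (the user's top-10 most visited over the full observation period; boundary ties go to the earlier-first-visited place) |
| `n_moves` | number of moving points |
| `n_unq` | distinct places visited |
| `div` | normalised visit entropy −Σⱼ vⱼ log vⱼ / log k ∈ [0, 1]; defined 0 for k ≤ 1 |

The reference centroid C̄ in the gyration radius is the dwell-weighted mean
of the visited coordinates (the unweighted mean is exposed as an option);
weighting the centroid the same way as the contributions is the
self-consistent choice. Metrics that are undefined on a day (std with one
leg, max displacement with no leg, gyration with zero dwell, home distance
without a home) are NaN plus an explicit `*_missing` flag column — never a
silent zero. Significant places are computed once over the whole period;
this mirrors the study design but leaks mild frequency information across
any later train/test split, which is acceptable because the counts carry no
label information.

**Window aggregates.** Over a history window [t−t_hist, t] each base metric
is summarised by mean, std (n−1; NaN for a one-day window), max, min and
the signed difference value(t) − value(t−t_hist). Aggregation refuses
windows with any day missing — availability is a sample-validity contract,
not something to impute. NaN metric values are skipped inside a window.

## Sample construction and balancing

A sample is anchored at (user, day t): features are the lagged daily
metrics for every day of [t−t_hist, t] plus the window aggregates; the
label is whether the user reported at least one of the eight surveyed
symptoms (fever, sore throat, cough, shortness of breath, headache, muscle
pain, malaise, cold) on day t+t_hor. Both t_hist and t_hor range over
{0, 1, 2} (an override exists). A candidate is valid only when mobility
rows exist for every window day and a diary entry exists at t+t_hor; one
sample set is materialised per t_hor so set sizes are comparable across
horizons. In the design matrix NaNs become 0 alongside the missingness
flags, keeping the matrix dense while preserving the information.

Symptom-free days dominate, so the majority class is randomly
under-sampled to the minority count (uniform, without replacement,
seed-deterministic). By default balancing is applied to the training
portion after splitting; the pooled cross-validation reporting mode
balances the full set first, mirroring the single-model, pooled-sample
study design.

## Classification and evaluation

Three families are supported: logistic regression behind a standard scaler
(LR), random forest (RF) and gradient boosted trees (GBT). Recursive
feature elimination (step 1; importance = |coefficient| for LR, impurity
importance for the ensembles) and a small documented hyperparameter grid
(LR C ∈ {0.1, 1, 10}; RF trees ∈ {100, 300}, depth ∈ {5, ∞}; GBT 100
estimators, depth ∈ {3, 5}) are tuned by 10-fold stratified CV maximising
precision; the best family is the one with the highest CV precision.
Reported metrics are precision, recall, F1, AUCROC (from continuous
predicted probabilities of the symptomatic class), and a row-normalised
2×2 confusion matrix (each true-class row sums to 1).

**Grouped cross-validation.** The pipeline's out-of-fold reports group
folds by user (stratified group K-fold). Windowed samples from one user
overlap in time, labels are autocorrelated within an illness episode, and
absolute geographic features (e.g. a user's characteristic home-to-work
distance) identify the user; with ungrouped folds a flexible model scores
above chance on symptom-free data by *recognising the user*, not the
mobility–symptom link. Grouping removes that bias: on decoupled
(zero-effect) synthetic cohorts the grouped out-of-fold AUCROC is
statistically indistinguishable from 0.5, while ungrouped folds sit at
≈ 0.55–0.61. The plain user-agnostic train/test split remains available
(and is the default of the split function) for parity with pooled-model
reporting.

## The synthetic cohort generator

Each agent has a home and 2–4 anchor places 0.6–4 km away (pairwise
≥ 400 m apart so they resolve into distinct clusters under the 200 m
rule), visited with per-anchor daily probabilities (a work-like anchor at
0.85, others 0.25–0.55). A simulated day pins the agent at home overnight
and in the evening (making the 7 pm–7 am home rule identifiable by
construction), strings 1–2.5 h anchor dwells through the daytime, and
interpolates straight-line travel at 20 km/h sampled every 5 min — fast
enough that the speed filter discards every travel point. Dwell points are
sampled every 20 min (30 min at night). Points get Gaussian positional
noise (15 m for GPS) and a GPS/NETWORK source mixture (80 % GPS with
reported accuracy U[5, 20] m; network accuracy U[60, 300] m with
correspondingly larger noise), so the 50 m filter removes network points.

Illness episodes are Poisson-placed at 1 per user-month, last 3–7 days,
carry 1–4 of the eight symptoms, and are preceded by a 2-day prodrome (the
generator's stand-in for "feeling unwell before reporting"; how far before
onset mobility actually changes is unknown, so this is a free parameter).
During prodrome and illness, mobility contracts by the effect size δ: each
anchor visit survives with probability scaled by (1−δ) and surviving
excursions are pulled toward home by the same factor — fewer distinct
places, shorter distances, lower visit entropy. δ = 0 decouples mobility
from symptoms entirely (the null configuration). Day-level gaps hit the
location and survey streams independently (10 % each). Defaults (50 users,
60 days) define the study conditions used by the recovery checks; a fixed
seed reproduces the tables byte-for-byte, and agent profiles come from a
dedicated seed stream so ground truth can be regenerated without
re-simulating.

What the simulator does **not** emulate: transport modes and road
networks, contact/proximity structure between users, weekday/weekend
rhythm, per-point timezone effects, survey fatigue or recall bias, and
symptom noise unrelated to episodes. Passing recovery tests therefore show
that the pipeline extracts a mobility-contraction signal when one exists
and reports chance when none does — not that real cohorts carry a signal
of this size.

## Numerical conventions and limitations

- Sample stds use the n−1 denominator throughout.
- The clustering is order-dependent by design; determinism is guaranteed
  only for identical input order.
- Signed (not absolute) window differences.
- All randomness fans out from one top-level seed via CRC-tagged seed
  sequences; repeated runs are bit-reproducible.
- Problem sizes in the recovery checks (50 users × 60 days; 10 null and 5
  signal cohorts; 3 + 2 cohorts in the acceptance script) are the package's
  chosen study conditions: large enough that chance AUCROC concentrates
  within a few points of 0.5, small enough to run comfortably on a laptop.
- Known limitations: no per-user personalisation, no multi-label
  per-symptom prediction, no imputation of missing days, and the
  significant-places list is not recomputed per CV fold (a
  `recompute_significant` workflow would need fold-aware feature
  extraction).
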