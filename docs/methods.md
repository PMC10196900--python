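# Methods

## Problem and labels

One *event* is one reported day for one participant, labeled N
(non-drinking), D (low-risk drinking: 1–3 drinks for women, 1–4 for men)
or BDE (binge: ≥4 / ≥5 drinks per occasion). The prediction task is
3-class classification of an event from sensor data collected in an
analysis window of `w` hours ending `d` hours before the (reported or
pseudo) drinking onset. Pseudo-onsets for non-drinking days are drawn
uniformly from the 15-minute grid in [18:00, 24:00). Onsets reported at
arbitrary minutes snap *down* to their containing 15-minute boundary; this
guarantees the temporal-separation invariant (no window epoch at or after
onset − d). Weekday and weekend events (weekend = Fri/Sat/Sun, where the
observed binge mass concentrates; configurable) are modeled separately.

All timestamps are stored as UTC epoch seconds; a per-participant fixed
UTC offset converts to local clock time for every time-of-day rule. This
avoids DST ambiguity while honoring local-time semantics.

## Synthetic cohort

No raw study data are available, so the package ships a first-class
generator. Defaults are the study conditions: 75 participants, 14 weeks,
71% women, expected pre-exclusion event mix 729:236:203
(N:D:BDE ≈ 0.62:0.20:0.17) over ~1168 reports, binge day-of-week
probabilities (2,0,5,7,36,52,20)/122 and onset-hour probabilities from the
observed 24-bin frequency table (n=122). Low-risk occasions use a
half-flattened onset mixture (the observed table constrains binge events
only). Compliance is a per-day Bernoulli process whose class-conditional
day-of-week distributions equal the configured vectors *exactly* — a
deliberate deviation from fixing two report days per participant, which
cannot satisfy the chi-square calibration property the generator is tested
against.

A latent per-day "social outing" state mediates every sensor effect:

* On drinking days with an evening onset, an outing precedes the onset
  with probability 0.85 (0.10 for daytime onsets — daytime occasions are
  mostly sensor-silent, so their onset clock time is their only signal);
  non-drinking days have a class-independent 20% outing rate.
* An outing is a venue tour over a per-event 4–10 h pre-onset horizon,
  ending ~1.5 h before onset; the night settles at the last venue or back
  home (40%). Tour size (2–3 stops) is class-independent. The *planted
  radius effect* is a pure dilation: venue distances from home scale by
  1 + U(0.8, 2.4) for BDE days and 1 + U(0.2, 1.4) for low-risk days.
  Tours run farthest-stop-first, so the window-end position says little
  about how far the evening roamed.
* With probability 0.5 (BDE), 0.12 (D) or 0.05 (N-outing) the tour takes
  place in one of two shared nightlife districts offset ~0.04° from the
  city center — the basis of the location-probability map and the
  coordinate-rounding privacy experiment. Homes cluster with σ = 0.02°,
  so district coordinates are a population-level signal that 0.1°
  rounding destroys.
* During the tour, accelerometer magnitude drops by 22% and communication
  rate by 40% (each applied per event with probability 0.6, so no channel
  is a deterministic marker).

Nuisance streams deliberately make poor clocks: wake times, activity and
usage multipliers vary per day; battery charging is opportunistic
(overnight on ~70% of nights plus random daytime top-ups, day-varying
drain); travel between anchors is interpolated at a per-trip speed drawn
from 5–25 m/s, so instantaneous GPS speed saturates instead of encoding
trip distance; 0.4% of fixes are km-scale multipath glitches. Without
this, window statistics of any diurnally structured stream act as
proxies for the time-of-day encoding and the planted hour effect cannot be
recovered as such.

Every effect size lives in [0, 1]. At zero, the day-of-week and
onset-hour distributions collapse to uninformative references (uniform
over days; uniform over 18:00–24:00, matching the pseudo-onset
convention), outing rates and timing decouple from the class, and the
streams carry no class information — the basis of the null-calibration
check. Missingness emulates the study's exclusion scale: a 28% daily
chance of disabled GPS, occasional multi-hour full blackouts, and
minute-scale dropouts; chosen once from the study's qualitative account,
not tuned to reproduce its exclusion mean exactly.

## Features

Exactly 70 features in five families (location 30, motion 6,
communication 12, device 18, environment 4), each computed on the pooled
local-time window; the same routine serves 15-minute epochs. Distances
are haversine with R = 6,371,000 m. Significant places come from
stay-point extraction (≤150 m, ≥10 min) followed by greedy 200 m
dwell-weighted centroid clustering over the full study period; home is the
place with maximal 00:00–06:00 dwell. Stationary/moving splits use a
1.4 m/s walking-pace threshold. Accelerometer statistics are two-stage:
per-minute mean magnitudes first, then window statistics. Circadian
movement integrates the normalized Lomb–Scargle periodogram over the
23.5–24.5 h period band (log scale, floor ln 1e-12) and requires the
window itself to span ≥24 h — it is therefore missing for all sub-day
analysis windows, by design: using data older than the window would
violate the storage-budget semantics that motivate `w`.

Features from a silent source stream are missing (NaN), except
communication/device/Wi-Fi counts where absence of events is a true zero.
Window aggregation recomputes every feature on the pooled window (counts
and durations become totals; mobility metrics are recomputed over the
pooled fixes), which is exact for the mobility family and equivalent up
to minute weighting elsewhere. Time encodings are the hour of day at
prediction time (window end) and the day of week of the onset.

## Modeling protocol

80/20 row-level split, stratified by class (a grouped-by-participant mode
is provided because row splitting lets models exploit participant
identity; both can be reported). Inside the training side only:
a greedy redundancy filter drops features with |Pearson r| > 0.85 to an
earlier-kept feature (several location-spread features are near-duplicate
measurements of one quantity; without the filter, tree models split
credit among them arbitrarily), then min-max scaling (constant columns
map to 0, test values are not clipped), median imputation of missing
values, and SMOTE (k = 5) raising every class to the majority count.
Base learners: XGBoost (200 trees, depth 4, η = 0.1, min_child_weight 4,
subsample 0.9, colsample 0.8 — sized for a few hundred instances by ~70
features), random forest, decision tree, SVM, logistic regression.

The grid evaluates every analysis window w ∈ {1,3,6,9,12} h at d = 1 h,
then prediction distances d ∈ {3,6} h at the best w per day class. Cell
selection uses the *cross-validated* BDE F1 on the training split (κ
breaks ties); held-out test metrics are what the result tables report.
Selecting on the 20% test split directly would make the chosen cell a
noisy lottery at desk scale. The seeded random hyperparameter search
samples the boosted-tree space (booster ∈ {gbtree, gblinear, dart},
depth 3–9, min_child_weight 2–10, η and γ log-uniform on [1e-8, 1], grow
policy, dart drop parameters active only for dart) with 10-fold
cross-validation, refitting scaling/imputation/SMOTE inside each fold;
candidates use 60 boosting rounds to keep a full search affordable on one
core. The day-of-week baseline predicts each test instance's
training-majority class for its day of week.

κ = (p_o − p_e)/(1 − p_e) with p_e from marginal products; if p_e = 1,
κ is defined as 0 with a warning. "The" F1 is macro-averaged across the
three classes (classes are imbalanced and per-class tables are also
emitted).

## Explanation layer

Boosted-tree models get exact tree-path Shapley attributions per class
(one-vs-rest margins); local accuracy (base + Σ attributions = margin)
holds to float precision. Non-tree models fall back to a seeded
permutation-sampling estimator in probability space that averages over
the whole background set at each step (exact for additive models).
Features removed by the redundancy filter receive exactly zero
attribution.

The reported global importance averages mean |attribution| over all of a
day class's instances across five fold models fitted with per-fold seeds
and stronger column subsampling: a single model assigns essentially
arbitrary credit within groups of near-duplicate features, while the fold
ensemble gives every group member its expected share. Per-model
importance (`global_importance`) is also available.

Partial dependence is computed in probability space on equal-count
(quantile) grids — 9 portions by default — centered so 0 is the expected
class probability; the two-way latitude × longitude variant flags cells
without observed support as extrapolated. The location-probability map
rounds mean coordinates to a configurable precision (1 decimal ≈ 11.1 km)
*before* binning and suppresses bins with fewer than 10 instances. The
privacy experiment retrains on coordinates rounded to 1 decimal and
compares held-out accuracy against full precision.

## Problem sizes and runtime

The acceptance script and heavy tests run the full pipeline at study
scale (75 participants × 14 weeks ≈ 1150 reported events, ≈ 800 after
exclusion) with a 20-trial search — about three minutes on one core. The
null-calibration check uses twenty 30-participant × 8-week effect-free
cohorts, since the property is scale-free. Unit tests use 3–30
participant cohorts generated on the fly; no data files ship with the
package.

## Known limitations

* The generator models statistical structure, not street-level behavior:
  dwell-and-hop trajectories, linear travel interpolation, and stylized
  device/communication processes. Passing tests demonstrate that the
  pipeline recovers planted effects under realistic noise and missingness
  — not that any particular accuracy transfers to real cohorts.
* Macro-F1 comparisons between a SMOTE-balanced classifier and a
  majority-style baseline carry a small systematic bias in the
  classifier's favor (spreading predictions over minority classes raises
  macro-F1 even without signal, while accuracy falls); see the null
  calibration discussion in the test suite.
* Row-level splitting (the reference protocol) lets models exploit
  participant identity through location features; the grouped split mode
  quantifies that gap but is not the default.
* The per-epoch instance mode is exposed through the same windowing
  machinery but the shipped protocol is event-level, where SMOTE and the
  80/20 split are well defined.
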