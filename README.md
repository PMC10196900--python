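# drinksense

Predicting imminent same-day binge-drinking events (BDEs) from passively
sensed smartphone data.

Young adults who binge drink (≥4 drinks per occasion for women, ≥5 for
men) could be reached by just-in-time mobile interventions — if the phone
could tell, a few hours ahead, that a drinking event is coming.
`drinksense` implements the full analysis pipeline for that problem:

1. **Sensing data model** — time-stamped GPS fixes, accelerometer samples,
   call/SMS logs, screen/app/battery events and Wi-Fi scans per
   participant, plus twice-weekly self-reports of drinking occasions
   (`drinksense.io`).
2. **Synthetic cohort generator** — a seeded simulator of a 75-participant,
   14-week study, calibrated to the observed binge day-of-week and
   onset-hour frequency tables, with a latent "social outing" state that
   couples the drinking class to mobility, accelerometry and communication
   (`drinksense.cohort`). No raw study data are required anywhere.
3. **Event building** — each reported day becomes one labeled event
   (N = non-drinking, D = low-risk, BDE); non-drinking days get a
   pseudo-onset drawn uniformly from the 18:00–24:00 evening grid. A
   24-hour lookback of 15-minute epochs precedes each onset, and an
   analysis window of `w` hours ending `d` hours before onset is cut from
   it, so the model never sees the `d`-hour separation period
   (`drinksense.events`).
4. **70 sensor features** per window — radius of gyration, location
   entropy and variance, circadian movement, significant-place dwell,
   travel statistics, two-stage accelerometer magnitudes, call/SMS counts
   and durations, screen/app/battery use, Wi-Fi hotspots — plus hour-of-day
   and day-of-week encodings (`drinksense.features`).
5. **Modeling** — redundancy filtering, min-max scaling, SMOTE
   oversampling (training side only), five algorithms (XGBoost, random
   forest, decision tree, SVM, logistic regression), a seeded random
   hyperparameter search with 10-fold cross-validation, a day-of-week
   majority baseline, and the full analysis-window × prediction-distance
   grid with separate weekday/weekend models (`drinksense.modeling`).
6. **Explanation** — exact tree Shapley attributions per class, global
   importance rankings, dependence data, 1-D/2-D partial dependence in
   probability space, a coarse location-probability map, and the
   privacy-versus-accuracy coordinate-rounding experiment
   (`drinksense.explain`).

The core quantities, in the field's notation: for an event with onset
*t₀*, features are computed on the pooled window [*t₀* − (*w*+*d*),
*t₀* − *d*) with *w* ∈ {1,3,6,9,12} h and *d* ∈ {1,3,6} h. The radius of
gyration is r_g = √(n⁻¹ Σᵢ dist(pᵢ, p̄)²) with great-circle distances;
location entropy is H = −Σ_c p_c ln p_c over significant-place dwell;
circadian movement is the log of the Lomb–Scargle band energy near the
24-hour period. Models are compared by accuracy, macro-F1 and Cohen's κ,
with per-class precision/recall/F1; the best grid cell is the one with the
highest cross-validated BDE F1 (κ breaks ties).

## Worked example

```python
import warnings; warnings.filterwarnings("ignore")
from drinksense import (
    CohortConfig, WindowConfig, simulate_cohort, build_instances,
    SplitConfig, split, evaluate, EventClassifier, baseline_day_of_week,
)
from drinksense.pipeline import prepare_events
from drinksense.modeling import prepare_xy

cfg = CohortConfig(n_participants=30, n_weeks=8, seed=7)
streams, truth = simulate_cohort(cfg)
events, excluded = prepare_events(streams, seed=7)
kept = events[events["exclusion_reason"] == ""]
print(f"events: {len(events)} reported, {len(excluded)} excluded, {len(kept)} analyzed")
print("class mix:", kept["label"].value_counts().to_dict())

wc = WindowConfig(w_hours=12, d_hours=1)
inst = build_instances(streams, kept, [wc])[wc]
weekend = inst[inst["day_class"] == "weekend"]
train, test = split(weekend, SplitConfig(seed=7))
X_tr, y_tr, cols = prepare_xy(train)
X_te, y_te, _ = prepare_xy(test)
model = EventClassifier(algorithm="xgboost", random_state=7).fit(X_tr, y_tr)
report = evaluate(y_te, model.predict(X_te))
base = baseline_day_of_week(train, test)
print(f"weekend {wc.tag}: accuracy {report.accuracy:.3f}, macro F1 {report.f1_macro:.3f}, "
      f"kappa {report.kappa:.3f}, BDE F1 {report.per_class['BDE']['f1']:.3f}")
print(f"day-of-week baseline: accuracy {base.accuracy:.3f}, macro F1 {base.f1_macro:.3f}")
```

Output:

```
events: 294 reported, 86 excluded, 208 analyzed
class mix: {'N': 119, 'D': 58, 'BDE': 31}
weekend W12D1: accuracy 0.708, macro F1 0.699, kappa 0.556, BDE F1 0.667
day-of-week baseline: accuracy 0.583, macro F1 0.582
```

Reading this: of 294 simulated self-reports, 86 were excluded for missing
sensor coverage (chiefly disabled GPS). Using 12 hours of sensor data
ending one hour before each (pseudo-)onset, the boosted-tree model
classifies weekend events into non-drinking / low-risk / binge with 71%
accuracy against 58% for a baseline that only knows the day of the week —
the sensors carry real pre-onset signal. `drinksense.pipeline.run_study`
runs the same protocol at full study scale across the whole window ×
distance grid, adds the hyperparameter search, Shapley explanation layer
and the privacy experiment.

## Command line

```bash
drinksense simulate --config cohort.yaml --seed 7 --out fixtures/
drinksense build    --fixtures fixtures/ --out build/ --seed 7
drinksense train    --build-dir build/ --out models/ --seed 7
drinksense explain  --build-dir build/ --models models/ --out explain/
drinksense report   --models models/ --explain-dir explain/ --out report.md
```

Every stage writes a manifest with input digests and is idempotent under a
fixed seed; `train` emits `grid_results.csv` (one row per window/distance/
algorithm cell plus baselines) and `explain` exports importance,
dependence, PDP and location-map tables as CSV.

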