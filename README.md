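# geopheno

Mobility phenotypes from smartphone location traces.

Passively collected GPS data is an increasingly common behavioral readout in
neuropsychiatric research, but a raw stream of (timestamp, latitude,
longitude, accuracy) fixes carries no context by itself. `geopheno`
implements a validated preprocessing framework that enriches such traces with
context — stationary states (*stay points*), non-stationary states
(*trajectories*) and recurrent stationary states (*place clusters*) — and
derives six behavioral phenotypes from the enriched data. It is aimed at
digital-phenotyping studies that need reproducible, auditable preprocessing
of per-subject location streams before any group-level statistics.

## Method

1. **Accuracy filtering.** Each fix carries a confidence radius: the distance
   within which the true position lies with 68% probability. Fixes above a
   configurable radius (default 200 m) are discarded; the trace is split into
   segments at sampling gaps longer than `max_gap` (default 60 min).
2. **Stay-point detection.** The anchor-sweep stay-point algorithm with a
   distance threshold θ_d and a time threshold θ_t: from an anchor fix the
   window grows while every fix stays within θ_d of the anchor; at the first
   exceedance the window becomes a stay point if its span is ≥ θ_t. Defaults
   θ_t = 60 min, θ_d = 350 m — a stay point is a group of coordinates that
   remains stationary for 60 min within an area of 350 m. Everything between
   stay points is a trajectory.
3. **Place clustering.** DBSCAN over stay-point centroids with the haversine
   metric, radius ε = 150 m (tuned by maximizing the Adjusted Rand Index
   against labelled data) and `min_points` = 1, merges repeated visits to the
   same real-world place into one recurrent entity.
4. **Phenotypes**, per local day and per window:
   - places visited, unique places, trajectories (counts; adjustable for
     observation length via residuals of an OLS fit on days observed),
   - **home stay** (hours and % of dwell time at the home cluster, home being
     the cluster with the most dwell inside the nightly 00:00–06:00 window),
   - **normalized entropy** −Σ pᵢ ln pᵢ / ln N of per-place dwell
     proportions (0 = all time at one place, 1 = uniform),
   - **diurnal movement**: log Lomb–Scargle spectral energy of the location
     series in a period band around 24 h (higher = more regular routine).

A labelled-trace simulator (`geopheno.simulate`) generates subjects with
known places, schedules, home, travel, sampling gaps and 68%-containment
positional noise, so every stage can be validated against ground truth.

## Worked example

```python
import geopheno as gp

trace, truth = gp.simulate_subject(7)          # 14 simulated days, labelled
result = gp.process_subject(trace, gp.PipelineConfig())
s = result.summary
print(len(trace), len(result.staypoints), len(result.clusters))
print(s["home_stay_pct"], s["normalized_entropy"])
scores = gp.evaluate_subject(result, truth)
```

prints (formatted):

```
fixes: 3637, stay points: 75, clusters: 4, trajectories: 53
home cluster: 0, home stay: 75.0% (16.7 h/day)
places/day: 5.36, unique places: 4, entropy: 0.603, diurnal movement: -0.97
stay-point accuracy: 98.9%, clustering accuracy: 100.0%, ARI: 1.00, home correct: True
```

The subject spent three quarters of accounted dwell time at the inferred
home cluster (which matches the simulated ground-truth home), visited 4
distinct places, and had a moderately uneven dwell distribution
(entropy 0.60). The pipeline recovered 98.9% of ground-truth dwell/travel
episodes correctly and clustered every visit to its true place.

The same stages are scriptable from a shell:

```sh
geopheno simulate --seed 42 --n-subjects 5 --out-dir sim/
geopheno detect --in sim/sim42_0_trace.csv --out staypoints.csv --theta-t-min 60 --theta-d-m 350
geopheno cluster --in staypoints.csv --out clusters.csv --eps-m 150
geopheno phenotype --in sim/sim42_0_trace.csv --out phenotypes.csv
geopheno evaluate --traces sim/ --out report.json
```

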