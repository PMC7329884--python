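# Methods

## Scope and data model

`geopheno` processes per-subject streams of smartphone location fixes. Each
fix is a WGS84 coordinate with an epoch-millisecond UTC timestamp and an
optional positional *confidence*: the radius in meters within which the true
position lies with 68% probability (this is how mobile OS location stacks
report accuracy). Timestamps are stored in UTC throughout; a single
configured IANA timezone per subject drives all local-day and night-window
logic, which keeps outputs identical across machines.

All distances are great-circle (haversine) on a sphere of mean radius
6 371 008.8 m. No map projection is used; at the city scales the framework
targets, haversine error is negligible relative to GPS noise.

## Preprocessing

**Accuracy filter.** Fixes with confidence above `max_confidence_m`
(default 200 m) are dropped. The threshold is deliberately permissive:
discarding sparse data silently is worse than carrying noisy fixes the
stay-point radius can absorb. Fixes with *missing* confidence are kept by
default (configurable), for the same reason. Duplicate timestamps keep the
first occurrence; out-of-range coordinates are dropped and counted in a load
report.

**Gap segmentation.** A hole longer than `max_gap` (default 60 min) splits
the trace into independent segments. The default equals θ_t because a gap of
θ_t or more cannot be confidently labelled stationary; detection never
bridges a gap.

**Stay-point detection.** The classic anchor-sweep algorithm with distance
threshold θ_d = 350 m and time threshold θ_t = 60 min (both configurable).
From anchor *i* the window extends over *j* while haversine(p_i, p_j) ≤ θ_d;
at the first exceedance (or segment end), if t_{j−1} − t_i ≥ θ_t the window
becomes a stay point (centroid = unweighted mean of member coordinates,
arrival = t_i, departure = t_{j−1}) and the anchor jumps past it; otherwise
the anchor advances by one fix. Three boundary choices are deliberate:

- the duration comparison is **inclusive** (≥ θ_t), making the "exactly
  60 min" case well-defined;
- the **anchor-based** distance test (distance to the window's first fix) is
  used rather than a pairwise-diameter test, matching the cited algorithm's
  classic form and keeping the sweep O(n · window);
- a **trailing window** truncated by the segment end still becomes a stay
  point if it spans θ_t, so dwells cut off by data gaps are not lost.

Centroids are unweighted means; confidence-weighting is left as a config
extension because it changes results only marginally and complicates the
audit trail. Trajectories are the maximal fix runs between consecutive stay
points (and between segment edges and the first/last stay point) that
contain at least one fix; their interval runs from the predecessor's
departure to the successor's arrival. Per-fix state labels (stationary /
non-stationary) partition every segment.

**Place clustering.** DBSCAN over stay-point centroids, haversine metric,
ε = 150 m, `min_points` = 1. With `min_points` = 1 density clustering is
exactly the transitive closure of the ε-neighborhood graph: every stay point
is assigned (singletons allowed), so "unique places" counts single visits,
and *recurrent* places are clusters with ≥ 2 visits. Clustering is done on
centroids, not raw member fixes — cheaper, and the centroid of an hour of
fixes is far less noisy than any fix. Cluster ids are canonicalized by each
cluster's earliest visit, making memberships and ids invariant to input
order. ε-tuning (`tune_epsilon`) clusters each labelled subject separately,
scores each with the Adjusted Rand Index against the subject's true place
labels, and reports mean ± SE (sample SD across subjects / √n) per ε; the
per-subject-then-average convention and the SE estimator are documented
choices.

## Phenotypes

**Counts.** Places visited (= stay points), unique places (= distinct
cluster ids) and trajectories, per local day and per window. A stay point
counts once on its *arrival* day even when it spans midnight (counts must
not double); a trajectory counts on its start day. Window summaries report
both totals and per-observed-day rates, since different study designs want
either aggregation.

**Duration adjustment.** Across a cohort, each count is regressed on the
number of observed days (OLS); the adjusted value is the residual plus the
grand mean, so the scale stays interpretable while the residuals are exactly
orthogonal to observation length. With constant observation length the
adjustment is the identity (warned).

**Home inference.** Home is the cluster accumulating the most dwell time
inside the nightly window, 00:00–06:00 local, summed over the whole
observation period. Ties break toward larger total dwell, then earlier first
visit — both deterministic. With no nighttime dwell at all, home is
undetermined and home-stay phenotypes are emitted missing rather than
guessed. The night window is configurable; 00:00–06:00 is the standard
choice in the passive-sensing literature and is validated against simulator
ground truth (100% recovery on the reference cohort).

**Home stay.** Per day, the dwell time of home-cluster stay points
intersected with that local day; stay points spanning midnight are split
proportionally across days so hours conserve time (≤ 24 h/day by
construction). The percentage denominator is total stay-point dwell that day
(default) rather than elapsed clock time, because smartphone duty-cycling
makes elapsed time unreliable; `homestay_denominator: elapsed` switches to a
24-h denominator.

**Normalized entropy.** −Σ pᵢ ln pᵢ / ln N over per-cluster dwell
proportions; 0 by convention when N = 1. Natural log; the normalization
cancels the base anyway.

**Diurnal movement.** The latitude and longitude series (degrees) are
sampled from stay-point centroids on a regular 10-min grid: inside a stay
point the centroid is used, after departure the last centroid is carried for
at most `max_gap`, longer gaps stay missing. Each mean-centered series gets
a Lomb–Scargle periodogram (scipy's least-squares formulation, exact for
irregular sampling) evaluated at 33 periods spanning 23.5–24.5 h; the score
is ln(E_lat + E_lon) of the summed band power, floored at ln(1e−12)
(≈ −27.6) so a constant location yields a finite score. Units are internal
(degree²-based): absolute magnitudes are not comparable across
implementations with different scalings, so only orderings and contrasts are
meaningful — the tests assert exactly those, plus exact agreement with an
independent single-frequency least-squares sinusoid fit.

Phenotypes needing ≥ 3 days of data (diurnal movement) are missing below
that.

## Synthetic labelled traces

The simulator emulates the study conditions the framework was built for:

- **Places:** home plus 2–4 day places (default 3), pairwise ≥ 600 m apart
  (rejection-sampled within a disc of 4× the separation); evaluation setups
  that demand ≥ 1 km use `min_separation_m=1000`.
- **Schedule:** per day, dwell at home until a morning departure
  (U[7.5, 9.5] h), 2–4 trips to day places with dwells of U[90, 240] min
  joined by constant-speed (30 km/h) straight-line travel, return home by
  21:30, home occupied through the night (p = 1.0 by default). Dwell and
  travel episodes tile the simulated span exactly.
- **Sampling:** 5-min interval with ~10% of time removed in 30-min dropout
  bursts — plausible smartphone duty-cycling.
- **Noise:** radial-Gaussian positional error with
  σ = confidence / √(−2 ln 0.32) ≈ confidence / 1.5096, so the 68th
  percentile of the radial error equals the per-fix confidence, honoring the
  containment semantics. The per-subject mean confidence is drawn uniformly
  from 25–170 m, matching the reported per-subject range.

Ground truth carries per-fix states, per-episode place identities and the
home place. What the simulator does **not** model: road networks (travel is
straight-line), multipath/urban-canyon error correlation (noise is i.i.d.),
within-building movement, device-specific duty cycles, or places closer
together than ε. Passing recovery tests therefore demonstrate correctness of
the algorithms under the stated noise model, not performance on any real
cohort — in particular, two real venues within 150 m will merge, a
documented limitation of the ε-radius approach.

## Evaluation metrics

- **Episode-level stay-point accuracy:** a ground-truth dwell counts as
  detected when detected stay-point intervals cover ≥ 50% of its duration; a
  travel episode is correct when covered < 50%. Accuracy = correct episodes
  / all episodes, reported per subject and as cohort mean ± SD. The 50%
  matching rule is this package's definition of "percentage correct" for
  user-confirmed states.
- **Clustering accuracy:** % of stay points whose cluster's majority true
  label equals their own (ties toward the earlier-visited label), plus the
  Adjusted Rand Index (scikit-learn's pair-counting implementation,
  cross-checked in the tests against an exhaustive contingency-table
  oracle).
- **Home accuracy:** the inferred home cluster is mapped to its majority
  ground-truth place; correct when that is the designated home.

`run_pipeline` writes a manifest (package version, full config, SHA-256 of
every input) so any output is reproducible from config + seeds + inputs.
Per-subject failures are logged and skipped; the run fails only if every
subject fails.

## Problem sizes and determinism

Reference checks use 14-day subjects at 5-min sampling (~4000 fixes each):
20 subjects for home-heuristic recovery and 5 for stay-point recovery, sizes
at which the measured accuracies are stable across seeds while the whole
validation runs in well under a minute. All randomness derives from one
master seed via numpy `default_rng`; identical seeds give byte-identical
traces and pipeline outputs.

## Known limitations

- Movement *within* a stationary location is invisible to the method by
  design; accelerometer fusion is out of scope.
- Detection accuracy interacts with fix precision: very precise fixes can
  make a dwell look like slow drift relative to a fixed θ_d. Thresholds are
  exposed per config rather than adapted per subject.
- The home heuristic assumes the subject sleeps at home most nights; shift
  workers would need a different night window.
- Diurnal-movement magnitudes are implementation-specific (see above).
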