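# Methods

## The assay being modeled

A head-restrained zebrafish larva (head embedded in agarose, tail free in
buffer) receives mechano-acoustic taps while a high-speed camera records at
640 frames/s.  Each frame carries two in-image metadata channels: a hardware
frame counter (emulating the camera's secure-image-signature timestamp) and a
TTL block marking the frames during which the tap solenoid fired.  Up to six
taps are delivered per trial at a 10 s inter-stimulus interval.

From each tap the analysis derives the standard startle metrics:

* **latency to first movement** — time from the stimulus to the first frame
  whose tail angle changes by more than 5° from rest;
* **escape / C-bend max** — the event is an escape when the angle crosses 60°
  from rest; the C-bend max is the largest absolute excursion;
* **latency to C-bend max** — time to the peak minus the latency to first
  movement;
* **latency class** — short-latency C-bend (SLC, < 13 ms; Mauthner-cell
  mediated), long-latency C-bend (LLC, 13–26 ms, both boundaries inclusive to
  LLC), or OTHER beyond 26 ms.

The tail angle is the paper-standard 20-point body measurement: the fish is
skeletonized, a spline is fit to the skeleton, 20 points are sampled at equal
arc length, and the signed angle of the total-least-squares line through the
last five points is measured against the restrained head axis.

## Tail tracking

1. **Segmentation** — the metadata band (top 8 rows) is masked, the frame is
   thresholded (Otsu by default, fixed threshold optional) and the largest
   connected component above `min_fish_area_px` (default 120 px) is kept.
   Frames with no plausible fish are flagged `failed`, never raised.
2. **Centerline** — morphological skeleton, reduced to the longest geodesic
   path between skeleton endpoints (side branches pruned; ties broken toward
   the head anchor), oriented head-first.  A ring-shaped skeleton (no
   endpoints) fails the frame.
3. **Resampling** — smoothing spline (`scipy.interpolate.splprep`, smoothing
   condition `0.1 × path length`) sampled at 20 equal-arc-length points.  The
   smoothing constant matters: values an order of magnitude larger flatten the
   body curvature and rotate the distal tail by several degrees, so the small
   default only suppresses single-pixel skeleton jitter.
4. **Subpixel refinement** — each resampled point is snapped to the
   intensity-weighted centroid of the grayscale profile along the local
   normal (±5 px, bilinear sampling, 2 iterations).  The morphological
   skeleton is only pixel-accurate; without this step its half-pixel
   placement noise dominates the angle error (~±1.6° static error, up to
   ~1.8° asymmetry under 90° frame rotation).  With it, static recovery error
   over bends in [−150°, 150°] is ≤ 0.4° and the measurement is rotation
   equivariant to ~0.25°.
5. **Angle and baseline** — total-least-squares direction of the last 5
   points versus the configured (or auto-detected) head axis; positive sign
   is +y in image coordinates (sign is only used for QC; event metrics use
   magnitudes).  The rest angle is the median over a 50 ms pre-first-stimulus
   window and is subtracted; event detection additionally re-baselines
   against the 50 ms preceding each tap, which makes the metrics robust to
   slow drift across the six taps.

Failed frames inside gaps of ≤ 3 frames are filled by linear interpolation
(flagged `fallback`); longer gaps stay NaN.  Trials with > 20% failed frames
are flagged low quality but still analyzed — exclusion is the caller's choice.

## Event detection

Each tap's search window is `response_window_ms` (default 1000 ms) but is
always clipped at the next tap, so one tap's response is never attributed to
its silent predecessor.  Latencies are inherently quantized to the frame grid
(multiples of 1000/fps ≈ 1.5625 ms).  With two equal angle maxima the earlier
frame is the peak.  An escape without a first-movement crossing is impossible
(60° > 5°) and asserted.  Responsiveness is reported per delivered stimulus,
with a per-larva roll-up (a larva responds if ≥ 1 tap elicits a response)
alongside.

## Synthetic rig and ground truth

No real recordings ship with the package; every downstream stage is validated
against generated videos whose kinematics are known in closed form.

* **Waveform** — rest until the scripted latency, half-sine rise to the peak
  angle over `time_to_peak_ms`, exponential relaxation (`relaxation_ms`)
  afterwards.  The real assay constrains only onset, peak and latencies; a
  smooth unimodal waveform keeps those unambiguous.
* **Body geometry** — straight head segment (first 30% of arc length,
  matching the agarose-restrained head), a constant-curvature arc carrying
  the whole bend (30–70%), and a straight distal segment whose direction is
  exactly the scripted bend angle.  Because the distal quarter is straight,
  the "last five of twenty points" measurement has a well-defined true value.
* **Rendering** — bright silhouette (elliptical head blob + tapered tail,
  pointed ~2 px tip) on a dark background, rasterized at 4× resolution and
  average-pooled so body placement is subpixel and edges are antialiased.
  Sensor noise (Gaussian, default σ = 2 gray levels) is added below the
  metadata band; rest-angle jitter (`baseline_noise_deg`) perturbs the
  waveform itself.
* **Ground truth** — stored per stimulus and per frame.  Two latency notions
  are recorded: the scripted kinematic onset, and the assay-definition
  latency (first frame at which the noise-free waveform exceeds the 5°
  threshold, in closed form on the half-sine rise).  The true latency class
  derives from the latter, because SLC/LLC bounds are defined on the measured
  latency.  Recovery comparisons use frame-grid truth — a camera cannot
  observe between frames.
* **Cohorts** — per-tap scripts are drawn from per-group distributions
  (uniform latency/peak/rise ranges plus a response probability).  Defaults
  emulate a healthy control group: 95% responsiveness, latency uniform in
  [4, 10] ms (median 7 ms), peaks 80–140°, rise 4–8 ms.  A knock-down-like
  group is obtained by shifting the latency range (e.g. +5 ms).

What the generator does **not** emulate: free swimming, body occlusion,
illumination gradients, motion blur within a frame, eye/pectoral-fin
structure, habituation across taps, or tracking-rig vibration.  Passing the
recovery tests therefore demonstrates the correctness of the measurement
chain, not robustness to every artifact of live recordings.

## Estimation statistics

Group comparisons follow the estimation-statistics style: unpaired median
difference (test − control), a 5000-resample percentile bootstrap 95% CI
(each group resampled with replacement at its own n; BCa available behind a
flag), and a two-sided permutation test on the absolute median difference.
Permutations are enumerated exhaustively when the number of distinct
assignments is ≤ 20 000; otherwise Monte-Carlo with the identity-inclusive
add-one estimator, p = (1 + #{perm ≥ obs}) / (1 + n_perms), which can never
return 0 — effects that would print as "p = 0.0" are reported as
p = 1/(n_perms + 1).  Tie comparisons use ≥ on the absolute statistic
(conservative).  One seeded generator drives each analysis; the seed is
logged in every output.

Phenotype count tables are tested with the plain Pearson chi-square test of
independence (no continuity correction).  The Pearson statistic cannot exceed
n·(min(rows, cols) − 1); when a caller supplies a reference statistic above
that bound for the same table, the function raises instead of comparing
against an impossible number.

Simulation checks included in the test suite: the permutation test's type-I
error at α = 0.05 is 5% ± 1.8% over 1000 null simulations (n = 30/group), and
the percentile CI covers a known location shift in 95% ± 2.5% of 500
simulations (n = 100/group).

## Pipeline, blinding, determinism

`run_pipeline` drives simulate/ingest → track → score → aggregate → test from
one config.  With blinding on (default), every intermediate artifact (event
tables, traces, QC log, ground-truth export) carries opaque `group_XX` codes
whose assignment is a seed-derived permutation; true labels appear only in
the final report (`stats.json`, `group_summary.json`).  Outputs are
deterministic given config + seed.

## Problem sizes and defaults

The protocol values (640 fps, 6 taps, 10 s ISI, 20/5 centerline points, 5°
and 60° thresholds, 13/26 ms class bounds, 5000 resamples) are the package
defaults.  Synthetic test runs compress the inter-stimulus interval to
0.2–0.3 s and use 128×128 frames: the escape concludes within tens of
milliseconds, so the quiet period and sensor size carry no information for
the analysis — they only scale runtime.  The recovery experiments in the test
suite and acceptance script use 100 single-tap trials (latency), a 20–150°
peak sweep, 60 events for classification, and two 10-fish groups (60 events
per group) for the end-to-end effect-recovery run.

## Known limitations

* The tail angle definition ("last five points against the head segment") is
  one of several readings of the assay description; the fitted-line variant
  was chosen for robustness to single-point jitter.  Chord-based variants
  differ by < 1° on the synthetic geometry.
* The timestamp row is an open binary-counter stand-in for the camera
  vendor's proprietary signature format; it preserves the property that
  matters (per-frame hardware time, frame-drop detection), not the format.
* Percentile (not BCa) intervals are the default; for strongly skewed
  measures at small n the percentile interval can under-cover.
* The tracker assumes one bright fish on a dark background with a fixed head
  anchor; it is not a free-swimming or multi-animal tracker.
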