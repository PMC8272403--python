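# startletrack

Analysis of larval zebrafish acoustic startle responses from high-speed video:
tail tracking, C-bend escape kinematics, short-/long-latency classification,
and estimation statistics — plus a synthetic video rig that generates
ground-truth trials so the whole measurement chain is testable without any
real recordings.

## The problem

A head-restrained 4-dpf larva receives mechano-acoustic taps (up to six, 10 s
apart) while a camera records the tail at 640 frames/s.  The Mauthner-cell
circuit drives short-latency C-bend escapes (SLC, latency < 13 ms); long
latency C-bends (LLC, 13–26 ms) are attributed to slower, non-Mauthner
pathways — so the *latency composition* of the responses is a readout of
hindbrain circuit integrity, distinct from responsiveness itself.

From each tap, the pipeline measures, per frame, the signed tail angle θ(t):
the fish silhouette is skeletonized, a spline fit to the skeleton is resampled
into 20 equal-arc-length points, and θ is the angle of the fitted line through
the last five points relative to the restrained head axis.  Per stimulus it
derives:

* **latency to first movement** — first frame with |θ − θ_rest| > 5°;
* **escape / C-bend max** — an escape when |θ − θ_rest| crosses 60°;
  C-bend max = max|θ − θ_rest|;
* **latency to C-bend max** — time-to-peak minus latency to first movement;
* **latency class** — SLC (< 13 ms), LLC (13–26 ms) or OTHER.

Group comparisons use estimation statistics: the unpaired median difference
Δ = median(test) − median(control) with a 5000-resample percentile bootstrap
95% CI and a two-sided permutation p-value, plus Pearson χ² on phenotype count
tables.  Stimulus times and per-frame timestamps are decoded from in-image
metadata (a binary frame-counter row and a TTL marker block), so frame drops
are detectable and latencies stay on the hardware time base.

## Worked example

The bundled demo simulates two 5-fish groups — a control (latency ~4–10 ms)
and a "morphant" with a +5 ms latency shift — renders the videos, tracks them,
scores the events and runs the statistics:

```bash
startletrack all --seed 7 --out demo_out
```

prints

```
control group: control
  control: responsiveness 0.93, SLC 1.00, LLC 0.00, median latency 7.03 ms
  morphant: responsiveness 0.93, SLC 0.50, LLC 0.50, median latency 13.28 ms
  latency median difference morphant - control: 6.25 ms [95% CI 4.69, 7.81], p = 0.0002
results written to demo_out
```

Reading the numbers: both groups respond to ~93% of taps (the knock-down does
not impair hearing), but the shifted group's median latency moves from 7.03 ms
to 13.28 ms — the median difference of 6.25 ms (4 frame periods at 640 fps,
scripted shift 5 ms) has a bootstrap CI excluding zero and a permutation
p ≈ 2·10⁻⁴ — and its SLC share collapses from 100% to 50% in favour of LLC
responses: the signature of a slowed, non-Mauthner-dominated escape.
`demo_out/` contains the per-event table (`events.csv`, blinded group codes),
per-group summaries, the statistics JSON (codes resolved), the generator
ground truth and a QC log.

The same machinery is available as a library (`startletrack.synthetic_rig`,
`acquisition_io`, `tail_tracking`, `event_kinematics`, `estimation_stats`,
`pipeline`) and as separate CLI verbs `simulate`, `track`, `score` and
`stats` for recorded TIFF stacks / PNG sequences.

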