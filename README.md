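# homebase

Origin-related exploration analysis for tracked 2-D trajectories.

Many exploring animals — and, at the pre-walking stage, human infants —
organize their movement around a *reference place* (a "home base" or
*origin*): the location marked by both the highest cumulative dwell time
and the highest number of visits, from which round-trip *excursions*
into the environment are performed. `homebase` implements the full
analysis chain for quantifying this structure from tracked positions of
an infant exploring a room in the presence of a stationary mother, and
for comparing groups of sessions (e.g. typically developing, TD, versus
non-typically developing, NTD, infants) on seven behavioral endpoints.

It is a library for researchers in computational ethology and
developmental behavior analysis, with a thin `homebase` CLI for running
the pipeline on cohorts of tracked sessions.

## What it computes

Given per-session positions `(t, x, y)` in floor centimetres (raw
image-plane tracks can be rectified with a fitted homography and
gap-filled by linear interpolation):

- **Visits by the ring algorithm** — a visit to a place begins when the
  subject enters an inner circle of radius `r_in` and ends when it
  leaves a concentric outer circle `r_out > r_in`; the hysteresis
  screens re-entrances caused by tracking jitter.
- **Dwell-time maps and preferred places** — time accumulated on a
  1-cm grid, smoothed with a 2-D Gaussian kernel (σ = 14 cm, truncated
  at 31 cm), local maxima retained at the top 4% and annotated with
  visit counts from a (30, 50) cm ring.
- **Customized mother radius and excursions** — `r_in` is scanned over
  30–120 cm (with `r_out = 1.1 r_in`); the smallest radius of the
  longest interval with a constant visit count defines the mother's
  boundary, and the path between consecutive mother visits is one
  excursion.
- **Proximity and contact** — per-object clearance series
  `d(t) = ‖p(t) − c‖ − r` (negative clearance = climbing on mother),
  proximity episodes below a radius, and kinematic contact episodes
  (clearance < 35 cm with ×1.2 hysteresis).
- **Seven endpoints and exact statistics** — excursions/min (√),
  proportion of time within 100 cm of mother (logit), average
  progression speed, proportion of room covered (logit), average speed
  beyond 100 cm, contact episodes/min (√), proportion of contact time
  (logit); compared across groups by the exact Wilcoxon rank-sum test
  (full enumeration of all C(n₁+n₂, n₁) assignments), pooled-SD effect
  size |x̄−ȳ|/s_p, Benjamini–Hochberg adjustment, and an exact
  label-permutation test for distance-profile curves.
- **Synthetic sessions** — a seeded generator emulating mother-anchored,
  excursion-partitioned (TD-archetype) and origin-free, away-lingering
  (NTD-archetype) sessions with ground truth for every stage, so the
  whole pipeline is testable without video data.

## Worked example

```bash
python examples/simulate_and_segment.py
```

```
session duration: 30.0 min, 3600 samples
customized mother radius r_in: 48 cm (visit count stable at 11)
mother visits: 12; complete excursions: 11 (0.367/min)
generator ground truth: 11 excursions (0.367/min)
longest excursion reach: 294 cm from mother
```

The radius scan found the visit count stable from 48 cm outward, so
48 cm becomes this session's mother boundary; the 12 visits bound 11
complete excursions, matching the generator's own bookkeeping exactly.
`examples/group_comparison.py` runs a full 5 + 7 cohort and prints the
endpoint comparison table; with the default presets the excursion-rate
row shows `W = 35, exact p = 0.00253` — the maximal rank-sum statistic,
meaning every TD session out-ranks every NTD session. Other examples
cover home-base detection from dwell maps and homography rectification
of raw pixel tracks.

The same pipeline is available from the shell:

```bash
homebase simulate --n-td 5 --n-ntd 7 --seed 1 --out cohort/
homebase analyze cohort/manifest.csv --out results/ --figures
```

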