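# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `homebase`. Parameters described as defaults are
the values the analysis is conventionally run with; all are exposed on
`RunConfig` or the relevant function.

## Coordinate frame and preprocessing

Sessions live in a rectangular room (reference layout: 365 × 545 cm) with
the origin at a fixed corner, `x ∈ [0, width]`, `y ∈ [0, length]`, units
cm. Raw image-plane tracks are rectified with a projective homography
fitted by least squares (DLT, via `skimage.transform.ProjectiveTransform`)
from 4–16 landmark correspondences; degenerate configurations (three
collinear source points, rank deficiency) raise an explicit error naming
the offending points. Tracks sampled every `step_frames` video frames
are resampled to a uniform grid `dt = step_frames / fps` (default 0.5 s,
matching every-15th-frame tracking at 30 fps), with interior missing
samples filled linearly and leading/trailing gaps trimmed rather than
extrapolated.

Trajectory smoothing is a centred running weighted average with Gaussian
weights: σ = `window_s`/2, truncated at ±`window_s` (default 1.0 s), and
edge-renormalized. This choice preserves lingering plateaus and
constant-velocity stretches (symmetric weights leave linear paths
unchanged in the interior) while damping manual-tracking jitter; the
kernel is deliberately simple and configurable since all downstream
results are parameterized on it. Points that rectification noise pushes
outside the room are clamped to the boundary and counted; more than 1%
clamped raises a warning, as does a session shorter than the 20-minute
tracking requirement.

## The ring algorithm

A visit to a place is defined by a two-state machine on the distance
series to the place's centre: OUT→IN on `d < r_in`, IN→OUT on
`d > r_out`, with `r_out > r_in`. Equality keeps the current state, so
behaviour is deterministic on grid-valued inputs. A series starting
inside the inner circle opens a visit at index 0 (sessions begin with
the infant seated at mother); an IN state at the series end yields a
final visit flagged incomplete. `count_visits` excludes incomplete
terminal visits by default so that counts are comparable across radii in
the calibration scan; the flag is exposed because the treatment of a
terminal IN state is a policy choice, not a property of the data. The
implementation is vectorized (event forward-fill); a sequential
brute-force state machine serves as the test oracle and the two agree
exactly on thousands of random series.

## Dwell-time maps and preferred places

Each sample contributes `dt` seconds to the 1-cm cell containing it, so
the raw map total equals the tracked duration exactly. The map is
smoothed with a 2-D Gaussian kernel, σ = 14 cm truncated at 31 cm (a
63 × 63 window at 1-cm cells). At the room boundary the kernel is
renormalized **on the source side**: each cell's dwell is redistributed
over the in-room part of its window. This conserves total dwell exactly
— the invariant the downstream peak analysis depends on — and coincides
with the target-side weighted average everywhere in the interior. The
alternative (renormalizing at the target) preserves constant fields
everywhere but inflates the total by several percent when dwell
concentrates at a wall, which is precisely the home-base situation
(mother sits against a wall); we chose mass conservation. Consequence: a
constant field is reproduced exactly only at cells farther than twice
the truncation radius from a wall.

Preferred places are local maxima of the smoothed field over 8-connected
neighbourhoods. Connected equal-valued plateaus (a by-product of grid
discretization) collapse to their centroid. Maxima closer than 50 cm to
a higher-valued maximum are suppressed: 50 cm is the outer radius of the
visit-counting ring, so two maxima within it describe the same place —
without this step, jittery tracked paths produce satellite micro-maxima
on transit corridors that would be retained as separate "places". Of the
surviving maxima the top 4% by value are kept (at least one, plus any
ties with the last retained), and each retained peak's visits are
counted with the (30, 50) cm ring. The 4% threshold is applied
per-session. Contour rendering uses the deciles of the positive smoothed
dwell.

## Mother radius calibration and excursions

The boundary of the mother's place is customized per session: the ring
algorithm is run with `r_in` from 30 to 120 cm in 1-cm steps (resolution
below tracking noise; the choice is verified to be stable under step
refinement) keeping `r_out = 1.1 r_in`. The chosen `r_in` is the left
endpoint of the longest radii interval with a constant visit count —
a region of stability — with ties resolved toward the smaller radius.
Visits at the chosen ring partition the session: an excursion spans from
one visit's end to the next visit's start; a terminal away segment with
no return is reported as incomplete and excluded from rates (some
sessions end with the infant retrieved by the mother rather than
returning). The excursion rate is complete excursions per tracked
minute. When a session starts and ends inside the ring, the number of
complete excursions is exactly the number of visits minus one, and
visit and excursion intervals tile the session — both are tested
invariants.

## Proximity and contact

Clearance to an object disc is `d(t) = ‖p(t) − c‖ − r`; negative values
mean the infant penetrated the disc (for the mother, climbing on her).
The mother's proximity radius defaults to 0 (centres-of-mass distance).
Proximity episodes are maximal runs below a radius `R` (display default
120 cm) with no hysteresis, so episode durations account exactly for the
samples below `R`. Physical contact is **not observable** from
centre-of-mass tracks; it is operationalized kinematically as clearance
below `contact_cm` (default 35 cm, roughly the sum of two trunk radii)
with a ×1.2 hysteresis exit so jitter does not split a single touch.
This is a proxy: it counts close grazes as contact and cannot
distinguish who initiated it. The threshold is exposed, logged in the
output provenance, and the generator's ground truth applies the same
rule to the noise-free path so that validation measures tracking-noise
robustness rather than definitional mismatch.

## Endpoints

Seven per-session scalars: excursions/min; proportion of time with
mother-distance < 100 cm; average progression speed; proportion of room
covered; average speed over samples with mother-distance > 100 cm;
contact episodes/min; proportion of contact time. Rates are normalized
by tracked minutes. Progression/lingering labels come from thresholding
per-sample speed; with `"auto"` the threshold sits at the antimode of
the (lightly smoothed) log-speed histogram, falling back to 5 cm/s with
a warning when the histogram is unimodal. Average progression speed is
the mean over progression-labelled samples only, per the endpoint's
name. Room coverage rasterizes the piecewise-linear path onto the 1-cm
grid (Bresenham lines between consecutive samples): sampled points alone
under-count badly — a 30-minute session has ~3,600 samples against
~200,000 cells, so point coverage could never reach the few-percent
range that moving sessions actually cover. Variance-stabilizing
transforms follow the endpoint family: square root for rates, logit for
proportions, with proportions clamped to `[1/(2n), 1 − 1/(2n)]`
(standard continuity correction) before the logit; the transforms are
monotone and therefore do not affect rank-based tests (tested).
A session never leaving the mother's vicinity has an undefined
outside-speed endpoint, reported as missing and dropped pairwise in
comparisons.

## Statistics

With 5 + 7 sessions all `C(12, 5) = 792` group assignments are
enumerable, so both tests are exact. The Wilcoxon rank-sum statistic is
reported in its Mann–Whitney form `W = #{(i,j): x_i > y_j}` (ties count
half, i.e. mid-ranks); the two-sided p doubles the smaller tail
(observation included) and caps at 1. At complete separation this gives
`W = 35`, `p = 2/792 ≈ 0.00253`. The effect size is `|x̄ − ȳ|/s_p` with
the pooled variance `s_p² = ((n_x−1)s_x² + (n_y−1)s_y²)/(n_x+n_y−2)`.
The seven endpoint p-values are adjusted with the Benjamini–Hochberg
step-up procedure (via statsmodels), controlling FDR at 0.05.

For comparing distance-profile curves (e.g. proportion of time within
radius `r` of mother, over a grid of radii) the package uses an exact
label-permutation test: the statistic is the integral over the grid of
`|mean₁(r) − mean₂(r)|` (a "max gap" variant is available), referred to
its full 792-assignment enumeration; p is the fraction of assignments
with a statistic at least the observed one. Note that with unequal
group sizes only the identity assignment attains the maximal area at
complete separation, so the smallest attainable p is 1/792. BH-adjusted
values are not idempotent under re-adjustment in general (re-running the
step-up inflates non-tied values); order preservation and
`adjusted ≥ raw` are the guaranteed properties.

## Synthetic sessions

The generator reproduces the reference recording conditions: 2 Hz sampling, 365 × 545 cm
room, mother at the periphery, isotropic Gaussian tracking noise
(default σ = 3 cm), sessions of at least 20 minutes.

**TD archetype** (default 30 min): the session alternates mother-dwell
bouts and excursions. The infant keeps a habitual sitting spot 45 cm
from the mother's centre and a lap spot at 12 cm, both fixed per
session, so dwell mass accumulates at a single place beside mother; half
of the dwell bouts include a climb onto the lap (contact). Excursions
are correlated walks (von Mises heading wobble, κ = 8; log-normal step
jitter) to targets sampled at 230 ± 50 cm from mother (minimum 160 cm,
comfortably beyond the largest scanned ring), routed via a fanned-out
waypoint so successive excursions take different corridors, with
optional log-normal lingering at the far point. Mean dwell duration is
derived from the programmed excursion rate (default 0.4/min ≈ 12
excursions per 30-minute session).

**NTD archetype** (default 20 min): a brief opening dwell on the
mother's lap, immediate departure, then long log-normal lingering bouts
(mean 240 s) at 1–2 fixed away places ≥ 220 cm from mother; each away
bout ends with probability 0.5 in a shallow approach to 48 cm from the
mother's centre — close enough to register as a visit at the calibrated
ring, far enough never to count as contact — giving ≈ 2 excursions per
session (≈ 0.1/min).

Lingering positions jitter by 2 cm per sample. Ground truth records the
noise-free path, visit/excursion intervals from the bout schedule,
progression labels, and contact episodes computed by the kinematic
contact rule on the noise-free path. The presets are calibration
targets for the archetypal group contrast (TD ≈ 12 excursions/session,
NTD ≈ 2), not claims about any individual.

What the generator does **not** emulate, and hence what passing tests do
not show about real data: biomechanics of crawling, mother movement or
mother-initiated contact, toy and furniture interactions, heavy-tailed
speed profiles, drifting tracking bias (only i.i.d. noise), or the
within-group heterogeneity of real cohorts — the synthetic archetypes
are stereotyped, so synthetic group contrasts are sharper than the real
ones (the default cohort separates completely on *all* seven endpoints,
which real data does not). Room coverage of the synthetic sessions
(median ≈ 0.025 TD / 0.010 NTD) is somewhat below values typical of real
crawling sessions, since the generator's paths are more economical than
real exploration.

## Numerical choices and degenerate inputs

Strict inequalities at both ring thresholds (equality keeps state);
peak-place ties broken by (value, then y, then x); radius-scan run ties
toward the smaller radius; empty or all-zero dwell maps yield an empty
peak list; zero pooled variance raises rather than returning an infinite
effect size; p-values outside (0, 1] are rejected before adjustment.
Seeds: every stochastic component takes a `numpy` `Generator` or an
integer seed; cohort session seeds are spawned from the cohort seed, so
a cohort is reproducible from one integer.

## Problem sizes in the validation suite

The test suite and the acceptance script validate on synthetic data at
the following scales, chosen to give stable Monte-Carlo estimates:
oracle equivalence on 1,000 random series; parameter recovery over
30–100 cohorts (360–1,200 sessions); home-base localization and
rate-separation structure over 50–100 TD sessions / cohort draws; null
calibration of both exact tests over 200–500 cohort draws with identical
presets for both pseudo-groups (binomial sampling slack is accounted for
when comparing rejection rates to the nominal level).
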