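"""Seeded synthetic sessions with the structure the analysis assumes.

Two behavioral archetypes are emulated, matching the qualitative
contrast between typically developing (TD) and non-typically developing
(NTD) infants exploring a room with a stationary mother at the
periphery:

* **TD** — mother-anchored, excursion-partitioned exploration: the
  session alternates between dwell bouts beside (or on) the mother and
  round-trip excursions into the room, each an outbound correlated walk
  to a sampled target, optional lingering at the far point, and a
  return.  Some dwell bouts are contact bouts (clearance near zero —
  climbing on mother).
* **NTD** — origin-free exploration: after briefly starting on the
  mother's lap the infant departs, lingers for long stretches at one or
  two away places, and only occasionally performs a shallow approach
  toward the mother without touching her.

Sessions are emitted at 2 Hz (dt = 0.5 s) in a 365 x 545 cm room with
isotropic Gaussian tracking noise, together with a :class:`GroundTruth`
record (true excursion intervals, near-mother fraction, contact bouts,
speed labels) that every pipeline stage can be validated against.  All
randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import RoomGeometry, default_room
from .tracking import Trajectory

NEAR_CM = 100.0


@dataclass(frozen=True)
class ArchetypeParams:
    """Generator parameters for one behavioral archetype.

    Defaults for the two archetypes are provided by :func:`td_params`
    and :func:`ntd_params`; they are calibration targets emulating the
    observed group contrasts (TD roughly 12 excursions in a 30-min
    session, i.e. ~0.4/min; NTD ~2 per session), not claims about any
    individual infant.
    """

    archetype: str = "TD"
    session_min: float = 30.0
    dt_s: float = 0.5
    excursion_rate_per_min: float = 0.4
    excursion_extent_mean_cm: float = 230.0
    excursion_extent_sd_cm: float = 50.0
    excursion_extent_min_cm: float = 160.0
    mid_linger_prob: float = 0.6
    mid_linger_mean_s: float = 35.0
    lingering_mean_s: float = 240.0  # NTD away-place lingering
    lingering_cv: float = 0.5
    away_place_count: int = 2
    approach_prob: float = 0.5  # NTD: chance an away bout ends in an approach
    approach_dist_cm: float = 48.0
    contact_prob_on_visit: float = 0.5
    sit_dist_cm: float = 45.0
    contact_dist_cm: float = 12.0
    progression_speed_cm_s: float = 18.0
    lingering_jitter_cm: float = 2.0
    tracking_noise_cm: float = 3.0
    heading_kappa: float = 8.0

    def __post_init__(self) -> None:
        if self.archetype not in ("TD", "NTD"):
            raise ValueError("archetype must be 'TD' or 'NTD'")
        if self.session_min < 20.0:
            raise ValueError("sessions are at least 20 minutes")
        if not 0 <= self.approach_prob <= 1 or not 0 <= self.contact_prob_on_visit <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        for name in ("dt_s", "excursion_rate_per_min", "progression_speed_cm_s",
                     "lingering_mean_s", "mid_linger_mean_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def td_params(**overrides) -> ArchetypeParams:
    """Default TD preset (~0.4 excursions/min over a 30-min session)."""
    return replace(ArchetypeParams(archetype="TD"), **overrides)


def ntd_params(**overrides) -> ArchetypeParams:
    """Default NTD preset (~2 excursions over a 20-min session)."""
    return replace(
        ArchetypeParams(
            archetype="NTD",
            session_min=20.0,
            excursion_rate_per_min=0.1,
            progression_speed_cm_s=15.0,
        ),
        **overrides,
    )


@dataclass
class GroundTruth:
    """Generator bookkeeping consistent with the emitted trajectory."""

    dt_s: float
    x_clean: np.ndarray
    y_clean: np.ndarray
    visit_spans: list[tuple[int, int]]
    excursion_intervals: list[tuple[int, int]]
    contact_spans: list[tuple[int, int]]
    progression_mask: np.ndarray
    bouts: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def n_excursions(self) -> int:
        return len(self.excursion_intervals)

    @property
    def duration_min(self) -> float:
        return len(self.x_clean) * self.dt_s / 60.0

    @property
    def excursion_rate_per_min(self) -> float:
        return self.n_excursions / self.duration_min

    def near_fraction(self, mother_center: tuple[float, float],
                      near_cm: float = NEAR_CM) -> float:
        d = np.hypot(self.x_clean - mother_center[0],
                     self.y_clean - mother_center[1])
        return float((d < near_cm).mean())

    @property
    def n_contacts(self) -> int:
        return len(self.contact_spans)

    @property
    def contact_time_s(self) -> float:
        return sum(e - s + 1 for s, e in self.contact_spans) * self.dt_s


# ---------------------------------------------------------------------------
# movement primitives
# ---------------------------------------------------------------------------

def _clip_to_room(pts: np.ndarray, room: RoomGeometry, margin: float = 2.0) -> np.ndarray:
    pts[:, 0] = np.clip(pts[:, 0], margin, room.width - margin)
    pts[:, 1] = np.clip(pts[:, 1], margin, room.length - margin)
    return pts


def _walk(rng: np.random.Generator, start: np.ndarray, target: np.ndarray,
          speed: float, dt: float, kappa: float, room: RoomGeometry) -> np.ndarray:
    """Correlated walk from start to target: heading aimed at the target
    with von-Mises wobble, per-step speed jittered log-normally.  Returns
    the emitted positions (excluding the start, ending within one step of
    the target)."""
    pos = np.asarray(start, dtype=float).copy()
    step_mean = speed * dt
    out = []
    max_steps = int(4 * np.linalg.norm(target - pos) / step_mean) + 20
    for _ in range(max_steps):
        delta = target - pos
        dist = np.linalg.norm(delta)
        if dist <= step_mean:
            break
        heading = np.arctan2(delta[1], delta[0]) + rng.vonmises(0.0, kappa)
        step = step_mean * rng.lognormal(0.0, 0.2)
        step = min(step, dist)
        pos = pos + step * np.array([np.cos(heading), np.sin(heading)])
        pos = _clip_to_room(pos[None, :], room)[0]
        out.append(pos.copy())
    return np.array(out).reshape(-1, 2)


def _linger(rng: np.random.Generator, anchor: np.ndarray, n: int,
            jitter: float, room: RoomGeometry) -> np.ndarray:
    pts = anchor[None, :] + rng.normal(0.0, jitter, size=(n, 2))
    return _clip_to_room(pts, room)


def _lognormal_duration(rng: np.random.Generator, mean: float, cv: float) -> float:
    sigma2 = np.log(1.0 + cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def _room_direction(rng: np.random.Generator, min_y_component: float = 0.2) -> np.ndarray:
    """A unit direction pointing into the room from the mother's wall."""
    while True:
        theta = rng.uniform(0.0, np.pi)
        d = np.array([np.cos(theta), np.sin(theta)])
        if d[1] >= min_y_component:
            return d


def _sample_target(rng: np.random.Generator, mother: np.ndarray,
                   params: ArchetypeParams, room: RoomGeometry,
                   margin: float = 15.0) -> np.ndarray:
    for _ in range(200):
        direction = _room_direction(rng)
        extent = rng.normal(params.excursion_extent_mean_cm,
                            params.excursion_extent_sd_cm)
        extent = max(extent, params.excursion_extent_min_cm)
        target = mother + extent * direction
        if (margin <= target[0] <= room.width - margin
                and margin <= target[1] <= room.length - margin):
            return target
    raise ValueError("excursion parameters place targets outside the room")


def _walk_via(rng: np.random.Generator, start: np.ndarray, target: np.ndarray,
              params: ArchetypeParams, room: RoomGeometry) -> np.ndarray:
    """Excursion leg routed via a lateral waypoint so successive
    excursions take different corridors rather than a single beaten
    path."""
    delta = target - start
    dist = np.linalg.norm(delta)
    if dist < 120.0:
        return _walk(rng, start, target, params.progression_speed_cm_s,
                     params.dt_s, params.heading_kappa, room)
    # depart on a fanned-out bearing before turning toward the target
    phi = rng.uniform(-1.35, 1.35)
    rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
    waypoint = start + rng.uniform(0.35, 0.55) * (rot @ delta)
    waypoint = _clip_to_room(waypoint[None, :], room, margin=15.0)[0]
    leg1 = _walk(rng, start, waypoint, params.progression_speed_cm_s,
                 params.dt_s, params.heading_kappa, room)
    mid_pos = leg1[-1] if len(leg1) else start
    leg2 = _walk(rng, mid_pos, target, params.progression_speed_cm_s,
                 params.dt_s, params.heading_kappa, room)
    return np.concatenate([leg1, leg2], axis=0) if len(leg1) or len(leg2) else leg1


# ---------------------------------------------------------------------------
# session assembly
# ---------------------------------------------------------------------------

class _SessionBuilder:
    def __init__(self, dt: float, n_total: int):
        self.dt = dt
        self.n_total = n_total
        self.chunks: list[np.ndarray] = []
        self.bouts: list[tuple[str, int, int]] = []
        self.n = 0

    @property
    def full(self) -> bool:
        return self.n >= self.n_total

    def add(self, kind: str, pts: np.ndarray) -> tuple[int, int, bool]:
        """Append a bout, truncating at the session end.

        Returns (start, end_inclusive, fully_emitted)."""
        room_left = self.n_total - self.n
        if len(pts) == 0 or room_left <= 0:
            return self.n, self.n - 1, len(pts) == 0
        emitted = pts[:room_left]
        start = self.n
        self.chunks.append(emitted)
        self.n += len(emitted)
        self.bouts.append((kind, start, self.n - 1))
        return start, self.n - 1, len(emitted) == len(pts)

    def positions(self) -> np.ndarray:
        return np.concatenate(self.chunks, axis=0)


def _dwell_sigma_mean(params: ArchetypeParams) -> float:
    """Mean mother-dwell duration implied by the target excursion rate."""
    travel = 2.0 * params.excursion_extent_mean_cm / params.progression_speed_cm_s * 1.15
    exc_mean = travel + params.mid_linger_prob * params.mid_linger_mean_s
    return max(20.0, 60.0 / params.excursion_rate_per_min - exc_mean)


def simulate_session(params: ArchetypeParams, room: RoomGeometry | None = None,
                     seed: int | np.random.Generator = 0,
                     session_id: str = "") -> tuple[Trajectory, GroundTruth]:
    """Generate one synthetic session and its ground truth.

    Fully reproducible from ``seed``.  The returned trajectory carries
    the tracking noise; the ground truth keeps the noise-free path.
    """
    room = room if room is not None else default_room()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mother = np.asarray(room.mother.center, dtype=float)
    dt = params.dt_s
    n_total = int(round(params.session_min * 60.0 / dt))
    b = _SessionBuilder(dt, n_total)

    visit_spans: list[tuple[int, int]] = []
    contact_spans: list[tuple[int, int]] = []
    excursion_done: list[tuple[int, int, bool]] = []  # start, end, next-visit-started
    progression_chunks: list[tuple[int, int]] = []

    if params.archetype == "TD":
        _simulate_td(rng, params, room, mother, b, visit_spans, contact_spans,
                     excursion_done, progression_chunks)
    else:
        _simulate_ntd(rng, params, room, mother, b, visit_spans, contact_spans,
                      excursion_done, progression_chunks)

    clean = b.positions()
    n = len(clean)
    t = dt * np.arange(n)
    # true contact episodes: the kinematic contact rule (hysteresis on
    # mother clearance) applied to the noise-free path, so shallow
    # grazes during transit count in the truth exactly as the pipeline
    # counts them on the tracked path
    from .proximity import CONTACT_CM, CONTACT_RING_RATIO
    from .visits import DistanceSeries, RingParams, detect_visits
    d_clean = np.hypot(clean[:, 0] - mother[0], clean[:, 1] - mother[1])
    contact_spans = [
        (v.start_index, v.end_index)
        for v in detect_visits(DistanceSeries(t, d_clean),
                               RingParams(CONTACT_CM, CONTACT_RING_RATIO * CONTACT_CM))
    ]
    noisy = clean + rng.normal(0.0, params.tracking_noise_cm, size=clean.shape)
    noisy = _clip_to_room(noisy, room, margin=0.0)
    progression = np.zeros(n, dtype=bool)
    for s, e in progression_chunks:
        progression[s:min(e + 1, n)] = True

    truth = GroundTruth(
        dt_s=dt,
        x_clean=clean[:, 0], y_clean=clean[:, 1],
        visit_spans=visit_spans,
        excursion_intervals=[(s, e) for s, e, ok in excursion_done if ok],
        contact_spans=contact_spans,
        progression_mask=progression,
        bouts=b.bouts,
    )
    traj = Trajectory(t, noisy[:, 0], noisy[:, 1], session_id=session_id,
                      meta={"archetype": params.archetype})
    return traj, truth


def _simulate_td(rng, params, room, mother, b, visit_spans, contact_spans,
                 excursion_done, progression_chunks) -> None:
    dwell_mean = _dwell_sigma_mean(params)
    # the infant keeps a habitual sitting spot beside mother and a lap
    # spot on her, fixed for the session and in the same direction, so
    # dwell mass accumulates at a single place near mother
    sit_dir = _room_direction(rng, min_y_component=0.4)
    sit_spot = mother + params.sit_dist_cm * sit_dir
    lap_spot = mother + params.contact_dist_cm * sit_dir
    pos = None
    pending_excursion_start = None
    while not b.full:
        # --- mother dwell bout: sit beside mother; in contact bouts the
        # infant then climbs onto her lap for the rest of the dwell ---
        contact = rng.uniform() < params.contact_prob_on_visit
        tangent = np.array([-sit_dir[1], sit_dir[0]])
        offset = rng.normal(0.0, 4.0) * tangent + rng.normal(0.0, 1.5) * sit_dir
        anchor = sit_spot + offset
        if pos is not None:
            pts = _walk_via(rng, pos, anchor, params, room)
            s, e, ok = b.add("return", pts)
            progression_chunks.append((s, e))
            if b.n:
                pos = b.positions()[-1]
            if b.full:
                break
        n_dwell = max(4, int(round(_lognormal_duration(rng, dwell_mean, 0.35) / params.dt_s)))
        n_sit = n_dwell - n_dwell // 2 if contact else n_dwell
        pts = _linger(rng, anchor, n_sit, params.lingering_jitter_cm, room)
        s, e, _ = b.add("dwell", pts)
        if pending_excursion_start is not None:
            excursion_done.append((pending_excursion_start, s - 1, True))
            pending_excursion_start = None
        visit_start = s
        pos = b.positions()[-1]
        if contact and not b.full:
            pts = _walk(rng, pos, lap_spot, params.progression_speed_cm_s,
                        params.dt_s, params.heading_kappa, room)
            b.add("climb", pts)
            pos = b.positions()[-1] if b.n else pos
            if not b.full:
                pts = _linger(rng, lap_spot, n_dwell // 2,
                              params.lingering_jitter_cm, room)
                cs, ce, _ = b.add("contact_dwell", pts)
                contact_spans.append((cs, ce))
                pos = b.positions()[-1]
        visit_spans.append((visit_start, b.n - 1))
        if b.full:
            break
        # --- excursion bout: outbound, optional far-point linger, inbound ---
        target = _sample_target(rng, mother, params, room)
        exc_start = b.n
        pts = _walk_via(rng, pos, target, params, room)
        s, e, _ = b.add("outbound", pts)
        progression_chunks.append((s, e))
        if b.n:
            pos = b.positions()[-1]
        if rng.uniform() < params.mid_linger_prob and not b.full:
            n_ml = max(2, int(round(_lognormal_duration(
                rng, params.mid_linger_mean_s, 0.6) / params.dt_s)))
            pts = _linger(rng, pos, n_ml, params.lingering_jitter_cm, room)
            b.add("far_linger", pts)
            pos = b.positions()[-1]
        pending_excursion_start = exc_start
        # the inbound leg and next dwell are emitted at the top of the loop


def _simulate_ntd(rng, params, room, mother, b, visit_spans, contact_spans,
                  excursion_done, progression_chunks) -> None:
    # away places fixed for the session
    places = []
    for _ in range(max(1, params.away_place_count)):
        for _ in range(500):
            cand = np.array([rng.uniform(25, room.width - 25),
                             rng.uniform(25, room.length - 25)])
            if 220.0 <= np.linalg.norm(cand - mother) <= 400.0:
                places.append(cand)
                break
        else:
            raise ValueError("could not place NTD away place inside the room")

    # opening: a few seconds on mother's lap, then departure
    lap = mother + 20.0 * _room_direction(rng)
    n_open = max(2, int(round(rng.uniform(10.0, 25.0) / params.dt_s)))
    pts = _linger(rng, lap, n_open, params.lingering_jitter_cm, room)
    s, e, _ = b.add("opening", pts)
    visit_spans.append((s, e))
    contact_spans.append((s, e))
    pos = b.positions()[-1]

    pending_excursion_start = b.n
    while not b.full:
        place = places[rng.integers(len(places))] + rng.normal(0.0, 30.0, 2)
        place = _clip_to_room(place[None, :], room, margin=20.0)[0]
        pts = _walk(rng, pos, place, params.progression_speed_cm_s,
                    params.dt_s, params.heading_kappa, room)
        s, e, _ = b.add("travel", pts)
        progression_chunks.append((s, e))
        if b.full:
            break
        pos = b.positions()[-1]
        n_lg = max(2, int(round(_lognormal_duration(
            rng, params.lingering_mean_s, params.lingering_cv) / params.dt_s)))
        pts = _linger(rng, place, n_lg, params.lingering_jitter_cm, room)
        b.add("away_linger", pts)
        pos = b.positions()[-1]
        if b.full:
            break
        if rng.uniform() < params.approach_prob:
            # shallow approach: toward mother but stopping well short of touch
            stop = mother + params.approach_dist_cm * _room_direction(rng)
            pts = _walk(rng, pos, stop, params.progression_speed_cm_s,
                        params.dt_s, params.heading_kappa, room)
            s, e, _ = b.add("approach_in", pts)
            progression_chunks.append((s, e))
            if b.full:
                break
            pos = b.positions()[-1]
            n_pause = max(2, int(round(rng.uniform(5.0, 12.0) / params.dt_s)))
            pts = _linger(rng, stop, n_pause, params.lingering_jitter_cm, room)
            s, e, _ = b.add("approach_pause", pts)
            excursion_done.append((pending_excursion_start, s - 1, True))
            visit_spans.append((s, e))
            pos = b.positions()[-1]
            pending_excursion_start = b.n


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSession:
    session_id: str
    group: str
    trajectory: Trajectory
    truth: GroundTruth


@dataclass
class Cohort:
    room: RoomGeometry
    sessions: list[CohortSession]

    def truth_endpoints(self) -> pd.DataFrame:
        """Ground-truth endpoint table (one row per session)."""
        rows = []
        for s in self.sessions:
            tr = s.truth
            rows.append({
                "session_id": s.session_id,
                "group": s.group,
                "duration_min": tr.duration_min,
                "excursions_per_min": tr.excursion_rate_per_min,
                "prop_time_near_mother": tr.near_fraction(self.room.mother.center),
                "contact_episodes_per_min": tr.n_contacts / tr.duration_min,
                "prop_contact_time": tr.contact_time_s / (len(tr.x_clean) * tr.dt_s),
            })
        return pd.DataFrame(rows)


def simulate_cohort(n_td: int = 5, n_ntd: int = 7,
                    td: ArchetypeParams | None = None,
                    ntd: ArchetypeParams | None = None,
                    room: RoomGeometry | None = None,
                    seed: int = 0) -> Cohort:
    """Simulate an independent seeded cohort of TD and NTD sessions."""
    if n_td < 2 or n_ntd < 2:
        raise ValueError("need at least 2 sessions per group")
    td = td if td is not None else td_params()
    ntd = ntd if ntd is not None else ntd_params()
    room = room if room is not None else default_room()
    rng = np.random.default_rng(seed)
    sessions = []
    for i in range(n_td):
        sid = f"td{i + 1:02d}"
        traj, truth = simulate_session(td, room, seed=rng.spawn(1)[0], session_id=sid)
        sessions.append(CohortSession(sid, "TD", traj, truth))
    for i in range(n_ntd):
        sid = f"ntd{i + 1:02d}"
        traj, truth = simulate_session(ntd, room, seed=rng.spawn(1)[0], session_id=sid)
        sessions.append(CohortSession(sid, "NTD", traj, truth))
    return Cohort(room=room, sessions=sessions)
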