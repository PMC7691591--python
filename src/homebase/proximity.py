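"""Proximity and contact episodes between the infant and room objects.

Proximity to an object is measured as clearance: the distance between
the infant's centre of mass and the object's centre, minus the object's
radius.  Negative clearance means the infant penetrated the object's
disc (for the mother: climbing on her).  Proximity episodes are maximal
runs below a radius ``R``; contact episodes use a tighter threshold with
hysteresis, since centre-of-mass tracks cannot observe touch directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Disc
from .tracking import Trajectory
from .visits import DistanceSeries, RingParams, detect_visits

#: default kinematic contact threshold: roughly the sum of infant and
#: mother trunk radii (cm)
CONTACT_CM = 35.0
CONTACT_RING_RATIO = 1.2
#: Fig-4 style proximity circle radius
PROXIMITY_R = 120.0


@dataclass(frozen=True)
class ProximityEpisode:
    """A maximal run of closeness to one object."""

    label: str
    start_index: int
    end_index: int
    start_t: float
    end_t: float
    min_clearance: float
    complete: bool = True

    @property
    def duration_s(self) -> float:
        return self.end_t - self.start_t


def object_clearance_series(traj: Trajectory, obj: Disc) -> DistanceSeries:
    """Clearance d(t) = ||p(t) - center|| - radius (negative inside disc).

    For the mother the configured radius is typically 0, which reduces
    clearance to the raw centres-of-mass distance.
    """
    d = np.hypot(traj.x - obj.center[0], traj.y - obj.center[1]) - obj.radius
    return DistanceSeries(traj.t, d, label=obj.label)


def proximity_episodes(d: DistanceSeries, R: float = PROXIMITY_R) -> list[ProximityEpisode]:
    """Maximal runs with d < R (no hysteresis), with per-run minimum clearance.

    The sum of episode durations (counting each sample as ``dt``)
    equals ``dt`` times the number of samples below ``R``.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    below = d.d < R
    edges = np.diff(np.concatenate([[0], below.astype(np.int8), [0]]))
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0]  # exclusive
    out = []
    for s, e in zip(starts, ends):
        out.append(ProximityEpisode(
            label=d.label,
            start_index=int(s), end_index=int(e - 1),
            start_t=float(d.t[s]), end_t=float(d.t[e - 1]),
            min_clearance=float(d.d[s:e].min()),
            complete=e < len(d) or not below[-1],
        ))
    return out


def contact_episodes(d_mother: DistanceSeries, contact_cm: float = CONTACT_CM,
                     ring_ratio: float = CONTACT_RING_RATIO) -> list[ProximityEpisode]:
    """Hysteresis contact episodes from the mother clearance series.

    Contact is operationalized kinematically: an episode starts when
    clearance drops below ``contact_cm`` and ends when it rises above
    ``ring_ratio * contact_cm``, so tracking jitter does not split one
    touch into many.  A session ending in contact yields a final episode
    flagged incomplete that still counts toward contact time.
    """
    if contact_cm <= 0:
        raise ValueError("contact threshold must be positive")
    visits = detect_visits(d_mother, RingParams(contact_cm, ring_ratio * contact_cm))
    out = []
    for v in visits:
        seg = d_mother.d[v.start_index:v.end_index + 1]
        out.append(ProximityEpisode(
            label=d_mother.label or "mother",
            start_index=v.start_index, end_index=v.end_index,
            start_t=v.start_t, end_t=v.end_t,
            min_clearance=float(seg.min()),
            complete=v.complete,
        ))
    return out


def total_episode_time(episodes: list[ProximityEpisode], dt: float) -> float:
    """Total seconds spent in episodes (inclusive sample counting)."""
    return sum((e.end_index - e.start_index + 1) * dt for e in episodes)
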