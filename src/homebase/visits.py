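"""The ring (two-threshold hysteresis) definition of a visit to a place.

A ring is centred on a place, with an inner circle of radius ``r_in``
and an outer circle of radius ``r_out > r_in``.  A visit starts when the
subject enters the inner circle and ends when it leaves the outer
circle; wandering within the annulus neither starts nor ends a visit,
which screens spurious re-entrances caused by tracking noise and
lingering jitter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tracking import Trajectory


@dataclass(frozen=True)
class RingParams:
    """Hysteresis radii in cm; entry at d < r_in, exit at d > r_out."""

    r_in: float
    r_out: float

    def __post_init__(self) -> None:
        if not 0 < self.r_in < self.r_out:
            raise ValueError(f"need 0 < r_in < r_out, got ({self.r_in}, {self.r_out})")


@dataclass(frozen=True)
class Visit:
    """One IN episode of the ring state machine, as sample indices/times."""

    start_index: int
    end_index: int
    start_t: float
    end_t: float
    complete: bool = True

    @property
    def duration_s(self) -> float:
        return self.end_t - self.start_t


@dataclass(frozen=True)
class DistanceSeries:
    """Distance (cm) of the subject from a reference point over time.

    When an object radius is subtracted (clearance) values may be
    negative, indicating penetration of the object's disc.
    """

    t: np.ndarray
    d: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        d = np.asarray(self.d, dtype=float)
        if len(t) != len(d) or len(t) == 0:
            raise ValueError("t and d must have equal nonzero length")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "d", d)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else 0.0


def distance_to_point(traj: Trajectory, center: tuple[float, float],
                      radius: float = 0.0, label: str = "") -> DistanceSeries:
    """Distance series from a trajectory to a fixed point, minus ``radius``."""
    d = np.hypot(traj.x - center[0], traj.y - center[1]) - radius
    return DistanceSeries(traj.t, d, label=label)


def detect_visits(d: DistanceSeries, ring: RingParams) -> list[Visit]:
    """Run the two-state (OUT/IN) machine over a distance series.

    Transitions use strict inequalities — OUT->IN on ``d < r_in``,
    IN->OUT on ``d > r_out`` — so samples exactly on a threshold keep
    the current state.  A series that starts below ``r_in`` opens a
    visit at index 0; an IN state at the end of the series yields a
    final visit flagged ``complete=False``.
    """
    dist = d.d
    # +1 where the sample forces IN, -1 where it forces OUT, 0 where the
    # state persists; forward-filling the last nonzero event reproduces
    # the sequential state machine.
    event = np.zeros(len(dist), dtype=np.int8)
    event[dist < ring.r_in] = 1
    event[dist > ring.r_out] = -1
    nz = np.nonzero(event)[0]
    state = np.zeros(len(dist), dtype=np.int8)  # 1 = IN, 0/-1 = OUT
    if len(nz):
        idx = np.zeros(len(dist), dtype=np.int64)
        idx[nz] = nz
        idx = np.maximum.accumulate(idx)
        filled = event[idx]
        filled[: nz[0]] = 0  # initial state is OUT until the first event
        state = (filled == 1).astype(np.int8)

    edges = np.diff(np.concatenate([[0], state, [0]]))
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0]  # exclusive: index of first OUT sample
    visits = []
    for s, e in zip(starts, ends):
        complete = e < len(dist)
        last = e - 1 if complete else len(dist) - 1
        # a complete visit ends at the first sample beyond r_out
        end_idx = e if complete else last
        visits.append(
            Visit(
                start_index=int(s),
                end_index=int(end_idx),
                start_t=float(d.t[s]),
                end_t=float(d.t[min(end_idx, len(dist) - 1)]),
                complete=complete,
            )
        )
    return visits


def count_visits(d: DistanceSeries, ring: RingParams,
                 include_incomplete: bool = False) -> int:
    """Number of visits in a series.

    By default an IN state persisting to the end of the session (an
    incomplete terminal visit) is excluded — the count is then stable
    under truncation of the final samples, which matters for the radius
    calibration scan — while an opening visit (series starting inside
    the ring) is always included.
    """
    visits = detect_visits(d, ring)
    if include_incomplete:
        return len(visits)
    return sum(1 for v in visits if v.complete)
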