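"""Customized mother radius and segmentation of the path into excursions.

The radius tracing the boundary of the mother's place is calibrated per
infant: the ring algorithm is run with ``r_in`` varying from 30 to
120 cm (keeping ``r_out = 1.1 r_in``) and the visit count recorded for
each radius.  The longest radii interval over which the count does not
change indicates a region of stability; its smallest radius becomes the
customized ``r_in``.  Visits to mother at that ring partition the
session: each path segment between the end of one visit and the start
of the next is an excursion (a round trip away from mother and back).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .visits import DistanceSeries, RingParams, Visit, count_visits, detect_visits

R_SCAN_MIN = 30.0
R_SCAN_MAX = 120.0
RING_RATIO = 1.1


@dataclass(frozen=True)
class RadiusScan:
    """Visit counts over the candidate-radius grid and the chosen radius."""

    radii: np.ndarray
    visit_counts: np.ndarray
    chosen_r_in: float

    @property
    def chosen_count(self) -> int:
        return int(self.visit_counts[np.searchsorted(self.radii, self.chosen_r_in)])


@dataclass(frozen=True)
class Excursion:
    """An away-and-back path module bounded by two consecutive mother visits."""

    start_index: int
    end_index: int
    start_t: float
    end_t: float
    max_distance: float
    complete: bool = True

    @property
    def duration_s(self) -> float:
        return self.end_t - self.start_t


def scan_mother_radius(d: DistanceSeries, r_min: float = R_SCAN_MIN,
                       r_max: float = R_SCAN_MAX, step: float = 1.0,
                       ratio: float = RING_RATIO) -> RadiusScan:
    """Choose the customized mother radius from the visit-count scan.

    ``chosen_r_in`` is the left endpoint of the longest maximal run of
    constant visit counts; when two runs tie in length the one at the
    smaller radius wins.  Counts exclude an incomplete terminal visit so
    they are comparable across radii.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if len(d) == 0:
        raise ValueError("empty distance series")
    radii = np.arange(r_min, r_max + step / 2, step)
    counts = np.array([
        count_visits(d, RingParams(r, ratio * r)) for r in radii
    ])
    # maximal runs of constant count
    change = np.nonzero(np.diff(counts))[0]
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change, [len(counts) - 1]])
    lengths = radii[ends] - radii[starts]
    best = int(np.argmax(lengths))  # argmax takes the first (smaller radius) tie
    return RadiusScan(radii=radii, visit_counts=counts,
                      chosen_r_in=float(radii[starts[best]]))


def segment_excursions(d: DistanceSeries, r_in: float,
                       ratio: float = RING_RATIO,
                       room_diagonal: float | None = None
                       ) -> tuple[list[Visit], list[Excursion]]:
    """Partition a mother-distance series into visits and excursions.

    Mother visits come from the ring state machine at
    ``(r_in, ratio * r_in)``.  An excursion spans from each visit's end
    to the next visit's start.  A terminal away segment with no return
    (e.g. a session ending with the infant retrieved by the mother) is
    reported with ``complete=False`` and excluded from rate counts by
    default.
    """
    if r_in <= 0 or (room_diagonal is not None and r_in >= room_diagonal):
        raise ValueError(f"r_in = {r_in} outside (0, room diagonal)")
    visits = detect_visits(d, RingParams(r_in, ratio * r_in))
    excursions: list[Excursion] = []
    for prev, nxt in zip(visits[:-1], visits[1:]):
        s, e = prev.end_index, nxt.start_index
        excursions.append(Excursion(
            start_index=s, end_index=e,
            start_t=float(d.t[s]), end_t=float(d.t[e]),
            max_distance=float(d.d[s:e + 1].max()),
            complete=True,
        ))
    if visits and visits[-1].complete and visits[-1].end_index < len(d) - 1:
        s = visits[-1].end_index
        excursions.append(Excursion(
            start_index=s, end_index=len(d) - 1,
            start_t=float(d.t[s]), end_t=float(d.t[-1]),
            max_distance=float(d.d[s:].max()),
            complete=False,
        ))
    return visits, excursions


def excursion_rate(excursions: list[Excursion], duration_min: float) -> float:
    """Complete excursions per minute of tracked session."""
    if duration_min <= 0:
        raise ValueError("duration must be positive")
    return sum(1 for e in excursions if e.complete) / duration_min
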