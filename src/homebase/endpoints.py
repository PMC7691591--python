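"""The seven per-infant endpoints and their variance-stabilizing transforms.

Each session is summarized by seven scalars entering the group
comparison: excursions to mother per minute (sqrt), proportion of time
near mother, i.e. closer than 100 cm (logit), average progression speed,
proportion of room covered (logit), average speed outside the mother's
vicinity, i.e. farther than 100 cm, contact episodes per minute (sqrt)
and proportion of contact time (logit).  Monotone transforms do not
affect rank-based tests; they symmetrize the distributions for
visualization and effect sizes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from skimage.draw import line as _raster_line

from .excursions import Excursion, excursion_rate
from .geometry import RoomGeometry
from .proximity import ProximityEpisode
from .tracking import Trajectory
from .visits import DistanceSeries

NEAR_MOTHER_CM = 100.0

#: endpoint label -> transform name, in Table order
ENDPOINT_TRANSFORMS = {
    "excursions_per_min": "sqrt",
    "prop_time_near_mother": "logit",
    "avg_progression_speed": "identity",
    "prop_room_covered": "logit",
    "avg_speed_outside_mother": "identity",
    "contact_episodes_per_min": "sqrt",
    "prop_contact_time": "logit",
}

ENDPOINT_LABELS = list(ENDPOINT_TRANSFORMS)


class AutoThresholdWarning(UserWarning):
    """Raised when the log-speed histogram is unimodal and the fallback is used."""


@dataclass
class EndpointRecord:
    """Raw and transformed endpoint values for one session."""

    session_id: str
    group: str
    duration_min: float
    excursions_per_min: float
    prop_time_near_mother: float
    avg_progression_speed: float
    prop_room_covered: float
    avg_speed_outside_mother: float
    contact_episodes_per_min: float
    prop_contact_time: float

    def raw(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in ENDPOINT_LABELS}

    def transformed(self, n_samples: int | None = None) -> dict[str, float]:
        out = {}
        for k, tf in ENDPOINT_TRANSFORMS.items():
            v = getattr(self, k)
            out[k] = transform_value(v, tf, n_samples)
        return out


def clamp_proportion(p: float, n: int | None) -> float:
    """Continuity correction before the logit: clamp to [1/(2n), 1 - 1/(2n)]."""
    if n is None or n <= 0:
        n = 1_000_000
    lo = 1.0 / (2 * n)
    return min(max(p, lo), 1.0 - lo)


def transform_value(v: float, tf: str, n_samples: int | None = None) -> float:
    if math.isnan(v):
        return math.nan
    if tf == "sqrt":
        return math.sqrt(v)
    if tf == "logit":
        p = clamp_proportion(v, n_samples)
        return math.log(p / (1.0 - p))
    return v


def label_progression(traj: Trajectory,
                      speed_threshold: float | str = "auto"
                      ) -> tuple[np.ndarray, float]:
    """Label each sample as progression (True) or lingering (False).

    The path of an exploring subject alternates between progression
    segments and staying-in-place (lingering) episodes, which shows up
    as a bimodal log-speed distribution.  With ``speed_threshold="auto"``
    the cutoff is placed at the antimode (the histogram minimum between
    the two dominant modes); if the histogram is unimodal a 5 cm/s
    fallback is used with a warning.  Returns (labels, threshold_used).
    """
    speeds = traj.speeds()
    if isinstance(speed_threshold, str):
        if speed_threshold != "auto":
            raise ValueError(f"unknown threshold {speed_threshold!r}")
        thr = _antimode_threshold(speeds)
    else:
        thr = float(speed_threshold)
    return speeds > thr, thr


def _antimode_threshold(speeds: np.ndarray, fallback: float = 5.0) -> float:
    pos = speeds[speeds > 1e-6]
    if pos.size < 10:
        warnings.warn("too few moving samples; using fallback threshold",
                      AutoThresholdWarning, stacklevel=3)
        return fallback
    logs = np.log10(pos)
    hist, edges = np.histogram(logs, bins=40)
    # light smoothing so single-bin dips do not masquerade as antimodes
    kern = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
    smooth = np.convolve(hist, kern / kern.sum(), mode="same")
    peaks = [i for i in range(1, len(smooth) - 1)
             if smooth[i] >= smooth[i - 1] and smooth[i] >= smooth[i + 1]
             and smooth[i] > 0]
    if len(peaks) < 2:
        warnings.warn("log-speed histogram unimodal; using fallback threshold",
                      AutoThresholdWarning, stacklevel=3)
        return fallback
    peaks.sort(key=lambda i: -smooth[i])
    lo, hi = sorted(peaks[:2])
    valley = lo + int(np.argmin(smooth[lo:hi + 1]))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return float(10 ** centers[valley])


def room_coverage(traj: Trajectory, room: RoomGeometry,
                  cell_cm: float = 1.0) -> float:
    """Fraction of room grid cells the path passes through.

    The piecewise-linear path between consecutive samples is rasterized
    onto the cell grid (Bresenham lines), so a moving subject covers
    every cell its path crosses, not only the cells containing samples.
    At 1-cm cells a 20-30 min crawling session covers a few per cent of
    a 365 x 545 room.
    """
    nx = int(math.ceil(room.width / cell_cm))
    ny = int(math.ceil(room.length / cell_cm))
    ix = np.clip((traj.x / cell_cm).astype(np.int64), 0, nx - 1)
    iy = np.clip((traj.y / cell_cm).astype(np.int64), 0, ny - 1)
    visited = np.zeros((nx, ny), dtype=bool)
    visited[ix, iy] = True
    moved = (np.diff(ix) != 0) | (np.diff(iy) != 0)
    for i in np.nonzero(moved)[0]:
        rr, cc = _raster_line(ix[i], iy[i], ix[i + 1], iy[i + 1])
        visited[rr, cc] = True
    return float(visited.sum()) / (nx * ny)


def compute_endpoints(traj: Trajectory, room: RoomGeometry,
                      d_mother: DistanceSeries,
                      excursions: list[Excursion],
                      contacts: list[ProximityEpisode],
                      group: str = "",
                      near_cm: float = NEAR_MOTHER_CM,
                      speed_threshold: float | str = "auto") -> EndpointRecord:
    """Assemble the seven endpoints for one session.

    Rates are normalized by the tracked duration in minutes.  The
    average speed outside the mother's vicinity is taken over samples
    with mother distance > ``near_cm``; if no sample qualifies the
    endpoint is undefined and reported as NaN.
    """
    duration_min = traj.duration_min
    speeds = traj.speeds()
    progressing, _thr = label_progression(traj, speed_threshold)

    near = d_mother.d < near_cm
    outside = d_mother.d > near_cm
    if progressing.any():
        avg_prog = float(speeds[progressing].mean())
    else:
        avg_prog = 0.0
    if outside.any():
        avg_out = float(speeds[outside].mean())
    else:
        warnings.warn(f"session {traj.session_id}: never outside mother vicinity; "
                      "avg_speed_outside_mother undefined", UserWarning, stacklevel=2)
        avg_out = math.nan

    contact_samples = sum(e.end_index - e.start_index + 1 for e in contacts)
    return EndpointRecord(
        session_id=traj.session_id,
        group=group,
        duration_min=duration_min,
        excursions_per_min=excursion_rate(excursions, duration_min),
        prop_time_near_mother=float(near.mean()),
        avg_progression_speed=avg_prog,
        prop_room_covered=room_coverage(traj, room),
        avg_speed_outside_mother=avg_out,
        contact_episodes_per_min=len(contacts) / duration_min,
        prop_contact_time=min(contact_samples / len(traj), 1.0),
    )
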