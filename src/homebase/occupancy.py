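"""Cumulative dwell-time maps, Gaussian smoothing, and preferred places.

The room is divided into a grid of 1 cm x 1 cm cells; each trajectory
sample contributes one time step ``dt`` to the cell containing it.  The
raw map is smoothed with a truncated 2-D Gaussian kernel (sigma = 14 cm,
truncated 31 cm away) and the local maxima of the smoothed field are
candidate preferred places; only the top few per cent by smoothed dwell
are retained, and the ring algorithm counts the visits each retained
peak received.  A place marked by both the highest cumulative dwell and
the highest number of visits is the session's origin (home base).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .geometry import RoomGeometry
from .tracking import Trajectory
from .visits import DistanceSeries, RingParams, Visit, detect_visits

#: ring used to count visits at peak dwell places
PEAK_RING = RingParams(30.0, 50.0)


@dataclass
class DwellMap:
    """Grid of dwell seconds; cell (i, j) covers [i, i+1) x [j, j+1) cm.

    ``values`` is indexed ``[ix, iy]`` so the first axis runs along room
    width (x) and the second along room length (y).
    """

    values: np.ndarray
    cell_cm: float = 1.0
    smoothed: bool = False

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        nx, ny = self.values.shape
        cx = (np.arange(nx) + 0.5) * self.cell_cm
        cy = (np.arange(ny) + 0.5) * self.cell_cm
        return cx, cy


@dataclass
class PeakPlace:
    """A retained local maximum of the smoothed dwell field."""

    center: tuple[float, float]
    value: float
    n_visits: int = 0
    visits: list[Visit] = field(default_factory=list)


def compute_dwell_map(traj: Trajectory, room: RoomGeometry,
                      cell_cm: float = 1.0) -> DwellMap:
    """Accumulate time spent in each grid cell.

    Each sample contributes ``dt`` seconds to the cell containing it, so
    the map total equals ``n_samples * dt``.  Samples on the far room
    edge fall into the last cell.
    """
    if cell_cm <= 0:
        raise ValueError("cell size must be positive")
    nx = int(math.ceil(room.width / cell_cm))
    ny = int(math.ceil(room.length / cell_cm))
    ix = np.clip((traj.x / cell_cm).astype(np.int64), 0, nx - 1)
    iy = np.clip((traj.y / cell_cm).astype(np.int64), 0, ny - 1)
    counts = np.zeros((nx, ny))
    np.add.at(counts, (ix, iy), traj.dt)
    return DwellMap(counts, cell_cm=cell_cm)


_W_IN_CACHE: dict = {}


def _truncated_gaussian_kernel(sigma_cm: float, truncate_cm: float,
                               cell_cm: float) -> np.ndarray:
    r = int(round(truncate_cm / cell_cm))
    ax = np.arange(-r, r + 1) * cell_cm
    xx, yy = np.meshgrid(ax, ax, indexing="ij")
    k = np.exp(-(xx**2 + yy**2) / (2.0 * sigma_cm**2))
    k[np.hypot(xx, yy) > truncate_cm] = 0.0
    return k / k.sum()


def smooth_dwell_map(dmap: DwellMap, sigma_cm: float = 14.0,
                     truncate_cm: float = 31.0) -> DwellMap:
    """Smooth the map with a truncated 2-D Gaussian kernel.

    In the interior each cell becomes the kernel-weighted average of its
    (2 * truncate + 1)^2 cm neighbourhood.  Where the window is clipped
    by the room boundary the kernel is renormalized on the source side:
    each cell's dwell is redistributed over the in-room part of its
    window.  This conserves total dwell exactly and avoids artificially
    depressing peripheral dwell — the mother sits at a wall, so boundary
    handling materially affects peak detection there.
    """
    if sigma_cm <= 0 or truncate_cm < sigma_cm:
        raise ValueError("need sigma > 0 and truncate >= sigma")
    k = _truncated_gaussian_kernel(sigma_cm, truncate_cm, dmap.cell_cm)
    # weight actually landing in-room from each source cell (kernel is
    # symmetric, so one convolution with ones serves); cached per room size
    key = (dmap.values.shape, sigma_cm, truncate_cm, dmap.cell_cm)
    w_in = _W_IN_CACHE.get(key)
    if w_in is None:
        w_in = signal.fftconvolve(np.ones_like(dmap.values), k, mode="same")
        _W_IN_CACHE[key] = w_in
    sm = signal.fftconvolve(dmap.values / w_in, k, mode="same")
    sm = np.clip(sm, 0.0, None)
    return DwellMap(sm, cell_cm=dmap.cell_cm, smoothed=True)


def find_peak_places(dmap: DwellMap, keep_fraction: float = 0.04,
                     min_separation_cm: float = 50.0) -> list[PeakPlace]:
    """Local maxima of a smoothed map, keeping the top ``keep_fraction``.

    Maxima are taken over 8-connected neighbourhoods; connected
    equal-valued plateaus collapse to a single peak at their centroid,
    and maxima closer than ``min_separation_cm`` to a higher-valued
    maximum are suppressed — two maxima within the visit-counting ring's
    outer radius describe the same place.  The survivors are sorted by
    value descending (ties broken by y then x) and
    ``ceil(keep_fraction * n)`` are retained (at least one), together
    with any maxima tied in value with the last retained one.
    """
    v = dmap.values
    if not np.any(v > 0):
        return []
    is_max = (ndimage.maximum_filter(v, size=3, mode="constant") == v) & (v > 0)
    labels, n = ndimage.label(is_max, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return []
    index = np.arange(1, n + 1)
    vals = ndimage.maximum(v, labels, index)
    centroids = ndimage.center_of_mass(is_max, labels, index)
    peaks = [
        PeakPlace(center=((cx + 0.5) * dmap.cell_cm, (cy + 0.5) * dmap.cell_cm),
                  value=float(val))
        for (cx, cy), val in zip(centroids, vals)
    ]
    peaks.sort(key=lambda p: (-p.value, p.center[1], p.center[0]))
    if min_separation_cm > 0:
        kept: list[PeakPlace] = []
        for p in peaks:
            if all(np.hypot(p.center[0] - q.center[0], p.center[1] - q.center[1])
                   >= min_separation_cm for q in kept):
                kept.append(p)
        peaks = kept
    n_keep = max(1, math.ceil(keep_fraction * len(peaks)))
    cutoff = peaks[n_keep - 1].value
    return [p for p in peaks if p.value >= cutoff]


def annotate_peak_visits(traj: Trajectory, peaks: list[PeakPlace],
                         ring: RingParams = PEAK_RING) -> list[PeakPlace]:
    """Count visits to each peak with the ring algorithm (r_in=30, r_out=50)."""
    for p in peaks:
        d = np.hypot(traj.x - p.center[0], traj.y - p.center[1])
        visits = detect_visits(DistanceSeries(traj.t, d), ring)
        p.visits = visits
        p.n_visits = len(visits)
    return peaks


def top_place(peaks: list[PeakPlace]) -> PeakPlace | None:
    """The origin candidate: highest smoothed dwell among annotated peaks."""
    return peaks[0] if peaks else None


def dwell_quantile_levels(dmap: DwellMap, step: float = 0.1) -> np.ndarray:
    """Contour levels at the deciles of the positive smoothed dwell."""
    pos = dmap.values[dmap.values > 0]
    if pos.size == 0:
        return np.array([])
    qs = np.arange(step, 1.0, step)
    return np.unique(np.quantile(pos, qs))
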