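"""Trajectory containers, gap filling, smoothing and delimited-text I/O.

Manual tracking samples the infant's position every ~15 video frames;
frames where the infant was occluded are missing and are completed by
linear interpolation.  After rectification and interpolation a session
is held as a :class:`Trajectory`: uniformly sampled ``(t, x, y)`` in
floor centimetres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import RoomGeometry

#: Sessions were meant to be filmed and tracked for at least 20 minutes.
MIN_SESSION_S = 20.0 * 60.0


class ShortSessionWarning(UserWarning):
    """Session shorter than the 20-minute tracking requirement."""


class ClampedPointsWarning(UserWarning):
    """More than 1% of rectified points fell outside the room rectangle."""


@dataclass(frozen=True)
class RawTrack:
    """Image-plane track: (frame_index, u, v) with NaN for missing samples."""

    frames: np.ndarray
    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.int64)
        u = np.asarray(self.u, dtype=float)
        v = np.asarray(self.v, dtype=float)
        if not (len(frames) == len(u) == len(v)):
            raise ValueError("frames, u, v must have equal length")
        if np.any(np.diff(frames) <= 0):
            raise ValueError("frame indices must be strictly increasing")
        if np.count_nonzero(~(np.isnan(u) | np.isnan(v))) < 2:
            raise ValueError("need at least 2 non-missing samples")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "v", v)

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.u) | np.isnan(self.v)


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled floor-plane path: t (s), x (cm), y (cm)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    session_id: str = ""
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if not (len(t) == len(x) == len(y)) or len(t) < 2:
            raise ValueError("t, x, y must have equal length >= 2")
        if np.any(np.isnan(x)) or np.any(np.isnan(y)):
            raise ValueError("trajectory must not contain missing values")
        steps = np.diff(t)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError("t must be uniformly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def duration_s(self) -> float:
        """Tracked duration including the dwell attributed to the last sample."""
        return len(self) * self.dt

    @property
    def duration_min(self) -> float:
        return self.duration_s / 60.0

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def speeds(self) -> np.ndarray:
        """Per-sample speed |dp|/dt (cm/s), central differences in the interior."""
        vx = np.gradient(self.x, self.dt)
        vy = np.gradient(self.y, self.dt)
        return np.hypot(vx, vy)

    def check_duration(self) -> bool:
        """Whether the >= 20 min tracking requirement holds; warns if not."""
        ok = self.duration_s >= MIN_SESSION_S
        if not ok:
            warnings.warn(
                f"session {self.session_id or '<unnamed>'} lasts "
                f"{self.duration_min:.1f} min (< 20 min)",
                ShortSessionWarning,
                stacklevel=2,
            )
        return ok


def interpolate_gaps(track: RawTrack, fps: float = 30.0,
                     step_frames: int = 15) -> Trajectory:
    """Resample a raw track to a uniform grid, filling gaps linearly.

    The output step is ``dt = step_frames / fps`` (0.5 s for every-15th-frame
    tracking at 30 fps).  Leading/trailing missing
    samples are trimmed rather than extrapolated; interior missing
    samples end up on the straight segment between their known
    neighbours.  Known samples whose frames fall on the output grid are
    conserved exactly.
    """
    if fps <= 0 or step_frames <= 0:
        raise ValueError("fps and step_frames must be positive")
    keep = ~track.missing
    frames = track.frames[keep]
    u = track.u[keep]
    v = track.v[keep]
    t_known = frames / fps
    dt = step_frames / fps
    n_steps = int(np.floor((t_known[-1] - t_known[0]) / dt + 1e-9))
    t = t_known[0] + dt * np.arange(n_steps + 1)
    x = np.interp(t, t_known, u)
    y = np.interp(t, t_known, v)
    return Trajectory(t - t[0], x, y)


def smooth_trajectory(traj: Trajectory, window_s: float = 1.0) -> Trajectory:
    """Centred Gaussian-weighted running average of the coordinates.

    The kernel has sigma = window_s / 2 and is truncated at +/- window_s;
    near the ends the clipped window is renormalized.  Constant input is
    unchanged and straight constant-velocity stretches are preserved in
    the interior (symmetric weights), while manual-tracking jitter is
    damped.
    """
    dt = traj.dt
    if window_s < dt:
        raise ValueError(f"window ({window_s} s) must be >= dt ({dt} s)")
    half = int(round(window_s / dt))
    sigma = window_s / 2.0 / dt
    offsets = np.arange(-half, half + 1)
    w = np.exp(-0.5 * (offsets / sigma) ** 2)
    w /= w.sum()
    norm = np.convolve(np.ones(len(traj)), w, mode="same")
    x = np.convolve(traj.x, w, mode="same") / norm
    y = np.convolve(traj.y, w, mode="same") / norm
    return Trajectory(traj.t, x, y, session_id=traj.session_id,
                      meta={**traj.meta, "smoothed_window_s": window_s})


def clamp_to_room(traj: Trajectory, room: RoomGeometry,
                  warn_fraction: float = 0.01) -> Trajectory:
    """Clamp points outside the room rectangle onto its boundary.

    Rectification noise at the walls can push points marginally outside
    the room.  The number of clamped points is recorded in ``meta``; if
    more than ``warn_fraction`` of samples needed clamping a
    :class:`ClampedPointsWarning` is issued.
    """
    inside = room.contains(traj.x, traj.y)
    n_clamped = int(np.count_nonzero(~inside))
    if n_clamped == 0:
        return traj
    x = np.clip(traj.x, 0.0, room.width)
    y = np.clip(traj.y, 0.0, room.length)
    if n_clamped > warn_fraction * len(traj):
        warnings.warn(
            f"{n_clamped}/{len(traj)} points clamped to the room boundary",
            ClampedPointsWarning,
            stacklevel=2,
        )
    return Trajectory(traj.t, x, y, session_id=traj.session_id,
                      meta={**traj.meta, "n_clamped": n_clamped})


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

def load_trajectory(path: str | Path, session_id: str | None = None) -> Trajectory:
    """Read a trajectory CSV with columns t_s, x_cm, y_cm."""
    df = pd.read_csv(path, comment="#")
    missing = {"t_s", "x_cm", "y_cm"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    sid = session_id if session_id is not None else Path(path).stem
    return Trajectory(df["t_s"].to_numpy(), df["x_cm"].to_numpy(),
                      df["y_cm"].to_numpy(), session_id=sid)


def save_trajectory(traj: Trajectory, path: str | Path) -> None:
    pd.DataFrame({"t_s": traj.t, "x_cm": traj.x, "y_cm": traj.y}).to_csv(
        path, index=False, float_format="%.3f"
    )


def load_raw_track(path: str | Path) -> RawTrack:
    """Read a raw track CSV with columns frame, u_px, v_px (blank = missing)."""
    df = pd.read_csv(path, comment="#")
    missing = {"frame", "u_px", "v_px"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return RawTrack(df["frame"].to_numpy(dtype=np.int64),
                    df["u_px"].to_numpy(dtype=float),
                    df["v_px"].to_numpy(dtype=float))
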