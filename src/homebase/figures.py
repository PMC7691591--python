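"""Figure rendering: derived views of the pipeline tables, never a
source of numbers.

Four panel types are produced per session: the smoothed dwell-time
contour map with visit stars on the retained peaks, the proximity
circle (timing/extent of closeness to mother on a clock-face dial), the
distance-to-mother series partitioned into excursions, and the cohort
contact raster.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .occupancy import dwell_quantile_levels


def plot_dwell_map(result, room, ax=None):
    """Contour map of smoothed dwell (decile levels) with visit stars."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 6))
    sm = result.smoothed_map
    if sm is None:
        raise ValueError("session was analyzed without maps")
    levels = dwell_quantile_levels(sm)
    cx, cy = sm.cell_centers()
    if levels.size == 0:
        warnings.warn("all-zero dwell map: no contours drawn", UserWarning,
                      stacklevel=2)
    else:
        ax.contourf(cx, cy, sm.values.T, levels=np.concatenate(
            [levels, [sm.values.max() + 1e-9]]), cmap="viridis")
    mx, my = room.mother.center
    ax.plot(mx, my, "r^", ms=10, label="mother")
    duration = result.trajectory.duration_s
    for p in result.peaks:
        _draw_visit_star(ax, p, duration)
    ax.set_xlim(0, room.width)
    ax.set_ylim(0, room.length)
    ax.set_aspect("equal")
    ax.set_title(f"{result.session_id}: smoothed dwell + visit stars")
    return ax


def _draw_visit_star(ax, peak, duration_s, radius=28.0):
    """Clock-face star: one wedge per visit, 12 o'clock = session start."""
    x0, y0 = peak.center
    if not peak.visits:
        ax.annotate("no visits", peak.center, color="w", fontsize=6)
        return
    for v in peak.visits:
        a0 = 90.0 - 360.0 * v.start_t / duration_s
        a1 = 90.0 - 360.0 * v.end_t / duration_s
        th = np.linspace(np.deg2rad(a0), np.deg2rad(a1), 12)
        xs = np.concatenate([[x0], x0 + radius * np.cos(th)])
        ys = np.concatenate([[y0], y0 + radius * np.sin(th)])
        ax.plot(xs, ys, "w-", lw=0.8)


def plot_proximity_circle(result, R=120.0, ax=None):
    """Dial of mother-proximity episodes over the normalized session."""
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    duration = result.trajectory.duration_s
    for e in result.mother_proximity:
        th0 = np.pi / 2 - 2 * np.pi * e.start_t / duration
        th1 = np.pi / 2 - 2 * np.pi * e.end_t / duration
        depth = max(0.0, R - max(e.min_clearance, 0.0)) / R
        th = np.linspace(th0, th1, 24)
        ax.fill_between(th, 1.0 - depth, 1.0, alpha=0.6, color="C0")
    ax.set_yticks([])
    ax.set_title(f"{result.session_id}: proximity within {R:.0f} cm")
    return ax


def plot_distance_partition(result, ax=None):
    """Distance-to-mother series with the excursion partition overlaid."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 2.5))
    d = result.d_mother
    ax.plot(d.t / 60.0, d.d, lw=0.7,
            color="C0" if result.group == "TD" else "C3")
    r = result.radius_scan.chosen_r_in
    ax.axhline(r, color="k", lw=1)
    for e in result.excursions:
        ax.axvline(e.start_t / 60.0, color="k", lw=0.5)
        ax.axvline(e.end_t / 60.0, color="k", lw=0.5)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("distance to mother (cm)")
    ax.set_title(f"{result.session_id}: excursion partition (r_in = {r:.0f} cm)")
    return ax


def plot_contact_raster(results, ax=None):
    """One row per session; dashes mark contact episodes."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 0.4 * len(results) + 1))
    for i, r in enumerate(sorted(results, key=lambda r: (r.group, r.session_id))):
        color = "C0" if r.group == "TD" else "C3"
        for e in r.contacts:
            ax.hlines(i, e.start_t / 60.0, e.end_t / 60.0, color=color, lw=4)
        ax.vlines(r.trajectory.duration_min, i - 0.3, i + 0.3, color="k", lw=1)
        ax.text(-0.5, i, r.session_id, ha="right", va="center", fontsize=7)
    ax.set_xlabel("time (min)")
    ax.set_yticks([])
    ax.set_title("contact episodes with mother")
    return ax


def render_figures(bundle: dict, out_dir: str | Path) -> list[Path]:
    """Write all session and cohort figures for a pipeline bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    room = bundle["room"]
    written = []
    for r in bundle["results"]:
        if r.smoothed_map is not None:
            ax = plot_dwell_map(r, room)
            path = out / f"{r.session_id}_dwell.png"
            ax.figure.savefig(path, dpi=100)
            plt.close(ax.figure)
            written.append(path)
        ax = plot_distance_partition(r)
        path = out / f"{r.session_id}_excursions.png"
        ax.figure.savefig(path, dpi=100)
        plt.close(ax.figure)
        written.append(path)
        ax = plot_proximity_circle(r)
        path = out / f"{r.session_id}_proximity.png"
        ax.figure.savefig(path, dpi=100)
        plt.close(ax.figure)
        written.append(path)
    ax = plot_contact_raster(bundle["results"])
    path = out / "contact_raster.png"
    ax.figure.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(ax.figure)
    written.append(path)
    return written
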