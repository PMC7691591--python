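"""Session- and cohort-level orchestration of the analysis pipeline.

A single :class:`RunConfig` carries every stage parameter (with the
conventional defaults: smoothing sigma 14 cm truncated at 31 cm, peak ring
(30, 50), radius scan 30-120 cm with ratio 1.1, near-mother band 100 cm)
and is serialized into every output for provenance.  The stages are:

1. preprocess: smooth, clamp to the room, check duration;
2. occupancy: dwell map, smoothing, peak places, visit stars;
3. mother reference: radius scan, visits, excursions;
4. proximity/contact episodes;
5. endpoints, and across sessions the group comparison table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .endpoints import EndpointRecord, compute_endpoints
from .excursions import Excursion, RadiusScan, scan_mother_radius, segment_excursions
from .geometry import RoomGeometry, load_room
from .occupancy import (DwellMap, PeakPlace, annotate_peak_visits,
                        compute_dwell_map, find_peak_places, smooth_dwell_map)
from .proximity import (ProximityEpisode, contact_episodes,
                        object_clearance_series, proximity_episodes)
from .stats import ComparisonRow, compare_groups, comparison_table
from .tracking import Trajectory, clamp_to_room, load_trajectory, smooth_trajectory
from .visits import DistanceSeries, RingParams, Visit, distance_to_point


@dataclass(frozen=True)
class RunConfig:
    """All stage parameters, with the conventional analysis defaults."""

    smooth_window_s: float = 1.0
    cell_cm: float = 1.0
    sigma_cm: float = 14.0
    truncate_cm: float = 31.0
    keep_fraction: float = 0.04
    peak_r_in: float = 30.0
    peak_r_out: float = 50.0
    scan_r_min: float = 30.0
    scan_r_max: float = 120.0
    scan_step: float = 1.0
    ring_ratio: float = 1.1
    near_cm: float = 100.0
    contact_cm: float = 35.0
    contact_ring_ratio: float = 1.2
    proximity_r: float = 120.0
    speed_threshold: float | str = "auto"
    mother_radius_override: float | None = None
    compute_maps: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.peak_r_in < self.peak_r_out):
            raise ValueError("peak ring radii must satisfy 0 < r_in < r_out")
        if not (0 < self.scan_r_min < self.scan_r_max):
            raise ValueError("scan range must satisfy 0 < r_min < r_max")
        if self.ring_ratio <= 1.0 or self.contact_ring_ratio <= 1.0:
            raise ValueError("hysteresis ratios must exceed 1")
        if not 0 < self.keep_fraction <= 1:
            raise ValueError("keep_fraction must lie in (0, 1]")

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class SessionResult:
    """Everything the pipeline derives from one session."""

    session_id: str
    group: str
    trajectory: Trajectory
    d_mother: DistanceSeries
    radius_scan: RadiusScan
    mother_visits: list[Visit]
    excursions: list[Excursion]
    contacts: list[ProximityEpisode]
    mother_proximity: list[ProximityEpisode]
    endpoints: EndpointRecord
    dwell_map: DwellMap | None = None
    smoothed_map: DwellMap | None = None
    peaks: list[PeakPlace] = field(default_factory=list)


def analyze_session(traj: Trajectory, room: RoomGeometry,
                    config: RunConfig = RunConfig(),
                    group: str = "", preprocess: bool = True) -> SessionResult:
    """Run the full per-session analysis."""
    if preprocess:
        traj = clamp_to_room(smooth_trajectory(traj, config.smooth_window_s), room)
        traj.check_duration()
    d_mother = distance_to_point(traj, room.mother.center, label="mother")

    scan = scan_mother_radius(d_mother, config.scan_r_min, config.scan_r_max,
                              config.scan_step, config.ring_ratio)
    r_in = (config.mother_radius_override
            if config.mother_radius_override is not None else scan.chosen_r_in)
    visits, excursions = segment_excursions(d_mother, r_in, config.ring_ratio,
                                            room_diagonal=room.diagonal)
    contacts = contact_episodes(d_mother, config.contact_cm, config.contact_ring_ratio)
    prox = proximity_episodes(d_mother, config.proximity_r)
    record = compute_endpoints(traj, room, d_mother, excursions, contacts,
                               group=group, near_cm=config.near_cm,
                               speed_threshold=config.speed_threshold)

    result = SessionResult(
        session_id=traj.session_id, group=group, trajectory=traj,
        d_mother=d_mother, radius_scan=scan, mother_visits=visits,
        excursions=excursions, contacts=contacts, mother_proximity=prox,
        endpoints=record,
    )
    if config.compute_maps:
        raw = compute_dwell_map(traj, room, config.cell_cm)
        sm = smooth_dwell_map(raw, config.sigma_cm, config.truncate_cm)
        peaks = find_peak_places(sm, config.keep_fraction)
        annotate_peak_visits(traj, peaks,
                             RingParams(config.peak_r_in, config.peak_r_out))
        result.dwell_map = raw
        result.smoothed_map = sm
        result.peaks = peaks
    return result


# ---------------------------------------------------------------------------
# cohort-level run with file outputs
# ---------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    header = (f"# homebase v{__version__} config={config.digest()}\n")
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format="%.6g")


def endpoint_table(results: list[SessionResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rec = r.endpoints
        row = {"session_id": rec.session_id, "group": rec.group,
               "duration_min": rec.duration_min,
               "chosen_r_in_cm": r.radius_scan.chosen_r_in,
               "n_mother_visits": len(r.mother_visits)}
        row.update(rec.raw())
        row.update({f"{k}_tf": v for k, v in rec.transformed(len(r.trajectory)).items()})
        rows.append(row)
    return pd.DataFrame(rows)


def excursion_table(results: list[SessionResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for i, e in enumerate(r.excursions):
            rows.append({"session_id": r.session_id, "index": i,
                         "start_s": e.start_t, "end_s": e.end_t,
                         "max_distance_cm": e.max_distance, "complete": e.complete})
    return pd.DataFrame(rows)


def peak_table(results: list[SessionResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for i, p in enumerate(r.peaks):
            rows.append({"session_id": r.session_id, "rank": i,
                         "x_cm": p.center[0], "y_cm": p.center[1],
                         "smoothed_dwell_s": p.value, "n_visits": p.n_visits})
    return pd.DataFrame(rows)


def run_pipeline(sessions: list[tuple[str, str, Trajectory]], room: RoomGeometry,
                 config: RunConfig = RunConfig(),
                 out_dir: str | Path | None = None,
                 figures: bool = False) -> dict:
    """Analyze a set of sessions and (optionally) write the output bundle.

    ``sessions`` is a list of ``(session_id, group, trajectory)``.
    Returns a bundle dict with per-session results, the endpoint table
    and — when both groups are present — the comparison table.
    """
    if not sessions:
        raise ValueError("need at least one session")
    results = []
    for sid, group, traj in sessions:
        traj = Trajectory(traj.t, traj.x, traj.y, session_id=sid, meta=traj.meta)
        results.append(analyze_session(traj, room, config, group=group))
    endpoints = endpoint_table(results)
    bundle: dict = {"results": results, "endpoints": endpoints, "config": config,
                    "room": room}
    groups = set(endpoints["group"])
    if {"TD", "NTD"} <= groups:
        n_samples = min(len(r.trajectory) for r in results)
        rows = compare_groups([r.endpoints for r in results], "TD", "NTD",
                              n_samples=n_samples)
        bundle["comparison_rows"] = rows
        bundle["comparison"] = comparison_table(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_csv(endpoints, out / "endpoints.csv", config)
        _write_csv(excursion_table(results), out / "excursions.csv", config)
        if config.compute_maps:
            _write_csv(peak_table(results), out / "peaks.csv", config)
        if "comparison" in bundle:
            _write_csv(bundle["comparison"], out / "comparison.csv", config)
        (out / "config.json").write_text(
            json.dumps(dataclasses.asdict(config), indent=2, default=str))
        if figures:
            from .figures import render_figures
            render_figures(bundle, out / "figures")
    return bundle


def load_manifest(manifest_path: str | Path) -> tuple[list[tuple[str, str, Trajectory]], RoomGeometry]:
    """Read a cohort manifest CSV (session_id, group, path) + room.yaml sibling."""
    mpath = Path(manifest_path)
    df = pd.read_csv(mpath, comment="#")
    missing = {"session_id", "group", "path"} - set(df.columns)
    if missing:
        raise FileNotFoundError(f"manifest missing columns {sorted(missing)}")
    sessions = []
    absent = [p for p in df["path"] if not (mpath.parent / p).exists()]
    if absent:
        raise FileNotFoundError(f"missing session files: {absent}")
    for _, row in df.iterrows():
        traj = load_trajectory(mpath.parent / row["path"], session_id=row["session_id"])
        sessions.append((row["session_id"], row["group"], traj))
    room = load_room(mpath.parent / "room.yaml")
    return sessions, room


def write_cohort(cohort, out_dir: str | Path) -> Path:
    """Write a synthetic cohort as trajectory CSVs + room.yaml + manifest.

    Ground truth goes to a JSON sidecar per session.  Returns the
    manifest path; the layout is exactly what :func:`load_manifest`
    consumes.
    """
    from .geometry import save_room
    from .tracking import save_trajectory
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort.sessions:
        fname = f"{s.session_id}.csv"
        save_trajectory(s.trajectory, out / fname)
        truth = {
            "n_excursions": s.truth.n_excursions,
            "excursion_rate_per_min": s.truth.excursion_rate_per_min,
            "near_fraction": s.truth.near_fraction(cohort.room.mother.center),
            "n_contacts": s.truth.n_contacts,
            "contact_time_s": s.truth.contact_time_s,
        }
        (out / f"{s.session_id}.truth.json").write_text(json.dumps(truth, indent=2))
        rows.append({"session_id": s.session_id, "group": s.group, "path": fname})
    save_room(cohort.room, out / "room.yaml")
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
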