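"""Room geometry and image-to-floor rectification.

The observation room is modelled as an axis-aligned rectangle in floor
coordinates (cm), with the origin at a fixed corner, ``x`` in
``[0, width]`` and ``y`` in ``[0, length]``.  The mother and furniture
items are discs (center + radius).  Raw tracks recorded in the image
plane of a high side-view camera are rectified to the floor plane with a
projective transformation estimated from 4-16 landmark correspondences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from skimage.transform import ProjectiveTransform


class DegenerateCalibrationError(ValueError):
    """Raised when landmark correspondences cannot determine a homography."""


@dataclass(frozen=True)
class Disc:
    """A circular place in the room: furniture item, door area or mother."""

    label: str
    center: tuple[float, float]
    radius: float = 0.0
    kind: str = "furniture"

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError(f"object {self.label!r}: radius must be >= 0")


@dataclass(frozen=True)
class RoomGeometry:
    """Rectangular room with a stationary mother and disc-shaped objects.

    The reference room is 365 cm x 545 cm; those are the defaults used by the
    synthetic generator and the examples.
    """

    width: float
    length: float
    mother: Disc
    objects: tuple[Disc, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.length <= 0:
            raise ValueError("room width and length must be positive")
        for obj in (self.mother, *self.objects):
            cx, cy = obj.center
            if not (0 <= cx <= self.width and 0 <= cy <= self.length):
                raise ValueError(
                    f"object {obj.label!r} center {obj.center} lies outside "
                    f"the {self.width} x {self.length} room"
                )

    @property
    def diagonal(self) -> float:
        return float(np.hypot(self.width, self.length))

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= 0) & (x <= self.width) & (y >= 0) & (y <= self.length)


def default_room(mother_center: tuple[float, float] = (182.5, 25.0),
                 mother_radius: float = 30.0) -> RoomGeometry:
    """The reference layout: 365 x 545 cm room, mother on a mattress at a wall."""
    return RoomGeometry(
        width=365.0,
        length=545.0,
        mother=Disc("mother", mother_center, mother_radius, kind="mattress"),
    )


# ---------------------------------------------------------------------------
# Homography
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Homography:
    """3x3 projective map from image pixels to floor centimetres.

    Normalised so the bottom-right entry equals 1.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("homography matrix must be 3x3")
        if abs(m[2, 2]) < 1e-12 or abs(np.linalg.det(m)) < 1e-12:
            raise DegenerateCalibrationError("homography matrix is singular")
        object.__setattr__(self, "matrix", m / m[2, 2])

    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.matrix))


def _collinear_triples(pts: np.ndarray, tol: float = 1e-9) -> list[tuple[int, int, int]]:
    bad = []
    n = len(pts)
    scale = max(float(np.ptp(pts)), 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                a, b = pts[j] - pts[i], pts[k] - pts[i]
                area = abs(a[0] * b[1] - a[1] * b[0])
                if area < tol * scale * scale:
                    bad.append((i, j, k))
    return bad


def fit_homography(src, dst) -> Homography:
    """Least-squares projective map taking ``src`` (pixels) to ``dst`` (cm).

    Exact for four non-degenerate correspondences; with 5-16 points the
    DLT least-squares solution is returned.  Raises
    :class:`DegenerateCalibrationError` naming the offending points when
    three source points are collinear or the system is rank deficient.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("src and dst must be matching (n, 2) arrays")
    n = len(src)
    if not 4 <= n <= 16:
        raise ValueError(f"need 4-16 correspondences, got {n}")
    bad = _collinear_triples(src)
    if bad:
        raise DegenerateCalibrationError(
            f"collinear source points {bad[0]}: {src[list(bad[0])].tolist()}"
        )
    tf = ProjectiveTransform.from_estimate(src, dst)
    if not tf or not np.all(np.isfinite(tf.params)):
        raise DegenerateCalibrationError("homography estimation failed (rank deficient)")
    return Homography(tf.params)


def apply_homography(h: Homography, pts) -> np.ndarray:
    """Map ``(u, v)`` points through ``h``, dehomogenizing the result."""
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    hom = np.column_stack([pts, np.ones(len(pts))])
    out = hom @ h.matrix.T
    w = out[:, 2]
    if np.any(np.abs(w) < 1e-12):
        idx = int(np.argmin(np.abs(w)))
        raise ValueError(f"point {pts[idx].tolist()} maps to the plane at infinity")
    return out[:, :2] / w[:, None]


# ---------------------------------------------------------------------------
# Room configuration I/O (YAML)
# ---------------------------------------------------------------------------

def load_room(path: str | Path) -> RoomGeometry:
    """Read a room configuration.

    Expected keys: ``width_cm``, ``length_cm``, ``mother: {center, radius}``
    and ``objects: [{label, center, radius, kind}]``.
    """
    data = yaml.safe_load(Path(path).read_text())
    mother = data.get("mother", {})
    objects = tuple(
        Disc(
            label=o["label"],
            center=tuple(float(c) for c in o["center"]),
            radius=float(o.get("radius", 0.0)),
            kind=o.get("kind", "furniture"),
        )
        for o in data.get("objects", [])
    )
    return RoomGeometry(
        width=float(data["width_cm"]),
        length=float(data["length_cm"]),
        mother=Disc(
            "mother",
            tuple(float(c) for c in mother["center"]),
            float(mother.get("radius", 0.0)),
            kind="mattress",
        ),
        objects=objects,
    )


def save_room(room: RoomGeometry, path: str | Path) -> None:
    data = {
        "width_cm": room.width,
        "length_cm": room.length,
        "mother": {"center": list(room.mother.center), "radius": room.mother.radius},
        "objects": [
            {
                "label": o.label,
                "center": list(o.center),
                "radius": o.radius,
                "kind": o.kind,
            }
            for o in room.objects
        ],
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_calibration(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a landmark file with columns u_px, v_px, x_cm, y_cm."""
    arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if arr.shape[1] != 4:
        raise ValueError("calibration file must have columns u_px,v_px,x_cm,y_cm")
    return arr[:, :2], arr[:, 2:]
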