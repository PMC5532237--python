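"""Closed cell-contour containers, file I/O and planar geometry.

Conventions used throughout the package: coordinates are in micrometres with
x to the right and y up; contours are simple closed polygons stored
counterclockwise (node N connects back to node 1, the first point is *not*
repeated at the end); angles are degrees at the API surface and radians
internally.

The polarization axis of a cell is the major axis of a least-squares ellipse
fit to the contour, with the front end chosen by persistent centroid motion
over subsequent frames.  Angular positions around the contour are measured at
the ellipse centre, 0 deg at the cell front, increasing counterclockwise, so
the "front half" is [0, 90) + (270, 360).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import LinearRing

logger = logging.getLogger(__name__)

__all__ = [
    "Contour",
    "ContourSeries",
    "EllipseFit",
    "ContourError",
    "ContourParseError",
    "ContourValidationError",
    "PolarizationError",
    "read_contour_series",
    "write_contour_series",
    "resample_equidistant",
    "signed_curvature",
    "circularity",
    "fit_polarization_axis",
    "angular_position",
    "angular_positions",
    "angle_of_point",
    "front_half_mask",
]


class ContourError(ValueError):
    """Base class for contour-related input problems."""


class ContourParseError(ContourError):
    """A contour file could not be parsed."""


class ContourValidationError(ContourError):
    """Parsed data violates a contour invariant."""


class PolarizationError(ContourError):
    """The front end of the polarization axis cannot be determined."""


def _polygon_area(xy: np.ndarray) -> float:
    """Signed area by the shoelace formula (positive for CCW)."""
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _polygon_centroid(xy: np.ndarray) -> np.ndarray:
    x, y = xy[:, 0], xy[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * float(np.sum(cross))
    if abs(a) < 1e-300:
        return xy.mean(axis=0)
    cx = float(np.sum((x + xn) * cross)) / (6.0 * a)
    cy = float(np.sum((y + yn) * cross)) / (6.0 * a)
    return np.array([cx, cy])


@dataclass
class Contour:
    """One closed cell outline (a simple CCW polygon, coordinates in um).

    ``intensity`` optionally carries one cortical-fluorescence value per node.
    Construction normalizes orientation to counterclockwise and strips an
    exactly repeated closing point; it rejects contours with fewer than 8
    nodes, consecutive duplicate points, or zero enclosed area.
    """

    frame_index: int
    nodes: np.ndarray
    intensity: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        if nodes.ndim != 2 or nodes.shape[1] != 2:
            raise ContourValidationError(
                f"frame {self.frame_index}: nodes must be an (N, 2) array"
            )
        inten = None
        if self.intensity is not None:
            inten = np.asarray(self.intensity, dtype=float).ravel()
        if len(nodes) >= 2 and np.array_equal(nodes[0], nodes[-1]):
            nodes = nodes[:-1]
            if inten is not None and len(inten) == len(nodes) + 1:
                inten = inten[:-1]
        if not np.isfinite(nodes).all():
            raise ContourValidationError(
                f"frame {self.frame_index}: non-finite coordinates"
            )
        if len(nodes) < 8:
            raise ContourValidationError(
                f"frame {self.frame_index}: contour has {len(nodes)} nodes, "
                "at least 8 required"
            )
        dup = np.all(nodes == np.roll(nodes, -1, axis=0), axis=1)
        if dup.any():
            i = int(np.argmax(dup))
            raise ContourValidationError(
                f"frame {self.frame_index}: duplicate consecutive point at "
                f"node {i}"
            )
        area = _polygon_area(nodes)
        if area == 0.0:
            raise ContourValidationError(
                f"frame {self.frame_index}: contour encloses zero area"
            )
        if area < 0.0:
            nodes = np.ascontiguousarray(nodes[::-1])
            if inten is not None:
                inten = np.ascontiguousarray(inten[::-1])
        if inten is not None and len(inten) != len(nodes):
            raise ContourValidationError(
                f"frame {self.frame_index}: intensity length {len(inten)} "
                f"!= node count {len(nodes)}"
            )
        self.nodes = nodes
        self.intensity = inten

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def segment_lengths(self) -> np.ndarray:
        """Edge lengths, segment i joining node i to node i+1 (cyclic)."""
        return np.linalg.norm(np.roll(self.nodes, -1, axis=0) - self.nodes, axis=1)

    @property
    def perimeter(self) -> float:
        return float(self.segment_lengths.sum())

    @property
    def area(self) -> float:
        return _polygon_area(self.nodes)

    @property
    def centroid(self) -> np.ndarray:
        return _polygon_centroid(self.nodes)

    @property
    def is_simple(self) -> bool:
        """True if the closed polygon has no self-intersections."""
        try:
            ring = LinearRing(self.nodes)
        except Exception:
            return False
        return bool(ring.is_simple and ring.is_valid)

    def copy(self) -> "Contour":
        return Contour(
            self.frame_index,
            self.nodes.copy(),
            None if self.intensity is None else self.intensity.copy(),
        )


@dataclass
class ContourSeries:
    """Contours of one cell ordered by frame, acquired at fixed interval.

    ``frame_interval`` is in seconds; the default 0.5 s corresponds to the
    2 fps acquisition the detection thresholds are calibrated for.
    """

    contours: list[Contour]
    frame_interval: float = 0.5

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ContourValidationError("frame_interval must be positive")
        idx = [c.frame_index for c in self.contours]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ContourValidationError("frame indices must be strictly increasing")

    @property
    def frame_indices(self) -> list[int]:
        return [c.frame_index for c in self.contours]

    @property
    def has_intensity(self) -> bool:
        return len(self.contours) > 0 and all(
            c.intensity is not None for c in self.contours
        )

    def frame(self, frame_index: int) -> Contour:
        for c in self.contours:
            if c.frame_index == frame_index:
                return c
        raise KeyError(f"no contour with frame_index {frame_index}")

    def position(self, frame_index: int) -> int:
        for i, c in enumerate(self.contours):
            if c.frame_index == frame_index:
                return i
        raise KeyError(f"no contour with frame_index {frame_index}")

    def __len__(self) -> int:
        return len(self.contours)

    def __iter__(self) -> Iterator[Contour]:
        return iter(self.contours)

    def __getitem__(self, i: int) -> Contour:
        return self.contours[i]


# ---------------------------------------------------------------------------
# File I/O
#
# CSV dialect: columns frame,node,x_um,y_um[,intensity]; one row per node,
# header mandatory, frames grouped and nodes in order.
# JSON dialect: list of {frame, points: [[x, y], ...], intensity: [...]|null,
# scale_um_per_unit}.
# ---------------------------------------------------------------------------

_CSV_REQUIRED = ("frame", "node", "x_um", "y_um")


def _infer_dialect(path: Path, dialect: Optional[str]) -> str:
    if dialect is not None:
        if dialect not in ("csv", "json"):
            raise ValueError(f"unknown dialect {dialect!r}")
        return dialect
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix == ".json":
        return "json"
    raise ValueError(f"cannot infer dialect from suffix {suffix!r}")


def read_contour_series(
    path, dialect: Optional[str] = None, frame_interval: float = 0.5
) -> ContourSeries:
    """Read a contour time series from CSV or JSON (dialects above).

    Coordinates are converted to um (the CSV columns are um by declaration;
    JSON records carry a ``scale_um_per_unit`` factor) and orientation is
    normalized to counterclockwise.  Malformed files raise
    :class:`ContourParseError` naming the offending record, invalid contours
    raise :class:`ContourValidationError`.
    """
    path = Path(path)
    d = _infer_dialect(path, dialect)
    if d == "csv":
        try:
            df = pd.read_csv(path, float_precision="round_trip")
        except Exception as exc:  # noqa: BLE001 - surface as parse error
            raise ContourParseError(f"{path}: {exc}") from exc
        missing = [c for c in _CSV_REQUIRED if c not in df.columns]
        if missing:
            raise ContourParseError(
                f"{path}: missing required column(s) {', '.join(missing)}"
            )
        has_int = "intensity" in df.columns
        contours = []
        for frame, grp in df.groupby("frame", sort=True):
            grp = grp.sort_values("node")
            xy = grp[["x_um", "y_um"]].to_numpy(dtype=float)
            inten = grp["intensity"].to_numpy(dtype=float) if has_int else None
            if inten is not None and np.isnan(inten).all():
                inten = None
            contours.append(Contour(int(frame), xy, inten))
        return ContourSeries(contours, frame_interval)
    # JSON
    try:
        with open(path) as fh:
            records = json.load(fh)
    except Exception as exc:  # noqa: BLE001
        raise ContourParseError(f"{path}: {exc}") from exc
    if not isinstance(records, list):
        raise ContourParseError(f"{path}: expected a JSON list of frame records")
    contours = []
    for i, rec in enumerate(records):
        try:
            scale = float(rec.get("scale_um_per_unit", 1.0))
            pts = np.asarray(rec["points"], dtype=float) * scale
            inten = rec.get("intensity")
            inten = None if inten is None else np.asarray(inten, dtype=float)
            contours.append(Contour(int(rec["frame"]), pts, inten))
        except ContourValidationError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise ContourParseError(f"{path}: record {i}: {exc}") from exc
    return ContourSeries(contours, frame_interval)


def write_contour_series(series: ContourSeries, path, dialect: Optional[str] = None) -> None:
    """Write a series in the CSV or JSON dialect (byte-stable round trip)."""
    path = Path(path)
    d = _infer_dialect(path, dialect)
    if d == "csv":
        # repr() floats for a lossless, byte-stable round trip
        with_int = series.has_intensity
        lines = ["frame,node,x_um,y_um" + (",intensity" if with_int else "")]
        for c in series:
            for i, (x, y) in enumerate(c.nodes):
                row = f"{c.frame_index},{i},{float(x)!r},{float(y)!r}"
                if with_int:
                    row += f",{float(c.intensity[i])!r}"
                lines.append(row)
        Path(path).write_text("\n".join(lines) + "\n")
        return
    records = []
    for c in series:
        records.append(
            {
                "frame": c.frame_index,
                "points": c.nodes.tolist(),
                "intensity": None if c.intensity is None else c.intensity.tolist(),
                "scale_um_per_unit": 1.0,
            }
        )
    with open(path, "w") as fh:
        json.dump(records, fh)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def resample_equidistant(contour: Contour, target_spacing: float) -> Contour:
    """Resample a contour to N = round(perimeter / spacing) equidistant nodes.

    Nodes are placed at equal arc-length intervals along the input polyline,
    anchored at the input's first node.  Intensity, when present, is linearly
    interpolated along arc length.
    """
    perimeter = contour.perimeter
    if not (0.0 < target_spacing < perimeter / 8.0):
        raise ValueError(
            f"target_spacing {target_spacing} outside (0, perimeter/8 = "
            f"{perimeter / 8.0:.4g})"
        )
    n_new = int(round(perimeter / target_spacing))
    closed = np.vstack([contour.nodes, contour.nodes[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    t = np.arange(n_new) * (cum[-1] / n_new)
    x = np.interp(t, cum, closed[:, 0])
    y = np.interp(t, cum, closed[:, 1])
    inten = None
    if contour.intensity is not None:
        closed_i = np.concatenate([contour.intensity, contour.intensity[:1]])
        inten = np.interp(t, cum, closed_i)
    out = Contour(contour.frame_index, np.column_stack([x, y]), inten)
    if not out.is_simple:
        raise ContourValidationError(
            f"frame {contour.frame_index}: self-intersecting after resampling"
        )
    return out


def signed_curvature(contour: Contour) -> np.ndarray:
    """Discrete signed curvature per node (1/um), positive where convex.

    Periodic central differences on the (approximately uniform arc-length)
    polygon; for a counterclockwise circle of radius r every value is +1/r.
    """
    xy = contour.nodes
    h = contour.perimeter / contour.n_nodes
    d1 = (np.roll(xy, -1, axis=0) - np.roll(xy, 1, axis=0)) / (2.0 * h)
    d2 = (np.roll(xy, -1, axis=0) - 2.0 * xy + np.roll(xy, 1, axis=0)) / (h * h)
    num = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    den = np.power(d1[:, 0] ** 2 + d1[:, 1] ** 2, 1.5)
    return num / den


def circularity(contour: Contour) -> float:
    """4 pi A / P**2: 1 for a circle, toward 0 for elongated shapes."""
    p = contour.perimeter
    return 4.0 * math.pi * abs(contour.area) / (p * p)


@dataclass
class EllipseFit:
    """Least-squares ellipse with a directed front along the major axis.

    ``major_axis_angle`` is the undirected axis direction in radians in
    [0, pi); ``front_end`` (+1 or -1) selects which end of that axis is the
    leading edge, so ``front_direction`` is the unit vector from the centre
    toward the cell front.
    """

    center: np.ndarray
    a: float  # semi-minor axis, um
    b: float  # semi-major axis, um
    major_axis_angle: float  # radians in [0, pi)
    front_end: int  # +1 or -1

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if not (self.b >= self.a > 0.0):
            raise ValueError("ellipse axes must satisfy b >= a > 0")
        if self.front_end not in (1, -1):
            raise ValueError("front_end must be +1 or -1")
        self.major_axis_angle = float(self.major_axis_angle) % math.pi

    @property
    def front_direction(self) -> np.ndarray:
        return self.front_end * np.array(
            [math.cos(self.major_axis_angle), math.sin(self.major_axis_angle)]
        )


def _fit_ellipse_lsq(xy: np.ndarray):
    """Direct least-squares conic fit; returns (center, a_minor, b_major, theta)."""
    from skimage.measure import EllipseModel

    if hasattr(EllipseModel, "from_estimate"):
        model = EllipseModel.from_estimate(xy)
        if not model:
            raise ContourError("ellipse fit failed (degenerate point set)")
        (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    else:  # scikit-image < 0.26
        model = EllipseModel()
        if not model.estimate(xy):
            raise ContourError("ellipse fit failed (degenerate point set)")
        xc, yc, a, b, theta = model.params
    if a >= b:
        major, minor, theta_major = a, b, theta
    else:
        major, minor, theta_major = b, a, theta + math.pi / 2.0
    return np.array([xc, yc]), float(minor), float(major), float(theta_major) % math.pi


def fit_polarization_axis(
    series: ContourSeries, frame: int, lookahead: int = 5
) -> EllipseFit:
    """Fit the polarization axis of ``frame`` and orient its front end.

    The axis is the major axis of a least-squares ellipse; the front end is
    the one whose direction has positive scalar product with the mean
    centroid displacement over the next ``lookahead`` frames.  With fewer
    subsequent frames available the lookahead is truncated (>= 1) with a
    logged warning; zero net displacement raises :class:`PolarizationError`
    so the caller can specify the front explicitly.
    """
    pos = series.position(frame)
    n_later = len(series) - pos - 1
    if n_later < 1:
        raise PolarizationError(
            f"frame {frame}: no subsequent frames to determine the cell front"
        )
    la = min(lookahead, n_later)
    if la < lookahead:
        logger.warning(
            "frame %s: lookahead truncated from %d to %d frames", frame, lookahead, la
        )
    contour = series[pos]
    center, a, b, theta = _fit_ellipse_lsq(contour.nodes)
    c0 = contour.centroid
    disp = np.mean([series[pos + j].centroid - c0 for j in range(1, la + 1)], axis=0)
    axis_dir = np.array([math.cos(theta), math.sin(theta)])
    s = float(np.dot(disp, axis_dir))
    if abs(s) < 1e-12:
        raise PolarizationError(
            f"frame {frame}: zero net displacement over lookahead; "
            "specify the front explicitly"
        )
    return EllipseFit(center, a, b, theta, 1 if s > 0 else -1)


def angle_of_point(point: np.ndarray, axis: EllipseFit) -> float:
    """Angle of a point about the ellipse centre, degrees in [0, 360).

    0 deg at the front end of the major axis, increasing counterclockwise.
    """
    v = np.asarray(point, dtype=float) - axis.center
    f = axis.front_direction
    ang = math.degrees(math.atan2(f[0] * v[1] - f[1] * v[0], f[0] * v[0] + f[1] * v[1]))
    return ang % 360.0


def angular_positions(contour: Contour, axis: EllipseFit) -> np.ndarray:
    """Angular position of every node, degrees in [0, 360), 0 at the front."""
    v = contour.nodes - axis.center
    f = axis.front_direction
    ang = np.degrees(np.arctan2(f[0] * v[:, 1] - f[1] * v[:, 0],
                                f[0] * v[:, 0] + f[1] * v[:, 1]))
    return np.mod(ang, 360.0)


def angular_position(contour: Contour, node: int, axis: EllipseFit) -> float:
    """Angular position of one node (degrees in [0, 360), 0 = cell front)."""
    if not (0 <= node < contour.n_nodes):
        raise IndexError(f"node {node} out of range for {contour.n_nodes} nodes")
    return angle_of_point(contour.nodes[node], axis)


def front_half_mask(angles_deg: np.ndarray) -> np.ndarray:
    """True where an angle lies in the front half, [0, 90) + (270, 360)."""
    a = np.mod(np.asarray(angles_deg, dtype=float), 360.0)
    return (a < 90.0) | (a > 270.0)
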