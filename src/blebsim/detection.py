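"""Detection of observed blebs from consecutive contour frames.

A protrusion candidate is a cyclically contiguous run of later-frame nodes
lying strictly outside the earlier-frame polygon (even-odd point-in-polygon
test; boundary points are not kept).  Because bleb expansion is fast
compared with actin-driven pseudopod growth, candidates are classified as
blebs when their maximum outward distance from the earlier boundary exceeds
a distance threshold per frame; slow protrusions fall below it.  Detections
are intended for a manual review pass downstream, which is why the series
driver also emits a review table rather than enforcing any interactive
step.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon

from .contours import (
    Contour,
    ContourSeries,
    EllipseFit,
    PolarizationError,
    angle_of_point,
    fit_polarization_axis,
)
from .ranking import BlebSitePrediction, _cyclic_span_contains

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateSpan",
    "DetectedBleb",
    "detect_protrusions",
    "classify_blebs",
    "match_blebs_to_predictions",
    "detect_bleb_series",
    "DEFAULT_THRESHOLD_UM",
    "REFERENCE_FRAME_INTERVAL",
]

# Distance a protrusion must advance within one frame to count as a bleb.
# Calibrated for 2 fps acquisition (0.5 s frames) and scaled linearly for
# other frame intervals.
DEFAULT_THRESHOLD_UM = 0.5
REFERENCE_FRAME_INTERVAL = 0.5


@dataclass
class CandidateSpan:
    """A contiguous run of later-frame nodes outside the earlier contour."""

    frame_index: int  # later frame
    earlier_frame_index: int
    nodes: np.ndarray  # later-contour node indices, cyclic-contiguous order
    max_outward_distance: float  # um, farthest node to earlier boundary
    farthest_node: int  # later-contour node index
    farthest_point: np.ndarray  # coordinates of that node, um
    protruded_area: float  # um^2, region between span and earlier boundary
    nearest_earlier_node: int  # earlier-contour node closest to farthest point


@dataclass
class DetectedBleb:
    """A protrusion classified as a bleb by the fast-expansion constraint."""

    frame_index: int
    node_span: tuple[int, int]  # (first, last) later-contour nodes, cyclic
    max_outward_distance: float
    protruded_area: float
    angle_deg: float  # NaN when no polarization axis was available
    farthest_node: int
    nearest_earlier_node: int
    earlier_frame_index: int


def _contiguous_runs(mask: np.ndarray) -> list[np.ndarray]:
    """Cyclically contiguous runs of True indices."""
    n = len(mask)
    if not mask.any():
        return []
    if mask.all():
        return [np.arange(n)]
    start = int(np.argmax(~mask))
    rolled = np.roll(mask, -start)
    idx = np.nonzero(rolled)[0]
    splits = np.nonzero(np.diff(idx) > 1)[0] + 1
    return [(chunk + start) % n for chunk in np.split(idx, splits)]


def detect_protrusions(earlier: Contour, later: Contour) -> list[CandidateSpan]:
    """Candidate protrusion spans of ``later`` relative to ``earlier``.

    Later-frame nodes are classified against the earlier polygon; contiguous
    runs of outside nodes become candidates with their maximum outward
    distance (point to earlier boundary) and protruded area (area of the
    difference-polygon component carrying the span).
    """
    poly_e = Polygon(earlier.nodes)
    if not poly_e.is_valid:
        poly_e = poly_e.buffer(0)
    pts = shapely.points(later.nodes)
    outside = ~shapely.covers(poly_e, pts)
    runs = _contiguous_runs(outside)
    if not runs:
        return []
    boundary = poly_e.exterior
    try:
        poly_l = Polygon(later.nodes)
        if not poly_l.is_valid:
            poly_l = poly_l.buffer(0)
        diff = poly_l.difference(poly_e)
        components = (
            list(diff.geoms) if diff.geom_type.startswith("Multi") else [diff]
        )
        components = [c for c in components if c.area > 0]
    except Exception:  # pragma: no cover - degenerate shapely input
        components = []
    spans = []
    for run in runs:
        d = shapely.distance(boundary, pts[run])
        far_local = int(np.argmax(d))
        far_node = int(run[far_local])
        far_point = later.nodes[far_node]
        area = 0.0
        if components:
            fp = shapely.points(far_point)
            dists = [shapely.distance(c, fp) for c in components]
            area = float(components[int(np.argmin(dists))].area)
        near = int(
            np.argmin(np.linalg.norm(earlier.nodes - far_point[None, :], axis=1))
        )
        spans.append(
            CandidateSpan(
                frame_index=later.frame_index,
                earlier_frame_index=earlier.frame_index,
                nodes=run,
                max_outward_distance=float(d[far_local]),
                farthest_node=far_node,
                farthest_point=np.asarray(far_point, dtype=float),
                protruded_area=area,
                nearest_earlier_node=near,
            )
        )
    return spans


def classify_blebs(
    candidates: Sequence[CandidateSpan],
    threshold_um: float = DEFAULT_THRESHOLD_UM,
    frame_interval: float = REFERENCE_FRAME_INTERVAL,
    axis: Optional[EllipseFit] = None,
) -> list[DetectedBleb]:
    """Keep candidates whose outward advance marks fast (bleb) expansion.

    The effective threshold is ``threshold_um * frame_interval / 0.5`` so
    that the same expansion *speed* is required whatever the acquisition
    rate.  Angles are measured about the polarization axis when given.
    """
    if threshold_um <= 0:
        raise ValueError("threshold_um must be positive")
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    effective = threshold_um * frame_interval / REFERENCE_FRAME_INTERVAL
    blebs = []
    for cand in candidates:
        if cand.max_outward_distance < effective:
            continue
        ang = (
            angle_of_point(cand.farthest_point, axis)
            if axis is not None
            else float("nan")
        )
        blebs.append(
            DetectedBleb(
                frame_index=cand.frame_index,
                node_span=(int(cand.nodes[0]), int(cand.nodes[-1])),
                max_outward_distance=cand.max_outward_distance,
                protruded_area=cand.protruded_area,
                angle_deg=ang,
                farthest_node=cand.farthest_node,
                nearest_earlier_node=cand.nearest_earlier_node,
                earlier_frame_index=cand.earlier_frame_index,
            )
        )
    return blebs


def match_blebs_to_predictions(
    blebs: Sequence[DetectedBleb],
    predictions: Sequence[BlebSitePrediction],
    earlier: Contour,
) -> list[tuple[DetectedBleb, Optional[int]]]:
    """Assign each bleb the rank of the predicted site whose width span (on
    the earlier contour) contains the bleb's nearest earlier-boundary node.

    Unmatched blebs get rank ``None``; when spans share their boundary
    minimum the better (lower) rank wins.
    """
    n = earlier.n_nodes
    out = []
    for bleb in blebs:
        node = bleb.nearest_earlier_node
        best: Optional[int] = None
        for pred in predictions:
            if _cyclic_span_contains(pred.width_span, node, n):
                if best is None or pred.rank < best:
                    best = pred.rank
        if best is None:
            logger.info(
                "frame %s: bleb at node %s matched no predicted site",
                bleb.frame_index, node,
            )
        out.append((bleb, best))
    return out


def detect_bleb_series(
    series: ContourSeries,
    threshold_um: float = DEFAULT_THRESHOLD_UM,
    axes: Optional[dict] = None,
    lookahead: int = 5,
) -> list[DetectedBleb]:
    """Run detection/classification across all consecutive frame pairs.

    ``axes`` maps earlier-frame indices to :class:`EllipseFit`; when omitted
    axes are fitted per frame, falling back to the last fittable axis for
    trailing frames (angles are NaN if no axis is ever available).
    """
    if len(series) < 2:
        raise ValueError("bleb detection needs at least 2 frames")
    blebs: list[DetectedBleb] = []
    last_axis: Optional[EllipseFit] = None
    for earlier, later in zip(series.contours, series.contours[1:]):
        axis = None
        if axes is not None:
            axis = axes.get(earlier.frame_index, None)
        else:
            try:
                axis = fit_polarization_axis(series, earlier.frame_index, lookahead)
                last_axis = axis
            except PolarizationError:
                axis = last_axis
        candidates = detect_protrusions(earlier, later)
        blebs.extend(
            classify_blebs(
                candidates, threshold_um, series.frame_interval, axis=axis
            )
        )
    return blebs
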