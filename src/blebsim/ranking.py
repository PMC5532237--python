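"""Sub-critical pressure search and bleb-site ranking.

The operating point for prediction is the *sub-critical pressure*: the
highest pressure difference at which relaxing the membrane breaks no linker.
At that pressure the per-node linker-extension profile around the contour is
the blebbing-propensity readout: local maxima are candidate nucleation
sites, ranked by extension (rank 1 = longest linker), and each site's width
runs between the first local minima on either side of its peak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .contours import Contour, EllipseFit, angular_positions, resample_equidistant
from .model import (
    ModelParams,
    ModelState,
    apply_linker_gradient,
    initialize_model,
    relax_membrane,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BlebSitePrediction",
    "PressureSearchError",
    "find_subcritical_pressure",
    "rank_bleb_sites",
    "bleb_site_width",
    "predict",
]

_REL_WIDTH = 1e-3  # relative bracket width of the pressure bisection
_MAX_DOUBLINGS = 12
_TIE_RTOL = 1e-12


class PressureSearchError(RuntimeError):
    """The sub-critical pressure bracket could not be established."""


@dataclass
class BlebSitePrediction:
    """One candidate nucleation site on a relaxed contour.

    ``width_span`` is the inclusive (start, end) node pair walking
    counterclockwise from start to end through the nucleation node;
    ``angle_deg`` is NaN when no polarization axis was supplied.
    """

    nucleation_node: int
    rank: int
    extension: float
    width_span: tuple[int, int]
    angle_deg: float


def _relax_at(state0: ModelState, pressure: float) -> ModelState:
    s = state0.copy()
    s.params = state0.params.replace(delta_p=pressure)
    return relax_membrane(s, allow_breaking=False)


def _subcritical(
    state0: ModelState, p_max: Optional[float] = None
) -> tuple[float, ModelState]:
    """Bisection for the sub-critical pressure; returns (p_sub, relaxed state)."""
    params = state0.params
    l_crit = params.L_crit

    cache: dict[float, ModelState] = {}

    def breaks(p: float) -> bool:
        relaxed = _relax_at(state0, p)
        cache[p] = relaxed
        return float(relaxed.extensions.max()) > l_crit

    if breaks(0.0):
        raise PressureSearchError("linkers exceed L_crit already at zero pressure")
    p_lo = 0.0
    if p_max is not None:
        if not breaks(p_max):
            raise PressureSearchError(f"no linker breaks even at p_max={p_max}")
        p_hi = p_max
    else:
        p_hi = params.p_start
        for _ in range(_MAX_DOUBLINGS + 1):
            if breaks(p_hi):
                break
            p_lo = p_hi
            p_hi *= 2.0
        else:
            raise PressureSearchError(
                f"no linker breaks after {_MAX_DOUBLINGS} doublings from "
                f"p_start={params.p_start}"
            )
    for _ in range(80):
        if p_lo > 0.0 and (p_hi - p_lo) <= _REL_WIDTH * p_lo:
            break
        mid = 0.5 * (p_lo + p_hi)
        if breaks(mid):
            p_hi = mid
        else:
            p_lo = mid
    if p_lo == 0.0:
        raise PressureSearchError("bisection collapsed to zero pressure")
    return p_lo, cache[p_lo]


def find_subcritical_pressure(
    contour: Contour,
    params: Optional[ModelParams] = None,
    p_max: Optional[float] = None,
    gradient: Optional[tuple[EllipseFit, float]] = None,
    return_state: bool = False,
):
    """Highest pressure at which relaxation breaks no linker.

    Bisection on the pressure, each evaluation relaxing the membrane with
    breaking disallowed and testing the maximum linker extension against
    ``L_crit``.  The bracket is auto-doubled from ``params.p_start`` when
    ``p_max`` is not given (at most 12 doublings) and narrowed to a relative
    width below 1e-3, so relaxing at the returned pressure breaks nothing
    while a 0.1% higher pressure stretches at least one linker past
    ``L_crit``.  ``gradient`` optionally applies an (axis, max_increase)
    linker-stiffness gradient before the search.  With ``return_state`` the
    relaxed state at the returned pressure is also returned.
    """
    params = params or ModelParams.default()
    state0 = initialize_model(contour, params)
    if gradient is not None:
        axis, max_increase = gradient
        state0 = apply_linker_gradient(state0, axis, max_increase)
    p_sub, relaxed = _subcritical(state0, p_max)
    return (p_sub, relaxed) if return_state else p_sub


# ---------------------------------------------------------------------------
# Extension-profile analysis
# ---------------------------------------------------------------------------


def _periodic_plateau_maxima(profile: np.ndarray) -> list[int]:
    """Local maxima of a cyclic profile; plateaus collapse to their central
    node (round-down on even plateaus).  Empty for a strictly uniform
    profile."""
    n = len(profile)
    boundary = profile != np.roll(profile, 1)
    if not boundary.any():
        return []
    start = int(np.argmax(boundary))  # first index beginning a run
    rolled = np.roll(profile, -start)
    run_starts = [0]
    for i in range(1, n):
        if rolled[i] != rolled[i - 1]:
            run_starts.append(i)
    run_ends = run_starts[1:] + [n]
    values = [rolled[s] for s in run_starts]
    m = len(run_starts)
    maxima = []
    for j in range(m):
        left = values[(j - 1) % m]
        right = values[(j + 1) % m]
        if values[j] > left and values[j] > right:
            s, e = run_starts[j], run_ends[j]
            center = s + (e - 1 - s) // 2
            maxima.append((center + start) % n)
    return sorted(maxima)


def bleb_site_width(
    state: ModelState,
    site: "BlebSitePrediction | int",
    profile: Optional[np.ndarray] = None,
) -> tuple[int, int]:
    """Inclusive node span between the first local minima either side of a
    site's nucleation node, walking the cyclic extension profile downhill."""
    e = state.extensions if profile is None else profile
    node = site.nucleation_node if isinstance(site, BlebSitePrediction) else int(site)
    n = len(e)
    peak = e[node]
    left = node
    # cross a flat peak plateau first, then descend strictly
    steps = 0
    while e[(left - 1) % n] == peak and steps < n:
        left -= 1
        steps += 1
    while e[(left - 1) % n] < e[left % n] and steps < n:
        left -= 1
        steps += 1
    right = node
    steps = 0
    while e[(right + 1) % n] == peak and steps < n:
        right += 1
        steps += 1
    while e[(right + 1) % n] < e[right % n] and steps < n:
        right += 1
        steps += 1
    return (left % n, right % n)


def _cyclic_span_contains(span: tuple[int, int], node: int, n: int) -> bool:
    s, e = span
    if s <= e:
        return s <= node <= e
    return node >= s or node <= e


def rank_bleb_sites(
    state: ModelState,
    axis: Optional[EllipseFit] = None,
    smooth: bool = False,
) -> list[BlebSitePrediction]:
    """Rank candidate bleb nucleation sites of a relaxed state.

    Sites are the local maxima of the cyclic linker-extension profile,
    ordered by extension descending (rank 1 = longest linker; all n sites
    are returned, the least likely with rank n).  Near-exact ties (relative
    difference below 1e-12) are broken by smaller angular distance to the
    cell front when an axis is given, then by lower node index.  ``smooth``
    applies a light 3-node moving average before extremum detection (for
    noisy experimental contours; off by default).  A strictly uniform
    profile -- a perfect circle -- yields an empty list with a logged
    symmetric-degeneracy notice.
    """
    e = state.extensions.astype(float)
    if smooth:
        e = (np.roll(e, 1) + e + np.roll(e, -1)) / 3.0
    nodes = _periodic_plateau_maxima(e)
    if not nodes:
        logger.info("uniform extension profile: symmetric degeneracy, no ranked sites")
        return []
    angles = angular_positions(state.membrane, axis) if axis is not None else None

    def sort_key(node: int):
        if angles is None:
            return (0.0, node)
        d = angles[node] % 360.0
        return (min(d, 360.0 - d), node)

    # group near-exact ties, order groups by extension descending
    order = sorted(nodes, key=lambda i: -e[i])
    ordered: list[int] = []
    i = 0
    while i < len(order):
        j = i
        ref = e[order[i]]
        scale = max(abs(ref), 1e-300)
        while j < len(order) and abs(e[order[j]] - ref) <= _TIE_RTOL * scale:
            j += 1
        ordered.extend(sorted(order[i:j], key=sort_key))
        i = j
    sites = []
    for rank, node in enumerate(ordered, start=1):
        span = bleb_site_width(state, node, profile=e)
        ang = float(angles[node]) if angles is not None else float("nan")
        sites.append(
            BlebSitePrediction(
                nucleation_node=int(node),
                rank=rank,
                extension=float(state.extensions[node]),
                width_span=span,
                angle_deg=ang,
            )
        )
    return sites


def predict(
    contour: Contour,
    params: Optional[ModelParams] = None,
    gradient: Optional[tuple[EllipseFit, float]] = None,
    axis: Optional[EllipseFit] = None,
    smooth: bool = False,
    return_state: bool = False,
):
    """One-call pipeline: initialize, optional stiffness gradient, find the
    sub-critical pressure, relax there, and rank sites with widths/angles.

    ``gradient`` is an (axis, max_increase) pair; ``axis`` alone annotates
    angles without imposing a gradient.  Deterministic for fixed params.
    With ``return_state`` the result is ``(sites, p_sub, relaxed_state)``.
    """
    params = params or ModelParams.default()
    mean_seg = contour.perimeter / contour.n_nodes
    if abs(mean_seg - params.spacing) > 0.01 * params.spacing:
        contour = resample_equidistant(contour, params.spacing)
    state0 = initialize_model(contour, params)
    used_axis = axis
    if gradient is not None:
        g_axis, max_increase = gradient
        used_axis = g_axis if used_axis is None else used_axis
        state0 = apply_linker_gradient(state0, g_axis, max_increase)
    p_sub, relaxed = _subcritical(state0)
    sites = rank_bleb_sites(relaxed, axis=used_axis, smooth=smooth)
    if return_state:
        return sites, p_sub, relaxed
    return sites
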