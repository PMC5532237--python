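"""Cortical-fluorescence profiles and the front-to-rear linker gradient.

Membrane-cortex linker proteins such as Talin accumulate at the rear of
migrating cells.  Given per-node cortical intensities (e.g. a TalA-mNeon
channel sampled along the segmented outline), this module normalizes them
per cell, expresses them as angular profiles about the polarization axis,
fits the front-to-rear exponential gradient

    I(theta) = A * exp(B * |theta| / 180),    theta in [-180, 180] from the front,

and correlates observed bleb frequency with local fluorescence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .contours import (
    ContourSeries,
    EllipseFit,
    PolarizationError,
    angular_positions,
    fit_polarization_axis,
)
from .detection import DetectedBleb

logger = logging.getLogger(__name__)

__all__ = [
    "FluorescenceProfile",
    "ExponentialFit",
    "FluorescenceCorrelation",
    "normalize_per_cell",
    "fit_exponential_gradient",
    "bleb_fluorescence_correlation",
]


@dataclass
class FluorescenceProfile:
    """Per-node normalized intensity and angular position for one frame."""

    frame_index: int
    intensity: np.ndarray  # normalized to [0, 1] over the whole cell
    angle_deg: np.ndarray  # [0, 360), 0 at the cell front


@dataclass
class ExponentialFit:
    """Result of the exponential front-to-rear gradient fit.

    The fitted model is ``I = amplitude * exp(rate * x) + offset`` with
    x = |theta|/180.  The free additive offset makes the rate invariant
    under the affine per-cell min-max normalization (and absorbs detector
    background), so the gradient steepness is comparable across cells.
    """

    amplitude: float  # A
    rate: float  # B
    r_squared: float
    offset: float  # fitted additive constant C


@dataclass
class FluorescenceCorrelation:
    """Bleb counts binned by normalized fluorescence plus rank correlation."""

    counts: np.ndarray
    bin_edges: np.ndarray
    spearman_rho: float  # NaN when undefined (no blebs / constant counts)


def _axes_for_series(series: ContourSeries, lookahead: int = 5) -> dict:
    """Polarization axis per frame, reusing the last fittable axis for
    trailing frames where persistent motion cannot be measured."""
    axes: dict = {}
    last: Optional[EllipseFit] = None
    for c in series:
        try:
            last = fit_polarization_axis(series, c.frame_index, lookahead)
        except PolarizationError:
            if last is None:
                continue
        axes[c.frame_index] = last
    missing = [c.frame_index for c in series if c.frame_index not in axes]
    if missing:
        raise PolarizationError(
            f"no polarization axis could be fitted for frames {missing}"
        )
    return axes


def normalize_per_cell(
    series: ContourSeries, axes: Optional[dict] = None
) -> list[FluorescenceProfile]:
    """Min-max normalize intensities pooled over all frames of one cell.

    The minimum maps to 0 and the maximum to 1 across the whole series (not
    per frame).  A constant raw signal maps to 0.5 everywhere with a logged
    warning.  ``axes`` maps frame indices to :class:`EllipseFit`; when
    omitted, axes are fitted from persistent motion.
    """
    if not series.has_intensity:
        raise ValueError("series has no intensity channel")
    if axes is None:
        axes = _axes_for_series(series)
    pooled_min = min(float(c.intensity.min()) for c in series)
    pooled_max = max(float(c.intensity.max()) for c in series)
    span = pooled_max - pooled_min
    constant = span <= 0
    if constant:
        logger.warning("constant fluorescence signal: mapping all values to 0.5")
    profiles = []
    for c in series:
        if constant:
            norm = np.full(c.n_nodes, 0.5)
        else:
            norm = (c.intensity - pooled_min) / span
        profiles.append(
            FluorescenceProfile(
                frame_index=c.frame_index,
                intensity=norm,
                angle_deg=angular_positions(c, axes[c.frame_index]),
            )
        )
    return profiles


def fit_exponential_gradient(
    profiles: Sequence[FluorescenceProfile], fold: bool = True
) -> ExponentialFit:
    """Least-squares fit of the exponential front-to-rear gradient.

    With ``fold=True`` (default) the angle from the front is folded to
    |theta| in [0, 180], pooling both flanks of the cell; ``fold=False``
    uses the unfolded angle theta in [0, 360) scaled by 360 instead.
    """
    ang = np.concatenate([p.angle_deg for p in profiles])
    inten = np.concatenate([p.intensity for p in profiles]).astype(float)
    if len(inten) < 20:
        raise ValueError(f"need at least 20 (angle, intensity) points, got {len(inten)}")
    if fold:
        theta = np.abs(((ang + 180.0) % 360.0) - 180.0)  # [0, 180]
        xdata = theta / 180.0
    else:
        xdata = (ang % 360.0) / 360.0
    ss_tot = float(np.sum((inten - inten.mean()) ** 2))
    if ss_tot < 1e-24:  # constant signal: no gradient to fit
        return ExponentialFit(0.0, 0.0, 0.0, float(inten.mean()))
    # initial guess: shift positive, then log-linear regression
    shift = max(0.0, 1e-6 - float(inten.min()))
    slope, logint = np.polyfit(xdata, np.log(inten + shift + 1e-12), 1)
    p0 = (float(np.exp(logint)), float(slope), -shift)

    def model(x, a, b, c):
        return a * np.exp(b * x) + c

    try:
        popt, _ = optimize.curve_fit(model, xdata, inten, p0=p0, maxfev=20000)
    except RuntimeError:
        popt = p0
    resid = inten - model(xdata, *popt)
    ss_res = float(np.sum(resid**2))
    r2 = 1.0 - ss_res / ss_tot
    return ExponentialFit(
        amplitude=float(popt[0]), rate=float(popt[1]),
        r_squared=r2, offset=float(popt[2]),
    )


def bleb_fluorescence_correlation(
    blebs: Sequence[DetectedBleb],
    profiles: Sequence[FluorescenceProfile],
    n_bins: int = 10,
) -> FluorescenceCorrelation:
    """Bleb frequency across equal-width normalized-fluorescence bins.

    Each bleb contributes the normalized fluorescence at its nucleation
    node (the farthest protruding node of its frame); the Spearman rank
    correlation is between bin centres and per-bin bleb counts.  With zero
    blebs the histogram is empty and the correlation NaN (flagged by a
    warning).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    by_frame = {p.frame_index: p for p in profiles}
    values = []
    for b in blebs:
        prof = by_frame.get(b.frame_index)
        if prof is None:
            logger.warning("bleb frame %s has no fluorescence profile", b.frame_index)
            continue
        values.append(float(prof.intensity[b.farthest_node]))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    if not values:
        logger.warning("no blebs: fluorescence correlation undefined")
        return FluorescenceCorrelation(
            np.zeros(n_bins, dtype=int), edges, float("nan")
        )
    counts, _ = np.histogram(np.clip(values, 0.0, 1.0), bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if np.all(counts == counts[0]):
        rho = float("nan")
    else:
        rho = float(stats.spearmanr(centers, counts).statistic)
    return FluorescenceCorrelation(counts, edges, rho)
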