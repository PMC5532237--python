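"""Seeded generators for synthetic cell contours, blebbing series and
fluorescence gradients.

Shapes are defined as smooth polar curves r(phi) about the cell centre and
then resampled to equidistant nodes:

* ``circle`` / ``ellipse`` -- the obvious parametric forms (major axis x).
* ``notched_circle`` -- a circle with Gaussian radial indentations
  r(phi) = R - depth * exp(-(phi - phi0)^2 / (2 w^2)), giving a single
  concave region of controllable minimum curvature (analytically
  differentiable, so tests can check curvature against the generator).
* ``polarized_cell`` -- an elongated ellipse (circularity < 0.6) with
  concave Gaussian flank indentations adjacent to a rounded front bump and
  a rounded rear, emulating the shape of a polarized migrating cell.

Blebbing time series morph a base shape with slow drift and low-amplitude
wobble (well below the fast-expansion detection threshold) and plant
single-frame outward bumps of stated amplitude and angular width as ground
truth blebs; slow pseudopods grow gradually at a per-frame rate.  The
fluorescence generator paints the rear-enriched exponential gradient
I = A exp(B |theta|/180) + Gaussian noise along each contour.  Everything
is exactly reproducible from (spec, seed); seeds are explicit fields, never
global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .contours import Contour, ContourSeries, resample_equidistant

__all__ = [
    "FixtureSpec",
    "GeneratorError",
    "make_contour",
    "make_bleb_series",
    "make_fluorescence",
    "generator_curvature",
]


class GeneratorError(ValueError):
    """Fixture parameters produce an invalid (self-intersecting) contour."""


@dataclass
class FixtureSpec:
    """Parameters of one synthetic fixture; reproducible from (spec, seed).

    ``planted_blebs`` rows are (frame, angle_deg, amplitude_um, width_deg);
    ``planted_pseudopods`` rows are (angle_deg, rate_um_per_frame,
    width_deg); ``notches`` rows are (angle_deg, depth_um, width_deg) and
    apply to ``notched_circle`` (the first notch is the primary one).
    """

    shape: str = "circle"
    radius: float = 5.0
    semi_major: float = 9.0
    semi_minor: float = 2.75
    notches: tuple = ((90.0, 1.0, 25.0),)
    flank_depth: float = 1.0
    rear_flank_depth: Optional[float] = None  # defaults to flank_depth
    flank_width_deg: float = 18.0
    front_flank_angle_deg: float = 45.0
    rear_flank_angle_deg: float = 135.0
    polar_notches: tuple = ()  # extra (angle, depth, width) dips, polarized_cell
    n_frames: int = 1
    frame_interval: float = 0.5
    drift_um_per_frame: float = 0.1
    drift_angle_deg: float = 0.0
    scale_per_frame: float = 1.0
    wobble_amplitude_um: float = 0.03
    planted_blebs: tuple = ()
    planted_pseudopods: tuple = ()
    fluor_amplitude: float = 0.2
    fluor_rate: float = 1.5
    fluor_sigma: float = 0.0
    spacing: float = 0.3
    rng_seed: int = 0

    def to_file(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_file(cls, path) -> "FixtureSpec":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("notches", "planted_blebs", "planted_pseudopods", "polar_notches"):
            if key in data and data[key] is not None:
                data[key] = tuple(tuple(row) for row in data[key])
        return cls(**data)


_SHAPES = ("circle", "ellipse", "notched_circle", "polarized_cell")
_DENSE = 2048


def _wrap_angle(delta: np.ndarray) -> np.ndarray:
    """Wrap angle differences to (-pi, pi]."""
    return np.mod(delta + math.pi, 2.0 * math.pi) - math.pi


def _gauss_dip(phi, angle_deg, depth, width_deg):
    d = _wrap_angle(phi - math.radians(angle_deg))
    w = math.radians(width_deg)
    return depth * np.exp(-(d**2) / (2.0 * w * w))


def _gauss_bump(phi, angle_deg, amplitude, width_deg):
    """Gaussian bump truncated at 3 widths so planted protrusions have
    compact support (pure tails would leave the whole contour microscopically
    outside the previous frame)."""
    d = _wrap_angle(phi - math.radians(angle_deg))
    w = math.radians(width_deg)
    cut = math.exp(-4.5)  # value at 3 widths
    g = (np.exp(-(d**2) / (2.0 * w * w)) - cut) / (1.0 - cut)
    return amplitude * np.clip(g, 0.0, None)


def _base_radius(spec: FixtureSpec, phi: np.ndarray) -> np.ndarray:
    if spec.shape == "circle":
        return np.full_like(phi, spec.radius)
    if spec.shape == "ellipse":
        a, b = spec.semi_major, spec.semi_minor
        return a * b / np.sqrt((b * np.cos(phi)) ** 2 + (a * np.sin(phi)) ** 2)
    if spec.shape == "notched_circle":
        r = np.full_like(phi, spec.radius)
        for angle_deg, depth, width_deg in spec.notches:
            r = r - _gauss_dip(phi, angle_deg, depth, width_deg)
        return r
    if spec.shape == "polarized_cell":
        a, b = spec.semi_major, spec.semi_minor
        r = a * b / np.sqrt((b * np.cos(phi)) ** 2 + (a * np.sin(phi)) ** 2)
        rear_depth = (spec.rear_flank_depth if spec.rear_flank_depth is not None
                      else spec.flank_depth)
        r = r - _gauss_dip(phi, spec.front_flank_angle_deg, spec.flank_depth,
                           spec.flank_width_deg)
        r = r - _gauss_dip(phi, spec.rear_flank_angle_deg, rear_depth,
                           spec.flank_width_deg)
        for angle_deg, depth, width_deg in spec.polar_notches:
            r = r - _gauss_dip(phi, angle_deg, depth, width_deg)
        return r
    raise ValueError(f"unknown shape {spec.shape!r}; expected one of {_SHAPES}")


def _polyline(spec: FixtureSpec, r: np.ndarray, phi: np.ndarray,
              center: np.ndarray, frame: int) -> Contour:
    if (r <= 0).any():
        raise GeneratorError("radial function is non-positive: shape parameters too deep")
    xy = np.column_stack([r * np.cos(phi), r * np.sin(phi)]) + center
    dense = Contour(frame, xy)
    out = resample_equidistant(dense, spec.spacing)
    if not out.is_simple:
        raise GeneratorError("generated contour self-intersects")
    return out


def make_contour(spec: FixtureSpec, frame: int = 0) -> Contour:
    """Generate one contour of the requested shape, resampled at
    ``spec.spacing``."""
    phi = np.linspace(0.0, 2.0 * math.pi, _DENSE, endpoint=False)
    r = _base_radius(spec, phi)
    return _polyline(spec, r, phi, np.zeros(2), frame)


def generator_curvature(spec: FixtureSpec, phi: np.ndarray) -> np.ndarray:
    """Signed curvature of the generating polar curve at angles ``phi``.

    Dense central differences (d phi = 1e-5) of the exact radial function
    feed the polar curvature formula
    kappa = (r^2 + 2 r'^2 - r r'') / (r^2 + r'^2)^(3/2);
    an oracle for the discrete curvature estimator, independent of the
    resampled polygon.
    """
    phi = np.asarray(phi, dtype=float)
    dphi = 1e-5
    r = _base_radius(spec, phi)
    rp = (_base_radius(spec, phi + dphi) - _base_radius(spec, phi - dphi)) / (2 * dphi)
    rpp = (
        _base_radius(spec, phi + dphi) - 2.0 * r + _base_radius(spec, phi - dphi)
    ) / (dphi * dphi)
    return (r * r + 2.0 * rp * rp - r * rpp) / np.power(r * r + rp * rp, 1.5)


def make_bleb_series(spec: FixtureSpec) -> tuple[ContourSeries, pd.DataFrame]:
    """Blebbing time series with planted ground truth.

    Frame-to-frame morphing combines centroid drift, optional uniform
    scaling, and a slowly evolving low-amplitude radial wobble -- all well
    below the fast-expansion threshold -- while planted blebs appear as
    single-frame outward Gaussian bumps (persisting afterwards, as a real
    bleb leaves the contour advanced) and pseudopods grow linearly per
    frame.  Returns the series and the truth table (frame, angle_deg,
    amplitude_um).
    """
    blebs = list(spec.planted_blebs)
    for i, (fa, aa, _, wa) in enumerate(blebs):
        for fb, ab, _, wb in blebs[i + 1:]:
            if fb != fa:
                continue
            sep = abs(float(_wrap_angle(np.array([math.radians(aa - ab)]))[0]))
            if math.degrees(sep) < (wa + wb):
                raise GeneratorError(
                    f"planted blebs in frame {fa} overlap closer than their widths"
                )
    rng = np.random.default_rng(spec.rng_seed)
    phi = np.linspace(0.0, 2.0 * math.pi, _DENSE, endpoint=False)
    base = _base_radius(spec, phi)
    modes = np.array([2, 3, 5])
    amps = spec.wobble_amplitude_um * rng.uniform(0.5, 1.0, size=modes.size)
    phases = rng.uniform(0.0, 2.0 * math.pi, size=modes.size)
    drift_dir = np.array(
        [math.cos(math.radians(spec.drift_angle_deg)),
         math.sin(math.radians(spec.drift_angle_deg))]
    )
    contours = []
    truth_rows = []
    for f in range(spec.n_frames):
        r = base * (spec.scale_per_frame ** f)
        if spec.wobble_amplitude_um > 0:
            for m, amp, ph in zip(modes, amps, phases):
                r = r + amp * np.cos(m * phi + ph + 0.15 * f)
        for angle_deg, rate, width_deg in spec.planted_pseudopods:
            r = r + _gauss_bump(phi, angle_deg, rate * f, width_deg)
        for frame_b, angle_deg, amplitude, width_deg in spec.planted_blebs:
            if f >= frame_b:
                r = r + _gauss_bump(phi, angle_deg, amplitude, width_deg)
        center = spec.drift_um_per_frame * f * drift_dir
        contours.append(_polyline(spec, r, phi, center, f))
    for frame_b, angle_deg, amplitude, width_deg in spec.planted_blebs:
        truth_rows.append(
            {"frame": int(frame_b), "angle_deg": float(angle_deg),
             "amplitude_um": float(amplitude)}
        )
    truth = pd.DataFrame(truth_rows, columns=["frame", "angle_deg", "amplitude_um"])
    return ContourSeries(contours, spec.frame_interval), truth


def make_fluorescence(spec: FixtureSpec, series: ContourSeries) -> ContourSeries:
    """Attach a rear-enriched exponential intensity channel to a series.

    Node angles are measured from the generator's known front direction
    (the drift direction) about each contour's centroid; intensity is
    A exp(B |theta|/180) plus seeded Gaussian noise of s.d.
    ``fluor_sigma``.
    """
    rng = np.random.default_rng(spec.rng_seed + 1)
    front = np.array(
        [math.cos(math.radians(spec.drift_angle_deg)),
         math.sin(math.radians(spec.drift_angle_deg))]
    )
    contours = []
    for c in series:
        v = c.nodes - c.centroid
        ang = np.degrees(
            np.arctan2(front[0] * v[:, 1] - front[1] * v[:, 0],
                       front[0] * v[:, 0] + front[1] * v[:, 1])
        )
        folded = np.abs(ang)  # |theta| in [0, 180]
        inten = spec.fluor_amplitude * np.exp(spec.fluor_rate * folded / 180.0)
        if spec.fluor_sigma > 0:
            inten = inten + rng.normal(0.0, spec.fluor_sigma, size=c.n_nodes)
        contours.append(Contour(c.frame_index, c.nodes.copy(), inten))
    return ContourSeries(contours, series.frame_interval)
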