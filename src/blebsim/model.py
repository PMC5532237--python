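"""Membrane-cortex-linker mechanics on a segmented cell contour.

The cell membrane is a closed chain of N nodes coupled by linear springs to
a rigid actin cortex, a parallel contour offset inward by the relaxed linker
length L0 (30 nm).  The total membrane energy is the discrete sum of

* tension      1/2 (alpha/h) (l_i - x0_i)^2      per segment,
* bending      1/2 beta |x_{i+1} - 2 x_i + x_{i-1}|^2 / h^3   per node,
* coupling     1/2 k_i (L_i - L0)^2              per intact linker,
* pressure     -delta_p * A(membrane),

where l_i are segment lengths, L_i linker lengths, h the reference node
spacing and A the enclosed area.  Each discrete linker coarse-grains the
ensemble of molecular linkers over one arc-length interval, so its spring
constant is the stiffness density times the spacing, k_i = k h; together
with the 1/h tension scaling this makes the energy density -- and hence
the sub-critical pressure and site ranking -- independent of the mesh.  The pressure enters as mechanical work so
that its variational derivative is an outward normal force of magnitude
delta_p per unit contour length -- intracellular pressure acts on the
membrane but not on the porous cortex.  The membrane is relaxed against the
fixed cortex by gradient descent with a backtracking line search; linkers
stretched beyond the critical extension L_crit break permanently (the cortex
does not remodel on the blebbing timescale, so there is no rebinding).

Bleb expansion after detachment is overdamped: node velocity equals force
over a Stokes drag coefficient gamma = 6 pi eta R, with R the radius of the
circular arc fitted to the detached membrane span.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
from shapely.geometry import LinearRing

from .contours import Contour, ContourValidationError, EllipseFit

logger = logging.getLogger(__name__)

__all__ = [
    "ModelParams",
    "LinkerSet",
    "ModelState",
    "NumericalStateError",
    "initialize_model",
    "total_energy",
    "energy_terms",
    "relax_membrane",
    "apply_linker_gradient",
    "expand_bleb_dynamics",
    "stokes_drag",
]


class NumericalStateError(RuntimeError):
    """The model state contains non-finite values."""


_INT_KEYS = {"max_iters", "rng_seed"}
_STR_KEYS = {"x0_mode"}


@dataclass
class ModelParams:
    """Physical constants and numerical settings of the contour model.

    Lengths are um.  ``x0_mode`` is either ``"initial"`` (segment rest
    lengths taken from the input contour, i.e. a tension-free start) or a
    number parsed as a fixed rest length.  ``L_crit`` is the critical linker
    *extension* beyond ``L0`` at which a linker breaks.  ``grad_tol`` is the
    convergence threshold on the maximum node displacement per descent step
    (default 1e-4 x spacing); ``descent_step`` is the initial and maximum
    line-search step.  ``p_start`` seeds the auto-bracketing of the
    sub-critical pressure search and ``dt`` is the expansion-dynamics time
    step.
    """

    alpha: float = 1.0
    beta: float = 0.01
    k: float = 1.0
    delta_p: float = 0.0
    x0_mode: str = "initial"
    L0: float = 0.03
    L_crit: float = 0.015
    eta: float = 1e-3
    spacing: float = 0.3
    descent_step: float = 0.05
    grad_tol: float = 3e-5
    max_iters: int = 40000
    rng_seed: int = 0
    p_start: float = 0.01
    dt: float = 2e-4

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "k", "L0", "eta", "spacing", "L_crit",
                     "descent_step", "grad_tol", "dt", "p_start"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.delta_p < 0:
            raise ValueError("delta_p must be non-negative")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.x0_mode != "initial":
            try:
                float(self.x0_mode)
            except ValueError as exc:
                raise ValueError(
                    f"x0_mode must be 'initial' or a number, got {self.x0_mode!r}"
                ) from exc

    # -- construction -----------------------------------------------------

    @classmethod
    def default(cls) -> "ModelParams":
        """Defaults loaded from the packaged parameter file."""
        ref = resources.files("blebsim").joinpath("data/default_params.txt")
        with resources.as_file(ref) as p:
            return cls.from_file(p)

    @classmethod
    def from_file(cls, path) -> "ModelParams":
        """Parse a flat ``key = value`` parameter file."""
        kwargs = {}
        known = {f.name for f in dataclasses.fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
            if key in _STR_KEYS:
                kwargs[key] = value
            elif key in _INT_KEYS:
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)

    def to_file(self, path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in dataclasses.fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    # -- helpers ----------------------------------------------------------

    def replace(self, **kwargs) -> "ModelParams":
        return dataclasses.replace(self, **kwargs)

    def with_spacing(self, spacing: float) -> "ModelParams":
        """Change the node spacing, rescaling grad_tol to 1e-4 x spacing."""
        return self.replace(spacing=spacing, grad_tol=1e-4 * spacing)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class LinkerSet:
    """Per-linker stiffness, rest length, current length and broken flag.

    Exactly one linker per membrane-cortex node pair; a broken linker exerts
    zero force thereafter.
    """

    stiffness: np.ndarray
    rest_length: float
    lengths: np.ndarray
    broken: np.ndarray

    @property
    def extensions(self) -> np.ndarray:
        return self.lengths - self.rest_length

    def copy(self) -> "LinkerSet":
        return LinkerSet(
            self.stiffness.copy(), self.rest_length,
            self.lengths.copy(), self.broken.copy(),
        )


@dataclass
class ModelState:
    """Membrane, fixed cortex, linkers and bookkeeping of one simulation."""

    membrane: Contour
    cortex: Contour
    linkers: LinkerSet
    params: ModelParams
    x0: np.ndarray  # per-segment rest lengths
    energy: float
    iterations: int = 0
    converged: bool = True
    break_order: list = field(default_factory=list)  # node indices, in order broken

    @property
    def n_nodes(self) -> int:
        return self.membrane.n_nodes

    @property
    def extensions(self) -> np.ndarray:
        return self.linkers.extensions

    def copy(self) -> "ModelState":
        return ModelState(
            self.membrane.copy(), self.cortex, self.linkers.copy(), self.params,
            self.x0.copy(), self.energy, self.iterations, self.converged,
            list(self.break_order),
        )


# ---------------------------------------------------------------------------
# Energy and gradient on raw arrays
# ---------------------------------------------------------------------------


def _energy_terms(x, cortex, ki, broken, x0, p: ModelParams):
    seg = np.roll(x, -1, axis=0) - x
    ell = np.linalg.norm(seg, axis=1)
    e_tension = 0.5 * (p.alpha / p.spacing) * float(np.sum((ell - x0) ** 2))
    d2 = np.roll(x, -1, axis=0) - 2.0 * x + np.roll(x, 1, axis=0)
    h3 = p.spacing ** 3
    e_bending = 0.5 * p.beta * float(np.sum(d2 * d2)) / h3
    dv = x - cortex
    L = np.linalg.norm(dv, axis=1)
    intact = ~broken
    e_coupling = 0.5 * float(np.sum(ki[intact] * (L[intact] - p.L0) ** 2))
    xs, ys = x[:, 0], x[:, 1]
    area = 0.5 * float(np.sum(xs * np.roll(ys, -1) - np.roll(xs, -1) * ys))
    e_pressure = -p.delta_p * area
    return e_tension, e_bending, e_coupling, e_pressure


def _energy(x, cortex, ki, broken, x0, p: ModelParams) -> float:
    return sum(_energy_terms(x, cortex, ki, broken, x0, p))


def _grad(x, cortex, ki, broken, x0, p: ModelParams) -> np.ndarray:
    n = len(x)
    g = np.zeros_like(x)
    # tension
    seg = np.roll(x, -1, axis=0) - x
    ell = np.linalg.norm(seg, axis=1)
    u = seg / ell[:, None]
    t = (p.alpha / p.spacing) * (ell - x0)[:, None] * u
    g += np.roll(t, 1, axis=0) - t
    # bending
    d2 = np.roll(x, -1, axis=0) - 2.0 * x + np.roll(x, 1, axis=0)
    g += (p.beta / p.spacing ** 3) * (
        np.roll(d2, 1, axis=0) - 2.0 * d2 + np.roll(d2, -1, axis=0)
    )
    # linker coupling
    dv = x - cortex
    L = np.linalg.norm(dv, axis=1)
    safe = np.where(L > 1e-12, L, 1.0)
    coeff = np.where((~broken) & (L > 1e-12), ki * (L - p.L0) / safe, 0.0)
    g += coeff[:, None] * dv
    # pressure work  -delta_p * A
    if p.delta_p != 0.0:
        xs, ys = x[:, 0], x[:, 1]
        gA = 0.5 * np.column_stack(
            [np.roll(ys, -1) - np.roll(ys, 1), np.roll(xs, 1) - np.roll(xs, -1)]
        )
        g -= p.delta_p * gA
    return g


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def initialize_model(contour: Contour, params: Optional[ModelParams] = None) -> ModelState:
    """Build membrane, cortex and homogeneous linkers from a contour.

    The cortex is the inward normal offset of the membrane by L0, with the
    same node count; every linker starts at rest (length L0, extension 0).
    With ``x0_mode = "initial"`` the segment rest lengths equal the initial
    segment lengths, so the initial state carries no tension.
    """
    params = params or ModelParams.default()
    xy = contour.nodes
    mean_seg = contour.perimeter / contour.n_nodes
    if abs(mean_seg - params.spacing) > 0.25 * params.spacing:
        logger.warning(
            "mean node spacing %.4g um differs from params.spacing %.4g um; "
            "resample the contour first", mean_seg, params.spacing,
        )
    tang = np.roll(xy, -1, axis=0) - np.roll(xy, 1, axis=0)
    tang /= np.linalg.norm(tang, axis=1)[:, None]
    inward = np.column_stack([-tang[:, 1], tang[:, 0]])
    cortex_xy = xy + params.L0 * inward
    try:
        ring = LinearRing(cortex_xy)
        ok = ring.is_simple and ring.is_valid
    except Exception:
        ok = False
    if not ok:
        raise ContourValidationError(
            "cortex offset self-intersects; contour is pathological at this spacing"
        )
    cortex = Contour(contour.frame_index, cortex_xy)
    if params.x0_mode == "initial":
        x0 = contour.segment_lengths.copy()
    else:
        x0 = np.full(contour.n_nodes, float(params.x0_mode))
    n = contour.n_nodes
    linkers = LinkerSet(
        stiffness=np.full(n, params.k * params.spacing),
        rest_length=params.L0,
        lengths=np.linalg.norm(xy - cortex_xy, axis=1),
        broken=np.zeros(n, dtype=bool),
    )
    energy = _energy(xy, cortex_xy, linkers.stiffness, linkers.broken, x0, params)
    logger.info("model initialized: N=%d, params=%s", n, params.as_dict())
    return ModelState(contour.copy(), cortex, linkers, params, x0, energy)


def total_energy(state: ModelState) -> float:
    """Recompute the total membrane energy of a state."""
    x = state.membrane.nodes
    if not np.isfinite(x).all():
        raise NumericalStateError("membrane coordinates are not finite")
    return _energy(
        x, state.cortex.nodes, state.linkers.stiffness, state.linkers.broken,
        state.x0, state.params,
    )


def energy_terms(state: ModelState) -> dict:
    """The four energy contributions, keyed tension/bending/coupling/pressure."""
    et, eb, ec, ep = _energy_terms(
        state.membrane.nodes, state.cortex.nodes, state.linkers.stiffness,
        state.linkers.broken, state.x0, state.params,
    )
    return {"tension": et, "bending": eb, "coupling": ec, "pressure": ep}


def relax_membrane(state: ModelState, allow_breaking: bool = False) -> ModelState:
    """Relax the membrane against the fixed cortex by gradient descent.

    Backtracking line search (step halving) keeps the energy non-increasing
    at every accepted step; convergence is declared when the maximum node
    displacement of a step falls below ``grad_tol``.  With
    ``allow_breaking`` any linker stretched beyond ``L_crit`` is permanently
    marked broken before the next step, in the order the extensions crossed
    the threshold (recorded in ``break_order``).  Returns a new state; the
    ``converged`` flag is False when ``max_iters`` was exhausted.
    """
    p = state.params
    cortex = state.cortex.nodes
    ki = state.linkers.stiffness
    x0 = state.x0
    x = state.membrane.nodes.copy()
    broken = state.linkers.broken.copy()
    break_order = list(state.break_order)
    energy = _energy(x, cortex, ki, broken, x0, p)
    if not np.isfinite(energy):
        raise NumericalStateError("non-finite energy at start of relaxation")
    step = p.descent_step
    converged = False
    it = 0
    for it in range(1, p.max_iters + 1):
        g = _grad(x, cortex, ki, broken, x0, p)
        gmax = float(np.sqrt((g * g).sum(axis=1).max()))
        if gmax == 0.0:
            converged = True
            break
        accepted = False
        while step > p.descent_step * 1e-14:
            xn = x - step * g
            en = _energy(xn, cortex, ki, broken, x0, p)
            if en <= energy:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            # no descent possible at machine-level steps: numerical minimum
            converged = True
            break
        disp = p.descent_step * gmax  # full-size step displacement: step-independent
        x, energy = xn, en
        if allow_breaking:
            L = np.linalg.norm(x - cortex, axis=1)
            newly = (~broken) & (L - p.L0 > p.L_crit)
            if newly.any():
                order = np.argsort(-(L - p.L0))
                for node in order:
                    if newly[node]:
                        break_order.append(int(node))
                broken = broken | newly
                energy = _energy(x, cortex, ki, broken, x0, p)
        step = min(step * 1.5, p.descent_step)
        if disp < p.grad_tol:
            converged = True
            break
    if not converged:
        logger.warning("relaxation did not converge in %d iterations", p.max_iters)
    lengths = np.linalg.norm(x - cortex, axis=1)
    linkers = LinkerSet(ki.copy(), p.L0, lengths, broken)
    membrane = Contour(state.membrane.frame_index, x, state.membrane.intensity)
    return ModelState(
        membrane, state.cortex, linkers, p, x0.copy(), energy,
        iterations=it, converged=converged, break_order=break_order,
    )


def apply_linker_gradient(
    state: ModelState, axis: EllipseFit, max_increase: float = 0.60
) -> ModelState:
    """Impose an exponential front-to-rear gradient in linker stiffness.

    Each linker gets stiffness ``k * exp(lambda * u)`` where ``u`` in [0, 1]
    is the node's normalized projection onto the major axis (0 at the front
    vertex, 1 at the rear) and ``lambda = ln(1 + max_increase)``, so the
    frontmost linker keeps the baseline stiffness and the rearmost is
    ``(1 + max_increase)`` times stiffer.  Rest lengths are unchanged.
    """
    if max_increase < 0:
        raise ValueError("max_increase must be >= 0")
    proj = (state.membrane.nodes - axis.center) @ axis.front_direction
    span = proj.max() - proj.min()
    if span <= 0:
        raise ValueError("degenerate contour: zero extent along the major axis")
    u = (proj.max() - proj) / span
    lam = math.log1p(max_increase)
    out = state.copy()
    p = state.params
    out.linkers.stiffness = p.k * p.spacing * np.exp(lam * u)
    out.energy = total_energy(out)
    return out


def stokes_drag(eta: float, v: float, R: float) -> float:
    """Stokes drag force 6 pi eta v R on a sphere of radius R at velocity v."""
    return 6.0 * math.pi * eta * v * R


def _broken_spans(broken: np.ndarray) -> list[np.ndarray]:
    """Cyclically contiguous runs of broken linkers, as index arrays."""
    n = len(broken)
    if broken.all():
        return [np.arange(n)]
    if not broken.any():
        return []
    # rotate so position 0 is intact, then split runs
    start = int(np.argmax(~broken))
    rolled = np.roll(broken, -start)
    idx = np.nonzero(rolled)[0]
    splits = np.nonzero(np.diff(idx) > 1)[0] + 1
    return [(chunk + start) % n for chunk in np.split(idx, splits)]


def _arc_radius(pts: np.ndarray, floor: float) -> float:
    """Radius of the least-squares circle through pts (Kasa fit)."""
    if len(pts) < 3:
        return floor
    A = np.column_stack([2.0 * pts[:, 0], 2.0 * pts[:, 1], np.ones(len(pts))])
    b = (pts ** 2).sum(axis=1)
    try:
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    except np.linalg.LinAlgError:
        return floor
    cx, cy, c = sol
    r2 = c + cx * cx + cy * cy
    if not np.isfinite(r2) or r2 <= 0:
        return floor
    return max(float(np.sqrt(r2)), floor)


def expand_bleb_dynamics(
    state: ModelState,
    duration: float,
    output_interval: Optional[float] = None,
) -> list[ModelState]:
    """Overdamped expansion of a detached membrane span under pressure.

    Node velocity is force over a Stokes drag gamma = 6 pi eta R, where R is
    the radius of the circular arc fitted to each detached span (floored at
    one node spacing), recomputed every step; attached nodes feel the same
    elastic and pressure forces plus their intact linkers, with the floor
    drag.  Explicit time stepping, with the step halved whenever it would
    increase the energy; expansion stops early once forces balance.  Returns
    the trajectory sampled at ``output_interval`` (default duration/20),
    ending with the final state.
    """
    if not state.linkers.broken.any():
        raise ValueError("no detached membrane span: at least one broken linker required")
    p = state.params
    cortex = state.cortex.nodes
    ki = state.linkers.stiffness
    x0 = state.x0
    x = state.membrane.nodes.copy()
    broken = state.linkers.broken.copy()
    break_order = list(state.break_order)
    out_int = output_interval if output_interval is not None else duration / 20.0
    gamma_floor = 6.0 * math.pi * p.eta * p.spacing

    def gammas() -> np.ndarray:
        gam = np.full(len(x), gamma_floor)
        for span in _broken_spans(broken):
            R = _arc_radius(x[span], p.spacing)
            gam[span] = 6.0 * math.pi * p.eta * R
        return gam

    def snapshot(t: float) -> ModelState:
        lengths = np.linalg.norm(x - cortex, axis=1)
        return ModelState(
            Contour(state.membrane.frame_index, x.copy()), state.cortex,
            LinkerSet(ki.copy(), p.L0, lengths, broken.copy()), p, x0.copy(),
            _energy(x, cortex, ki, broken, x0, p),
            iterations=state.iterations, converged=True,
            break_order=list(break_order),
        )

    traj = [snapshot(0.0)]
    energy = traj[0].energy
    dt = p.dt
    t = 0.0
    next_out = out_int
    while t < duration:
        g = _grad(x, cortex, ki, broken, x0, p)
        v = -g / gammas()[:, None]
        vmax = float(np.sqrt((v * v).sum(axis=1).max()))
        # stalled once the motion achievable in the remaining time is
        # negligible on the node-spacing scale: forces have balanced
        if vmax * (duration - t) < 0.01 * p.spacing:
            break
        stepped = False
        while dt > p.dt * 1e-9:
            xn = x + dt * v
            en = _energy(xn, cortex, ki, broken, x0, p)
            if en <= energy:
                stepped = True
                break
            dt *= 0.5
        if not stepped:
            break
        x, energy = xn, en
        t += dt
        L = np.linalg.norm(x - cortex, axis=1)
        newly = (~broken) & (L - p.L0 > p.L_crit)
        if newly.any():
            order = np.argsort(-(L - p.L0))
            for node in order:
                if newly[node]:
                    break_order.append(int(node))
            broken = broken | newly
            energy = _energy(x, cortex, ki, broken, x0, p)
        dt = min(dt * 1.5, p.dt)
        if t >= next_out:
            traj.append(snapshot(t))
            next_out += out_int
    traj.append(snapshot(t))
    return traj
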