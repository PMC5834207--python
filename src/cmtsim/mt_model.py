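"""Single-microtubule dynamics: growth rule, encounters, anchoring, ends.

A microtubule is an ordered chain of unit vectors, one per 8 nm tubulin
ring, anchored at its nucleation (minus) end.  Growth appends a vector at
the plus end whose direction is a weighted average of the previous
direction, a fresh isotropic random unit vector (weight ``r_d``) and, when a
directional cue acts, the cue direction (weight ``b_d``).  Treadmilling
arises from stochastic minus-end shrinkage; plus-end catastrophes are
triggered by steep encounters with other microtubules or with the membrane.

These functions are the reference formulation of the rules; the stepping
kernel in :mod:`cmtsim._kernels` applies the identical rules over the whole
network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import SurfaceProbe

ELL_UM = 0.008  # length of one tubulin ring / simulation unit vector, μm


class ModelError(ValueError):
    pass


@dataclass
class GrowthParams:
    """Microtubule dynamics parameters (defaults for interphase plant cells).

    n_p
        nucleation probability per unit surface (one unit = ℓ² = 64 nm²)
        per time step.
    n_s
        probability per step for the minus end to start shrinking.
    r_d
        directional-noise weight; the nominal persistence length is
        ``2 ℓ / r_d²`` (25.6 μm at the default).
    b_d
        directional-cue weight (0 disables the cue term).
    alpha_deg
        encounter threshold angle between filament lines; shallower than
        ``alpha`` zippers, steeper triggers a catastrophe.
    anchoring
        "weak" (volume growth, membrane encounters deflect or kill) or
        "strong" (growth confined to the local tangent plane).
    """

    n_p: float = 4.7e-7
    n_s: float = 1e-3
    r_d: float = 0.025
    b_d: float = 0.0
    alpha_deg: float = 40.0
    anchoring: str = "weak"
    ell: float = ELL_UM
    step_seconds: float = 0.12
    nucleation_direction: str = "tangential"  # or "isotropic"
    interaction_radius: float = 0.025  # μm, tip-to-segment encounter distance
    membrane_distance: float = 0.010   # μm, membrane-rule trigger distance

    def __post_init__(self):
        if not (0.0 <= self.r_d and 0.0 <= self.b_d
                and self.r_d + self.b_d <= 1.0):
            raise ModelError("need 0 <= r_d, b_d and r_d + b_d <= 1")
        if not (0.0 < self.alpha_deg < 90.0):
            raise ModelError("alpha must lie strictly between 0 and 90 deg")
        if self.n_p < 0 or self.n_s < 0 or self.ell <= 0:
            raise ModelError("rates must be >= 0 and ell > 0")
        if self.anchoring not in ("weak", "strong"):
            raise ModelError("anchoring must be 'weak' or 'strong'")
        if self.nucleation_direction not in ("isotropic", "tangential"):
            raise ModelError("nucleation_direction must be "
                             "'isotropic' or 'tangential'")

    @property
    def alpha_rad(self) -> float:
        return math.radians(self.alpha_deg)

    @property
    def persistence_length(self) -> float:
        """Nominal persistence length 2ℓ/r_d² in μm."""
        return 2.0 * self.ell / self.r_d ** 2


@dataclass
class CueField:
    """A directional bias field; ``circumferential`` is hoop-wise around
    ``axis`` (the long axis of an ellipsoid of revolution)."""

    kind: str = "none"  # "none" | "circumferential"
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.kind not in ("none", "circumferential"):
            raise ModelError(f"unknown cue kind {self.kind!r}")
        a = np.linalg.norm(self.axis)
        if self.kind != "none" and not math.isclose(a, 1.0, rel_tol=1e-6):
            object.__setattr__(self, "axis",
                               tuple(np.asarray(self.axis) / a))


@dataclass
class Microtubule:
    """Reference single-filament container for rule-level scenarios.

    ``origin`` is the minus-end anchor; ``directions`` holds one unit vector
    per segment, minus to plus.  Endpoints are the cumulative sum of
    ``ell * direction`` from the origin.
    """

    origin: np.ndarray
    directions: list = field(default_factory=list)
    ell: float = ELL_UM
    minus_shrinking: bool = False
    plus_catastrophe: bool = False

    @property
    def n_segments(self) -> int:
        return len(self.directions)

    @property
    def alive(self) -> bool:
        return self.n_segments > 0

    def endpoints(self) -> np.ndarray:
        if not self.directions:
            return np.empty((0, 3))
        return (np.asarray(self.origin)
                + self.ell * np.cumsum(self.directions, axis=0))

    @property
    def tip(self) -> np.ndarray:
        return self.endpoints()[-1]

    @property
    def tip_direction(self) -> np.ndarray:
        return np.asarray(self.directions[-1])


def random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.normal(size=3)
        n2 = v @ v
        if n2 > 1e-12:
            return v / math.sqrt(n2)


def propose_growth_direction(r_prev, rng, params: GrowthParams,
                             b=None) -> np.ndarray:
    """New growth direction: normalize((1-r_d-b_d) r_prev + r_d u + b_d b).

    ``u`` is a fresh isotropic unit vector; with no cue the ``b_d`` term is
    absent.  Measure-zero zero-norm combinations redraw ``u``.
    """
    r_prev = np.asarray(r_prev, dtype=float)
    b_d = params.b_d if b is not None else 0.0
    bvec = np.zeros(3) if b is None else np.asarray(b, dtype=float)
    w = 1.0 - params.r_d - b_d
    while True:
        u = random_unit_vector(rng)
        v = w * r_prev + params.r_d * u + b_d * bvec
        n2 = v @ v
        if n2 > 1e-18:
            return v / math.sqrt(n2)


def expected_step_correlation(r_d: float) -> float:
    """Exact E[r_{n+1}·r_n] for the noise-only growth rule.

    With u isotropic, c = u·r_prev is uniform on [-1, 1] and the expectation
    reduces to a 1D integral evaluated by adaptive quadrature (used as the
    oracle for the directional-persistence tests; ~ 1 - r_d²/3 at low order).
    """
    from scipy.integrate import quad
    a, b = 1.0 - r_d, r_d
    val, _ = quad(lambda c: 0.5 * (a + b * c)
                  / math.sqrt(a * a + b * b + 2 * a * b * c), -1.0, 1.0)
    return val


def free_growth_correlation(r_d: float, n_steps: int, n_traj: int,
                            seed: int, record_every: int = 50):
    """Mean tangent-tangent correlation of free growth vs. arclength.

    Returns ``(s, corr)`` with ``s`` in segments.  Runs the kernel's own
    direction rule over ``n_traj`` independent trajectories.
    """
    from . import _kernels
    _kernels.seed_rng(seed)
    corr = _kernels.free_walk_correlations(n_traj, n_steps, r_d, record_every)
    s = np.arange(len(corr)) * record_every
    return s, corr


def fit_decay_rate(s, corr) -> float:
    """Per-segment exponential decay rate of a correlation curve (log-linear
    least squares over the positive part)."""
    s = np.asarray(s, dtype=float)
    corr = np.asarray(corr, dtype=float)
    keep = corr > 0.05
    slope, _ = np.polyfit(s[keep], np.log(corr[keep]), 1)
    return -float(slope)


def circumferential_cue(position, axis, center=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Unit cue vector orthoradial to ``axis`` at ``position``.

    b = normalize(axis × radial); undefined on the axis itself.
    """
    position = np.asarray(position, dtype=float)
    axis = np.asarray(axis, dtype=float)
    rad = position - np.asarray(center, dtype=float)
    rad = rad - (rad @ axis) * axis
    n = np.linalg.norm(rad)
    if n < 1e-9:
        raise ModelError("circumferential cue is undefined on the axis")
    b = np.cross(axis, rad / n)
    return b / np.linalg.norm(b)


def classify_encounter(tip_dir, target_dir, alpha_deg: float):
    """Outcome of a tip meeting another filament.

    The angle is measured between undirected lines: the target direction's
    sign is chosen to make the angle acute.  Returns ``("zipper", d)`` with
    the sign-adjusted target direction for angles strictly below ``alpha``,
    else ``("catastrophe", None)``.
    """
    tip_dir = np.asarray(tip_dir, dtype=float)
    target_dir = np.asarray(target_dir, dtype=float)
    c = float(tip_dir @ target_dir)
    if abs(c) > math.cos(math.radians(alpha_deg)):
        return "zipper", target_dir * (1.0 if c >= 0 else -1.0)
    return "catastrophe", None


def apply_strong_anchoring(direction, plane_normal) -> np.ndarray:
    """Project a proposed direction onto the local tangent plane."""
    direction = np.asarray(direction, dtype=float)
    n = np.asarray(plane_normal, dtype=float)
    p = direction - (direction @ n) * n
    norm = np.linalg.norm(p)
    if norm < 1e-9:
        raise ModelError("direction parallel to the surface normal; "
                         "redraw the noise vector upstream")
    return p / norm


def apply_weak_anchoring(tip_endpoint, proposed_dir, probe: SurfaceProbe,
                         params: GrowthParams, rng, surface,
                         b=None, max_retries: int = 32):
    """Membrane rule for a tip within 10 nm of the surface.

    Steeper than ``alpha`` to the tangent plane: catastrophe.  Otherwise the
    proposal is accepted if the new endpoint stays inside (or on) the cell;
    if not, the random vector is redrawn (up to ``max_retries``), finally
    falling back to the tangential projection.  Returns
    ``("catastrophe", None)`` or ``("grow", direction)``.
    """
    tip = np.asarray(tip_endpoint, dtype=float)
    d = np.asarray(proposed_dir, dtype=float)
    n = probe.normal
    if abs(d @ n) > math.sin(math.radians(params.alpha_deg)):
        return "catastrophe", None
    prev = d
    for _ in range(max_retries):
        cand = tip + params.ell * d
        if not surface.contains(cand[None, :])[0]:
            d = propose_growth_direction(prev, rng, params, b=b)
            continue
        return "grow", d
    return "grow", apply_strong_anchoring(d, n)


def nucleate(surface, params: GrowthParams, rng) -> Microtubule:
    """Create a one-segment microtubule at a uniform surface point.

    Weak anchoring draws an isotropic initial direction resampled until it
    points inward (or tangentially); strong anchoring draws a uniform
    tangential direction.  The expected number of nucleations per step is
    ``n_p * area / ell²``.
    """
    pos, normal = surface.sample(1, rng)
    pos, normal = pos[0], normal[0]
    tangential = (params.anchoring == "strong"
                  or params.nucleation_direction == "tangential")
    if tangential:
        while True:
            u = random_unit_vector(rng)
            t = u - (u @ normal) * normal
            nn = np.linalg.norm(t)
            if nn > 1e-6:
                d = t / nn
                break
    else:
        while True:
            d = random_unit_vector(rng)
            if d @ normal <= 1e-12:
                break
    return Microtubule(origin=pos, directions=[d], ell=params.ell)


def expected_nucleations_per_step(params: GrowthParams, area_um2: float) -> float:
    return params.n_p * area_um2 / params.ell ** 2


def minus_end_update(mt: Microtubule, n_s: float, rng) -> Microtubule:
    """Treadmilling minus end: start shrinking with probability ``n_s``;
    once shrinking, remove one segment per step until the filament is gone."""
    if not mt.alive:
        return mt
    if mt.minus_shrinking:
        d0 = mt.directions.pop(0)
        mt.origin = np.asarray(mt.origin) + mt.ell * np.asarray(d0)
    elif rng.random() < n_s:
        mt.minus_shrinking = True
    return mt


def plus_end_update(mt: Microtubule, neighbor_query, surface,
                    params: GrowthParams, rng, cue: CueField | None = None):
    """One plus-end step for a standalone filament; returns the event name.

    ``neighbor_query(tip) -> (segment_endpoint, segment_dir, distance) or
    None`` supplies the nearest other-filament segment.  Mirrors the network
    kernel: catastrophe shrinkage, else encounter test, else membrane rule
    per anchoring mode, else free growth.
    """
    if not mt.alive:
        return "dead"
    if mt.plus_catastrophe:
        mt.directions.pop()
        return "shrink"
    tip = mt.tip
    b = None
    if cue is not None and cue.kind == "circumferential":
        try:
            b = circumferential_cue(tip, cue.axis, cue.center)
        except ModelError:
            b = None
    d = propose_growth_direction(mt.tip_direction, rng, params, b=b)
    hit = neighbor_query(tip) if neighbor_query is not None else None
    if hit is not None and hit[2] < params.interaction_radius:
        outcome, aligned = classify_encounter(mt.tip_direction, hit[1],
                                              params.alpha_deg)
        if outcome == "zipper":
            # the host line becomes the reference direction; the per-step
            # noise applies around it
            mt.directions.append(
                propose_growth_direction(aligned, rng, params, b=b))
            return "zipper"
        mt.plus_catastrophe = True
        return "catastrophe_start"
    if surface is not None:
        probe = surface.probe(tip)
        if params.anchoring == "strong":
            try:
                d = apply_strong_anchoring(d, probe.normal)
            except ModelError:
                d = apply_strong_anchoring(
                    propose_growth_direction(mt.tip_direction, rng, params,
                                             b=b), probe.normal)
            new_tip = surface.probe(tip + params.ell * d).nearest_point
            v = new_tip - tip
            mt.directions.append(v / np.linalg.norm(v))
            return "grow"
        if probe.distance <= params.membrane_distance:
            outcome, d2 = apply_weak_anchoring(tip, d, probe, params, rng,
                                               surface, b=b)
            if outcome == "catastrophe":
                mt.plus_catastrophe = True
                return "catastrophe_start"
            d = d2
            cand = tip + params.ell * d
            if not surface.contains(cand[None, :])[0]:
                # curved-region tangential steps can overshoot the mesh by a
                # sub-nanometre margin; pull the endpoint back to the surface
                near = surface.probe(cand).nearest_point
                d = (near - tip) / np.linalg.norm(near - tip)
    mt.directions.append(d)
    return "grow"
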