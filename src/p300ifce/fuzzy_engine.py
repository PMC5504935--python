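"""Fuzzy decision core of the color extractor.

The angle between a candidate pixel and the seed pixel is fuzzified over
three input sets (negative / zero / positive, triangular-trapezoidal
memberships with breakpoints ``alpha1`` and ``alpha2``), mapped by two rules
to matched / unmatched weights, and defuzzified by the centroid of the
clipped output envelope over the output domain ``[0, pi/2]`` (matched
membership a descending ramp hitting zero at ``rho_u``; unmatched an
ascending ramp starting at ``rho_m``, with ``rho_m + rho_u = pi/2``).  The
candidate is extracted when the crisp output ``delta_rho_f`` falls below the
per-object threshold ``sigma``.

The centroid is computed analytically on the piecewise-linear envelope; a
trapezoid-rule integrator over a uniform grid is provided as an independent
numeric cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .color_pattern import vector_angle

__all__ = [
    "HALF_PI",
    "FuzzyParams",
    "RuleWeights",
    "ZeroAreaError",
    "input_memberships",
    "output_memberships",
    "rule_weights",
    "defuzzify",
    "defuzzify_numeric",
    "match_decision",
    "angle_match_threshold",
]

HALF_PI = math.pi / 2.0


class ZeroAreaError(ValueError):
    """Centroid undefined: both rule weights are zero (empty envelope)."""


@dataclass(frozen=True)
class FuzzyParams:
    """Per-object fuzzy parameters.

    Parameters
    ----------
    alpha1, alpha2 : float
        Input membership breakpoints in radians; the zero (matched) set is
        full below ``alpha1`` and empty above ``alpha2``.
    rho_m : float
        Start of the unmatched output ramp, radians.  The matched ramp ends
        at ``rho_u = pi/2 - rho_m``.
    sigma : float
        Extraction threshold on the defuzzified output, radians.
    r : float
        Squared-RGB-distance gate for region growing (squared 8-bit
        intensity units); ``inf`` disables the gate.
    gap_threshold : int
        Row/column gap-filling threshold in pixels (strict: runs shorter
        than this are filled).
    """

    alpha1: float
    alpha2: float
    rho_m: float
    sigma: float
    r: float = 1000.0
    gap_threshold: int = 3

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha1 < self.alpha2 <= HALF_PI):
            raise ValueError(f"need 0 < alpha1 < alpha2 <= pi/2, got {self.alpha1}, {self.alpha2}")
        if not (0.0 < self.rho_m < HALF_PI):
            raise ValueError(f"need 0 < rho_m < pi/2, got {self.rho_m}")
        if not (0.0 < self.sigma < HALF_PI):
            raise ValueError(f"need sigma in (0, pi/2), got {self.sigma}")
        if not self.r > 0:
            raise ValueError(f"need r > 0, got {self.r}")
        if self.gap_threshold < 0:
            raise ValueError(f"need gap_threshold >= 0, got {self.gap_threshold}")

    @property
    def rho_u(self) -> float:
        return HALF_PI - self.rho_m


@dataclass(frozen=True)
class RuleWeights:
    """Matched / unmatched rule firing strengths, each in [0, 1]."""

    matched: float
    unmatched: float

    def __post_init__(self) -> None:
        for name, w in (("matched", self.matched), ("unmatched", self.unmatched)):
            if not (0.0 <= w <= 1.0):
                raise ValueError(f"{name} weight must lie in [0, 1], got {w}")


def input_memberships(x: float, params: FuzzyParams) -> tuple[float, float, float]:
    """Memberships ``(mu_N, mu_Z, mu_P)`` of an angle in the input sets.

    Piecewise linear with half-open (left-closed) breakpoint intervals.
    The negative half of the domain is retained for completeness even
    though RGB vector angles are always >= 0.
    """
    a1, a2 = params.alpha1, params.alpha2
    if not (-HALF_PI <= x <= HALF_PI):
        raise ValueError(f"angle {x} outside [-pi/2, pi/2]")

    if x < -a2:
        mu_n = 1.0
    elif x < -a1:
        mu_n = (x + a1) / (a1 - a2)
    else:
        mu_n = 0.0

    if x < -a2:
        mu_z = 0.0
    elif x < -a1:
        mu_z = (x + a2) / (a2 - a1)
    elif x < a1:
        mu_z = 1.0
    elif x < a2:
        mu_z = (a2 - x) / (a2 - a1)
    else:
        mu_z = 0.0

    if x < a1:  # printed definition leaves [-a1, a1) open; 0 by symmetry with mu_N
        mu_p = 0.0
    elif x < a2:
        mu_p = (x - a1) / (a2 - a1)
    else:
        mu_p = 1.0

    return mu_n, mu_z, mu_p


def output_memberships(x, params: FuzzyParams):
    """Memberships ``(mu_M, mu_U)`` of the output sets at ``x`` in [0, pi/2].

    Vectorized over ``x``.
    """
    x = np.asarray(x, dtype=float)
    rho_u, rho_m = params.rho_u, params.rho_m
    mu_m = np.where(x < rho_u, (rho_u - x) / rho_u, 0.0)
    mu_u = np.where(x < rho_m, 0.0, (x - rho_m) / (HALF_PI - rho_m))
    return mu_m, mu_u


def rule_weights(memberships: tuple[float, float, float]) -> RuleWeights:
    """Apply the two fuzzy rules: matched <- zero; unmatched <- negative|positive."""
    mu_n, mu_z, mu_p = memberships
    return RuleWeights(matched=mu_z, unmatched=max(mu_n, mu_p))


def _envelope_segments(weights: RuleWeights, params: FuzzyParams):
    """Linear segments (x0, x1, y0, y1) of max(min(wm, mu_M), min(wu, mu_U))."""
    wm, wu = weights.matched, weights.unmatched
    rho_u, rho_m = params.rho_u, params.rho_m

    def f1(x: float) -> float:  # matched set clipped at wm
        return min(wm, max(0.0, (rho_u - x) / rho_u))

    def f2(x: float) -> float:  # unmatched set clipped at wu
        return min(wu, max(0.0, (x - rho_m) / (HALF_PI - rho_m)))

    breaks = {0.0, HALF_PI, rho_u, rho_m}
    breaks.add(min(HALF_PI, max(0.0, rho_u * (1.0 - wm))))  # mu_M hits wm
    breaks.add(min(HALF_PI, max(0.0, rho_m + wu * (HALF_PI - rho_m))))  # mu_U hits wu
    xs = sorted(breaks)

    segments = []
    for x0, x1 in zip(xs[:-1], xs[1:]):
        if x1 <= x0:
            continue
        # both clipped memberships are linear on (x0, x1); add their crossing
        y10, y11 = f1(x0), f1(x1)
        y20, y21 = f2(x0), f2(x1)
        pts = [x0, x1]
        denom = (y11 - y10) - (y21 - y20)
        if denom != 0.0:
            t = (y20 - y10) / denom
            if 0.0 < t < 1.0:
                pts.insert(1, x0 + t * (x1 - x0))
        for u0, u1 in zip(pts[:-1], pts[1:]):
            mid = 0.5 * (u0 + u1)
            if f1(mid) >= f2(mid):
                segments.append((u0, u1, f1(u0), f1(u1)))
            else:
                segments.append((u0, u1, f2(u0), f2(u1)))
    return segments


def defuzzify(weights: RuleWeights, params: FuzzyParams) -> float:
    """Centroid of the clipped output envelope (crisp ``delta_rho_f``).

    Exact piecewise-linear integration of ``integral(mu_out * x) /
    integral(mu_out)`` over [0, pi/2].

    Raises
    ------
    ZeroAreaError
        If both rule weights are zero.
    """
    if weights.matched == 0.0 and weights.unmatched == 0.0:
        raise ZeroAreaError("both rule weights are zero; centroid undefined")
    area = 0.0
    moment = 0.0
    for x0, x1, y0, y1 in _envelope_segments(weights, params):
        h = x1 - x0
        if h == 0.0:
            continue
        b = (y1 - y0) / h
        a = y0 - b * x0
        area += a * h + 0.5 * b * (x1 * x1 - x0 * x0)
        moment += 0.5 * a * (x1 * x1 - x0 * x0) + b * (x1**3 - x0**3) / 3.0
    if area <= 0.0:
        raise ZeroAreaError("degenerate envelope with zero area")
    return moment / area


def defuzzify_numeric(weights: RuleWeights, params: FuzzyParams, panels: int = 4096) -> float:
    """Trapezoid-rule centroid on a uniform grid; numeric cross-check for
    :func:`defuzzify` (independent of the segment decomposition)."""
    if weights.matched == 0.0 and weights.unmatched == 0.0:
        raise ZeroAreaError("both rule weights are zero; centroid undefined")
    x = np.linspace(0.0, HALF_PI, panels + 1)
    mu_m, mu_u = output_memberships(x, params)
    env = np.maximum(np.minimum(weights.matched, mu_m), np.minimum(weights.unmatched, mu_u))
    area = np.trapezoid(env, x)
    moment = np.trapezoid(env * x, x)
    return float(moment / area)


def match_decision(p, seed, params: FuzzyParams) -> bool:
    """Full fuzzy chain for one candidate pixel: extract iff
    ``delta_rho_f < sigma``."""
    angle = vector_angle(p, seed)
    w = rule_weights(input_memberships(angle, params))
    return defuzzify(w, params) < params.sigma


def angle_match_threshold(params: FuzzyParams, tol: float = 1e-13) -> float:
    """Critical angle ``a*`` with ``match_decision`` true iff angle < ``a*``.

    ``delta_rho_f`` is nondecreasing and continuous in the input angle, so
    the match set is the interval ``[0, a*)``.  Returns ``-inf`` when even
    a zero angle fails (nothing matches) and ``+inf`` when every angle in
    ``[0, pi/2]`` matches.  Bisection; used to vectorize segmentation.
    """

    def crisp(angle: float) -> float:
        return defuzzify(rule_weights(input_memberships(angle, params)), params)

    sigma = params.sigma
    if crisp(0.0) >= sigma:
        return -math.inf
    if crisp(HALF_PI) < sigma:
        return math.inf
    lo, hi = 0.0, HALF_PI  # crisp(lo) < sigma <= crisp(hi)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if crisp(mid) < sigma:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
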