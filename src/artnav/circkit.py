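"""Circular-statistics primitives for heading-based navigation models.

Conventions
-----------
Angles are in radians, counter-clockwise positive, with 0 along the +x
axis, and are wrapped to the half-open interval (-pi, pi].  The Von Mises
distribution VM(mu, kappa) is the circular analogue of the normal
distribution; ``kappa`` is a concentration (precision) parameter and
``kappa = 0`` denotes the uniform distribution on the circle.

The "circular standard deviation" equivalent of a concentration kappa is

    sd(kappa) = sqrt(-2 * ln Rbar(kappa)),   Rbar = I1(kappa) / I0(kappa),

where Rbar is the mean resultant length and I0, I1 are modified Bessel
functions.  This is the scale on which spread parameters are usually
reported alongside kappa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

TWO_PI = 2.0 * math.pi

__all__ = [
    "TWO_PI",
    "VonMisesComponent",
    "DegenerateMeanError",
    "wrap_angle",
    "bearing",
    "sample_von_mises",
    "circular_sd_from_kappa",
    "kappa_from_circular_sd",
    "weighted_circular_mean",
    "circular_mean_resultant",
]


class DegenerateMeanError(ValueError):
    """Raised when a weighted circular mean has (numerically) zero resultant.

    This happens only for perfectly opposed samples; callers are expected
    to apply their own tie-break (the navigation model retains the
    previous heading).
    """


def wrap_angle(theta: float) -> float:
    """Wrap an angle in radians to the interval (-pi, pi].

    Idempotent and 2*pi-periodic.  Raises ``ValueError`` on non-finite
    input.
    """
    theta = float(theta)
    if not math.isfinite(theta):
        raise ValueError(f"cannot wrap non-finite angle {theta!r}")
    w = math.remainder(theta, TWO_PI)  # in [-pi, pi], banker's rounding
    if w <= -math.pi:
        w += TWO_PI
    return w


def bearing(from_xy: tuple[float, float], to_xy: tuple[float, float]) -> float:
    """Four-quadrant bearing (radians) of ``to_xy`` as seen from ``from_xy``.

    Raises ``ValueError`` for coincident points, where the bearing is
    undefined; callers must handle "already there" separately.
    """
    dx = float(to_xy[0]) - float(from_xy[0])
    dy = float(to_xy[1]) - float(from_xy[1])
    if dx == 0.0 and dy == 0.0:
        raise ValueError("bearing undefined for coincident points")
    return math.atan2(dy, dx)


@dataclass(frozen=True)
class VonMisesComponent:
    """A single Von Mises distribution VM(mu, kappa).

    ``kappa = 0`` encodes the uniform circular distribution (``mu`` is
    then irrelevant).
    """

    mu: float
    kappa: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.mu):
            raise ValueError("mu must be finite")
        if not (self.kappa >= 0.0):
            raise ValueError(f"kappa must be >= 0, got {self.kappa}")
        object.__setattr__(self, "mu", wrap_angle(self.mu))


def sample_von_mises(component: VonMisesComponent, rng: np.random.Generator) -> float:
    """Draw one angle from a Von Mises component.

    ``kappa = 0`` yields a uniform draw on (-pi, pi].  Reproducible under
    a seeded ``numpy.random.Generator``.
    """
    if component.kappa == 0.0:
        return wrap_angle(rng.uniform(-math.pi, math.pi))
    return wrap_angle(component.mu + rng.vonmises(0.0, component.kappa))


def _mean_resultant_length(kappa: float) -> float:
    # exponentially-scaled Bessel ratio avoids overflow for large kappa
    return float(special.i1e(kappa) / special.i0e(kappa))


def circular_sd_from_kappa(kappa: float) -> float:
    """Circular standard deviation sqrt(-2 ln Rbar(kappa)).

    Monotone decreasing in kappa.  ``kappa <= 0`` is rejected: the
    uniform distribution has no finite circular SD.
    """
    kappa = float(kappa)
    if not (kappa > 0.0):
        raise ValueError("kappa must be > 0 for a finite circular SD")
    return math.sqrt(-2.0 * math.log(_mean_resultant_length(kappa)))


def kappa_from_circular_sd(sd: float) -> float:
    """Numerical inverse of :func:`circular_sd_from_kappa`.

    Round-trips with the forward conversion to better than 1e-8 relative
    error over the practically relevant range.
    """
    sd = float(sd)
    if not (sd > 0.0):
        raise ValueError("circular SD must be > 0")
    target = math.exp(-0.5 * sd * sd)  # desired mean resultant length

    def f(kappa: float) -> float:
        return _mean_resultant_length(kappa) - target

    lo, hi = 1e-12, 1.0
    while f(hi) < 0.0:
        hi *= 10.0
        if hi > 1e16:  # pragma: no cover - sd would have to be ~0
            break
    return float(optimize.brentq(f, lo, hi, xtol=1e-14, rtol=1e-13))


def circular_mean_resultant(
    samples, weights
) -> tuple[float, float]:
    """Weighted resultant of unit vectors: returns (angle, resultant length).

    The resultant length is normalised by the weight sum, so it lies in
    [0, 1] for non-negative weights.
    """
    sx = 0.0
    sy = 0.0
    wsum = 0.0
    for a, w in zip(samples, weights, strict=True):
        sx += w * math.cos(a)
        sy += w * math.sin(a)
        wsum += w
    if wsum <= 0.0:
        raise ValueError("weights must have positive sum")
    r = math.hypot(sx, sy) / wsum
    return math.atan2(sy, sx), r


def weighted_circular_mean(samples, weights, *, weight_tol: float = 1e-9) -> float:
    """Weighted circular mean: atan2 of the weight-scaled sums of sines and
    cosines of the samples.

    ``weights`` must be non-negative and sum to 1 within ``weight_tol``.
    Raises :class:`DegenerateMeanError` when the resultant is numerically
    zero (perfectly opposed samples); the caller applies its documented
    tie-break.
    """
    samples = [float(s) for s in samples]
    weights = [float(w) for w in weights]
    if len(samples) != len(weights):
        raise ValueError("samples and weights must have equal length")
    if any(w < 0.0 for w in weights):
        raise ValueError("weights must be non-negative")
    if abs(sum(weights) - 1.0) > weight_tol:
        raise ValueError(f"weights must sum to 1 (got {sum(weights)!r})")
    angle, r = circular_mean_resultant(samples, weights)
    if r < 1e-12:
        raise DegenerateMeanError("resultant length below 1e-12")
    return wrap_angle(angle)
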