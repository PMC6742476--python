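"""Closed-form geometry of spherocylindrical and prolate-spheroidal cells.

Conventions
-----------
* ``w`` is the cell **diameter** (width), not the radius.  A spherocylinder
  is a cylinder of diameter ``w`` capped by two hemispheres; its pole-to-pole
  length ``L`` includes the caps, so ``L >= w`` and the shape degenerates to
  a sphere at ``L == w``.
* Spheroid axes ``a`` (minor) and ``c`` (major) are **semi-axes**.
* The aspect ratio is ``eta = L/w`` for rods and ``eta = c/a`` for spheroids;
  both are >= 1.
* The scaling prefactor is the dimensionless ``gamma = S / V**(2/3)``.  For a
  sphere ``gamma = 6**(2/3) * pi**(1/3) ~= 4.836``, the minimum over both
  shape families; ``gamma`` grows monotonically with elongation.

Mixing radius and diameter conventions silently corrupts ``gamma`` — every
function below takes diameters/semi-axes exactly as stated above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

__all__ = [
    "GAMMA_SPHERE",
    "RodShape",
    "SpheroidShape",
    "rod_surface",
    "rod_volume",
    "gamma_from_eta_rod",
    "eta_from_gamma_rod",
    "spheroid_surface",
    "spheroid_volume",
    "gamma_from_eta_spheroid",
    "rod_dimensions_from_volume",
    "approx_rod_sv_eta4",
]

#: Prefactor S/V^(2/3) of a sphere, the lower bound for both shape families.
GAMMA_SPHERE: float = 6.0 ** (2.0 / 3.0) * math.pi ** (1.0 / 3.0)

# Relative eccentricity below which the spheroid surface switches to the
# sphere formula (removable 0/0 singularity at c == a).
_SPHEROID_SPHERE_TOL = 1e-8


@dataclass(frozen=True)
class RodShape:
    """Spherocylinder: pole-to-pole length ``length`` and diameter ``width``, in um."""

    length: float
    width: float

    def __post_init__(self) -> None:
        if not (self.width > 0.0):
            raise ValueError(f"width must be positive, got {self.width}")
        if self.length < self.width:
            raise ValueError(
                f"invalid spherocylinder: length {self.length} < width {self.width}"
            )

    @property
    def eta(self) -> float:
        """Aspect ratio L/w (>= 1)."""
        return self.length / self.width


@dataclass(frozen=True)
class SpheroidShape:
    """Prolate spheroid with minor/major **semi-axes** ``a`` and ``c``, in um."""

    a: float
    c: float

    def __post_init__(self) -> None:
        if not (self.a > 0.0):
            raise ValueError(f"minor semi-axis must be positive, got {self.a}")
        if self.c < self.a:
            raise ValueError(f"prolate spheroid requires c >= a, got c={self.c}, a={self.a}")

    @property
    def eta(self) -> float:
        """Aspect ratio c/a (>= 1)."""
        return self.c / self.a


def rod_surface(shape: RodShape) -> float:
    """Surface area pi*w*L of a spherocylinder, um^2.

    The cylinder side (pi*w*(L-w)) plus two hemispherical caps (pi*w^2)
    collapse to the single term pi*w*L.
    """
    return math.pi * shape.width * shape.length


def rod_volume(shape: RodShape) -> float:
    """Volume (pi/4)*w^2*L - (pi/12)*w^3 of a spherocylinder, um^3."""
    L, w = shape.length, shape.width
    return math.pi / 4.0 * w * w * L - math.pi / 12.0 * w ** 3


def gamma_from_eta_rod(eta: float) -> float:
    """Prefactor S/V^(2/3) of a spherocylinder with aspect ratio ``eta``.

    gamma(eta) = eta*pi * (eta*pi/4 - pi/12)**(-2/3); strictly increasing,
    gamma(1) = 6^(2/3)*pi^(1/3) (sphere).
    """
    if eta < 1.0:
        raise ValueError(f"spherocylinder aspect ratio must be >= 1, got {eta}")
    return eta * math.pi * (eta * math.pi / 4.0 - math.pi / 12.0) ** (-2.0 / 3.0)


def eta_from_gamma_rod(gamma: float) -> float:
    """Aspect ratio of the spherocylinder whose prefactor S/V^(2/3) is ``gamma``.

    Inverts :func:`gamma_from_eta_rod` by bracketed root-finding (Brent, on
    [1, 1e4], xtol 1e-12); the forward map is strictly increasing so the root
    is unique.  Values within ~1e-9 below the sphere prefactor are accepted
    as the sphere itself (floating-point slack).

    Raises
    ------
    ValueError
        If ``gamma`` lies below the sphere prefactor: no spherocylinder exists.
    """
    if gamma < GAMMA_SPHERE:
        if gamma > GAMMA_SPHERE * (1.0 - 1e-9):
            return 1.0
        raise ValueError(
            f"gamma={gamma} is below the sphere prefactor {GAMMA_SPHERE:.6f}; "
            "no spherocylinder has this surface-to-volume prefactor"
        )
    hi = 1e4
    if gamma >= gamma_from_eta_rod(hi):
        raise ValueError(f"gamma={gamma} exceeds the eta<=1e4 inversion bracket")
    return brentq(lambda e: gamma_from_eta_rod(e) - gamma, 1.0, hi, xtol=1e-12, rtol=1e-14)


def spheroid_surface(shape: SpheroidShape) -> float:
    """Surface area of a prolate spheroid, um^2.

    S = 2*pi*a^2 + 2*pi*a*c^2/sqrt(c^2-a^2) * arcsin(sqrt(c^2-a^2)/c),
    with the sphere formula 4*pi*a^2 below relative eccentricity 1e-8
    (the general expression is 0/0 at c == a).
    """
    a, c = shape.a, shape.c
    if (c - a) / a < _SPHEROID_SPHERE_TOL:
        return 4.0 * math.pi * a * a
    e = math.sqrt(c * c - a * a)
    return 2.0 * math.pi * a * a + 2.0 * math.pi * a * c * c / e * math.asin(e / c)


def spheroid_volume(shape: SpheroidShape) -> float:
    """Volume (4*pi/3)*a^2*c of a prolate spheroid, um^3."""
    return 4.0 * math.pi / 3.0 * shape.a * shape.a * shape.c


def gamma_from_eta_spheroid(eta: float) -> float:
    """Prefactor S/V^(2/3) of a prolate spheroid with aspect ratio ``eta`` = c/a.

    Scale-free: evaluated at (a=1, c=eta).
    """
    if eta < 1.0:
        raise ValueError(f"prolate spheroid aspect ratio must be >= 1, got {eta}")
    s = SpheroidShape(a=1.0, c=eta)
    return spheroid_surface(s) / spheroid_volume(s) ** (2.0 / 3.0)


def rod_dimensions_from_volume(volume: float, eta: float) -> RodShape:
    """The unique spherocylinder with given volume and aspect ratio.

    Solves w^3 * (pi*eta/4 - pi/12) = V in closed form and sets L = eta*w.
    For eta = 4 this is V = (11*pi/12) * w^3 — note the *exact* cubic is used,
    not the rounder approximations of :func:`approx_rod_sv_eta4`.
    """
    if volume <= 0.0:
        raise ValueError(f"volume must be positive, got {volume}")
    if eta < 1.0:
        raise ValueError(f"aspect ratio must be >= 1, got {eta}")
    w = (volume / (math.pi * eta / 4.0 - math.pi / 12.0)) ** (1.0 / 3.0)
    return RodShape(length=eta * w, width=w)


def approx_rod_sv_eta4(width: float) -> tuple[float, float]:
    """Approximate (S, V) of an aspect-ratio-4 rod from its width alone.

    Convenience comparison helper: combining S ~= 2*pi*V^(2/3) with
    S ~= 4*pi*w^2 gives V ~= sqrt(8)*w^3 ~= 2.83*w^3, close to the exact
    spherocylinder value V(eta=4) = (11*pi/12)*w^3 ~= 2.88*w^3.  Use
    :func:`rod_dimensions_from_volume` for exact work; this exists only to
    quantify how rough the back-of-envelope relations are.
    """
    if width <= 0.0:
        raise ValueError(f"width must be positive, got {width}")
    return 4.0 * math.pi * width ** 2, math.sqrt(8.0) * width ** 3
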