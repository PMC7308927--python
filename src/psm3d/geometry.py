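"""Plane and line primitives in the target-centred Cartesian frame.

All lengths are millimetres and all angles radians.  Planes are carried in
Hesse normal form ``n . x = rho`` with the unit normal parameterised by
spherical angles::

    n = (sin(theta) cos(phi), sin(theta) sin(phi), cos(theta))

with ``theta in [0, pi]``, ``phi in [-pi, pi]`` and ``rho >= 0``.  The sign
ambiguity of the normal is removed by a canonical orientation (see
:func:`canonical_hesse`) so that plane equality is testable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateInputError, InvalidPlaneError, NoUniqueLineError

__all__ = [
    "PlaneGeneral",
    "PlaneHesse",
    "LineParam",
    "as_point",
    "canonical_hesse",
    "hesse_from_general",
    "general_from_hesse",
    "eval_plane",
    "plane_from_three_points",
    "line_from_two_planes",
]

#: default tolerance on the cross-product norm (mm^2) below which three
#: points are treated as collinear
COLLINEARITY_TOL = 1e-9


def as_point(p) -> np.ndarray:
    """Coerce array-like into a finite (3,) float vector (mm)."""
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("point has non-finite components")
    return a


@dataclass(frozen=True)
class PlaneGeneral:
    """Plane in general form A x + B y + C z + D = 0."""

    a: float
    b: float
    c: float
    d: float

    @property
    def normal(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c], dtype=float)


@dataclass(frozen=True)
class PlaneHesse:
    """Plane in Hesse normal form, spherical-angle parameterisation.

    ``theta`` is the angle between the normal and +Z; ``phi`` the azimuth of
    the normal's XY projection from +X; ``rho`` the (nonnegative) distance
    of the plane from the origin in mm.
    """

    theta: float
    phi: float
    rho: float

    @property
    def normal(self) -> np.ndarray:
        st = math.sin(self.theta)
        return np.array(
            [st * math.cos(self.phi), st * math.sin(self.phi), math.cos(self.theta)]
        )


@dataclass(frozen=True)
class LineParam:
    """Line given by a point on it and a unit direction."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", as_point(self.point))
        d = as_point(self.direction)
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise ValueError("line direction must be nonzero")
        object.__setattr__(self, "direction", d / n)


def canonical_hesse(normal, rho: float, *, _tiny: float = 1e-12) -> PlaneHesse:
    """Build the canonical :class:`PlaneHesse` from any (normal, rho) pair.

    The normal need not be unit length.  Canonicalisation rules: rho >= 0
    always; when rho == 0 the normal with theta <= pi/2 is taken, and for
    theta == pi/2 the one with phi in (-pi/2, pi/2].  For theta in {0, pi}
    phi is meaningless and set to 0.
    """
    n = np.asarray(normal, dtype=float)
    norm = np.linalg.norm(n)
    if norm < _tiny:
        raise InvalidPlaneError("zero plane normal")
    n = n / norm
    rho = float(rho) / norm

    if rho < -_tiny:
        n, rho = -n, -rho
    elif abs(rho) <= _tiny:
        rho = 0.0
        if n[2] < -_tiny:
            n = -n
        elif abs(n[2]) <= _tiny:  # theta == pi/2: pick phi in (-pi/2, pi/2]
            if n[0] < -_tiny or (abs(n[0]) <= _tiny and n[1] < 0):
                n = -n

    theta = math.acos(max(-1.0, min(1.0, n[2])))
    if math.hypot(n[0], n[1]) <= _tiny:
        phi = 0.0
    else:
        phi = math.atan2(n[1], n[0])
    return PlaneHesse(theta=float(theta), phi=float(phi), rho=float(rho))


def hesse_from_general(p: PlaneGeneral) -> PlaneHesse:
    """Convert A x + B y + C z + D = 0 to canonical Hesse form.

    The plane satisfies ``n . x = rho`` with ``rho = -D / |(A,B,C)|`` before
    canonical sign choice.
    """
    return canonical_hesse(p.normal, -p.d)


def general_from_hesse(plane: PlaneHesse) -> PlaneGeneral:
    """Inverse of :func:`hesse_from_general` (up to scaling)."""
    n = plane.normal
    return PlaneGeneral(a=n[0], b=n[1], c=n[2], d=-plane.rho)


def eval_plane(p, plane: PlaneHesse) -> float:
    """Signed residual (mm) of a point under the plane equation.

    Returns ``x sin(theta)cos(phi) + y sin(theta)sin(phi) + z cos(theta)
    - rho``; zero iff the point lies on the plane, and its absolute value is
    the point-plane distance because the normal is unit.
    """
    return float(np.dot(as_point(p), plane.normal) - plane.rho)


def plane_from_three_points(a, b, c, *, tol: float = COLLINEARITY_TOL) -> PlaneHesse:
    """Canonical plane through three non-collinear points.

    Raises :class:`DegenerateInputError` when the cross-product norm of
    (b - a) x (c - a) is below ``tol`` (mm^2), which also covers duplicated
    points.
    """
    a, b, c = as_point(a), as_point(b), as_point(c)
    n = np.cross(b - a, c - a)
    if np.linalg.norm(n) <= tol:
        raise DegenerateInputError("points are collinear or not distinct")
    return canonical_hesse(n, float(np.dot(n, a)))


def line_from_two_planes(p1: PlaneGeneral, p2: PlaneGeneral,
                         *, tol: float = 1e-9) -> LineParam:
    """Intersection line of two general-form planes.

    Raises :class:`NoUniqueLineError` for parallel or identical planes
    (cross product of the normals below ``tol``).
    """
    n1, n2 = p1.normal, p2.normal
    if np.linalg.norm(n1) < tol or np.linalg.norm(n2) < tol:
        raise InvalidPlaneError("zero plane normal")
    d = np.cross(n1, n2)
    nd = np.linalg.norm(d)
    if nd <= tol:
        raise NoUniqueLineError("planes are parallel or identical")
    d = d / nd
    # Point on both planes: solve the 2x3 system picking the best-conditioned
    # pair of coordinates (least-squares on the stacked system is exact here).
    A = np.vstack([n1, n2])
    rhs = np.array([-p1.d, -p2.d])
    point, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    return LineParam(point=point, direction=d)
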