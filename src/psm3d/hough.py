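"""3D Hough plane detection and the dual-space three-point match.

The classical 3D Hough transform votes every point onto the surface
``rho(theta, phi) = x sin(theta)cos(phi) + y sin(theta)sin(phi) +
z cos(theta)`` in a binned (theta, phi, rho) parameter space; the
highest-count cell is the plane supported by the most points.

The improved variant used for sector matching avoids the full accumulator:
three non-collinear points define exactly one plane, so their three dual
surfaces intersect in a single parameter-space point.  Matching a probe
frame against the sector database therefore reduces to testing, sector by
sector, whether the frame's two probe points lie on the stored sector plane
(equivalently, whether the three-point solution for (A_k, B, C) coincides
with sector k's stored parameters).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import (
    AmbiguousPeakError,
    ConfigError,
    DegenerateInputError,
    InsufficientDataError,
)
from .geometry import PlaneHesse, as_point, canonical_hesse, eval_plane
from .sector_db import SectorDatabase, circular_distance

__all__ = [
    "HoughBinSpec",
    "HoughAccumulator",
    "MatchResult",
    "dual_value",
    "accumulate",
    "detect_plane",
    "solve_three_points",
    "match_sector",
]


@dataclass(frozen=True)
class HoughBinSpec:
    """Binning of the (theta, phi, rho) parameter space.

    theta spans [0, pi], phi spans [-pi, pi], rho spans [0, rho_max];
    defaults of 1 degree / 0.5 mm resolve the finest sector spacing used
    here (2pi/128 = 2.8 degrees).
    """

    d_theta: float = math.radians(1.0)
    d_phi: float = math.radians(1.0)
    d_rho: float = 0.5
    rho_max: float = 50.0

    def __post_init__(self):
        if min(self.d_theta, self.d_phi, self.d_rho) <= 0 or self.rho_max <= 0:
            raise ConfigError("all Hough bin widths and rho_max must be positive")

    @property
    def n_theta(self) -> int:
        return max(1, int(math.ceil(math.pi / self.d_theta - 1e-9)))

    @property
    def n_phi(self) -> int:
        return max(1, int(math.ceil(2.0 * math.pi / self.d_phi - 1e-9)))

    @property
    def n_rho(self) -> int:
        return max(1, int(math.ceil(self.rho_max / self.d_rho - 1e-9)))

    def theta_samples(self) -> np.ndarray:
        """Angle values at which dual surfaces are sampled: i * d_theta.

        Sampling at bin lower edges keeps the exact axis-aligned values
        (theta = 0, phi = 0, ...) on the grid, so planes at those
        orientations vote into a single cell instead of splitting across a
        bin boundary.
        """
        return np.arange(self.n_theta) * (math.pi / self.n_theta)

    def phi_samples(self) -> np.ndarray:
        return -math.pi + np.arange(self.n_phi) * (2.0 * math.pi / self.n_phi)

    def rho_centers(self) -> np.ndarray:
        return (np.arange(self.n_rho) + 0.5) * (self.rho_max / self.n_rho)


@dataclass
class HoughAccumulator:
    spec: HoughBinSpec
    counts: np.ndarray  # (n_theta, n_phi, n_rho) nonnegative ints

    @property
    def total_votes(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching a probe frame against the sector database.

    ``matched`` is False when no sector scored within tolerance; the message
    then carries the standard advice (rebuild with larger delta_v).
    """

    sector_id: int
    score: float
    matched_plane: PlaneHesse | None
    matched: bool
    message: str = ""


def dual_value(p, theta: float, phi: float) -> float:
    """rho coordinate of point ``p``'s dual surface at (theta, phi).

    May be negative; callers decide how to clip to the rho range.
    """
    p = as_point(p)
    st = math.sin(theta)
    return float(p[0] * st * math.cos(phi) + p[1] * st * math.sin(phi)
                 + p[2] * math.cos(theta))


def accumulate(points, spec: HoughBinSpec) -> HoughAccumulator:
    """Vote every point onto its dual surface over the binned grid.

    Each point casts exactly one vote per (theta, phi) bin-centre pair, at
    the rho bin containing its dual value; (theta, phi) cells whose rho
    falls outside [0, rho_max] are skipped.  Empty input yields an all-zero
    accumulator.
    """
    counts = np.zeros((spec.n_theta, spec.n_phi, spec.n_rho), dtype=np.int64)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        return HoughAccumulator(spec=spec, counts=counts)
    if pts.shape[1] != 3:
        raise ValueError("points must be (n, 3)")

    th = spec.theta_samples()
    ph = spec.phi_samples()
    st, ct = np.sin(th), np.cos(th)
    cp, sp = np.cos(ph), np.sin(ph)
    # normal grid components, shape (n_theta, n_phi)
    nx = st[:, None] * cp[None, :]
    ny = st[:, None] * sp[None, :]
    nz = np.broadcast_to(ct[:, None], nx.shape)

    n_rho = spec.n_rho
    bin_w = spec.rho_max / n_rho
    flat = counts.reshape(-1, n_rho)
    cell_index = np.arange(nx.size)
    for p in pts:
        rho = p[0] * nx + p[1] * ny + p[2] * nz
        rho = rho.ravel()
        ok = (rho >= 0.0) & (rho <= spec.rho_max)
        idx = np.minimum((rho[ok] / bin_w).astype(np.int64), n_rho - 1)
        np.add.at(flat, (cell_index[ok], idx), 1)
    return HoughAccumulator(spec=spec, counts=counts)


def detect_plane(points, spec: HoughBinSpec,
                 refine: bool = True) -> tuple[PlaneHesse, int]:
    """Peak of the accumulator as a plane, with its vote count.

    The peak cell's angles are the grid sample values and rho its bin
    centre; ties break to the smallest (theta, phi, rho) bin index
    lexicographically (the first maximum in C order).  With ``refine=True``
    (default) the quantised peak plane is polished by a total-least-squares
    fit to the points within one rho bin of the peak plane, which removes
    the bin-quantisation error (for noiseless planar clouds the result is
    the exact plane, always within a bin width of the truth per
    coordinate).

    Requires >= 3 points; coincident points are rejected because every
    (theta, phi) column then peaks equally at its own rho and the peak
    carries no plane information.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 3:
        raise InsufficientDataError("plane detection needs at least 3 points")
    if np.ptp(pts, axis=0).max() < 1e-12:
        raise AmbiguousPeakError("all points coincident; accumulator peak "
                                 "is ambiguous")
    acc = accumulate(pts, spec)
    flat_idx = int(np.argmax(acc.counts))
    it, ip, ir = np.unravel_index(flat_idx, acc.counts.shape)
    votes = int(acc.counts[it, ip, ir])
    plane = PlaneHesse(
        theta=float(spec.theta_samples()[it]),
        phi=float(spec.phi_samples()[ip]),
        rho=float(spec.rho_centers()[ir]),
    )
    if refine:
        refined = _refine_peak_plane(pts, plane, spec.d_rho)
        if refined is not None:
            plane = refined
    return plane, votes


def _refine_peak_plane(pts: np.ndarray, cell_plane: PlaneHesse,
                       d_rho: float) -> PlaneHesse | None:
    """Total-least-squares plane through the peak cell's inlier points."""
    resid = pts @ cell_plane.normal - cell_plane.rho
    inliers = pts[np.abs(resid) <= d_rho]
    if inliers.shape[0] < 3:
        return None
    centroid = inliers.mean(axis=0)
    _, s, vt = np.linalg.svd(inliers - centroid)
    if s.size < 2 or s[1] <= 1e-12 * max(1.0, s[0]):
        return None  # inliers collinear; keep the quantised peak plane
    n = vt[2]
    return canonical_hesse(n, float(np.dot(n, centroid)))


def solve_three_points(a, b, c) -> tuple[float, float, float]:
    """Simultaneous solution (theta, phi, rho) of the three dual equations.

    Subtracting the equations pairwise eliminates rho and leaves two linear
    constraints on the unit normal; the normal is the null space of the
    2x3 difference matrix (via SVD), a numerical route independent of the
    cross-product construction in :func:`geometry.plane_from_three_points`.
    Returns the canonical parameters.
    """
    a, b, c = as_point(a), as_point(b), as_point(c)
    diff = np.vstack([a - c, b - c])
    # collinear/coincident triples have a rank-deficient difference matrix
    _, s, vt = np.linalg.svd(diff)
    if s.size < 2 or s[1] <= 1e-9 * max(1.0, s[0]):
        raise DegenerateInputError("points are collinear or not distinct")
    n = vt[2]  # unit null vector of the two difference constraints
    plane = canonical_hesse(n, float(np.dot(n, a)))
    return plane.theta, plane.phi, plane.rho


def match_sector(b, c, db: SectorDatabase, tol: float | None = None,
                 probe_azimuth: float = 0.0) -> MatchResult:
    """Match two probe-frame points against the sector database.

    Candidate sectors are tried in order of angular proximity of their
    azimuth to ``probe_azimuth`` (ties to the lower sector id); the first
    sector whose full plane holds both points within ``tol`` (worst
    point-plane distance) is accepted.  Because a full plane covers two
    opposite half-plane sectors, proximity ordering also performs the
    half-plane disambiguation: the sector within pi/2 of the probe azimuth
    is reached first.

    ``tol=None`` defaults to ``working_radius * 1e-3``.
    """
    b, c = as_point(b), as_point(c)
    if np.allclose(b, c):
        raise DegenerateInputError("probe points b and c must be distinct")
    if not db.sectors:
        raise ConfigError("empty sector database")
    if tol is None:
        tol = db.working_radius * 1e-3

    # snap distances to 1e-9 rad so exact bisector ties resolve to the lower
    # sector id instead of float noise
    order = sorted(
        db.sectors,
        key=lambda s: (round(circular_distance(s.azimuth, probe_azimuth), 9),
                       s.sector_id),
    )
    best_score = math.inf
    for s in order:
        score = max(abs(eval_plane(b, s.plane)), abs(eval_plane(c, s.plane)))
        best_score = min(best_score, score)
        if score <= tol:
            return MatchResult(sector_id=s.sector_id, score=score,
                               matched_plane=s.plane, matched=True)
    return MatchResult(
        sector_id=-1,
        score=best_score,
        matched_plane=None,
        matched=False,
        message=("no sector within tolerance; rebuild the sector database "
                 "with a larger vertical resolution (delta_v)"),
    )
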