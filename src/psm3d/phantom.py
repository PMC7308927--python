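"""Synthetic ring-phantom acquisition simulator.

The ground-truth target is a torus (a "ring") lying in the XY plane and
centred on the origin; the probe circles it in that plane, one frame per
database azimuth, imaging radially inward.  Echoes are rendered
geometrically by one-way time of flight: each scanline's distance to the
torus boundary is cast as a ray, converted to a time, optionally perturbed
by the two study conditions, and written into the frame at the depth the
NOMINAL echo model would assign to that time.  Perturbations therefore show
up as depth displacement of the target, exactly what the downstream
compensation must undo:

* surface change: the probe-target distance D varies with azimuth along a
  periodic curve seeded from the surface calibration table; the recorded
  pose stays on the nominal contact circle (the squeeze moves the target,
  not the tracked probe), so only the pressure channel sees it;
* medium change: the transmission medium coefficient varies with azimuth
  along a curve seeded from the TMC calibration table, scaling every echo
  time by tmc_echo_time(TMC)/T_ref.

Generation is fully deterministic given the seed (bit-identical output).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.spatial.transform import Rotation

from .exceptions import ConfigError
from .geometry import as_point
from .sensors import (
    REFERENCE_DISTANCE_MM,
    SURFACE_DISTANCES_MM,
    TMC_VALUES,
    CalibrationMap,
    EchoModel,
    PressureReading,
    ProbePose,
    echo_time,
)

__all__ = [
    "RingPhantom",
    "SurfaceCurve",
    "TMCCurve",
    "AcquisitionFrame",
    "SimConfig",
    "curve_from_controls",
    "default_surface_curve",
    "default_tmc_curve",
    "ray_ring_distance",
    "simulate_acquisition",
    "BASE_DEPTH_DIR",
    "BASE_LATERAL_DIR",
]

# Probe body frame at attitude = identity: the centre scanline looks along
# BASE_DEPTH_DIR and the array extends along BASE_LATERAL_DIR.  The
# simulator reaches azimuth alpha by rotating this frame about +Z, so the
# scan direction becomes (-cos a, -sin a, 0): radially inward.
BASE_DEPTH_DIR = np.array([-1.0, 0.0, 0.0])
BASE_LATERAL_DIR = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class RingPhantom:
    """Torus ground truth: ring (centre-line) radius and tube half-thickness."""

    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    ring_radius: float = 20.0
    tube_radius: float = 2.0
    plane_normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self):
        object.__setattr__(self, "center", as_point(self.center))
        n = as_point(self.plane_normal)
        nn = np.linalg.norm(n)
        if nn < 1e-12:
            raise ConfigError("plane_normal must be nonzero")
        object.__setattr__(self, "plane_normal", n / nn)
        if not self.ring_radius > self.tube_radius > 0:
            raise ConfigError("need ring_radius > tube_radius > 0")

    def local_coords(self, points) -> tuple[np.ndarray, np.ndarray]:
        """(in-plane radius u, height z) of points in the ring frame."""
        p = np.atleast_2d(np.asarray(points, dtype=float)) - self.center
        # rotate so the ring plane normal is +Z
        n = self.plane_normal
        if abs(n[2] - 1.0) > 1e-12:
            rot, _ = Rotation.align_vectors([[0.0, 0.0, 1.0]], [n])
            p = rot.apply(p)
        return np.hypot(p[:, 0], p[:, 1]), p[:, 2]

    def centerline_distance(self, points) -> np.ndarray:
        """Distance of points to the ring centre-line circle."""
        u, z = self.local_coords(points)
        return np.hypot(u - self.ring_radius, z)

    def front_radius(self, z) -> np.ndarray:
        """In-plane radius of the OUTER tube boundary at height z.

        This is the surface an inward-looking probe insonifies first; NaN
        beyond the tube's vertical extent.
        """
        z = np.asarray(z, dtype=float)
        with np.errstate(invalid="ignore"):
            c = np.sqrt(self.tube_radius ** 2 - z ** 2)
        return self.ring_radius + c

    def boundary_distance(self, points) -> np.ndarray:
        """Signed distance to the torus surface (negative inside the tube)."""
        return self.centerline_distance(points) - self.tube_radius


class _PeriodicCurve:
    """Monotone piecewise-cubic interpolation, periodic over [0, 2*pi).

    Exact at the control angles and bounded between consecutive control
    values (PCHIP produces no overshoot); built on three tiled periods so
    the wrap-around derivative is consistent.
    """

    def __init__(self, control_radians, control_values):
        x = np.asarray(control_radians, dtype=float)
        v = np.asarray(control_values, dtype=float)
        if x.size < 2 or x.size != v.size:
            raise ConfigError("need >= 2 control points")
        if np.any(np.diff(x) <= 0) or x[0] < 0 or x[-1] >= 2 * math.pi:
            raise ConfigError("control angles must be strictly increasing "
                              "within [0, 2*pi)")
        self.control_radians = x
        self.control_values = v
        xx = np.concatenate([x - 2 * math.pi, x, x + 2 * math.pi])
        vv = np.tile(v, 3)
        self._interp = PchipInterpolator(xx, vv)

    def __call__(self, angle):
        a = np.mod(np.asarray(angle, dtype=float), 2.0 * math.pi)
        out = self._interp(a)
        return float(out) if np.isscalar(angle) else out


class SurfaceCurve(_PeriodicCurve):
    """Azimuth -> probe-target distance D (mm)."""


class TMCCurve(_PeriodicCurve):
    """Azimuth -> transmission medium coefficient (dimensionless)."""


def curve_from_controls(values, kind: str = "surface", angles=None):
    """Periodic perturbation curve through evenly spaced control values.

    ``angles=None`` spreads the controls evenly over [0, 2*pi) starting at
    azimuth 0.  ``kind`` selects the returned type ('surface' or 'tmc').
    """
    v = np.asarray(values, dtype=float)
    if angles is None:
        angles = np.arange(v.size) * (2.0 * math.pi / v.size)
    cls = {"surface": SurfaceCurve, "tmc": TMCCurve}.get(kind)
    if cls is None:
        raise ConfigError(f"unknown curve kind {kind!r}")
    return cls(angles, v)


def _rotate_to_reference(values, reference_value) -> list:
    """Cyclic rotation of the table column so the reference row is first."""
    vals = list(values)
    i = vals.index(reference_value)
    return vals[i:] + vals[:i]


def default_surface_curve() -> SurfaceCurve:
    """Surface curve seeded from the calibration table's D column.

    Controls are placed evenly over [0, 2*pi) in cyclic table order, rotated
    so the undistorted reference row (D = 4 mm) sits at azimuth 0, the
    reference sector.
    """
    return curve_from_controls(
        _rotate_to_reference(SURFACE_DISTANCES_MM, REFERENCE_DISTANCE_MM),
        kind="surface")


def default_tmc_curve() -> TMCCurve:
    """TMC curve seeded from the calibration table's TMC column (TMC = 1 at
    azimuth 0, the reference sector)."""
    return curve_from_controls(_rotate_to_reference(TMC_VALUES, 1.0), kind="tmc")


@dataclass(frozen=True)
class AcquisitionFrame:
    """One simulated (or ingested) 2D echo frame with its sensor channels.

    ``image`` is (n_lines, n_depth) with intensities in [0, 1]; sample k of
    a scanline sits at depth ``k * depth_spacing_mm`` from the transducer
    face.  ``tmc_reading`` is the sensor-derived medium-coefficient
    estimate.  ``true_azimuth`` / ``true_distance`` are simulator ground
    truth (NaN when ingested from hardware).
    """

    image: np.ndarray
    pose: ProbePose
    pressure: PressureReading
    depth_spacing_mm: float
    tmc_reading: float = 1.0
    true_azimuth: float = float("nan")
    true_distance: float = float("nan")

    def __post_init__(self):
        img = np.asarray(self.image, dtype=float)
        if img.ndim != 2:
            raise ConfigError("frame image must be 2-D (n_lines, n_depth)")
        if img.size and (img.min() < 0 or img.max() > 1):
            raise ConfigError("frame intensities must lie in [0, 1]")
        object.__setattr__(self, "image", img)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the numerical experiments.

    Defaults mirror the published setup: a 128-element linear array
    (delta_h = 0.3 mm pitch), working radius 20 mm imaging a 20/2 mm ring
    from the nominal contact circle at ring + tube + n = 26 mm, frames at
    delta_v evenly spaced azimuths, 18 frames/s timestamps.  Noise levels
    model a consumer optical tracker: pose 0.1 mm, attitude 0.2 deg,
    pressure 0.05 N; the medium estimate is noiseless by default.
    """

    delta_v: int = 8
    working_radius: float = 20.0
    n_lines: int = 128
    n_depth: int = 512
    delta_h: float = 0.3
    seed: int = 0
    pose_sd: float = 0.1            # mm, per axis
    angle_sd: float = math.radians(0.2)  # rad
    pressure_sd: float = 0.05       # N
    tmc_sd: float = 0.0
    surface_curve: SurfaceCurve | None = None
    tmc_curve: TMCCurve | None = None
    reference_azimuth: float = 0.0
    frame_rate: float = 18.0        # frames/s

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.delta_v < 2 or self.delta_v % 2:
            raise ConfigError("delta_v must be even and >= 2")
        if min(self.working_radius, self.n_lines, self.n_depth,
               self.delta_h, self.frame_rate) <= 0:
            raise ConfigError("geometry parameters must be positive")
        if min(self.pose_sd, self.angle_sd, self.pressure_sd, self.tmc_sd) < 0:
            raise ConfigError("noise SDs must be nonnegative")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


def ray_ring_distance(origin, direction, phantom: RingPhantom,
                      *, t_max: float | None = None, step: float = 0.01,
                      tol: float = 1e-6):
    """First-hit distance of a ray against the torus boundary, or None.

    Brackets the first sign change of (distance-to-centre-line -
    tube_radius) on a ``step`` grid along the ray, then bisects to ``tol``
    mm.  ``t_max`` defaults to twice the origin's distance to the ring
    centre plus the tube radius.
    """
    origin = as_point(origin)
    direction = as_point(direction)
    if abs(np.linalg.norm(direction) - 1.0) > 1e-9:
        raise ValueError("direction must be a unit vector")
    out = _ray_ring_distances(origin[None, :], direction[None, :], phantom,
                              t_max=t_max, step=step, tol=tol)[0]
    return None if math.isnan(out) else float(out)


def _ray_ring_distances(origins, directions, phantom: RingPhantom,
                        *, t_max: float | None = None, step: float = 0.01,
                        tol: float = 1e-6) -> np.ndarray:
    """Vectorised ray casting; NaN marks a miss."""
    O = np.atleast_2d(np.asarray(origins, dtype=float))
    D = np.atleast_2d(np.asarray(directions, dtype=float))
    if t_max is None:
        t_max = 2.0 * (np.linalg.norm(O - phantom.center, axis=1).max()
                       + phantom.tube_radius)
    ts = np.arange(0.0, t_max + step, step)
    # f(t) per ray: distance to centreline minus tube radius
    pts = O[:, None, :] + ts[None, :, None] * D[:, None, :]
    f = phantom.boundary_distance(pts.reshape(-1, 3)).reshape(O.shape[0], ts.size)
    hit = f <= 0.0
    out = np.full(O.shape[0], np.nan)
    any_hit = hit.any(axis=1)
    if not any_hit.any():
        return out
    first = np.argmax(hit, axis=1)
    for i in np.flatnonzero(any_hit):
        j = first[i]
        if j == 0:  # starts inside the tube
            out[i] = 0.0
            continue
        lo, hi = ts[j - 1], ts[j]
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if phantom.boundary_distance(O[i] + mid * D[i])[0] <= 0.0:
                hi = mid
            else:
                lo = mid
        out[i] = 0.5 * (lo + hi)
    return out


def simulate_acquisition(phantom: RingPhantom, cfg: SimConfig,
                         cal: CalibrationMap | None = None,
                         echo_model: EchoModel | None = None
                         ) -> list[AcquisitionFrame]:
    """Render one frame per database azimuth with sensor channels.

    See the module docstring for the physical model.  The nominal contact
    circle has radius ring_radius + tube_radius + n; the recorded pose is
    the nominal contact pose plus seeded Gaussian noise, the pressure is the
    inverse of the calibration's displacement map applied to (n - D(alpha))
    (clamped at zero force), and the medium channel carries TMC(alpha).
    """
    cal = cal or CalibrationMap()
    model = echo_model or EchoModel()
    rng = np.random.default_rng(cfg.seed)
    n = model.reference_distance
    contact_radius = phantom.ring_radius + phantom.tube_radius + n
    depth_spacing = cfg.working_radius / cfg.n_depth
    lateral = (np.arange(cfg.n_lines) - (cfg.n_lines - 1) / 2.0) * cfg.delta_h

    frames = []
    for k in range(cfg.delta_v):
        alpha = 2.0 * math.pi * k / cfg.delta_v
        d_true = (cfg.surface_curve(alpha) if cfg.surface_curve is not None
                  else n)
        tmc = cfg.tmc_curve(alpha) if cfg.tmc_curve is not None else 1.0
        factor = (cal.tmc_echo_time(tmc) / model.reference_time
                  if cfg.tmc_curve is not None else 1.0)

        u = np.array([math.cos(alpha), math.sin(alpha), 0.0])
        inward = -u
        # true acoustic element positions: surface change moves the target
        # relative to the probe, i.e. the true stand-off is D(alpha)
        acoustic_radius = phantom.ring_radius + phantom.tube_radius + d_true
        origins = (phantom.center + acoustic_radius * u
                   + lateral[:, None] * BASE_LATERAL_DIR[None, :])
        dirs = np.broadcast_to(inward, origins.shape)
        dists = _ray_ring_distances(origins, dirs, phantom,
                                    t_max=2.0 * cfg.working_radius)

        image = np.zeros((cfg.n_lines, cfg.n_depth))
        times = np.where(np.isnan(dists), np.nan,
                         echo_time(np.nan_to_num(dists), model.speed_of_sound)
                         * factor)
        depth_obs = times * model.mm_per_us
        idx = np.round(depth_obs / depth_spacing)
        ok = (~np.isnan(idx)) & (idx >= 0) & (idx < cfg.n_depth)
        image[np.flatnonzero(ok), idx[ok].astype(int)] = 1.0

        # recorded sensor channels (pose deliberately nominal + noise: the
        # tracker cannot see the squeezed target)
        pos = (phantom.center + contact_radius * u
               + rng.normal(0.0, cfg.pose_sd, 3))
        rot = Rotation.from_rotvec([0.0, 0.0, alpha])
        if cfg.angle_sd > 0:
            rot = Rotation.from_rotvec(rng.normal(0.0, cfg.angle_sd, 3)) * rot
        rotvec = rot.as_rotvec()
        angle = float(np.linalg.norm(rotvec))
        axis = rotvec / angle if angle > 1e-12 else np.array([0.0, 0.0, 1.0])
        t_s = k / cfg.frame_rate
        force = cal.force_from_displacement(n - d_true)
        force = max(0.0, force + rng.normal(0.0, cfg.pressure_sd))
        tmc_read = tmc + (rng.normal(0.0, cfg.tmc_sd) if cfg.tmc_sd > 0 else 0.0)

        frames.append(AcquisitionFrame(
            image=image,
            pose=ProbePose(position=pos, axis=axis, angle=angle, timestamp=t_s),
            pressure=PressureReading(force=force, timestamp=t_s),
            depth_spacing_mm=depth_spacing,
            tmc_reading=tmc_read,
            true_azimuth=alpha,
            true_distance=float(d_true),
        ))
    return frames
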