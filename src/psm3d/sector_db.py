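"""Sector database: the space-plane inverse operation.

Before any acquisition, every image plane the probe may occupy around the
target is precomputed.  With the target P on an axis line L, the ``delta_v``
candidate sectors are half-planes bounded by L at evenly spaced azimuths
``2*pi*k/delta_v``; each pair of opposite half-planes shares one full plane,
so ``delta_v`` sectors correspond to ``delta_v / 2`` distinct planes (four
planes partition the surrounding cylinder into eight equal parts when
``delta_v = 8``).

Azimuths are measured in a local frame in which the axis is +Z; a general
axis is handled by rotating that frame into place.  The database is
serialised to JSON losslessly (shortest round-trip float representation,
canonical key order), so build -> save -> load -> save is bit-exact.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import ConfigError, GeometryError
from .geometry import LineParam, PlaneHesse, as_point, canonical_hesse, eval_plane

__all__ = [
    "SectorSpec",
    "SectorDatabase",
    "build_sector_database",
    "nearest_sector",
    "sector_sample_grid",
    "save_database",
    "load_database",
]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class SectorSpec:
    """One candidate half-plane of the database.

    ``azimuth`` is the in-plane direction (radians, local frame) of the half
    plane; ``half_plane_sign`` is +1 for the first delta_v/2 sectors and -1
    for their opposites, which share the same full ``plane``.  The
    ``representative_point`` is the point A handed to the three-point dual
    test during matching; it sits at half the working radius from the axis.
    """

    sector_id: int
    azimuth: float
    plane: PlaneHesse
    half_plane_sign: int
    representative_point: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "representative_point", as_point(self.representative_point)
        )


@dataclass(frozen=True)
class SectorDatabase:
    """Precomputed set of candidate sector planes around the target.

    target : imaging target P (mm); axis : line L through P; working_radius :
    probe imaging depth r (mm); delta_v : vertical resolution (number of
    half-plane sectors, even); delta_h : lateral scanline pitch (mm).
    """

    target: np.ndarray
    axis: LineParam
    working_radius: float
    delta_v: int
    delta_h: float
    sectors: tuple

    def __post_init__(self):
        object.__setattr__(self, "target", as_point(self.target))

    @property
    def azimuths(self) -> np.ndarray:
        return np.array([s.azimuth for s in self.sectors])

    def local_frame(self):
        """Orthonormal (e1, e2, e3) with e3 = axis direction.

        Azimuth a maps to the world direction cos(a) e1 + sin(a) e2.
        """
        return _axis_frame(self.axis.direction)

    def azimuth_direction(self, azimuth: float) -> np.ndarray:
        """World-frame unit vector of an in-plane azimuth direction."""
        e1, e2, _ = self.local_frame()
        return math.cos(azimuth) * e1 + math.sin(azimuth) * e2


def _axis_frame(direction: np.ndarray):
    """Right-handed orthonormal frame with the third vector = direction.

    When the axis is (close to) +Z the frame is exactly (X, Y, Z), so the
    common target-centred case introduces no rotation at all.
    """
    e3 = np.asarray(direction, dtype=float)
    e3 = e3 / np.linalg.norm(e3)
    if abs(e3[2] - 1.0) < 1e-12:
        return np.eye(3)[0], np.eye(3)[1], np.array([0.0, 0.0, 1.0])
    # pick the world axis least aligned with e3 to seed e1
    seed = np.eye(3)[int(np.argmin(np.abs(e3)))]
    e1 = seed - np.dot(seed, e3) * e3
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(e3, e1)
    return e1, e2, e3


def build_sector_database(target, axis: LineParam | None, r: float,
                          delta_v: int, delta_h: float) -> SectorDatabase:
    """Precompute the ``delta_v`` candidate sectors around ``target``.

    ``axis=None`` uses the Z axis through the target (the standard
    simplification).  ``delta_v`` must be even and >= 2 so half-planes pair
    into full planes.  Deterministic; O(delta_v).
    """
    target = as_point(target)
    if axis is None:
        axis = LineParam(point=target, direction=np.array([0.0, 0.0, 1.0]))
    if int(delta_v) != delta_v or delta_v < 2 or delta_v % 2 != 0:
        raise ConfigError(f"delta_v must be an even integer >= 2, got {delta_v}")
    delta_v = int(delta_v)
    if r <= 0:
        raise ConfigError(f"working radius must be positive, got {r}")
    if delta_h <= 0:
        raise ConfigError(f"delta_h must be positive, got {delta_h}")

    e1, e2, e3 = _axis_frame(axis.direction)
    half = delta_v // 2
    sectors = []
    for k in range(delta_v):
        az = 2.0 * math.pi * k / delta_v
        u = math.cos(az) * e1 + math.sin(az) * e2
        # full plane through the axis containing direction u: normal = e3 x u
        normal = np.cross(e3, u)
        plane = canonical_hesse(normal, float(np.dot(normal, target)))
        rep = target + 0.5 * r * u
        sectors.append(
            SectorSpec(
                sector_id=k,
                azimuth=az,
                plane=plane,
                half_plane_sign=1 if k < half else -1,
                representative_point=rep,
            )
        )
    return SectorDatabase(
        target=target,
        axis=axis,
        working_radius=float(r),
        delta_v=delta_v,
        delta_h=float(delta_h),
        sectors=tuple(sectors),
    )


def circular_distance(a: float, b: float) -> float:
    """Smallest absolute angular distance between two azimuths."""
    d = math.fmod(a - b, 2.0 * math.pi)
    if d < 0:
        d += 2.0 * math.pi
    return min(d, 2.0 * math.pi - d)


def nearest_sector(db: SectorDatabase, azimuth: float) -> tuple[int, float]:
    """Sector minimising circular azimuth distance; ties go to the lower id."""
    best_id, best_d = 0, math.inf
    for s in db.sectors:
        d = circular_distance(s.azimuth, azimuth)
        if d < best_d - 1e-15:
            best_id, best_d = s.sector_id, d
    return best_id, best_d


def sector_sample_grid(s: SectorSpec, db: SectorDatabase, n_lines: int,
                       n_depth: int, probe_contact,
                       *, tol: float = 1e-6) -> np.ndarray:
    """Pixel-centre positions of a frame lying in sector ``s``.

    Scanlines are parallel (linear array), spaced ``delta_h`` along the axis
    direction and centred on the contact point; depth samples step
    ``r / n_depth`` from the contact surface toward the axis.  Returns an
    (n_lines, n_depth, 3) array whose every point satisfies the sector plane
    equation to < 1e-6 mm.
    """
    if n_lines < 1 or n_depth < 1:
        raise ConfigError("n_lines and n_depth must be >= 1")
    contact = as_point(probe_contact)
    if abs(eval_plane(contact, s.plane)) > tol:
        raise GeometryError("probe contact point does not lie on the sector plane")

    _, _, e3 = db.local_frame()
    u = db.azimuth_direction(s.azimuth)
    inward = -u  # from the contact surface toward the axis
    lateral_off = (np.arange(n_lines) - (n_lines - 1) / 2.0) * db.delta_h
    depth_off = (np.arange(n_depth) + 1.0) * (db.working_radius / n_depth)
    grid = (
        contact[None, None, :]
        + lateral_off[:, None, None] * e3[None, None, :]
        + depth_off[None, :, None] * inward[None, None, :]
    )
    return grid


# ---------------------------------------------------------------------------
# JSON serialisation (lossless: python's shortest-round-trip float repr)
# ---------------------------------------------------------------------------

def _plane_to_dict(p: PlaneHesse) -> dict:
    return {"theta": p.theta, "phi": p.phi, "rho": p.rho}


def _plane_from_dict(d: dict) -> PlaneHesse:
    return PlaneHesse(theta=d["theta"], phi=d["phi"], rho=d["rho"])


def database_to_dict(db: SectorDatabase) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "target_mm": list(db.target),
        "axis_point_mm": list(db.axis.point),
        "axis_direction": list(db.axis.direction),
        "working_radius_mm": db.working_radius,
        "delta_v": db.delta_v,
        "delta_h_mm": db.delta_h,
        "sectors": [
            {
                "sector_id": s.sector_id,
                "azimuth_rad": s.azimuth,
                "plane": _plane_to_dict(s.plane),
                "half_plane_sign": s.half_plane_sign,
                "representative_point_mm": list(s.representative_point),
            }
            for s in db.sectors
        ],
    }


def database_from_dict(d: dict) -> SectorDatabase:
    if d.get("schema_version") != SCHEMA_VERSION:
        raise ConfigError(f"unsupported sector database schema: "
                          f"{d.get('schema_version')!r}")
    sectors = tuple(
        SectorSpec(
            sector_id=s["sector_id"],
            azimuth=s["azimuth_rad"],
            plane=_plane_from_dict(s["plane"]),
            half_plane_sign=s["half_plane_sign"],
            representative_point=np.array(s["representative_point_mm"]),
        )
        for s in d["sectors"]
    )
    return SectorDatabase(
        target=np.array(d["target_mm"]),
        axis=LineParam(point=np.array(d["axis_point_mm"]),
                       direction=np.array(d["axis_direction"])),
        working_radius=d["working_radius_mm"],
        delta_v=d["delta_v"],
        delta_h=d["delta_h_mm"],
        sectors=sectors,
    )


def save_database(db: SectorDatabase, path) -> None:
    text = json.dumps(database_to_dict(db), sort_keys=True, indent=2)
    Path(path).write_text(text + "\n", encoding="utf-8")


def load_database(path) -> SectorDatabase:
    return database_from_dict(json.loads(Path(path).read_text(encoding="utf-8")))
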