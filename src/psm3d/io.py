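"""On-disk formats: run configuration, frame stacks, pose CSV, PLY, reports.

Frame stacks live in a directory of 16-bit grayscale PNGs
(``frame_0000.png`` ...) with one JSON sidecar (``frames.json``: poses,
pressures, ground truth, config echo) and a pose CSV in the sensor-stream
dialect (columns t_s, x_mm, y_mm, z_mm, ax, ay, az, angle_rad, force_N).
Floats are serialised with Python's shortest round-trip representation, so
write-then-read reproduces metadata exactly and images bit-exactly (image
intensities are quantised to 16 bits on first write).
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError
from .phantom import AcquisitionFrame, RingPhantom, SimConfig
from .sensors import CalibrationMap, EchoModel, PressureReading, ProbePose

__all__ = [
    "RunConfig",
    "load_config",
    "dump_config",
    "write_frames",
    "read_frames",
    "write_pose_csv",
    "read_pose_csv",
    "write_ply",
    "read_ply",
]

POSE_CSV_COLUMNS = ["t_s", "x_mm", "y_mm", "z_mm", "ax", "ay", "az",
                    "angle_rad", "force_N"]

FRAMES_SIDECAR = "frames.json"
FRAMES_SCHEMA_VERSION = 1


@dataclasses.dataclass
class RunConfig:
    """Validated run configuration; angles in DEGREES at this surface only.

    Defaults reproduce the published numerical setup: c = 1500 m/s,
    n = 4 mm, delta_v = 8, a 128-element linear array.
    """

    target: tuple = (0.0, 0.0, 0.0)
    working_radius: float = 20.0
    delta_v: int = 8
    delta_h: float = 0.3
    n_lines: int = 128
    n_depth: int = 512
    seed: int = 0
    speed_of_sound: float = 1500.0
    reference_distance: float = 4.0
    reference_time: float = 2.7
    ultrasound_frequency_hz: float = 1000.0  # recorded, unused by the model
    ring_radius: float = 20.0
    tube_radius: float = 2.0
    k_pressure: float = 0.5
    baseline_force: float = 10.0
    pose_sd: float = 0.1
    angle_sd_deg: float = 0.2
    pressure_sd: float = 0.05
    tmc_sd: float = 0.0
    surface_curve: bool = False
    tmc_curve: bool = False
    compensate: bool = True
    match_tol: float | None = 0.5
    detection_threshold: float = 0.5

    def __post_init__(self):
        self.target = tuple(float(v) for v in self.target)
        if len(self.target) != 3:
            raise ConfigError("target must have three coordinates")
        if self.delta_v % 2 or self.delta_v < 2:
            raise ConfigError("delta_v must be even and >= 2")

    # -- derived objects ----------------------------------------------------

    def echo_model(self) -> EchoModel:
        return EchoModel(speed_of_sound=self.speed_of_sound,
                         reference_distance=self.reference_distance,
                         reference_time=self.reference_time)

    def calibration(self) -> CalibrationMap:
        return CalibrationMap(k_pressure=self.k_pressure,
                              baseline_force=self.baseline_force)

    def phantom(self) -> RingPhantom:
        return RingPhantom(ring_radius=self.ring_radius,
                           tube_radius=self.tube_radius)

    def contact_radius(self) -> float:
        return self.ring_radius + self.tube_radius + self.reference_distance

    def sim_config(self) -> SimConfig:
        from .phantom import default_surface_curve, default_tmc_curve

        return SimConfig(
            delta_v=self.delta_v,
            working_radius=self.working_radius,
            n_lines=self.n_lines,
            n_depth=self.n_depth,
            delta_h=self.delta_h,
            seed=self.seed,
            pose_sd=self.pose_sd,
            angle_sd=math.radians(self.angle_sd_deg),
            pressure_sd=self.pressure_sd,
            tmc_sd=self.tmc_sd,
            surface_curve=default_surface_curve() if self.surface_curve else None,
            tmc_curve=default_tmc_curve() if self.tmc_curve else None,
        )


def load_config(path) -> RunConfig:
    """Read a YAML run configuration; unknown keys are rejected by name."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    data = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(unknown)}")
    try:
        return RunConfig(**data)
    except TypeError as e:  # pragma: no cover - defensive
        raise ConfigError(str(e)) from e


def dump_config(cfg: RunConfig, path) -> None:
    d = dataclasses.asdict(cfg)
    d["target"] = list(d["target"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True), encoding="utf-8")


# ---------------------------------------------------------------------------
# frame stacks
# ---------------------------------------------------------------------------

def _pose_to_dict(p: ProbePose) -> dict:
    return {"position_mm": list(p.position), "axis": list(p.axis),
            "angle_rad": p.angle, "t_s": p.timestamp}


def _pose_from_dict(d: dict) -> ProbePose:
    return ProbePose(position=np.array(d["position_mm"]),
                     axis=np.array(d["axis"]), angle=d["angle_rad"],
                     timestamp=d["t_s"])


def write_frames(frames, directory) -> None:
    """Write a frame stack: PNGs + JSON sidecar + pose CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {"schema_version": FRAMES_SCHEMA_VERSION, "frames": []}
    for i, f in enumerate(frames):
        name = f"frame_{i:04d}.png"
        img16 = np.round(np.clip(f.image, 0.0, 1.0) * 65535).astype(np.uint16)
        iio.imwrite(directory / name, img16)
        meta["frames"].append({
            "image": name,
            "pose": _pose_to_dict(f.pose),
            "force_N": f.pressure.force,
            "force_t_s": f.pressure.timestamp,
            "depth_spacing_mm": f.depth_spacing_mm,
            "tmc_reading": f.tmc_reading,
            "true_azimuth_rad": f.true_azimuth,
            "true_distance_mm": f.true_distance,
        })
    (directory / FRAMES_SIDECAR).write_text(
        json.dumps(meta, sort_keys=True, indent=2) + "\n", encoding="utf-8")
    write_pose_csv(frames, directory / "poses.csv")


def read_frames(directory) -> list[AcquisitionFrame]:
    """Read a frame stack written by :func:`write_frames`.

    Raises :class:`ConfigError` on a missing sidecar, malformed JSON, or an
    image/metadata count mismatch.
    """
    directory = Path(directory)
    sidecar = directory / FRAMES_SIDECAR
    if not sidecar.exists():
        raise ConfigError(f"missing frame sidecar: {sidecar}")
    try:
        meta = json.loads(sidecar.read_text(encoding="utf-8"))
    except json.JSONDecodeError as e:
        raise ConfigError(f"malformed sidecar {sidecar}: {e}") from e
    if meta.get("schema_version") != FRAMES_SCHEMA_VERSION:
        raise ConfigError("unsupported frame-stack schema")
    pngs = sorted(p.name for p in directory.glob("frame_*.png"))
    names = [fr["image"] for fr in meta["frames"]]
    if pngs != sorted(names):
        raise ConfigError(
            f"image/metadata mismatch in {directory}: {len(pngs)} PNGs vs "
            f"{len(names)} sidecar entries")
    frames = []
    for fr in meta["frames"]:
        img = iio.imread(directory / fr["image"]).astype(float) / 65535.0
        frames.append(AcquisitionFrame(
            image=img,
            pose=_pose_from_dict(fr["pose"]),
            pressure=PressureReading(force=fr["force_N"],
                                     timestamp=fr["force_t_s"]),
            depth_spacing_mm=fr["depth_spacing_mm"],
            tmc_reading=fr["tmc_reading"],
            true_azimuth=fr["true_azimuth_rad"],
            true_distance=fr["true_distance_mm"],
        ))
    return frames


def write_pose_csv(frames, path) -> None:
    rows = [
        {
            "t_s": f.pose.timestamp,
            "x_mm": f.pose.position[0],
            "y_mm": f.pose.position[1],
            "z_mm": f.pose.position[2],
            "ax": f.pose.axis[0],
            "ay": f.pose.axis[1],
            "az": f.pose.axis[2],
            "angle_rad": f.pose.angle,
            "force_N": f.pressure.force,
        }
        for f in frames
    ]
    pd.DataFrame(rows, columns=POSE_CSV_COLUMNS).to_csv(path, index=False)


def read_pose_csv(path) -> list[tuple[ProbePose, PressureReading]]:
    """Parse a pose-stream CSV; malformed rows are reported by line number."""
    df = pd.read_csv(path)
    missing = [c for c in POSE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"pose CSV missing column(s): {', '.join(missing)}")
    out = []
    for i, row in df.iterrows():
        try:
            pose = ProbePose(
                position=np.array([row.x_mm, row.y_mm, row.z_mm], dtype=float),
                axis=np.array([row.ax, row.ay, row.az], dtype=float),
                angle=float(row.angle_rad), timestamp=float(row.t_s))
            reading = PressureReading(force=float(row.force_N),
                                      timestamp=float(row.t_s))
        except (ValueError, TypeError) as e:
            raise ConfigError(f"malformed pose CSV row at line {i + 2}: {e}") from e
        out.append((pose, reading))
    return out


# ---------------------------------------------------------------------------
# ASCII PLY point clouds (x, y, z, intensity)
# ---------------------------------------------------------------------------

def write_ply(points, intensities, path) -> None:
    points = np.atleast_2d(np.asarray(points, dtype=float))
    intensities = np.asarray(intensities, dtype=float)
    header = "\n".join([
        "ply",
        "format ascii 1.0",
        f"element vertex {points.shape[0]}",
        "property float x",
        "property float y",
        "property float z",
        "property float intensity",
        "end_header",
    ])
    body = "\n".join(
        f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {w:.6f}"
        for p, w in zip(points, intensities)
    )
    Path(path).write_text(header + "\n" + (body + "\n" if body else ""),
                          encoding="utf-8")


def read_ply(path) -> tuple[np.ndarray, np.ndarray]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    try:
        end = lines.index("end_header")
    except ValueError:
        raise ConfigError(f"not an ASCII PLY file: {path}")
    n = next(int(l.split()[-1]) for l in lines[:end]
             if l.startswith("element vertex"))
    data = np.array([[float(v) for v in l.split()]
                     for l in lines[end + 1:end + 1 + n]])
    data = data.reshape(n, 4) if n else np.empty((0, 4))
    return data[:, :3], data[:, 3]
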