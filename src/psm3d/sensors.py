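"""Echo time-of-flight model, pressure and medium feedback, edge errors.

Conventions
-----------
Echo times are ONE-WAY (distance / c): the reference arithmetic
4 mm / 1500 m/s = 2.667 us, rounded to 2.7 us, only balances one-way even
though a physical echo travels out and back.  Times are microseconds,
distances millimetres, the speed of sound metres per second.

The reference sector sits at probe-target distance n = 4 mm, giving the
reference time T_ref = 2.7 us; every echo-time error is measured against
T_ref.  The transmission medium coefficient (TMC) is a dimensionless
empirical factor: TMC = 1 is the reference medium, larger values transmit
more slowly.  Its relation to echo time is tabulated, not closed-form, and
is interpolated monotonically between the calibration controls.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .exceptions import ConfigError
from .geometry import as_point

__all__ = [
    "SPEED_OF_SOUND_M_S",
    "REFERENCE_DISTANCE_MM",
    "REFERENCE_TIME_US",
    "SURFACE_DISTANCES_MM",
    "SURFACE_ECHO_TIMES_US",
    "TMC_VALUES",
    "TMC_ECHO_TIMES_US",
    "EchoModel",
    "ProbePose",
    "PressureReading",
    "CalibrationMap",
    "EdgeErrorProfile",
    "echo_time",
    "echo_time_rounded",
    "echo_time_error",
    "tmc_echo_time",
    "pressure_to_radius_correction",
    "edge_error_profile",
    "corrected_radius",
]

log = logging.getLogger(__name__)

SPEED_OF_SOUND_M_S = 1500.0
REFERENCE_DISTANCE_MM = 4.0   # n: probe-target distance on the reference sector
REFERENCE_TIME_US = 2.7       # T_ref: one-way echo time at n, rounded to 0.1 us

# Calibration table for a changing surface: probe-target distance D (mm)
# against the one-way echo time T (us) it produces; the error column of the
# published table is T - T_ref.
SURFACE_DISTANCES_MM = (1.75, 2.5, 3.25, 4.0, 4.75, 5.5, 6.25, 7.0)
SURFACE_ECHO_TIMES_US = (1.2, 1.7, 2.2, 2.7, 3.2, 3.7, 4.2, 4.7)

# Calibration table for a changing medium at fixed D = 4 mm: TMC against the
# observed echo time (us).  Listed here in published order (descending TMC).
TMC_VALUES = (2.77, 2.04, 1.28, 1.0, 0.85, 0.82, 0.81, 0.75)
TMC_ECHO_TIMES_US = (11.2, 7.7, 4.0, 2.7, 2.0, 1.8, 1.7, 1.5)


def echo_time(distance_mm, c: float = SPEED_OF_SOUND_M_S):
    """One-way echo time (us) over ``distance_mm`` at sound speed ``c`` (m/s)."""
    d = np.asarray(distance_mm, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be nonnegative")
    if c <= 0:
        raise ValueError("speed of sound must be positive")
    t = d / (c * 1e-3)  # c*1e-3 is mm/us
    return float(t) if np.isscalar(distance_mm) else t


def echo_time_rounded(distance_mm, c: float = SPEED_OF_SOUND_M_S):
    """Echo time rounded to 0.1 us, the precision of the calibration tables."""
    t = np.asarray(echo_time(distance_mm, c))
    r = np.round(t * 10.0) / 10.0
    return float(r) if np.isscalar(distance_mm) else r


@dataclass(frozen=True)
class EchoModel:
    speed_of_sound: float = SPEED_OF_SOUND_M_S       # m/s
    reference_distance: float = REFERENCE_DISTANCE_MM  # mm
    reference_time: float = REFERENCE_TIME_US          # us

    def __post_init__(self):
        got = echo_time_rounded(self.reference_distance, self.speed_of_sound)
        if abs(got - self.reference_time) > 1e-9:
            raise ConfigError(
                f"inconsistent echo model: {self.reference_distance} mm at "
                f"{self.speed_of_sound} m/s gives {got} us, not "
                f"{self.reference_time} us")

    @property
    def mm_per_us(self) -> float:
        return self.speed_of_sound * 1e-3


def echo_time_error(t_us, model: EchoModel | None = None):
    """Echo-time error dt = t - T_ref (us)."""
    ref = REFERENCE_TIME_US if model is None else model.reference_time
    t = np.asarray(t_us, dtype=float)
    out = t - ref
    return float(out) if np.isscalar(t_us) else out


@dataclass(frozen=True)
class ProbePose:
    """Probe position (mm) and attitude as an axis-angle rotation."""

    position: np.ndarray
    axis: np.ndarray
    angle: float
    timestamp: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "position", as_point(self.position))
        a = as_point(self.axis)
        n = np.linalg.norm(a)
        if n < 1e-12:
            a = np.array([0.0, 0.0, 1.0])  # identity rotation: axis arbitrary
        else:
            a = a / n
        object.__setattr__(self, "axis", a)

    def rotation_matrix(self) -> np.ndarray:
        from scipy.spatial.transform import Rotation

        return Rotation.from_rotvec(self.axis * self.angle).as_matrix()


@dataclass(frozen=True)
class PressureReading:
    force: float        # newtons, >= 0
    timestamp: float = 0.0

    def __post_init__(self):
        if self.force < 0:
            raise ValueError("pressure force must be nonnegative")


@dataclass(frozen=True)
class CalibrationMap:
    """Pressure and medium calibration used by the compensation step.

    k_pressure : linear pressure-to-displacement gain (mm per newton).
    baseline_force : contact force at the nominal probe-target distance (N);
        deviations of the measured force from this baseline encode the
        surface displacement in BOTH directions (a pure proportional reading
        clamped at zero could only report a squeezed surface).
    tmc_controls : ordered (TMC, echo time us) control pairs, strictly
        increasing in TMC, interpolated with a monotone piecewise cubic.
    """

    k_pressure: float = 0.5
    baseline_force: float = 10.0
    tmc_controls: tuple = field(
        default=tuple(sorted(zip(TMC_VALUES, TMC_ECHO_TIMES_US))))

    def __post_init__(self):
        if self.k_pressure < 0:
            raise ConfigError("k_pressure must be nonnegative")
        if self.baseline_force < 0:
            raise ConfigError("baseline_force must be nonnegative")
        tmc = [c[0] for c in self.tmc_controls]
        if len(tmc) < 2 or any(b <= a for a, b in zip(tmc, tmc[1:])):
            raise ConfigError("tmc_controls must be >= 2 pairs, strictly "
                              "increasing in TMC")

    def _interp(self) -> PchipInterpolator:
        x = np.array([c[0] for c in self.tmc_controls])
        y = np.array([c[1] for c in self.tmc_controls])
        return PchipInterpolator(x, y)

    @property
    def tmc_range(self) -> tuple[float, float]:
        return self.tmc_controls[0][0], self.tmc_controls[-1][0]

    def tmc_echo_time(self, tmc) -> float:
        """Echo time (us) at the given TMC; exact at controls, monotone."""
        lo, hi = self.tmc_range
        t = np.asarray(tmc, dtype=float)
        if np.any(t < lo) or np.any(t > hi):
            raise ValueError(f"TMC {tmc} outside calibrated range [{lo}, {hi}]"
                             " (extrapolation refused)")
        out = self._interp()(t)
        return float(out) if np.isscalar(tmc) else out

    def displacement_from_force(self, force: float) -> float:
        """Signed working-radius correction (mm) from a force reading.

        Positive when the surface is squeezed toward the probe (force above
        baseline), i.e. the working radius must grow to keep the target in
        view.
        """
        return self.k_pressure * (force - self.baseline_force)

    def force_from_displacement(self, delta_mm: float) -> float:
        """Inverse of :meth:`displacement_from_force`, clamped at zero.

        Used by the simulator to produce the pressure channel.
        """
        if self.k_pressure == 0:
            return self.baseline_force
        return max(0.0, self.baseline_force + delta_mm / self.k_pressure)


def tmc_echo_time(tmc: float, cal: CalibrationMap) -> float:
    """Functional form of :meth:`CalibrationMap.tmc_echo_time`."""
    return cal.tmc_echo_time(tmc)


def pressure_to_radius_correction(p: PressureReading, cal: CalibrationMap) -> float:
    """Raw linear pressure-to-radius map dr = k_pressure * force (mm).

    The sign convention is that a positive dr increases the working radius.
    Net corrections relative to the contact baseline are obtained with
    :meth:`CalibrationMap.displacement_from_force`.
    """
    return cal.k_pressure * p.force


@dataclass(frozen=True)
class EdgeErrorProfile:
    """Per-element working-radius reduction when the array face lifts.

    With the probe flush on the surface all entries are zero; otherwise the
    centre elements stay in contact (zero error) and the error grows toward
    the edges.
    """

    n_elements: int
    delta_r: np.ndarray

    def __post_init__(self):
        dr = np.asarray(self.delta_r, dtype=float)
        if dr.shape != (self.n_elements,):
            raise ValueError("delta_r length must equal n_elements")
        if np.any(dr < 0):
            raise ValueError("edge errors must be nonnegative")
        object.__setattr__(self, "delta_r", dr)


def edge_error_profile(n_elements: int, delta_r_max: float,
                       flush: bool = False) -> EdgeErrorProfile:
    """Quadratic bow: dr_i = max * ((2i - n - 1)/(n - 1))^2, i = 1..n.

    Zero at the array centre and ``delta_r_max`` at both edges; ``flush``
    (or a single element) gives all zeros.
    """
    if n_elements < 1:
        raise ValueError("n_elements must be >= 1")
    if delta_r_max < 0:
        raise ValueError("delta_r_max must be nonnegative")
    if flush or n_elements == 1:
        dr = np.zeros(n_elements)
    else:
        i = np.arange(1, n_elements + 1, dtype=float)
        dr = delta_r_max * ((2.0 * i - n_elements - 1) / (n_elements - 1)) ** 2
    return EdgeErrorProfile(n_elements=n_elements, delta_r=dr)


def corrected_radius(r: float, dr_pressure: float, profile: EdgeErrorProfile,
                     element: int) -> float:
    """Effective working radius of one element: r + dr_pressure - dr_edge.

    ``element`` is 1-based.  Negative results are clamped to zero with a
    warning, since a radius cannot be negative.
    """
    if not 1 <= element <= profile.n_elements:
        raise IndexError(f"element {element} outside 1..{profile.n_elements}")
    out = r + dr_pressure - profile.delta_r[element - 1]
    if out < 0:
        warnings.warn("corrected working radius clamped to 0", stacklevel=2)
        return 0.0
    return float(out)
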