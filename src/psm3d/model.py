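"""Model / Results interface over the reconstruction pipeline.

``PSMModel`` bundles a frame stack with the sector database and sensor
calibrations; ``fit()`` runs match -> compensate -> place and returns a
``PSMResults`` carrying the point cloud, per-frame feedback diagnostics and
accuracy metrics.  This mirrors the fit/results split of statistical
modelling packages: the model holds data and configuration, the results
hold everything derived from them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import RingPhantom, SimConfig, simulate_acquisition
from .reconstruct import (
    ErrorReport,
    Reconstruction,
    TargetCurve,
    error_report,
    psm_reconstruct,
    target_curve,
)
from .sector_db import SectorDatabase, build_sector_database
from .sensors import CalibrationMap, EchoModel

__all__ = ["PSMModel", "PSMResults"]


class PSMModel:
    """Probe-sector-matching reconstruction model.

    Parameters
    ----------
    frames : sequence of AcquisitionFrame
    database : SectorDatabase
        Precomputed candidate sector planes around the target.
    calibration, echo_model : sensor calibrations (defaults: published
        reference values).
    contact_radius : nominal axis-to-probe-face distance (mm); defaults to
        the database working radius.
    match_tol : point-plane tolerance (mm) of the sector match; ``None``
        uses working_radius * 1e-3 (appropriate for noiseless poses — raise
        to a few times the expected pose-noise residual for tracked data).
    detection_threshold : echo detection threshold in (0, 1).
    """

    def __init__(self, frames, database: SectorDatabase,
                 calibration: CalibrationMap | None = None,
                 echo_model: EchoModel | None = None,
                 contact_radius: float | None = None,
                 match_tol: float | None = None,
                 detection_threshold: float = 0.5):
        self.frames = list(frames)
        self.database = database
        self.calibration = calibration or CalibrationMap()
        self.echo_model = echo_model or EchoModel()
        self.contact_radius = contact_radius
        self.match_tol = match_tol
        self.detection_threshold = detection_threshold

    @classmethod
    def from_simulation(cls, phantom: RingPhantom, cfg: SimConfig,
                        calibration: CalibrationMap | None = None,
                        echo_model: EchoModel | None = None,
                        database: SectorDatabase | None = None,
                        **kwargs) -> "PSMModel":
        """Simulate an acquisition and set up the matching geometry for it."""
        calibration = calibration or CalibrationMap()
        echo_model = echo_model or EchoModel()
        frames = simulate_acquisition(phantom, cfg, calibration, echo_model)
        if database is None:
            database = build_sector_database(
                phantom.center, None, cfg.working_radius, cfg.delta_v,
                cfg.delta_h)
        contact = (phantom.ring_radius + phantom.tube_radius
                   + echo_model.reference_distance)
        kwargs.setdefault("contact_radius", contact)
        return cls(frames, database, calibration, echo_model, **kwargs)

    def fit(self, compensate: bool = True) -> "PSMResults":
        recon = psm_reconstruct(
            self.frames, self.database, self.calibration, self.echo_model,
            compensate=compensate, tol=self.match_tol,
            threshold=self.detection_threshold,
            contact_radius=self.contact_radius,
        )
        return PSMResults(model=self, reconstruction=recon,
                          compensated=compensate)


@dataclass
class PSMResults:
    """Fitted reconstruction: point cloud, feedback and diagnostics."""

    model: PSMModel
    reconstruction: Reconstruction
    compensated: bool

    @property
    def points(self) -> np.ndarray:
        return self.reconstruction.points

    @property
    def intensities(self) -> np.ndarray:
        return self.reconstruction.intensities

    @property
    def n_frames(self) -> int:
        return len(self.model.frames)

    @property
    def n_matched(self) -> int:
        return len(self.reconstruction.matched_sectors)

    @property
    def n_skipped(self) -> int:
        return self.reconstruction.n_skipped

    def feedback_frame(self) -> pd.DataFrame:
        """Per-frame feedback intensities as a DataFrame."""
        fb = self.reconstruction.feedback
        return pd.DataFrame(
            {
                "frame_index": [f.frame_index for f in fb],
                "azimuth_rad": [f.azimuth for f in fb],
                "correction_mm": [f.correction_mm for f in fb],
            }
        )

    def target_curve(self) -> TargetCurve:
        return target_curve(self.reconstruction, target=self.model.database.target)

    def error_report(self, phantom: RingPhantom) -> ErrorReport:
        return error_report(self.reconstruction, phantom)

    def summary(self, phantom: RingPhantom | None = None) -> str:
        """Plain-text summary table of the fitted reconstruction."""
        fb = self.feedback_frame()
        lines = [
            "Probe sector matching reconstruction",
            "=" * 44,
            f"frames:            {self.n_frames}",
            f"matched:           {self.n_matched}",
            f"skipped:           {self.n_skipped}",
            f"placed points:     {self.reconstruction.n_points}",
            f"compensation:      {'on' if self.compensated else 'off'}",
            f"database delta_v:  {self.model.database.delta_v}",
            f"working radius:    {self.model.database.working_radius:g} mm",
        ]
        if len(fb):
            lines.append(f"mean feedback:     {fb.correction_mm.mean():.4f} mm")
            lines.append(f"max feedback:      {fb.correction_mm.max():.4f} mm")
        if phantom is not None:
            rep = self.error_report(phantom)
            lines.append(f"radial RMSE:       {rep.radial_rmse:.4f} mm")
            lines.append(f"max radial error:  {rep.max_radial_error:.4f} mm")
        return "\n".join(lines)

    # ---------------- plotting (matplotlib, lazily imported) --------------

    def plot_reconstruction(self, ax=None, **scatter_kw):
        """3D scatter of the placed points."""
        import matplotlib.pyplot as plt

        if ax is None:
            fig = plt.figure()
            ax = fig.add_subplot(111, projection="3d")
        p = self.points
        scatter_kw.setdefault("s", 2)
        ax.scatter(p[:, 0], p[:, 1], p[:, 2], c=self.intensities, **scatter_kw)
        ax.set_xlabel("x (mm)"); ax.set_ylabel("y (mm)"); ax.set_zlabel("z (mm)")
        return ax

    def plot_feedback(self, ax=None):
        """Feedback intensity versus azimuth (radial stem plot analogue)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(subplot_kw={"projection": "polar"})
        fb = self.feedback_frame()
        ax.stem(fb.azimuth_rad, fb.correction_mm, linefmt="r--", basefmt=" ")
        ax.set_title("feedback intensity (mm)")
        return ax

    def plot_target_curve(self, reference: TargetCurve | None = None, ax=None):
        """Cumulative X/Y curves, optionally against an ideal reference."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tc = self.target_curve()
        ax.plot(tc.radians, tc.cum_x, "r.", label="cum X")
        ax.plot(tc.radians, tc.cum_y, "m.", label="cum Y")
        if reference is not None:
            ax.plot(reference.radians, reference.cum_x, "b+", label="ideal cum X")
            ax.plot(reference.radians, reference.cum_y, "c+", label="ideal cum Y")
        ax.set_xlabel("azimuth (rad)")
        ax.set_ylabel("accumulated coordinate (mm)")
        ax.legend()
        return ax
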