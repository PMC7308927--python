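# Methods

This note records the model behind `psm3d`, the choices made where the
method left room, and what the synthetic experiments do and do not show.

## Coordinate and plane conventions

All computation happens in a Cartesian frame centred on the imaging target
P, lengths in millimetres, angles in radians (degrees only at the CLI/config
surface). Planes are kept in Hesse normal form, the unit normal
parameterised by spherical angles (θ, φ) and the origin distance ρ. The
form has a sign ambiguity (−n̂, −ρ describes the same plane), removed by a
canonical orientation: ρ ≥ 0 always; for ρ = 0 the normal with θ ≤ π/2 is
taken, and at θ = π/2 the one with φ ∈ (−π/2, π/2]; at the poles
(sin θ = 0) φ is set to 0. Canonical form makes plane equality testable,
which the matching step and the database round-trip rely on.

Degeneracy tolerances: three points are collinear when the cross-product
norm of their difference vectors is below 1e−9 mm² (configurable); two
planes are parallel when the cross product of their normals is below 1e−9.
Both limits are far below any geometry the pipeline produces and exist only
to give clean errors instead of noise-dominated output.

## Sector database

The database enumerates the Δv half-planes through the axis L at azimuths
2πk/Δv. Δv must be even: opposite half-planes share one full plane, so Δv
sectors = Δv/2 planes, and the Δv = 8 case reproduces the four-planes /
eight-parts partition of the surrounding cylinder. Sectors store their full
plane, the half-plane side, and a representative point placed at half the
working radius from the axis — a point well away from both the axis (where
all planes nearly coincide) and the contact surface, hence well-conditioned
for the three-point test. A general axis is handled by building an
orthonormal frame whose third vector is the axis direction; for the
standard Z axis this frame is exactly the identity, so no rotation noise is
introduced in the common case.

Frames are modelled as rectangles (parallel scanlines at the element pitch
Δh, default 0.3 mm for a 128-element linear array), not fans: the hardware
is a linear array, whatever the word "sector" suggests.

## 3D Hough transform and matching

The classical transform votes each point, for every sampled (θ, φ), into
the ρ bin containing its dual value, skipping cells outside [0, ρ_max].
Angles are sampled at bin lower edges (θ_i = iΔθ, φ_j = −π + jΔφ): this
keeps the exact axis-aligned orientations on the grid, so planes at those
orientations collect all their votes in one cell instead of splitting
across a bin boundary. Default bins are 1° / 0.5 mm — fine enough to
separate the closest sector spacing used here (2π/128 = 2.8°). Peak ties
break to the lexicographically smallest bin index, making detection
deterministic. Because the quantised peak can still sit a bin or two off
for unluckily aligned clouds, `detect_plane` polishes the peak with a
total-least-squares fit over the points within one ρ bin of the peak plane
(switchable off); for noiseless planar clouds this returns the exact plane.

The matching step does not need the accumulator at all: three non-collinear
points define exactly one plane, so the operative test is whether the plane
through (A_k, B, C) — sector k's representative point plus two frame points
— coincides with sector k's stored plane. This is implemented as a
point-plane distance threshold: score_k = max(|residual(B)|, |residual(C)|)
against sector k's plane, accepting the first sector within tolerance when
candidates are ordered by azimuthal proximity to the probe pose (ties to
the lower id, distances snapped at 1e−9 rad). Proximity ordering makes the
search near-constant-time and disambiguates the two half-planes sharing a
full plane. `solve_three_points` solves the three dual equations through an
SVD null space — a numerical route independent of the cross-product
construction — and the two are held equal to < 1e−6 by a standing property
test.

**Match tolerance.** The default is working_radius × 1e−3 (0.02 mm at the
default r = 20 mm), appropriate for noiseless poses. Under the simulator's
default tracker noise (0.1 mm position, 0.2° attitude) the frame points
carry ~0.1–0.3 mm of plane residual, so reconstructions of noisy data use
tol = 0.5 mm: about four standard deviations of the noise-induced residual,
and still well under the 1.27 mm separation of adjacent Δv = 128 sector
planes at the contact point, so the azimuth-ordered search still accepts
the correct sector first. Frames matching no sector are skipped and
counted, and an all-unmatched run raises an error advising a larger Δv.

## Echo model and sensor feedback

Echo times are one-way times of flight: T = D/c with c = 1500 m/s, reported
in μs and rounded to 0.1 μs where the calibration tables are reproduced
(4 mm → 2.7 μs, the reference time; a physical echo travels out and back,
but the calibration arithmetic is one-way and the code follows it). Echo
time errors are measured against T_ref = 2.7 μs.

The transmission medium coefficient (TMC) has no closed-form relation to
echo time; the eight calibration pairs (TMC 0.75 → 1.5 μs … 2.77 →
11.2 μs) are interpolated with a monotone piecewise cubic (PCHIP), exact at
the controls, extrapolation refused.

Pressure feedback is linear: a displacement gain k_pressure (default
0.5 mm/N) around a baseline contact force (default 10 N). The baseline
matters: the probe pushes against the surface with some nominal force, and
deviations in either direction encode whether the target moved toward or
away from the probe. A proportional-only reading clamped at zero force
could report only the squeezed direction, while the calibrated experiments
span stand-offs both above and below the 4 mm reference. The raw map
Δr = k·force is exposed as well; compensation uses the baseline-relative
form k·(force − f₀).

The medium estimate is carried as its own per-frame sensor channel
(`tmc_reading`): physically it derives from the same contact-force sensing
(denser media push back harder), but surface displacement and medium
density are not identifiable from one scalar, so the simulator and the
compensator exchange the estimated coefficient directly.

Edge errors (the array face lifting off a curved surface) are modelled as a
symmetric quadratic bow, zero at the centre elements and maximal at the
edges — the minimal model consistent with centre-flush contact; it is a
modelling choice, not a calibrated curve, and is exposed but not used by
the simulator (which assumes flush contact).

## Ring-phantom simulator

The ground truth is a torus: ring radius l = 20 mm, tube radius 2 mm,
lying in the XY plane. Neither dimension is calibrated by the tables; they
were chosen once as a realistic small imaging target whose geometry keeps
every distorted echo inside the image (see working radius below). The probe
circles the ring in its plane, one frame per database azimuth, scanlines
pointing radially inward with the array extended along Z, contact nominally
at radius l + tube + n = 26 mm.

Echoes are rendered geometrically: each scanline's first intersection with
the torus boundary (bracketed 0.01 mm grid search plus bisection to
1e−6 mm) gives the echo distance, converted to time, scaled by the medium
factor, and written at the depth the *nominal* model assigns to that time.
Working radius (image depth) is r = 20 mm with 512 depth samples
(0.039 mm/sample): deep enough for the largest medium-distorted echo
(4 mm × 11.2/2.7 ≈ 16.6 mm plus tube curvature) while keeping the deepest
matched point 6 mm off-axis, where adjacent sector planes are still
separated. A full-wave (Huygens) simulation would add nothing testable to
this time-of-flight arithmetic, which is the quantitative content being
validated.

The two study conditions are azimuth-periodic curves through the
calibration-table columns, controls evenly spaced over [0, 2π) in cyclic
table order rotated so the undistorted reference row (D = 4 mm, TMC = 1)
sits at azimuth 0, the reference sector. Interpolation is periodic PCHIP —
exact at controls, bounded between adjacent control values.

Surface-change semantics: the squeeze displaces the *target*, not the
tracked probe, so the recorded pose stays on the nominal contact circle
(plus noise) while the true acoustic stand-off follows D(α). The pose is
deliberately uninformative about the distortion — compensation must come
from the pressure channel, whose force is the inverse displacement map of
(n − D(α)), clamped at zero (never active at the defaults).

Noise defaults: pose 0.1 mm per axis, attitude 0.2°, pressure 0.05 N,
medium estimate noiseless — plausible magnitudes for a consumer optical
tracker and a strain-gauge handle. All output is bit-reproducible given the
seed.

**What the simulator does not model:** speckle, beamforming, attenuation
and TGC, refraction, multiple scattering, elevation beam width, tissue
deformation beyond a rigid radial shift, and any nonlinearity between
pressure and displacement. Passing tests therefore demonstrate the
geometric and calibration logic of the pipeline, not robustness to real
tissue imaging. (The stated 1 kHz ultrasound frequency of the calibration
setup is recorded in configuration but unused by a geometric model.)

## Reconstruction and evaluation

Per frame: derive B (contact) and C (deepest centre-scanline point) from
the recorded pose; match; detect per-scanline first-crossing echoes above
an intensity threshold (default 0.5 — the synthetic images are binary);
compensate (depths divided by the medium time ratio, then shifted by the
pressure displacement); place into the matched sector's stored geometry —
contact ray at the nominal contact radius, lateral offsets along the axis,
depths inward — so every placed point satisfies its plane equation exactly.
The feedback intensity of a frame is the mean absolute depth shift applied.

Radial error of a placed point is the deviation of its in-plane radius from
the expected outer tube boundary at the point's height — the surface an
inward-looking probe insonifies first. Under this metric a rigid depth
distortion d scores |d| on every scanline, a perfect reconstruction scores
zero, and the uncompensated per-azimuth error reproduces |D(α) − 4|. The
comparison curve accumulates point X and Y coordinates in azimuth order;
"accumulated coordinates" admits more than one reading, so the cumulative
sum sits in one small function (`target_curve`) where an alternative is a
one-line change.

Measured at Δv = 128, seed 1: compensated RMSE ≈ 0.03 mm in both perturbed
experiments (dominated by the 0.039 mm depth quantisation and the 0.025 mm
pressure-noise floor), uncompensated ≈ 1.6 mm (surface) and ≈ 5.2 mm
(medium). These are recomputed, not quoted, by `scripts/acceptance.py` and
the test suite.

## Known limitations

- The general-axis workflow (axis from two plane equations) is supported in
  the geometry layer, but databases are built around an explicit axis; the
  elevational Δh sweep along the axis is not implemented.
- Matching uses two frame points plus the stored representative point; it
  assumes the pose error is small against the sector spacing. Heavy
  trackers drift would require raising the tolerance or Δv escalation.
- Compensation assumes the surface displacement is purely radial and the
  medium factor uniform along a scanline.
- Voxel compounding (hole filling, PNN/FNN) and surface meshing are out of
  scope; the output is a point cloud.
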