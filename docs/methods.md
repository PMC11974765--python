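# Methods

This package re-creates, on synthetic data with exact ground truth, a
micro-CT + Doppler based computational-hemodynamics workflow for a murine
end-to-side arteriovenous fistula (AVF): geometry acquisition, lumen
segmentation, centerline morphometry, Doppler flow estimation, pulsatile
incompressible flow simulation, and wall-shear post-processing (TAWSS, OSI,
Q-criterion). This note records the models, the parameter choices and their
rationale, the numerical policies, and the limits of what the synthetic
validation can show.

## Synthetic AVF geometry

The lumen is the union of two straight variable-diameter tubes in the z = 0
plane: a carotid-like artery through the origin and a fistula/vein branch
leaving the anastomosis (arclength origin, s = 0) at 60 degrees. Sixty
degrees is a typical end-to-side surgical angle; nothing downstream depends
on it strongly and it is a free parameter.

The fistula/vein diameter profile D(s) is a monotone cubic (PCHIP) baseline
through a small set of knots, blended inside a cosine-tapered window of full
width `stenosis_length` to the stenotic diameter
`fistula_diameter * (1 - stenosis_severity)`. The cosine taper makes D(s)
continuously differentiable with its minimum exactly at the prescribed
stenosis centre, so every downstream claim ("the TAWSS peak co-localizes
with the diameter minimum") has an unambiguous ground truth.

Two canonical parameter sets, `AVFShapeParams.day7()` and `.day21()`,
represent the early and late remodeling states. Their free knots (entry and
post-stenotic recovery diameter) are calibrated once, by deterministic root
finding (`calibrate_fistula_profile`), so that the analytic segment
statistics over the first 2 mm and 4 mm of fistula reproduce the study's
remodeling table: day 7 = 0.74 (0.46–0.95) / 0.88 (0.46–1.07) mm, day 21 =
0.58 (0.31–0.96) / 0.86 (0.31–1.71) mm, with artery calibers 0.29→0.39 mm
(proximal) and 0.36→0.46 mm (distal). The day-7 stenosis is short (1.2 mm
window centred at s = 1.4 mm); the day-21 stenosis is longer (1.4 mm) and
shifted downstream (centre 1.8 mm), with entry-region dilation and marked
venous ballooning — the qualitative remodeling pattern described for this
model. The calibrated profiles yield a day-21/day-7 Poiseuille resistance
ratio of ~4.5 for the 4 mm segment; the ratio reported for the in-vivo
geometries (~9) depends on profile details between the tabulated summary
statistics, which a minimal calibrated profile cannot pin down.

## CT emulation and segmentation

`rasterize_to_ct` renders a geometry into a 72 µm isotropic volume (the
imaging protocol's voxel size): voxel centres inside the lumen take 600 HU —
mid-window of the 300–1000 HU contrast-segmentation window — on a 0 HU
background, plus seeded i.i.d. Gaussian noise. The emulation deliberately
omits bone, soft-tissue classes, beam hardening, partial-volume blur and
contrast kinetics: passing the round-trip tests shows the *pipeline* is
self-consistent at the stated voxel size and noise level, not that it would
segment a real neck scan.

Segmentation follows the classical contrast-CT recipe: inclusive HU-window
threshold (default 300–1000), seed-based region growing that keeps only
components containing a seed (6-connectivity by default — the conservative
choice that prevents diagonal leakage across thin walls), then an automated
cleanup (hole filling plus removal of islands under 27 voxels) standing in
for the manual editing a human operator would do; manual steps are not
reproducible, a documented morphological proxy is. Surfaces are 0.5-level
marching-cubes iso-surfaces in physical coordinates, zero-padded first so
border-touching lumens are capped (flagged in metadata), with optional
volume-preserving Taubin smoothing (default 10 iterations) in place of
interactive mesh repair.

## Centerline morphometry

Centerlines are extracted by 3-D skeletonization of the mask, decomposition
of the skeleton graph into endpoint-to-junction paths (loops are rejected:
the vasculature here is a tree), smoothing, and extension of each open end
along its tangent to the mask boundary — skeletonization retreats about one
radius from open tube ends, and the extension restores that length to voxel
accuracy. The inscribed radius is the Euclidean distance transform sampled
along the path. Cross-sections are resampled on planes normal to the local
tangent at half-voxel resolution; the lumen area is the in-plane connected
component containing the centerline point, which keeps a nearby parallel
branch from contaminating the section. "Diameter" is always the
equivalent-circle diameter 2·sqrt(A/pi) — robust to mild non-circularity and
testable through the identity A = pi D²/4. Sections within ~0.4 mm of the
branch confluence are excluded from measured segment statistics:
perpendicular sections are geometrically ill-defined there (the analytic
ground-truth statistics use the full windows).

Two registration details matter for comparisons against ground truth. The
medial-axis junction of an end-to-side connection lies up to one parent
radius inside the daughter branch, so the fistula arclength origin is
relocated to the anatomical anastomosis by back-projecting the junction onto
the artery centerline along the fistula direction (offset d/sin θ, with d
the junction-to-artery-axis distance and θ the branch angle). Even so, a
measured profile carries roughly one voxel of arclength registration
uncertainty, which on a steep stenosis flank is indistinguishable from a
diameter error; round-trip accuracy is therefore assessed against the
ground-truth envelope over ±1 voxel of arclength (a one-voxel band in both
axes).

Segment statistics are sample means on uniform arclength steps (the
tabulated "mean" convention is unstated in such tables; uniform-step sample
mean is the simplest defensible reading). Poiseuille resistance integrates
128 mu / (pi D(s)^4) by the trapezoid rule on the native profile step.

## Doppler flow estimation

Flow follows Q = A·Vbar with Vbar = Vmax/2, the parabolic-profile
convention, applied uniformly at all sites — including the AVF, where real
flow is disturbed; this is a stated fidelity limit of the convention, not of
the implementation. Beam-angle correction by 1/cos(theta) is implemented but
off by default: acquisition protocols bound the angle (< 60 degrees) without
recording it. Inlet boundary data are parabolic profiles whose centerline
value follows the waveform, so the patch-mean is half the peak and the
instantaneous flux is A·V(t)/2.

The waveform generator provides a sinusoid and a "pulse" shape (a von-Mises
bump on a diastolic baseline, the shape of an arterial PW-Doppler trace),
each calibrated on its stored samples so the time-mean and the pulsatility
index (max−min)/mean are met exactly under trapezoidal quadrature. Real
murine traces are not published for this model; the family is a stand-in
with the correct rate (450 beats/min, period 0.1333 s) and pulsatility
class, not an inferred waveform.

## Flow solver

The solver integrates the incompressible Navier–Stokes equations for
Newtonian blood (rho = 1040 kg/m³, mu = 4×10⁻³ Pa·s) in rigid-walled 2-D
planar or axisymmetric body-fitted structured domains, using a collocated
finite-volume method: SIMPLEC pressure–velocity coupling with Rhie–Chow face
interpolation, second-order linear-upwind convection (first-order fallback
behind a flag), over-relaxed non-orthogonality-corrected diffusion,
backward-Euler time stepping, and normalized residual convergence to 10⁻⁶.
Pressure is gauged to zero at the (venous) outlet; inlets carry Dirichlet
velocity profiles; walls are no-slip (optionally moving, for the Couette
test); the axis/symmetry boundary is flux-free.

The AVF is solved on its proximal-artery → fistula → vein flow path as an
axisymmetric variable-radius tube built from the ground-truth D(s) (with a
short cosine blend across the junction step). A body-fitted single-branch
grid keeps the discretization smooth enough for the 1% grid-independence
criterion; a stair-step masked junction grid would not, and a full 3-D
junction solver is out of scope at desk scale. The junction's disturbed-flow
physics (separation at the anastomosis) is therefore only represented by
its axisymmetric analog — the post-stenotic expansion.

Time step: fixed per run, dt = min(CFL bound, T/400), where the CFL bound
keeps the estimated maximum cell CFL at 0.1 (peak inlet centerline velocity
amplified by the worst inlet-to-throat area ratio, against the axial
spacing) and the T/400 floor controls the first-order backward-Euler phase
error. Both bounds respect "max cell CFL ≤ 0.1"; a fixed dt makes step
counts reproducible. Pulsatile runs integrate three cycles and store only
the final one (up to 80–100 samples) for analysis.

Two implementation notes on the inner iterations: transient steps relax less
(alpha_u = 0.9, alpha_p = 0.95) than steady solves (0.7 / 0.7) because the
rho V/dt diagonal already stabilizes the Picard loop; and the
pressure-correction matrix is refreshed only every 10 iterations — the same
cached coefficients are used for the matrix and the flux corrections, so
discrete continuity is enforced exactly at every iteration and only the
convergence path changes. Momentum systems in transient mode are solved by
Jacobi-preconditioned BiCGStab warm-started from the previous iterate, with
a direct-solve fallback.

Validation surfaces: steady Poiseuille flow (centerline velocity, pressure
gradient, wall shear, all within 2–3% at the reference resolution; the wall
shear uses a one-sided quadratic stencil through the wall value, exact for
parabolic profiles); Womersley oscillatory flow at alpha = 3, where the
fundamental harmonic of the computed centerline velocity is compared with
the Bessel-function solution through the analytic centerline-per-flux ratio
(amplitude and phase within 5%, measured ~0.3% and ~0.001 rad); plane
Couette shear (exact); Stokes-regime linearity; and the three-resolution
grid-independence study on the synthetic AVF path (shipped resolutions
48×10 / 96×20 / 192×40 cells; station-sampled cross-section-averaged
velocity and pressure differences between medium and fine below 1%, relative
to the finer profile's scale — pressure is range-normalized because it is
gauged to zero at the outlet).

## Wall metrics

WSS is the tangential viscous traction mu ∂v_t/∂n at the wall, evaluated
with the one-sided quadratic stencil; it is vector-valued (sign follows the
near-wall tangential flow), which is what makes the oscillatory shear index
meaningful. TAWSS is the trapezoidal time-average of |tau| over the final
cycle, with a wrap-around closing segment so the stored samples integrate
over exactly one period. OSI = ½(1 − |∫tau dt| / ∫|tau| dt) — the standard
vector form, with the magnitude of the time-averaged vector in the
numerator. The printed form of this index in the source literature is
typographically ambiguous; the vector form is the only reading compatible
with the stated range (0 unidirectional, 0.5 complete reversal). Elements
with zero TAWSS get OSI 0 (not NaN) so field statistics stay bounded. Both
integrals share one quadrature rule, so the OSI bounds hold to rounding.

Q-criterion: Q = ½(‖Ω‖² − ‖S‖²) with Frobenius norms of the antisymmetric
and symmetric velocity-gradient parts, from metric-corrected index-space
differences (second-order interior; boundary cells use one-sided stencils
and are flagged). Axisymmetric fields include the hoop stretching term v/r.

Wall metrics are binned by nearest centerline arclength (default 0.1–0.2 mm
bins) into max and area-weighted mean profiles; empty bins are reported as
gaps, never interpolated. Correlations between co-located profiles use
Spearman rank correlation; zero-variance inputs are flagged degenerate
rather than silently reported as 0.

## Study conditions for the pulsatile fistula run

The pulsatile stenosed-fistula analyses (tests and `analysis/05`) drive the
day-7 path model with the day-7 AVF flow, 1.33 mL/min at 450 beats/min, with
pulsatility index 1.5 (murine carotid traces typically fall between ~1.3 and
2) and the "pulse" waveform shape. The solver mesh is 60×16 cells over the
first 6 mm of fistula/vein — sized so the CFL-0.1 policy keeps a full
three-cycle run tractable on one CPU; the grid-independence study at the
shipped finer resolutions bounds the residual discretization error. At these
conditions the stenotic jet Reynolds number is a few tens and the Womersley
number ~1.3, so the flow is laminar and quasi-steady with transient
post-stenotic separation during systolic deceleration — the mechanism that
generates nonzero OSI downstream of the constriction where TAWSS is low,
hence the inverse TAWSS–OSI relationship asserted (as a sign) in the tests.

## Known limitations

* Rigid walls and Newtonian rheology (as in the modeled protocol);
  fluid–structure interaction is out of scope.
* The solver domain is a single axisymmetric branch; junction secondary
  flows, and therefore the anastomosis-side OSI elevation seen in 3-D, are
  represented only by their post-stenotic analog. Absolute TAWSS/OSI
  magnitudes of the in-vivo geometries are not reproducible from summary
  statistics and are not targeted.
* The CT emulation contains no anatomy apart from the vessels; segmentation
  robustness claims are limited to the stated noise model.
* The waveform family is a stand-in; measured traces for this model are not
  public.
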