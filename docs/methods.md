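# Methods

## Model and statistics

**Cylinder field.** Veins are treated as infinite cylinders of
paramagnetic (deoxygenated) blood. The extravascular angular-frequency
offset at perpendicular distance r ≥ R from the axis is
`k·Δχω0·(R/r)²·cos(2φ)·sin²ν` and the intravascular offset is
`k·Δχω0·(3cos²ν − 1)`, with ν the tilt of the axis to B0. The product
Δχ·ω0 is a single opaque scale (rad/s) and the dimensionless prefactor k
defaults to 1/2, the standard infinite-cylinder convention; the
literature varies in where factors of 2π or 1/2 are absorbed, so k is an
explicit configuration field rather than claimed physics. Every
statistic the pipeline reports is a ratio (relative CV, fitted phase,
amplitude ordering), so the choice of k and Δχω0 cancels. Tilts are
folded into [0, π/2] via the absolute dot product before evaluation —
both offsets are even in cos ν. No diffusion, finite-length or
time-domain dephasing effects are modelled.

**Orientation angle.** θ_B0 is the angle between the cortical surface
normal and the B0 axis, folded into [0°, 90°] (the normal's sign is
meaningless). Per-face normals come from the triangle edge cross
product; the face winding of the generated meshes is consistent and
outward. A pial vein tangent to the surface has ν = 90° − θ_B0, so the
extravascular envelope sin²ν equals cos²θ_B0 — the fluctuation law the
GRE-like phantom injects. By default θ_B0 is computed on the
mid-thickness surface (vertex-wise average of matched pial/white
meshes), giving one unambiguous angle per cortical column; pial or white
can be selected instead. Surface angles are moved into voxel space by
assigning each gray-matter voxel the angle of the nearest face centroid
(world mm, k-d tree). Nearest-centroid lookup is exact on the test
phantoms and order-independent; how multiple faces mapping to one voxel
should be aggregated is genuinely open, and this is the package's
choice. The B0 axis defaults to world +z and is configurable. Angles are
stored in degrees everywhere; radians appear only inside trig calls.

**CV.** `CV = σ/(μ·√TR_vol)` per voxel, computed after discarding the
initial non-steady-state frames (2 at TR_vol = 3 s; 3 for the faster
1.7 s protocol). σ is the sample standard deviation (ddof = 1) — the
convention is not externally fixed, so it is documented and frozen here.
Voxels with μ ≤ 0 are flagged missing and excluded, never imputed. The
√TR normalisation makes runs with different volume TRs comparable.

**Equal-count binning.** Surface normals of a closed cortex are
sine-distributed in θ_B0 (CDF 1 − cos θ), so fixed-width bins would
weight θ ≈ 90° heavily. Bins are therefore empirical quantiles: a stable
sort assigns ranks and bin k holds ranks in [k·N/n, (k+1)·N/n), so
counts differ by at most one even under massive ties (up-sampled voxels
are 64-fold copies); a warning is emitted when a tie block straddles an
edge. The bin abscissa is the bin-mean θ.

**Relative CV.** Within a stratum, `CV_rel(θ) = 100·(CV̄(θ) −
CV̄(ref))/CV̄(ref)` in percent, where the reference is the bin with the
largest mean θ — a deterministic rule for "the θ ≈ 90° bin" under any
binning. The reference bin is exactly 0 by construction.

**Strata.** One curve for the whole ribbon, one per depth 1–5, and —
when a vein mask is present — one per proximity class (optionally
crossed with depth). Binning is recomputed inside each stratum. Strata
smaller than the bin count are skipped with a warning.

**Depth layering.** The ribbon is up-sampled ×4 (nearest neighbour,
affine rescaled so world coordinates are preserved) before layering; at
native resolution a 2–3 voxel ribbon cannot express five classes. For
each GM voxel, d = dist_CSF/(dist_CSF + dist_WM) with exact Euclidean
distances (voxel centre to nearest non-GM voxel centre of each class,
world mm, anisotropy handled through the EDT sampling); depth index =
ceil(d·5) clamped to [1, 5], so the boundary value d = k/5 falls in
class k. This is standard two-boundary equidistant layering; equivalence
with any particular external layering tool is not claimed. A GM voxel
that can see only one boundary class (the other absent from the grid) is
assigned from the single available distance and counted in a QC field.

**Vein proximity.** Exact EDT of the binary vein mask in world mm;
classes are right-closed bins [0, 0.71], (0.71, 1.41], (1.41, 2.12] mm,
with 0.71 mm itself in the high class and distances beyond 2.12 mm
excluded from proximity analyses. The edges are treated as fixed
constants. The optional SWI path (high-pass phase via complex-phasor
Gaussian smoothing, linear sigmoid weight over the vein-signed half of
the phase range applied n = 4 times, root-sum-of-squares echo
combination, Hessian tubularity score thresholded at a quantile) is
configuration throughout — published SWI chains do not pin these
parameters, the phase sign convention depends on scanner handedness, and
the tubularity score is a generic vesselness rather than any specific
published response function. The phantom path supplies masks directly,
so downstream statistics never depend on these defaults.

**cos² fit.** Nonlinear least squares of `A·cos²(θ + C)` (optionally
`+ D`) on the (bin-mean θ, bin-mean CV or CV_rel) pairs; the
two-parameter form is the default. C is folded into (−90°, 90°]. The
amplitude's standard error is evaluated in the linear harmonic
parameterisation `y = d + p·cos2θ + q·sin2θ` (A = 2√(p²+q²)): at A → 0
the phase is unidentified and the nonlinear covariance collapses, while
(p, q) stay well-conditioned, keeping amplitude significance tests
calibrated for flat curves. R² is computed against the bin means.

**Repeatability.** Pearson correlation of per-bin mean CV between two
runs, default 30 equal-count orientation ranges; undefined (NaN) when a
curve has zero variance.

## The phantom

**Geometry.** `sphere_shell` (default): concentric icospheres (outer
9 mm, inner 6.5 mm → 2.5 mm ribbon, a realistic cortical thickness)
voxelised at 0.4 mm isotropic, ~3·10⁴ native ribbon voxels covering all
orientations with the sine-law histogram a closed cortex produces.
Analytic ground truth: θ from the radial direction, depth from the
radial fraction. `folded_shell` adds a low-order radial perturbation;
its ground-truth normals come from the numerical gradient of the
implicit level function. `flat_slab` has a single θ everywhere (set via
the B0 axis) and exact planar depths. The voxel-weighted θ histogram
follows the sine density only up to grid quantisation; the agreement
tightens as the grid refines, and the exact law is asserted on sampled
normals instead.

**Veins.** Pial vein centerlines are great circles of the outer sphere
(tangent to the surface everywhere, as pial veins follow the folding) or
straight lines in the slab's pial plane; optional ascending veins run
along local normals. Exact point-to-centerline distances are stored for
every voxel (closed-form circle/segment distance), and voxels within the
vein radius (default 0.4 mm, a large pial vein) form the mask.

**Fluctuation law.** Frames are i.i.d. Gaussian: mean
μ0·depth_mean_profile(d), SD σ_th + σ_vasc with

    gre_like:   σ_vasc = g·μ0·cos²(θ_B0)·depth_sd_profile(d)·min(1, (R/r)^falloff)
    bssfp_like: σ_vasc = g·μ0·depth_sd_profile(d)

Defaults: μ0 = 100 a.u., σ_th = 2 a.u. (CV ≈ 0.0115 1/√s at TR 3 s, a
plausible resting-state floor), flat depth profiles, falloff exponent 2
(the cylinder-field law), 200 frames at TR 3 s (a ~10 min run). The
amplitude-modulated surrogate is deliberate: the analysis consumes only
μ and σ, so matching the first two moments keeps every expectation
closed-form (`expected_cv` is returned with the series) without a
biophysical dephasing simulation. Temporal autocorrelation, drift,
motion and physiological noise are not emulated — passing recovery tests
therefore demonstrates the correctness of the analysis chain, not
robustness to real-data artefacts. Swapping the contrast law changes
only σ, never μ, by construction.

**Calibration.** For recovery experiments the gain g is solved in closed
form so that the expected CV_rel of the lowest-θ bin hits a requested
target (default experiments use +50%): with flat depth profiles and no
veins, the expected bin-mean CV is proportional to σ_th + g·μ0·⟨cos²θ⟩_bin,
so the target fixes g from the phantom's own binned orientation
distribution, computed from geometry alone before any noise is drawn.

**Seeding.** One mandatory master seed expands into independent
substreams for geometry, vein placement and noise, so each can be varied
in isolation; identical configurations reproduce byte-identical outputs.

## Numerical choices and degenerate inputs

- Distances: `scipy.ndimage.distance_transform_edt` (exact EDT) with the
  affine's column norms as sampling — anisotropic voxels measured in mm.
- Up-sampling affine: output voxel i′ maps to input coordinate
  (i′ + 0.5)/f − 0.5, tiling each voxel symmetrically so world
  coordinates and label histograms are preserved exactly.
- Degenerate triangles (area ≤ 1e-12 mm²) raise, naming the face index;
  empty ribbons, empty vein masks and constant vesselness inputs raise.
- Depth-bin ties resolved by ceil; proximity edges right-closed.
- The cos² fit starts at (span, 0[, min]) and raises on non-convergence
  with the starting point in the message.
- Pipeline problem sizes in the shipped validation: 0.4 mm phantoms
  (~1.9·10⁶ up-sampled ribbon voxels) for recovery runs, 0.8 mm for the
  quick worked example — sizes chosen so the orientation effect is
  measured with sub-percent precision while a full validation pass stays
  in the tens of seconds.

## Known limitations

- The voxelised θ assigns one angle per voxel from one surface; partial
  volume across the ribbon and across sulcal banks is not modelled.
- Equidistant layering is not equi-volume layering; curvature-driven
  laminar thickness variation is ignored.
- The SWI/vesselness path is a configurable stand-in adequate for mask
  generation on phantoms; its defaults are not tuned to any scanner.
- The phantom's noise model is white Gaussian amplitude modulation;
  conclusions about autocorrelated or structured physiological noise are
  out of scope.
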