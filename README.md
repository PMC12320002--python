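# cortivasc

Analysis of how resting-state fMRI signal fluctuation depends on the
orientation of the cerebral cortex to the main magnetic field B0, on
cortical depth, and on the distance to large veins — together with a
seeded synthetic cortical-vascular phantom that makes every stage of the
analysis verifiable by parameter recovery.

## The scientific problem

Large pial (draining) veins run tangent to the cortical surface, so their
orientation to B0 is well approximated by the cortical orientation angle
θ_B0, the angle between the local surface normal and the field direction.
Modelling a vein as an infinitely long paramagnetic cylinder, the
extravascular frequency offset it creates is

    Δω_extra ∝ Δχ·ω0 · (R/r)² · cos(2φ) · sin²(ν),      ν = 90° − θ_B0,

with cylinder radius R, perpendicular observation distance r ≥ R, in-plane
polar angle φ, and tilt ν of the vein axis to B0; the intravascular offset
is Δω_intra ∝ Δχ·ω0 · (3cos²ν − 1). For T2\*-weighted sequences
(GRE-EPI) this predicts signal fluctuation growing as cos²(θ_B0) and
decaying as (R/r)² away from veins, while sequences with low macrovascular
sensitivity (bSSFP) should show an orientation-flat fluctuation profile.

The package quantifies fluctuation with the TR-normalised coefficient of
temporal variation

    CV = σ / (μ · √TR_vol)        [1/√s],

the reciprocal of the tSNR efficiency, and measures its dependence on

- **orientation** — per-voxel θ_B0 from triangulated pial/white surface
  meshes, averaged into equal-count bins (empirical quantiles of θ_B0,
  cancelling the sine-law over-representation of θ ≈ 90°) and expressed
  relative to the θ ≈ 90° bin: `CV_rel = 100·(CV̄(θ) − CV̄(ref))/CV̄(ref)`;
- **cortical depth** — five equidistant depth classes across the
  up-sampled gray-matter ribbon (depth 1 at CSF, depth 5 at WM), profiled
  relative to depth 5;
- **vein proximity** — exact Euclidean distance to a vein mask, binned
  into high (0–0.71 mm), medium (0.71–1.41 mm) and low (1.41–2.12 mm)
  proximity classes.

Curves are fitted with `CV = A·cos²(θ_B0 + C)` and compared across runs
via the Pearson correlation of per-bin CV over 30 orientation ranges.

Because suitable in-vivo data cannot be shipped, the `phantom` module
generates all inputs synthetically — closed two-surface cortices
(spherical, folded or slab), a CSF/GM/WM ribbon, pial vein centerlines
with exact distances, and Gaussian time series whose fluctuation SD
follows a configurable orientation/depth/vein-distance law (cos²θ_B0 with
(R/r)² falloff for GRE-like contrast, flat for bSSFP-like) — with
closed-form expected CV exposed for tests.

## Worked example

```python
import dataclasses
from cortivasc import (PhantomConfig, build_geometry, calibrate_orientation_gain,
                       generate_phantom, run_pipeline_on_phantom)

cfg = PhantomConfig(seed=7, voxel_size_mm=0.8, outer_radius_mm=8.0,
                    inner_radius_mm=6.0, n_frames=100)
geo = build_geometry(cfg)
gain = calibrate_orientation_gain(cfg, geo, target_cv_rel_pct=50.0)
cfg = dataclasses.replace(cfg, orientation_gain=gain)
report = run_pipeline_on_phantom(generate_phantom(cfg))

curve = report.curves["ribbon"]
print(f"ribbon voxels (up-sampled): {report.qc['ribbon_voxels_upsampled']}")
print(f"CV_rel at theta={curve.theta_mean_deg[0]:.1f} deg: {curve.cv_rel_pct[0]:+.1f}%")
fit = report.fits["ribbon"]
print(f"cos^2 fit: A={fit.amplitude:.1f}%  C={fit.phase_deg:+.2f} deg  R^2={fit.r_squared:.4f}")
```

prints

```
ribbon voxels (up-sampled): 159232
CV_rel at theta=13.0 deg: +51.1%
cos^2 fit: A=53.5%  C=+0.78 deg  R^2=0.9983
```

The phantom was calibrated so that the expected relative CV of the
lowest-orientation bin is +50%; the pipeline recovers +51.1% from the
noisy series, and the fitted cos² curve has its maximum at θ_B0 ≈ 0
(C ≈ 0) with R² ≈ 1 — the injected orientation law is recovered
end-to-end. A bSSFP-like phantom (`contrast_law="bssfp_like"`) run the
same way stays flat within a fraction of a percent at every bin.

A thin CLI wraps the same pipeline:

```sh
cortivasc phantom-generate --out phantom/ --seed 7
cortivasc run --phantom-dir phantom/ --out report/
cortivasc compare report_a/ report_b/
```

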