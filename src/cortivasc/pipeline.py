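"""End-to-end pipeline: time series + anatomy in, stratified curves,
depth profiles, cos^2 fits and a machine-readable report out.

Stage order mirrors the analysis the package implements: discard
non-steady-state frames -> CV map at native resolution -> per-face
theta_B0 voxelised onto the ribbon -> 4x nearest-neighbour up-sampling
of all maps -> equidistant depth assignment -> vein distance binning ->
equal-count orientation curves per stratum -> relative CV -> cos^2 fits.
Everything is deterministic given the configuration (the only random
input is the phantom, which carries its own seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import io as cio
from .depths import DepthVolume, RibbonVolume, equidistant_depths, upsample_nearest
from .metrics import (
    CvVolume,
    FmriSeries,
    StratifiedCurve,
    cv_map,
    depth_profile,
    discard_initial_frames,
    fit_cos2,
    intersession_correlation,
    stratified_curves,
)
from .surfaces import OrientationVolume, face_normals, midthickness, theta_b0, voxelize_theta
from .veins import PROXIMITY_EDGES_MM, VeinMask, distance_to_veins

log = logging.getLogger("cortivasc")

__all__ = ["PipelineConfig", "AnalysisReport", "run_pipeline", "run_pipeline_on_phantom", "compare_sessions"]

CURVE_COLUMNS = ["stratum", "bin_index", "theta_mean_deg", "cv_mean", "cv_rel_pct", "n_voxels"]


@dataclass
class PipelineConfig:
    """Knobs of the analysis chain, with the defaults used throughout.

    n_discard: initial frames dropped (2 for a 3 s volume TR).
    upsample_factor: nearest-neighbour up-sampling before layering (4).
    n_depths: equidistant depth classes (5).
    n_bins_curves / n_bins_correlation: equal-count orientation bins for
    curves (15) and for inter-session correlation (30).
    proximity_edges_mm: vein distance class edges (0.71/1.41/2.12 mm).
    surface: which surface's normals define theta_B0 per voxel
    ("mid" | "pial" | "white").
    fit_include_offset: add the additive offset D to the cos^2 fits.
    """

    n_discard: int = 2
    upsample_factor: int = 4
    n_depths: int = 5
    n_bins_curves: int = 15
    n_bins_correlation: int = 30
    proximity_edges_mm: tuple = PROXIMITY_EDGES_MM
    b0_axis: tuple = (0.0, 0.0, 1.0)
    surface: str = "mid"
    fit_include_offset: bool = False
    cross_depth_proximity: bool = False
    out_dir: str | None = None
    seed: int | None = None

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """Curves, profiles, fits and QC of one pipeline run."""

    curves: dict
    depth_profile: pd.DataFrame
    fits: dict
    qc: dict
    provenance: dict

    def curves_frame(self) -> pd.DataFrame:
        frames = [c.to_frame() for c in self.curves.values()]
        return pd.concat(frames, ignore_index=True)[CURVE_COLUMNS]

    def fits_frame(self) -> pd.DataFrame:
        rows = []
        for stratum, fit in self.fits.items():
            rows.append(
                {
                    "stratum": stratum,
                    "amplitude": fit.amplitude,
                    "phase_deg": fit.phase_deg,
                    "offset": fit.offset if fit.offset is not None else np.nan,
                    "r_squared": fit.r_squared,
                    "amplitude_stderr": fit.amplitude_stderr,
                    "phase_stderr": fit.phase_stderr,
                }
            )
        return pd.DataFrame(rows)


def _select_surface(config: PipelineConfig, pial, white):
    if config.surface == "mid":
        return midthickness(pial, white)
    if config.surface == "pial":
        return pial
    if config.surface == "white":
        return white
    raise ValueError(f"unknown surface choice '{config.surface}'")


def run_pipeline(
    series: FmriSeries,
    pial,
    white,
    ribbon: RibbonVolume,
    vein_mask: VeinMask | None = None,
    config: PipelineConfig | None = None,
) -> AnalysisReport:
    """Run the full analysis on in-memory inputs.

    All volumes must share the ribbon's grid.  A missing vein mask simply
    drops the proximity strata; everything else is produced.
    """
    config = config or PipelineConfig()
    if series.data.shape[:3] != ribbon.data.shape:
        raise ValueError(
            f"series grid {series.data.shape[:3]} does not match ribbon grid {ribbon.data.shape}"
        )
    if vein_mask is not None and vein_mask.data.shape != ribbon.data.shape:
        raise ValueError("vein mask is not on the ribbon grid")

    log.info("discarding %d initial frames of %d", config.n_discard, series.n_frames)
    series = discard_initial_frames(series, config.n_discard)
    cv_native = cv_map(series)

    surf = _select_surface(config, pial, white)
    normals = face_normals(surf)
    per_face = theta_b0(normals, config.b0_axis)
    theta_native = voxelize_theta(
        surf, per_face, ribbon.affine, ribbon.data.shape, ribbon.gm_mask, config.b0_axis
    )
    log.info("voxelised theta over %d ribbon voxels", int(ribbon.gm_mask.sum()))

    f = config.upsample_factor
    rib_up_data, up_affine = upsample_nearest(ribbon.data, ribbon.affine, f)
    ribbon_up = RibbonVolume(rib_up_data, up_affine)
    theta_up_data, _ = upsample_nearest(theta_native.data, ribbon.affine, f)
    theta_up = OrientationVolume(theta_up_data, up_affine, tuple(config.b0_axis))
    cv_up, _ = upsample_nearest(cv_native.cv, ribbon.affine, f)
    mu_up, _ = upsample_nearest(cv_native.mu, ribbon.affine, f)
    sd_up, _ = upsample_nearest(cv_native.sigma, ribbon.affine, f)
    cv_vol = CvVolume(cv_up, mu_up, sd_up, series.tr_s, up_affine)

    depths = equidistant_depths(ribbon_up, config.n_depths, f)
    log.info("layered %d up-sampled GM voxels into %d depths", int((depths.data > 0).sum()), config.n_depths)

    proximity = None
    if vein_mask is not None and vein_mask.n_vein_voxels > 0:
        mask_up, _ = upsample_nearest(vein_mask.data, ribbon.affine, f)
        proximity = distance_to_veins(VeinMask(mask_up, up_affine), config.proximity_edges_mm)

    curves = stratified_curves(
        cv_vol, theta_up, depths, proximity, config.n_bins_curves, config.cross_depth_proximity
    )
    profile = depth_profile(cv_vol, theta_up, depths, normalize_to=config.n_depths)

    fits = {}
    for name, curve in curves.items():
        try:
            fits[name] = fit_cos2(curve, include_offset=config.fit_include_offset, use_relative=True)
        except RuntimeError as err:  # keep the report; record the failure
            warnings.warn(f"cos^2 fit failed for stratum '{name}': {err}", stacklevel=2)

    ribbon_total = int((depths.data > 0).sum())
    depth_counts = {f"depth_{k}": int((depths.data == k).sum()) for k in range(1, config.n_depths + 1)}
    qc = {
        "ribbon_voxels_upsampled": ribbon_total,
        "ribbon_voxels_native": int(ribbon.gm_mask.sum()),
        "depth_counts": depth_counts,
        "depth_count_total": int(sum(depth_counts.values())),
        "ribbon_bin_count_total": int(curves["ribbon"].n_voxels.sum()) if "ribbon" in curves else 0,
        "unreachable_boundary_voxels": depths.n_unreachable,
        "n_vein_voxels_upsampled": int(proximity is not None and (proximity.distance_mm == 0).sum()),
    }
    provenance = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "n_frames_analyzed": series.n_frames,
        "tr_s": series.tr_s,
    }
    report = AnalysisReport(curves, profile, fits, qc, provenance)
    if config.out_dir is not None:
        write_report(report, config.out_dir)
    return report


def run_pipeline_on_phantom(bundle, config: PipelineConfig | None = None) -> AnalysisReport:
    """Convenience wrapper: analyse a generated phantom bundle."""
    vein_mask = bundle.veins.mask if bundle.veins is not None else None
    return run_pipeline(
        bundle.series, bundle.geometry.pial, bundle.geometry.white, bundle.geometry.ribbon,
        vein_mask, config,
    )


def write_report(report: AnalysisReport, out_dir) -> None:
    """Write curves.csv, depth_profile.csv, fits.csv and report.json.

    Fixed column order and explicit float formatting keep reruns of the
    same configuration byte-identical.
    """
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = "%.10g"
    report.curves_frame().to_csv(out / "curves.csv", index=False, float_format=fmt)
    report.depth_profile.to_csv(out / "depth_profile.csv", index=False, float_format=fmt)
    report.fits_frame().to_csv(out / "fits.csv", index=False, float_format=fmt)
    payload = {
        "qc": report.qc,
        "provenance": report.provenance,
        "fits": {
            name: {
                "amplitude": fit.amplitude,
                "phase_deg": fit.phase_deg,
                "offset": fit.offset,
                "r_squared": fit.r_squared,
                "amplitude_stderr": fit.amplitude_stderr,
                "phase_stderr": fit.phase_stderr,
            }
            for name, fit in report.fits.items()
        },
    }
    with open(out / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=float)


def compare_sessions(report_a: AnalysisReport, report_b: AnalysisReport) -> pd.DataFrame:
    """Pearson correlation of per-bin mean CV between two runs/sessions.

    One row per stratum present in both reports; raises when matched
    strata were binned differently.
    """
    rows = []
    for name in report_a.curves:
        if name not in report_b.curves:
            continue
        a, b = report_a.curves[name], report_b.curves[name]
        if a.n_bins != b.n_bins:
            raise ValueError(f"stratum '{name}' binned with {a.n_bins} vs {b.n_bins} bins")
        rows.append({"stratum": name, "pearson_r": intersession_correlation(a, b), "n_bins": a.n_bins})
    return pd.DataFrame(rows)
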