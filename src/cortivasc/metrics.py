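"""Fluctuation metrics: CV maps, equal-count orientation binning,
relative CV, stratified curves, cos^2 fits and inter-session correlation.

The central statistic is the TR-normalised coefficient of temporal
variation

    CV = sigma / (mu * sqrt(TR_vol))      [1/sqrt(s)]

the reciprocal of the tSNR efficiency, computed per voxel after
discarding the initial non-steady-state frames.  Because surface normals
of a folded (roughly spherical) cortex are far more often near 90 deg to
B0 than near 0 deg (sine density), orientation curves are built over
equal-count bins — empirical quantiles of theta_B0 — so every plotted
point averages the same number of voxels.  Within each bin, CV is
expressed relative to the bin with the largest mean theta (theta ~ 90
deg, where pial veins are parallel to B0 and fluctuation is lowest):

    CV_rel(theta) = 100 * (CVbar(theta) - CVbar(ref)) / CVbar(ref)   [%]

Curves are fitted with CV = A * cos^2(theta + C) (optionally plus an
additive offset D), the functional form the extravascular cylinder field
predicts for vessels tangent to the cortical surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "FmriSeries",
    "CvVolume",
    "BinAssignment",
    "StratifiedCurve",
    "Cos2Fit",
    "discard_initial_frames",
    "cv_map",
    "equal_count_bins",
    "relative_cv",
    "stratified_curves",
    "depth_profile",
    "fit_cos2",
    "intersession_correlation",
]


@dataclass
class FmriSeries:
    """4D time series (x, y, z, t) with volume TR in seconds and affine."""

    data: np.ndarray
    tr_s: float
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("series data must be 4D (x, y, z, t)")
        if not self.tr_s > 0:
            raise ValueError("volume TR must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]


@dataclass
class CvVolume:
    """Per-voxel CV (1/sqrt(s)) with the mean and SD maps retained.

    CV is NaN where the temporal mean is non-positive (no meaningful
    signal to normalise by).
    """

    cv: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    tr_s: float
    affine: np.ndarray


@dataclass
class BinAssignment:
    """Result of equal-count binning of theta values.

    bin_index: per-input bin label 0..n_bins-1 (ascending theta);
    theta_mean: per-bin mean theta (the curve abscissa); counts: per-bin
    voxel counts (differing by at most 1); edges: empirical quantile
    edges (n_bins + 1 values, for reporting).
    """

    bin_index: np.ndarray
    theta_mean: np.ndarray
    counts: np.ndarray
    edges: np.ndarray


@dataclass
class StratifiedCurve:
    """Equal-count orientation curve for one stratum.

    stratum: "ribbon", "depth_k", a proximity class name, or a
    combination; arrays are ordered by ascending bin theta.
    """

    stratum: str
    theta_mean_deg: np.ndarray
    cv_mean: np.ndarray
    n_voxels: np.ndarray
    cv_rel_pct: np.ndarray | None = None
    reference_cv: float | None = None

    @property
    def n_bins(self) -> int:
        return len(self.theta_mean_deg)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum": self.stratum,
                "bin_index": np.arange(self.n_bins),
                "theta_mean_deg": self.theta_mean_deg,
                "cv_mean": self.cv_mean,
                "cv_rel_pct": self.cv_rel_pct if self.cv_rel_pct is not None else np.nan,
                "n_voxels": self.n_voxels,
            }
        )


@dataclass
class Cos2Fit:
    """Parameters of y = A * cos^2(theta + C) [+ D]."""

    amplitude: float
    phase_deg: float
    offset: float | None
    r_squared: float
    amplitude_stderr: float
    phase_stderr: float


def discard_initial_frames(series: FmriSeries, n: int) -> FmriSeries:
    """Drop the first ``n`` frames (acquired before the steady state)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if n >= series.n_frames:
        raise ValueError(f"cannot discard {n} of {series.n_frames} frames")
    if n == 0:
        return series
    return FmriSeries(series.data[..., n:], series.tr_s, series.affine)


def cv_map(series: FmriSeries) -> CvVolume:
    """Voxel-wise TR-normalised coefficient of variation.

    sigma is the sample standard deviation (ddof = 1); voxels with
    non-positive temporal mean are flagged NaN rather than imputed.
    """
    if series.n_frames < 2:
        raise ValueError("need at least 2 frames to estimate a standard deviation")
    data = series.data.astype(np.float64, copy=False)
    mu = data.mean(axis=3)
    sigma = data.std(axis=3, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sigma / (mu * np.sqrt(series.tr_s))
    cv = np.where(mu > 0, cv, np.nan)
    return CvVolume(cv, mu, sigma, series.tr_s, series.affine)


def equal_count_bins(theta_values: np.ndarray, n_bins: int) -> BinAssignment:
    """Split theta values into ``n_bins`` equal-count bins by rank.

    A stable sort assigns ranks; bin k holds the values with rank in
    [k*N/n, (k+1)*N/n), so counts differ by at most 1 regardless of ties.
    When tied values straddle a bin edge the split inside the tie block
    is arbitrary (but deterministic); a warning reports it.
    """
    theta = np.asarray(theta_values, dtype=float).ravel()
    n = theta.size
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if n < n_bins:
        raise ValueError(f"cannot form {n_bins} bins from {n} values")
    order = np.argsort(theta, kind="stable")
    bin_of_rank = (np.arange(n, dtype=np.int64) * n_bins) // n
    bin_index = np.empty(n, dtype=np.int32)
    bin_index[order] = bin_of_rank

    sorted_theta = theta[order]
    boundary_ranks = np.flatnonzero(np.diff(bin_of_rank)) + 1
    if np.any(sorted_theta[boundary_ranks] == sorted_theta[boundary_ranks - 1]):
        warnings.warn(
            "tied theta values straddle an equal-count bin edge; the tie "
            "block was split to keep counts equal",
            stacklevel=2,
        )
    counts = np.bincount(bin_index, minlength=n_bins)
    sums = np.bincount(bin_index, weights=theta, minlength=n_bins)
    theta_mean = sums / counts
    interior = sorted_theta[boundary_ranks]
    edges = np.concatenate(([sorted_theta[0]], interior, [sorted_theta[-1]]))
    return BinAssignment(bin_index, theta_mean, counts, edges)


def relative_cv(curve: StratifiedCurve) -> StratifiedCurve:
    """Fill CV_rel (%) relative to the bin with the largest mean theta."""
    ref = int(np.argmax(curve.theta_mean_deg))
    ref_cv = float(curve.cv_mean[ref])
    if ref_cv == 0:
        raise ValueError("reference-bin CV is zero; relative CV undefined")
    rel = 100.0 * (curve.cv_mean - ref_cv) / ref_cv
    rel[ref] = 0.0  # exact by construction
    return replace(curve, cv_rel_pct=rel, reference_cv=ref_cv)


def _curve_for_stratum(theta, cv, n_bins, stratum) -> StratifiedCurve:
    bins = equal_count_bins(theta, n_bins)
    cv_sums = np.bincount(bins.bin_index, weights=cv, minlength=n_bins)
    curve = StratifiedCurve(
        stratum=stratum,
        theta_mean_deg=bins.theta_mean,
        cv_mean=cv_sums / bins.counts,
        n_voxels=bins.counts,
    )
    return relative_cv(curve)


def stratified_curves(
    cv_vol: CvVolume,
    theta_vol,
    depth_vol,
    proximity=None,
    n_bins: int = 15,
    cross_depth_proximity: bool = False,
) -> dict:
    """Equal-count orientation curves for the ribbon and each stratum.

    Returns a dict keyed by stratum name: "ribbon", "depth_1".."depth_n",
    and — when a vein distance volume is given — each proximity class
    ("high", "medium", "low"), optionally crossed with depth.  Binning is
    recomputed inside every stratum so per-bin counts stay equal.  Strata
    with fewer voxels than ``n_bins`` are skipped with a warning.
    """
    theta = np.asarray(theta_vol.data, dtype=float)
    depth = np.asarray(depth_vol.data)
    if theta.shape != cv_vol.cv.shape or depth.shape != cv_vol.cv.shape:
        raise ValueError("CV, orientation and depth volumes must share one grid")
    valid = np.isfinite(cv_vol.cv) & np.isfinite(theta) & (depth > 0)

    strata: dict[str, np.ndarray] = {"ribbon": valid}
    n_depths = int(depth_vol.n_depths)
    for k in range(1, n_depths + 1):
        strata[f"depth_{k}"] = valid & (depth == k)
    if proximity is not None:
        if proximity.proximity_class.shape != cv_vol.cv.shape:
            raise ValueError("vein distance volume is not on the analysis grid")
        from .veins import PROXIMITY_NAMES

        for name in PROXIMITY_NAMES[:3]:
            strata[name] = valid & proximity.class_mask(name)
            if cross_depth_proximity:
                for k in range(1, n_depths + 1):
                    strata[f"{name}_depth_{k}"] = strata[name] & (depth == k)

    out: dict[str, StratifiedCurve] = {}
    for name, mask in strata.items():
        n = int(mask.sum())
        if n < n_bins:
            warnings.warn(f"stratum '{name}' has {n} voxels (< {n_bins} bins); skipped", stacklevel=2)
            continue
        out[name] = _curve_for_stratum(theta[mask], cv_vol.cv[mask], n_bins, name)
    return out


def depth_profile(
    cv_vol: CvVolume,
    theta_vol,
    depth_vol,
    n_theta_groups: int = 6,
    normalize_to: int = 5,
) -> pd.DataFrame:
    """Mean CV, mu and sigma per (theta group, depth), absolute and
    relative to a reference depth.

    Theta groups are equal-count over the ribbon.  The reference depth
    defaults to the deepest class (closest to WM, farthest from pial
    veins), whose CV varies least across orientations; relative values
    are 100 * (x_d - x_ref) / x_ref in percent.  Empty cells are NaN.
    """
    theta = np.asarray(theta_vol.data, dtype=float)
    depth = np.asarray(depth_vol.data)
    valid = np.isfinite(cv_vol.cv) & np.isfinite(theta) & (depth > 0)
    n_depths = int(depth_vol.n_depths)
    if not 1 <= normalize_to <= n_depths:
        raise ValueError(f"normalize_to must be in 1..{n_depths}")
    bins = equal_count_bins(theta[valid], n_theta_groups)

    idx = np.argwhere(valid)
    group = bins.bin_index
    d = depth[valid]
    rows = []
    for g in range(n_theta_groups):
        in_g = group == g
        ref_vals = {}
        cells = {}
        for k in range(1, n_depths + 1):
            cell = in_g & (d == k)
            if cell.any():
                sel = tuple(idx[cell].T)
                cells[k] = {
                    "cv": float(np.mean(cv_vol.cv[sel])),
                    "mu": float(np.mean(cv_vol.mu[sel])),
                    "sigma": float(np.mean(cv_vol.sigma[sel])),
                    "n_voxels": int(cell.sum()),
                }
            else:
                cells[k] = None
        ref = cells.get(normalize_to)
        for k in range(1, n_depths + 1):
            c = cells[k]
            row = {
                "theta_group": g,
                "theta_group_mean_deg": float(bins.theta_mean[g]),
                "depth": k,
                "cv": np.nan,
                "mu": np.nan,
                "sigma": np.nan,
                "cv_rel_pct": np.nan,
                "mu_rel_pct": np.nan,
                "sigma_rel_pct": np.nan,
                "n_voxels": 0,
            }
            if c is not None:
                row.update(cv=c["cv"], mu=c["mu"], sigma=c["sigma"], n_voxels=c["n_voxels"])
                if ref is not None:
                    for key in ("cv", "mu", "sigma"):
                        if ref[key] != 0:
                            row[f"{key}_rel_pct"] = 100.0 * (c[key] - ref[key]) / ref[key]
            rows.append(row)
    return pd.DataFrame(rows)


def _cos2(theta_deg, amplitude, phase_deg):
    return amplitude * np.cos(np.deg2rad(theta_deg + phase_deg)) ** 2


def _harmonic_amplitude_stderr(theta_deg: np.ndarray, y: np.ndarray) -> float:
    """Standard error of the cos^2 amplitude via the linear (p, q) form.

    A cos^2(t + C) + D = (D + A/2) + p cos(2t) + q sin(2t) with
    A = 2 sqrt(p^2 + q^2); OLS gives the covariance of (p, q) and the
    amplitude error is 2 * rms of their standard errors.
    """
    t = np.deg2rad(theta_deg)
    design = np.column_stack([np.ones_like(t), np.cos(2 * t), np.sin(2 * t)])
    coef, res, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    dof = len(y) - rank
    if dof <= 0:
        return float("nan")
    resid = y - design @ coef
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.pinv(design.T @ design)
    return 2.0 * float(np.sqrt(0.5 * (cov[1, 1] + cov[2, 2])))


def _fold_phase(phase_deg: float) -> float:
    """Fold the fitted phase into (-90, 90] (cos^2 has period 180 deg)."""
    folded = (phase_deg + 90.0) % 180.0 - 90.0
    if folded == -90.0:
        folded = 90.0
    return folded


def fit_cos2(curve: StratifiedCurve, include_offset: bool = False, use_relative: bool = False) -> Cos2Fit:
    """Nonlinear least-squares fit of y = A cos^2(theta + C) [+ D].

    Fits the per-bin means (CV by default, CV_rel in percent with
    ``use_relative``).  The phase C is reported in degrees, folded into
    (-90, 90]; R^2 is computed against the bin means.  Non-convergence
    raises with the residual state attached.
    """
    if curve.n_bins < 4:
        raise ValueError("need at least 4 bins for a cos^2 fit")
    x = np.asarray(curve.theta_mean_deg, dtype=float)
    if use_relative:
        if curve.cv_rel_pct is None:
            raise ValueError("curve has no relative CV; call relative_cv first")
        y = np.asarray(curve.cv_rel_pct, dtype=float)
    else:
        y = np.asarray(curve.cv_mean, dtype=float)

    span = float(y.max() - y.min())
    if include_offset:
        model = lambda t, a, c, d: _cos2(t, a, c) + d  # noqa: E731
        p0 = [span if span > 0 else 1.0, 0.0, float(y.min())]
    else:
        model = _cos2
        p0 = [span if span > 0 else 1.0, 0.0]
    try:
        popt, pcov = optimize.curve_fit(model, x, y, p0=p0, maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(f"cos^2 fit did not converge (start {p0}): {err}") from err
    perr = np.sqrt(np.diag(pcov))
    resid = y - model(x, *popt)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    amplitude, phase = float(popt[0]), float(popt[1])
    # cos^2(t + C) is invariant under (A, C) -> (A, C + 180); fold C, and
    # report the amplitude with its fitted sign.  The amplitude standard
    # error comes from the linear harmonic parameterisation
    # y = d + p cos(2t) + q sin(2t) with A = 2 sqrt(p^2 + q^2): at A -> 0
    # the phase C is unidentified and the nonlinear covariance collapses,
    # while (p, q) stay well-conditioned, so amplitude significance tests
    # remain calibrated for flat curves.
    amp_se = _harmonic_amplitude_stderr(x, y)
    return Cos2Fit(
        amplitude=amplitude,
        phase_deg=_fold_phase(phase),
        offset=float(popt[2]) if include_offset else None,
        r_squared=r2,
        amplitude_stderr=amp_se,
        phase_stderr=float(perr[1]),
    )


def intersession_correlation(curve_a: StratifiedCurve, curve_b: StratifiedCurve) -> float:
    """Pearson correlation of per-bin mean CV across two sessions.

    Returns NaN when either curve has zero variance (correlation
    undefined).  Both curves must share the bin count (default analyses
    use 30 orientation ranges).
    """
    if curve_a.n_bins != curve_b.n_bins:
        raise ValueError("curves must share the same number of bins")
    a = np.asarray(curve_a.cv_mean, dtype=float)
    b = np.asarray(curve_b.cv_mean, dtype=float)
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)
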