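"""Vein masks, vein distance maps and proximity classes.

Voxels are stratified by their Euclidean distance (world mm) to the
nearest vein voxel: high proximity 0-0.71 mm, medium 0.71-1.41 mm, low
1.41-2.12 mm; everything farther is "beyond" and excluded from the
proximity analyses.  The bins are half-open on the right, so a distance
of exactly 0.71 mm is high proximity, and a distance of 0 mm means the
voxel lies inside a vein.

A vein mask can be supplied directly (the phantom's path) or derived
from multi-echo gradient-echo data via a susceptibility-weighted image:
the high-pass filtered phase is mapped through a sigmoid weight that
suppresses paramagnetic-sign phase, the weight is applied repeatedly to
the magnitude, echoes are combined as a root sum of squares, and a
Hessian tubularity score thresholded at a quantile yields the mask.
The sigmoid shape, number of applications, high-pass kernel, tubularity
scales and threshold are all explicit configuration; the mask, not the
filter, is what the downstream statistics consume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import sato

__all__ = [
    "PROXIMITY_EDGES_MM",
    "PROXIMITY_NAMES",
    "VeinMask",
    "VeinDistanceVolume",
    "MultiEchoComplexVolume",
    "distance_to_veins",
    "swi_from_multiecho",
    "vesselness_mask",
]

PROXIMITY_EDGES_MM = (0.71, 1.41, 2.12)
PROXIMITY_NAMES = ("high", "medium", "low", "beyond")


@dataclass
class VeinMask:
    """Binary vein mask (1 = vein) with its affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.isin(np.unique(self.data), (0, 1)).all():
            raise ValueError("vein mask must be binary")
        self.data = self.data.astype(np.uint8)

    def voxel_sizes(self) -> np.ndarray:
        return np.linalg.norm(np.asarray(self.affine, dtype=float)[:3, :3], axis=0)

    @property
    def n_vein_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class VeinDistanceVolume:
    """Per-voxel distance to the nearest vein (mm) and proximity class.

    ``proximity_class``: 0 = high, 1 = medium, 2 = low, 3 = beyond
    (``PROXIMITY_NAMES``).  Distance is exactly 0 on vein voxels.
    """

    distance_mm: np.ndarray
    proximity_class: np.ndarray
    affine: np.ndarray
    edges_mm: tuple[float, float, float] = PROXIMITY_EDGES_MM

    def class_mask(self, name: str) -> np.ndarray:
        return self.proximity_class == PROXIMITY_NAMES.index(name)


@dataclass
class MultiEchoComplexVolume:
    """Per-echo magnitude and phase grids with echo times (ms)."""

    magnitudes: list
    phases: list
    echo_times_ms: list

    def __post_init__(self) -> None:
        if len(self.magnitudes) != len(self.phases) or len(self.magnitudes) != len(self.echo_times_ms):
            raise ValueError("magnitudes, phases and echo times must align")
        if not self.magnitudes:
            raise ValueError("at least one echo required")


def distance_to_veins(mask: VeinMask, edges_mm=PROXIMITY_EDGES_MM) -> VeinDistanceVolume:
    """Exact Euclidean distance transform of a vein mask, binned by proximity.

    Raises on an empty mask (no vein voxel to measure from).
    """
    if mask.n_vein_voxels == 0:
        raise ValueError("vein mask is empty; no distances can be computed")
    dist = ndimage.distance_transform_edt(mask.data == 0, sampling=mask.voxel_sizes())
    # side='left': a distance exactly on an edge stays in the nearer class.
    cls = np.searchsorted(np.asarray(edges_mm, dtype=float), dist, side="left").astype(np.int8)
    return VeinDistanceVolume(dist.astype(np.float32), cls, np.asarray(mask.affine, dtype=float), tuple(edges_mm))


def _highpass_phase(phase: np.ndarray, kernel_mm: float, voxel_size_mm) -> np.ndarray:
    """High-pass filter a wrapped phase map via its complex phasor.

    Smoothing exp(i*phase) with a Gaussian of FWHM ``kernel_mm`` and
    taking the phase of the ratio removes slowly varying background phase
    without unwrapping artefacts.
    """
    if kernel_mm <= 0:
        return phase
    sigma_vox = (kernel_mm / 2.3548) / np.asarray(voxel_size_mm, dtype=float)
    phasor = np.exp(1j * phase)
    low = ndimage.gaussian_filter(phasor.real, sigma_vox) + 1j * ndimage.gaussian_filter(
        phasor.imag, sigma_vox
    )
    low = np.where(np.abs(low) == 0, 1.0, low)
    return np.angle(phasor * np.conj(low / np.abs(low)))


def swi_from_multiecho(
    data: MultiEchoComplexVolume,
    n_sigmoid_applications: int = 4,
    highpass_kernel_mm: float = 8.0,
    voxel_size_mm=1.0,
    vein_phase_negative: bool = True,
):
    """Susceptibility-weighted image from multi-echo magnitude/phase data.

    Per echo the high-pass filtered phase is mapped through a linear
    sigmoid weight w in [0, 1] over the vein-sign half of the phase range
    (w = 1 at phase 0, w = 0 at the vein-sign pole), the weight is applied
    ``n`` times multiplicatively to the magnitude, and echoes are combined
    as the root sum of squares.  Phase values outside (-pi, pi] are
    wrapped, with a warning reporting the count.
    """
    if n_sigmoid_applications < 0:
        raise ValueError("n_sigmoid_applications must be >= 0")
    combined = None
    n_wrapped = 0
    for mag, phase in zip(data.magnitudes, data.phases):
        mag = np.asarray(mag, dtype=float)
        phase = np.asarray(phase, dtype=float)
        out_of_range = (phase <= -np.pi) | (phase > np.pi)
        if out_of_range.any():
            n_wrapped += int(out_of_range.sum())
            phase = np.angle(np.exp(1j * phase))
        hp = _highpass_phase(phase, highpass_kernel_mm, voxel_size_mm)
        if vein_phase_negative:
            w = np.clip(1.0 + hp / np.pi, 0.0, 1.0)
        else:
            w = np.clip(1.0 - hp / np.pi, 0.0, 1.0)
        swi_echo = mag * w**n_sigmoid_applications
        combined = swi_echo**2 if combined is None else combined + swi_echo**2
    if n_wrapped:
        warnings.warn(f"wrapped {n_wrapped} phase values outside (-pi, pi]", stacklevel=2)
    return np.sqrt(combined)


def vesselness_mask(
    vessel_weighted: np.ndarray,
    threshold_quantile: float = 0.99,
    scales_mm=(0.5, 1.0),
    voxel_size_mm: float = 1.0,
    affine: np.ndarray | None = None,
) -> VeinMask:
    """Threshold a Hessian tubularity score into a binary vein mask.

    Veins are dark tubes in the SWI, so the tubularity score (a generic
    Hessian-eigenvalue vesselness, used here in place of any particular
    published response function) is evaluated with dark-ridge polarity
    and thresholded at the given quantile of its distribution.
    """
    img = np.asarray(vessel_weighted, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("vessel-weighted image must be finite")
    if img.max() == img.min():
        raise ValueError("constant input has no vessel contrast")
    if not 0.0 < threshold_quantile < 1.0:
        raise ValueError("threshold_quantile must be in (0, 1)")
    sigmas = np.asarray(scales_mm, dtype=float) / float(voxel_size_mm)
    score = sato(img, sigmas=sigmas, black_ridges=True)
    thr = np.quantile(score, threshold_quantile)
    mask = (score > thr).astype(np.uint8)
    if affine is None:
        affine = np.diag([voxel_size_mm] * 3 + [1.0])
    return VeinMask(mask, np.asarray(affine, dtype=float))
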