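"""Magnitude-image preprocessing: noise estimation, SNR conversion,
grid interpolation, smoothing and SNR-based voxel exclusion.

The fixed order of operations is

1. voxel-wise conversion of magnitude signal to SNR on the native 19F grid,
   with the Gudbjartsson-Patz correction for the Rician (non-Gaussian) noise
   distribution of low-SNR magnitude data:

       SNR = sqrt(SI_m^2 - sigma_g^2) / sigma_g

   where the Gaussian noise SD is inferred from the magnitude SD in a
   signal-free ROI: sigma_g = sigma_m / sqrt(2 - pi/2);
2. cubic ("bicubic") interpolation to the anatomical resolution;
3. in-plane Gaussian smoothing (default SD 3 anatomical pixels);
4. exclusion of all voxels with smoothed SNR < 5 on the TR = 5 s image.

Where SI_m < sigma_g the radicand is negative and SNR is clamped to 0:
those voxels are below the noise floor and the TR4 threshold removes them
from analysis anyway.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .image_io import MagnitudeSeries, RoiSet, resample_between_grids

__all__ = [
    "RICIAN_SD_FACTOR",
    "NoiseEstimate",
    "SnrSeries",
    "estimate_noise",
    "magnitude_to_snr",
    "smooth_snr",
    "build_validity_mask",
    "roi_mean_snr",
    "preprocess_session",
]

# SD of a zero-signal Rician (Rayleigh) variable is sigma_g * sqrt(2 - pi/2)
RICIAN_SD_FACTOR = float(np.sqrt(2.0 - np.pi / 2.0))

DEFAULT_SNR_THRESHOLD = 5.0
DEFAULT_SMOOTH_SD_PX = 3.0


@dataclass(frozen=True)
class NoiseEstimate:
    """Magnitude-noise estimate from a signal-free ROI.

    ``sigma_m`` is the sample SD of the magnitude signal in the ROI;
    ``sigma_g = sigma_m / sqrt(2 - pi/2)`` is the implied SD of the
    underlying complex Gaussian noise channels.
    """

    sigma_m: float
    sigma_g: float
    n_voxels: int


@dataclass
class SnrSeries:
    """Noise-corrected SNR volumes on the anatomical grid.

    ``validity`` marks voxels that survive the TR4 SNR threshold; excluded
    voxels carry no value for analysis purposes.  ``provenance`` records the
    sigma estimates, smoothing width and threshold used.
    """

    tr_ms: np.ndarray
    volumes: np.ndarray          # (n_tr, nx, ny, nz), smoothed SNR
    affine: np.ndarray
    validity: np.ndarray         # boolean, same spatial shape
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tr_ms = np.asarray(self.tr_ms, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.validity = np.asarray(self.validity, dtype=bool)
        if self.volumes.shape[1:] != self.validity.shape:
            raise ValueError("validity mask must match volume grid")
        if np.any(self.volumes[:, self.validity] < 0):
            raise ValueError("SNR must be nonnegative where defined")


def estimate_noise(volume: np.ndarray, background_mask: np.ndarray) -> NoiseEstimate:
    """Estimate sigma_m and sigma_g from a signal-free background ROI.

    The ROI must contain at least 10 voxels and show nonzero variance.
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(background_mask, dtype=bool)
    if mask.shape != volume.shape:
        raise ValueError("background ROI must be on the volume's grid")
    vals = volume[mask]
    if vals.size < 10:
        raise ValueError(f"background ROI too small ({vals.size} voxels, need >= 10)")
    sigma_m = float(np.std(vals, ddof=1))
    if sigma_m <= 0:
        raise ValueError("background ROI has zero variance; not a noise region")
    return NoiseEstimate(
        sigma_m=sigma_m, sigma_g=sigma_m / RICIAN_SD_FACTOR, n_voxels=int(vals.size)
    )


def magnitude_to_snr(volume: np.ndarray, sigma_g: float) -> np.ndarray:
    """Gudbjartsson-Patz corrected SNR: sqrt(SI_m^2 - sigma_g^2) / sigma_g.

    Sub-noise-floor voxels (SI_m < sigma_g) are clamped to SNR 0.
    """
    if sigma_g <= 0:
        raise ValueError("sigma_g must be positive")
    si = np.asarray(volume, dtype=float)
    radicand = np.maximum(si**2 - sigma_g**2, 0.0)
    return np.sqrt(radicand) / sigma_g


def smooth_snr(
    volume: np.ndarray, sd_px: float = DEFAULT_SMOOTH_SD_PX, in_plane: bool = True
) -> np.ndarray:
    """Gaussian smoothing of an SNR volume (SD in pixels).

    Default is 2-D in-plane smoothing per slice, because slices are thick
    and gapped; set ``in_plane=False`` for isotropic 3-D smoothing.
    """
    if sd_px <= 0:
        raise ValueError("smoothing SD must be positive")
    vol = np.asarray(volume, dtype=float)
    sigma = (sd_px, sd_px, 0.0) if in_plane else (sd_px, sd_px, sd_px)
    return ndimage.gaussian_filter(vol, sigma=sigma, mode="nearest")


def build_validity_mask(
    snr_volumes: np.ndarray,
    tr_ms: Sequence[float],
    threshold: float = DEFAULT_SNR_THRESHOLD,
    reference_tr_ms: float = 5000.0,
) -> np.ndarray:
    """Voxels kept for analysis: smoothed SNR >= threshold on the TR = 5 s image."""
    tr = np.asarray(tr_ms, dtype=float)
    idx = np.flatnonzero(np.isclose(tr, reference_tr_ms))
    if idx.size == 0:
        raise ValueError(f"series has no TR = {reference_tr_ms} ms image")
    return np.asarray(snr_volumes)[idx[0]] >= threshold


def preprocess_session(
    series: MagnitudeSeries,
    background_mask_native: np.ndarray,
    target_shape: tuple[int, int, int],
    target_affine: np.ndarray,
    smooth_sd_px: float = DEFAULT_SMOOTH_SD_PX,
    snr_threshold: float = DEFAULT_SNR_THRESHOLD,
    interp_order: int = 3,
    in_plane: bool = True,
    sigma_per_tr: bool = False,
) -> SnrSeries:
    """Run the full preprocessing chain on one multi-TR session.

    Noise is estimated once from the least T1-weighted (longest-TR) image
    and reused for all TRs of the session (identical receiver settings
    within a series); ``sigma_per_tr=True`` estimates it per TR instead.
    """
    noise_ref = estimate_noise(series.volumes[-1], background_mask_native)
    out = []
    sigmas = []
    for vol in series.volumes:
        est = (
            estimate_noise(vol, background_mask_native) if sigma_per_tr else noise_ref
        )
        sigmas.append(est.sigma_g)
        snr = magnitude_to_snr(vol, est.sigma_g)
        snr_anat = resample_between_grids(
            snr, series.affine, target_shape, target_affine, order=interp_order
        )
        # cubic interpolation can undershoot below zero near edges
        snr_anat = np.maximum(snr_anat, 0.0)
        out.append(smooth_snr(snr_anat, smooth_sd_px, in_plane=in_plane))
    volumes = np.stack(out)
    validity = build_validity_mask(volumes, series.tr_ms, threshold=snr_threshold)
    return SnrSeries(
        tr_ms=series.tr_ms.copy(),
        volumes=volumes,
        affine=np.asarray(target_affine, dtype=float),
        validity=validity,
        provenance={
            "sigma_m": noise_ref.sigma_m,
            "sigma_g": noise_ref.sigma_g,
            "sigma_g_per_tr": sigmas,
            "noise_roi_voxels": noise_ref.n_voxels,
            "smooth_sd_px": smooth_sd_px,
            "snr_threshold": snr_threshold,
            "interp_order": interp_order,
            "in_plane_smoothing": in_plane,
        },
    )


def roi_mean_snr(
    snr: SnrSeries, rois: RoiSet, label: int
) -> tuple[np.ndarray | None, int]:
    """Mean SNR per TR over (placenta ROI intersect validity mask).

    Returns ``(means, n_valid_voxels)``; if the intersection is empty the
    placenta is unusable for fitting and ``(None, 0)`` is returned.
    """
    if label not in rois.label_map:
        raise KeyError(f"unknown placenta label {label}")
    if rois.labels.shape != snr.validity.shape:
        raise ValueError("ROI labels and SNR series are on different grids")
    mask = rois.mask(label) & snr.validity
    n = int(mask.sum())
    if n == 0:
        return None, 0
    return snr.volumes[:, mask].mean(axis=1), n
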