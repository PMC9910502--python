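"""Photon-counting detector model: blur, pixel binning, Poisson counts.

The default detector is an idealized photon-counting device with 50-um
square pixels, a single-pixel point-spread function (each pixel integrates
the intensity over its own footprint and nothing else), unit absorption
efficiency, and ideal scatter rejection (no additive background).  The
optional Gaussian ``sigma_det`` path models a detector of finite resolution
for fringe-visibility studies; for single-pixel-PSF detectors the effective
resolution is taken to be two pixel pitches (the Nyquist limit of the
sampled image), which is carried as metadata rather than as a blur.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .wave_optics import IntensityImage

__all__ = [
    "DetectorModel",
    "apply_detector_blur",
    "bin_to_pixels",
    "expected_counts",
    "poisson_counts",
    "display_operator",
]


@dataclass
class DetectorModel:
    """Detector parameters; lengths in mm, fluence in photons/mm^2."""

    pixel_pitch: float = 0.05
    sigma_det: float = 0.0          # 0 = single-pixel (box) PSF
    fluence: float = 3.6e6
    seed: int = 0
    sensor_material: str = "cdte"   # metadata only: efficiency fixed at 1
    sensor_thickness: float = 0.75  # metadata only

    def __post_init__(self):
        if not self.pixel_pitch > 0:
            raise ValueError("pixel_pitch must be > 0")
        if self.fluence < 0:
            raise ValueError("fluence must be >= 0")
        if self.sigma_det < 0:
            raise ValueError("sigma_det must be >= 0")

    @property
    def resolution(self) -> float:
        """Effective spatial resolution: 2x pitch for a single-pixel PSF."""
        return self.sigma_det if self.sigma_det > 0 else 2.0 * self.pixel_pitch


def apply_detector_blur(img: IntensityImage, sigma_det: float) -> IntensityImage:
    """Convolve with a normalized Gaussian of standard deviation ``sigma_det`` (mm).

    ``sigma_det = 0`` is the identity.  A sigma below the grid pitch is
    under-resolved; the discrete kernel is still normalized but a warning is
    emitted.
    """
    if sigma_det < 0:
        raise ValueError("sigma_det must be >= 0")
    if sigma_det == 0:
        return IntensityImage(img.grid_pitch, img.values.copy(),
                              img.normalization_region)
    if sigma_det < img.grid_pitch:
        warnings.warn(
            f"sigma_det {sigma_det:g} mm below grid pitch {img.grid_pitch:g} mm: "
            "blur kernel is under-resolved", stacklevel=2)
    sigma_px = sigma_det / img.grid_pitch
    # wide truncation: the Gaussian semigroup property holds to ~1e-7
    if img.values.ndim == 1:
        out = gaussian_filter1d(img.values, sigma_px, mode="nearest", truncate=8.0)
    else:
        out = gaussian_filter(img.values, sigma_px, mode="nearest", truncate=8.0)
    return IntensityImage(img.grid_pitch, out, img.normalization_region)


def bin_to_pixels(img: IntensityImage, pitch: float) -> IntensityImage:
    """Area-integrate onto detector pixels of ``pitch`` mm.

    The pixel pitch must be an integer multiple of the simulation grid
    pitch and the grid size divisible by that ratio; each pixel value is
    the mean of the simulation samples in its footprint.
    """
    ratio = pitch / img.grid_pitch
    k = int(round(ratio))
    if abs(ratio - k) > 1e-9 or k < 1:
        near = max(1, int(round(ratio))) * img.grid_pitch
        raise ValueError(
            f"pixel pitch {pitch:g} mm is not an integer multiple of the grid "
            f"pitch {img.grid_pitch:g} mm; nearest valid pitch is {near:g} mm"
        )
    vals = img.values
    if vals.shape[-1] % k:
        raise ValueError(
            f"grid size {vals.shape[-1]} not divisible by binning factor {k}"
        )
    if vals.ndim == 1:
        out = vals.reshape(-1, k).mean(axis=1)
    else:
        if vals.shape[0] % k:
            raise ValueError(
                f"grid size {vals.shape[0]} not divisible by binning factor {k}"
            )
        out = vals.reshape(vals.shape[0] // k, k, vals.shape[1] // k, k).mean(axis=(1, 3))
    return IntensityImage(grid_pitch=pitch, values=out)


def expected_counts(img: IntensityImage, fluence: float, pitch: float | None = None,
                    background_transmission: float = 1.0) -> np.ndarray:
    """Mean photon count per pixel.

    ``counts = fluence * pitch^2 * background_transmission * (I/I0)`` --
    incident fluence on the patient, square pixel area, Beer-Lambert
    transmission of the undisturbed background ray, and the normalized
    intensity.  Ideal scatter rejection: no additive term.
    """
    if fluence < 0:
        raise ValueError("fluence must be >= 0")
    if pitch is None:
        pitch = img.grid_pitch
    return fluence * pitch ** 2 * background_transmission * img.values


def poisson_counts(expected: np.ndarray, seed: int) -> np.ndarray:
    """Independent Poisson draws per pixel; identical seed, identical image."""
    expected = np.asarray(expected)
    if np.any(expected < 0):
        raise ValueError("expected counts must be >= 0")
    rng = np.random.default_rng(seed)
    return rng.poisson(expected)


def display_operator(counts: np.ndarray, unsharp_sigma_px: float = 2.0,
                     unsharp_gain: float = 1.0,
                     window: tuple[float, float] | None = None) -> np.ndarray:
    """Generic display rendering: unsharp masking plus windowing.

    A deliberately simple, non-reproducing stand-in for vendor
    post-processing chains; off by default everywhere.
    """
    arr = np.asarray(counts, dtype=float)
    if unsharp_gain > 0 and unsharp_sigma_px > 0:
        low = (gaussian_filter1d(arr, unsharp_sigma_px, mode="nearest")
               if arr.ndim == 1 else
               gaussian_filter(arr, unsharp_sigma_px, mode="nearest"))
        arr = arr + unsharp_gain * (arr - low)
    if window is not None:
        lo, hi = window
        arr = np.clip((arr - lo) / max(hi - lo, 1e-12), 0.0, 1.0)
    return arr
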