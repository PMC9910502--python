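"""Complex exit wavefronts and single-distance Fresnel propagation.

The projection approximation turns a thickness map into a complex
transmission ``T(x) = exp(-sum_m mu_m t_m / 2) * exp(i*phi)`` with
``phi = -(2*pi/lambda) * sum_m delta_m t_m``.  Free-space propagation over a
distance ``z`` is the convolution with the Fresnel kernel, evaluated
spectrally with the transfer function ``H(nu) = exp(-i*pi*lambda*z*|nu|^2)``
(the global ``exp(ikz)`` phase is dropped) on an edge-replication-padded
grid.  The sign pair (phi as above, H as above) is self-consistent; a direct
O(N^2) quadrature of the Fresnel integral with the matching kernel
``exp(+i*pi*(x-x')^2/(lambda*z))`` is provided as an independent oracle.

A parallel beam (unit magnification) is assumed throughout; cone-beam
geometries are handled upstream by rescaling to the effective propagation
distance, not by a divergent propagator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import MaterialTable
from .phantom import ThicknessMap, check_sampling
from .spectrum import wavelength_from_energy

__all__ = [
    "ComplexWavefront",
    "IntensityImage",
    "PropagationPlan",
    "PropagationError",
    "transmission_function",
    "fresnel_propagate",
    "fresnel_integral_direct",
    "intensity_image",
]


class PropagationError(ValueError):
    """Sampling violation or invalid propagation request."""


@dataclass
class ComplexWavefront:
    """Complex amplitude on a regular grid at a fixed plane.

    ``samples`` is 1D or 2D complex; ``grid_pitch`` in mm; ``wavelength`` in
    mm; ``plane_z`` records the accumulated propagation distance in mm.
    """

    grid_pitch: float
    samples: np.ndarray
    wavelength: float
    plane_z: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples)
        if not np.iscomplexobj(self.samples):
            self.samples = self.samples.astype(complex)
        if not self.grid_pitch > 0:
            raise ValueError("grid_pitch must be > 0")
        if not self.wavelength > 0:
            raise ValueError("wavelength must be > 0")
        if not np.all(np.isfinite(self.samples.view(float))):
            raise ValueError("wavefront samples must be finite")

    def intensity(self) -> np.ndarray:
        return np.abs(self.samples) ** 2


@dataclass
class IntensityImage:
    """Relative intensity I/I0 on a regular grid.

    ``normalization_region`` is the index range (slice, or pair of slices in
    2D) whose mean defined I0; it averages to 1 after normalization.
    """

    grid_pitch: float
    values: np.ndarray
    normalization_region: object = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("intensity values must be >= 0")

    @property
    def x(self) -> np.ndarray:
        n = self.values.shape[-1]
        return self.grid_pitch * (np.arange(n) - n // 2)


@dataclass
class PropagationPlan:
    """How to propagate: distance, padding and method.

    ``padding_factor >= 2`` edge-replication padding suppresses wrap-around
    from the circular spectral convolution; the result is cropped back to
    the input extent.  Negative distances (back-propagation) must be enabled
    explicitly with ``inverse=True``.
    """

    distance: float
    padding_factor: int = 2
    pad_mode: str = "edge"
    method: str = "spectral"
    inverse: bool = False
    crop: bool = True  # False returns the full padded grid (diagnostics)

    def __post_init__(self):
        if self.method != "spectral":
            raise ValueError("only the spectral method is implemented in the plan")
        if self.padding_factor < 2:
            raise ValueError("padding_factor must be >= 2 for the spectral method")
        if self.distance < 0 and not self.inverse:
            raise PropagationError(
                "negative distance requires the explicit inverse flag"
            )


def transmission_function(tmap: ThicknessMap, table: MaterialTable,
                          energy: float) -> ComplexWavefront:
    """Exit wavefront of a unit plane wave through a thickness map.

    Per sample: ``phi = -(2*pi/lambda) * sum_m delta_m(E) * t_m`` and
    amplitude ``exp(-sum_m mu_m(E) * t_m / 2)``.
    """
    lam = wavelength_from_energy(energy)
    shape = next(iter(tmap.thickness.values())).shape
    delta_t = np.zeros(shape)
    mu_t = np.zeros(shape)
    for name, t in tmap.thickness.items():
        mat = table[name]
        delta_t = delta_t + mat.delta_at(energy) * t
        mu_t = mu_t + mat.mu_at(energy) * t
    phi = -(2.0 * np.pi / lam) * delta_t
    amp = np.exp(-mu_t / 2.0)
    return ComplexWavefront(grid_pitch=tmap.grid_pitch,
                            samples=amp * np.exp(1j * phi),
                            wavelength=lam, plane_z=0.0)


def _pad_1d(a: np.ndarray, factor: int, mode: str) -> tuple[np.ndarray, tuple[int, int]]:
    n = a.shape[-1]
    total = n * (factor - 1)
    before = total // 2
    after = total - before
    return np.pad(a, [(0, 0)] * (a.ndim - 1) + [(before, after)], mode=mode), (before, after)


def fresnel_propagate(wf: ComplexWavefront, plan: PropagationPlan) -> ComplexWavefront:
    """Propagate a wavefront by ``plan.distance`` with the spectral method.

    Refuses to run when the grid violates the sampling bound
    ``pitch <= sqrt(lambda*|z|)/2``.  ``z = 0`` returns an identical copy.
    """
    z = plan.distance
    if z == 0:
        return ComplexWavefront(wf.grid_pitch, wf.samples.copy(),
                                wf.wavelength, wf.plane_z)
    chk = check_sampling(wf.grid_pitch, wf.wavelength, abs(z))
    if not chk.passed:
        raise PropagationError(
            f"grid pitch {wf.grid_pitch:g} mm violates the sampling bound "
            f"sqrt(lambda*z)/2 = {chk.bound:g} mm (ratio {chk.ratio:.2f})"
        )
    a = wf.samples
    if a.ndim == 1:
        padded, (before, _after) = _pad_1d(a, plan.padding_factor, plan.pad_mode)
        n = padded.shape[0]
        nu = np.fft.fftfreq(n, d=wf.grid_pitch)
        H = np.exp(-1j * np.pi * wf.wavelength * z * nu ** 2)
        out = np.fft.ifft(np.fft.fft(padded) * H)
        if plan.crop:
            out = out[before:before + a.shape[0]]
    elif a.ndim == 2:
        pads = []
        padded = a
        for axis in (0, 1):
            npix = padded.shape[axis]
            total = npix * (plan.padding_factor - 1)
            b = total // 2
            pw = [(0, 0), (0, 0)]
            pw[axis] = (b, total - b)
            padded = np.pad(padded, pw, mode=plan.pad_mode)
            pads.append(b)
        ny, nx = padded.shape
        nuy = np.fft.fftfreq(ny, d=wf.grid_pitch)[:, None]
        nux = np.fft.fftfreq(nx, d=wf.grid_pitch)[None, :]
        H = np.exp(-1j * np.pi * wf.wavelength * z * (nux ** 2 + nuy ** 2))
        out = np.fft.ifft2(np.fft.fft2(padded) * H)
        if plan.crop:
            out = out[pads[0]:pads[0] + a.shape[0], pads[1]:pads[1] + a.shape[1]]
    else:
        raise ValueError("wavefront must be 1D or 2D")
    return ComplexWavefront(wf.grid_pitch, out, wf.wavelength, wf.plane_z + z)


def fresnel_integral_direct(wf: ComplexWavefront, z: float,
                            max_samples: int = 4096) -> ComplexWavefront:
    """Direct O(N^2) quadrature of the 1D Fresnel integral (test oracle).

    ``u'(x) = exp(-i*pi/4)/sqrt(lambda*z) * sum_k u(x_k) *
    exp(i*pi*(x-x_k)^2/(lambda*z)) * dx``, the convolution form of the
    Fresnel diffraction integral with the global ``exp(ikz)`` phase dropped
    (matching the spectral transfer function).  Valid as an oracle only
    where the sampled chirp is not aliased over the grid, i.e. for
    ``N * pitch^2 <~ lambda*z``.
    """
    if wf.samples.ndim != 1:
        raise ValueError("direct integral oracle is 1D only")
    n = wf.samples.shape[0]
    if n > max_samples:
        raise ValueError(f"grid too large for O(N^2) oracle ({n} > {max_samples})")
    if z == 0:
        return ComplexWavefront(wf.grid_pitch, wf.samples.copy(),
                                wf.wavelength, wf.plane_z)
    lam = wf.wavelength
    p = wf.grid_pitch
    m = np.arange(-(n - 1), n) * p
    kernel = np.exp(1j * np.pi * m ** 2 / (lam * z))
    pref = np.exp(-1j * np.pi / 4.0) / np.sqrt(lam * abs(z)) * p
    if z < 0:
        kernel = np.conj(np.exp(1j * np.pi * m ** 2 / (lam * abs(z))))
        pref = np.conj(np.exp(-1j * np.pi / 4.0)) / np.sqrt(lam * abs(z)) * p
    out = pref * np.convolve(wf.samples, kernel, mode="valid")
    return ComplexWavefront(p, out, lam, wf.plane_z + z)


def intensity_image(wf: ComplexWavefront, normalization_region=None) -> IntensityImage:
    """Squared magnitude normalized to the mean over a background region.

    ``normalization_region`` is an index slice (or pair of slices in 2D)
    that must lie in undisturbed background; ``None`` normalizes to the
    global mean.
    """
    inten = wf.intensity()
    region = inten if normalization_region is None else inten[normalization_region]
    i0 = float(np.mean(region))
    if i0 == 0:
        raise ValueError("normalization region has zero mean intensity")
    return IntensityImage(grid_pitch=wf.grid_pitch, values=inten / i0,
                          normalization_region=normalization_region)
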