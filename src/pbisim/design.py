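"""System-design algebra for propagation-based phase-contrast imaging.

Near-field fringes have a characteristic transverse scale set by the first
Fresnel zone, ``sigma_FZ = sqrt(lambda*z)``.  Resolving them requires a
numerical (or detector) sampling of at most ``sigma_FZ/2``, and seeing them
requires transverse coherence ``l_t ~ R*lambda/sigma_src`` of at least
``sigma_FZ/2``, which fixes the minimal source-to-patient distance for a
given source size.  With a divergent beam the magnification
``M = (R + d)/R`` rescales the patient-to-detector distance ``d`` to an
effective propagation distance ``z_eff = d/M``.  All lengths in mm,
energies in keV; the formulas are dimensionally homogeneous so any
consistent length unit gives the same dimensionless ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectrum import wavelength_from_energy

__all__ = [
    "GeometryDesign",
    "fresnel_zone_width",
    "sampling_bound",
    "coherence_length",
    "required_ratio",
    "minimal_R",
    "effective_distance",
    "solve_patient_detector_distance",
    "system_report",
]


def fresnel_zone_width(wavelength: float, z: float) -> float:
    """First-Fresnel-zone width ``sigma_FZ = sqrt(lambda*z)`` in mm."""
    if not wavelength > 0:
        raise ValueError("wavelength must be > 0")
    if z < 0:
        raise ValueError("z must be >= 0")
    return float(np.sqrt(wavelength * z))


def sampling_bound(wavelength: float, z: float) -> float:
    """Maximum admissible sampling pitch ``sqrt(lambda*z)/2`` in mm."""
    return fresnel_zone_width(wavelength, z) / 2.0


def coherence_length(R: float, wavelength: float, sigma_src: float) -> float:
    """Transverse coherence length ``l_t = R*lambda/sigma_src`` in mm."""
    if not (R > 0 and wavelength > 0 and sigma_src > 0):
        raise ValueError("R, wavelength and sigma_src must all be > 0")
    return R * wavelength / sigma_src


def required_ratio(z: float, wavelength: float) -> float:
    """Minimum ``R/sigma_src`` for coherent fringes: ``sqrt(z/(2*lambda))``.

    Algebraically equivalent to demanding a transverse coherence length of
    at least ``sigma_FZ/sqrt(2) = sqrt(lambda*z/2)``, the coherence
    criterion this package adopts throughout.
    """
    if not wavelength > 0:
        raise ValueError("wavelength must be > 0")
    if z < 0:
        raise ValueError("z must be >= 0")
    return float(np.sqrt(z / (2.0 * wavelength)))


def minimal_R(sigma_src: float, z: float, wavelength: float) -> float:
    """Minimal source-to-patient distance ``sigma_src*sqrt(z/(2*lambda))`` in mm."""
    if not sigma_src > 0:
        raise ValueError("sigma_src must be > 0")
    return sigma_src * required_ratio(z, wavelength)


def effective_distance(dpd: float, M: float) -> float:
    """Effective propagation distance ``d/M`` of a magnifying geometry."""
    if not M >= 1:
        raise ValueError("magnification must be >= 1")
    return dpd / M


def solve_patient_detector_distance(R: float, z_eff: float) -> tuple[float, float]:
    """Patient-to-detector distance and magnification for a target ``z_eff``.

    Solves ``z_eff = d/M`` with ``M = (R + d)/R`` for ``d``:
    ``d = R*z_eff/(R - z_eff)``.  Infeasible when ``z_eff >= R``.
    """
    if not R > 0:
        raise ValueError("R must be > 0")
    if z_eff < 0:
        raise ValueError("z_eff must be >= 0")
    if z_eff >= R:
        raise ValueError(
            f"infeasible geometry: z_eff {z_eff:g} must be < R {R:g}"
        )
    dpd = R * z_eff / (R - z_eff)
    M = (R + dpd) / R
    return dpd, M


@dataclass
class GeometryDesign:
    """A complete source/patient/detector geometry.

    Either construct directly, or use :meth:`from_effective_distance` to
    derive the patient-to-detector distance from a target ``z_eff``.
    ``R = inf`` (parallel beam) gives ``M = 1`` and ``z_eff = dpd``.
    """

    energy: float
    source_size: float             # sigma_src, mm
    source_to_patient: float       # R, mm (may be inf for parallel beam)
    patient_to_detector: float     # dpd, mm
    detector_resolution: float = 0.1   # sigma_det, mm
    wavelength: float = field(init=False)

    def __post_init__(self):
        self.wavelength = wavelength_from_energy(self.energy)
        if self.patient_to_detector < 0:
            raise ValueError("patient_to_detector must be >= 0")
        if not self.source_size > 0:
            raise ValueError("source_size must be > 0")
        if not self.source_to_patient > 0:
            raise ValueError("source_to_patient must be > 0 (inf = parallel)")

    @classmethod
    def from_effective_distance(cls, energy: float, source_size: float,
                                source_to_patient: float, z_eff: float,
                                detector_resolution: float = 0.1):
        if np.isinf(source_to_patient):
            dpd = z_eff
        else:
            dpd, _ = solve_patient_detector_distance(source_to_patient, z_eff)
        return cls(energy=energy, source_size=source_size,
                   source_to_patient=source_to_patient,
                   patient_to_detector=dpd,
                   detector_resolution=detector_resolution)

    @property
    def parallel_beam(self) -> bool:
        return bool(np.isinf(self.source_to_patient))

    @property
    def magnification(self) -> float:
        if self.parallel_beam:
            return 1.0
        return (self.source_to_patient + self.patient_to_detector) / self.source_to_patient

    @property
    def z_eff(self) -> float:
        return self.patient_to_detector / self.magnification


def system_report(design: GeometryDesign) -> dict:
    """Summarize a geometry: lengths, Fresnel-zone scale, coherence and
    detector-resolution regime.

    The coherence criterion is ``l_t >= sigma_FZ/sqrt(2)`` (equivalent to
    ``R/sigma_src >= sqrt(z/(2*lambda))``); the detector is in the "ideal"
    regime when ``sigma_det <= sigma_FZ/2`` (optimal fringe visibility),
    and detector-limited otherwise.
    """
    lam = design.wavelength
    z = design.z_eff
    s_fz = fresnel_zone_width(lam, z)
    bound = sampling_bound(lam, z)
    if design.parallel_beam:
        l_t = float("inf")
        total = float("inf")
    else:
        l_t = coherence_length(design.source_to_patient, lam, design.source_size)
        total = design.source_to_patient + design.patient_to_detector
    coh_need = s_fz / np.sqrt(2.0)
    coherent = l_t >= coh_need
    ideal = design.detector_resolution <= s_fz / 2.0
    boundary = design.detector_resolution == s_fz / 2.0
    return {
        "energy_keV": design.energy,
        "wavelength_mm": lam,
        "source_size_mm": design.source_size,
        "source_to_patient_mm": design.source_to_patient,
        "patient_to_detector_mm": design.patient_to_detector,
        "magnification": design.magnification,
        "effective_distance_mm": z,
        "total_length_mm": total,
        "fresnel_zone_width_mm": s_fz,
        "sampling_bound_mm": bound,
        "coherence_length_mm": l_t,
        "coherence_ok": bool(coherent),
        "coherence_margin": float(l_t / coh_need) if s_fz > 0 else float("inf"),
        "detector_resolution_mm": design.detector_resolution,
        "detector_regime": ("ideal-boundary" if boundary
                            else "ideal" if ideal else "detector-limited"),
    }
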