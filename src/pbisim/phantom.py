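"""Analytic phantom scenes and their projection into thickness maps.

Scenes are desk-scale stand-ins for full anthropomorphic anatomy: isolated
airways (air-filled cylinders with a muscle-like wall), muscle-equivalent
spherical nodules, embedded in a homogeneous lung-parenchyma slab that every
ray traverses.  Objects displace the background along their chord, so the
per-ray total thickness always equals the slab thickness exactly.

Projection is analytic (circle chords), which is exact for these shapes; a
nearest-neighbour voxel-grid projector is provided for small user-supplied
voxel phantoms.  The transverse grid is centered at 0 with sample positions
``pitch * (i - n/2)`` and even sample count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CylinderAirway",
    "SphereNodule",
    "PhantomScene",
    "ThicknessMap",
    "SamplingCheck",
    "GeometryError",
    "SamplingError",
    "chord_length_circle",
    "grid_axis",
    "project_airway",
    "project_scene",
    "project_voxel_grid",
    "check_sampling",
    "build_fig3_scene",
    "build_nodule_scene",
]


class GeometryError(ValueError):
    """Invalid or inconsistent scene geometry."""


class SamplingError(ValueError):
    """Grid pitch too coarse for the requested operation."""


def chord_length_circle(offset: float, radius: float) -> float:
    """Chord length of a circle of ``radius`` at transverse ``offset`` (mm).

    ``2*sqrt(radius**2 - offset**2)`` inside the circle, 0 at or beyond the
    tangent ray.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if abs(offset) >= radius:
        return 0.0
    return 2.0 * float(np.sqrt(radius * radius - offset * offset))


def _chords(x: np.ndarray, center: float, radius: float) -> np.ndarray:
    """Vectorized circle chords at transverse positions ``x``."""
    off2 = (x - center) ** 2
    return 2.0 * np.sqrt(np.maximum(radius * radius - off2, 0.0))


@dataclass
class CylinderAirway:
    """Air-filled cylinder with a concentric wall, axis perpendicular to the beam.

    ``lumen_diameter`` is the inner (air) diameter D in mm, ``wall_thickness``
    the wall thickness d in mm; the outer radius is ``D/2 + d``.
    """

    lumen_diameter: float
    wall_thickness: float
    center_offset: float = 0.0
    lumen_material: str = "air"
    wall_material: str = "muscle"

    def __post_init__(self):
        if not self.lumen_diameter > 0:
            raise GeometryError("lumen_diameter must be > 0")
        if self.wall_thickness < 0:
            raise GeometryError("wall_thickness must be >= 0")

    @property
    def inner_radius(self) -> float:
        return self.lumen_diameter / 2.0

    @property
    def outer_radius(self) -> float:
        return self.lumen_diameter / 2.0 + self.wall_thickness

    @property
    def interval(self) -> tuple[float, float]:
        return (self.center_offset - self.outer_radius,
                self.center_offset + self.outer_radius)


@dataclass
class SphereNodule:
    """Solid sphere of ``diameter`` mm, muscle-equivalent by default."""

    diameter: float
    center: tuple[float, float] = (0.0, 0.0)
    material: str = "muscle"

    def __post_init__(self):
        if not self.diameter > 0:
            raise GeometryError("diameter must be > 0")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def interval(self) -> tuple[float, float]:
        return (self.center[0] - self.radius, self.center[0] + self.radius)


@dataclass
class PhantomScene:
    """Objects embedded in (and displacing) a homogeneous background slab."""

    background_material: str = "lung_parenchyma"
    background_thickness: float = 100.0
    objects: list = field(default_factory=list)
    extent: float = 10.0

    def __post_init__(self):
        if not self.background_thickness > 0:
            raise GeometryError("background_thickness must be > 0")
        if not self.extent > 0:
            raise GeometryError("extent must be > 0")
        for obj in self.objects:
            lo, hi = obj.interval
            if lo < -self.extent / 2 or hi > self.extent / 2:
                raise GeometryError(
                    f"object spans [{lo:g}, {hi:g}] mm, outside extent "
                    f"+/-{self.extent / 2:g} mm"
                )
            chord = 2 * (obj.outer_radius if isinstance(obj, CylinderAirway)
                         else obj.radius)
            if chord > self.background_thickness:
                raise GeometryError(
                    "object chord exceeds background slab thickness"
                )
        ivals = sorted(obj.interval for obj in self.objects)
        for (lo1, hi1), (lo2, hi2) in zip(ivals, ivals[1:]):
            if lo2 < hi1:
                raise GeometryError("objects overlap in projection")


@dataclass
class ThicknessMap:
    """Per-material projected path length on a regular transverse grid.

    ``thickness`` maps material name to an array (1D profile or 2D image) of
    path lengths in mm.  For every ray the per-material thicknesses sum to
    the background slab thickness (displacement conservation).
    """

    grid_pitch: float
    thickness: dict[str, np.ndarray]
    background_thickness: float

    def __post_init__(self):
        if not self.grid_pitch > 0:
            raise GeometryError("grid_pitch must be > 0")
        for name, arr in self.thickness.items():
            if np.any(arr < -1e-12):
                raise GeometryError(f"negative thickness for {name!r}")

    @property
    def n(self) -> int:
        return next(iter(self.thickness.values())).shape[-1]

    @property
    def x(self) -> np.ndarray:
        return grid_axis(self.grid_pitch, self.n)

    def total(self) -> np.ndarray:
        return sum(self.thickness.values())


def grid_axis(pitch: float, n: int) -> np.ndarray:
    """Sample positions ``pitch * (i - n/2)`` for an even-count grid."""
    if n % 2:
        raise ValueError("grid size must be even")
    return pitch * (np.arange(n) - n // 2)


def _grid_for(scene: PhantomScene, pitch: float) -> np.ndarray:
    n = int(np.ceil(scene.extent / pitch))
    n += n % 2
    return grid_axis(pitch, n)


def project_airway(airway: CylinderAirway, pitch: float, extent: float = 10.0,
                   allow_unresolved: bool = False) -> ThicknessMap:
    """Project a single airway (no background) onto a 1D profile.

    Lumen thickness is the inner-circle chord; wall thickness is the outer
    minus inner chord.  Refuses a pitch coarser than the wall thickness
    unless ``allow_unresolved`` is set.
    """
    if airway.wall_thickness > 0 and pitch > airway.wall_thickness and not allow_unresolved:
        raise SamplingError(
            f"pitch {pitch:g} mm does not resolve wall thickness "
            f"{airway.wall_thickness:g} mm (pass allow_unresolved to override)"
        )
    x = _grid_for(PhantomScene(extent=extent), pitch)
    inner = _chords(x, airway.center_offset, airway.inner_radius)
    outer = _chords(x, airway.center_offset, airway.outer_radius)
    return ThicknessMap(
        grid_pitch=pitch,
        thickness={airway.lumen_material: inner,
                   airway.wall_material: outer - inner},
        background_thickness=0.0,
    )


def project_scene(scene: PhantomScene, pitch: float, mode: str = "1d",
                  allow_unresolved: bool = False) -> ThicknessMap:
    """Project a scene onto a thickness map at wave-optics pitch.

    ``mode="1d"`` produces a transverse profile (cylinder cross-section
    studies); ``mode="2d"`` a square image (nodule regions of interest).
    Objects displace the background along their chord, so per-ray totals
    equal the slab thickness to machine precision.
    """
    x = _grid_for(scene, pitch)
    if mode == "2d":
        y = x.copy()
        shape = (len(y), len(x))
    elif mode == "1d":
        shape = (len(x),)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    maps: dict[str, np.ndarray] = {
        scene.background_material: np.full(shape, scene.background_thickness)
    }

    def add(material: str, arr: np.ndarray):
        maps[material] = maps.get(material, np.zeros(shape)) + arr
        maps[scene.background_material] = maps[scene.background_material] - arr

    for obj in scene.objects:
        if isinstance(obj, CylinderAirway):
            if (obj.wall_thickness > 0 and pitch > obj.wall_thickness
                    and not allow_unresolved):
                raise SamplingError(
                    f"pitch {pitch:g} mm does not resolve wall thickness "
                    f"{obj.wall_thickness:g} mm"
                )
            inner = _chords(x, obj.center_offset, obj.inner_radius)
            outer = _chords(x, obj.center_offset, obj.outer_radius)
            if mode == "2d":
                inner = np.broadcast_to(inner, shape).copy()
                outer = np.broadcast_to(outer, shape).copy()
            add(obj.lumen_material, inner)
            add(obj.wall_material, outer - inner)
        elif isinstance(obj, SphereNodule):
            if mode == "2d":
                r2 = ((x[None, :] - obj.center[0]) ** 2
                      + (y[:, None] - obj.center[1]) ** 2)
            else:
                r2 = (x - obj.center[0]) ** 2 + obj.center[1] ** 2
            chord = 2.0 * np.sqrt(np.maximum(obj.radius ** 2 - r2, 0.0))
            add(obj.material, chord)
        else:
            raise GeometryError(f"unsupported object type {type(obj).__name__}")

    bg = maps[scene.background_material]
    if np.any(bg < -1e-9):
        raise GeometryError("objects displace more than the background slab")
    maps[scene.background_material] = np.maximum(bg, 0.0)
    return ThicknessMap(grid_pitch=pitch, thickness=maps,
                        background_thickness=scene.background_thickness)


def project_voxel_grid(grid: np.ndarray, voxel_pitch: float,
                       material_codes: dict[int, str],
                       background_thickness: float = 0.0) -> ThicknessMap:
    """Nearest-neighbour ray sum through a small voxel phantom.

    ``grid`` is a (nz, nx) or (nz, ny, nx) integer array of material codes;
    the beam runs along axis 0.  Each voxel contributes ``voxel_pitch`` of
    path length to its material.
    """
    grid = np.asarray(grid)
    maps: dict[str, np.ndarray] = {}
    for code, name in material_codes.items():
        maps[name] = (grid == code).sum(axis=0).astype(float) * voxel_pitch
    return ThicknessMap(grid_pitch=voxel_pitch, thickness=maps,
                        background_thickness=background_thickness)


@dataclass
class SamplingCheck:
    passed: bool
    bound: float          # max admissible pitch sqrt(lambda*z)/2, mm
    ratio: float          # pitch / bound (inf when bound = 0 and pitch > 0)
    no_propagation: bool  # z = 0: nothing to sample


def check_sampling(pitch: float, wavelength: float, z: float) -> SamplingCheck:
    """Wave-propagation sampling guard: pass iff ``pitch <= sqrt(lambda*z)/2``.

    At ``z = 0`` there is no diffraction to resolve and the check passes
    trivially, flagged ``no_propagation``.
    """
    if not wavelength > 0:
        raise ValueError("wavelength must be > 0")
    if z < 0:
        raise ValueError("z must be >= 0 (use the inverse flag for back-propagation)")
    if z == 0:
        return SamplingCheck(True, 0.0, 0.0, True)
    bound = float(np.sqrt(wavelength * z) / 2.0)
    return SamplingCheck(pitch <= bound, bound, pitch / bound, False)


def build_fig3_scene(wall_thickness: float, background_thickness: float = 100.0,
                     extent: float = 10.0) -> PhantomScene:
    """Canonical isolated-airway scene: 2-mm air lumen, muscle wall, parenchyma slab.

    ``wall_thickness`` must lie in (0, 1] mm (the studied range is
    0.1-0.4 mm).  The parenchyma slab thickness is a configurable stand-in:
    intensities are normalized to the parenchyma-only region, so its exact
    value only sets the overall attenuation level.
    """
    if not (0 < wall_thickness <= 1.0):
        raise GeometryError(
            f"wall_thickness must be in (0, 1] mm, got {wall_thickness}"
        )
    airway = CylinderAirway(lumen_diameter=2.0, wall_thickness=wall_thickness)
    return PhantomScene(background_material="lung_parenchyma",
                        background_thickness=background_thickness,
                        objects=[airway], extent=extent)


def build_nodule_scene(diameter: float, background_thickness: float = 100.0,
                       extent: float | None = None) -> PhantomScene:
    """Muscle-equivalent sphere in a parenchyma slab (nodule ROI scene)."""
    if extent is None:
        extent = max(4.0 * diameter, diameter + 4.0)
    nodule = SphereNodule(diameter=diameter)
    return PhantomScene(background_material="lung_parenchyma",
                        background_thickness=background_thickness,
                        objects=[nodule], extent=extent)
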