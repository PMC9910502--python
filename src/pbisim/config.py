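"""Run configuration and the end-to-end simulation pipeline.

A :class:`RunConfig` captures one virtual-radiography run: scene, spectrum,
propagation distance, wave-optics grid, detector, and output paths.  The
three canonical acquisition settings are

* ``phase_contrast`` -- monochromatic beam, ``z > 0``;
* ``conventional``   -- filtered tungsten spectrum, ``z = 0``;
* ``control``        -- monochromatic beam, ``z = 0``.

``run_simulation`` executes project -> transmit -> propagate -> blur ->
bin -> counts -> metrics and is a pure function of (config, seed): the run
report echoes every parameter so a run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .detector import (DetectorModel, apply_detector_blur, bin_to_pixels,
                       expected_counts, poisson_counts)
from .materials import MaterialTable, builtin_table, load_material_table
from .metrics import edge_width, extract_profile, fringe_visibility, wall_thickness_estimate
from .phantom import (PhantomScene, build_fig3_scene, build_nodule_scene,
                      check_sampling, project_scene)
from .spectrum import (Spectrum, bundled_tungsten_120kvp, mean_energy,
                       monochromatic, polychromatic_image, read_spectrum,
                       wavelength_from_energy)
from .wave_optics import (IntensityImage, PropagationPlan, fresnel_propagate,
                          intensity_image, transmission_function)

__all__ = [
    "RunConfig", "SimulationResult", "ConfigError",
    "run_simulation", "load_config", "save_config",
    "write_image", "write_profile", "write_report",
]

MODES = ("phase_contrast", "conventional", "control")


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """One simulation run.  Lengths mm, energies keV, fluence photons/mm^2."""

    mode: str = "phase_contrast"
    scene: dict = field(default_factory=lambda: {
        "kind": "fig3_airway", "wall_thickness": 0.2,
        "background_thickness": 100.0, "extent": 10.0})
    spectrum: dict = field(default_factory=lambda: {"energy": 60.0})
    geometry: dict = field(default_factory=lambda: {"z": 12000.0})
    grid: dict = field(default_factory=lambda: {"pitch": 0.005, "mode": "1d"})
    detector: dict = field(default_factory=lambda: {
        "pixel_pitch": 0.05, "sigma_det": 0.0, "fluence": 3.6e6, "seed": 0})
    materials_file: str | None = None
    experimental_polychromatic: bool = False
    output: dict = field(default_factory=lambda: {"directory": None, "prefix": "run"})

    def validate(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"mode must be one of {MODES}, got {self.mode!r}")
        z = float(self.geometry.get("z", 0.0))
        if self.mode in ("conventional", "control") and z != 0:
            raise ConfigError(f"mode {self.mode!r} forces z = 0, got z = {z:g}")
        if self.mode == "phase_contrast":
            if not z > 0:
                raise ConfigError("phase_contrast mode requires z > 0")
            if "file" in self.spectrum and not self.experimental_polychromatic:
                raise ConfigError(
                    "phase_contrast with a polychromatic spectrum requires "
                    "experimental_polychromatic: true"
                )

    # -- resolved pieces ---------------------------------------------------

    def build_scene(self) -> PhantomScene:
        s = dict(self.scene)
        kind = s.pop("kind", "fig3_airway")
        if kind == "fig3_airway":
            return build_fig3_scene(
                wall_thickness=s.get("wall_thickness", 0.2),
                background_thickness=s.get("background_thickness", 100.0),
                extent=s.get("extent", 10.0))
        if kind == "nodule_roi":
            return build_nodule_scene(
                diameter=s.get("diameter", 8.0),
                background_thickness=s.get("background_thickness", 100.0),
                extent=s.get("extent"))
        raise ConfigError(f"unknown scene kind {kind!r}")

    def build_spectrum(self) -> Spectrum:
        if self.mode == "conventional":
            if "file" in self.spectrum:
                return read_spectrum(self.spectrum["file"])
            return bundled_tungsten_120kvp()
        if "file" in self.spectrum:
            return read_spectrum(self.spectrum["file"])
        return monochromatic(float(self.spectrum.get("energy", 60.0)))

    def build_materials(self) -> MaterialTable:
        if self.materials_file:
            return load_material_table(self.materials_file)
        return builtin_table()

    def build_detector(self) -> DetectorModel:
        d = self.detector
        return DetectorModel(pixel_pitch=d.get("pixel_pitch", 0.05),
                             sigma_det=d.get("sigma_det", 0.0),
                             fluence=d.get("fluence", 3.6e6),
                             seed=int(d.get("seed", 0)))


@dataclass
class SimulationResult:
    """Outputs of one run, in memory plus the paths written (if any)."""

    intensity_fine: IntensityImage
    intensity_binned: IntensityImage
    counts: np.ndarray
    metrics: dict
    run_report: dict
    files: dict = field(default_factory=dict)


def _background_region(scene: PhantomScene, pitch: float, n: int,
                       margin: float = 0.5) -> slice:
    """Index slice of undisturbed background at the right edge of the grid."""
    occupied = max((abs(b) for obj in scene.objects for b in obj.interval),
                   default=0.0)
    x = pitch * (np.arange(n) - n // 2)
    start = int(np.searchsorted(x, occupied + margin))
    # leave the padded border out of the baseline
    stop = int(0.98 * n)
    if stop - start < 4:
        raise ConfigError("grid extent leaves no background region for I0")
    return slice(start, stop)


def run_simulation(config: RunConfig, outdir: str | Path | None = None) -> SimulationResult:
    """Execute the full imaging chain for one configuration.

    Writes pixel image (16-bit TIFF + sidecar scale), fine/binned intensity
    profiles, a metrics report and a run report when an output directory is
    given (``outdir`` argument or ``config.output['directory']``).  Partial
    outputs are removed if any stage fails.
    """
    config.validate()
    stage = "setup"
    files: dict[str, Path] = {}
    try:
        scene = config.build_scene()
        spec = config.build_spectrum()
        table = config.build_materials()
        det = config.build_detector()
        pitch = float(config.grid.get("pitch", 0.005))
        mode2d = config.grid.get("mode", "1d") == "2d"
        z = float(config.geometry.get("z", 0.0))

        stage = "sampling-check"
        if z > 0:
            lam_min = wavelength_from_energy(float(spec.energies.max()))
            chk = check_sampling(pitch, lam_min, z)
            if not chk.passed:
                raise ConfigError(
                    f"grid pitch {pitch:g} mm violates sampling bound "
                    f"{chk.bound:g} mm at z = {z:g} mm")

        stage = "projection"
        tmap = project_scene(scene, pitch, mode="2d" if mode2d else "1d")
        n = tmap.n
        region = _background_region(scene, pitch, n)
        region_nd = (region, region) if mode2d else region

        stage = "wave-optics"
        if len(spec.bins) == 1:
            wf = transmission_function(tmap, table, float(spec.energies[0]))
            if z > 0:
                wf = fresnel_propagate(wf, PropagationPlan(distance=z))
            img = intensity_image(wf, region_nd)
        else:
            img = polychromatic_image(scene, spec, z, pitch, table=table,
                                      normalization_region=region_nd,
                                      mode="2d" if mode2d else "1d")

        stage = "detector"
        blurred = apply_detector_blur(img, det.sigma_det)
        binned = bin_to_pixels(blurred, det.pixel_pitch)
        bg = table[scene.background_material]
        w = spec.fluences / spec.fluences.sum()
        t_bg = float(np.sum(w * np.exp(
            -np.array([bg.mu_at(e) for e in spec.energies])
            * scene.background_thickness)))
        expected = expected_counts(binned, det.fluence, det.pixel_pitch, t_bg)
        counts = poisson_counts(expected, det.seed)

        stage = "metrics"
        metrics = _compute_metrics(config, scene, img, binned, det)

        stage = "report"
        run_report = {
            "software": "pbisim", "version": __version__,
            "config": asdict(config), "seed": det.seed,
            "grid_samples": int(n),
            "mean_energy_keV": mean_energy(spec),
            "background_transmission": t_bg,
            "propagation_distance_mm": z,
        }

        result = SimulationResult(intensity_fine=img, intensity_binned=binned,
                                  counts=counts, metrics=metrics,
                                  run_report=run_report)

        outdir = outdir or config.output.get("directory")
        if outdir is not None:
            stage = "output"
            outdir = Path(outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            prefix = config.output.get("prefix", "run")
            files["image"] = write_image(counts, outdir / f"{prefix}_counts.tif")
            if not mode2d:
                files["profile_fine"] = write_profile(
                    img.x, img.values, outdir / f"{prefix}_profile_fine.txt")
                files["profile_binned"] = write_profile(
                    binned.x, binned.values, outdir / f"{prefix}_profile_binned.txt")
            files["metrics"] = write_report(metrics, outdir / f"{prefix}_metrics.json")
            files["run_report"] = write_report(run_report, outdir / f"{prefix}_run.json")
            result.files = {k: str(v) for k, v in files.items()}
        return result
    except Exception as exc:
        for p in files.values():
            for q in ([p, Path(str(p) + ".scale.json")] if str(p).endswith(".tif") else [p]):
                Path(q).unlink(missing_ok=True)
        if isinstance(exc, (ConfigError,)) or stage == "setup":
            raise
        raise type(exc)(f"[stage: {stage}] {exc}") from exc


def _compute_metrics(config: RunConfig, scene: PhantomScene,
                     img: IntensityImage, binned: IntensityImage,
                     det: DetectorModel) -> dict:
    metrics: dict = {}
    if binned.values.ndim != 1:
        x, prof = extract_profile(binned, ("row", binned.values.shape[0] // 2))
    else:
        x, prof = extract_profile(binned)
    nb = len(prof)
    region_b = _background_region(scene, binned.grid_pitch, nb)
    metrics["fringe_visibility"] = fringe_visibility(prof, region_b)
    if config.scene.get("kind", "fig3_airway") == "fig3_airway":
        airway = scene.objects[0]
        r_in, r_out = airway.inner_radius, airway.outer_radius
        half_wall = (r_out - r_in) / 2.0
        win = slice(int(np.searchsorted(x, r_in - 3 * half_wall - 0.05)),
                    int(np.searchsorted(x, r_in + half_wall)))
        try:
            em = edge_width(prof, binned.grid_pitch, region_b, window=win,
                            positions=x)
            metrics["edge"] = {
                "interface_position_mm": em.interface_position,
                "overshoot_peak": em.overshoot_peak,
                "undershoot_trough": em.undershoot_trough,
                "width_mm": em.width,
                "pixels_spanned": em.pixels_spanned,
                "fringe_detected": em.fringe_detected,
            }
        except Exception as exc:
            metrics["edge"] = {"error": str(exc)}
        we = wall_thickness_estimate(prof, binned.grid_pitch, region_b,
                                     positions=x,
                                     true_thickness=airway.wall_thickness)
        metrics["wall_thickness"] = {
            "estimated_mm": we.estimated_thickness,
            "true_mm": we.true_thickness,
            "fringe_detected": we.fringe_detected,
            "method": we.method,
        }
    return metrics


# -- file I/O ---------------------------------------------------------------

def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**data)
    cfg.validate()
    return cfg


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=False))


def write_image(counts: np.ndarray, path: str | Path) -> Path:
    """Write counts as 16-bit grayscale TIFF with a JSON sidecar scale.

    ``counts = stored * scale + offset`` reconstructs the original values
    exactly for integer counts within range.
    """
    import tifffile

    path = Path(path)
    arr = np.atleast_2d(np.asarray(counts))
    cmin, cmax = float(arr.min()), float(arr.max())
    if cmax <= 65535 and cmin >= 0 and np.allclose(arr, np.round(arr)):
        scale, offset = 1.0, 0.0
        stored = arr.astype(np.uint16)
    else:
        scale = (cmax - cmin) / 65535.0 or 1.0
        offset = cmin
        stored = np.round((arr - offset) / scale).astype(np.uint16)
    tifffile.imwrite(path, stored)
    sidecar = Path(str(path) + ".scale.json")
    sidecar.write_text(json.dumps({"scale": scale, "offset": offset,
                                   "shape": list(arr.shape)}))
    return path


def read_image(path: str | Path) -> np.ndarray:
    import tifffile

    arr = tifffile.imread(path).astype(float)
    sidecar = Path(str(path) + ".scale.json")
    meta = json.loads(sidecar.read_text())
    return arr * meta["scale"] + meta["offset"]


def write_profile(x: np.ndarray, values: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# position_mm value\n")
        for xi, vi in zip(x, values):
            fh.write(f"{xi:.9g} {vi:.9g}\n")
    return path


def write_report(report: dict, path: str | Path) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    path.write_text(json.dumps(report, indent=2, default=default))
    return path
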