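"""Canonical ready-to-run configurations for the studied scenarios."""

from __future__ import annotations

from .config import RunConfig

__all__ = ["build_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("fig3_airway", "airway_sweep", "nodule_roi")


def build_fixture(name: str, **params):
    """Return a complete :class:`RunConfig` (or list) for a named scenario.

    ``fig3_airway``: isolated 2-mm-lumen airway with a muscle wall
    (``wall_thickness`` keyword, default 0.2 mm), 60 keV, z = 12 m, 5-um
    wave-optics grid, 50-um photon-counting pixels, fluence 3.6e6 /mm^2.

    ``airway_sweep``: list of three such configs with wall thicknesses
    0.1, 0.2 and 0.4 mm.

    ``nodule_roi``: 2D parenchyma slab with a muscle-equivalent sphere
    (``diameter`` keyword, default 8 mm), conventional setting by default
    (attenuation-only; pass ``mode='phase_contrast'`` and a fine enough
    grid pitch for a propagated run).
    """
    if name == "fig3_airway":
        d = float(params.pop("wall_thickness", 0.2))
        cfg = RunConfig(
            mode=params.pop("mode", "phase_contrast"),
            scene={"kind": "fig3_airway", "wall_thickness": d,
                   "background_thickness": params.pop("background_thickness", 100.0),
                   "extent": params.pop("extent", 10.0)},
            spectrum={"energy": 60.0},
            geometry={"z": params.pop("z", 12000.0)},
            grid={"pitch": params.pop("pitch", 0.005), "mode": "1d"},
        )
        _apply_detector(cfg, params)
        cfg.validate()
        return cfg
    if name == "airway_sweep":
        return [build_fixture("fig3_airway", wall_thickness=d, **dict(params))
                for d in (0.1, 0.2, 0.4)]
    if name == "nodule_roi":
        diameter = float(params.pop("diameter", 8.0))
        mode = params.pop("mode", "conventional")
        z = params.pop("z", 0.0 if mode != "phase_contrast" else 12000.0)
        cfg = RunConfig(
            mode=mode,
            scene={"kind": "nodule_roi", "diameter": diameter,
                   "background_thickness": params.pop("background_thickness", 100.0),
                   "extent": params.pop("extent", max(2.0 * diameter, diameter + 4.0))},
            spectrum={"energy": 60.0},
            geometry={"z": z},
            grid={"pitch": params.pop("pitch", 0.005), "mode": "2d"},
        )
        _apply_detector(cfg, params)
        cfg.validate()
        return cfg
    raise ValueError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")


def _apply_detector(cfg: RunConfig, params: dict) -> None:
    for key in ("pixel_pitch", "sigma_det", "fluence", "seed"):
        if key in params:
            cfg.detector[key] = params.pop(key)
    if params:
        raise ValueError(f"unknown fixture parameters: {sorted(params)}")
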