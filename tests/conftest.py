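import numpy as np
import pytest

import pbisim as pb


@pytest.fixture(scope="session")
def table():
    return pb.builtin_table()


@pytest.fixture(scope="session")
def lam60():
    return pb.wavelength_from_energy(60.0)


def airway_intensity(table, wall_thickness, z=12000.0, pitch=0.005,
                     center_offset=0.0, extent=10.0):
    """Propagated, normalized intensity profile of the isolated-airway scene."""
    from pbisim.phantom import CylinderAirway, PhantomScene

    airway = CylinderAirway(lumen_diameter=2.0, wall_thickness=wall_thickness,
                            center_offset=center_offset)
    scene = PhantomScene(objects=[airway], extent=extent)
    tmap = pb.project_scene(scene, pitch)
    wf = pb.transmission_function(tmap, table, 60.0)
    if z > 0:
        wf = pb.fresnel_propagate(wf, pb.PropagationPlan(distance=z))
    n = tmap.n
    region = slice(int(0.75 * n), int(0.98 * n))
    return pb.intensity_image(wf, region), region


@pytest.fixture(scope="session")
def fig3_images(table):
    """Fine-grid propagated airway profiles for the three studied walls."""
    return {d: airway_intensity(table, d) for d in (0.1, 0.2, 0.4)}


from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("deterministic", derandomize=True, deadline=None)
_hyp_settings.load_profile("deterministic")
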