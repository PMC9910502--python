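import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pbisim as pb
from pbisim.phantom import (CylinderAirway, GeometryError, PhantomScene,
                            SamplingError, SphereNodule, build_fig3_scene,
                            check_sampling, chord_length_circle,
                            project_airway, project_scene, project_voxel_grid)


class TestChord:
    @pytest.mark.parametrize("offset,radius,expected", [
        (0.0, 1.0, 2.0),            # diameter chord
        (1.0, 1.0, 0.0),            # tangent ray
        (0.5, 1.0, np.sqrt(3.0)),   # 2*sqrt(1 - 0.25)
        (1.2, 1.0, 0.0),            # outside
    ])
    def test_closed_form(self, offset, radius, expected):
        assert chord_length_circle(offset, radius) == pytest.approx(expected)

    @given(off=st.floats(-2, 2), r=st.floats(0, 2))
    @settings(max_examples=100, deadline=None)
    def test_nonnegative_and_bounded_by_diameter(self, off, r):
        c = chord_length_circle(off, r)
        assert 0.0 <= c <= 2 * r + 1e-12


class TestProjectAirway:
    def test_on_axis_chords(self):
        aw = CylinderAirway(lumen_diameter=2.0, wall_thickness=0.1)
        tmap = project_airway(aw, pitch=0.005)
        i0 = tmap.n // 2  # x = 0
        assert tmap.thickness["air"][i0] == pytest.approx(2.0)
        assert tmap.thickness["muscle"][i0] == pytest.approx(0.2)

    def test_inner_edge_tangent_wall_chord(self):
        aw = CylinderAirway(lumen_diameter=2.0, wall_thickness=0.1)
        tmap = project_airway(aw, pitch=0.005)
        i = int(np.argmin(np.abs(tmap.x - 1.0)))
        assert tmap.thickness["air"][i] == pytest.approx(0.0)
        assert tmap.thickness["muscle"][i] == pytest.approx(
            2 * np.sqrt(1.1 ** 2 - 1.0 ** 2), rel=1e-9)

    def test_outside_object_zero(self):
        aw = CylinderAirway(lumen_diameter=2.0, wall_thickness=0.1)
        tmap = project_airway(aw, pitch=0.005)
        i = int(np.argmin(np.abs(tmap.x - 1.2)))
        assert tmap.thickness["air"][i] == 0.0
        assert tmap.thickness["muscle"][i] == 0.0

    def test_unresolved_wall_refused(self):
        aw = CylinderAirway(lumen_diameter=2.0, wall_thickness=0.01)
        with pytest.raises(SamplingError):
            project_airway(aw, pitch=0.05)
        tmap = project_airway(aw, pitch=0.05, allow_unresolved=True)
        assert tmap.n > 0


class TestProjectScene:
    def test_empty_scene_uniform_background(self):
        scene = PhantomScene(background_thickness=100.0, extent=10.0)
        tmap = project_scene(scene, 0.01)
        assert np.all(tmap.thickness["lung_parenchyma"] == 100.0)

    def test_sphere_displaces_background(self):
        scene = PhantomScene(objects=[SphereNodule(diameter=8.0)],
                             extent=20.0, background_thickness=100.0)
        tmap = project_scene(scene, 0.01)
        i0 = tmap.n // 2
        assert tmap.thickness["muscle"][i0] == pytest.approx(8.0)
        assert tmap.thickness["lung_parenchyma"][i0] == pytest.approx(92.0)

    def test_conservation_fig3_scene(self):
        tmap = project_scene(build_fig3_scene(0.2), 0.005)
        assert np.max(np.abs(tmap.total() - 100.0)) < 1e-12 * 100

    @given(d=st.floats(0.05, 0.5), off=st.floats(-1.0, 1.0),
           slab=st.floats(20.0, 200.0))
    @settings(max_examples=30, deadline=None)
    def test_conservation_property(self, d, off, slab):
        aw = CylinderAirway(lumen_diameter=2.0, wall_thickness=d,
                            center_offset=off)
        scene = PhantomScene(objects=[aw], extent=12.0,
                             background_thickness=slab)
        tmap = project_scene(scene, 0.01)
        assert np.max(np.abs(tmap.total() - slab)) < 1e-10 * slab
        for arr in tmap.thickness.values():
            assert np.all(arr >= -1e-12)

    def test_centered_projection_symmetry(self):
        tmap = project_scene(build_fig3_scene(0.2), 0.005)
        t = tmap.thickness["muscle"]
        # sample i and n-i mirror about the center sample n//2
        assert np.allclose(t[1:], t[1:][::-1])

    def test_overlapping_objects_rejected(self):
        a = CylinderAirway(lumen_diameter=2.0, wall_thickness=0.1)
        b = CylinderAirway(lumen_diameter=2.0, wall_thickness=0.1,
                           center_offset=1.0)
        with pytest.raises(GeometryError):
            PhantomScene(objects=[a, b], extent=10.0)

    def test_object_outside_extent_rejected(self):
        a = CylinderAirway(lumen_diameter=2.0, wall_thickness=0.1,
                           center_offset=5.0)
        with pytest.raises(GeometryError):
            PhantomScene(objects=[a], extent=10.0)

    def test_chord_exceeding_slab_rejected(self):
        with pytest.raises(GeometryError):
            PhantomScene(objects=[SphereNodule(diameter=8.0)], extent=20.0,
                         background_thickness=5.0)

    def test_2d_mode_sphere(self):
        scene = PhantomScene(objects=[SphereNodule(diameter=4.0)],
                             extent=8.0, background_thickness=100.0)
        tmap = project_scene(scene, 0.05, mode="2d")
        t = tmap.thickness["muscle"]
        assert t.ndim == 2
        i0 = t.shape[0] // 2
        assert t[i0, i0] == pytest.approx(4.0, rel=1e-9)
        assert np.max(np.abs(tmap.total() - 100.0)) < 1e-10


class TestVoxelProjector:
    def test_analytic_vs_voxel_line_integration(self):
        """Chord projection agrees with brute-force ray sums through a
        1-um-voxel cylinder to < 0.5% away from tangent rays."""
        r = 0.5
        vox = 0.001
        nz = nx = int(2 * r / vox) + 2
        zc = (np.arange(nz) - nz // 2) * vox
        xc = (np.arange(nx) - nx // 2) * vox
        grid = ((zc[:, None] ** 2 + xc[None, :] ** 2) <= r * r).astype(int)
        tmap = project_voxel_grid(grid, vox, {1: "muscle"})
        numeric = tmap.thickness["muscle"]
        analytic = np.array([chord_length_circle(x, r) for x in xc])
        interior = np.abs(xc) < 0.9 * r
        rel = np.abs(numeric[interior] - analytic[interior]) / analytic[interior]
        assert np.max(rel) < 0.005


class TestSamplingGuard:
    def test_pass_at_7um_12m(self, lam60):
        chk = check_sampling(0.007, lam60, 12000.0)
        assert chk.passed
        assert chk.bound == pytest.approx(7.87e-3, rel=1e-2)

    def test_fail_at_10um_12m(self, lam60):
        assert not check_sampling(0.010, lam60, 12000.0).passed

    def test_z_zero_trivially_passes(self, lam60):
        chk = check_sampling(1.0, lam60, 0.0)
        assert chk.passed and chk.no_propagation


class TestFig3Scene:
    @pytest.mark.parametrize("d,outer", [(0.1, 2.2), (0.4, 2.8)])
    def test_outer_diameter(self, d, outer):
        scene = build_fig3_scene(d)
        assert 2 * scene.objects[0].outer_radius == pytest.approx(outer)

    def test_degenerate_wall_rejected(self):
        with pytest.raises(GeometryError):
            build_fig3_scene(0.0)
        with pytest.raises(GeometryError):
            build_fig3_scene(1.5)
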