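import numpy as np
import pytest

import pbisim as pb
from pbisim.wave_optics import (ComplexWavefront, PropagationError,
                                PropagationPlan, fresnel_integral_direct,
                                fresnel_propagate, intensity_image,
                                transmission_function)

HC = 1.23984193e-6  # keV mm


def smooth_test_field(n=1024, pitch=1e-3, wavelength=1e-6):
    """Band-limited amplitude+phase bump on uniform background."""
    x = pitch * (np.arange(n) - n // 2)
    amp = 1.0 - 0.5 * np.exp(-(x / 0.05) ** 2)
    phase = 2.0 * np.exp(-(x / 0.03) ** 2)
    return ComplexWavefront(pitch, amp * np.exp(1j * phase), wavelength)


class TestTransmission:
    def test_vacuum_ray_unit_amplitude_zero_phase(self, table):
        from pbisim.phantom import ThicknessMap
        tmap = ThicknessMap(grid_pitch=0.01,
                            thickness={"vacuum": np.full(8, 50.0)},
                            background_thickness=50.0)
        wf = transmission_function(tmap, table, 60.0)
        assert np.allclose(wf.samples, 1.0)

    def test_uniform_parenchyma_phase(self, table):
        """100 mm of parenchyma at 60 keV: phi = -(2 pi/lambda)*delta*t
        ~ -1.025e3 rad (compared modulo 2 pi on the stored samples)."""
        from pbisim.phantom import ThicknessMap
        tmap = ThicknessMap(grid_pitch=0.01,
                            thickness={"lung_parenchyma": np.full(8, 100.0)},
                            background_thickness=100.0)
        wf = transmission_function(tmap, table, 60.0)
        lam = HC / 60.0
        phi = -(2 * np.pi / lam) * 3.37e-8 * 100.0
        assert phi == pytest.approx(-1024.7, rel=1e-3)
        expected = np.exp(-table.mu_at("lung_parenchyma", 60.0) * 100.0 / 2
                          + 1j * phi)
        assert np.allclose(wf.samples, expected)

    def test_airway_relative_phase_on_axis(self, table):
        """Relative exit phase lumen-vs-background for the 0.1-mm wall:
        -(2 pi/lambda)[(d_air - d_par)*2 + (d_mus - d_par)*0.2] ~ +18.45 rad."""
        tmap = pb.project_scene(pb.build_fig3_scene(0.1), 0.005)
        wf = transmission_function(tmap, table, 60.0)
        n = tmap.n
        rel = wf.samples[n // 2] * np.conj(wf.samples[-10])
        lam = HC / 60.0
        dphi = -(2 * np.pi / lam) * ((6.91e-11 - 3.37e-8) * 2.0
                                     + (6.66e-8 - 3.37e-8) * 0.2)
        assert dphi == pytest.approx(18.45, abs=0.01)
        expected = (dphi + np.pi) % (2 * np.pi) - np.pi
        assert np.angle(rel) == pytest.approx(expected, abs=1e-3)

    def test_amplitude_never_exceeds_unity(self, table):
        tmap = pb.project_scene(pb.build_fig3_scene(0.2), 0.005)
        wf = transmission_function(tmap, table, 60.0)
        assert np.max(np.abs(wf.samples)) <= 1.0 + 1e-12


class TestFresnelPropagate:
    def test_z_zero_identity_bit_for_bit(self):
        wf = smooth_test_field()
        out = fresnel_propagate(wf, PropagationPlan(distance=0.0))
        assert np.array_equal(out.samples, wf.samples)

    def test_uniform_field_is_eigenfunction(self):
        wf = ComplexWavefront(1e-3, np.full(512, 0.7 + 0.0j), 1e-6)
        out = fresnel_propagate(wf, PropagationPlan(distance=1000.0))
        assert np.allclose(np.abs(out.samples), 0.7, atol=1e-9)

    def test_sampling_violation_refused_with_bound(self, lam60):
        wf = ComplexWavefront(0.01, np.ones(128, complex), lam60)
        with pytest.raises(PropagationError, match="bound"):
            fresnel_propagate(wf, PropagationPlan(distance=12000.0))

    def test_negative_z_needs_inverse_flag(self):
        with pytest.raises(PropagationError):
            PropagationPlan(distance=-100.0)

    def test_parseval_on_padded_grid(self):
        wf = smooth_test_field()
        out = fresnel_propagate(wf, PropagationPlan(distance=2500.0, crop=False))
        padded = np.pad(wf.samples, (512, 512), mode="edge")
        e_in = np.mean(np.abs(padded) ** 2)
        e_out = np.mean(np.abs(out.samples) ** 2)
        assert abs(e_out - e_in) / e_in < 1e-9

    def test_unitarity_forward_then_back(self):
        wf = smooth_test_field()
        fwd = fresnel_propagate(wf, PropagationPlan(distance=2500.0))
        back = fresnel_propagate(fwd, PropagationPlan(distance=-2500.0,
                                                      inverse=True))
        err = np.max(np.abs(back.samples - wf.samples))
        assert err / np.max(np.abs(wf.samples)) < 1e-6

    def test_semigroup_composition(self):
        wf = smooth_test_field()
        two = fresnel_propagate(
            fresnel_propagate(wf, PropagationPlan(distance=1200.0)),
            PropagationPlan(distance=1300.0))
        one = fresnel_propagate(wf, PropagationPlan(distance=2500.0))
        err = np.max(np.abs(two.samples - one.samples))
        assert err / np.max(np.abs(one.samples)) < 1e-6

    def test_2d_propagation_separable_consistency(self):
        """A field varying along one axis only must propagate like its 1D
        cross-section."""
        wf1 = smooth_test_field(n=256)
        arr2 = np.tile(wf1.samples, (256, 1))
        wf2 = ComplexWavefront(wf1.grid_pitch, arr2, wf1.wavelength)
        out1 = fresnel_propagate(wf1, PropagationPlan(distance=800.0))
        out2 = fresnel_propagate(wf2, PropagationPlan(distance=800.0))
        mid = out2.samples[128, :]
        assert np.max(np.abs(mid - out1.samples)) < 1e-6


class TestDirectIntegralOracle:
    def test_spectral_matches_direct_quadrature(self):
        """Independent O(N^2) Fresnel quadrature agrees with the spectral
        propagator to < 1e-3 max relative intensity deviation (in the
        regime where the sampled chirp is unaliased, N*pitch^2 < lambda*z).
        A compactly supported packet keeps both methods on the same
        aperture."""
        pitch, lam = 1e-3, 1e-6
        x = pitch * (np.arange(1024) - 512)
        samples = (np.exp(-(x / 0.1) ** 2)
                   * np.exp(1j * 1.2 * np.exp(-(x / 0.05) ** 2)))
        wf = ComplexWavefront(pitch, samples, lam)
        z = 2417.0
        spectral = fresnel_propagate(wf, PropagationPlan(distance=z))
        padded = ComplexWavefront(wf.grid_pitch,
                                  np.pad(wf.samples, (512, 512), mode="edge"),
                                  wf.wavelength)
        direct = fresnel_integral_direct(padded, z)
        dc = direct.samples[512:512 + 1024]
        i_s = np.abs(spectral.samples) ** 2
        i_d = np.abs(dc) ** 2
        assert np.max(np.abs(i_s - i_d)) / np.max(i_d) < 1e-3

    def test_far_field_single_slit_sinc(self):
        """At large z a narrow slit tends to the sinc^2 far-field pattern."""
        pitch = 1e-3
        lam = 1e-6
        n = 1024
        a = 0.01  # nominal slit width, mm
        x = pitch * (np.arange(n) - n // 2)
        field = (np.abs(x) <= a / 2).astype(complex)
        # discrete slit: the sampled rectangle is a_eff = (k samples)*pitch
        a_eff = field.real.sum() * pitch
        wf = ComplexWavefront(pitch, field, lam)
        z = 1.0e4
        out = fresnel_integral_direct(wf, z)
        inten = np.abs(out.samples) ** 2
        expected = np.sinc(a_eff * x / (lam * z)) ** 2
        got = inten / inten.max()
        want = expected / expected.max()
        assert np.max(np.abs(got - want)) < 0.05

    def test_identity_and_uniform(self):
        wf = smooth_test_field(n=256)
        out = fresnel_integral_direct(wf, 0.0)
        assert np.array_equal(out.samples, wf.samples)
        # A uniform field keeps unit magnitude away from the hard-aperture
        # borders; the slowly decaying edge ringing bounds the tolerance.
        uni = ComplexWavefront(1e-3, np.ones(256, complex), 1e-6)
        out = fresnel_integral_direct(uni, 2000.0)
        inner = slice(64, 192)
        mag = np.abs(out.samples[inner])
        assert abs(mag.mean() - 1.0) < 0.05
        assert np.max(np.abs(mag - 1.0)) < 0.15

    def test_large_grid_refused(self):
        wf = ComplexWavefront(1e-3, np.ones(5000, complex), 1e-6)
        with pytest.raises(ValueError, match="too large"):
            fresnel_integral_direct(wf, 100.0)


class TestIntensityImage:
    def test_uniform_field_normalizes_to_one(self):
        wf = ComplexWavefront(0.01, np.full(64, 0.3 + 0.4j), 1e-6)
        img = intensity_image(wf, slice(0, 16))
        assert np.allclose(img.values, 1.0)

    def test_beer_lambert_at_z_zero(self, table):
        """Absorption-only slab relative to an empty region follows
        exp(-mu t)."""
        from pbisim.phantom import ThicknessMap
        t = np.zeros(64)
        t[32:] = 50.0
        tmap = ThicknessMap(grid_pitch=0.01,
                            thickness={"muscle": t},
                            background_thickness=50.0)
        wf = transmission_function(tmap, table, 60.0)
        img = intensity_image(wf, slice(0, 16))
        mu = table.mu_at("muscle", 60.0)
        assert img.values[-1] == pytest.approx(np.exp(-mu * 50.0), rel=1e-9)

    def test_zero_region_rejected(self):
        wf = ComplexWavefront(0.01, np.zeros(16, complex), 1e-6)
        with pytest.raises(ValueError):
            intensity_image(wf, slice(0, 4))

    def test_fig3_fringes_paired_overshoot_undershoot(self, fig3_images):
        """Propagation introduces paired over/undershoot at each air/wall
        interface of the airway."""
        img, region = fig3_images[0.2]
        x = img.x
        for interface in (1.0, 1.2):
            near = (x > interface - 0.03) & (x < interface + 0.03)
            assert img.values[near].max() > 1.05
            assert img.values[near].min() < 0.95
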