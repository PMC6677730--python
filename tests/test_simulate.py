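"""Synthetic hologram generator: transmission maps, forward model vs the
brute-force Fresnel-Kirchhoff oracle, partial coherence, targets and noise."""

import numpy as np
import pytest

import holokit as hk
from holokit.simulate import (
    NoiseModel,
    Scene,
    SceneObject,
    add_noise,
    apply_partial_coherence,
    direct_integral_oracle,
    simulate_hologram,
    spherical_illumination,
    synth_usaf_target,
    transmission_map,
)

from conftest import small_setup


def _radial_profile(img):
    n = img.shape[0]
    y, x = np.mgrid[0:n, 0:n]
    rho = np.hypot(y - n // 2, x - n // 2).astype(int)
    sums = np.bincount(rho.ravel(), weights=img.ravel())
    counts = np.bincount(rho.ravel())
    return sums / counts


class TestTransmissionMap:
    def test_empty_scene_is_unity(self):
        scene = Scene([], small_setup())
        t = transmission_map(scene, 5.91e-3, 32, 32, 1.12e-6)
        assert np.all(t == 1.0)

    def test_opaque_disk_coverage(self):
        setup = small_setup(n=128)
        r = 5e-6
        scene = Scene([SceneObject("opaque_disk", (0, 0), 5.91e-3, radius=r)], setup)
        t = transmission_map(scene, 5.91e-3, 128, 128, 1.12e-6)
        covered = np.sum(1.0 - np.abs(t))
        expected = np.pi * r**2 / 1.12e-6**2
        assert covered == pytest.approx(expected, rel=0.02)
        # fully opaque core, untouched far field
        assert np.abs(t[64, 64]) == 0.0
        assert t[0, 0] == 1.0

    def test_phase_sphere_projected_thickness(self):
        setup = small_setup(n=64)
        scene = Scene(
            [
                SceneObject(
                    "phase_sphere", (0, 0), 5.91e-3, radius=3.25e-6, delta_n=0.1
                )
            ],
            setup,
        )
        t = transmission_map(scene, 5.91e-3, 64, 64, 1.12e-6)
        k = 2 * np.pi / 405e-9
        max_phase = k * 0.1 * 2 * 3.25e-6  # 10.08 rad at the centre
        assert np.angle(t[32, 32]) == pytest.approx(
            np.angle(np.exp(1j * max_phase)), abs=1e-6
        )
        assert np.abs(t[32, 32]) == pytest.approx(1.0)

    def test_other_planes_unaffected(self):
        setup = small_setup(n=32)
        scene = Scene(
            [SceneObject("opaque_disk", (0, 0), 5.91e-3, radius=3e-6)], setup
        )
        t = transmission_map(scene, 4e-3, 32, 32, 1.12e-6)
        assert np.all(t == 1.0)


class TestIllumination:
    def test_plane_option_unit_field(self):
        f = spherical_illumination(small_setup(), 32, 32, 1.12e-6, 5.91e-3, kind="plane")
        assert np.allclose(np.abs(f.amplitude), 1.0)
        assert f.amplitude[0, 0] != 0

    def test_on_axis_phase(self):
        setup = small_setup()
        d = setup.source_detector_distance - 5.91e-3
        f = spherical_illumination(setup, 33, 33, 1.12e-6, 5.91e-3)
        k = 2 * np.pi / setup.wavelength
        on_axis = f.amplitude[16, 16]
        assert np.angle(on_axis) == pytest.approx(
            np.angle(np.exp(1j * k * d)), abs=1e-9
        )

    def test_quadratic_phase_offset(self):
        setup = small_setup()
        d = setup.source_detector_distance - 5.91e-3
        f = spherical_illumination(setup, 33, 33, 1.12e-6, 5.91e-3)
        k = 2 * np.pi / setup.wavelength
        rho = 10 * 1.12e-6
        expected = k * rho**2 / (2 * d)
        measured = np.angle(f.amplitude[16, 26] / f.amplitude[16, 16])
        assert measured == pytest.approx(expected % (2 * np.pi), abs=1e-6)

    def test_out_of_range_plane(self):
        with pytest.raises(ValueError):
            spherical_illumination(small_setup(), 32, 32, 1.12e-6, 40e-3)


class TestForwardModel:
    def test_empty_scene_equals_background(self):
        scene = Scene([], small_setup(n=64))
        holo = simulate_hologram(scene, 64, 64)
        dev = np.max(np.abs(holo.intensity - holo.background)) / holo.background.max()
        assert dev < 1e-12

    def test_disk_matches_direct_integral(self):
        """FFT cascade vs the exact-distance double sum, 64^2, laser geometry."""
        setup = small_setup(n=64)
        scene = Scene(
            [SceneObject("opaque_disk", (0, 0), 5.91e-3, radius=3.25e-6)], setup
        )
        oracle = direct_integral_oracle(scene, 64, 64)
        sim = simulate_hologram(scene, 64, 64, aperture="finite", pad_to=512)
        rms = np.sqrt(
            np.mean((sim.intensity - oracle.intensity) ** 2)
            / np.mean(oracle.intensity**2)
        )
        assert rms < 0.01
        # radial fringe profiles agree pointwise as well
        p_sim = _radial_profile(sim.intensity)[:24]
        p_orc = _radial_profile(oracle.intensity)[:24]
        assert np.sqrt(np.mean((p_sim - p_orc) ** 2) / np.mean(p_orc**2)) < 0.01

    def test_weak_hologram_linearity(self):
        """Two well-separated weak disks superpose to first order."""
        setup = small_setup(n=256, s=2e-3)
        a = SceneObject("opaque_disk", (-40e-6, 0), 2e-3, radius=2.5e-6,
                        amplitude_transmittance=0.7)
        b = SceneObject("opaque_disk", (40e-6, 0), 2e-3, radius=2.5e-6,
                        amplitude_transmittance=0.7)
        h_ab = simulate_hologram(Scene([a, b], setup), 256, 256)
        h_a = simulate_hologram(Scene([a], setup), 256, 256)
        h_b = simulate_hologram(Scene([b], setup), 256, 256)
        contrast_ab = h_ab.intensity - h_ab.background
        sum_contrast = (h_a.intensity - h_a.background) + (
            h_b.intensity - h_b.background
        )
        scale = np.max(np.abs(contrast_ab))
        resid = np.abs(contrast_ab - sum_contrast) / scale
        assert np.median(resid) < 0.05

    def test_depth_outside_gap_rejected(self):
        with pytest.raises(ValueError):
            Scene(
                [SceneObject("opaque_disk", (0, 0), 40e-3, radius=3e-6)],
                small_setup(),
            )

    def test_overlapping_objects_warn(self):
        setup = small_setup()
        with pytest.warns(UserWarning, match="overlap"):
            Scene(
                [
                    SceneObject("opaque_disk", (0, 0), 5.91e-3, radius=3e-6),
                    SceneObject("opaque_disk", (2e-6, 0), 5.91e-3, radius=3e-6),
                ],
                setup,
            )


class TestOracle:
    def test_uniform_field_free_propagation(self):
        """Plane-wave illuminated unit transmission: the oracle's central
        intensity is flat up to the Fresnel edge ripple of the truncated
        aperture and keeps the unit plane-wave level."""
        z = 600e-6
        setup = small_setup(n=64, s=z)
        # transparent pin-size disk = effectively empty object plane
        scene = Scene(
            [
                SceneObject(
                    "opaque_disk", (0, 0), z, radius=1e-9,
                    amplitude_transmittance=1.0,
                )
            ],
            setup,
        )
        holo = direct_integral_oracle(scene, 64, 64, illumination="plane")
        centre = holo.intensity[28:36, 28:36]
        assert centre.std() / centre.mean() < 0.05
        assert centre.mean() == pytest.approx(1.0, rel=0.15)

    def test_single_subpixel_aperture_inverse_square(self):
        """A single-pixel aperture in an opaque screen radiates a spherical
        wavelet: oracle intensity follows the 1/|r - R|^2 envelope exactly."""
        pitch, wl = 1.12e-6, 405e-9
        n = 33
        z = 80e-6
        setup = small_setup(n=n, s=z)
        scene = Scene(
            [SceneObject("opaque_disk", (0, 0), z, radius=1e-9)], setup
        )
        pinhole = np.zeros((n, n), dtype=complex)
        pinhole[n // 2, n // 2] = 1.0
        holo = direct_integral_oracle(
            scene, n, n, illumination="plane", transmission=pinhole
        )
        profile = holo.intensity[n // 2, n // 2 :]
        r2 = (np.arange(n // 2 + 1) * pitch) ** 2 + z**2
        expected = profile[0] * r2[0] / r2
        assert np.allclose(profile, expected, rtol=1e-9)

    def test_large_grid_refused(self):
        scene = Scene(
            [SceneObject("opaque_disk", (0, 0), 5.91e-3, radius=3e-6)],
            small_setup(n=128),
        )
        with pytest.raises(ValueError):
            direct_integral_oracle(scene, 128, 128)


class TestPartialCoherence:
    def test_degenerate_averaging_is_coherent(self):
        setup = small_setup(n=64)
        scene = Scene(
            [SceneObject("opaque_disk", (0, 0), 5.91e-3, radius=3.25e-6)], setup
        )
        coherent = simulate_hologram(scene, 64, 64)
        averaged = apply_partial_coherence(
            scene, 64, 64, bandwidth=0.0, source_diameter=0.0,
            n_wavelengths=1, n_source_points=1,
        )
        assert np.array_equal(coherent.intensity, averaged.intensity)
        assert np.array_equal(coherent.background, averaged.background)

    def test_led_fewer_fringes_than_laser(self):
        """Partial coherence suppresses the outer fringes of a disk hologram."""
        from scipy.signal import find_peaks

        n = 256
        setup_ld = small_setup(n=n)
        setup_led = small_setup(wavelength=430e-9, n=n, bandwidth=15e-9,
                                source_aperture_diameter=15e-6)
        disk = lambda stp: Scene(
            [SceneObject("opaque_disk", (0, 0), 5.91e-3, radius=3.25e-6)], stp
        )
        ld = simulate_hologram(disk(setup_ld), n, n)
        led = apply_partial_coherence(
            disk(setup_led), n, n, n_wavelengths=5, n_source_points=7
        )

        def fringe_count(holo):
            contrast = np.abs(holo.intensity - holo.background)
            prof = _radial_profile(contrast / holo.background.mean())
            peaks, _ = find_peaks(prof[: n // 2], prominence=2e-4)
            return len(peaks)

        assert fringe_count(led) < fringe_count(ld)

    def test_fringe_visibility_decreases_with_source_size(self):
        """Visibility at a fixed outer fringe drops monotonically with the
        source aperture diameter."""
        n = 128
        setup = small_setup(n=n, s=2e-3)
        scene = Scene(
            [SceneObject("opaque_disk", (0, 0), 2e-3, radius=3.25e-6)], setup
        )
        # fixed radial band around an outer fringe of the coherent pattern
        band = slice(30, 50)
        vis = []
        for dia in (0.0, 5e-6, 15e-6, 30e-6):
            holo = apply_partial_coherence(
                scene, n, n, bandwidth=0.0, source_diameter=dia,
                n_wavelengths=1, n_source_points=13,
            )
            prof = _radial_profile(holo.intensity / holo.background.mean())[band]
            vis.append((prof.max() - prof.min()) / (prof.max() + prof.min()))
        assert all(b < a for a, b in zip(vis, vis[1:]))


class TestUSAFTarget:
    def test_bar_widths_in_pixels(self):
        pitch = 1.12e-6
        panel, table = synth_usaf_target([(6, 1)], 512, 512, pitch)
        row = table[table.orientation == "vertical"].iloc[0]
        width = hk.usaf_line_width(hk.USAFElement(6, 1))
        # count dark pixels along the modulation axis at the element centre row
        r = (row.row0 + row.row1) // 2
        dark = np.abs(panel[r, row.col0 : row.col1]) < 0.5
        runs = np.diff(np.flatnonzero(np.diff(np.concatenate([[0], dark, [0]]))))
        bars = runs[::2]
        assert len(bars) == 5
        assert np.allclose(bars, round(width / pitch), atol=1)

    def test_dark_area_fraction(self):
        pitch = 1.12e-6
        panel, table = synth_usaf_target([(6, 2)], 512, 512, pitch)
        row = table[table.orientation == "horizontal"].iloc[0]
        patch = np.abs(panel[row.row0 : row.row1, row.col0 : row.col1])
        w = row.line_width
        roi_area = (row.row1 - row.row0) * (row.col1 - row.col0) * pitch**2
        expected = 5 * (w * 5 * w) / roi_area
        assert 1.0 - patch.mean() == pytest.approx(expected, rel=0.15)

    def test_roi_table_csv_round_trip(self, tmp_path):
        import pandas as pd

        _, table = synth_usaf_target([6], 1024, 1024, 1.12e-6)
        path = tmp_path / "rois.csv"
        table.to_csv(path, index=False)
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(
            back, table.reset_index(drop=True), check_dtype=False
        )

    def test_unprintable_element_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="below 2x pitch"):
            panel, table = synth_usaf_target([(9, 1)], 256, 256, 1.12e-6)
        assert not table.printable.any()
        assert np.all(np.abs(panel) == 1.0)


class TestNoise:
    def _holo(self, value=1.0):
        return hk.Hologram(
            np.full((32, 32), value), small_setup(n=32), np.full((32, 32), value)
        )

    def test_none_model_is_identity(self):
        holo = self._holo()
        out = add_noise(holo, None)
        assert np.array_equal(out.intensity, holo.intensity)
        out = add_noise(holo, NoiseModel())
        assert np.array_equal(out.intensity, holo.intensity)

    def test_poisson_mean_preserved(self):
        holo = self._holo(2.0)
        means = []
        for seed in range(1000):
            noisy = add_noise(
                holo, NoiseModel(photons_per_pixel=50.0, seed=seed)
            )
            means.append(noisy.intensity.mean())
        assert np.mean(means) == pytest.approx(2.0, rel=0.01)

    def test_quantization_level_count(self):
        rng = np.random.default_rng(3)
        holo = hk.Hologram(
            rng.uniform(0, 1, (64, 64)), small_setup(n=64)
        )
        noisy = add_noise(holo, NoiseModel(bit_depth=8))
        assert len(np.unique(noisy.intensity)) <= 2**8

    def test_seed_mandatory_for_shot_noise(self):
        with pytest.raises(ValueError):
            NoiseModel(photons_per_pixel=100.0)

    def test_reproducible_per_seed(self):
        holo = self._holo(1.5)
        a = add_noise(holo, NoiseModel(photons_per_pixel=20.0, seed=7))
        b = add_noise(holo, NoiseModel(photons_per_pixel=20.0, seed=7))
        assert np.array_equal(a.intensity, b.intensity)
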