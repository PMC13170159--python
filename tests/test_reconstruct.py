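"""Multi-wavelength Gerchberg–Saxton reconstruction, per-object focus and
colour composition."""

import numpy as np
import pytest

import holostain as hs
from holostain.reconstruct import N_STACK_SLICES


class TestGSReconstruct:
    def test_stack_geometry(self, gs_stack, sparse_hologram):
        assert gs_stack.slices.shape[:2] == (3, N_STACK_SLICES)
        assert len(gs_stack.zs) == N_STACK_SLICES
        assert np.allclose(np.diff(gs_stack.zs), 1.0)
        assert gs_stack.z_hat == pytest.approx(sparse_hologram.z_true)

    def test_in_focus_amplitude_matches_ground_truth(self, gs_stack,
                                                     sparse_phantom):
        j = 15  # z_hat slice == true plane for this fixture
        for c in range(3):
            rec = np.abs(gs_stack.slices[c, j])
            corr = np.corrcoef(rec.ravel(),
                               sparse_phantom.amplitude[c].ravel())[0, 1]
            assert corr >= 0.95

    def test_residuals_non_increasing_on_noiseless_input(self, gs_stack):
        assert np.all(np.diff(gs_stack.gs_residuals) <= 0)

    def test_sensor_projection_is_exact(self, sparse_hologram):
        """The sensor-plane projection replaces the amplitude with the
        measured sqrt(intensity); re-propagating the z_hat slice back to
        the sensor reproduces it, up to the stack's single-precision
        storage."""
        stack = hs.gs_reconstruct(sparse_hologram, sparse_hologram.z_true,
                                  max_iters=5, tol=0.0)
        from holostain.optics import ComplexField, propagate
        meas = np.sqrt(sparse_hologram.frames[0])
        field = ComplexField(stack.slices[0, 15].astype(complex), stack.pitch,
                             stack.wavelengths[0])
        sensor_amp = np.abs(propagate(field, stack.z_hat).values)
        assert np.abs(sensor_amp - meas).max() <= 1e-3

    def test_non_convergence_flag_instead_of_exception(self, sparse_hologram):
        stack = hs.gs_reconstruct(sparse_hologram, sparse_hologram.z_true,
                                  max_iters=2, tol=0.0)
        assert stack.converged is False
        assert len(stack.gs_residuals) == 2

    def test_single_wavelength_mode_warns(self, cfg256, sparse_phantom):
        cfg1 = hs.OpticalConfig(wavelengths=(0.52,), grid_shape=(256, 256),
                                grid_pitch=0.25, sensor_pitch=0.25,
                                z_nominal=600.0, z_jitter=0.0)
        ph = hs.generate_phantom(cfg1, "GNB", 500, seed=2, z_span=0.0)
        holo = hs.record_hologram(ph, cfg1, seed=2, noise=hs.NOISELESS)
        with pytest.warns(UserWarning, match="single-wavelength"):
            hs.gs_reconstruct(holo, cfg1.z_nominal, max_iters=2)

    def test_fidelity_degrades_with_read_noise(self, cfg256):
        """Mean ground-truth correlation decreases (in expectation) as the
        read noise grows; three levels, several seeds each."""
        mean_corr = []
        for sigma in (0.0, 0.03, 0.12):
            vals = []
            for seed in range(4):
                ph = hs.generate_phantom(cfg256, "GNB", 1500, 0.0, seed=seed,
                                         z_span=0.0)
                holo = hs.record_hologram(ph, cfg256, seed=seed,
                                          noise=hs.NoiseModel(0.0, sigma))
                stack = hs.gs_reconstruct(holo, holo.z_true, max_iters=20)
                vals.append(np.mean([
                    np.corrcoef(np.abs(stack.slices[c, 15]).ravel(),
                                ph.amplitude[c].ravel())[0, 1]
                    for c in range(3)]))
            mean_corr.append(np.mean(vals))
        assert mean_corr[0] > mean_corr[1] > mean_corr[2]


class TestPerObjectFocus:
    @pytest.fixture(scope="class")
    def two_depth_stack(self, cfg256):
        objs = [hs.SceneObject("coccus", (20.0, 32.0), 1.2,
                               gram_reaction="positive", group_id=0,
                               z_offset=-5.0),
                hs.SceneObject("coccus", (44.0, 32.0), 1.2,
                               gram_reaction="positive", group_id=1,
                               z_offset=5.0)]
        amp, phs = hs.render_fields(cfg256, objs, 0.0)
        ph = hs.SpecimenPhantom(tuple(objs), "GPC_pairs_chains", 0.0, 0.0, 7,
                                cfg256, amp, phs)
        holo = hs.record_hologram(ph, cfg256, seed=7, noise=hs.NOISELESS)
        curve = hs.coarse_focus(holo, cfg256.z_nominal - 110,
                                cfg256.z_nominal + 110, n_slices=34)
        stack = hs.gs_reconstruct(holo, curve.z_hat, max_iters=40)
        masks = []
        for obj in objs:
            m = np.zeros(cfg256.grid_shape, bool)
            ci = int(obj.center[1] / cfg256.grid_pitch)
            cj = int(obj.center[0] / cfg256.grid_pitch)
            m[ci - 8:ci + 8, cj - 8:cj + 8] = True
            masks.append(m)
        return stack, masks

    def test_depth_separation_recovered(self, two_depth_stack):
        stack, masks = two_depth_stack
        zs, _ = hs.per_object_focus(stack, masks)
        assert abs(zs[0] - zs[1]) == pytest.approx(10.0, abs=2.0)

    def test_focus_map_constant_on_each_mask(self, two_depth_stack):
        stack, masks = two_depth_stack
        zs, fmap = hs.per_object_focus(stack, masks)
        for z, m in zip(zs, masks):
            assert np.all(fmap[m] == z)

    def test_whole_image_mask_reduces_to_global_argmax(self, gs_stack):
        """A whole-image mask is just per-field focus: its selected slice
        equals the background fill chosen for unmasked pixels."""
        whole = np.ones(gs_stack.slices.shape[2:], bool)
        zs, fmap = hs.per_object_focus(gs_stack, [whole])
        assert np.all(fmap == zs[0])
        # and matches the background fill of a run with no usable mask
        with pytest.warns(UserWarning):
            _, background = hs.per_object_focus(
                gs_stack, [np.zeros(gs_stack.slices.shape[2:], bool)])
        assert np.all(background == zs[0])

    def test_empty_mask_skipped_with_warning(self, gs_stack):
        empty = np.zeros(gs_stack.slices.shape[2:], bool)
        with pytest.warns(UserWarning, match="empty"):
            zs, _ = hs.per_object_focus(gs_stack, [empty])
        assert np.isnan(zs[0])


class TestComposeColor:
    def test_empty_scene_is_bright(self, cfg256):
        ph = hs.generate_phantom(cfg256, "GNB", 0.0, seed=1,
                                 red_cell_density=0.0)
        holo = hs.record_hologram(ph, cfg256, seed=1, noise=hs.NOISELESS)
        stack = hs.gs_reconstruct(holo, holo.z_true, max_iters=3)
        img = hs.compose_color(stack)
        assert img.rgb.min() >= 0.95

    def test_channel_permutation_symmetry(self, gs_stack):
        """Reordering the wavelength channels leaves the image unchanged
        because primaries are assigned by wavelength."""
        from dataclasses import replace

        img = hs.compose_color(gs_stack)
        perm = [2, 0, 1]
        permuted = replace(
            gs_stack, slices=gs_stack.slices[perm],
            wavelengths=tuple(gs_stack.wavelengths[p] for p in perm))
        img_p = hs.compose_color(permuted)
        assert np.array_equal(img.rgb, img_p.rgb)

    def test_channels_bounded_and_focus_map_in_range(self, gs_stack):
        img = hs.compose_color(gs_stack)
        assert img.rgb.min() >= 0.0 and img.rgb.max() <= 1.0
        assert img.focus_map.min() >= gs_stack.zs[0]
        assert img.focus_map.max() <= gs_stack.zs[-1]

    def test_gnb_mean_hue_in_pink_band(self, cfg256):
        from skimage import color as skcolor
        from holostain import spectra

        ph = hs.generate_phantom(cfg256, "GNB", 1500, 0.0, seed=11, z_span=0.0)
        holo = hs.record_hologram(ph, cfg256, seed=11, noise=hs.NOISELESS)
        stack = hs.gs_reconstruct(holo, holo.z_true, max_iters=30)
        img = hs.compose_color(stack)
        mask = ph.bacteria_mask() & (1 - img.rgb.min(axis=2) > 0.16)
        mean_rgb = img.rgb[mask].mean(axis=0)
        hue = float(skcolor.rgb2hsv(mean_rgb[None, None, :])[0, 0, 0] * 360)
        assert spectra.hue_band(hue, spectra.PINK_HUE_DEG)

    def test_upsampled_output_grid(self, gs_stack):
        img = hs.compose_color(gs_stack, upsample=2)
        assert img.rgb.shape[:2] == tuple(2 * s for s in
                                          gs_stack.slices.shape[2:])
        assert img.pitch == pytest.approx(gs_stack.pitch / 2)

    def test_io_round_trip(self, gs_stack, tmp_path):
        import tifffile

        img = hs.compose_color(gs_stack)
        hs.save_color_image(img, tmp_path / "img")
        assert (tmp_path / "img.png").exists()
        data = tifffile.imread(tmp_path / "img.tif")
        assert np.allclose(data, img.rgb.astype(np.float32))
        hs.save_recon_stack(gs_stack, tmp_path / "stack")
        assert (tmp_path / "stack.tif").exists()
        import json
        sidecar = json.loads((tmp_path / "stack.json").read_text())
        assert len(sidecar["zs"]) == 30
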