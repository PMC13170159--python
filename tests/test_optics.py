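"""Angular-spectrum propagation and hologram recording."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import holostain as hs


class TestPropagate:
    def test_zero_distance_is_identity(self, bandlimited_field):
        out = hs.propagate(bandlimited_field, 0.0)
        assert np.array_equal(out.values, bandlimited_field.values)

    def test_round_trip_unitarity(self, bandlimited_field):
        out = hs.propagate(hs.propagate(bandlimited_field, 300.0), -300.0)
        dev = np.abs(out.values - bandlimited_field.values).max()
        assert dev <= 1e-10

    def test_energy_conservation(self, bandlimited_field):
        e0 = np.sum(np.abs(bandlimited_field.values) ** 2)
        e1 = np.sum(np.abs(hs.propagate(bandlimited_field, 450.0).values) ** 2)
        assert abs(e1 - e0) / e0 <= 1e-10

    def test_talbot_self_imaging(self):
        """A sinusoidal amplitude grating reimages itself at z_T = 2p²/λ."""
        n, pitch, wavelength = 512, 0.25, 0.52
        period = n * pitch / 16  # integer number of periods across the grid
        x = np.arange(n) * pitch
        grating = (1 + 0.4 * np.cos(2 * np.pi * x / period))[None, :] * np.ones((n, 1))
        grating = grating / grating.max()
        field = hs.ComplexField(grating.astype(complex), pitch, wavelength)
        z_talbot = 2 * period**2 / wavelength
        out = hs.propagate(field, z_talbot)
        i0, i1 = np.abs(field.values) ** 2, np.abs(out.values) ** 2
        rel_rms = np.sqrt(np.mean((i1 - i0) ** 2)) / np.sqrt(np.mean(i0**2))
        assert rel_rms <= 0.01

    @given(a=st.floats(-2, 2), b=st.floats(-2, 2))
    def test_linearity(self, bandlimited_field, a, b):
        f = bandlimited_field
        g = hs.ComplexField(np.roll(f.values, 7, axis=0), f.pitch, f.wavelength)
        lhs = hs.propagate(
            hs.ComplexField(a * f.values + b * g.values, f.pitch, f.wavelength),
            180.0).values
        rhs = a * hs.propagate(f, 180.0).values + b * hs.propagate(g, 180.0).values
        assert np.abs(lhs - rhs).max() <= 1e-12 * max(abs(a) + abs(b), 1.0)

    def test_non_finite_input_rejected(self):
        bad = np.ones((8, 8), complex)
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            hs.ComplexField(bad, 0.25, 0.5)
        field = hs.ComplexField(np.ones((8, 8), complex), 0.25, 0.5)
        with pytest.raises(ValueError):
            hs.propagate(field, np.inf)

    def test_anti_alias_limit_removes_high_frequencies(self, bandlimited_field):
        strict = hs.propagate(bandlimited_field, 400.0, anti_alias=True)
        loose = hs.propagate(bandlimited_field, 400.0, anti_alias=False)
        assert np.sum(np.abs(strict.values) ** 2) < np.sum(np.abs(loose.values) ** 2)


class TestRecordHologram:
    def test_empty_scene_gives_flat_frames(self, cfg256):
        ph = hs.generate_phantom(cfg256, "GNB", 0.0, seed=1,
                                 red_cell_density=0.0)
        holo = hs.record_hologram(ph, cfg256, seed=1, noise=hs.NOISELESS)
        for frame in holo.frames:
            assert frame.std() / frame.mean() <= 1e-9

    def test_seed_determinism(self, cfg256, sparse_phantom):
        a = hs.record_hologram(sparse_phantom, cfg256, seed=3,
                               noise=hs.NoiseModel())
        b = hs.record_hologram(sparse_phantom, cfg256, seed=3,
                               noise=hs.NoiseModel())
        assert np.array_equal(a.frames, b.frames)
        assert a.z_true == b.z_true

    def test_back_propagation_recovers_scene(self, cfg256):
        """A single back-propagation of sqrt(intensity) recovers the
        specimen layout; the residual twin image caps the correlation well
        below the iterative multi-wavelength reconstruction's."""
        ph = hs.generate_phantom(cfg256, "GNB", 800, 0.0, seed=5, z_span=0.0,
                                 red_cell_density=0.0)
        holo = hs.record_hologram(ph, cfg256, seed=5, noise=hs.NOISELESS)
        f = hs.ComplexField(np.sqrt(holo.frames[0]).astype(complex),
                            cfg256.sensor_pitch, cfg256.wavelengths[0])
        amp = np.abs(hs.propagate(f, -holo.z_true).values)
        corr = np.corrcoef(amp.ravel(), ph.amplitude[0].ravel())[0, 1]
        assert corr >= 0.70

    def test_fringes_exceed_read_noise(self, cfg256, sparse_phantom):
        noise = hs.NoiseModel(shot_scale=0.0, read_sigma=0.002)
        holo = hs.record_hologram(sparse_phantom, cfg256, seed=2, noise=noise)
        assert holo.frames[0].var() > 4 * noise.read_sigma**2

    def test_one_frame_per_wavelength_and_binning_shape(self, sparse_phantom):
        cfg = hs.small_config(256, binning=4, z_jitter=0.0)
        ph = hs.generate_phantom(cfg, "GNB", 800, seed=5, z_span=0.0)
        holo = hs.record_hologram(ph, cfg, seed=5)
        assert holo.frames.shape == (3, 64, 64)
        assert holo.frames.min() >= 0.0

    def test_grid_mismatch_rejected(self, sparse_phantom):
        other = hs.small_config(128)
        with pytest.raises(ValueError):
            hs.record_hologram(sparse_phantom, other, seed=0)

    def test_depth_offsets_shift_the_focal_plane(self, cfg256):
        """An object placed closer to the sensor focuses at a shorter
        back-propagation distance."""
        objs = [hs.SceneObject("coccus", (32.0, 32.0), 1.2,
                               gram_reaction="positive", z_offset=5.0)]
        amp, phs = hs.render_fields(cfg256, objs, 0.0)
        ph = hs.SpecimenPhantom(tuple(objs), "GPC_pairs_chains", 0.0, 0.0, 0,
                                cfg256, amp, phs)
        holo = hs.record_hologram(ph, cfg256, seed=0, noise=hs.NOISELESS)
        f = hs.ComplexField(np.sqrt(holo.frames[0]).astype(complex),
                            cfg256.sensor_pitch, cfg256.wavelengths[0])
        zs = np.linspace(holo.z_true - 10, holo.z_true + 10, 41)
        scores = [hs.tamura_gradient_score(np.abs(hs.propagate(f, -z).values))
                  for z in zs]
        z_best = zs[int(np.argmax(scores))]
        assert z_best == pytest.approx(holo.z_true - 5.0, abs=1.5)


class TestHologramIO:
    def test_round_trip_uint16_bit_exact(self, cfg256, sparse_phantom, tmp_path):
        holo = hs.record_hologram(sparse_phantom, cfg256, seed=9,
                                  noise=hs.NoiseModel())
        hs.save_hologram(holo, tmp_path / "h")
        back = hs.load_hologram(tmp_path / "h")
        hs.save_hologram(back, tmp_path / "h2")
        assert (tmp_path / "h.tif").read_bytes() == (tmp_path / "h2.tif").read_bytes()
        assert back.config == holo.config
        assert back.z_true == holo.z_true

    def test_z_true_redaction(self, cfg256, sparse_phantom, tmp_path):
        holo = hs.record_hologram(sparse_phantom, cfg256, seed=9)
        hs.save_hologram(holo, tmp_path / "r", redact_z_true=True)
        assert hs.load_hologram(tmp_path / "r").z_true is None


class TestOpticalConfig:
    @pytest.mark.parametrize("kwargs", [
        {"wavelengths": (0.45, 0.45, 0.63)},          # duplicate
        {"wavelengths": (0.2, 0.52, 0.63)},           # out of band
        {"grid_pitch": -1.0},
        {"grid_pitch": 0.3},                          # non-integer binning
        {"grid_shape": (255, 256)},                   # odd
        {"z_nominal": 5.0},                           # too close
    ])
    def test_invalid_configs_rejected(self, kwargs):
        base = dict(grid_shape=(256, 256), grid_pitch=0.25, sensor_pitch=0.25,
                    z_nominal=600.0, z_jitter=0.0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            hs.OpticalConfig(**base)

    def test_round_trip_dict(self, cfg256):
        assert hs.OpticalConfig.from_dict(cfg256.to_dict()) == cfg256
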