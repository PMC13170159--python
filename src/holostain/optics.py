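"""Scalar-diffraction forward model for lensless in-line holography.

Free-space propagation uses the angular spectrum method (ASM): the field's
spatial spectrum is multiplied by the exact transfer function
``exp(i 2π z sqrt(1/λ² - fx² - fy²))`` with evanescent components
(``fx² + fy² > 1/λ²``) set to zero.  On the periodic FFT grid this transfer
function is unitary, so forward/backward propagation round-trips exactly —
the property every reconstruction step in this package relies on.  An
optional anti-aliasing band limit (Matsushima-style) is available for
simulating isolated, non-periodic fields.

``record_hologram`` emulates the acquisition: a unit plane wave passes
through the specimen's transmittance plane(s), propagates to the sensor,
and the squared modulus is block-averaged to the sensor pitch, degraded by
scaled-Poisson shot noise plus Gaussian read noise and clipped to the well
depth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Tuple

import numpy as np
import tifffile

from .config import DEFAULT_WELL_DEPTH, NoiseModel, OpticalConfig
from .phantom import SpecimenPhantom, render_fields


@dataclass(frozen=True)
class ComplexField:
    """A monochromatic complex field sampled on a regular grid."""

    values: np.ndarray  # 2D complex
    pitch: float        # µm / pixel
    wavelength: float   # µm

    def __post_init__(self) -> None:
        if self.pitch <= 0 or self.wavelength <= 0:
            raise ValueError("pitch and wavelength must be positive")
        if self.values.ndim != 2:
            raise ValueError("field must be 2D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field contains non-finite values")

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.values) ** 2


def _asm_transfer(shape: Tuple[int, int], pitch: float, wavelength: float,
                  z: float, anti_alias: bool) -> np.ndarray:
    fy = np.fft.fftfreq(shape[0], d=pitch)
    fx = np.fft.fftfreq(shape[1], d=pitch)
    fy2 = fy[:, None] ** 2
    fx2 = fx[None, :] ** 2
    arg = 1.0 / wavelength**2 - fx2 - fy2
    propagating = arg > 0
    transfer = np.zeros(shape, dtype=complex)
    transfer[propagating] = np.exp(
        1j * 2.0 * np.pi * z * np.sqrt(arg[propagating]))
    if anti_alias and z != 0.0:
        # local-frequency sampling limit of the transfer-function chirp
        dfy = 1.0 / (shape[0] * pitch)
        dfx = 1.0 / (shape[1] * pitch)
        fy_lim = 1.0 / (wavelength * np.sqrt((2.0 * dfy * abs(z)) ** 2 + 1.0))
        fx_lim = 1.0 / (wavelength * np.sqrt((2.0 * dfx * abs(z)) ** 2 + 1.0))
        transfer[(np.abs(fy[:, None]) > fy_lim) | (np.abs(fx[None, :]) > fx_lim)] = 0.0
    return transfer


def propagate(field: ComplexField, z: float, *, anti_alias: bool = False) -> ComplexField:
    """Propagate a field by a signed distance ``z`` (µm) with the ASM.

    Positive ``z`` moves toward the sensor.  Evanescent spectral components
    are discarded; the energy carried by propagating components is conserved
    exactly (the transfer function is unimodular on its support).
    """
    if not np.isfinite(z):
        raise ValueError("propagation distance must be finite")
    if z == 0.0 and not anti_alias:
        return field
    spectrum = np.fft.fft2(field.values)
    transfer = _asm_transfer(field.values.shape, field.pitch, field.wavelength,
                             z, anti_alias)
    out = np.fft.ifft2(spectrum * transfer)
    return ComplexField(values=out, pitch=field.pitch, wavelength=field.wavelength)


def block_average(array: np.ndarray, factor: int) -> np.ndarray:
    """Average ``factor`` × ``factor`` pixel blocks (sensor pixel binning)."""
    if factor == 1:
        return array
    h, w = array.shape
    if h % factor or w % factor:
        raise ValueError("array shape must divide the binning factor")
    return array.reshape(h // factor, factor, w // factor, factor).mean(axis=(1, 3))


def block_upsample(array: np.ndarray, factor: int) -> np.ndarray:
    """Nearest-neighbour inverse of :func:`block_average` (values repeated)."""
    if factor == 1:
        return array
    return np.repeat(np.repeat(array, factor, axis=0), factor, axis=1)


@dataclass(frozen=True)
class Hologram:
    """Per-wavelength intensity frames recorded at the sensor plane.

    ``z_true`` is hidden ground-truth metadata carried for testing and may
    be redacted on export.  ``tile_area`` records the nominal slide area the
    acquisition represents (mm²).
    """

    frames: np.ndarray  # (n_wavelengths, H, W) float, >= 0
    config: OpticalConfig
    z_true: float | None = None
    well_depth: float = DEFAULT_WELL_DEPTH
    tile_area: float = 30.0
    tile_id: str = "tile-0"

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_wavelengths, H, W)")
        if self.frames.shape[0] != len(self.config.wavelengths):
            raise ValueError("one frame per configured wavelength required")
        if self.frames.shape[1:] != self.config.sensor_shape:
            raise ValueError("frame shape must equal grid_shape / binning")
        if np.min(self.frames) < 0 or np.max(self.frames) > self.well_depth + 1e-9:
            raise ValueError("intensities must lie in [0, well_depth]")

    def frame(self, channel: int) -> np.ndarray:
        return self.frames[channel]


def record_hologram(phantom: SpecimenPhantom, config: OpticalConfig | None = None,
                    seed: int = 0, noise: NoiseModel = NoiseModel(), *,
                    well_depth: float = DEFAULT_WELL_DEPTH,
                    tile_area: float = 30.0, tile_id: str = "tile-0") -> Hologram:
    """Record a multi-wavelength in-line hologram of a phantom.

    The true sample-to-sensor distance is ``z_nominal`` plus a seeded
    uniform jitter within ±``z_jitter``.  Objects at distinct ``z_offset``
    planes are applied as successive thin transmittance planes along the
    propagation path, so depth differences inside the specimen are encoded
    in the recorded fringes.
    """
    config = config or phantom.config
    if config.grid_shape != phantom.config.grid_shape or \
            config.grid_pitch != phantom.config.grid_pitch or \
            config.wavelengths != phantom.config.wavelengths:
        raise ValueError("phantom was rendered on a different grid than config")
    rng = np.random.default_rng(seed)
    jitter = rng.uniform(-config.z_jitter, config.z_jitter) if config.z_jitter else 0.0
    z_true = config.z_nominal + jitter

    planes = phantom.z_planes() or [0.0]
    per_plane: Dict[float, Tuple[np.ndarray, np.ndarray]] = {}
    if len(planes) == 1:
        per_plane[planes[0]] = (phantom.amplitude, phantom.phase)
    else:
        for zp in planes:
            subset = [o for o in phantom.objects if o.z_offset == zp]
            per_plane[zp] = render_fields(config, subset, phantom.stain_quality)

    frames = np.empty((len(config.wavelengths),) + config.sensor_shape)
    for k, wl in enumerate(config.wavelengths):
        # march from the farthest plane toward the sensor
        field = None
        prev_z = None
        for zp in planes:  # ascending z_offset = toward the sensor
            amp, phs = per_plane[zp]
            t_plane = amp[k] * np.exp(1j * phs[k])
            if field is None:
                field = ComplexField(t_plane.astype(complex), config.grid_pitch, wl)
            else:
                field = propagate(field, zp - prev_z)
                field = ComplexField(field.values * t_plane, config.grid_pitch, wl)
            prev_z = zp
        sensor = propagate(field, z_true - prev_z)
        intensity = block_average(sensor.intensity, config.binning)
        if noise.shot_scale > 0:
            intensity = rng.poisson(np.maximum(intensity, 0.0) * noise.shot_scale)
            intensity = intensity / noise.shot_scale
        if noise.read_sigma > 0:
            intensity = intensity + rng.normal(0.0, noise.read_sigma, intensity.shape)
        frames[k] = np.clip(intensity, 0.0, well_depth)
    return Hologram(frames=frames, config=config, z_true=z_true,
                    well_depth=well_depth, tile_area=tile_area, tile_id=tile_id)


# ---------------------------------------------------------------------------
# Persistence: uint16 multi-page TIFF + JSON sidecar.  Frames are quantized
# to the 16-bit well-depth range; the written digital numbers round-trip
# bit-exactly.

def save_hologram(hologram: Hologram, path: str | Path, *,
                  redact_z_true: bool = False) -> None:
    base = Path(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    scale = hologram.well_depth / 65535.0
    dn = np.round(hologram.frames / scale).astype(np.uint16)
    tifffile.imwrite(base.with_suffix(".tif"), dn)
    sidecar = {
        "config": hologram.config.to_dict(),
        "well_depth": hologram.well_depth,
        "tile_area": hologram.tile_area,
        "tile_id": hologram.tile_id,
        "z_true": None if redact_z_true else hologram.z_true,
        "dn_scale": scale,
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_hologram(path: str | Path) -> Hologram:
    base = Path(path)
    sidecar = json.loads(base.with_suffix(".json").read_text())
    dn = tifffile.imread(base.with_suffix(".tif"))
    if dn.ndim == 2:
        dn = dn[None]
    frames = dn.astype(float) * sidecar["dn_scale"]
    return Hologram(
        frames=frames, config=OpticalConfig.from_dict(sidecar["config"]),
        z_true=sidecar["z_true"], well_depth=sidecar["well_depth"],
        tile_area=sidecar["tile_area"], tile_id=sidecar["tile_id"])
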