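"""Acquisition geometry and noise configuration.

All physical lengths are in micrometres (µm).  The lensless geometry is
unit-magnification: a coherent plane wave illuminates the specimen and the
sensor directly samples the diffracted intensity a distance ``z_nominal``
downstream.  The simulation grid (``grid_pitch``) may be finer than the
sensor (``sensor_pitch``); recorded frames are block-averaged by the integer
ratio between the two, emulating large sensor pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple


@dataclass(frozen=True)
class OpticalConfig:
    """Geometry of one multi-wavelength lensless acquisition.

    Parameters
    ----------
    wavelengths:
        Vacuum wavelengths in µm, all distinct, within the visible band
        used by the instrument class being emulated (0.3–0.8 µm).
    grid_shape:
        (rows, cols) of the sample-plane simulation grid; even sizes keep
        the FFT grids symmetric.
    grid_pitch:
        Sample-plane sampling in µm/pixel.
    sensor_pitch:
        Sensor sampling in µm/pixel; must be an integer multiple of
        ``grid_pitch``.
    z_nominal:
        Nominal sample-to-sensor distance (µm).
    z_jitter:
        Maximum random offset of the true distance around ``z_nominal``
        (µm), emulating slide-loading tolerance.
    """

    wavelengths: Tuple[float, ...] = (0.45, 0.52, 0.63)
    grid_shape: Tuple[int, int] = (1024, 1024)
    grid_pitch: float = 0.25
    sensor_pitch: float = 1.0
    z_nominal: float = 600.0
    z_jitter: float = 30.0

    def __post_init__(self) -> None:
        wl = tuple(float(w) for w in self.wavelengths)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "grid_shape", tuple(int(n) for n in self.grid_shape))
        if len(set(wl)) != len(wl):
            raise ValueError("wavelengths must be distinct")
        if not wl:
            raise ValueError("at least one wavelength required")
        for w in wl:
            if not (0.3 <= w <= 0.8):
                raise ValueError(f"wavelength {w} µm outside the 0.3-0.8 µm band")
        if self.grid_pitch <= 0:
            raise ValueError("grid_pitch must be positive")
        ratio = self.sensor_pitch / self.grid_pitch
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValueError("sensor_pitch must be a positive integer multiple of grid_pitch")
        if any(n <= 0 or n % 2 for n in self.grid_shape):
            raise ValueError("grid dimensions must be positive and even")
        if self.z_nominal <= 10.0 * max(wl):
            raise ValueError("z_nominal must exceed 10x the longest wavelength")
        if self.z_jitter < 0:
            raise ValueError("z_jitter must be non-negative")

    @property
    def binning(self) -> int:
        """Integer block-averaging factor from grid to sensor."""
        return int(round(self.sensor_pitch / self.grid_pitch))

    @property
    def sensor_shape(self) -> Tuple[int, int]:
        b = self.binning
        return (self.grid_shape[0] // b, self.grid_shape[1] // b)

    @property
    def field_extent(self) -> Tuple[float, float]:
        """Physical (height, width) of the simulated field in µm."""
        return (self.grid_shape[0] * self.grid_pitch, self.grid_shape[1] * self.grid_pitch)

    @property
    def field_area_mm2(self) -> float:
        h, w = self.field_extent
        return h * w * 1e-6

    def to_dict(self) -> dict:
        d = asdict(self)
        d["wavelengths"] = list(self.wavelengths)
        d["grid_shape"] = list(self.grid_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "OpticalConfig":
        return cls(
            wavelengths=tuple(d["wavelengths"]),
            grid_shape=tuple(d["grid_shape"]),
            grid_pitch=d["grid_pitch"],
            sensor_pitch=d["sensor_pitch"],
            z_nominal=d["z_nominal"],
            z_jitter=d["z_jitter"],
        )


@dataclass(frozen=True)
class NoiseModel:
    """Sensor noise: scaled-Poisson shot noise plus additive Gaussian read noise.

    ``shot_scale`` is the expected photon count corresponding to unit
    intensity (the plane-wave background); 0 disables shot noise.
    ``read_sigma`` is the read-noise standard deviation in the same
    normalized intensity units.
    """

    shot_scale: float = 5000.0
    read_sigma: float = 0.005

    def __post_init__(self) -> None:
        if self.shot_scale < 0 or self.read_sigma < 0:
            raise ValueError("noise parameters must be non-negative")

    @property
    def noiseless(self) -> bool:
        return self.shot_scale == 0 and self.read_sigma == 0


NOISELESS = NoiseModel(shot_scale=0.0, read_sigma=0.0)

#: Sensor saturation level in normalized intensity units (plane wave = 1).
DEFAULT_WELL_DEPTH = 4.0


def small_config(n: int = 256, *, binning: int = 1, z_nominal: float = 600.0,
                 z_jitter: float = 30.0) -> OpticalConfig:
    """Desk-scale configuration used by tests, examples and the benchmark.

    Same optics as the default, on a smaller grid so a full pipeline run
    stays interactive on one CPU.
    """
    return OpticalConfig(
        grid_shape=(n, n),
        grid_pitch=0.25,
        sensor_pitch=0.25 * binning,
        z_nominal=z_nominal,
        z_jitter=z_jitter,
    )
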