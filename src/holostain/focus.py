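"""Computational autofocus for in-line holograms.

The sample-to-sensor distance is estimated without any moving parts: the
square root of a single-wavelength hologram is back-propagated to a grid of
candidate depths spanning at least 200 µm (≥30 slices), each amplitude image
is scored with a contrast metric, and the depth with the maximal score is
the coarse focal estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import numpy as np
from scipy import ndimage

from .optics import ComplexField, Hologram, block_average, propagate

MIN_FOCUS_SLICES = 30
MIN_FOCUS_SPAN = 200.0  # µm


class FocusRangeWarning(UserWarning):
    """Focus score peaked at the boundary of the scanned z range."""


def _check_image(amplitude: np.ndarray) -> np.ndarray:
    amplitude = np.asarray(amplitude, dtype=float)
    if amplitude.ndim != 2 or amplitude.size == 0:
        raise ValueError("focus metrics expect a non-empty 2D array")
    if not np.any(np.isfinite(amplitude)):
        raise ValueError("focus metric input is all non-finite")
    return amplitude


def focus_score(amplitude: np.ndarray) -> float:
    """Tenengrad contrast: mean squared Sobel gradient magnitude.

    Invariant to adding a constant, zero for constant images, strictly
    positive otherwise.  Well suited to extended absorbing content; for
    sparse holographic scenes the normalized metrics below are more robust
    (see :func:`coarse_focus`).
    """
    amplitude = _check_image(amplitude)
    gx = ndimage.sobel(amplitude, axis=1, mode="reflect")
    gy = ndimage.sobel(amplitude, axis=0, mode="reflect")
    return float(np.mean(gx * gx + gy * gy))


def tamura_gradient_score(amplitude: np.ndarray) -> float:
    """Tamura coefficient of the gradient magnitude, sqrt(std/mean).

    A normalized contrast/sparsity measure: defocus spreads fringe energy
    over the field (gradient everywhere, low dispersion) while at focus the
    gradient concentrates on object edges (high dispersion).  Robust for
    the sparse scenes typical of in-line holograms; invariant to adding a
    constant and to rescaling the image.
    """
    amplitude = _check_image(amplitude)
    gx = ndimage.sobel(amplitude, axis=1, mode="reflect")
    gy = ndimage.sobel(amplitude, axis=0, mode="reflect")
    g = np.sqrt(gx * gx + gy * gy)
    mean = float(g.mean())
    if mean <= 0:
        return 0.0
    return float(np.sqrt(g.std() / mean))


FOCUS_METRICS = {
    "tenengrad": focus_score,
    "tamura_gradient": tamura_gradient_score,
}


@dataclass(frozen=True)
class FocusCurve:
    """Focus score as a function of back-propagation distance."""

    zs: np.ndarray       # sampled distances, ascending (µm)
    scores: np.ndarray   # contrast score per distance
    z_hat: float         # argmax distance (ties -> smaller z)
    channel: int
    at_boundary: bool

    def __post_init__(self) -> None:
        if len(self.zs) < MIN_FOCUS_SLICES:
            raise ValueError("focus curve requires at least 30 samples")
        if self.zs[-1] - self.zs[0] < MIN_FOCUS_SPAN - 1e-9:
            raise ValueError("focus curve must span at least 200 µm")

    @property
    def spacing(self) -> float:
        return float(self.zs[1] - self.zs[0])


def coarse_focus(hologram: Hologram, z_min: float, z_max: float,
                 n_slices: int = 31, channel: int = 0, *,
                 downsample: int = 2,
                 metric: str = "tamura_gradient") -> FocusCurve:
    """Estimate the focal distance by a single-channel back-propagation scan.

    Parameters
    ----------
    z_min, z_max:
        Scan range (µm); must span at least 200 µm.
    n_slices:
        Number of uniformly spaced candidate depths, at least 30.
    channel:
        Wavelength index used for the scan.
    downsample:
        Integer block-averaging factor applied to the hologram before the
        scan (low-resolution propagations keep the scan cheap).
    metric:
        One of ``FOCUS_METRICS``.  The default Tamura-of-gradient score is
        robust for sparse smears; ``"tenengrad"`` is available for
        extended absorbing content.
    """
    if n_slices < MIN_FOCUS_SLICES:
        raise ValueError(f"n_slices must be >= {MIN_FOCUS_SLICES}")
    if z_max - z_min < MIN_FOCUS_SPAN - 1e-9:
        raise ValueError(f"scan range must span at least {MIN_FOCUS_SPAN} µm")
    if not (0 <= channel < len(hologram.config.wavelengths)):
        raise ValueError("channel out of range")
    try:
        score = FOCUS_METRICS[metric]
    except KeyError:
        raise ValueError(f"unknown focus metric {metric!r}; "
                         f"choose from {sorted(FOCUS_METRICS)}") from None
    frame = hologram.frame(channel)
    ds = max(int(downsample), 1)
    while ds > 1 and (frame.shape[0] % ds or frame.shape[1] % ds):
        ds -= 1
    intensity = block_average(frame, ds)
    pitch = hologram.config.sensor_pitch * ds
    wavelength = hologram.config.wavelengths[channel]
    field = ComplexField(np.sqrt(np.maximum(intensity, 0.0)).astype(complex),
                         pitch, wavelength)
    zs = np.linspace(z_min, z_max, n_slices)
    scores = np.empty(n_slices)
    for i, z in enumerate(zs):
        scores[i] = score(np.abs(propagate(field, -z).values))
    best = int(np.argmax(scores))  # first maximum -> tie toward smaller z
    at_boundary = best in (0, n_slices - 1)
    if at_boundary:
        warnings.warn("focus at range boundary; true focus may lie outside the scan",
                      FocusRangeWarning, stacklevel=2)
    return FocusCurve(zs=zs, scores=scores, z_hat=float(zs[best]),
                      channel=channel, at_boundary=at_boundary)


def refine_focus(hologram: Hologram, z_center: float, half_width: float,
                 n_steps: int = 9, channel: int = 0, *, downsample: int = 1,
                 metric: str = "tamura_gradient") -> float:
    """Fine focal search around a coarse estimate.

    Scans ``n_steps`` depths in ``z_center ± half_width`` at full (or
    lightly downsampled) resolution and returns the best depth.  Used
    between the coarse scan and phase retrieval: the iterative loop is
    noticeably happier when the sample plane is right.
    """
    score = FOCUS_METRICS[metric]
    frame = hologram.frame(channel)
    ds = max(int(downsample), 1)
    while ds > 1 and (frame.shape[0] % ds or frame.shape[1] % ds):
        ds -= 1
    intensity = block_average(frame, ds)
    field = ComplexField(np.sqrt(np.maximum(intensity, 0.0)).astype(complex),
                         hologram.config.sensor_pitch * ds,
                         hologram.config.wavelengths[channel])
    zs = np.linspace(z_center - half_width, z_center + half_width, n_steps)
    scores = [score(np.abs(propagate(field, -z).values)) for z in zs]
    return float(zs[int(np.argmax(scores))])
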