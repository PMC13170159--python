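"""Hologram inversion: multi-wavelength phase retrieval and colour composition.

``gs_reconstruct`` runs an angular-spectrum Gerchberg–Saxton loop over the
wavelength channels.  The specimen is modelled as thin and weakly
dispersive, so one optical-path-length (OPL) map is shared across channels
and the sample-plane phase at wavelength λ is ``2π·OPL/λ``; each channel
additionally keeps its own sample-plane amplitude (stain absorption is
strongly wavelength dependent).  At the sensor plane the measured amplitude
replaces the estimate (exactly at native sampling; as a block-ratio
correction when the sensor is coarser than the grid), and the loop cycles
channels in ascending wavelength order until the relative residual change
falls below ``tol``.

The converged field is then propagated to a 30-slice z-stack at 1 µm steps
around the focal estimate, from which per-object focal planes are selected
and an RGB colour image is composed (longest wavelength → red, shortest →
blue).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np
import tifffile
from scipy import ndimage
from skimage.transform import rescale

from .focus import focus_score, tamura_gradient_score
from .optics import ComplexField, Hologram, block_average, block_upsample, propagate

N_STACK_SLICES = 30
STACK_STEP = 1.0  # µm


@dataclass(frozen=True)
class ReconStack:
    """Per-wavelength complex reconstructions over a 30-slice z-stack.

    ``slices[c, j]`` is the complex field of channel ``c`` back-propagated
    to distance ``zs[j]`` from the sensor; ``zs`` covers
    ``z_hat-15 … z_hat+14`` µm in 1 µm steps.
    """

    slices: np.ndarray        # (n_channels, 30, H, W) complex
    zs: np.ndarray            # (30,) distances from sensor, µm
    wavelengths: Tuple[float, ...]
    pitch: float              # µm / pixel
    gs_residuals: np.ndarray  # per-iteration relative sensor-amplitude mismatch
    converged: bool
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.slices.shape[1] != N_STACK_SLICES or len(self.zs) != N_STACK_SLICES:
            raise ValueError("stack must hold exactly 30 slices")

    @property
    def z_hat(self) -> float:
        return float(self.zs[15])

    def amplitude(self, channel: int, slice_index: int) -> np.ndarray:
        return np.abs(self.slices[channel, slice_index])

    def mean_amplitude_stack(self) -> np.ndarray:
        """Channel-averaged amplitude, (30, H, W)."""
        return np.mean(np.abs(self.slices), axis=0)

    def in_focus_slice(self) -> int:
        """Index of the globally sharpest slice (channel-averaged,
        Tamura-of-gradient score)."""
        amps = self.mean_amplitude_stack()
        scores = np.array([tamura_gradient_score(a) for a in amps])
        return int(np.argmax(scores))


def gs_reconstruct(hologram: Hologram, z_hat: float, max_iters: int = 100,
                   tol: float = 1e-4) -> ReconStack:
    """Multi-wavelength Gerchberg–Saxton phase retrieval.

    Returns a :class:`ReconStack`; if the residual has not levelled off
    within ``max_iters`` the stack's ``converged`` flag is False (no
    exception is raised).
    """
    if max_iters < 1:
        raise ValueError("max_iters must be >= 1")
    config = hologram.config
    n_ch = len(config.wavelengths)
    if n_ch < 2:
        warnings.warn("single-wavelength reconstruction: phase retrieval is "
                      "under-constrained", UserWarning, stacklevel=2)
    order = list(np.argsort(config.wavelengths))
    binning = config.binning
    pitch = config.grid_pitch
    meas_amp = {c: np.sqrt(np.maximum(hologram.frame(c), 0.0)) for c in range(n_ch)}
    eps = 1e-12

    # init: measured amplitude of the first (shortest-wavelength) channel,
    # zero phase, back-propagated to the sample plane
    c0 = order[0]
    wl0 = config.wavelengths[c0]
    sensor0 = ComplexField(block_upsample(meas_amp[c0], binning).astype(complex),
                           pitch, wl0)
    sample0 = propagate(sensor0, -z_hat)
    sample_amp = {c: np.abs(sample0.values).copy() for c in range(n_ch)}
    opl = np.angle(sample0.values) * wl0 / (2.0 * np.pi)

    residuals: List[float] = []
    converged = False
    sensor_fields: dict[int, np.ndarray] = {}
    best_res = np.inf
    best_state: tuple | None = None
    stall = 0
    for _ in range(max_iters):
        channel_res = []
        for c in order:
            wl = config.wavelengths[c]
            # object-domain constraints: a passive thin specimen transmits
            # at most unity and only retards the wave (OPL >= 0)
            amp_c = np.clip(sample_amp[c], 0.0, 1.0)
            opl_c = np.maximum(opl, 0.0)
            sample = ComplexField(
                amp_c * np.exp(1j * 2.0 * np.pi * opl_c / wl), pitch, wl)
            sensor = propagate(sample, z_hat)
            sim_intensity = block_average(np.abs(sensor.values) ** 2, binning)
            sim_amp = np.sqrt(sim_intensity)
            channel_res.append(
                float(np.sqrt(np.mean((sim_amp - meas_amp[c]) ** 2))
                      / max(np.sqrt(np.mean(meas_amp[c] ** 2)), eps)))
            if binning == 1:
                projected = meas_amp[c] * np.exp(1j * np.angle(sensor.values))
            else:
                ratio = meas_amp[c] / np.maximum(sim_amp, eps)
                projected = sensor.values * block_upsample(ratio, binning)
            sensor_fields[c] = projected
            back = propagate(ComplexField(projected, pitch, wl), -z_hat)
            sample_amp[c] = np.abs(back.values)
            opl = np.angle(back.values) * wl / (2.0 * np.pi)
        cycle_res = float(np.mean(channel_res))
        residuals.append(cycle_res)
        if cycle_res < best_res:
            best_res = cycle_res
            best_state = (dict(sensor_fields), {c: a.copy() for c, a in
                                                sample_amp.items()}, opl.copy())
            stall = 0
        else:
            stall += 1
            if stall >= 3:  # residual no longer improving
                converged = True
                break
        if len(residuals) >= 2:
            prev, cur = residuals[-2], residuals[-1]
            if abs(prev - cur) < tol * max(prev, eps):
                converged = True
                break
    if best_state is not None:
        sensor_fields, sample_amp, opl = best_state
        # the returned stack corresponds to the best state; residuals of
        # discarded plateau cycles are dropped from its history
        best_idx = int(np.argmin(residuals))
        residuals = residuals[:best_idx + 1]

    zs = z_hat + STACK_STEP * (np.arange(N_STACK_SLICES) - 15)
    height, width = config.grid_shape
    slices = np.empty((n_ch, N_STACK_SLICES, height, width), dtype=np.complex64)
    for c in range(n_ch):
        wl = config.wavelengths[c]
        field = ComplexField(sensor_fields[c], pitch, wl)
        for j, d in enumerate(zs):
            slices[c, j] = propagate(field, -float(d)).values
    return ReconStack(slices=slices, zs=zs, wavelengths=config.wavelengths,
                      pitch=pitch, gs_residuals=np.asarray(residuals),
                      converged=converged, provenance=hologram.tile_id)


def _masked_focus_scores(amps: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Tenengrad score of each slice restricted to a pixel mask.

    Inside a tight object mask the local edge energy is the right sharpness
    signal (the whole-field twin-image bias that motivates the normalized
    global metric does not apply there)."""
    scores = np.empty(amps.shape[0])
    for j, a in enumerate(amps):
        gx = ndimage.sobel(a, axis=1, mode="reflect")
        gy = ndimage.sobel(a, axis=0, mode="reflect")
        scores[j] = float(np.mean((gx * gx + gy * gy)[mask]))
    return scores


def per_object_focus(stack: ReconStack, masks: Sequence[np.ndarray]
                     ) -> Tuple[List[float], np.ndarray]:
    """Select a focal slice for each object mask.

    Returns ``(per_object_z, focus_map)`` where ``focus_map`` assigns every
    pixel its selected z (µm); background pixels take the globally sharpest
    slice.  Ties break toward the slice nearest the stack centre; empty
    masks are skipped with a warning (their z is NaN).
    """
    amps = stack.mean_amplitude_stack()
    center = (N_STACK_SLICES - 1) / 2.0
    whole = np.ones(amps.shape[1:], dtype=bool)
    whole_scores = _masked_focus_scores(amps, whole)
    global_best = max(range(N_STACK_SLICES),
                      key=lambda j: (whole_scores[j], -abs(j - center)))
    focus_map = np.full(amps.shape[1:], stack.zs[global_best])
    zs_out: List[float] = []
    for i, mask in enumerate(masks):
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != amps.shape[1:]:
            raise ValueError("mask shape does not match the stack")
        if not mask.any():
            warnings.warn(f"empty object mask {i} skipped", UserWarning, stacklevel=2)
            zs_out.append(float("nan"))
            continue
        scores = _masked_focus_scores(amps, mask)
        best = max(range(N_STACK_SLICES),
                   key=lambda j: (scores[j], -abs(j - center)))
        zs_out.append(float(stack.zs[best]))
        focus_map[mask] = stack.zs[best]
    return zs_out, focus_map


@dataclass(frozen=True)
class ColorImage:
    """RGB composition of a reconstruction with its per-pixel focus choice."""

    rgb: np.ndarray        # (H, W, 3) in [0, 1]
    focus_map: np.ndarray  # (H, W) selected z, µm
    pitch: float           # µm / pixel
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("rgb must be (H, W, 3)")
        if np.min(self.rgb) < -1e-9 or np.max(self.rgb) > 1 + 1e-9:
            raise ValueError("rgb channels must lie in [0, 1]")


def compose_color(stack: ReconStack, focus_map: np.ndarray | None = None, *,
                  gamma: float = 1.8, upsample: int = 1) -> ColorImage:
    """Compose an RGB image from per-wavelength amplitudes at the per-pixel
    focal slice.

    Channels are assigned to primaries by wavelength (longest → red,
    shortest → blue), normalized to the bright background, and
    gamma-encoded.  ``upsample`` optionally resamples the output onto a
    finer display grid (bicubic), emulating the instrument's finer output
    pixel convention without claiming extra optical resolution.
    """
    if len(stack.wavelengths) != 3:
        raise ValueError("colour composition requires exactly 3 wavelength channels")
    if focus_map is None:
        focus_map = np.full(stack.slices.shape[2:], stack.zs[stack.in_focus_slice()])
    if focus_map.shape != stack.slices.shape[2:]:
        raise ValueError("focus_map shape does not match the stack")
    idx = np.clip(np.round((focus_map - stack.zs[0]) / STACK_STEP).astype(int),
                  0, N_STACK_SLICES - 1)
    # longest wavelength drives red
    channel_order = list(np.argsort(stack.wavelengths)[::-1])
    planes = []
    for c in channel_order:
        amp = np.abs(stack.slices[c])
        plane = np.take_along_axis(amp, idx[None], axis=0)[0]
        background = np.percentile(plane, 80)
        plane = np.clip(plane / max(background, 1e-9), 0.0, 1.0)
        planes.append(plane ** (1.0 / gamma))
    rgb = np.stack(planes, axis=-1)
    pitch = stack.pitch
    if upsample > 1:
        rgb = np.clip(rescale(rgb, upsample, channel_axis=2, order=3), 0.0, 1.0)
        focus_map = rescale(focus_map, upsample, order=0)
        pitch = pitch / upsample
    return ColorImage(rgb=rgb, focus_map=focus_map, pitch=pitch,
                      provenance=stack.provenance)


# ---------------------------------------------------------------------------
# Persistence

def save_recon_stack(stack: ReconStack, path: str | Path) -> None:
    """Write amplitude/phase pages (float32) plus a JSON sidecar."""
    base = Path(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    n_ch = stack.slices.shape[0]
    pages = []
    for c in range(n_ch):
        pages.append(np.abs(stack.slices[c]).astype(np.float32))
        pages.append(np.angle(stack.slices[c]).astype(np.float32))
    tifffile.imwrite(base.with_suffix(".tif"), np.concatenate(pages))
    sidecar = {
        "zs": list(map(float, stack.zs)),
        "wavelengths": list(stack.wavelengths),
        "pitch": stack.pitch,
        "gs_residuals": list(map(float, stack.gs_residuals)),
        "converged": stack.converged,
        "provenance": stack.provenance,
        "page_layout": "30 amplitude then 30 phase pages per channel",
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def save_color_image(image: ColorImage, path: str | Path) -> None:
    """Write an 8-bit PNG and a float32 TIFF of the RGB composition."""
    import imageio.v3 as iio

    base = Path(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(base.with_suffix(".png"),
                np.round(image.rgb * 255).astype(np.uint8))
    tifffile.imwrite(base.with_suffix(".tif"), image.rgb.astype(np.float32),
                     photometric="rgb")
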