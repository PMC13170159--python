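"""Synthetic Gram-stained blood-culture smear phantoms.

A phantom is a ground-truth scene — bacterial cells, red-cell background and
optional debris, each with position, size, Gram reaction and arrangement
group — rendered as per-wavelength complex amplitude-transmittance fields on
the simulation grid.  Three slide classes are generated, matching the most
common blood-culture morphologies: Gram-negative bacilli (GNB),
Gram-positive cocci in clusters (GPC_clusters) and Gram-positive cocci in
pairs/chains (GPC_pairs_chains).

Rendering uses a thin-specimen model: each object contributes a projected
chord-thickness profile, converted to absorption through the two-chromophore
stain model in :mod:`holostain.spectra` and to a phase delay through a fixed
refractive-index contrast.  Objects carry a per-group axial offset
``z_offset`` so that different arrangement groups sit at slightly different
depths, as they do in a real smear.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np
import tifffile

from .config import OpticalConfig
from . import spectra

SLIDE_CLASSES = ("GNB", "GPC_clusters", "GPC_pairs_chains")

MANIFEST_SCHEMA_VERSION = 1

# Per-kind optical constants: stain uptake (extinction multiplier per µm of
# chord thickness) and refractive-index contrast for the phase term.
_STAIN_STRENGTH = {"coccus": 1.3, "bacillus": 1.3, "red_cell": 0.12, "debris": 0.45}
_DELTA_N = {"coccus": 0.04, "bacillus": 0.04, "red_cell": 0.03, "debris": 0.05}

#: Default axial span of the specimen (µm); group z-offsets are drawn inside
#: ±span/2 and quantized to 1 µm (the reconstruction slice step).
DEFAULT_Z_SPAN = 4.0

#: Default red-cell background density (cells per mm²).
DEFAULT_RED_CELL_DENSITY = 150.0


class SpecimenTooDenseError(ValueError):
    """Raised when bounded rejection sampling cannot place the requested
    number of objects — the synthetic analogue of a smear too thick to
    image."""


@dataclass(frozen=True)
class SceneObject:
    """One physical object on the slide.

    ``size`` is a diameter (µm) for round objects or ``(length, width)`` for
    bacilli.  ``group_id`` ties together the members of one arrangement
    group (a chain, a cluster, or a singleton).  ``z_offset`` is the axial
    position within the specimen thickness, positive toward the sensor.
    """

    kind: str
    center: Tuple[float, float]
    size: float | Tuple[float, float]
    orientation: float = 0.0
    gram_reaction: str = "not_applicable"
    group_id: int = 0
    z_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("coccus", "bacillus", "red_cell", "debris"):
            raise ValueError(f"unknown object kind {self.kind!r}")
        if self.kind == "bacillus":
            length, width = self.size  # type: ignore[misc]
            if not (length > width > 0):
                raise ValueError("bacillus requires length > width > 0")
        else:
            if not float(self.size) > 0:  # type: ignore[arg-type]
                raise ValueError("size must be positive")
        if self.kind == "coccus" and not (0.5 <= float(self.size) <= 1.5):
            raise ValueError("coccus diameter must lie in 0.5-1.5 µm")
        if abs(self.z_offset) > 15.0:
            raise ValueError("z_offset must lie within the ±15 µm reconstruction span")

    @property
    def equivalent_diameter(self) -> float:
        if self.kind == "bacillus":
            length, width = self.size  # type: ignore[misc]
            return float(np.sqrt(length * width))
        return float(self.size)  # type: ignore[arg-type]

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "center": list(self.center),
            "size": list(self.size) if self.kind == "bacillus" else float(self.size),
            "orientation": self.orientation,
            "gram_reaction": self.gram_reaction,
            "group_id": self.group_id,
            "z_offset": self.z_offset,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SceneObject":
        size = tuple(d["size"]) if isinstance(d["size"], list) else d["size"]
        return cls(
            kind=d["kind"], center=tuple(d["center"]), size=size,
            orientation=d["orientation"], gram_reaction=d["gram_reaction"],
            group_id=d["group_id"], z_offset=d["z_offset"],
        )


@dataclass(frozen=True)
class SpecimenPhantom:
    """A rendered synthetic smear with its ground truth."""

    objects: Tuple[SceneObject, ...]
    true_label: str
    density: float
    stain_quality: float
    seed: int
    config: OpticalConfig
    amplitude: np.ndarray  # (n_wavelengths, H, W) float32 in [0, 1]
    phase: np.ndarray      # (n_wavelengths, H, W) float32, radians

    @property
    def transmittance(self) -> np.ndarray:
        """Per-wavelength complex transmittance (complex64)."""
        return (self.amplitude * np.exp(1j * self.phase)).astype(np.complex64)

    @property
    def bacteria(self) -> Tuple[SceneObject, ...]:
        return tuple(o for o in self.objects if o.kind in ("coccus", "bacillus"))

    def z_planes(self) -> List[float]:
        """Distinct object z-offsets, sorted ascending (farthest from sensor
        first)."""
        return sorted({o.z_offset for o in self.objects})

    def bacteria_mask(self, dilate_um: float = 0.0) -> np.ndarray:
        """Boolean pixel mask covering the bacterial objects (ground truth)."""
        thickness = np.zeros(self.config.grid_shape)
        for obj in self.bacteria:
            _add_thickness(thickness, obj, self.config.grid_pitch, pad_um=dilate_um)
        return thickness > 0


def _object_window(obj: SceneObject, pitch: float, shape: Tuple[int, int],
                   pad_um: float) -> Tuple[slice, slice] | None:
    """Index window (rows, cols) covering the object plus padding."""
    x, y = obj.center
    if obj.kind == "bacillus":
        radius = 0.5 * float(obj.size[0])  # type: ignore[index]
    else:
        radius = 0.5 * float(obj.size)  # type: ignore[arg-type]
    radius += pad_um + pitch
    r0 = int(np.floor((y - radius) / pitch))
    r1 = int(np.ceil((y + radius) / pitch)) + 1
    c0 = int(np.floor((x - radius) / pitch))
    c1 = int(np.ceil((x + radius) / pitch)) + 1
    r0, r1 = max(r0, 0), min(r1, shape[0])
    c0, c1 = max(c0, 0), min(c1, shape[1])
    if r0 >= r1 or c0 >= c1:
        return None
    return slice(r0, r1), slice(c0, c1)


def _chord_thickness(obj: SceneObject, xx: np.ndarray, yy: np.ndarray,
                     pad_um: float = 0.0) -> np.ndarray:
    """Projected chord thickness (µm) of the object at sample points."""
    x0, y0 = obj.center
    dx, dy = xx - x0, yy - y0
    if obj.kind in ("coccus",):
        r = 0.5 * float(obj.size) + pad_um  # type: ignore[arg-type]
        rho2 = dx * dx + dy * dy
        return 2.0 * np.sqrt(np.maximum(r * r - rho2, 0.0))
    if obj.kind == "bacillus":
        length, width = obj.size  # type: ignore[misc]
        c, s = np.cos(obj.orientation), np.sin(obj.orientation)
        along = dx * c + dy * s
        perp = -dx * s + dy * c
        half = max(0.5 * length - 0.5 * width, 0.0)
        d_axis = np.sqrt(np.maximum(np.abs(along) - half, 0.0) ** 2 + perp * perp)
        r = 0.5 * width + pad_um
        return 2.0 * np.sqrt(np.maximum(r * r - d_axis * d_axis, 0.0))
    if obj.kind == "red_cell":
        r = 0.5 * float(obj.size) + pad_um  # type: ignore[arg-type]
        rho = np.sqrt(dx * dx + dy * dy)
        # pale dried disk with a soft 0.4 µm rim
        edge = np.clip((r - rho) / 0.4, 0.0, 1.0)
        return 1.2 * edge
    # debris: lumpy soft blob (ellipse with angular modulation)
    r = 0.5 * float(obj.size) + pad_um  # type: ignore[arg-type]
    c, s = np.cos(obj.orientation), np.sin(obj.orientation)
    u = dx * c + dy * s
    v = -dx * s + dy * c
    rho = np.sqrt((u / 1.4) ** 2 + v * v)
    ang = np.arctan2(v, u)
    wobble = 1.0 + 0.25 * np.sin(3.0 * ang + obj.orientation)
    edge = np.clip((r * wobble - rho) / 0.8, 0.0, 1.0)
    return 1.5 * edge


def _add_thickness(target: np.ndarray, obj: SceneObject, pitch: float,
                   pad_um: float = 0.0) -> None:
    win = _object_window(obj, pitch, target.shape, pad_um)
    if win is None:
        return
    rows, cols = win
    yy, xx = np.meshgrid(
        np.arange(rows.start, rows.stop) * pitch,
        np.arange(cols.start, cols.stop) * pitch,
        indexing="ij",
    )
    target[rows, cols] += _chord_thickness(obj, xx, yy, pad_um=pad_um)


def render_fields(config: OpticalConfig, objects: Sequence[SceneObject],
                  stain_quality: float) -> Tuple[np.ndarray, np.ndarray]:
    """Render per-wavelength (amplitude, phase) float32 stacks for a set of
    objects under the two-chromophore stain model."""
    shape = config.grid_shape
    n_wl = len(config.wavelengths)
    optical_depth = np.zeros((n_wl,) + shape)
    opl = np.zeros(shape)  # optical path length, µm
    for obj in objects:
        win = _object_window(obj, config.grid_pitch, shape, 0.0)
        if win is None:
            continue
        rows, cols = win
        yy, xx = np.meshgrid(
            np.arange(rows.start, rows.stop) * config.grid_pitch,
            np.arange(cols.start, cols.stop) * config.grid_pitch,
            indexing="ij",
        )
        t = _chord_thickness(obj, xx, yy)
        strength = _STAIN_STRENGTH[obj.kind]
        for k, wl in enumerate(config.wavelengths):
            eps = spectra.mixed_extinction(wl, obj.gram_reaction, stain_quality)
            optical_depth[k, rows, cols] += eps * strength * t
        opl[rows, cols] += _DELTA_N[obj.kind] * t
    amplitude = np.exp(-optical_depth).astype(np.float32)
    phase = np.stack(
        [(2.0 * np.pi * opl / wl) for wl in config.wavelengths]
    ).astype(np.float32)
    return amplitude, phase


def _draw_coccus_diameter(rng: np.random.Generator) -> float:
    return float(np.clip(rng.normal(1.05, 0.12), 0.6, 1.4))


def _propose_group(rng: np.random.Generator, label: str, center: Tuple[float, float],
                   group_id: int, z_offset: float,
                   remaining: int = 10**9) -> List[SceneObject]:
    """One arrangement group of the slide class at the given location.

    ``remaining`` caps the group size near the cell budget still to place
    (clusters keep their ≥4, chains their ≥2 definitional minima).
    """
    x0, y0 = center
    if label == "GNB":
        length = rng.uniform(2.5, 4.5)
        width = min(rng.uniform(0.8, 1.1), length / 2.2)
        return [SceneObject("bacillus", (x0, y0), (length, width),
                            orientation=rng.uniform(0, np.pi),
                            gram_reaction="negative", group_id=group_id,
                            z_offset=z_offset)]
    if label == "GPC_clusters":
        # grape-like clump: members touch their neighbours but are not
        # superimposed (rejection sampling with a minimum spacing)
        n = min(int(rng.integers(4, 13)), max(remaining, 4))
        d0 = _draw_coccus_diameter(rng)
        sigma = 1.15 * d0
        placed: List[Tuple[float, float, float]] = []
        out = []
        for _ in range(n):
            d = _draw_coccus_diameter(rng)
            for _attempt in range(40):
                px, py = x0 + rng.normal(0, sigma), y0 + rng.normal(0, sigma)
                if all(np.hypot(px - qx, py - qy) >= 0.5 * (d + qd)
                       for qx, qy, qd in placed):
                    break
            placed.append((px, py, d))
            out.append(SceneObject(
                "coccus", (px, py), d, gram_reaction="positive",
                group_id=group_id, z_offset=z_offset))
        return out
    if label == "GPC_pairs_chains":
        n = min(int(rng.integers(2, 13)), max(remaining, 2))
        theta = rng.uniform(0, np.pi)
        c, s = np.cos(theta), np.sin(theta)
        out = []
        pos = 0.0
        prev_d = None
        for _ in range(n):
            d = _draw_coccus_diameter(rng)
            if prev_d is not None:
                pos += 0.5 * (prev_d + d) * rng.uniform(1.0, 1.15)
            jitter = rng.normal(0, 0.05 * d)
            out.append(SceneObject(
                "coccus", (x0 + pos * c - jitter * s, y0 + pos * s + jitter * c), d,
                gram_reaction="positive", group_id=group_id, z_offset=z_offset))
            prev_d = d
        return out
    raise ValueError(f"unknown slide class {label!r}")


def _group_envelope(members: Sequence[SceneObject]) -> Tuple[float, float, float]:
    xs = np.array([m.center[0] for m in members])
    ys = np.array([m.center[1] for m in members])
    cx, cy = float(xs.mean()), float(ys.mean())
    radii = np.hypot(xs - cx, ys - cy) + [0.5 * m.equivalent_diameter for m in members]
    return cx, cy, float(np.max(radii))


def generate_phantom(config: OpticalConfig, label: str, density: float,
                     stain_quality: float = 0.0, seed: int = 0, *,
                     red_cell_density: float = DEFAULT_RED_CELL_DENSITY,
                     z_span: float = DEFAULT_Z_SPAN,
                     max_attempts_per_group: int = 40) -> SpecimenPhantom:
    """Generate a seeded synthetic smear of one slide class.

    Parameters
    ----------
    density:
        Target bacterial cell density (cells per mm² of field).
    stain_quality:
        Decolorization quality in [-1, 1]; 0 is a well-executed stain.
    z_span:
        Axial extent of the specimen; each arrangement group receives a
        z-offset quantized to 1 µm inside ±z_span/2.

    Raises
    ------
    SpecimenTooDenseError
        If bounded rejection sampling cannot place non-overlapping
        arrangement groups at the requested density.
    """
    if density < 0:
        raise ValueError("density must be non-negative")
    if label not in SLIDE_CLASSES:
        raise ValueError(f"label must be one of {SLIDE_CLASSES}")
    if not (-1.0 <= stain_quality <= 1.0):
        raise ValueError("stain_quality must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    height, width = config.field_extent
    margin = 2.5
    area = config.field_area_mm2
    target_cells = int(rng.poisson(density * area)) if density > 0 else 0

    def draw_z() -> float:
        half = max(int(round(z_span / 2.0)), 0)
        return float(rng.integers(-half, half + 1)) if half else 0.0

    objects: List[SceneObject] = []
    envelopes: List[Tuple[float, float, float]] = []
    placed_cells = 0
    group_id = 0
    attempts = 0
    max_attempts = max_attempts_per_group * max(target_cells, 1)
    while placed_cells < target_cells:
        if attempts >= max_attempts:
            raise SpecimenTooDenseError(
                f"could not place {target_cells} cells at density "
                f"{density}/mm² after {attempts} attempts; specimen too dense")
        attempts += 1
        center = (rng.uniform(margin, width - margin), rng.uniform(margin, height - margin))
        members = _propose_group(rng, label, center, group_id, draw_z(),
                                 remaining=target_cells - placed_cells)
        cx, cy, radius = _group_envelope(members)
        if any(np.hypot(cx - ex, cy - ey) < 1.15 * (radius + er)
               for ex, ey, er in envelopes):
            continue
        if not all(margin * 0.2 <= m.center[0] <= width - margin * 0.2
                   and margin * 0.2 <= m.center[1] <= height - margin * 0.2
                   for m in members):
            continue
        objects.extend(members)
        envelopes.append((cx, cy, radius))
        placed_cells += len(members)
        group_id += 1

    n_rbc = int(rng.poisson(red_cell_density * area)) if red_cell_density > 0 else 0
    for _ in range(n_rbc):
        d = float(np.clip(rng.normal(6.5, 0.6), 4.5, 8.5))
        objects.append(SceneObject(
            "red_cell",
            (rng.uniform(0, width), rng.uniform(0, height)), d,
            gram_reaction="not_applicable", group_id=group_id, z_offset=draw_z()))
        group_id += 1

    amplitude, phase = render_fields(config, objects, stain_quality)
    return SpecimenPhantom(
        objects=tuple(objects), true_label=label, density=density,
        stain_quality=stain_quality, seed=seed, config=config,
        amplitude=amplitude, phase=phase)


# ---------------------------------------------------------------------------
# Persistence: float32 multi-page TIFF (amplitude, phase per wavelength) plus
# a JSON manifest.  Round-trips are bit-exact because the in-memory fields
# are float32.

def save_phantom(phantom: SpecimenPhantom, path: str | Path) -> dict:
    """Write ``<path>.tif`` (image stack) and ``<path>.json`` (manifest).

    Returns the manifest dictionary.
    """
    base = Path(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    pages = []
    for k in range(len(phantom.config.wavelengths)):
        pages.append(phantom.amplitude[k])
        pages.append(phantom.phase[k])
    tifffile.imwrite(base.with_suffix(".tif"), np.stack(pages).astype(np.float32))
    manifest = {
        "schema_version": MANIFEST_SCHEMA_VERSION,
        "true_label": phantom.true_label,
        "density": phantom.density,
        "stain_quality": phantom.stain_quality,
        "seed": phantom.seed,
        "config": phantom.config.to_dict(),
        "n_objects": len(phantom.objects),
        "objects": [o.to_dict() for o in phantom.objects],
        "page_layout": "amplitude,phase per wavelength, wavelength-major",
    }
    base.with_suffix(".json").write_text(json.dumps(manifest, indent=1))
    return manifest


def load_phantom(path: str | Path) -> SpecimenPhantom:
    base = Path(path)
    manifest = json.loads(base.with_suffix(".json").read_text())
    if manifest["schema_version"] != MANIFEST_SCHEMA_VERSION:
        raise ValueError("unsupported phantom manifest schema")
    config = OpticalConfig.from_dict(manifest["config"])
    stack = tifffile.imread(base.with_suffix(".tif"))
    n_wl = len(config.wavelengths)
    amplitude = np.stack([stack[2 * k] for k in range(n_wl)])
    phase = np.stack([stack[2 * k + 1] for k in range(n_wl)])
    return SpecimenPhantom(
        objects=tuple(SceneObject.from_dict(d) for d in manifest["objects"]),
        true_label=manifest["true_label"], density=manifest["density"],
        stain_quality=manifest["stain_quality"], seed=manifest["seed"],
        config=config, amplitude=amplitude, phase=phase)
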