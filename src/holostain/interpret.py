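"""Automated Gram-morphology interpretation of reconstructed colour images.

The slide-level call is produced by interpretable classical rules standing
in for a trained interpretation network, with the same call vocabulary:
Gram-negative bacilli (GNB), Gram-positive cocci in clusters
(GPC_clusters), Gram-positive cocci in pairs/chains (GPC_pairs_chains) and
Undefined.  The stages are

1. segmentation of stained objects (adaptive darkness threshold, size
   filters excluding pale red cells, watershed splitting of touching cocci);
2. per-object Gram reaction (circular hue band membership, linked to the
   generator's two-chromophore stain model) and shape (aspect-ratio rule);
3. arrangement analysis on a centroid proximity graph (clusters vs
   collinear pairs/chains vs singletons);
4. majority aggregation across all detections of a slide with an Undefined
   fallback, plus an attention map supported only on detected objects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from skimage import color as skcolor
from skimage import measure, morphology, segmentation as skseg

from . import spectra
from .reconstruct import ColorImage

SLIDE_CALL_CATEGORIES = ("GNB", "GPC_clusters", "GPC_pairs_chains", "Undefined")


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable segmentation/classification knobs (lengths in µm)."""

    darkness_threshold: float = 0.16   # 1 - min(RGB) above which a pixel is "stained"
    min_area: float = 0.25             # µm², rejects speckle
    max_area: float = 20.0             # µm², rejects red cells / large debris
    split_h_depth: float = 0.14        # µm: watershed marker depth (h-maxima)
    smooth_sigma: float = 0.5          # px: pre-threshold darkness smoothing
    chain_split_aspect: float = 2.2    # purple blobs above this AR are chains
    chain_split_max_width: float = 1.8  # µm: ... if no wider than a coccus
    bacillus_aspect: float = 1.8       # aspect ratio at/above which shape = bacillus
    touch_factor: float = 2.0          # proximity-graph edge: dist <= factor * mean diameter
    line_tol: float = 0.45             # collinearity: centroid RMS <= tol * diameter
    line_width_rms: float = 0.72       # µm: max perpendicular pixel RMS of a chain
    purple_hue_deg: float = spectra.PURPLE_HUE_DEG
    pink_hue_deg: float = spectra.PINK_HUE_DEG
    hue_half_width_deg: float = spectra.HUE_HALF_WIDTH_DEG


@dataclass
class ObjectDetection:
    """One segmented object with its morphology evidence."""

    mask: np.ndarray                 # boolean, full-image shape
    centroid: Tuple[float, float]    # (x, y) µm
    area: float                      # µm²
    circularity: float               # 4πA/P², clipped to (0, 1]
    aspect_ratio: float              # major/minor axis length
    hue_mean_deg: float              # circular mean hue over the mask
    hue_dispersion: float            # 1 - resultant length, in [0, 1]
    focus_z: float                   # µm, from the focus map
    gram_call: Optional[str] = None  # "positive" / "negative"
    shape_call: Optional[str] = None  # "coccus" / "bacillus"
    arrangement: Optional[str] = None  # "cluster" / "pair_chain" / "singleton"
    gram_confidence: float = 0.0
    degenerate: bool = False

    @property
    def equivalent_diameter(self) -> float:
        return float(2.0 * np.sqrt(self.area / np.pi))


def _circular_hue_stats(hues_deg: np.ndarray) -> Tuple[float, float]:
    ang = np.deg2rad(hues_deg)
    vec = np.exp(1j * ang).mean()
    mean = float(np.rad2deg(np.angle(vec)) % 360.0)
    return mean, float(1.0 - np.abs(vec))


def segment_objects(image: ColorImage,
                    params: SegmentationParams = SegmentationParams()
                    ) -> List[ObjectDetection]:
    """Detect stained objects in a reconstructed colour image.

    Stained pixels are darker than the bright background in at least one
    channel; pale large structures (red cells) fall below the darkness
    threshold or above the area cut and are excluded.  Touching cocci are
    split by a distance-transform watershed.
    """
    rgb = image.rgb
    darkness = 1.0 - rgb.min(axis=2)
    if params.smooth_sigma > 0:
        darkness = ndimage.gaussian_filter(darkness, params.smooth_sigma)
    stained = darkness > params.darkness_threshold
    px_area = image.pitch ** 2
    min_px = max(int(round(params.min_area / px_area)), 1)
    if min_px > 1:
        stained = morphology.remove_small_objects(stained, max_size=min_px - 1)
    if not stained.any():
        return []

    # split touching cocci: h-maxima of the distance transform keep one
    # marker per convex lobe while a rod's flat ridge stays a single marker
    distance = ndimage.distance_transform_edt(stained) * image.pitch
    distance = ndimage.gaussian_filter(distance, 0.8)
    maxima = morphology.h_maxima(distance, params.split_h_depth)
    markers, n_markers = ndimage.label(maxima)
    if n_markers == 0:
        labels, _ = ndimage.label(stained)
    else:
        labels = skseg.watershed(-distance, markers, mask=stained)

    labels = _subdivide_merged_chains(labels, rgb, image.pitch, params)

    hsv = skcolor.rgb2hsv(rgb)
    hue_deg = hsv[..., 0] * 360.0
    detections: List[ObjectDetection] = []
    for region in measure.regionprops(labels):
        area_um2 = region.area * px_area
        if not (params.min_area <= area_um2 <= params.max_area):
            continue
        mask = labels == region.label
        perimeter = measure.perimeter(mask) * image.pitch
        circularity = 1.0 if perimeter == 0 else \
            float(np.clip(4.0 * np.pi * area_um2 / perimeter**2, 1e-6, 1.0))
        minor = max(region.axis_minor_length, 1e-9)
        aspect = float(max(region.axis_major_length / minor, 1.0))
        # hue of the mean RGB over the mask: averaging in RGB first is far
        # more robust to per-pixel halo/ringing than averaging pixel hues
        mean_rgb = rgb[mask].mean(axis=0)
        hue_mean = float(skcolor.rgb2hsv(mean_rgb[None, None, :])[0, 0, 0] * 360.0)
        _, hue_disp = _circular_hue_stats(hue_deg[mask])
        cy, cx = region.centroid
        focus_z = float(np.median(image.focus_map[mask]))
        detections.append(ObjectDetection(
            mask=mask, centroid=(cx * image.pitch, cy * image.pitch),
            area=float(area_um2), circularity=circularity, aspect_ratio=aspect,
            hue_mean_deg=hue_mean, hue_dispersion=hue_disp, focus_z=focus_z,
            degenerate=region.area <= 1))
    return detections


def _subdivide_merged_chains(labels: np.ndarray, rgb: np.ndarray, pitch: float,
                             params: SegmentationParams) -> np.ndarray:
    """Split elongated crystal-violet blobs along their major axis.

    Touching cocci in a chain blur into a single sausage at the
    reconstruction's resolution.  An elongated purple object no wider than
    a coccus cannot be anything but such a merged chain (Gram-positive rods
    are outside the call vocabulary), so it is subdivided into
    round(aspect) pieces.  Pink rods (true bacilli) are left alone.
    """
    next_label = int(labels.max()) + 1
    for region in measure.regionprops(labels):
        minor = region.axis_minor_length * pitch
        major = region.axis_major_length * pitch
        if minor <= 0:
            continue
        aspect = major / minor
        if aspect < params.chain_split_aspect or \
                minor > params.chain_split_max_width:
            continue
        mask = labels == region.label
        mean_rgb = rgb[mask].mean(axis=0)
        hue = float(skcolor.rgb2hsv(mean_rgb[None, None, :])[0, 0, 0] * 360.0)
        d_purple = spectra.circular_hue_distance(hue, params.purple_hue_deg)
        d_pink = spectra.circular_hue_distance(hue, params.pink_hue_deg)
        if d_purple > d_pink:
            continue
        n_pieces = int(round(aspect))
        if n_pieces < 2:
            continue
        rr, cc = np.nonzero(mask)
        coords = np.c_[rr, cc].astype(float)
        coords -= coords.mean(axis=0)
        _, _, vt = np.linalg.svd(coords, full_matrices=False)
        t = coords @ vt[0]
        edges = np.quantile(t, np.linspace(0, 1, n_pieces + 1)[1:-1])
        piece = np.digitize(t, edges)
        labels[rr, cc] = next_label + piece
        next_label += n_pieces
    return labels


def gram_and_shape(detection: ObjectDetection,
                   params: SegmentationParams = SegmentationParams()
                   ) -> ObjectDetection:
    """Assign the Gram reaction (hue-band membership) and shape call.

    A tie between the purple and pink bands resolves toward the nearer band
    centre.  One-pixel masks are flagged degenerate and excluded from
    aggregation by the caller.
    """
    d_purple = float(spectra.circular_hue_distance(detection.hue_mean_deg,
                                                   params.purple_hue_deg))
    d_pink = float(spectra.circular_hue_distance(detection.hue_mean_deg,
                                                 params.pink_hue_deg))
    gram = "positive" if d_purple <= d_pink else "negative"
    nearest = min(d_purple, d_pink)
    confidence = float(np.clip(1.0 - nearest / params.hue_half_width_deg, 0.0, 1.0))
    shape = "bacillus" if detection.aspect_ratio >= params.bacillus_aspect else "coccus"
    detection.gram_call = gram
    detection.shape_call = shape
    detection.gram_confidence = confidence
    return detection


def arrangement(detections: Sequence[ObjectDetection],
                params: SegmentationParams = SegmentationParams()
                ) -> List[str]:
    """Label each detection cluster / pair_chain / singleton.

    Builds a proximity graph (edge when centroid distance ≤ touch_factor ×
    mean diameter of the pair) and classifies each connected component:
    collinear components of size ≥ 2 are pairs/chains, non-collinear
    components of size ≥ 4 are clusters, everything else is singleton.
    """
    n = len(detections)
    if n == 0:
        return []
    pts = np.array([d.centroid for d in detections])
    diam = np.array([d.equivalent_diameter for d in detections])
    tree = cKDTree(pts)
    pairs = tree.query_pairs(params.touch_factor * float(diam.max()),
                             output_type="ndarray")
    if len(pairs):
        dist = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
        mean_d = 0.5 * (diam[pairs[:, 0]] + diam[pairs[:, 1]])
        keep = dist <= params.touch_factor * mean_d
        pairs = pairs[keep]
    if len(pairs):
        adj = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                         shape=(n, n))
        _, comp = connected_components(adj, directed=False)
    else:
        comp = np.arange(n)

    out = ["singleton"] * n
    pitch_scale = None
    for cid in np.unique(comp):
        members = np.flatnonzero(comp == cid)
        size = len(members)
        if size == 1:
            continue
        sub = pts[members] - pts[members].mean(axis=0)
        # centroid collinearity about the principal axis
        _, svals, _ = np.linalg.svd(sub, full_matrices=False)
        rms_centroid = float(svals[-1] / np.sqrt(size)) if len(svals) > 1 else 0.0
        mean_diam = float(diam[members].mean())
        # pixel-level test: a chain is only one coccus wide, a clump is not
        pix = np.vstack([np.argwhere(detections[m].mask) for m in members]).astype(float)
        if pitch_scale is None:
            # infer µm/px from one member's mask area vs its area in µm²
            m0 = members[0]
            pitch_scale = float(np.sqrt(detections[m0].area /
                                        max(detections[m0].mask.sum(), 1)))
        pix = (pix - pix.mean(axis=0)) * pitch_scale
        _, psv, _ = np.linalg.svd(pix, full_matrices=False)
        rms_width = float(psv[-1] / np.sqrt(len(pix))) if len(psv) > 1 else 0.0
        collinear = (rms_centroid <= params.line_tol * mean_diam and
                     rms_width <= params.line_width_rms)
        if collinear:
            label = "pair_chain"
        elif size >= 4:
            label = "cluster"
        else:
            label = "singleton"
        for m in members:
            out[m] = label
    for d, label in zip(detections, out):
        d.arrangement = label
    return out


@dataclass(frozen=True)
class SlideCall:
    """Slide-level Gram morphology interpretation."""

    category: str
    attention_map: np.ndarray     # per-pixel weight in [0, 1]
    evidence: Dict[str, int]      # per-category classifiable vote counts
    n_objects: int

    def __post_init__(self) -> None:
        if self.category not in SLIDE_CALL_CATEGORIES:
            raise ValueError(f"unknown slide category {self.category!r}")


def _vote(detection: ObjectDetection) -> Optional[str]:
    """Map one classified detection to a slide-call vote, or None if its
    evidence combination matches no category (abstain)."""
    if detection.degenerate or detection.gram_call is None:
        return None
    if detection.gram_call == "negative" and detection.shape_call == "bacillus":
        return "GNB"
    if detection.gram_call == "positive" and detection.shape_call == "coccus":
        if detection.arrangement == "cluster":
            return "GPC_clusters"
        if detection.arrangement == "pair_chain":
            return "GPC_pairs_chains"
    return None


def slide_call(detections: Sequence[ObjectDetection], image_shape: Tuple[int, int],
               *, min_objects: int = 10, majority_frac: float = 0.6) -> SlideCall:
    """Aggregate per-object evidence into the slide-level call.

    A category wins when it carries more than ``majority_frac`` of the
    classifiable votes and the slide holds at least ``min_objects``
    detections; otherwise the call is Undefined.  The attention map covers
    the winning category's objects (all detected objects when Undefined),
    weighted by per-object Gram-call confidence.
    """
    votes: Dict[str, int] = {c: 0 for c in SLIDE_CALL_CATEGORIES[:3]}
    for det in detections:
        v = _vote(det)
        if v is not None:
            votes[v] += 1
    n_classifiable = sum(votes.values())
    n_objects = len(detections)
    category = "Undefined"
    if n_classifiable > 0 and n_objects >= min_objects:
        best = max(votes, key=lambda c: votes[c])
        if votes[best] > majority_frac * n_classifiable:
            category = best

    attention = np.zeros(image_shape)
    for det in detections:
        if det.degenerate:
            continue
        if category != "Undefined" and _vote(det) != category:
            continue
        weight = max(det.gram_confidence, 0.05)
        attention[det.mask] = np.maximum(attention[det.mask], weight)
    peak = attention.max()
    if peak > 0:
        attention = attention / peak
    return SlideCall(category=category, attention_map=attention,
                     evidence=votes, n_objects=n_objects)


def interpret_image(image: ColorImage,
                    params: SegmentationParams = SegmentationParams()
                    ) -> List[ObjectDetection]:
    """Segment and fully classify one colour image."""
    detections = segment_objects(image, params)
    for det in detections:
        gram_and_shape(det, params)
    arrangement(detections, params)
    return detections


def attention_overlay(image: ColorImage, call: SlideCall,
                      color: Tuple[float, float, float] = (1.0, 0.2, 0.2),
                      alpha: float = 0.45) -> np.ndarray:
    """Blend the attention map over the colour image (RGB float array)."""
    overlay = image.rgb.copy()
    w = (alpha * call.attention_map)[..., None]
    return np.clip(overlay * (1 - w) + np.asarray(color) * w, 0.0, 1.0)
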