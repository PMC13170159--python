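"""Two-chromophore stain colour model shared by the phantom generator and
the interpretation rules.

Gram staining leaves Gram-positive organisms loaded with a crystal-violet-
like chromophore (purple) and Gram-negative organisms with a safranin-like
counterstain (pink).  Each chromophore is modelled as a wavelength-dependent
extinction coefficient per µm of stained material; a cell's amplitude
transmittance at wavelength lambda is ``exp(-eps_mix(lambda) * strength * t)``
where ``t`` is the local chord thickness.

Decolorization quality shifts the mix: over-decolorization (negative
``stain_quality``) strips crystal violet from Gram-positives, pushing them
toward pink; under-decolorization (positive) leaves crystal violet in
Gram-negatives, pushing them toward purple.  The interpretation module's hue
bands (below) are the image-side counterpart of this generator model: they
are where the two mixes land after RGB composition, and the pair must be
kept in sync if either side changes.
"""

from __future__ import annotations

import numpy as np

# Extinction per µm at the anchor wavelengths (µm); linearly interpolated.
_ANCHOR_WL = np.array([0.45, 0.52, 0.63])
_CRYSTAL_VIOLET = np.array([0.14, 1.10, 0.55])   # absorbs green/red -> purple
_SAFRANIN = np.array([0.55, 1.00, 0.15])         # absorbs blue/green -> pink

#: Hue band centres (circular degrees, HSV) of the two stain appearances in
#: composed RGB images, with their common half-width.  Linked to the
#: extinction curves above.
PURPLE_HUE_DEG = 280.0
PINK_HUE_DEG = 333.0
HUE_HALF_WIDTH_DEG = 40.0


def extinction(wavelength: float, chromophore: str) -> float:
    """Extinction coefficient (per µm) of one chromophore at ``wavelength``."""
    curve = {"crystal_violet": _CRYSTAL_VIOLET, "safranin": _SAFRANIN}[chromophore]
    return float(np.interp(wavelength, _ANCHOR_WL, curve))


def crystal_violet_fraction(gram_reaction: str, stain_quality: float) -> float:
    """Fraction of the chromophore mix that is crystal-violet-like.

    Gram-positive cells are crystal-violet dominated, Gram-negative cells
    safranin dominated; ``stain_quality`` in [-1, 1] moves each toward the
    other (over-decolorized < 0 < under-decolorized).
    """
    sq = float(np.clip(stain_quality, -1.0, 1.0))
    if gram_reaction == "positive":
        f = 0.9 + (0.40 * sq if sq < 0 else 0.1 * sq)
    elif gram_reaction == "negative":
        f = 0.1 + (0.55 * sq if sq > 0 else 0.05 * sq)
    else:  # unstained background material (red cells, debris)
        f = 0.5
    return float(np.clip(f, 0.0, 1.0))


def mixed_extinction(wavelength: float, gram_reaction: str, stain_quality: float) -> float:
    f = crystal_violet_fraction(gram_reaction, stain_quality)
    return f * extinction(wavelength, "crystal_violet") + (1.0 - f) * extinction(
        wavelength, "safranin"
    )


def circular_hue_distance(hue_deg: np.ndarray | float, center_deg: float) -> np.ndarray:
    """Absolute circular distance between hues, in degrees, in [0, 180]."""
    d = np.abs((np.asarray(hue_deg, dtype=float) - center_deg + 180.0) % 360.0 - 180.0)
    return d


def hue_band(hue_deg: np.ndarray | float, center_deg: float,
             half_width_deg: float = HUE_HALF_WIDTH_DEG) -> np.ndarray:
    """Boolean membership of hues in a circular band."""
    return circular_hue_distance(hue_deg, center_deg) <= half_width_deg
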