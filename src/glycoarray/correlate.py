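"""Spatial correlation of SIMS glycan maps with SPRi protein-binding maps.

ToF-SIMS is destructive, so chemical and binding images come from replicate
surfaces printed in parallel (or, here, from a shared synthetic ground
truth). The binding image is resampled onto the SIMS pixel grid, the binding
region is outlined by thresholding, the outline is overlaid on the glycan
map, and agreement is quantified with Dice/Jaccard overlap of the masks plus
a pixelwise Pearson correlation of the aligned images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .ion_maps import CategoryMap, binarize, dice_coefficient, jaccard_index

__all__ = [
    "AlignedPair",
    "coregister",
    "binding_contour",
    "overlay",
    "spatial_agreement",
]


@dataclass
class AlignedPair:
    """A SIMS map and an SPRi response image on the same pixel grid."""

    sims_map: np.ndarray
    spri_map: np.ndarray
    transform: tuple[tuple[float, float], float] | str

    def __post_init__(self) -> None:
        if self.sims_map.shape != self.spri_map.shape:
            raise ValueError("aligned images must share a shape")


def _as_image(m) -> np.ndarray:
    return m.image if isinstance(m, CategoryMap) else np.asarray(m, dtype=float)


def coregister(
    sims_map: CategoryMap | np.ndarray,
    spri_frame: np.ndarray,
    transform: tuple[tuple[float, float], float] | str = "identity",
) -> AlignedPair:
    """Resample an SPRi frame onto the SIMS pixel grid.

    `transform` is "identity" (requires equal grids) or
    ((offset_row_px, offset_col_px), scale): SIMS pixel (r, c) samples the
    SPRi frame at (r*scale + offset_row, c*scale + offset_col) by bilinear
    interpolation; samples outside the frame read 0.
    """
    sims = _as_image(sims_map)
    spri = np.asarray(spri_frame, dtype=float)
    if transform == "identity":
        if sims.shape != spri.shape:
            raise ValueError("identity transform requires equal grids")
        return AlignedPair(sims, spri.copy(), "identity")
    (dr, dc), scale = transform
    rr, cc = np.meshgrid(
        np.arange(sims.shape[0]), np.arange(sims.shape[1]), indexing="ij"
    )
    coords = np.stack([rr * scale + dr, cc * scale + dc])
    resampled = ndimage.map_coordinates(
        spri, coords, order=1, mode="constant", cval=0.0
    )
    return AlignedPair(sims, resampled, transform)


def binding_contour(
    spri_map: np.ndarray, method: str = "otsu", level: float | None = None
) -> np.ndarray:
    """Binary protein-binding region from a single-time SPRi response image."""
    return binarize(np.asarray(spri_map, dtype=float), method=method, level=level)


def overlay(
    sims_map: CategoryMap | np.ndarray, binding_mask: np.ndarray
) -> np.ndarray:
    """Grayscale glycan map with the binding-region outline burned in red.

    The outline is the 1-pixel inner contour of the mask (mask minus its
    erosion; mask pixels on the image border count as contour). Returns an
    RGB float image in [0, 1].
    """
    img = _as_image(sims_map)
    mask = np.asarray(binding_mask, dtype=bool)
    if img.shape != mask.shape:
        raise ValueError("shape mismatch between image and mask")
    lo, hi = float(img.min()), float(img.max())
    gray = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    contour = mask & ~ndimage.binary_erosion(mask, border_value=0)
    rgb = np.stack([gray, gray, gray], axis=-1)
    rgb[contour] = (1.0, 0.0, 0.0)
    return rgb


def spatial_agreement(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    image_a: np.ndarray | None = None,
    image_b: np.ndarray | None = None,
) -> dict:
    """Overlap statistics between two aligned binary masks (and images).

    Reports Dice and Jaccard of the masks; when both images are supplied and
    non-constant, also the all-pixel Pearson r (flagged undefined otherwise).
    No single headline number is privileged — the three statistics answer
    slightly different questions about where chemistry and bioactivity agree.
    """
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != mask_b.shape:
        raise ValueError("masks must share a shape")
    out = {
        "dice": dice_coefficient(mask_a, mask_b),
        "jaccard": jaccard_index(mask_a, mask_b),
        "pearson_r": None,
        "pearson_defined": False,
    }
    if image_a is not None and image_b is not None:
        a = np.asarray(image_a, dtype=float).ravel()
        b = np.asarray(image_b, dtype=float).ravel()
        if a.shape != b.shape:
            raise ValueError("images must share a shape")
        if np.ptp(a) > 0 and np.ptp(b) > 0:
            out["pearson_r"] = float(stats.pearsonr(a, b).statistic)
            out["pearson_defined"] = True
    return out
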