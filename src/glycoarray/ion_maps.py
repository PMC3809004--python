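"""Category-summed ion images, thresholded masks, RGB chemical maps and
spot morphology.

Ion maps sum the counts of all channels assigned to one fragment source
(GDAP glycan, OEG/SAM monolayer, gold substrate). Maps are min-max
normalized for display, binarized (Otsu by default), and combined into an
RGB chemical map — red for glycan, green for OEG/SAM, blue for gold. Spot
morphology (area, equivalent diameter, centroid, eccentricity, Dice overlap
with a reference mask) is measured on the largest 8-connected component of
a binary mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage import measure
from skimage.filters import threshold_otsu

from .sims_cube import (
    CONTAMINANT_CATEGORIES,
    PeakTable,
    SimsCube,
    match_channel_index,
)

__all__ = [
    "CategoryMap",
    "CompositeImage",
    "category_image",
    "normalize_image",
    "binarize",
    "composite_rgb",
    "spot_metrics",
    "dice_coefficient",
    "jaccard_index",
    "radial_profile",
    "write_map_tiff",
    "write_composite_png",
]

DEFAULT_RGB_CATEGORIES = ("GDAP", "OEG/SAM", "Gold")


@dataclass
class CategoryMap:
    """Per-pixel summed ion counts for one fragment source category."""

    category: str
    image: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise ValueError("image must be 2-D")
        if np.any(self.image < 0):
            raise ValueError("image must be non-negative")
        if self.normalized and self.image.max() > 1.0 + 1e-12:
            raise ValueError("normalized image must lie in [0, 1]")


@dataclass
class CompositeImage:
    """RGB chemical map; channel_categories maps (red, green, blue) to sources."""

    rgb: np.ndarray
    channel_categories: tuple[str, str, str] = DEFAULT_RGB_CATEGORIES


def _as_image(m: CategoryMap | np.ndarray) -> np.ndarray:
    return m.image if isinstance(m, CategoryMap) else np.asarray(m, dtype=float)


def category_image(
    cube: SimsCube,
    peaks: PeakTable,
    category: str,
    allow_contaminants: bool = False,
) -> CategoryMap:
    """Sum the cube channels assigned to `category` into one ion map.

    `peaks` may be any assigned peak table (e.g. the selected-ion table from
    PCA). Hydrocarbon and salt maps are refused unless `allow_contaminants`
    is set: those adventitious species are dropped from chemical mapping by
    default and only produced explicitly for contamination QC.
    """
    if isinstance(peaks, PeakTable):
        table = peaks
    else:  # IonSelection quacks via .selected_peaks
        table = peaks.selected_peaks
    if category in CONTAMINANT_CATEGORIES and not allow_contaminants:
        raise ValueError(
            f"{category} is a contaminant category; pass allow_contaminants=True"
        )
    sub = table.subset(category)
    if len(sub) == 0:
        raise ValueError(f"no peaks carry category {category!r}")
    idx = [match_channel_index(cube.channel_mz, mz, table.mz_tol) for mz in sub.mz]
    return CategoryMap(category=category, image=cube.counts[:, :, idx].sum(axis=2))


def normalize_image(cmap: CategoryMap) -> CategoryMap:
    """Min-max scale an ion map to [0, 1] for display and thresholding."""
    img = cmap.image
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        raise ValueError("degenerate contrast")
    return CategoryMap(cmap.category, (img - lo) / (hi - lo), normalized=True)


def binarize(
    m: CategoryMap | np.ndarray,
    method: str = "otsu",
    level: float | None = None,
) -> np.ndarray:
    """Binary mask = image >= threshold.

    method "otsu" maximizes between-class variance over a 256-bin histogram;
    method "fixed" uses the given `level`. Constant images have no contrast
    to threshold and raise.
    """
    img = _as_image(m)
    if img.max() == img.min():
        raise ValueError("degenerate contrast")
    if method == "otsu":
        thr = float(threshold_otsu(img, nbins=256))
    elif method == "fixed":
        if level is None:
            raise ValueError("fixed method requires a level")
        thr = float(level)
    else:
        raise ValueError(f"unknown method {method!r}")
    return img >= thr


def composite_rgb(
    maps: tuple[CategoryMap | np.ndarray, ...],
    channel_categories: tuple[str, str, str] = DEFAULT_RGB_CATEGORIES,
) -> CompositeImage:
    """Stack three normalized maps (or binary masks) into an RGB image."""
    if len(maps) != 3:
        raise ValueError("exactly three maps required (red, green, blue)")
    imgs = [np.asarray(_as_image(m), dtype=float) for m in maps]
    if not (imgs[0].shape == imgs[1].shape == imgs[2].shape):
        raise ValueError("shape mismatch between channel maps")
    for img in imgs:
        if img.min() < 0 or img.max() > 1 + 1e-12:
            raise ValueError("channel values must lie in [0, 1]")
    return CompositeImage(
        rgb=np.clip(np.stack(imgs, axis=-1), 0.0, 1.0),
        channel_categories=channel_categories,
    )


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) of two binary masks (1 if both empty)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom


def jaccard_index(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard overlap |A∩B| / |A∪B| of two binary masks (1 if both empty)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return np.logical_and(a, b).sum() / union


def spot_metrics(
    mask: np.ndarray,
    pixel_um: float,
    truth_mask: np.ndarray | None = None,
) -> dict:
    """Morphology of the largest 8-connected component of a spot mask.

    Returns area (um^2), equivalent-circle diameter (um), centroid (x_um,
    y_um; pixel-center convention), eccentricity, and — when a ground-truth
    mask is given — the Dice coefficient of the *full* mask against it. An
    empty mask yields NaN morphology flagged undefined, with Dice 0.
    """
    mask = np.asarray(mask, dtype=bool)
    out: dict = {"defined": bool(mask.any())}
    if mask.any():
        lab = measure.label(mask, connectivity=2)
        props = max(measure.regionprops(lab), key=lambda p: p.area)
        out["area_um2"] = float(props.area) * pixel_um**2
        out["equivalent_diameter_um"] = (
            float(props.equivalent_diameter_area) * pixel_um
        )
        r0, c0 = props.centroid
        out["centroid_um"] = ((c0 + 0.5) * pixel_um, (r0 + 0.5) * pixel_um)
        out["eccentricity"] = float(props.eccentricity)
    else:
        out.update(
            area_um2=float("nan"),
            equivalent_diameter_um=float("nan"),
            centroid_um=(float("nan"), float("nan")),
            eccentricity=float("nan"),
        )
    if truth_mask is not None:
        out["dice"] = 0.0 if not mask.any() else dice_coefficient(mask, truth_mask)
    return out


def radial_profile(
    image: np.ndarray,
    center_um: tuple[float, float],
    pixel_um: float,
    bin_um: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean intensity vs. distance from a center, in radial bins.

    Returns (bin_center_um, mean_intensity); used to locate rim enrichment
    ("coffee stain") in ion maps.
    """
    img = np.asarray(image, dtype=float)
    rows, cols = img.shape
    xc = (np.arange(cols) + 0.5) * pixel_um - center_um[0]
    yc = (np.arange(rows) + 0.5) * pixel_um - center_um[1]
    dist = np.hypot(xc[None, :], yc[:, None]).ravel()
    vals = img.ravel()
    nbins = int(np.ceil(dist.max() / bin_um))
    idx = np.minimum((dist / bin_um).astype(int), nbins - 1)
    sums = np.bincount(idx, weights=vals, minlength=nbins)
    counts = np.bincount(idx, minlength=nbins)
    with np.errstate(invalid="ignore"):
        prof = sums / counts
    centers = (np.arange(nbins) + 0.5) * bin_um
    return centers, prof


def write_map_tiff(m: CategoryMap | np.ndarray, path: str | Path) -> None:
    """Write an ion map or mask as 16-bit TIFF (normalized maps scaled to 65535)."""
    import tifffile

    img = _as_image(m)
    if img.dtype == bool or img.max() <= 1.0:
        data = (img.astype(float) * 65535).round().astype(np.uint16)
    else:
        data = np.clip(img, 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), data)


def write_composite_png(comp: CompositeImage, path: str | Path) -> None:
    import imageio.v3 as iio

    iio.imwrite(str(path), (comp.rgb * 255).round().astype(np.uint8))
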