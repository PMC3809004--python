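"""End-to-end analysis chains tying the modules together.

These are the workflows the numbered analysis scripts, the test suite and
the acceptance script all share: replicate-cube ion discovery (peak picking
-> ROI spectrum matrix -> PCA -> PC1 ion selection -> region separation),
and glycan-map reconstruction scored against the planted ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import ion_maps, pca_roi, sims_cube
from .pca_roi import IonSelection, PcaResult
from .sims_cube import PeakTable, RoiSpec, SimsCube, SpectrumMatrix
from .synthetic_data import GroundTruth, simulate_sims_cube

__all__ = ["standard_rois", "DiscoveryResult", "discover_ions", "glycan_map_dice"]


def standard_rois(field_um: float, roi_um: float = 100.0, margin_um: float = 25.0):
    """The three-ROI layout used for region PCA: upper-left (I), center (II),
    lower-right (III) squares of side `roi_um`."""
    c = field_um / 2 - roi_um / 2
    lr = field_um - margin_um - roi_um
    return {
        "I": RoiSpec(margin_um, margin_um, roi_um, roi_um),
        "II": RoiSpec(c, c, roi_um, roi_um),
        "III": RoiSpec(lr, lr, roi_um, roi_um),
    }


@dataclass
class DiscoveryResult:
    """Everything the ion-discovery chain produces."""

    cubes: list[SimsCube]
    picked: PeakTable  # assigned, contaminants still present
    analysis_peaks: PeakTable  # contaminants removed
    matrix: SpectrumMatrix
    normalized: SpectrumMatrix
    pca: PcaResult
    selection: IonSelection
    p_spot_vs_background: float
    p_background_similarity: float

    @property
    def spot_rows(self) -> list[int]:
        return [i for i, lab in enumerate(self.matrix.labels) if lab.endswith(":II")]

    @property
    def background_rows(self) -> list[int]:
        return [i for i, lab in enumerate(self.matrix.labels) if not lab.endswith(":II")]


def discover_ions(
    gt: GroundTruth,
    n_images: int = 5,
    seed: int = 0,
    k: float = 3.0,
    threshold: float = pca_roi.DEFAULT_LOADING_THRESHOLD,
    cubes: list[SimsCube] | None = None,
) -> DiscoveryResult:
    """Replicate-image ROI PCA ion discovery.

    Simulates `n_images` replicate cubes (seeds seed..seed+n_images-1) unless
    given, picks peaks >= k x noise floor on the first cube, assigns them from
    the ground truth's reference table, drops hydrocarbon/salt contaminants,
    builds the (3 ROIs x n_images)-row spectrum matrix, total-ion-normalizes
    and mean-centers it, fits PCA, orients PC1 so background ROIs score
    positive, selects ions at |PC1 loading| >= threshold, and Welch-tests the
    spot-vs-background and background-I-vs-III score contrasts.
    """
    if cubes is None:
        cubes = [simulate_sims_cube(gt, seed=seed + i) for i in range(n_images)]
    picked = sims_cube.pick_peaks(
        cubes[0], sims_cube.noise_floor_background(cubes[0]), k=k
    )
    picked = sims_cube.assign_categories(picked, gt.peaks)
    analysis_peaks = picked.drop(*sims_cube.CONTAMINANT_CATEGORIES)

    rois = standard_rois(gt.field_um)
    matrix = sims_cube.spectrum_matrix(cubes, rois, analysis_peaks)
    normalized, centered = sims_cube.normalize_spectra(matrix)
    pca = pca_roi.fit_pca(centered)

    background_rows = [
        i for i, lab in enumerate(matrix.labels) if not lab.endswith(":II")
    ]
    pca = pca_roi.orient_pc1(pca, background_rows)
    selection = pca_roi.select_ions(pca, analysis_peaks, threshold)

    pc1 = pca.scores[:, 0]
    region = np.array([lab.split(":")[1] for lab in matrix.labels])
    p_spot = pca_roi.group_separation(
        pc1, np.where(region == "II", "spot", "background")
    )
    keep = region != "II"
    p_bg = pca_roi.group_separation(pc1[keep], region[keep])

    return DiscoveryResult(
        cubes=cubes,
        picked=picked,
        analysis_peaks=analysis_peaks,
        matrix=matrix,
        normalized=normalized,
        pca=pca,
        selection=selection,
        p_spot_vs_background=p_spot,
        p_background_similarity=p_bg,
    )


def glycan_map_dice(
    gt: GroundTruth, cube: SimsCube, peaks: PeakTable
) -> tuple[float, np.ndarray]:
    """Dice of the Otsu-binarized GDAP ion map against the planted spot mask.

    Returns (dice, mask). The reference is the printed disk; a wash tail in
    the cube sits well below the Otsu threshold at default amplitudes, so it
    does not join the mask.
    """
    gdap = ion_maps.category_image(cube, peaks, "GDAP")
    mask = ion_maps.binarize(ion_maps.normalize_image(gdap))
    return ion_maps.dice_coefficient(mask, gt.spot_mask), mask
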