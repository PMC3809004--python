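"""Hyperspectral ToF-SIMS image cubes: data model, imzML I/O and spectral operations.

A cube holds per-pixel secondary-ion counts on a fixed list of m/z channels,
acquired (or simulated) over a square field with a known pixel size. The
operations here cover the standard preprocessing chain for ROI-based
multivariate analysis of such cubes: fragment mass calculation, peak picking
against a noise background, ROI spectrum extraction, and total-ion /
mean-centering normalization.

Conventions used throughout the package
---------------------------------------
* pixel grid is 0-based, row-major, origin at the top-left of the field;
  pixel (r, c) covers the half-open square
  [c*pixel_um, (c+1)*pixel_um) x [r*pixel_um, (r+1)*pixel_um) in (x, y);
* a pixel belongs to an ROI iff its *center* falls inside the half-open
  ROI rectangle.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _ptmass
from scipy.constants import elementary_charge

__all__ = [
    "CATEGORIES",
    "CONTAMINANT_CATEGORIES",
    "STATIC_SIMS_LIMIT",
    "SimsCube",
    "PeakTable",
    "RoiSpec",
    "SpectrumMatrix",
    "DoseReport",
    "fragment_mz",
    "reference_peak_table",
    "read_cube",
    "write_cube",
    "total_ion_image",
    "pick_peaks",
    "background_from_roi",
    "noise_floor_background",
    "assign_categories",
    "extract_roi_spectrum",
    "spectrum_matrix",
    "normalize_spectra",
    "ion_dose",
    "roi_pixel_slices",
    "match_channel_index",
]

#: Closed set of fragment source categories.
CATEGORIES = ("GDAP", "OEG/SAM", "Gold", "Hydrocarbon", "Salt", "Unassigned")

#: Adventitious contaminants from printing/handling, excluded from chemical maps.
CONTAMINANT_CATEGORIES = ("Hydrocarbon", "Salt")

#: Static-SIMS primary ion dose limit (ions/cm^2).
STATIC_SIMS_LIMIT = 1.0e12

#: Analysis mass window (Da).
MZ_WINDOW = (1.0, 350.0)

#: Tolerance for matching a fragment mass to a cube channel (Da).
MZ_MATCH_TOL = 0.02

_ELECTRON_DA = _ptmass.nist_mass["e*"][0][0]
_ALLOWED_ELEMENTS = ("C", "H", "N", "O", "S", "Na", "K", "Au")
_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def fragment_mz(formula: str, charge: int = 1) -> float:
    """Monoisotopic m/z of a singly charged secondary-ion fragment.

    The formula lists the atoms of the cation itself (e.g. ``"C2H5O"`` for
    C2H5O+, ``"Au"`` for Au+); the mass of ``charge`` electrons is subtracted
    from the neutral monoisotopic mass. Allowed elements are C, H, N, O, S,
    Na, K, Au — the constituents of glycan/DAP, OEG-thiol SAM, buffer salt
    and gold-substrate fragments seen in positive-ion spectra of these
    surfaces.

    Parameters
    ----------
    formula:
        Elemental formula such as ``"AuC2H4"``. Element symbols with
        optional integer counts; no parentheses or isotope labels.
    charge:
        Only +1 is supported (positive-ion mode, singly charged).
    """
    if not formula:
        raise ValueError("empty formula")
    if charge != 1:
        raise ValueError("only charge +1 is supported")
    pos = 0
    total = 0.0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        el, count = m.group(1), int(m.group(2) or 1)
        if el not in _ALLOWED_ELEMENTS:
            raise ValueError(f"unknown element symbol {el!r} in {formula!r}")
        total += count * _ptmass.nist_mass[el][0][0]
        pos = m.end()
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return (total - charge * _ELECTRON_DA) / charge


# Fragment assignments commonly observed on DAP-glycan spots printed onto
# NHS-activated OEG disulfide SAMs on gold (positive ions, m/z 1-350):
# glycan/DAP-related amines and oxocarbenium fragments, OEG/SAM ether and
# thiol fragments, gold and gold-thiolate cluster ions, plus hydrocarbon and
# buffer-salt contaminants.
_REFERENCE_ASSIGNMENTS: tuple[tuple[str, str], ...] = (
    ("CH3", "Hydrocarbon"),
    ("NH4", "GDAP"),
    ("Na", "Salt"),
    ("C2H3", "Hydrocarbon"),
    ("C2H4", "Hydrocarbon"),
    ("CHO", "OEG/SAM"),
    ("C2H5", "Hydrocarbon"),
    ("CH4N", "GDAP"),
    ("K", "Salt"),
    ("C3H5", "Hydrocarbon"),
    ("C2H3O", "OEG/SAM"),
    ("C2H6N", "GDAP"),
    ("CHS", "OEG/SAM"),
    ("C2H5O", "OEG/SAM"),
    ("C3H3O", "OEG/SAM"),
    ("C3H4O", "OEG/SAM"),
    ("C3H6N", "GDAP"),
    ("C2H3S", "OEG/SAM"),
    ("C3H7O", "GDAP"),
    ("C2H6NO", "GDAP"),
    ("C2H5S", "OEG/SAM"),
    ("C3H5N2", "GDAP"),
    ("C4H8N", "GDAP"),
    ("C4H10N", "GDAP"),
    ("C3H7O2", "OEG/SAM"),
    ("C4H6NO", "GDAP"),
    ("C5H10N", "GDAP"),
    ("C5H7O2", "OEG/SAM"),
    ("C6H10N2", "GDAP"),
    ("C5H8O3", "OEG/SAM"),
    ("Au", "Gold"),
    ("AuC2H4", "Gold"),
    ("AuC2H4S", "Gold"),
)


@dataclass
class PeakTable:
    """Table of m/z channels with fragment formula and source category.

    Thin wrapper over a pandas DataFrame with columns ``mz`` (Da),
    ``formula`` (elemental formula or empty string) and ``category``
    (one of :data:`CATEGORIES`).
    """

    df: pd.DataFrame
    mz_tol: float = MZ_MATCH_TOL

    def __post_init__(self) -> None:
        required = {"mz", "formula", "category"}
        if not required.issubset(self.df.columns):
            raise ValueError(f"PeakTable needs columns {sorted(required)}")
        self.df = self.df.reset_index(drop=True)
        mz = self.df["mz"].to_numpy(dtype=float)
        if np.any(mz <= 0) or np.any(mz > MZ_WINDOW[1]):
            raise ValueError(f"mz values must lie in (0, {MZ_WINDOW[1]}]")
        bad = set(self.df["category"]) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown categories {sorted(bad)}")
        order = np.sort(mz)
        if len(order) > 1 and np.min(np.diff(order)) <= self.mz_tol:
            raise ValueError("duplicate mz within matching tolerance")

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[float, str, str]], **kw
    ) -> "PeakTable":
        df = pd.DataFrame(records, columns=["mz", "formula", "category"])
        return cls(df, **kw)

    @classmethod
    def from_csv(cls, path: str | Path, **kw) -> "PeakTable":
        df = pd.read_csv(path, dtype={"formula": str}).fillna({"formula": ""})
        return cls(df[["mz", "formula", "category"]], **kw)

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def mz(self) -> np.ndarray:
        return self.df["mz"].to_numpy(dtype=float)

    @property
    def categories(self) -> np.ndarray:
        return self.df["category"].to_numpy()

    def subset(self, *categories: str) -> "PeakTable":
        keep = self.df["category"].isin(categories)
        return PeakTable(self.df[keep], mz_tol=self.mz_tol)

    def drop(self, *categories: str) -> "PeakTable":
        keep = ~self.df["category"].isin(categories)
        return PeakTable(self.df[keep], mz_tol=self.mz_tol)


def reference_peak_table() -> PeakTable:
    """Reference fragment assignment table with computed monoisotopic m/z."""
    records = [
        (fragment_mz(f), f, cat) for f, cat in _REFERENCE_ASSIGNMENTS
    ]
    records.sort()
    return PeakTable.from_records(records)


@dataclass
class SimsCube:
    """Per-pixel peak-channel count cube (rows x cols x channels)."""

    counts: np.ndarray
    channel_mz: np.ndarray
    pixel_um: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.channel_mz = np.asarray(self.channel_mz, dtype=float)
        if self.counts.ndim != 3:
            raise ValueError("counts must be rows x cols x channels")
        rows, cols, nch = self.counts.shape
        if rows < 1 or cols < 1:
            raise ValueError("cube needs at least one pixel")
        if nch != len(self.channel_mz):
            raise ValueError("channel_mz length must equal channel count")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(self.channel_mz) > 1 and np.any(np.diff(self.channel_mz) <= 0):
            raise ValueError("channel_mz must be strictly increasing")
        if self.pixel_um <= 0:
            raise ValueError("pixel_um must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts.shape

    @property
    def field_um(self) -> tuple[float, float]:
        """(width, height) of the imaged field in micrometers."""
        rows, cols, _ = self.counts.shape
        return (cols * self.pixel_um, rows * self.pixel_um)


@dataclass(frozen=True)
class RoiSpec:
    """Axis-aligned rectangular region of interest, in micrometers.

    (x_um, y_um) is the top-left corner; the rectangle is half-open:
    a pixel belongs to the ROI iff its center lies in
    [x_um, x_um+width_um) x [y_um, y_um+height_um).
    """

    x_um: float
    y_um: float
    width_um: float
    height_um: float

    def __post_init__(self) -> None:
        if self.width_um <= 0 or self.height_um <= 0:
            raise ValueError("ROI extent must be strictly positive")


def roi_pixel_slices(
    roi: RoiSpec,
    shape: tuple[int, int],
    pixel_um: float,
    origin: tuple[float, float] = (0.0, 0.0),
) -> tuple[slice, slice]:
    """(row, col) slices of the pixels whose centers fall inside `roi`.

    Raises if the ROI extends beyond the field or covers no pixel centers.
    """
    rows, cols = shape
    ox, oy = origin
    if (
        roi.x_um < ox
        or roi.y_um < oy
        or roi.x_um + roi.width_um > ox + cols * pixel_um + 1e-9
        or roi.y_um + roi.height_um > oy + rows * pixel_um + 1e-9
    ):
        raise ValueError("ROI outside field")
    xc = ox + (np.arange(cols) + 0.5) * pixel_um
    yc = oy + (np.arange(rows) + 0.5) * pixel_um
    cs = np.nonzero((xc >= roi.x_um) & (xc < roi.x_um + roi.width_um))[0]
    rs = np.nonzero((yc >= roi.y_um) & (yc < roi.y_um + roi.height_um))[0]
    if len(cs) == 0 or len(rs) == 0:
        raise ValueError("ROI covers no pixel centers")
    return slice(rs[0], rs[-1] + 1), slice(cs[0], cs[-1] + 1)


@dataclass
class SpectrumMatrix:
    """n_spectra x n_peaks matrix of ROI-averaged spectra."""

    values: np.ndarray
    labels: list[str]
    peak_mz: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.peak_mz = np.asarray(self.peak_mz, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[0] != len(self.labels):
            raise ValueError("one label per spectrum required")
        if self.values.shape[1] != len(self.peak_mz):
            raise ValueError("column count must equal peak count")


# ---------------------------------------------------------------------------
# imzML I/O


def write_cube(cube: SimsCube, path: str | Path) -> None:
    """Write a cube as continuous-mode imzML (plus the paired .ibd file).

    Pixel size is stored as the IMS pixel-size cvParams in scanSettings so
    that the file round-trips through :func:`read_cube` bit-exactly.
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    path = str(path)
    rows, cols, _ = cube.counts.shape
    with ImzMLWriter(path, mode="continuous", polarity="positive") as w:
        for r in range(rows):
            for c in range(cols):
                w.addSpectrum(
                    cube.channel_mz,
                    cube.counts[r, c, :].astype(np.float32),
                    (c + 1, r + 1, 1),
                )
    _inject_pixel_size(path, cube.pixel_um)


def _inject_pixel_size(path: str, pixel_um: float) -> None:
    # pyimzml's writer has no pixel-size argument; add the IMS cvParams that
    # its parser reads back into imzmldict["pixel size x"/"pixel size y"].
    from lxml import etree

    ns = "http://psi.hupo.org/ms/mzml"
    tree = etree.parse(path)
    ss = tree.find(f".//{{{ns}}}scanSettingsList/{{{ns}}}scanSettings")
    if ss is None:
        raise ValueError("imzML file lacks a scanSettings element")
    for acc, name in (("IMS:1000046", "pixel size (x)"), ("IMS:1000047", "pixel size y")):
        etree.SubElement(
            ss,
            f"{{{ns}}}cvParam",
            cvRef="IMS",
            accession=acc,
            name=name,
            value=repr(float(pixel_um)),
            unitCvRef="UO",
            unitAccession="UO:0000017",
            unitName="micrometer",
        )
    tree.write(path, xml_declaration=True, encoding="ISO-8859-1")


def read_cube(path: str | Path) -> SimsCube:
    """Read a continuous-mode imzML cube written by :func:`write_cube`.

    Requires a uniform m/z axis shared by all spectra (continuous mode) and
    pixel-size metadata; intensities are rounded back to integer counts.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    p = ImzMLParser(str(path))
    try:
        px = float(p.imzmldict["pixel size x"])
        py = float(p.imzmldict["pixel size y"])
    except KeyError as exc:
        raise ValueError("missing pixel-size metadata") from exc
    if not np.isclose(px, py):
        raise ValueError("anisotropic pixels are not supported")
    coords = np.asarray(p.coordinates)
    cols = int(coords[:, 0].max())
    rows = int(coords[:, 1].max())
    mz0, _ = p.getspectrum(0)
    counts = np.zeros((rows, cols, len(mz0)), dtype=np.int64)
    for i, (x, y, _z) in enumerate(p.coordinates):
        mz, inten = p.getspectrum(i)
        if len(mz) != len(mz0) or not np.array_equal(mz, mz0):
            raise ValueError("continuous mode required (uniform m/z axis)")
        counts[y - 1, x - 1, :] = np.rint(inten).astype(np.int64)
    return SimsCube(counts=counts, channel_mz=mz0, pixel_um=px)


# ---------------------------------------------------------------------------
# Spectral operations


def total_ion_image(cube: SimsCube) -> np.ndarray:
    """Per-pixel sum of counts over all channels."""
    return cube.counts.sum(axis=2)


def match_channel_index(
    channel_mz: np.ndarray, mz: float, tol: float = MZ_MATCH_TOL
) -> int:
    """Index of the cube channel closest to `mz`, within `tol` Da."""
    channel_mz = np.asarray(channel_mz, dtype=float)
    i = int(np.argmin(np.abs(channel_mz - mz)))
    if abs(channel_mz[i] - mz) > tol:
        raise ValueError(f"no channel within {tol} Da of m/z {mz}")
    return i


def pick_peaks(
    cube: SimsCube,
    background: np.ndarray | float,
    k: float = 3.0,
) -> PeakTable:
    """Select channels whose total intensity is >= k x background.

    `background` is the per-channel noise level on the summed-spectrum scale
    (scalar or length-n_channels array); the comparison is inclusive and
    restricted to the m/z 1-350 analysis window. Selected channels come back
    as an Unassigned :class:`PeakTable` (use :func:`assign_categories` with a
    reference table to label them).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    background = np.broadcast_to(
        np.asarray(background, dtype=float), (cube.shape[2],)
    )
    if np.any(background < 0):
        raise ValueError("background must be non-negative")
    summed = cube.counts.sum(axis=(0, 1)).astype(float)
    in_window = (cube.channel_mz >= MZ_WINDOW[0]) & (cube.channel_mz <= MZ_WINDOW[1])
    selected = (summed >= k * background) & in_window
    records = [(mz, "", "Unassigned") for mz in cube.channel_mz[selected]]
    return PeakTable.from_records(records)


def background_from_roi(cube: SimsCube, roi: RoiSpec) -> np.ndarray:
    """Per-channel background from a designated blank region.

    Median per-pixel count over the ROI, scaled to the summed-spectrum scale
    (x total pixel count) so it is directly comparable in :func:`pick_peaks`.
    """
    rs, cs = roi_pixel_slices(roi, cube.shape[:2], cube.pixel_um, cube.origin)
    med = np.median(
        cube.counts[rs, cs, :].reshape(-1, cube.shape[2]).astype(float), axis=0
    )
    rows, cols, _ = cube.shape
    return med * rows * cols


def noise_floor_background(cube: SimsCube) -> np.ndarray:
    """Per-channel noise floor estimated as the median channel total.

    Appropriate when most channels of the acquisition window carry no
    surface species (the usual case for a sparse peak list over a wide m/z
    window): the median of the per-channel summed intensities is then the
    counting-noise floor. Returned as a constant vector.
    """
    summed = cube.counts.sum(axis=(0, 1)).astype(float)
    return np.full(cube.shape[2], float(np.median(summed)))


def assign_categories(
    picked: PeakTable, reference: PeakTable, tol: float = MZ_MATCH_TOL
) -> PeakTable:
    """Label picked peaks with formula/category from a reference table.

    Peaks with no reference entry within `tol` Da stay Unassigned.
    """
    df = picked.df.copy()
    ref_mz = reference.mz
    for i, mz in enumerate(df["mz"]):
        j = int(np.argmin(np.abs(ref_mz - mz)))
        if abs(ref_mz[j] - mz) <= tol:
            df.loc[i, "formula"] = reference.df["formula"].iloc[j]
            df.loc[i, "category"] = reference.df["category"].iloc[j]
    return PeakTable(df, mz_tol=picked.mz_tol)


def extract_roi_spectrum(
    cube: SimsCube, roi: RoiSpec, peaks: PeakTable
) -> np.ndarray:
    """Mean count per selected peak over the pixels inside `roi`."""
    if len(peaks) == 0:
        raise ValueError("peaks must be non-empty")
    rs, cs = roi_pixel_slices(roi, cube.shape[:2], cube.pixel_um, cube.origin)
    block = cube.counts[rs, cs, :].reshape(-1, cube.shape[2]).astype(float)
    idx = [match_channel_index(cube.channel_mz, mz, peaks.mz_tol) for mz in peaks.mz]
    return block.mean(axis=0)[idx]


def spectrum_matrix(
    cubes: Sequence[SimsCube],
    rois: Mapping[str, RoiSpec],
    peaks: PeakTable,
) -> SpectrumMatrix:
    """Stack ROI spectra from several cubes into an n_spectra x n_peaks matrix.

    Row labels are ``"img{i}:{roi_name}"``, one row per (cube, ROI) pair.
    """
    values, labels = [], []
    for i, cube in enumerate(cubes):
        for name, roi in rois.items():
            values.append(extract_roi_spectrum(cube, roi, peaks))
            labels.append(f"img{i}:{name}")
    return SpectrumMatrix(np.asarray(values), labels, peaks.mz)


def normalize_spectra(
    matrix: SpectrumMatrix,
) -> tuple[SpectrumMatrix, SpectrumMatrix]:
    """Total-ion normalization followed by column mean-centering.

    Each row is divided by its total over the selected peaks (rows of the
    first returned matrix sum to 1), then each column is mean-centered across
    rows (second returned matrix, the input to PCA). Normalizing before
    centering makes the PCA act on composition rather than absolute yield.
    """
    totals = matrix.values.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("empty spectrum in ROI")
    normalized = matrix.values / totals[:, None]
    centered = normalized - normalized.mean(axis=0, keepdims=True)
    return (
        SpectrumMatrix(normalized, list(matrix.labels), matrix.peak_mz),
        SpectrumMatrix(centered, list(matrix.labels), matrix.peak_mz),
    )


@dataclass(frozen=True)
class DoseReport:
    """Primary-ion dose and whether it stays below the static-SIMS limit."""

    dose_per_cm2: float
    below_static_limit: bool


def ion_dose(current_pA: float, time_s: float, area_cm2: float) -> DoseReport:
    """Primary-ion dose (ions/cm^2) for a continuous beam over an area.

    dose = (current x time / elementary charge) / area. The report flags
    whether the dose stays below the static-SIMS limit of 1e12 ions/cm^2,
    under which each primary ion impact samples undamaged surface.
    """
    if current_pA < 0 or time_s < 0:
        raise ValueError("current and time must be non-negative")
    if area_cm2 <= 0:
        raise ValueError("area must be positive")
    n_ions = current_pA * 1e-12 * time_s / elementary_charge
    dose = n_ions / area_cm2
    return DoseReport(dose_per_cm2=dose, below_static_limit=dose < STATIC_SIMS_LIMIT)
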