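"""Co-registered synthetic ToF-SIMS cubes and SPRi stacks with known ground truth.

The generator emulates a single printed glycan-microarray element: a square
field (default 500 um at 3.9 um/pixel, i.e. a 128 x 128 grid) containing a
printed spot 150-250 um in diameter with the two artifacts characteristic of
contact printing — a rim-enriched "coffee stain" ring and a wash-direction
"tail". A shared relative glycan-density map drives both modalities:

* the SIMS simulator draws per-pixel, per-channel Poisson counts whose means
  are a uniform noise floor plus a category yield — glycan (GDAP) channels
  scale with density, OEG/SAM and gold channels with (1 - density) because
  immobilized glycan masks the monolayer, and hydrocarbon/salt contaminant
  channels are density-independent;
* the SPRi simulator evaluates a 1:1 Langmuir binding response proportional
  to local density, with additive Gaussian read noise per frame.

The wash tail is visible to SIMS but, by default, not to the protein-binding
readout, so the two modalities agree on the spot but differ on the artifact —
the situation the correlation stage is meant to quantify.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .sims_cube import (
    CATEGORIES,
    MZ_MATCH_TOL,
    PeakTable,
    SimsCube,
    reference_peak_table,
)
from .spri import KineticParams, SpriStack, langmuir_response

__all__ = [
    "GroundTruth",
    "KineticParams",
    "DEFAULT_CATEGORY_YIELDS",
    "make_ground_truth",
    "simulate_sims_cube",
    "simulate_spri_stack",
]

#: Mean secondary-ion yield (counts/pixel at unit weight) per category.
#: Glycan yields exceed the masked monolayer+gold loss (12*80*d > 530*d) so
#: the printed spot is brighter than background in the total-ion image.
DEFAULT_CATEGORY_YIELDS: dict[str, float] = {
    "GDAP": 80.0,
    "OEG/SAM": 40.0,
    "Gold": 30.0,
    "Hydrocarbon": 10.0,
    "Salt": 15.0,
    "Unassigned": 0.0,
}

# RNG stream keys so either simulator reproduces alone for a given seed.
_SIMS_STREAM = 0
_SPRI_STREAM = 1


@dataclass
class GroundTruth:
    """Shared ground truth for the SIMS and SPRi simulators.

    `density_map` is the relative glycan surface density in [0, 1] seen by
    SIMS (spot + ring + tail); `binding_map` is the density bioavailable to
    protein binding (spot + ring, no wash tail). Both are zero outside the
    printed features.
    """

    field_um: float
    pixel_um: float
    spot_center_um: tuple[float, float]
    spot_diameter_um: float
    ring_fraction: float
    ring_width_fraction: float
    tail_vector_um: tuple[float, float]
    tail_amplitude: float
    noise_floor: float
    category_yields: dict[str, float]
    peaks: PeakTable
    kinetics: KineticParams
    seed: int
    n_noise_channels: int
    density_map: np.ndarray = field(repr=False)
    binding_map: np.ndarray = field(repr=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.density_map.shape

    @property
    def spot_mask(self) -> np.ndarray:
        """Pixels whose centers lie within the printed spot disk (ring included)."""
        dist = _center_distances(self.shape, self.pixel_um, self.spot_center_um)
        if self.spot_diameter_um <= 0:
            return np.zeros(self.shape, dtype=bool)
        return dist <= self.spot_diameter_um / 2

    @property
    def category_signatures(self) -> dict[str, list[tuple[float, float]]]:
        """category -> [(m/z channel, mean yield per unit weight), ...]."""
        out: dict[str, list[tuple[float, float]]] = {}
        for mz, cat in zip(self.peaks.mz, self.peaks.categories):
            out.setdefault(cat, []).append((float(mz), self.category_yields[cat]))
        return out

    def config(self) -> dict:
        return {
            "field_um": self.field_um,
            "pixel_um": self.pixel_um,
            "spot_center_um": list(self.spot_center_um),
            "spot_diameter_um": self.spot_diameter_um,
            "ring_fraction": self.ring_fraction,
            "ring_width_fraction": self.ring_width_fraction,
            "tail_vector_um": list(self.tail_vector_um),
            "tail_amplitude": self.tail_amplitude,
            "noise_floor": self.noise_floor,
            "category_yields": self.category_yields,
            "kinetics": {
                "k_on": self.kinetics.k_on,
                "k_off": self.kinetics.k_off,
                "r_max": self.kinetics.r_max,
                "concentration": self.kinetics.concentration,
                "t_assoc_end": self.kinetics.t_assoc_end,
            },
            "n_noise_channels": self.n_noise_channels,
            "seed": self.seed,
        }

    def to_json(self, path: str | Path) -> None:
        """Persist the generator configuration (maps are rebuilt on load)."""
        Path(path).write_text(json.dumps(self.config(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        cfg = json.loads(Path(path).read_text())
        cfg["spot_center_um"] = tuple(cfg["spot_center_um"])
        cfg["tail_vector_um"] = tuple(cfg["tail_vector_um"])
        cfg["kinetics"] = KineticParams(**cfg["kinetics"])
        return make_ground_truth(**cfg)


def _center_distances(
    shape: tuple[int, int], pixel_um: float, center_um: tuple[float, float]
) -> np.ndarray:
    rows, cols = shape
    xc = (np.arange(cols) + 0.5) * pixel_um
    yc = (np.arange(rows) + 0.5) * pixel_um
    dx = xc[None, :] - center_um[0]
    dy = yc[:, None] - center_um[1]
    return np.hypot(dx, dy)


def _noise_channel_mz(planted_mz: np.ndarray, n: int) -> np.ndarray:
    """Deterministic grid of unassigned noise-floor channels avoiding planted peaks."""
    grid = np.linspace(2.0, 349.0, n)
    out = []
    for mz in grid:
        while np.any(np.abs(planted_mz - mz) <= 2 * MZ_MATCH_TOL) or any(
            abs(mz - o) <= 2 * MZ_MATCH_TOL for o in out[-2:]
        ):
            mz += 0.05
        out.append(mz)
    return np.asarray(out)


def make_ground_truth(
    field_um: float = 500.0,
    pixel_um: float = 3.9,
    spot_center_um: tuple[float, float] | None = None,
    spot_diameter_um: float = 200.0,
    ring_fraction: float = 0.5,
    ring_width_fraction: float = 0.1,
    tail_vector_um: tuple[float, float] = (60.0, 0.0),
    tail_amplitude: float = 0.3,
    noise_floor: float = 0.2,
    category_yields: Mapping[str, float] | None = None,
    peaks: PeakTable | None = None,
    kinetics: KineticParams | None = None,
    n_noise_channels: int = 300,
    seed: int = 0,
) -> GroundTruth:
    """Build the deterministic ground truth shared by both simulators.

    The density map is a unit disk of diameter `spot_diameter_um`, boosted by
    a factor (1 + ring_fraction) on a rim annulus of width
    ring_width_fraction x diameter ("coffee stain"), with an exponentially
    decaying half-strip tail of width = diameter in the direction of
    `tail_vector_um` (whose norm sets the decay length) at relative amplitude
    `tail_amplitude`. The composed map is rescaled to max 1, so with a ring
    the rim sits at density 1 and the interior at 1/(1 + ring_fraction).

    No randomness is consumed here; `seed` only labels the object so the
    simulators derive their streams from it.
    """
    if field_um <= 0 or pixel_um <= 0 or pixel_um > field_um:
        raise ValueError("field and pixel sizes must satisfy 0 < pixel_um <= field_um")
    if spot_diameter_um < 0 or ring_fraction < 0 or tail_amplitude < 0:
        raise ValueError("spot_diameter_um, ring_fraction, tail_amplitude must be >= 0")
    if not 0 < ring_width_fraction < 1:
        raise ValueError("ring_width_fraction must be in (0, 1)")
    if noise_floor < 0:
        raise ValueError("noise_floor must be non-negative")
    if spot_center_um is None:
        spot_center_um = (field_um / 2, field_um / 2)
    r = spot_diameter_um / 2
    cx, cy = spot_center_um
    if cx - r < 0 or cy - r < 0 or cx + r > field_um or cy + r > field_um:
        raise ValueError("spot outside field")

    n = int(np.floor(field_um / pixel_um))
    shape = (n, n)
    dist = _center_distances(shape, pixel_um, spot_center_um)

    density = np.zeros(shape)
    if spot_diameter_um > 0:
        disk = dist <= r
        density[disk] = 1.0
        rim = disk & (dist > r * (1.0 - ring_width_fraction))
        density[rim] *= 1.0 + ring_fraction

    tail = np.zeros(shape)
    tv = np.asarray(tail_vector_um, dtype=float)
    decay_um = float(np.hypot(*tv))
    if spot_diameter_um > 0 and decay_um > 0 and tail_amplitude > 0:
        u = tv / decay_um
        xc = (np.arange(n) + 0.5) * pixel_um
        yc = (np.arange(n) + 0.5) * pixel_um
        px = xc[None, :] - cx
        py = yc[:, None] - cy
        s = px * u[0] + py * u[1]
        perp = np.abs(px * (-u[1]) + py * u[0])
        strip = (s > r) & (perp <= r)
        tail[strip] = (
            tail_amplitude * (1.0 + ring_fraction) * np.exp(-(s[strip] - r) / decay_um)
        )

    binding = density.copy()
    density = np.maximum(density, tail)
    peak_max = density.max()
    if peak_max > 0:
        density = density / peak_max
        binding = binding / peak_max

    yields = dict(DEFAULT_CATEGORY_YIELDS)
    if category_yields:
        unknown = set(category_yields) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories {sorted(unknown)}")
        yields.update(category_yields)

    if peaks is None:
        ref = reference_peak_table()
        noise_mz = _noise_channel_mz(ref.mz, n_noise_channels)
        records = [
            (mz, f, c)
            for mz, f, c in zip(ref.mz, ref.df["formula"], ref.categories)
        ] + [(mz, "", "Unassigned") for mz in noise_mz]
        records.sort(key=lambda rec: rec[0])
        peaks = PeakTable.from_records(records)

    return GroundTruth(
        field_um=field_um,
        pixel_um=pixel_um,
        spot_center_um=spot_center_um,
        spot_diameter_um=spot_diameter_um,
        ring_fraction=ring_fraction,
        ring_width_fraction=ring_width_fraction,
        tail_vector_um=tuple(tail_vector_um),
        tail_amplitude=tail_amplitude,
        noise_floor=noise_floor,
        category_yields=yields,
        peaks=peaks,
        kinetics=kinetics or KineticParams(),
        seed=seed,
        n_noise_channels=n_noise_channels,
        density_map=density,
        binding_map=binding,
    )


def _category_weight(category: str, density: np.ndarray) -> np.ndarray | float:
    if category == "GDAP":
        return density
    if category in ("OEG/SAM", "Gold"):
        return 1.0 - density
    if category in ("Hydrocarbon", "Salt"):
        return 1.0
    if category == "Unassigned":
        return 0.0
    raise ValueError(f"unknown category label {category!r}")


def simulate_sims_cube(
    gt: GroundTruth,
    peaks: PeakTable | None = None,
    noise_scale: float = 1.0,
    seed: int = 0,
) -> SimsCube:
    """Draw a Poisson count cube from the ground truth.

    Per-pixel counts are independent Poisson draws per channel with mean
    noise_scale * noise_floor + yield * weight(category), where the weight is
    the density map for glycan channels, (1 - density) for OEG/SAM and gold
    (glycan masks the monolayer), 1 for contaminants and 0 for unassigned
    noise channels. Identical seeds give bit-identical cubes.
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be non-negative")
    if peaks is None:
        peaks = gt.peaks
    gt_mz = gt.peaks.mz
    gt_cat = gt.peaks.categories
    order = np.argsort(peaks.mz)
    mz_sorted = peaks.mz[order]

    density = gt.density_map
    floor = noise_scale * gt.noise_floor
    mean = np.empty(gt.shape + (len(mz_sorted),))
    for j, mz in enumerate(mz_sorted):
        i = int(np.argmin(np.abs(gt_mz - mz)))
        if abs(gt_mz[i] - mz) > peaks.mz_tol:
            raise ValueError(f"peak m/z {mz} has no category signature")
        cat = gt_cat[i]
        mean[:, :, j] = floor + gt.category_yields[cat] * _category_weight(cat, density)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _SIMS_STREAM]))
    counts = rng.poisson(mean)
    return SimsCube(counts=counts, channel_mz=mz_sorted, pixel_um=gt.pixel_um)


def simulate_spri_stack(
    gt: GroundTruth,
    times: Sequence[float] | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
    include_tail: bool = False,
) -> SpriStack:
    """Simulate the protein-binding image stack over the same pixel grid.

    Each pixel follows the 1:1 Langmuir response scaled by its bioavailable
    density (the wash tail is excluded unless `include_tail`), with additive
    Gaussian read noise of sd `noise_sd` per frame. Default times cover a
    12 min association plus 18 min dissociation at 2 s per frame.
    """
    if times is None:
        times = np.arange(0.0, 1801.0, 2.0)
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("empty times")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    density = gt.density_map if include_tail else gt.binding_map
    base = langmuir_response(gt.kinetics, times)
    frames = base[:, None, None] * density[None, :, :]
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), _SPRI_STREAM]))
        frames = frames + rng.normal(0.0, noise_sd, size=frames.shape)
    return SpriStack(frames=frames, t_seconds=times, pixel_um=gt.pixel_um)
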