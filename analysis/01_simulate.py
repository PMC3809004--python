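#!/usr/bin/env python
"""Simulate one printed glycan-array element in both modalities.

Builds the default ground truth (500 um field, 3.9 um pixels, 200 um spot
with coffee-stain ring and wash tail), draws the ToF-SIMS Poisson count cube
and the SPRi Langmuir binding stack from it, and writes the instrument-format
artifacts (imzML cube, multi-page TIFF stack) under scratch/ with the small
text summaries under results/.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from glycoarray import sims_cube as sc
from glycoarray import spri
from glycoarray import synthetic_data as sd


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--scratch", type=Path, default=Path("scratch"))
    args = ap.parse_args()
    args.results.mkdir(parents=True, exist_ok=True)
    args.scratch.mkdir(parents=True, exist_ok=True)

    gt = sd.make_ground_truth(seed=args.seed)
    gt.to_json(args.results / "ground_truth.json")

    cube = sd.simulate_sims_cube(gt, seed=args.seed)
    sc.write_cube(cube, args.scratch / "sims_cube.imzML")

    stack = sd.simulate_spri_stack(
        gt, times=np.arange(0.0, 1801.0, 2.0), noise_sd=1.0, seed=args.seed
    )
    spri.write_stack(
        stack, args.scratch / "spri_stack.tiff", args.scratch / "spri_times.csv"
    )

    summary = {
        "grid": list(gt.shape),
        "n_spectra": int(np.prod(gt.shape)),
        "n_channels": int(cube.shape[2]),
        "spot_pixels": int(gt.spot_mask.sum()),
        "tail_pixels": int(((gt.density_map > 0) & ~gt.spot_mask).sum()),
        "total_counts": int(cube.counts.sum()),
        "n_frames": int(stack.frames.shape[0]),
    }
    (args.results / "simulation_summary.json").write_text(json.dumps(summary, indent=2))
    print(
        f"simulated {summary['grid'][0]}x{summary['grid'][1]} field "
        f"({summary['n_spectra']} spectra, {summary['n_channels']} channels), "
        f"spot covers {summary['spot_pixels']} px + {summary['tail_pixels']} tail px; "
        f"{summary['n_frames']}-frame SPRi stack"
    )


if __name__ == "__main__":
    main()
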