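#!/usr/bin/env python
"""Run the DEM -> inundation-score pipeline on a synthetic valley.

Builds a 100x60-cell (5 m) concave footslope with a 30-cell-wide
parabolic channel, runs the full scoring pipeline, and samples
axis/flank observation points.  Expected outcome: channel-axis cells
carry the largest scores, flank cells near zero.

Writes results/synthetic_valley_sites.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from inunscore.score import score_dem, extract_sites
from inunscore.simulate import DemSimConfig, simulate_dem

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = DemSimConfig(rows=100, cols=60, cell_size=5.0, base_slope=0.002,
                       profile_curvature=2e-5, channel_depth=1.5,
                       channel_width=30, noise_sd=0.02, seed=1)
    surfaces = score_dem(simulate_dem(cfg))
    axis = (cfg.cols - 1) // 2
    points = [(r, c, f"{tag}_{r}") for r in (30, 50, 70)
              for tag, c in (("axis", axis), ("west_flank", 8), ("east_flank", cfg.cols - 9))]
    records = extract_sites(surfaces, points)
    df = pd.DataFrame([vars(r) for r in records])
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "synthetic_valley_sites.csv", index=False)

    axis_mean = df[df.site_name.str.startswith("axis")].inundation_score.mean()
    flank_mean = df[df.site_name.str.contains("flank")].inundation_score.mean()
    print(f"axis mean score  = {axis_mean:.4f}")
    print(f"flank mean score = {flank_mean:.2e}")
    print("channel cells dominate, as the composite intends"
          if axis_mean > flank_mean else "WARNING: flanks out-score the channel")
    v = surfaces.score.values
    print(f"max score column = {int(np.nanargmax(np.nanmean(v[20:-20, 1:-1], axis=0))) + 1}"
          f" (channel axis at {axis})")


if __name__ == "__main__":
    main()
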