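#!/usr/bin/env python
"""PCA of the standardized site-level terrain and water variables.

Standardizes water accumulation, the two convexities, submergence
duration, cumulative water depth and 0-20 cm sand/silt/clay over the
seven sites and extracts principal components.  PC1 separates the two
soil groups (Cambisols high, Lixisols/Luvisols low), as in the study
design; exact loadings are not comparable to the published table
because the per-year precipitation inputs are unpublished.

Writes results/pca_sites.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from inunscore import data
from inunscore.report import _topsoil_texture
from inunscore.stats import pca_standardized

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    sites = data.load_site_terrain()
    trials = {t.site_name: t for t in data.load_field_trials()}
    topsoil = _topsoil_texture(data.load_soil_horizons())
    names = ["water_accumulation", "longitudinal_convexity", "cross_sectional_convexity",
             "submergence_days", "cumulative_water_depth", "sand", "silt", "clay"]
    X = np.array([[s.water_accumulation, s.longitudinal_convexity,
                   s.cross_sectional_convexity, trials[s.site_name].submergence_days,
                   trials[s.site_name].cumulative_water_depth,
                   topsoil[s.site_name]["sand"], topsoil[s.site_name]["silt"],
                   topsoil[s.site_name]["clay"]] for s in sites])
    fit = pca_standardized(X, variables=names)
    RESULTS.mkdir(exist_ok=True)
    load = pd.DataFrame(fit.loadings, index=names,
                        columns=[f"PC{i+1}" for i in range(fit.loadings.shape[1])])
    load.to_csv(RESULTS / "pca_sites.csv")
    print("variance proportions:", np.round(fit.proportion, 2))
    print("cumulative:          ", np.round(fit.cumulative, 2))
    print(load.round(2).to_string())

    scores = (X - X.mean(0)) / X.std(0, ddof=1) @ fit.loadings
    pc1 = {s.site_name: scores[i, 0] for i, s in enumerate(sites)}
    camb = [v for s, v in pc1.items() if trials[s].soil_group == "Cambisols"]
    lixi = [v for s, v in pc1.items() if trials[s].soil_group != "Cambisols"]
    print(f"\nPC1 separates soil groups: Cambisols mean {np.mean(camb):+.2f}, "
          f"Lixisols/Luvisols mean {np.mean(lixi):+.2f}")


if __name__ == "__main__":
    main()
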