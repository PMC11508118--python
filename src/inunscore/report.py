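"""End-to-end analysis report over the packaged (or user) tables.

:func:`run_full_analysis` recomputes every table-level statistic of the
study from the site-terrain, field-trial and soil-horizon tables:
per-site composite scores, soil-group means, the four score→yield
regressions, the score→water-condition regressions with and without the
configured site exclusion, the relative-yield (PR/TSP) regression, the
texture-vs-chemistry Spearman matrix, the BS/EBS recomputation check
and a PCA summary of the standardized site variables.  The result is a
plain nested dict, deterministic for identical inputs, serialized by
the CLI as JSON.
"""

from __future__ import annotations

from importlib.metadata import version as _pkg_version

import numpy as np

from . import data as data_mod
from .score import ScorePipelineConfig, compose_score, group_mean_scores
from .stats import (
    base_saturation,
    effective_base_saturation,
    correlation_matrix,
    ols_fit,
    pca_standardized,
    relative_yield,
    yield_increase,
)
from .util import round_half_up

TEXTURE_VARS = ["sand", "silt", "clay"]
CHEMISTRY_VARS = ["total_c", "total_n", "ph_h2o", "ph_kcl", "ec", "bray1_p", "bray2_p",
                  "exch_al", "exch_na", "exch_k", "exch_ca", "exch_mg", "cec", "bs", "ebs"]


def _fit_dict(fit) -> dict:
    return {
        "slope": fit.slope,
        "intercept": fit.intercept,
        "r2": fit.r2,
        "r2_adj": fit.r2_adj,
        "p_value": fit.p_value,
        "n": fit.n,
    }


def run_full_analysis(
    sites=None,
    trials=None,
    horizons=None,
    exclude_sites: tuple[str, ...] = ("Nandiala",),
    score_config: ScorePipelineConfig | None = None,
    seed: int | None = None,
) -> dict:
    """Assemble the full report (see module docstring).

    ``exclude_sites`` applies only to the water-condition regressions
    (submergence duration, cumulative water depth), mirroring the
    analysis decision to drop the one site whose submergence is
    dominated by groundwater and a road embankment rather than
    terrain; the exclusion is recorded in the report.
    """
    config = score_config or ScorePipelineConfig()
    sites = data_mod.load_site_terrain() if sites is None else sites
    trials = data_mod.load_field_trials() if trials is None else trials
    horizons = data_mod.load_soil_horizons() if horizons is None else horizons

    report: dict = {
        "package_version": _pkg_version("inunscore"),
        "seed": seed,
        "config": {
            "scale_factor": config.scale_factor,
            "convexity_mode": config.convexity_mode,
            "excluded_sites_water_regressions": list(exclude_sites),
        },
        "fixture_checksums": data_mod.table_checksums(),
    }

    # -- per-site score recomputation from terrain components --------
    site_rows = []
    for s in sites:
        recomputed = compose_score(s.water_accumulation, s.longitudinal_convexity, config,
                                   cross_sectional_convexity=s.cross_sectional_convexity)
        site_rows.append(
            {
                "site": s.site_name,
                "soil_group": s.soil_group,
                "water_accumulation": s.water_accumulation,
                "longitudinal_convexity": s.longitudinal_convexity,
                "cross_sectional_convexity": s.cross_sectional_convexity,
                "score_tabulated": s.inundation_score,
                "score_recomputed": round_half_up(recomputed, 2),
            }
        )
    report["site_scores"] = site_rows
    report["group_mean_scores"] = group_mean_scores(sites)

    score_by_site = {s.site_name: s.inundation_score for s in sites}

    # -- score -> yield regressions, one per treatment ----------------
    x_all = [score_by_site[t.site_name] for t in trials]
    yields = {}
    for treatment in ("CT", "NK", "NK+PR", "NK+TSP"):
        y = [t.yield_mean(treatment) for t in trials]
        yields[treatment] = _fit_dict(ols_fit(x_all, y))
    report["yield_regressions"] = yields

    # -- score -> water-condition regressions, with/without exclusion -
    water = {}
    for var, getter in (
        ("submergence_days", lambda t: t.submergence_days),
        ("cumulative_water_depth", lambda t: t.cumulative_water_depth),
    ):
        full = ols_fit(x_all, [getter(t) for t in trials])
        kept = [t for t in trials if t.site_name not in exclude_sites]
        sub = ols_fit([score_by_site[t.site_name] for t in kept], [getter(t) for t in kept])
        water[var] = {"all_sites": _fit_dict(full), "excluded": _fit_dict(sub)}
    report["water_condition_regressions"] = water

    # -- relative yield (PR over TSP) on score ------------------------
    rel = [relative_yield(t) for t in trials]
    report["relative_yield_regression"] = _fit_dict(ols_fit(x_all, rel))
    report["relative_yields"] = {t.site_name: r for t, r in zip(trials, rel)}

    # -- yield increases over CT --------------------------------------
    report["yield_increases"] = {
        t.site_name: {tr: round_half_up(yield_increase(t, tr), 2)
                      for tr in ("NK", "NK+PR", "NK+TSP")}
        for t in trials
    }

    # -- texture vs chemistry correlations on complete horizons -------
    # Both flavors are reported: the published matrix reproduces under
    # the product-moment (Pearson) coefficient.
    complete = [h for h in horizons if h.has_complete_chemistry()]
    import pandas as pd

    hframe = pd.DataFrame(
        [{v: getattr(h, v) for v in TEXTURE_VARS + CHEMISTRY_VARS} for h in complete]
    )
    report["correlations"] = {"n": len(complete)}
    for method in ("pearson", "spearman"):
        rho, pval = correlation_matrix(hframe, TEXTURE_VARS + CHEMISTRY_VARS,
                                       TEXTURE_VARS, method=method)
        report["correlations"][method] = {
            "rho": {a: {b: round(float(rho.loc[a, b]), 4) for b in TEXTURE_VARS}
                    for a in rho.index},
            "p": {a: {b: float(pval.loc[a, b]) for b in TEXTURE_VARS} for a in pval.index},
        }

    # -- BS / EBS recomputation check ---------------------------------
    bs_err, ebs_err = [], []
    for h in complete:
        if h.bs is not None:
            bs_err.append(abs(base_saturation(h) - h.bs))
        if h.ebs is not None:
            ebs_err.append(abs(effective_base_saturation(h) - h.ebs))
    report["saturation_check"] = {
        "n": len(complete),
        "bs_max_abs_error": round(max(bs_err), 3),
        "ebs_max_abs_error": round(max(ebs_err), 3),
    }

    # -- PCA of standardized site variables ---------------------------
    topsoil = _topsoil_texture(horizons)
    pca_vars = ["water_accumulation", "longitudinal_convexity", "cross_sectional_convexity",
                "submergence_days", "cumulative_water_depth", "sand", "silt", "clay"]
    trials_by_site = {t.site_name: t for t in trials}
    X = np.array(
        [
            [
                s.water_accumulation,
                s.longitudinal_convexity,
                s.cross_sectional_convexity,
                trials_by_site[s.site_name].submergence_days,
                trials_by_site[s.site_name].cumulative_water_depth,
                topsoil[s.site_name]["sand"],
                topsoil[s.site_name]["silt"],
                topsoil[s.site_name]["clay"],
            ]
            for s in sites
        ]
    )
    fit = pca_standardized(X, variables=pca_vars)
    report["pca"] = {
        "variables": pca_vars,
        "n_sites": len(sites),
        "sdev": [round(float(v), 4) for v in fit.sdev],
        "proportion": [round(float(v), 4) for v in fit.proportion],
        "cumulative": [round(float(v), 4) for v in fit.cumulative],
        "loadings_pc1": [round(float(v), 4) for v in fit.loadings[:, 0]],
    }
    return report


def _topsoil_texture(horizons, depth_cm: float = 20.0) -> dict[str, dict[str, float]]:
    """Depth-weighted 0–20 cm sand/silt/clay per site."""
    out: dict[str, dict[str, float]] = {}
    sites = sorted({h.site_name for h in horizons})
    for site in sites:
        hs = [h for h in horizons if h.site_name == site and h.has_texture()
              and h.depth_top is not None and h.depth_top < depth_cm]
        weights, fracs = [], []
        for h in hs:
            bottom = h.depth_bottom if h.depth_bottom is not None else depth_cm
            w = min(bottom, depth_cm) - h.depth_top
            if w <= 0:
                continue
            weights.append(w)
            fracs.append((h.sand, h.silt, h.clay))
        w = np.asarray(weights, dtype=float)
        f = np.asarray(fracs, dtype=float)
        sand, silt, clay = (w @ f) / w.sum()
        out[site] = {"sand": float(sand), "silt": float(silt), "clay": float(clay)}
    return out
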