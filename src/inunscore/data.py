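"""Packaged study tables.

Three CSVs ship inside the package, transcribed from the published
study tables at their printed precision (the exponent-notation
convexity strings are kept verbatim in ``*_printed`` columns for
provenance):

* ``site_terrain.csv`` — terrain components and inundation score of
  the seven observation sites, plus the two soil-group summary rows.
* ``field_trials.csv`` — per-site submergence duration, cumulative
  water depth, and grain yield mean ± SD for the four fertilization
  treatments (CT, NK, NK+PR, NK+TSP), plus group/all-site summary rows.
* ``soil_horizons.csv`` — the 38 described soil horizons of the seven
  profile pits (34 with complete chemistry, 37 with texture).
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path

import pandas as pd

from .score import SiteTerrainRecord
from .stats import HorizonRecord, TrialRecord

_TABLES = {
    "site_terrain": "site_terrain.csv",
    "field_trials": "field_trials.csv",
    "soil_horizons": "soil_horizons.csv",
}


def _data_path(name: str) -> Path:
    return Path(resources.files("inunscore").joinpath("data", _TABLES[name]))


def table_checksums() -> dict[str, str]:
    """SHA-256 of each packaged CSV, for report provenance."""
    out = {}
    for name in _TABLES:
        out[name] = hashlib.sha256(_data_path(name).read_bytes()).hexdigest()
    return out


def load_site_terrain_frame() -> pd.DataFrame:
    return pd.read_csv(_data_path("site_terrain"))


def load_site_terrain(include_groups: bool = False):
    """Site terrain records (7 sites); group rows on request.

    Returns the list of :class:`SiteTerrainRecord`, or a
    ``(records, group_rows)`` pair when ``include_groups`` is True.
    """
    df = load_site_terrain_frame()
    sites = df[df.row_type == "site"]
    records = [
        SiteTerrainRecord(
            site_name=r.site,
            soil_group=r.soil_group,
            water_accumulation=r.water_accumulation,
            longitudinal_convexity=r.longitudinal_convexity,
            cross_sectional_convexity=r.cross_sectional_convexity,
            inundation_score=r.inundation_score,
        )
        for r in sites.itertuples()
    ]
    if include_groups:
        return records, df[df.row_type == "group"].reset_index(drop=True)
    return records


def load_field_trials_frame() -> pd.DataFrame:
    return pd.read_csv(_data_path("field_trials"))


def load_field_trials(include_groups: bool = False):
    """Field-trial records (7 sites); summary rows on request."""
    df = load_field_trials_frame()
    sites = df[df.row_type == "site"]
    records = [
        TrialRecord(
            site_name=r.site,
            soil_group=r.soil_group,
            submergence_days=r.submergence_days,
            submergence_days_sd=r.submergence_days_sd,
            cumulative_water_depth=r.water_depth_cm,
            cumulative_water_depth_sd=r.water_depth_cm_sd,
            yield_by_treatment={
                "CT": (r.yield_ct, r.yield_ct_sd),
                "NK": (r.yield_nk, r.yield_nk_sd),
                "NK+PR": (r.yield_nkpr, r.yield_nkpr_sd),
                "NK+TSP": (r.yield_nktsp, r.yield_nktsp_sd),
            },
        )
        for r in sites.itertuples()
    ]
    if include_groups:
        return records, df[df.row_type == "group"].reset_index(drop=True)
    return records


def load_soil_horizons_frame() -> pd.DataFrame:
    return pd.read_csv(_data_path("soil_horizons"))


def load_soil_horizons() -> list[HorizonRecord]:
    """All 38 described horizons as records (None for unsampled fields)."""
    df = load_soil_horizons_frame()
    records = []
    for r in df.itertuples():
        kwargs = {}
        for col in ("depth_top", "depth_bottom", "sand", "silt", "clay", "total_c",
                    "total_n", "ph_h2o", "ph_kcl", "ec", "bray1_p", "bray2_p",
                    "exch_al", "exch_na", "exch_k", "exch_ca", "exch_mg",
                    "cec", "bs", "ebs"):
            v = getattr(r, col)
            kwargs[col] = None if pd.isna(v) else float(v)
        tc = r.texture_class
        records.append(
            HorizonRecord(
                site_name=r.site,
                soil_group=r.soil_group,
                horizon_name=r.horizon,
                texture_class=None if pd.isna(tc) else tc,
                **kwargs,
            )
        )
    return records


def complete_chemistry_horizons() -> list[HorizonRecord]:
    """The horizons with the full physicochemical suite (n = 34)."""
    return [h for h in load_soil_horizons() if h.has_complete_chemistry()]
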