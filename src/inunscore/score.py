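"""Composite inundation scoring.

The inundation score for a cell (or a field site) combines two terrain
signals derived from a projected DEM:

* the *water accumulation score* — log-transformed, smoothed and
  min–max normalized D8 flow accumulation, a [0, 1] proxy for how much
  upstream water converges on the cell, and
* the *longitudinal convexity* — curvature along the slope direction;
  negative values mark concave, water-stagnating landforms.

Where the longitudinal convexity is non-negative water is assumed not
to stagnate and the score is zero; otherwise the score is the water
accumulation score times the absolute convexity, scaled (default ×100)
into a convenient 0–1ish range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import hydro, raster
from .raster import RasterGrid, RasterError
from .util import round_half_up

#: Pipeline stages a convexity surface can be computed from.
CONVEXITY_SOURCES = ("raw", "pre_smoothed", "post_smoothed_once", "post_smoothed_twice")


@dataclass
class SiteTerrainRecord:
    """Terrain components and composite score at one observation point."""

    site_name: str
    soil_group: str
    water_accumulation: float
    longitudinal_convexity: float
    cross_sectional_convexity: float
    inundation_score: float
    elevation: float | None = None

    def __post_init__(self):
        if self.inundation_score < 0:
            raise ValueError(f"{self.site_name}: inundation_score must be >= 0")


@dataclass
class ScorePipelineConfig:
    """Knobs of the DEM -> inundation-score pipeline.

    Defaults follow the reference procedure: 5×5 pre-smoothing of the
    integer DEM, log10 transform of the accumulation counts, two 25×25
    smoothing passes, convexity from the once-25×25-smoothed DEM, score
    from the longitudinal convexity only, scaled by 100.
    """

    pre_filter_window: int = 5
    post_filter_window: int = 25
    post_filter_passes: int = 2
    convexity_source: str = "post_smoothed_once"
    convexity_mode: str = "longitudinal_only"
    scale_factor: float = 100.0
    log_base: float = 10.0
    fill_epsilon: float = 0.0

    def __post_init__(self):
        for name in ("pre_filter_window", "post_filter_window"):
            w = getattr(self, name)
            if w < 1 or w % 2 == 0:
                raise ValueError(f"{name} must be an odd integer >= 1, got {w}")
        if self.post_filter_passes < 0:
            raise ValueError("post_filter_passes must be >= 0")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be > 0")
        if self.convexity_source not in CONVEXITY_SOURCES:
            raise ValueError(
                f"convexity_source must be one of {CONVEXITY_SOURCES}, got {self.convexity_source!r}"
            )
        if self.convexity_mode not in ("longitudinal_only", "product_of_both"):
            raise ValueError(f"unknown convexity_mode {self.convexity_mode!r}")
        if self.log_base not in (10, 10.0, np.e):
            raise ValueError("log_base must be 10 or e")


def compose_score(
    water_accumulation: float,
    longitudinal_convexity: float,
    config: ScorePipelineConfig | None = None,
    cross_sectional_convexity: float | None = None,
) -> float:
    """Combine a water-accumulation score and convexity into the composite.

    Returns 0 when the longitudinal convexity is non-negative (no
    stagnation); otherwise ``water_accumulation × |convexity| ×
    scale_factor``.  In ``product_of_both`` mode the absolute
    cross-sectional convexity multiplies in as well; the zero-clip test
    always uses the longitudinal convexity alone.
    """
    config = config or ScorePipelineConfig()
    if not (0.0 <= water_accumulation <= 1.0):
        raise ValueError(
            f"water_accumulation must lie in [0, 1], got {water_accumulation}"
        )
    if longitudinal_convexity >= 0:
        return 0.0
    score = water_accumulation * abs(longitudinal_convexity) * config.scale_factor
    if config.convexity_mode == "product_of_both":
        if cross_sectional_convexity is None:
            raise ValueError("product_of_both mode requires cross_sectional_convexity")
        score *= abs(cross_sectional_convexity)
    return score


@dataclass
class ScoreSurfaces:
    """All intermediate and final surfaces of one pipeline run."""

    dem: RasterGrid
    water_accumulation: RasterGrid
    longitudinal_convexity: RasterGrid
    cross_sectional_convexity: RasterGrid
    score: RasterGrid
    config: ScorePipelineConfig = field(default_factory=ScorePipelineConfig)


def score_dem(dem: RasterGrid, config: ScorePipelineConfig | None = None) -> ScoreSurfaces:
    """Run the full DEM -> inundation-score pipeline.

    Stages: pre-smooth -> fill depressions -> D8 directions -> flow
    accumulation -> log transform -> post-smooth (×passes) -> min–max
    normalize ⇒ water-accumulation surface; convexity of the configured
    smoothed DEM ⇒ convexity surfaces; per-cell composite score.
    """
    config = config or ScorePipelineConfig()
    dem.require_nonempty()
    pre = raster.focal_mean(dem, config.pre_filter_window)
    filled = hydro.fill_depressions(pre, epsilon=config.fill_epsilon)
    dirs = hydro.d8_directions(filled)
    acc = hydro.flow_accumulation(dirs)
    acc_grid = pre.with_values(
        np.where(~acc.nodata_mask, acc.counts.astype(float), np.nan)
    )
    wa = raster.log_transform(acc_grid, base=config.log_base)
    post_once = None
    for i in range(config.post_filter_passes):
        wa = raster.focal_mean(wa, config.post_filter_window)
        if i == 0:
            post_once = wa
    wa = raster.normalize_01(wa)

    conv_dem = {
        "raw": dem,
        "pre_smoothed": pre,
        "post_smoothed_once": None,
        "post_smoothed_twice": None,
    }[config.convexity_source]
    if conv_dem is None:
        conv_dem = pre
        passes = 1 if config.convexity_source == "post_smoothed_once" else 2
        for _ in range(passes):
            conv_dem = raster.focal_mean(conv_dem, config.post_filter_window)
    conv = hydro.convexity(conv_dem)
    lc = dem.with_values(conv.longitudinal, nodata_mask=conv.nodata_mask.copy())
    cc = dem.with_values(conv.cross_sectional, nodata_mask=conv.nodata_mask.copy())

    mask = wa.nodata_mask | conv.nodata_mask
    wav, lcv, ccv = wa.values, conv.longitudinal, conv.cross_sectional
    with np.errstate(invalid="ignore"):
        score_vals = np.where(lcv < 0, wav * np.abs(lcv) * config.scale_factor, 0.0)
        if config.convexity_mode == "product_of_both":
            score_vals = np.where(lcv < 0, score_vals * np.abs(ccv), 0.0)
    score_vals = np.where(mask, np.nan, score_vals)
    score = dem.with_values(score_vals, nodata_mask=mask)
    return ScoreSurfaces(
        dem=dem,
        water_accumulation=wa,
        longitudinal_convexity=lc,
        cross_sectional_convexity=cc,
        score=score,
        config=config,
    )


class SiteLookupError(RasterError):
    """A requested site cell is outside the grid or nodata."""


def extract_sites(
    surfaces: ScoreSurfaces,
    points: list[tuple[int, int, str]],
    soil_groups: dict[str, str] | None = None,
) -> list[SiteTerrainRecord]:
    """Sample the pipeline surfaces at (row, col, site_name) points."""
    records = []
    rows, cols = surfaces.score.shape
    for row, col, name in points:
        if not (0 <= row < rows and 0 <= col < cols):
            raise SiteLookupError(f"site {name!r}: cell ({row}, {col}) outside grid {rows}x{cols}")
        if surfaces.score.nodata_mask[row, col]:
            raise SiteLookupError(f"site {name!r}: cell ({row}, {col}) is nodata")
        records.append(
            SiteTerrainRecord(
                site_name=name,
                soil_group=(soil_groups or {}).get(name, ""),
                water_accumulation=float(surfaces.water_accumulation.values[row, col]),
                longitudinal_convexity=float(surfaces.longitudinal_convexity.values[row, col]),
                cross_sectional_convexity=float(surfaces.cross_sectional_convexity.values[row, col]),
                inundation_score=float(surfaces.score.values[row, col]),
                elevation=float(surfaces.dem.values[row, col]),
            )
        )
    return records


def group_mean_scores(
    records: list[SiteTerrainRecord],
    grouping: dict[str, list[str]] | None = None,
    ndigits: int | None = 2,
) -> dict[str, float]:
    """Mean inundation score per soil group.

    ``grouping`` maps a group label to the soil_group values pooled
    under it (default: ``{"Lixisols and Luvisols": [Lixisols, Luvisols],
    "Cambisols": [Cambisols]}``).  Rounded half-up to ``ndigits`` for
    printed-table reproduction; pass ``ndigits=None`` for full precision.
    """
    if grouping is None:
        grouping = {
            "Lixisols and Luvisols": ["Lixisols", "Luvisols"],
            "Cambisols": ["Cambisols"],
        }
    out: dict[str, float] = {}
    for label, members in grouping.items():
        scores = [r.inundation_score for r in records if r.soil_group in members]
        if not scores:
            raise ValueError(f"group {label!r} is empty")
        mean = float(np.mean(scores))
        out[label] = round_half_up(mean, ndigits) if ndigits is not None else mean
    return out
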