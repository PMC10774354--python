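"""Regression layer: raster-pair validation and the HH-diversity grid.

Two uses of the same ordinary-least-squares fit:

* validating one elevation raster against another by sampling both at
  random cell centers and regressing the paired values (also reporting the
  mean offset between the two surfaces); and
* the height-heterogeneity inference grid — for every combination of
  heterogeneity index, CHM resolution and survey response (flower
  richness, bee richness, bee abundance), regress the response on the
  per-transect HH value and record slope, R^2 and p.

Inference is deliberately plain OLS with t-distribution p-values; no
mixed models or spatial-autocorrelation corrections. Per-cell significance
is reported at alpha = 0.05, with a Bonferroni-adjusted flag across the
grid carried as an extra column for the user.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .heterogeneity import HeterogeneityMeasure
from .synthetic import SurveyRecord

__all__ = [
    "RegressionFit",
    "DegenerateRegressorError",
    "InsufficientDataError",
    "RESPONSES",
    "linear_fit",
    "validate_raster_pair",
    "hh_diversity_grid",
    "surveys_to_frame",
    "measures_to_frame",
]

RESPONSES = ("flower_richness", "bee_richness", "bee_abundance")


class DegenerateRegressorError(ValueError):
    """The regressor is constant; the slope is undefined."""


class InsufficientDataError(ValueError):
    """Fewer than 3 valid observations."""


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit summary: y = intercept + slope * x."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    residual_sd: float
    mean_offset: float | None = None  # mean(y) - mean(x); raster validation only

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def linear_fit(x: Sequence[float], y: Sequence[float],
               mean_offset: bool = False) -> RegressionFit:
    """Closed-form ordinary least squares with a two-sided t-test on the slope."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"need at least 3 observations, got {n}")
    if np.ptp(x) == 0:
        raise DegenerateRegressorError("regressor x is constant")
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    sse = float(np.sum(resid**2))
    residual_sd = float(np.sqrt(sse / (n - 2)))
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=n,
        residual_sd=residual_sd,
        mean_offset=float(np.mean(y) - np.mean(x)) if mean_offset else None,
    )


def validate_raster_pair(
    raster_a,
    raster_b,
    n_points: int = 10,
    zones: Iterable[tuple[float, float, float, float]] | None = None,
    seed: int = 0,
) -> RegressionFit:
    """Validate raster_b against raster_a by random point sampling.

    Draws ``n_points`` random cell centers per zone (zones are
    (xmin, ymin, xmax, ymax) rectangles; default one zone covering the
    common grid), reads both rasters at those cells, drops pairs where
    either is nodata, and fits ``b ~ a``. ``mean_offset`` in the result is
    mean(b) - mean(a) over the sampled pairs, the systematic elevation
    shift between the two surfaces. Sampling is at cell centers so both
    rasters are read without interpolation.
    """
    if not raster_a.same_geometry(raster_b):
        raise ValueError("rasters must share a common grid; resample first")
    xs, ys = raster_a.cell_centers()
    if zones is None:
        zones = [(xs.min(), ys.min(), xs.max(), ys.max())]
    zones = sorted(zones)  # invariant to caller's zone ordering
    rng = np.random.default_rng(seed)
    a_vals, b_vals = [], []
    for xmin, ymin, xmax, ymax in zones:
        ci = np.nonzero((xs >= xmin) & (xs <= xmax))[0]
        ri = np.nonzero((ys >= ymin) & (ys <= ymax))[0]
        if ci.size == 0 or ri.size == 0:
            continue
        rr = rng.choice(ri, size=n_points, replace=True)
        cc = rng.choice(ci, size=n_points, replace=True)
        a_vals.append(raster_a.values[rr, cc])
        b_vals.append(raster_b.values[rr, cc])
    if not a_vals:
        raise InsufficientDataError("no zone overlaps the raster grid")
    a = np.concatenate(a_vals)
    b = np.concatenate(b_vals)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise InsufficientDataError(f"only {int(ok.sum())} valid sample pairs")
    return linear_fit(a[ok], b[ok], mean_offset=True)


def measures_to_frame(measures: Iterable[HeterogeneityMeasure]) -> pd.DataFrame:
    """Long table of HH measures: transect_id, index, resolution, bin_width, value, n_cells."""
    rows = [
        {
            "transect_id": m.transect_id,
            "index": m.index_name,
            "resolution": m.resolution,
            "bin_width": m.bin_width,
            "value": m.value,
            "n_cells": m.n_cells,
        }
        for m in measures
    ]
    return pd.DataFrame(rows)


def surveys_to_frame(surveys: Iterable[SurveyRecord]) -> pd.DataFrame:
    rows = [
        {
            "transect_id": s.transect_id,
            "flower_richness": s.flower_richness,
            "bee_richness": s.bee_richness,
            "bee_abundance": s.bee_abundance,
        }
        for s in surveys
    ]
    return pd.DataFrame(rows)


def hh_diversity_grid(
    measures: Iterable[HeterogeneityMeasure] | pd.DataFrame,
    surveys: Iterable[SurveyRecord] | pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Regress every survey response on every (index, resolution) HH value.

    Joins measures and surveys on transect_id (exact string match;
    unmatched transects are dropped per cell) and fits one OLS per
    (index, resolution, response) cell. Returns a long table with columns
    index, resolution, response, slope, intercept, r_squared, p_value, n,
    significant (at ``alpha``), significant_bonferroni (alpha divided by
    the number of fitted cells), and error for cells that could not be
    fitted.
    """
    mf = measures if isinstance(measures, pd.DataFrame) else measures_to_frame(measures)
    sf = surveys if isinstance(surveys, pd.DataFrame) else surveys_to_frame(surveys)
    mf = mf.copy()
    sf = sf.copy()
    mf["transect_id"] = mf["transect_id"].astype(str)
    sf["transect_id"] = sf["transect_id"].astype(str)
    responses = [r for r in RESPONSES if r in sf.columns]
    rows = []
    for (index_name, resolution), grp in mf.groupby(["index", "resolution"], sort=True):
        joined = grp.merge(sf, on="transect_id", how="inner")
        for resp in responses:
            row = {"index": index_name, "resolution": resolution, "response": resp}
            try:
                fit = linear_fit(joined["value"].to_numpy(),
                                 joined[resp].to_numpy(dtype=float))
            except (InsufficientDataError, DegenerateRegressorError) as exc:
                row.update(
                    slope=np.nan, intercept=np.nan, r_squared=np.nan,
                    p_value=np.nan, n=len(joined), error=str(exc),
                )
            else:
                row.update(
                    slope=fit.slope, intercept=fit.intercept,
                    r_squared=fit.r_squared, p_value=fit.p_value,
                    n=fit.n, error="",
                )
            rows.append(row)
    grid = pd.DataFrame(rows)
    n_cells = int(grid["p_value"].notna().sum())
    grid["significant"] = grid["p_value"] < alpha
    grid["significant_bonferroni"] = grid["p_value"] < (alpha / max(n_cells, 1))
    return grid
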