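"""Gridded ensemble predictions with coefficient-of-variation uncertainty.

Predictions are made at cell centroids of a regular grid (default 10 × 10 km)
using the same feature construction as training, with the plot-size feature
fixed (default 500 m², the most common plot size in training data) and the
neighborhood-radius feature fixed (default 5 km, matching the cell size).
Adjusting those two features moves the prediction to a different spatial
scale, exploiting the species–area relationship the model has learned; both
should stay within the range spanned by the training data.

Per cell, the ensemble mean is the prediction and the coefficient of
variation CV = sd/mean (population sd across members) is its uncertainty.
Cells with CV above the median over all cells in the run are masked as
high-uncertainty; downstream regional summaries use unmasked cells only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FEATURE_SETS, RASTER_FEATURES, FeatureTable, _window_counts_all
from .model import Ensemble
from .raster import RasterLayer


@dataclass
class PredictionGrid:
    """Per-cell ensemble summary on a regular grid."""

    centroids: np.ndarray            # (n, 2) projected meters
    cell_size: float
    mean: np.ndarray
    sd: np.ndarray
    cv: np.ndarray
    mask: np.ndarray                 # True = high uncertainty (CV > median)
    median_cv: float
    n_zero_mean: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x": self.centroids[:, 0], "y": self.centroids[:, 1],
            "mean": self.mean, "sd": self.sd, "cv": self.cv,
            "high_uncertainty": self.mask,
        })

    def to_rasters(self) -> dict[str, RasterLayer]:
        """Mean/sd/cv/mask as raster layers (cells absent from the grid are NaN)."""
        xs = np.unique(self.centroids[:, 0])
        ys = np.unique(self.centroids[:, 1])
        x0 = xs.min() - self.cell_size / 2
        y1 = ys.max() + self.cell_size / 2
        ncol = int(round((xs.max() - xs.min()) / self.cell_size)) + 1
        nrow = int(round((ys.max() - ys.min()) / self.cell_size)) + 1
        col = np.round((self.centroids[:, 0] - xs.min()) / self.cell_size).astype(int)
        row = np.round((ys.max() - self.centroids[:, 1]) / self.cell_size).astype(int)
        out = {}
        for name, vals in [("mean", self.mean), ("sd", self.sd), ("cv", self.cv),
                           ("mask", self.mask.astype(float))]:
            grid = np.full((nrow, ncol), np.nan)
            grid[row, col] = vals
            out[name] = RasterLayer(name, grid, x0, y1, self.cell_size)
        return out


def make_grid(extent: tuple[float, float, float, float], cell_size: float,
              land_mask: RasterLayer | None = None) -> np.ndarray:
    """Centroids of all cells whose centers fall inside ``extent``.

    ``extent`` is (xmin, ymin, xmax, ymax) in projected meters. Cells whose
    centers land outside the extent (partial edge cells) are excluded. If a
    ``land_mask`` raster is given, centers on cells with value 0 or nodata are
    dropped as well.
    """
    xmin, ymin, xmax, ymax = extent
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    if xmax <= xmin or ymax <= ymin:
        raise ValueError(f"degenerate extent {extent}")
    xs = np.arange(xmin + cell_size / 2, xmax, cell_size)
    ys = np.arange(ymin + cell_size / 2, ymax, cell_size)
    if len(xs) == 0 or len(ys) == 0:
        raise ValueError("extent too small for any full cell")
    gx, gy = np.meshgrid(xs, ys)
    centroids = np.column_stack([gx.ravel(), gy.ravel()])
    if land_mask is not None:
        values = land_mask.value_at(centroids[:, 0], centroids[:, 1])
        keep = np.nan_to_num(values, nan=0.0) != 0
        centroids = centroids[keep]
        if len(centroids) == 0:
            raise ValueError("land mask excludes every grid cell")
    return centroids


def grid_features(centroids: np.ndarray,
                  layers,
                  occurrences: pd.DataFrame | None,
                  plot_size: float,
                  radius: float,
                  scaler_table: FeatureTable,
                  feature_set: str = "full27",
                  window_side: float = 10_000.0) -> FeatureTable:
    """Feature table at grid centroids, scaled with the *training* scaler.

    Plot size and radius are constant columns. If either falls outside the
    range the scaler was fitted on (i.e., the training range), a warning is
    emitted — predictions outside the trained species–area range extrapolate.
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {feature_set!r}")
    if scaler_table.scaler is None:
        raise ValueError("scaler_table must carry a fitted scaler")
    names = FEATURE_SETS[feature_set]
    xs, ys = centroids[:, 0], centroids[:, 1]
    n = len(centroids)

    for feat, value in [("Vegetation plot size", plot_size),
                        ("Neighborhood radius", radius)]:
        if feat in scaler_table.scaler:
            lo, hi = scaler_table.scaler[feat]
            if not (lo <= value <= hi):
                warnings.warn(
                    f"{feat} = {value} is outside the training range "
                    f"[{lo}, {hi}]; predictions extrapolate", stacklevel=2)

    columns: dict[str, np.ndarray] = {}
    for name in names:
        if name == "Longitude":
            columns[name] = xs
        elif name == "Latitude":
            columns[name] = ys
        elif name == "Vegetation plot size":
            columns[name] = np.full(n, float(plot_size))
        elif name == "Neighborhood radius":
            columns[name] = np.full(n, float(radius))
        elif name in RASTER_FEATURES:
            if name not in layers:
                raise ValueError(f"missing raster layer for feature {name!r}")
            columns[name] = layers[name].value_at(xs, ys)
    if "Sampling effort" in names or "# of sampled species" in names:
        if occurrences is None:
            raise ValueError("occurrence table required for sampling-effort features")
        n_rec, n_sp = _window_counts_all(occurrences, centroids, window_side)
        columns["Sampling effort"] = n_rec.astype(float)
        columns["# of sampled species"] = n_sp.astype(float)

    values = np.column_stack([columns[nm] for nm in names])
    table = FeatureTable(
        site_ids=[f"cell_{i}" for i in range(n)],
        feature_names=names, values=values,
        scaler={nm: scaler_table.scaler[nm] for nm in names},
    )
    return table


def predict_ensemble(ensemble: Ensemble, table: FeatureTable,
                     cell_size: float = 10_000.0,
                     centroids: np.ndarray | None = None) -> PredictionGrid:
    """Ensemble mean, population sd, CV and the median-CV mask per cell.

    Member predictions are inverse-label-scaled to the diversity scale before
    aggregation. CV at cells with zero mean is set to 0 and counted in
    ``n_zero_mean`` (softplus makes this practically impossible, but it is
    guarded). Cells with CV exactly equal to the median stay unmasked,
    matching the convention that retained cells have CV *smaller than* the
    median.
    """
    expected = FEATURE_SETS.get(ensemble.config.feature_set)
    if expected is not None and tuple(table.feature_names) != tuple(expected):
        raise ValueError(
            f"feature columns {table.feature_names} do not match the "
            f"ensemble's feature set {ensemble.config.feature_set!r}")
    X, _ = table.transform()
    member_preds = ensemble.predict_members(X)
    mean = member_preds.mean(axis=0)
    sd = member_preds.std(axis=0)  # population form: the ensemble is complete
    zero = mean == 0
    cv = np.zeros_like(mean)
    cv[~zero] = sd[~zero] / mean[~zero]
    median_cv = float(np.median(cv))
    mask = cv > median_cv
    if centroids is None:
        centroids = np.column_stack([np.arange(len(mean)), np.zeros(len(mean))])
    return PredictionGrid(
        centroids=np.asarray(centroids, dtype=float), cell_size=cell_size,
        mean=mean, sd=sd, cv=cv, mask=mask, median_cv=median_cv,
        n_zero_mean=int(zero.sum()),
    )


def summarize_by_region(grid: PredictionGrid, regions: RasterLayer,
                        quantiles=(0.05, 0.25, 0.5, 0.75, 0.95)) -> pd.DataFrame:
    """Per-region prediction summaries over *unmasked* (low-CV) cells.

    ``regions`` is a category raster whose integer cell values name regions
    (e.g. biomes). For each region overlapping the grid the summary reports
    total and unmasked cell counts and mean/quantiles of the ensemble-mean
    prediction over unmasked cells; regions whose cells are all masked get
    ``n_unmasked = 0`` and NaN statistics.
    """
    row, col = regions.cell_index(grid.centroids[:, 0], grid.centroids[:, 1])
    nrow, ncol = regions.data.shape
    in_bounds = (row >= 0) & (row < nrow) & (col >= 0) & (col < ncol)
    region_vals = np.full(len(grid.centroids), np.nan)
    region_vals[in_bounds] = regions.data[row[in_bounds], col[in_bounds]]
    if regions.nodata is not None:
        region_vals[region_vals == regions.nodata] = np.nan
    ok = np.isfinite(region_vals)
    if not np.any(ok):
        raise ValueError("region raster does not overlap the prediction grid")
    rows = []
    for region in np.unique(region_vals[ok]):
        in_region = region_vals == region
        unmasked = in_region & ~grid.mask
        row = {
            "region": region,
            "n_cells": int(in_region.sum()),
            "n_unmasked": int(unmasked.sum()),
        }
        if row["n_unmasked"] > 0:
            vals = grid.mean[unmasked]
            row["mean"] = float(vals.mean())
            for q in quantiles:
                row[f"q{int(q * 100):02d}"] = float(np.quantile(vals, q))
        else:
            row["mean"] = float("nan")
            for q in quantiles:
                row[f"q{int(q * 100):02d}"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
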