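"""Per-site feature tables: occurrence filtering, window counts, raster
extraction, named feature subsets, and 0–1 min-max rescaling.

The full feature list has 27 entries: site coordinates, two occurrence-derived
sampling-effort measures (record count and distinct-species count inside a
10 × 10 km window), human footprint, elevation, the 19 bioclimatic variables
BIO1–BIO19, the vegetation-plot size, and the neighborhood radius at which the
gamma label was computed. Two reduced sets are used in model selection: an
8-feature set (coordinates + human footprint, elevation, BIO1, BIO12, plot
size, radius) and a 6-feature set that additionally drops the coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .labels import DiversitySite, PlotRecord, normalize_name
from .raster import RasterLayer

_BIO = [f"BIO{i}" for i in range(1, 20)]

#: All 27 feature names, in canonical order.
FULL27: tuple[str, ...] = tuple(
    ["Longitude", "Latitude", "Sampling effort", "# of sampled species",
     "Human footprint", "Elevation"]
    + _BIO
    + ["Vegetation plot size", "Neighborhood radius"]
)

#: 8-feature subset: coordinates plus the strongest environmental predictors.
SUBSET8: tuple[str, ...] = (
    "Longitude", "Latitude", "Human footprint", "Elevation", "BIO1", "BIO12",
    "Vegetation plot size", "Neighborhood radius",
)

#: 6-feature subset: SUBSET8 without the coordinate columns.
SUBSET6: tuple[str, ...] = (
    "Human footprint", "Elevation", "BIO1", "BIO12",
    "Vegetation plot size", "Neighborhood radius",
)

FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "full27": FULL27,
    "subset8": SUBSET8,
    "subset6": SUBSET6,
}

#: Feature names sourced from raster layers.
RASTER_FEATURES: tuple[str, ...] = ("Human footprint", "Elevation") + tuple(_BIO)


@dataclass
class FeatureTable:
    """Per-site feature matrix with optional fitted min-max scaler.

    ``values`` holds raw (unscaled) features; after :func:`fit_apply_scaler`
    the per-feature training (min, max) lives in ``scaler`` and
    :meth:`transform` maps any compatible matrix to the scaled space.
    """

    site_ids: list[str]
    feature_names: tuple[str, ...]
    values: np.ndarray
    scaler: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.site_ids), len(self.feature_names)):
            raise ValueError("values shape does not match ids × feature names")

    def transform(self, values: np.ndarray | None = None):
        """Apply the fitted scaler.

        Returns ``(scaled, n_out_of_range)``: values below/above the fitted
        range are *not* clipped (they fall outside [0, 1]) and are counted.
        """
        if self.scaler is None:
            raise ValueError("scaler has not been fitted; call fit_apply_scaler")
        raw = self.values if values is None else np.asarray(values, dtype=float)
        lo = np.array([self.scaler[n][0] for n in self.feature_names])
        hi = np.array([self.scaler[n][1] for n in self.feature_names])
        span = hi - lo
        scaled = np.zeros_like(raw)
        ok = span > 0
        scaled[:, ok] = (raw[:, ok] - lo[ok]) / span[ok]
        # constant features map to 0 by convention
        finite = np.isfinite(scaled)
        n_out = int(np.sum((scaled < 0) | (scaled > 1), where=finite))
        return scaled, n_out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.site_ids,
                            columns=list(self.feature_names))


def filter_occurrences(occurrences: pd.DataFrame, checklist) -> pd.DataFrame:
    """Keep occurrence records that pass the standard cleaning rules.

    A row survives iff it is non-fossil, based on human observation, carries no
    geospatial issue flags, has a binomial name (exactly two whitespace-
    separated tokens), and its name is present in the accepted-name checklist.
    Name comparison is exact after trimming and case-folding.
    """
    names = set(normalize_name(n) for n in _checklist_names(checklist))
    if not names:
        raise ValueError("checklist must be non-empty")
    df = occurrences
    species = df["species"].map(normalize_name)
    binomial = species.str.split().str.len() == 2
    basis = df["basis_of_record"].astype(str).str.strip().str.casefold()
    human = basis.isin({"human_observation", "humanobservation", "human observation"})
    flags = df.get("issue_flags")
    if flags is None:
        clean = pd.Series(True, index=df.index)
    else:
        clean = flags.fillna("").astype(str).str.strip() == ""
    fossil = df.get("is_fossil")
    non_fossil = ~fossil.astype(bool) if fossil is not None else pd.Series(True, index=df.index)
    in_checklist = species.isin(names)
    keep = binomial & human & clean & non_fossil & in_checklist
    return df.loc[keep].copy()


def _checklist_names(checklist):
    if isinstance(checklist, pd.DataFrame):
        return checklist["accepted_name"].tolist()
    return list(checklist)


def window_counts(occurrences: pd.DataFrame, center: tuple[float, float],
                  window_side: float = 10_000.0) -> tuple[int, int]:
    """Occurrence record and distinct-species counts in a square window.

    The window is centered on ``center`` with side ``window_side`` meters and
    treated half-open on its max edges (``[c − s/2, c + s/2)``) so occurrences
    on grid seams are never counted twice by adjacent windows.
    """
    if window_side <= 0:
        raise ValueError("window_side must be positive")
    cx, cy = center
    half = window_side / 2.0
    x = occurrences["x"].to_numpy(dtype=float)
    y = occurrences["y"].to_numpy(dtype=float)
    inside = (x >= cx - half) & (x < cx + half) & (y >= cy - half) & (y < cy + half)
    n_records = int(inside.sum())
    if n_records == 0:
        return 0, 0
    n_species = int(occurrences.loc[inside, "species"].map(normalize_name).nunique())
    return n_records, n_species


def _window_counts_all(occurrences: pd.DataFrame, centers: np.ndarray,
                       window_side: float) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized window counts for many centers (KD-tree prefilter)."""
    from scipy.spatial import cKDTree

    xy = occurrences[["x", "y"]].to_numpy(dtype=float)
    n_rec = np.zeros(len(centers), dtype=int)
    n_sp = np.zeros(len(centers), dtype=int)
    if len(xy) == 0:
        return n_rec, n_sp
    species = occurrences["species"].map(normalize_name).to_numpy()
    tree = cKDTree(xy)
    half = window_side / 2.0
    # circumscribing radius prefilter, exact square test afterwards
    candidates = tree.query_ball_point(centers, r=half * np.sqrt(2) + 1e-9)
    for i, (cx, cy) in enumerate(centers):
        cand = np.asarray(candidates[i], dtype=int)
        if cand.size == 0:
            continue
        px, py = xy[cand, 0], xy[cand, 1]
        inside = (px >= cx - half) & (px < cx + half) & (py >= cy - half) & (py < cy + half)
        n_rec[i] = int(inside.sum())
        if n_rec[i]:
            n_sp[i] = len(set(species[cand[inside]]))
    return n_rec, n_sp


def assemble_features(sites: Sequence[DiversitySite],
                      plots: Sequence[PlotRecord],
                      occurrences: pd.DataFrame | None,
                      layers: Mapping[str, RasterLayer],
                      feature_set: str = "full27",
                      window_side: float = 10_000.0) -> FeatureTable:
    """Build the per-site feature table for one of the named feature sets.

    Raster-derived columns come from nearest-cell lookup in ``layers`` (keyed
    by feature name); the two sampling-effort columns from
    :func:`window_counts` over the (already filtered) occurrence table; plot
    size from the plot record and radius from the diversity site.
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {feature_set!r}; "
                         f"expected one of {sorted(FEATURE_SETS)}")
    names = FEATURE_SETS[feature_set]
    plot_by_id = {p.plot_id: p for p in plots}
    missing = [s.plot_id for s in sites if s.plot_id not in plot_by_id]
    if missing:
        raise ValueError(f"sites without plot records: {missing[:5]}")
    xs = np.array([plot_by_id[s.plot_id].x for s in sites])
    ys = np.array([plot_by_id[s.plot_id].y for s in sites])

    columns: dict[str, np.ndarray] = {}
    for name in names:
        if name == "Longitude":
            columns[name] = xs
        elif name == "Latitude":
            columns[name] = ys
        elif name == "Vegetation plot size":
            columns[name] = np.array([plot_by_id[s.plot_id].area for s in sites])
        elif name == "Neighborhood radius":
            columns[name] = np.array([s.radius for s in sites])
        elif name in ("Sampling effort", "# of sampled species"):
            if "Sampling effort" not in columns and "# of sampled species" not in columns:
                pass  # computed once below
        elif name in RASTER_FEATURES:
            if name not in layers:
                raise ValueError(f"missing raster layer for feature {name!r}")
            columns[name] = layers[name].value_at(xs, ys)
        else:  # pragma: no cover - names is a fixed tuple
            raise ValueError(f"unhandled feature {name!r}")
    if "Sampling effort" in names or "# of sampled species" in names:
        if occurrences is None:
            raise ValueError("occurrence table required for sampling-effort features")
        centers = np.column_stack([xs, ys])
        n_rec, n_sp = _window_counts_all(occurrences, centers, window_side)
        columns["Sampling effort"] = n_rec.astype(float)
        columns["# of sampled species"] = n_sp.astype(float)

    values = np.column_stack([columns[n] for n in names])
    return FeatureTable(site_ids=[s.plot_id for s in sites],
                        feature_names=names, values=values)


def fit_apply_scaler(table: FeatureTable, fit_rows=None) -> FeatureTable:
    """Fit per-feature min-max scaling on ``fit_rows`` and attach the scaler.

    ``fit_rows`` defaults to all rows. The returned table shares the raw
    values but carries a fitted ``scaler``; use :meth:`FeatureTable.transform`
    to obtain scaled values and the out-of-fitted-range count (values outside
    the training range are deliberately not clipped). Constant features scale
    to 0.
    """
    rows = np.arange(len(table.site_ids)) if fit_rows is None else np.asarray(fit_rows)
    fit = table.values[rows]
    scaler = {}
    for j, name in enumerate(table.feature_names):
        col = fit[:, j]
        col = col[np.isfinite(col)]
        if col.size == 0:
            scaler[name] = (0.0, 0.0)
        else:
            scaler[name] = (float(col.min()), float(col.max()))
    return replace(table, scaler=scaler)
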