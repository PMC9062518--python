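"""Readers and writers for the package's interchange formats.

Tables are delimited text (comma or tab, sniffed automatically); rasters are
GeoTIFF or ESRI ASCII grids (see :mod:`diversitynet.raster`); run
configuration and fitted scalers are JSON. Plot tables are accepted in two
layouts:

* **wide** — one row per plot with a delimited species-list column
  (``plot_id, lon, lat, area_m2, species``; species separated by ``;``);
* **long** — one row per (plot, species) pair with the plot metadata repeated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .labels import DiversitySite, PlotRecord
from .projection import DEFAULT_STANDARD_PARALLEL, project_cea
from .raster import RasterLayer, read_raster, write_raster  # re-exported

PLOT_COLUMNS = ("plot_id", "lon", "lat", "area_m2", "species")
OCCURRENCE_COLUMNS = ("species", "lon", "lat", "basis_of_record")


@dataclass
class RunConfig:
    """Declarative configuration of one full pipeline run.

    Defaults mirror the reference analysis: neighborhoods of N = 50 plots,
    10 × 10 km sampling-effort windows and prediction cells, prediction plot
    size 500 m² and radius 5 km, ensembles of 50 networks.
    """

    plots_path: str | None = None
    occurrences_path: str | None = None
    checklist_path: str | None = None
    raster_dir: str | None = None
    regions_path: str | None = None
    output_dir: str = "output"
    n_neighbors: int = 50
    window_side: float = 10_000.0
    cell_size: float = 10_000.0
    prediction_plot_size: float = 500.0
    prediction_radius: float = 5_000.0
    metrics: tuple[str, ...] = ("alpha", "beta", "gamma")
    feature_set: str = "full27"
    seed: int = 0
    n_ensemble: int = 50

    def __post_init__(self) -> None:
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be at least 1")
        if min(self.window_side, self.cell_size, self.prediction_plot_size,
               self.prediction_radius) <= 0:
            raise ValueError("window/cell/plot-size/radius must be positive")

    def to_json(self, path) -> Path:
        path = Path(path)
        payload = asdict(self)
        payload["metrics"] = list(self.metrics)
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        return path

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        payload["metrics"] = tuple(payload.get("metrics", ("alpha", "beta", "gamma")))
        return cls(**payload)


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise ValueError(f"{path}: empty file")
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        raise ValueError(f"{path}: file contains no data rows")
    return df


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _parse_coords(df: pd.DataFrame, path) -> tuple[np.ndarray, np.ndarray]:
    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    bad = df.index[lon.isna() | lat.isna()].tolist()
    if bad:
        lines = [i + 2 for i in bad[:5]]  # +2: header and 1-based lines
        raise ValueError(f"{path}: unparseable coordinates on line(s) {lines}")
    return lon.to_numpy(), lat.to_numpy()


def read_plots(path, standard_parallel: float = DEFAULT_STANDARD_PARALLEL,
               species_sep: str = ";") -> list[PlotRecord]:
    """Read a plot table (wide or long layout) into projected PlotRecords."""
    df = _read_table(path)
    _require_columns(df, PLOT_COLUMNS, path)
    lon, lat = _parse_coords(df, path)
    x, y = project_cea(lon, lat, standard_parallel)
    df = df.assign(_x=x, _y=y)
    area = pd.to_numeric(df["area_m2"], errors="coerce")
    bad = df.index[area.isna()].tolist()
    if bad:
        raise ValueError(f"{path}: unparseable area_m2 on line(s) "
                         f"{[i + 2 for i in bad[:5]]}")
    df["area_m2"] = area

    is_long = df["plot_id"].duplicated().any()
    records: list[PlotRecord] = []
    if is_long:
        for plot_id, group in df.groupby("plot_id", sort=True):
            first = group.iloc[0]
            species = frozenset(str(s) for s in group["species"])
            records.append(PlotRecord(str(plot_id), float(first["_x"]),
                                      float(first["_y"]), float(first["area_m2"]),
                                      species))
    else:
        for _, row in df.iterrows():
            raw = str(row["species"]) if not pd.isna(row["species"]) else ""
            species = frozenset(s for s in raw.split(species_sep) if s.strip())
            records.append(PlotRecord(str(row["plot_id"]), float(row["_x"]),
                                      float(row["_y"]), float(row["area_m2"]),
                                      species))
    return records


def read_occurrences(path,
                     standard_parallel: float = DEFAULT_STANDARD_PARALLEL) -> pd.DataFrame:
    """Read an occurrence table and add projected ``x``/``y`` columns."""
    df = _read_table(path)
    _require_columns(df, OCCURRENCE_COLUMNS, path)
    lon, lat = _parse_coords(df, path)
    x, y = project_cea(lon, lat, standard_parallel)
    out = df.copy()
    out["x"] = x
    out["y"] = y
    if "issue_flags" not in out.columns:
        out["issue_flags"] = ""
    out["issue_flags"] = out["issue_flags"].fillna("")
    if "is_fossil" not in out.columns:
        out["is_fossil"] = False
    out["is_fossil"] = out["is_fossil"].astype(bool)
    return out


def read_checklist(path) -> pd.DataFrame:
    df = _read_table(path)
    _require_columns(df, ("accepted_name",), path)
    return df


def read_fixture(directory) -> dict:
    """Read everything :func:`diversitynet.synthetic.write_fixture` wrote."""
    directory = Path(directory)
    manifest = json.loads((directory / "landscape.json").read_text())
    layers = {name: read_raster(directory / fname, name=name)
              for name, fname in manifest["layers"].items()}
    return {
        "plots": read_plots(directory / "plots.csv"),
        "occurrences": read_occurrences(directory / "occurrences.csv"),
        "checklist": read_checklist(directory / "checklist.csv"),
        "layers": layers,
        "manifest": manifest,
    }


def write_labels_table(sites, path) -> Path:
    """Write diversity labels as plot_id, alpha, beta, gamma, radius_m, N."""
    path = Path(path)
    df = pd.DataFrame({
        "plot_id": [s.plot_id for s in sites],
        "alpha": [s.alpha for s in sites],
        "beta": [s.beta for s in sites],
        "gamma": [s.gamma for s in sites],
        "radius_m": [s.radius for s in sites],
        "N": [s.N for s in sites],
    })
    df.to_csv(path, index=False)
    return path


def read_labels_table(path) -> pd.DataFrame:
    df = _read_table(path)
    _require_columns(df, ("plot_id", "alpha", "beta", "gamma", "radius_m", "N"), path)
    return df


def write_feature_table(table, path, scaler_path=None) -> Path:
    """Write raw feature values (header = feature names); scaler as JSON."""
    path = Path(path)
    table.to_frame().rename_axis("site_id").to_csv(path)
    if scaler_path is not None and table.scaler is not None:
        Path(scaler_path).write_text(json.dumps(
            {k: list(v) for k, v in table.scaler.items()}, indent=2))
    return path


def write_grid_table(grid, path) -> Path:
    """Write a per-cell prediction table (x, y, mean, sd, cv, mask)."""
    path = Path(path)
    grid.to_frame().to_csv(path, index=False)
    return path


def write_manifest(config: RunConfig, path, extra: dict | None = None) -> Path:
    """Machine-readable run manifest: full config + seeds (+ extras)."""
    path = Path(path)
    payload = asdict(config)
    payload["metrics"] = list(config.metrics)
    if extra:
        payload.update(extra)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
    return path
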