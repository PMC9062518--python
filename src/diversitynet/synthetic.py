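"""Self-contained synthetic landscapes with a known diversity–environment link.

The generator emulates the structure of the real training inputs — vegetation
plots with complete species inventories (areas 50–10,000 m², spatially
clustered sites), occurrence points with spatially uneven sampling density,
smooth environmental raster surfaces, and an accepted-name checklist — while
keeping the data-generating process known, so every downstream stage
(labeling, feature assembly, model training, prediction) can be tested
without external downloads.

The stated world:

* environmental layers are sums of low-frequency sinusoids (smooth and
  spatially autocorrelated, like bioclim surfaces);
* expected plot richness is a deterministic increasing function of one
  designated layer (BIO1) and of log plot area, giving the model a learnable
  species–area relationship: ``μ = base · exp(g · e(x, y)) · (area/500)^z``
  with z = 0.25, a typical species–area exponent;
* realized richness is Poisson around μ (floored at one species);
* species composition is drawn from a pool whose members have spatially
  decaying availability, so nearby plots share species (beta diversity is
  neither 0 nor 1);
* occurrence density follows an intensity ∝ exp(bias · human-footprint),
  emulating roadside/city sampling bias, and a configurable fraction of
  records violates each cleaning rule (fossils, non-human basis, geospatial
  issue flags, non-binomial names, names missing from the checklist).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .labels import PlotRecord
from .projection import inverse_cea
from .raster import RasterLayer, write_raster

#: Layer names in generation order; the first 21 cover every raster feature.
LAYER_NAMES: tuple[str, ...] = ("Human footprint", "Elevation") + tuple(
    f"BIO{i}" for i in range(1, 20))

#: The environmental layer that drives expected richness.
RICHNESS_DRIVER = "BIO1"

SPECIES_AREA_EXPONENT = 0.25
BASE_RICHNESS = 15.0
REFERENCE_AREA = 500.0  # most common plot size in real vegetation-plot data


@dataclass(frozen=True)
class LandscapeConfig:
    """Parameters of one synthetic landscape."""

    seed: int = 0
    extent: tuple[float, float, float, float] = (0.0, 0.0, 200_000.0, 200_000.0)
    n_plots: int = 800
    n_species_pool: int = 400
    plot_area_range: tuple[float, float] = (50.0, 10_000.0)
    richness_gradient_strength: float = 1.5
    occurrence_density_bias: float = 2.0
    n_env_layers: int = 21
    n_occurrences: int = 5000
    contamination: float = 0.12
    checklist_noise_fraction: float = 0.10
    n_plot_clusters: int = 15
    raster_cell_size: float = 2_000.0
    composition_decay_m: float = 10_000.0

    def __post_init__(self) -> None:
        xmin, ymin, xmax, ymax = self.extent
        if xmax <= xmin or ymax <= ymin:
            raise ValueError(f"degenerate extent {self.extent}")
        if self.n_plots < 2:
            raise ValueError("n_plots must be at least 2")
        lo, hi = self.plot_area_range
        if not (0 < lo <= hi):
            raise ValueError("invalid plot_area_range")
        if self.richness_gradient_strength < 0 or self.occurrence_density_bias < 0:
            raise ValueError("gradient strength and density bias must be non-negative")
        if not (1 <= self.n_env_layers <= len(LAYER_NAMES)):
            raise ValueError(f"n_env_layers must be in [1, {len(LAYER_NAMES)}]")


@dataclass
class SyntheticLandscape:
    """Generated rasters, plots, occurrences, checklist and the known truth."""

    config: LandscapeConfig
    env_rasters: dict[str, RasterLayer]
    plots: list[PlotRecord]
    occurrences: pd.DataFrame
    checklist: pd.DataFrame
    truth: np.ndarray  # per-plot expected richness μ


def _smooth_field(rng: np.random.Generator, gx: np.ndarray, gy: np.ndarray,
                  extent, n_waves: int = 5) -> np.ndarray:
    """Smooth autocorrelated surface in [0, 1]: sum of low-frequency sinusoids."""
    xmin, ymin, xmax, ymax = extent
    width, height = xmax - xmin, ymax - ymin
    u = (gx - xmin) / width
    v = (gy - ymin) / height
    surface = np.zeros_like(u)
    for _ in range(n_waves):
        fx, fy = rng.uniform(0.5, 3.0, size=2)
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.5, 1.0)
        surface += amp * np.sin(2 * np.pi * (fx * u + fy * v) + phase)
    lo, hi = surface.min(), surface.max()
    return (surface - lo) / (hi - lo) if hi > lo else np.zeros_like(surface)


def _env_value(layer: RasterLayer, x, y, lo: float, hi: float):
    """Layer value at points, rescaled back to [0, 1] given its stated range."""
    return (layer.value_at(x, y) - lo) / (hi - lo) if hi > lo else 0.0


# plausible value ranges per layer so rasters look like real units
_LAYER_RANGES = {"Human footprint": (0.0, 50.0), "Elevation": (0.0, 1500.0),
                 "BIO1": (5.0, 30.0), "BIO12": (100.0, 3000.0)}


def generate_landscape(config: LandscapeConfig) -> SyntheticLandscape:
    """Generate a reproducible synthetic landscape from a config."""
    rng = np.random.default_rng(config.seed)
    xmin, ymin, xmax, ymax = config.extent

    # --- environmental rasters ---------------------------------------
    cell = config.raster_cell_size
    ncol = max(2, int(np.ceil((xmax - xmin) / cell)))
    nrow = max(2, int(np.ceil((ymax - ymin) / cell)))
    cols = xmin + (np.arange(ncol) + 0.5) * cell
    rows = ymax - (np.arange(nrow) + 0.5) * cell
    gx, gy = np.meshgrid(cols, rows)
    layers: dict[str, RasterLayer] = {}
    layer_ranges: dict[str, tuple[float, float]] = {}
    for name in LAYER_NAMES[: config.n_env_layers]:
        field01 = _smooth_field(rng, gx, gy, config.extent)
        lo, hi = _LAYER_RANGES.get(name, (0.0, 100.0))
        layers[name] = RasterLayer(name, lo + field01 * (hi - lo), xmin, ymax, cell)
        layer_ranges[name] = (lo, hi)

    # --- species pool with spatially decaying availability ------------
    n_pool = config.n_species_pool
    genus = rng.integers(0, max(1, n_pool // 6), size=n_pool)
    pool_names = np.array(
        [f"genus{g:03d} species{s:03d}" for s, g in enumerate(genus)])
    pool_xy = np.column_stack([
        rng.uniform(xmin, xmax, n_pool), rng.uniform(ymin, ymax, n_pool)])

    def availability(px: float, py: float) -> np.ndarray:
        d = np.hypot(pool_xy[:, 0] - px, pool_xy[:, 1] - py)
        return np.exp(-d / config.composition_decay_m) + 0.02

    # --- spatially clustered plots ------------------------------------
    n_clusters = min(config.n_plot_clusters, config.n_plots)
    centers = np.column_stack([
        rng.uniform(xmin, xmax, n_clusters), rng.uniform(ymin, ymax, n_clusters)])
    cluster_sd = 0.02 * min(xmax - xmin, ymax - ymin)
    assignment = rng.integers(0, n_clusters, size=config.n_plots)
    # 1 m inset keeps edge points inside the rasters even after a lon/lat
    # round trip through fixture files
    px = np.clip(centers[assignment, 0] + rng.normal(0, cluster_sd, config.n_plots),
                 xmin + 1.0, xmax - 1.0)
    py = np.clip(centers[assignment, 1] + rng.normal(0, cluster_sd, config.n_plots),
                 ymin + 1.0, ymax - 1.0)
    log_lo, log_hi = np.log(config.plot_area_range[0]), np.log(config.plot_area_range[1])
    areas = np.exp(rng.uniform(log_lo, log_hi, config.n_plots))

    driver = layers.get(RICHNESS_DRIVER, layers[next(iter(layers))])
    driver_lo, driver_hi = layer_ranges.get(RICHNESS_DRIVER,
                                            next(iter(layer_ranges.values())))
    env01 = _env_value(driver, px, py, driver_lo, driver_hi)
    mu = (BASE_RICHNESS
          * np.exp(config.richness_gradient_strength * (env01 - 0.5))
          * (areas / REFERENCE_AREA) ** SPECIES_AREA_EXPONENT)
    alpha = np.maximum(1, rng.poisson(mu))
    alpha = np.minimum(alpha, n_pool)

    plots: list[PlotRecord] = []
    for i in range(config.n_plots):
        w = availability(px[i], py[i])
        # weighted sampling without replacement via the Gumbel-top-k trick
        keys = np.log(w) + rng.gumbel(size=n_pool)
        chosen = np.argpartition(-keys, alpha[i] - 1)[: alpha[i]]
        plots.append(PlotRecord(
            plot_id=f"plot_{i:05d}", x=float(px[i]), y=float(py[i]),
            area=float(areas[i]), species=frozenset(pool_names[chosen])))

    # --- occurrence points with uneven sampling density ---------------
    hf = layers.get("Human footprint", driver)
    hf_lo, hf_hi = layer_ranges.get("Human footprint", (driver_lo, driver_hi))
    flat = _env_value(hf, gx.ravel(), gy.ravel(), hf_lo, hf_hi)
    weights = np.exp(config.occurrence_density_bias * flat)
    weights /= weights.sum()
    cells = rng.choice(len(flat), size=config.n_occurrences, p=weights)
    ox = gx.ravel()[cells] + rng.uniform(-cell / 2, cell / 2, config.n_occurrences)
    oy = gy.ravel()[cells] + rng.uniform(-cell / 2, cell / 2, config.n_occurrences)
    ox = np.clip(ox, xmin + 1.0, xmax - 1.0)
    oy = np.clip(oy, ymin + 1.0, ymax - 1.0)
    occ_species = []
    for i in range(config.n_occurrences):
        w = availability(ox[i], oy[i])
        occ_species.append(pool_names[rng.choice(n_pool, p=w / w.sum())])
    occ = pd.DataFrame({
        "species": occ_species, "x": ox, "y": oy,
        "basis_of_record": "HUMAN_OBSERVATION",
        "issue_flags": "", "is_fossil": False,
    })

    # contaminate a fraction of rows, one violation type each
    n_bad = int(round(config.contamination * config.n_occurrences))
    if n_bad:
        bad = rng.choice(config.n_occurrences, size=n_bad, replace=False)
        kinds = rng.integers(0, 5, size=n_bad)
        occ.loc[bad[kinds == 0], "is_fossil"] = True
        occ.loc[bad[kinds == 1], "basis_of_record"] = "PRESERVED_SPECIMEN"
        occ.loc[bad[kinds == 2], "issue_flags"] = "COORDINATE_ROUNDED"
        occ.loc[bad[kinds == 3], "species"] = [
            s.split()[0] for s in occ.loc[bad[kinds == 3], "species"]]
        occ.loc[bad[kinds == 4], "species"] = [
            f"phantomgenus species{i:03d}" for i in range(int((kinds == 4).sum()))]

    # --- checklist: full pool plus unmatched noise names ---------------
    n_noise = int(round(config.checklist_noise_fraction * n_pool))
    noise = [f"ghostgenus species{i:03d}" for i in range(n_noise)]
    checklist = pd.DataFrame({"accepted_name": np.concatenate([pool_names, noise])})

    return SyntheticLandscape(config=config, env_rasters=layers, plots=plots,
                              occurrences=occ, checklist=checklist, truth=mu)


def write_fixture(landscape: SyntheticLandscape, directory,
                  raster_format: str = "tif") -> dict[str, Path]:
    """Write a landscape as delimited text + rasters; round-trips through
    :mod:`diversitynet.io` readers.

    Plot and occurrence coordinates are written as lon/lat degrees (inverse
    CEA of the internal projected coordinates). Returns the map of written
    paths; output is byte-identical for identical landscapes.
    """
    if not landscape.plots:
        raise ValueError("cannot write an empty landscape (no plots)")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    lon, lat = inverse_cea(np.array([p.x for p in landscape.plots]),
                           np.array([p.y for p in landscape.plots]))
    plots_df = pd.DataFrame({
        "plot_id": [p.plot_id for p in landscape.plots],
        "lon": lon, "lat": lat,
        "area_m2": [p.area for p in landscape.plots],
        "species": [";".join(sorted(p.species)) for p in landscape.plots],
    })
    paths["plots"] = directory / "plots.csv"
    plots_df.to_csv(paths["plots"], index=False, float_format="%.10f")

    olon, olat = inverse_cea(landscape.occurrences["x"].to_numpy(),
                             landscape.occurrences["y"].to_numpy())
    occ_df = landscape.occurrences.drop(columns=["x", "y"]).copy()
    occ_df.insert(1, "lon", olon)
    occ_df.insert(2, "lat", olat)
    paths["occurrences"] = directory / "occurrences.csv"
    occ_df.to_csv(paths["occurrences"], index=False, float_format="%.10f")

    paths["checklist"] = directory / "checklist.csv"
    landscape.checklist.to_csv(paths["checklist"], index=False)

    truth_df = pd.DataFrame({
        "plot_id": [p.plot_id for p in landscape.plots],
        "expected_richness": landscape.truth,
    })
    paths["truth"] = directory / "truth.csv"
    truth_df.to_csv(paths["truth"], index=False, float_format="%.10f")

    layer_files = {}
    for name, layer in landscape.env_rasters.items():
        fname = "env_" + "".join(c if c.isalnum() else "_" for c in name)
        fpath = directory / f"{fname}.{raster_format}"
        write_raster(layer, fpath)
        layer_files[name] = fpath.name
        paths[f"raster:{name}"] = fpath

    manifest = {
        "config": asdict(landscape.config),
        "layers": layer_files,
        "files": {k: v.name for k, v in paths.items() if not k.startswith("raster:")},
    }
    paths["manifest"] = directory / "landscape.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths
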