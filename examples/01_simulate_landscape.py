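"""Simulate a synthetic landscape and inspect its built-in diversity structure.

The generator produces environmental rasters, clustered vegetation plots with
species inventories, biased occurrence points, and an accepted-name checklist
— with a known environment→richness relationship to test everything against.
"""

import numpy as np

from diversitynet import LandscapeConfig, generate_landscape, write_fixture

config = LandscapeConfig(seed=7, n_plots=400, n_occurrences=2_000)
landscape = generate_landscape(config)

alphas = np.array([len(p.species) for p in landscape.plots])
areas = np.array([p.area for p in landscape.plots])
print(f"plots: {len(landscape.plots)}, species pool: {config.n_species_pool}")
print(f"plot areas: {areas.min():.0f}-{areas.max():.0f} m^2 "
      f"(training-range bounds are 50-10,000 m^2)")
print(f"realized richness: {alphas.min()}-{alphas.max()} species per plot")
print(f"raster layers: {len(landscape.env_rasters)} "
      f"({', '.join(list(landscape.env_rasters)[:4])}, ...)")

# richness grows with plot area -- the species-area relationship the
# downstream network is supposed to learn
small = alphas[areas < np.median(areas)].mean()
large = alphas[areas >= np.median(areas)].mean()
print(f"mean richness below/above median plot area: {small:.1f} / {large:.1f} "
      "(larger plots hold more species)")

paths = write_fixture(landscape, "scratch/landscape_fixture")
print(f"fixture written: {len(paths)} files under scratch/landscape_fixture/")
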