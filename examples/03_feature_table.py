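"""Assemble and scale the per-site feature table.

Occurrence records are first cleaned (human observations only, no geospatial
issue flags, binomial names cross-checked against the checklist), then counted
in a 10 × 10 km window per site as a sampling-effort proxy. Climatic and
anthropogenic values come from raster lookup; plot size and neighborhood
radius complete the table. Everything is min-max scaled to [0, 1] on the
training rows.
"""

import numpy as np

from diversitynet import (
    LandscapeConfig, assemble_features, filter_occurrences, fit_apply_scaler,
    generate_landscape, label_all_sites,
)

landscape = generate_landscape(LandscapeConfig(seed=7, n_plots=400,
                                               n_occurrences=2_000))
sites = label_all_sites(landscape.plots, N=10)

occ = filter_occurrences(landscape.occurrences, landscape.checklist)
print(f"occurrence cleaning kept {len(occ)} of {len(landscape.occurrences)} records "
      "(fossils, non-human-observation records, flagged coordinates,")
print("  non-binomial names and names missing from the checklist are dropped)")

for feature_set in ("full27", "subset8", "subset6"):
    table = assemble_features(sites, landscape.plots, occ,
                              landscape.env_rasters, feature_set)
    print(f"{feature_set}: {table.values.shape[1]} columns -> "
          f"{', '.join(table.feature_names[:4])}, ...")

table = fit_apply_scaler(assemble_features(sites, landscape.plots, occ,
                                           landscape.env_rasters, "full27"))
scaled, n_out = table.transform()
print(f"scaled feature matrix: {scaled.shape}, values in "
      f"[{scaled.min():.2f}, {scaled.max():.2f}], {n_out} outside the fitted range")
effort = table.values[:, list(table.feature_names).index("Sampling effort")]
print(f"sampling effort per site (records in a 10 km window): "
      f"median {np.median(effort):.0f}, max {effort.max():.0f}")
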