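import numpy as np
import pytest

from diversitynet import (
    LandscapeConfig,
    PlotRecord,
    filter_occurrences,
    generate_landscape,
    label_all_sites,
)


def make_plot(plot_id, x, y, species, area=500.0):
    return PlotRecord(plot_id=plot_id, x=float(x), y=float(y), area=area,
                      species=frozenset(species))


def random_plots(rng, n, extent=100_000.0, pool_size=30, max_richness=12):
    """Random plots with species drawn from a small shared pool."""
    pool = [f"sp{i:02d} x{i:02d}" for i in range(pool_size)]
    plots = []
    for i in range(n):
        k = rng.integers(1, max_richness + 1)
        species = rng.choice(pool, size=k, replace=False)
        plots.append(make_plot(f"p{i:04d}", rng.uniform(0, extent),
                               rng.uniform(0, extent), species))
    return plots


@pytest.fixture(scope="session")
def landscape():
    """Small shared landscape for integration-style tests."""
    return generate_landscape(LandscapeConfig(
        seed=42, n_plots=200, n_occurrences=1200,
        extent=(0.0, 0.0, 120_000.0, 120_000.0)))


@pytest.fixture(scope="session")
def labeled_sites(landscape):
    return label_all_sites(landscape.plots, N=10)


@pytest.fixture(scope="session")
def clean_occurrences(landscape):
    return filter_occurrences(landscape.occurrences, landscape.checklist)
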