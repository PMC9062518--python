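"""Feature construction: CEA projection, occurrence filtering, window counts,
raster extraction, named feature sets, and min-max scaling."""

import numpy as np
import pandas as pd
import pytest

from diversitynet import (
    EARTH_RADIUS_M,
    FULL27,
    SUBSET6,
    SUBSET8,
    FeatureTable,
    RasterLayer,
    assemble_features,
    extract_raster_values,
    filter_occurrences,
    fit_apply_scaler,
    inverse_cea,
    project_cea,
    window_counts,
)
from diversitynet.features import _window_counts_all


class TestProjection:
    def test_origin_maps_to_origin(self):
        assert project_cea(0.0, 0.0) == (0.0, 0.0)

    def test_round_trip_precision(self):
        rng = np.random.default_rng(0)
        lon = rng.uniform(-180, 180, 100)
        lat = rng.uniform(-89.9, 89.9, 100)
        x, y = project_cea(lon, lat)
        lon2, lat2 = inverse_cea(x, y)
        assert np.allclose(lon2, lon, atol=1e-9)
        assert np.allclose(lat2, lat, atol=1e-9)

    def test_latitude_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            project_cea(0.0, 91.0)

    def test_equal_area_at_standard_parallel(self):
        """Projected area of a 1°×1° cell at the standard parallel matches the
        true spherical area (numerical integration oracle) within 0.5%."""
        sp = -30.0
        lon0, lat0 = 10.0, sp - 0.5
        x0, y0 = project_cea(lon0, lat0, sp)
        x1, y1 = project_cea(lon0 + 1.0, lat0 + 1.0, sp)
        projected_area = abs((x1 - x0) * (y1 - y0))
        # spherical area: R^2 * dλ * ∫cos(φ)dφ over the cell
        lats = np.linspace(np.deg2rad(lat0), np.deg2rad(lat0 + 1.0), 10_001)
        spherical_area = (EARTH_RADIUS_M ** 2 * np.deg2rad(1.0)
                          * np.trapezoid(np.cos(lats), lats))
        assert projected_area == pytest.approx(spherical_area, rel=0.005)

    def test_equal_area_everywhere(self):
        """CEA preserves area at every latitude, not just the standard parallel."""
        sp = -30.0
        for lat0 in (-60.0, 0.0, 45.0):
            x0, y0 = project_cea(0.0, lat0, sp)
            x1, y1 = project_cea(1.0, lat0 + 1.0, sp)
            lats = np.linspace(np.deg2rad(lat0), np.deg2rad(lat0 + 1.0), 10_001)
            spherical = (EARTH_RADIUS_M ** 2 * np.deg2rad(1.0)
                         * np.trapezoid(np.cos(lats), lats))
            assert abs((x1 - x0) * (y1 - y0)) == pytest.approx(spherical, rel=1e-6)


def occ_frame(rows):
    return pd.DataFrame(rows, columns=["species", "x", "y", "basis_of_record",
                                       "issue_flags", "is_fossil"])


CHECKLIST = ["Eucalyptus regnans", "Acacia dealbata", "Banksia serrata"]


class TestFilterOccurrences:
    def test_non_binomial_dropped(self):
        df = occ_frame([("Eucalyptus", 0, 0, "HUMAN_OBSERVATION", "", False)])
        assert len(filter_occurrences(df, CHECKLIST)) == 0

    def test_fossil_dropped_despite_valid_name(self):
        df = occ_frame([("Eucalyptus regnans", 0, 0, "HUMAN_OBSERVATION", "", True)])
        assert len(filter_occurrences(df, CHECKLIST)) == 0

    def test_flagged_and_non_human_dropped(self):
        df = occ_frame([
            ("Eucalyptus regnans", 0, 0, "HUMAN_OBSERVATION", "COORDINATE_ROUNDED", False),
            ("Acacia dealbata", 0, 0, "PRESERVED_SPECIMEN", "", False),
            ("Banksia serrata", 0, 0, "HUMAN_OBSERVATION", "", False),
        ])
        out = filter_occurrences(df, CHECKLIST)
        assert out["species"].tolist() == ["Banksia serrata"]

    def test_matches_row_by_row_predicate_oracle(self):
        rng = np.random.default_rng(21)
        names = CHECKLIST + ["Eucalyptus", "Notinchecklist species", "Acacia x y z"]
        rows = []
        for _ in range(100):
            rows.append((
                names[rng.integers(len(names))], 0.0, 0.0,
                rng.choice(["HUMAN_OBSERVATION", "PRESERVED_SPECIMEN"]),
                rng.choice(["", "COORDINATE_ROUNDED"]),
                bool(rng.integers(2)),
            ))
        df = occ_frame(rows)
        checklist_norm = {n.casefold() for n in CHECKLIST}

        def keep(row):
            return (not row.is_fossil
                    and row.basis_of_record == "HUMAN_OBSERVATION"
                    and row.issue_flags == ""
                    and len(row.species.split()) == 2
                    and row.species.casefold() in checklist_norm)

        expected = sum(keep(r) for r in df.itertuples())
        assert len(filter_occurrences(df, CHECKLIST)) == expected

    def test_subset_and_idempotent(self):
        rng = np.random.default_rng(22)
        df = occ_frame([
            (rng.choice(CHECKLIST + ["Eucalyptus"]), 0, 0,
             "HUMAN_OBSERVATION", rng.choice(["", "ZERO_COORDINATE"]), False)
            for _ in range(50)])
        once = filter_occurrences(df, CHECKLIST)
        assert set(once.index).issubset(set(df.index))
        pd.testing.assert_frame_equal(filter_occurrences(once, CHECKLIST), once)

    def test_empty_checklist_rejected(self):
        with pytest.raises(ValueError):
            filter_occurrences(occ_frame([]), [])


class TestWindowCounts:
    def test_containment(self):
        inside = [(f"Sp a{i}", 100 + i, 200.0) for i in range(5)]
        outside = [("Sp b", 20_000.0, 0.0), ("Sp c", 0.0, -20_000.0)]
        df = pd.DataFrame([(s, x, y) for s, x, y in inside + outside],
                          columns=["species", "x", "y"])
        n_rec, n_sp = window_counts(df, center=(0.0, 0.0), window_side=10_000.0)
        assert n_rec == 5
        assert n_sp == 5

    def test_single_species(self):
        df = pd.DataFrame([("Same species", i, 0.0) for i in range(10)],
                          columns=["species", "x", "y"])
        assert window_counts(df, (0.0, 0.0), 10_000.0) == (10, 1)

    def test_half_open_max_edges(self):
        df = pd.DataFrame([("Sp a", 5_000.0, 0.0), ("Sp b", -5_000.0, 0.0)],
                          columns=["species", "x", "y"])
        n_rec, _ = window_counts(df, (0.0, 0.0), 10_000.0)
        assert n_rec == 1  # +s/2 edge excluded, −s/2 edge included

    def test_matches_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(31)
        df = pd.DataFrame({
            "species": [f"G{i % 40:02d} s{i % 40:02d}" for i in range(500)],
            "x": rng.uniform(-30_000, 30_000, 500),
            "y": rng.uniform(-30_000, 30_000, 500),
        })
        centers = rng.uniform(-20_000, 20_000, size=(20, 2))
        for cx, cy in centers:
            n_rec, n_sp = window_counts(df, (cx, cy), 10_000.0)
            in_win = [(s, x, y) for s, x, y in zip(df.species, df.x, df.y)
                      if cx - 5_000 <= x < cx + 5_000 and cy - 5_000 <= y < cy + 5_000]
            assert n_rec == len(in_win)
            assert n_sp == len({s.casefold() for s, _, _ in in_win})
        # vectorized many-center path agrees with the scalar one
        n_rec_all, n_sp_all = _window_counts_all(df, centers, 10_000.0)
        for i, (cx, cy) in enumerate(centers):
            assert (n_rec_all[i], n_sp_all[i]) == window_counts(df, (cx, cy), 10_000.0)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(33)
        df = pd.DataFrame({
            "species": [f"G{i:02d} s{i:02d}" for i in range(100)],
            "x": rng.uniform(0, 20_000, 100), "y": rng.uniform(0, 20_000, 100)})
        base = window_counts(df, (10_000.0, 10_000.0), 8_000.0)
        shifted = df.assign(x=df.x + 123_456.0, y=df.y - 7_890.0)
        assert window_counts(shifted, (10_000.0 + 123_456.0, 10_000.0 - 7_890.0),
                             8_000.0) == base


class TestRasterExtraction:
    def grid(self):
        data = np.arange(20, dtype=float).reshape(4, 5)
        return RasterLayer("test", data, x_origin=0.0, y_origin=4_000.0,
                           cell_size=1_000.0)

    def test_exact_cell_center_hit(self):
        layer = self.grid()
        # center of row 1, col 2 -> value 1*5+2 = 7
        assert layer.value_at(2_500.0, 2_500.0)[0] == 7.0

    def test_constant_raster_gives_constant_column(self):
        layer = RasterLayer("const", np.full((3, 3), 4.2), 0, 3_000.0, 1_000.0)
        rng = np.random.default_rng(1)
        vals = extract_raster_values({"const": layer},
                                     rng.uniform(0, 3_000, 50),
                                     rng.uniform(0, 3_000, 50))
        assert np.all(vals["const"] == 4.2)

    def test_matches_index_arithmetic_oracle(self):
        layer = self.grid()
        rng = np.random.default_rng(2)
        xs = rng.uniform(0, 4_999.999, 50)
        ys = rng.uniform(0.001, 4_000, 50)
        got = layer.value_at(xs, ys)
        for x, y, v in zip(xs, ys, got):
            col = int(np.floor(x / 1_000.0))
            row = int(np.floor((4_000.0 - y) / 1_000.0))
            assert v == layer.data[row, col]

    def test_point_outside_named_in_error(self):
        with pytest.raises(ValueError, match="outside raster 'test'"):
            self.grid().value_at(99_999.0, 0.0)

    def test_nodata_propagates_as_nan(self):
        data = np.array([[1.0, -9999.0], [3.0, 4.0]])
        layer = RasterLayer("nd", data, 0, 2_000.0, 1_000.0, nodata=-9999.0)
        vals = layer.value_at([500.0, 1_500.0], [1_500.0, 1_500.0])
        assert vals[0] == 1.0 and np.isnan(vals[1])


class TestAssembleFeatures:
    def test_full27_columns(self, landscape, labeled_sites, clean_occurrences):
        table = assemble_features(labeled_sites, landscape.plots,
                                  clean_occurrences, landscape.env_rasters, "full27")
        assert table.feature_names == FULL27
        assert table.values.shape == (len(labeled_sites), 27)

    def test_subset6_has_no_coordinates(self, landscape, labeled_sites):
        table = assemble_features(labeled_sites, landscape.plots, None,
                                  landscape.env_rasters, "subset6")
        assert table.feature_names == SUBSET6
        assert len(table.feature_names) == 6
        assert "Longitude" not in table.feature_names
        assert "Latitude" not in table.feature_names

    def test_subset8_minus_subset6_is_coordinates(self):
        assert set(SUBSET8) - set(SUBSET6) == {"Longitude", "Latitude"}
        assert set(SUBSET8) < set(FULL27)

    def test_unknown_feature_set_rejected(self, landscape, labeled_sites):
        with pytest.raises(ValueError, match="unknown feature set"):
            assemble_features(labeled_sites, landscape.plots, None,
                              landscape.env_rasters, "subset99")

    def test_missing_layer_named(self, landscape, labeled_sites):
        layers = {k: v for k, v in landscape.env_rasters.items() if k != "BIO12"}
        with pytest.raises(ValueError, match="BIO12"):
            assemble_features(labeled_sites, landscape.plots, None, layers, "subset6")

    def test_deterministic_and_order_stable(self, landscape, labeled_sites,
                                            clean_occurrences):
        t1 = assemble_features(labeled_sites, landscape.plots, clean_occurrences,
                               landscape.env_rasters, "subset8")
        t2 = assemble_features(labeled_sites, landscape.plots, clean_occurrences,
                               landscape.env_rasters, "subset8")
        assert t1.feature_names == t2.feature_names
        assert np.array_equal(t1.values, t2.values)

    def test_plot_size_and_radius_columns(self, landscape, labeled_sites):
        table = assemble_features(labeled_sites, landscape.plots, None,
                                  landscape.env_rasters, "subset6")
        by_id = {p.plot_id: p for p in landscape.plots}
        j_size = table.feature_names.index("Vegetation plot size")
        j_rad = table.feature_names.index("Neighborhood radius")
        for i, site in enumerate(labeled_sites):
            assert table.values[i, j_size] == by_id[site.plot_id].area
            assert table.values[i, j_rad] == site.radius


class TestScaler:
    def table(self, column):
        vals = np.asarray(column, dtype=float)[:, None]
        return FeatureTable(site_ids=[f"s{i}" for i in range(len(vals))],
                            feature_names=("f",), values=vals)

    def test_min_max_definition(self):
        scaled, n_out = fit_apply_scaler(self.table([0, 5, 10])).transform()
        assert np.allclose(scaled[:, 0], [0.0, 0.5, 1.0])
        assert n_out == 0

    def test_constant_column_maps_to_zero(self):
        scaled, _ = fit_apply_scaler(self.table([7, 7, 7])).transform()
        assert np.all(scaled == 0.0)

    def test_out_of_range_not_clipped_and_counted(self):
        fitted = fit_apply_scaler(self.table([0, 5, 10, 12]), fit_rows=[0, 1, 2])
        scaled, n_out = fitted.transform()
        assert scaled[3, 0] == pytest.approx(1.2)
        assert n_out == 1

    def test_affine_order_preserving(self):
        rng = np.random.default_rng(4)
        col = rng.normal(size=30)
        scaled, _ = fit_apply_scaler(self.table(col)).transform()
        assert np.array_equal(np.argsort(scaled[:, 0]), np.argsort(col))

    def test_training_rows_land_in_unit_interval(self, landscape, labeled_sites,
                                                 clean_occurrences):
        table = assemble_features(labeled_sites, landscape.plots, clean_occurrences,
                                  landscape.env_rasters, "full27")
        fit_rows = np.arange(0, len(labeled_sites), 2)
        scaled, _ = fit_apply_scaler(table, fit_rows).transform()
        sub = scaled[fit_rows]
        assert sub.min() >= 0.0 and sub.max() <= 1.0
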