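"""Lineage distribution models: partition contracts and worked examples."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from lineagemaps import (
    Grid,
    LineageDistributionModel,
    OccurrenceTable,
    apply_min_value,
    fit_ldm,
    make_landscape,
    make_lineage_points,
    transect_profile,
    Barrier,
    GaussianPatch,
    LandscapeSpec,
)


def table_on_grid(cells, origin_y):
    """Records placed at the centres of (species, lineage, row, col) cells."""
    recs = []
    for species, lineage, r, c in cells:
        recs.append((species, lineage, c + 0.5, origin_y - r - 0.5))
    return OccurrenceTable.from_records(recs)


class TestFitLdm:
    def test_single_lineage_returns_sdm_bit_identically(self):
        rng = np.random.default_rng(5)
        sdm = Grid(rng.random((12, 12)), origin_y=12.0)
        table = table_on_grid([("sp", "only", 3, 3), ("sp", "only", 8, 8)],
                              origin_y=12.0)
        ms = fit_ldm(sdm, table, "sp")
        assert ms.lineages == ["only"]
        assert np.array_equal(ms.models["only"].values, sdm.values)

    def test_equidistant_cell_splits_evenly(self):
        # uniform landscape, sources symmetric about the centre column
        sdm = Grid(np.full((5, 9), 0.8), origin_y=5.0)
        table = table_on_grid([("sp", "west", 2, 1), ("sp", "east", 2, 7)],
                              origin_y=5.0)
        ms = fit_ldm(sdm, table, "sp")
        mid = (2, 4)
        assert ms.models["west"].values[mid] == pytest.approx(0.4, abs=1e-12)
        assert ms.models["east"].values[mid] == pytest.approx(0.4, abs=1e-12)

    def test_inverse_square_worked_example(self):
        """Cost distances 1 and 2 at a perfectly suitable cell -> 0.8 / 0.2.

        On a 1x3 grid the test cell (suitability 1, cost 0) sits between
        a source of lineage A on a cell of cost 2 (edge weight 1) and a
        source of lineage B on a cell of cost 4 (edge weight 2).
        """
        sdm = Grid(np.array([[math.exp(-2.0), 1.0, math.exp(-4.0)]]),
                   origin_y=1.0)
        table = table_on_grid([("sp", "A", 0, 0), ("sp", "B", 0, 2)],
                              origin_y=1.0)
        ms = fit_ldm(sdm, table, "sp")
        assert ms.models["A"].values[0, 1] == pytest.approx(0.8, abs=1e-12)
        assert ms.models["B"].values[0, 1] == pytest.approx(0.2, abs=1e-12)

    def test_source_cell_goes_fully_to_its_lineage(self):
        sdm = Grid(np.full((5, 9), 0.6), origin_y=5.0)
        table = table_on_grid([("sp", "a", 2, 1), ("sp", "b", 2, 7)],
                              origin_y=5.0)
        ms = fit_ldm(sdm, table, "sp")
        assert ms.models["a"].values[2, 1] == pytest.approx(0.6, abs=1e-15)
        assert ms.models["b"].values[2, 1] == 0.0

    def test_shared_source_cell_splits_equally(self):
        sdm = Grid(np.full((3, 3), 0.5), origin_y=3.0)
        table = table_on_grid([("sp", "a", 1, 1), ("sp", "b", 1, 1)],
                              origin_y=3.0)
        ms = fit_ldm(sdm, table, "sp")
        assert ms.models["a"].values[1, 1] == pytest.approx(0.25, abs=1e-15)
        assert ms.models["b"].values[1, 1] == pytest.approx(0.25, abs=1e-15)

    @pytest.mark.parametrize("seed", range(5))
    def test_conservation_on_random_landscapes(self, seed):
        rng = np.random.default_rng(seed)
        n_lineages = int(rng.integers(2, 6))
        spec = LandscapeSpec(
            shape=(30, 30),
            features=tuple(
                GaussianPatch(
                    center=(float(rng.uniform(4, 26)), float(rng.uniform(4, 26))),
                    sd=float(rng.uniform(3, 6)),
                )
                for _ in range(n_lineages)
            ),
        )
        landscape = make_landscape(spec)
        points = make_lineage_points(landscape, n_lineages, 4, seed=seed)
        ms = fit_ldm(landscape, points, "sp1")
        allocated = ~ms.unallocated_mask & ~landscape.nodata_mask
        np.testing.assert_allclose(
            ms.total()[allocated], landscape.values[allocated], atol=1e-9
        )
        assert np.all(ms.model_arrays() >= 0)

    def test_unreachable_lineage_gets_zero_weight(self):
        # hard barrier: lineage b cannot reach the left side
        vals = np.full((5, 5), 0.9)
        vals[:, 2] = 0.0
        sdm = Grid(vals, origin_y=5.0)
        table = table_on_grid([("sp", "a", 2, 0), ("sp", "b", 2, 4)],
                              origin_y=5.0)
        ms = fit_ldm(sdm, table, "sp")
        left = ms.models["b"].values[:, :2]
        assert np.all(left == 0.0)
        np.testing.assert_allclose(ms.models["a"].values[:, :2],
                                   vals[:, :2], atol=1e-12)

    def test_barrier_shifts_share_toward_connected_lineage(self):
        base = np.full((5, 7), 0.9)
        open_sdm = Grid(base.copy(), origin_y=5.0)
        blocked = base.copy()
        blocked[:, 2] = 1e-7  # below impassable threshold, between cell and A
        blocked_sdm = Grid(blocked, origin_y=5.0)
        table = table_on_grid([("sp", "A", 2, 0), ("sp", "B", 2, 6)],
                              origin_y=5.0)
        cell = (2, 4)
        ms_open = fit_ldm(open_sdm, table, "sp")
        ms_blocked = fit_ldm(blocked_sdm, table, "sp")
        assert (ms_blocked.models["A"].values[cell]
                <= ms_open.models["A"].values[cell])
        share_open = ms_open.models["B"].values[cell] / base[cell]
        share_blocked = ms_blocked.models["B"].values[cell] / blocked[cell]
        assert share_blocked >= share_open

    def test_relabelling_permutes_outputs(self, two_lineage_setup):
        landscape, points = two_lineage_setup
        ms = fit_ldm(landscape, points, "sp1")
        swapped_df = points.data.copy()
        swapped_df["lineage"] = swapped_df["lineage"].map(
            {"lin1": "lin2", "lin2": "lin1", "": ""})
        ms_swapped = fit_ldm(landscape, OccurrenceTable(swapped_df), "sp1")
        np.testing.assert_array_equal(ms.models["lin1"].values,
                                      ms_swapped.models["lin2"].values)
        np.testing.assert_array_equal(ms.models["lin2"].values,
                                      ms_swapped.models["lin1"].values)

    def test_no_labelled_records_error(self):
        sdm = Grid(np.full((3, 3), 0.5))
        with pytest.raises(ValueError):
            fit_ldm(sdm, OccurrenceTable.from_records(
                [("sp", "", 1.0, 1.0)]), "sp")


class TestApplyMinValue:
    def test_threshold_boundary_kept(self):
        sdm = Grid(np.array([[0.009, 0.010, 0.5]]), origin_y=1.0)
        table = table_on_grid([("sp", "only", 0, 1)], origin_y=1.0)
        ms = fit_ldm(sdm, table, "sp")
        filtered = apply_min_value(ms, 0.01)
        np.testing.assert_array_equal(filtered.models["only"].values,
                                      [[0.0, 0.010, 0.5]])
        assert filtered.min_value_applied

    def test_zero_threshold_is_identity(self, two_lineage_setup):
        landscape, points = two_lineage_setup
        ms = fit_ldm(landscape, points, "sp1")
        same = apply_min_value(ms, 0.0)
        for label in ms.lineages:
            np.testing.assert_array_equal(same.models[label].values,
                                          ms.models[label].values)
        assert not same.min_value_applied

    def test_all_below_threshold_warns(self):
        sdm = Grid(np.full((2, 2), 0.004), origin_y=2.0)
        table = table_on_grid([("sp", "only", 0, 0)], origin_y=2.0)
        ms = fit_ldm(sdm, table, "sp")
        with pytest.warns(UserWarning, match="all-zero"):
            filtered = apply_min_value(ms, 0.01)
        assert not np.any(filtered.models["only"].values)

    def test_negative_threshold_rejected(self, two_lineage_setup):
        landscape, points = two_lineage_setup
        ms = fit_ldm(landscape, points, "sp1")
        with pytest.raises(ValueError):
            apply_min_value(ms, -0.1)


class TestTransect:
    def test_total_equals_sdm_prefilter(self, two_lineage_setup):
        landscape, points = two_lineage_setup
        ms = fit_ldm(landscape, points, "sp1")
        line = [(r, 10) for r in range(40)]
        prof = transect_profile(ms, line)
        reachable = ~ms.unallocated_mask[[r for r, _ in line],
                                         [c for _, c in line]]
        np.testing.assert_allclose(
            prof["total"].to_numpy()[reachable],
            landscape.values[[r for r, _ in line], [c for _, c in line]][reachable],
            atol=1e-9,
        )

    def test_single_lineage_column_equals_total(self):
        sdm = Grid(np.full((4, 4), 0.3), origin_y=4.0)
        table = table_on_grid([("sp", "only", 1, 1)], origin_y=4.0)
        prof = transect_profile(fit_ldm(sdm, table, "sp"),
                                [(0, 0), (1, 1), (2, 2)])
        pd.testing.assert_series_equal(prof["only"], prof["total"],
                                       check_names=False)

    def test_symmetric_landscape_mirrors(self):
        # two identical patches, mirror-symmetric about the centre column
        spec = LandscapeSpec(
            shape=(9, 21),
            features=(GaussianPatch((4, 5), 2.5), GaussianPatch((4, 15), 2.5)),
        )
        landscape = make_landscape(spec)
        table = table_on_grid([("sp", "L", 4, 5), ("sp", "R", 4, 15)],
                              origin_y=9.0)
        ms = fit_ldm(landscape, table, "sp")
        line = [(4, c) for c in range(21)]
        prof = transect_profile(ms, line)
        np.testing.assert_allclose(prof["L"].to_numpy(),
                                   prof["R"].to_numpy()[::-1], atol=1e-9)

    def test_out_of_extent_cell_rejected(self, two_lineage_setup):
        landscape, points = two_lineage_setup
        ms = fit_ldm(landscape, points, "sp1")
        with pytest.raises(ValueError, match="outside"):
            transect_profile(ms, [(0, 0), (99, 0)])


class TestEstimator:
    def test_fit_sets_attributes_and_filters(self, two_lineage_setup):
        landscape, points = two_lineage_setup
        est = LineageDistributionModel(species="sp1").fit(landscape, points)
        assert est.n_lineages_ == 2
        assert set(est.models_) == {"lin1", "lin2"}
        assert est.model_set_.min_value_applied
        # filtered values never sit in (0, min_value)
        for g in est.models_.values():
            nz = g.values[g.values > 0]
            assert np.all(nz >= 0.01)

    def test_species_inferred_when_unambiguous(self, two_lineage_setup):
        landscape, points = two_lineage_setup
        est = LineageDistributionModel().fit(landscape, points)
        assert est.species_ == "sp1"

    def test_sklearn_param_protocol(self):
        est = LineageDistributionModel(exponent=3.0)
        assert clone(est).get_params()["exponent"] == 3.0
        est.set_params(min_value=0.05)
        assert est.get_params()["min_value"] == 0.05

    def test_unfitted_access_raises(self):
        with pytest.raises(AttributeError):
            LineageDistributionModel().transect([(0, 0)])
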