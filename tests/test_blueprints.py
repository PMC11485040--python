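"""Tract matrices and connectivity blueprints, including the exact
per-streamline oracle identity."""

import numpy as np
import pytest

from conftest import grid_of, mask_of

from tractspace.blueprints import (
    ConnectivityBlueprint,
    average_region_profile,
    build_blueprint,
    build_tract_matrix,
    exclude_region,
    group_average_blueprints,
    streamline_oracle_blueprint,
)
from tractspace.tracking import PathDistribution, TrackingConfig
from tractspace.tract_metrics import normalise


def npd_of(counts, n_valid, tract):
    counts = np.asarray(counts, dtype=float)
    pd_ = PathDistribution(counts=grid_of(counts), n_valid=n_valid,
                           n_seeded=max(n_valid, 1), seed=0,
                           config=TrackingConfig())
    return normalise(pd_, tract=tract)


@pytest.fixture()
def tiny_setup():
    """4x4x4 fine grid, 2 mm coarse grid fully inside the 'brain'."""
    coarse = mask_of(np.ones((2, 2, 2)), voxel=2.0)
    # voxel centers of the coarse grid sit at the block centers
    coarse.affine[:3, 3] = 0.5
    return coarse


class TestTractMatrix:
    def test_block_average_matches_manual_arithmetic(self, tiny_setup):
        counts = np.zeros((4, 4, 4))
        counts[0, 0, 0] = 8.0
        counts[1, 1, 1] = 4.0  # same 2x2x2 block
        tm = build_tract_matrix([npd_of(counts, 10, "t")], tiny_setup)
        # block sum 12 over block of 8 voxels, n_valid 10
        expected = 12.0 / (10 * 8)
        idx = np.flatnonzero(tm.voxel_indices == 0)
        assert tm.values[idx[0], 0] == pytest.approx(expected)

    def test_identical_tracts_give_identical_columns(self, tiny_setup):
        counts = np.random.default_rng(0).integers(0, 9, (4, 4, 4))
        tm = build_tract_matrix(
            [npd_of(counts, 7, "a"), npd_of(counts, 7, "b")], tiny_setup)
        assert np.array_equal(tm.values[:, 0], tm.values[:, 1])

    def test_zero_tract_gives_zero_column(self, tiny_setup):
        tm = build_tract_matrix([npd_of(np.zeros((4, 4, 4)), 5, "z")],
                                tiny_setup)
        assert np.all(tm.values == 0)

    def test_name_collision_rejected(self, tiny_setup):
        npd = npd_of(np.ones((4, 4, 4)), 5, "dup")
        with pytest.raises(ValueError, match="collision"):
            build_tract_matrix([npd, npd], tiny_setup)


class TestBuildBlueprint:
    def test_hand_matrix_product(self, tiny_setup):
        counts_a = np.zeros((4, 4, 4))
        counts_a[0, 0, 0] = 2
        counts_b = np.zeros((4, 4, 4))
        counts_b[3, 3, 3] = 6
        tm = build_tract_matrix(
            [npd_of(counts_a, 4, "a"), npd_of(counts_b, 12, "b")],
            tiny_setup)
        conn = np.zeros((2, 8), dtype=np.int64)
        conn[0, tm.voxel_indices[0]] = 3
        conn[1, tm.voxel_indices[-1]] = 5
        bp = build_blueprint(conn, tm, normalise=False)
        manual = conn[:, tm.voxel_indices].astype(float) @ tm.values
        assert np.allclose(bp.values, manual)

    def test_unit_row_connectivity_reproduces_tract_matrix_rows(
            self, tiny_setup):
        rng = np.random.default_rng(1)
        tm = build_tract_matrix(
            [npd_of(rng.integers(0, 9, (4, 4, 4)), 11, "a"),
             npd_of(rng.integers(0, 9, (4, 4, 4)), 13, "b")], tiny_setup)
        n = len(tm.voxel_indices)
        conn = np.zeros((n, 8), dtype=np.int64)
        conn[np.arange(n), tm.voxel_indices] = 1
        bp = build_blueprint(conn, tm, normalise=False)
        assert np.allclose(bp.values, tm.values)

    def test_single_uniform_tract_normalises_to_ones(self, tiny_setup):
        tm = build_tract_matrix([npd_of(np.ones((4, 4, 4)), 2, "only")],
                                tiny_setup)
        conn = np.random.default_rng(2).integers(1, 5, (3, 8)).astype(
            np.int64)
        bp = build_blueprint(conn, tm)
        assert np.allclose(bp.values, 1.0)

    def test_zero_rows_are_excluded_not_normalised(self, tiny_setup):
        tm = build_tract_matrix([npd_of(np.ones((4, 4, 4)), 2, "t")],
                                tiny_setup)
        conn = np.zeros((2, 8), dtype=np.int64)
        conn[0, tm.voxel_indices[0]] = 1
        bp = build_blueprint(conn, tm)
        assert not bp.excluded[0]
        assert bp.excluded[1]
        assert np.all(bp.values[1] == 0)

    def test_row_stochastic_after_normalisation(self, surface_conn,
                                                tract_matrix):
        bp = build_blueprint(surface_conn, tract_matrix)
        sums = bp.values[~bp.excluded].sum(axis=1)
        assert np.all(np.abs(sums - 1.0) < 1e-9)

    def test_column_permutation_consistency(self, surface_conn,
                                            tract_matrix):
        bp = build_blueprint(surface_conn, tract_matrix)
        order = np.arange(tract_matrix.n_tracts)[::-1]
        bp_perm = build_blueprint(surface_conn, tract_matrix.permuted(order))
        assert bp_perm.tract_names == [tract_matrix.tract_names[i]
                                       for i in order]
        # the raw integer-accumulated product permutes exactly; the row
        # normalisation sums columns in a different order, so allow float
        # round-off there
        assert np.array_equal(bp_perm.raw, bp.raw[:, order])
        assert np.allclose(bp_perm.values, bp.values[:, order], atol=1e-12,
                           rtol=0)


class TestStreamlineOracle:
    def test_product_equals_per_streamline_accumulation_bitwise(
            self, phantom, tract_matrix, fast_cfg):
        conn = __import__("tractspace.tracking", fromlist=["x"]) \
            .run_surface_seeded_tractography(
                phantom.field, phantom.surface, phantom.brain_mask,
                tract_matrix.coarse_grid, fast_cfg)
        bp = build_blueprint(conn, tract_matrix)
        oracle = streamline_oracle_blueprint(
            phantom.field, phantom.surface, phantom.brain_mask,
            tract_matrix, fast_cfg)
        assert np.array_equal(bp.raw, oracle.raw)
        assert np.array_equal(bp.values, oracle.values)
        assert np.array_equal(bp.excluded, oracle.excluded)

    def test_zero_streamlines_excludes_all_rows(self, phantom, tract_matrix):
        cfg = TrackingConfig(streamlines_per_surface_vertex=0, seed=1)
        oracle = streamline_oracle_blueprint(
            phantom.field, phantom.surface, phantom.brain_mask,
            tract_matrix, cfg)
        assert oracle.excluded.all()

    def test_parcel_over_private_tube_concentrates_in_that_tract(
            self, phantom, surface_conn, tract_matrix):
        bp = build_blueprint(surface_conn, tract_matrix)
        col = tract_matrix.tract_names.index("rad_l")
        parcel = phantom.parcel_names.index("L4")
        sel = (phantom.parcel_labels == parcel) & ~bp.excluded
        mean_profile = bp.values[sel].mean(axis=0)
        assert np.argmax(mean_profile) == col
        assert mean_profile[col] > 0.5


class TestGroupAverage:
    def _bp(self, values, excluded=None):
        values = np.asarray(values, dtype=float)
        if excluded is None:
            excluded = np.zeros(len(values), dtype=bool)
        return ConnectivityBlueprint(values=values, tract_names=["a", "b"],
                                     excluded=np.asarray(excluded))

    def test_identical_inputs_average_to_themselves(self):
        bp = self._bp([[0.3, 0.7], [0.6, 0.4]])
        avg = group_average_blueprints([bp, bp])
        assert np.allclose(avg.values, bp.values)

    def test_excluded_vertex_averaged_over_remaining_subject(self):
        bp1 = self._bp([[0.2, 0.8]], excluded=[True])
        bp2 = self._bp([[0.6, 0.4]])
        avg = group_average_blueprints([bp1, bp2])
        assert np.allclose(avg.values[0], [0.6, 0.4])
        assert not avg.excluded[0]

    def test_vertex_excluded_everywhere_stays_excluded(self):
        bp1 = self._bp([[0.0, 0.0]], excluded=[True])
        avg = group_average_blueprints([bp1, bp1])
        assert avg.excluded[0]

    def test_rows_sum_to_one_after_averaging(self):
        rng = np.random.default_rng(4)
        v1 = rng.random((5, 2))
        v2 = rng.random((5, 2))
        bps = [self._bp(v1 / v1.sum(1, keepdims=True)),
               self._bp(v2 / v2.sum(1, keepdims=True))]
        avg = group_average_blueprints(bps)
        assert np.allclose(avg.values.sum(axis=1), 1.0)

    def test_frame_mismatch_rejected(self):
        bp1 = self._bp([[1.0, 0.0]])
        bp2 = ConnectivityBlueprint(values=np.ones((1, 2)) / 2,
                                    tract_names=["x", "y"],
                                    excluded=np.zeros(1, dtype=bool))
        with pytest.raises(ValueError, match="frames"):
            group_average_blueprints([bp1, bp2])


class TestRegions:
    def _bp(self):
        vals = np.array([[0.2, 0.8], [0.4, 0.6], [0.5, 0.5], [0.9, 0.1]])
        return ConnectivityBlueprint(values=vals, tract_names=["a", "b"],
                                     excluded=np.zeros(4, dtype=bool))

    def test_empty_mask_is_identity(self):
        bp = self._bp()
        out = exclude_region(bp, np.zeros(4, dtype=bool))
        assert np.array_equal(out.excluded, bp.excluded)

    def test_exclusion_counting(self):
        bp = self._bp()
        mask = np.array([True, False, True, False])
        out = exclude_region(bp, mask)
        assert out.excluded.sum() == 2

    def test_region_profile_is_renormalised_row_mean(self):
        bp = self._bp()
        prof = average_region_profile(bp, np.array([True, True, False,
                                                    False]))
        assert np.allclose(prof, [0.3, 0.7])
        assert prof.sum() == pytest.approx(1.0)

    def test_single_vertex_region_returns_its_row(self):
        bp = self._bp()
        prof = average_region_profile(bp, np.array([False, False, False,
                                                    True]))
        assert np.allclose(prof, [0.9, 0.1])

    def test_fully_excluded_region_rejected(self):
        bp = exclude_region(self._bp(), np.ones(4, dtype=bool))
        with pytest.raises(ValueError, match="empty"):
            average_region_profile(bp, np.ones(4, dtype=bool))
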