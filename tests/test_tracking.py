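"""Streamline propagation semantics and protocol-constrained tracking."""

import dataclasses

import numpy as np
import pytest

from conftest import make_uniform_field

from tractspace.imaging import BinaryMask
from tractspace.phantom import FiberOrientationField
from tractspace.tracking import (
    ProtocolROIs,
    TrackingConfig,
    propagate_streamline,
    run_protocol_tractography,
    run_surface_seeded_tractography,
)


class TestPropagation:
    def test_straight_field_spans_mask_and_leaves_it(self, uniform_field):
        field, mask = uniform_field
        cfg = TrackingConfig(seed=1, max_steps=500)
        res = propagate_streamline(field, mask, np.zeros(3), cfg,
                                   streamline_seed=7)
        assert res.reason_forward == "left_mask"
        assert res.reason_backward == "left_mask"
        pts = res.points
        # straight in x: y and z constant
        assert np.allclose(pts[:, 1], 0.0, atol=1e-9)
        assert np.allclose(pts[:, 2], 0.0, atol=1e-9)
        # spans most of the 20 mm cube
        assert pts[:, 0].max() - pts[:, 0].min() > 16.0

    def test_max_steps_one_bounds_polyline(self, uniform_field):
        field, mask = uniform_field
        cfg = TrackingConfig(seed=1, max_steps=1)
        res = propagate_streamline(field, mask, np.zeros(3), cfg,
                                   streamline_seed=7)
        assert res.reason_forward == "max_steps"
        assert len(res.points) <= 3  # seed + one step each way

    def test_orthogonal_interface_terminates_with_curvature(self):
        field, mask = make_uniform_field()
        # flip orientation to +y in the right half (x >= 3 mm)
        centers_x = np.arange(20) - 9.5
        right = centers_x >= 3.0
        field.directions[right, :, :, 0, :] = (0.0, 1.0, 0.0)
        cfg = TrackingConfig(seed=1, curvature_limit_deg=80.0, max_steps=500)
        res = propagate_streamline(field, mask, np.zeros(3), cfg,
                                   streamline_seed=7)
        assert "curvature" in res.reasons
        # the forward half must stop at the interface, not cross it
        assert res.points[:, 0].max() < 4.0

    def test_no_orientation_above_threshold_is_no_fibre(self):
        field, mask = make_uniform_field(fraction=0.005)  # below 1 %
        cfg = TrackingConfig(seed=1)
        res = propagate_streamline(field, mask, np.zeros(3), cfg,
                                   streamline_seed=7)
        assert res.reasons == ("no_fibre", "no_fibre")
        assert len(res.points) == 1

    def test_stop_mask_terminates(self):
        field, mask = make_uniform_field()
        stop = np.zeros(mask.shape, dtype=bool)
        stop[15:, :, :] = True
        cfg = TrackingConfig(seed=1, max_steps=500)
        res = propagate_streamline(
            field, mask, np.zeros(3), cfg, streamline_seed=7,
            stop_mask=BinaryMask(stop, mask.affine))
        assert "stop" in res.reasons

    def test_curvature_limit_holds_along_phantom_polylines(self, phantom):
        cfg = TrackingConfig(seed=2, max_steps=400)
        cos_lim = cfg.cos_limit
        rng = np.random.default_rng(0)
        verts = phantom.surface.vertices
        for i in rng.choice(len(verts), size=15, replace=False):
            res = propagate_streamline(phantom.field, phantom.brain_mask,
                                       verts[i], cfg, streamline_seed=int(i))
            pts = res.points
            if len(pts) < 3:
                continue
            seg = np.diff(pts, axis=0)
            seg /= np.linalg.norm(seg, axis=1, keepdims=True)
            # the seed sits mid-polyline; the two halves meet there with
            # opposite tracking directions, so skip that single joint
            cosang = np.sum(seg[:-1] * seg[1:], axis=1)
            n_back = np.argmin(cosang) if cosang.min() < 0 else -1
            keep = np.ones(len(cosang), dtype=bool)
            if n_back >= 0:
                keep[n_back] = False
            assert np.all(cosang[keep] >= cos_lim - 1e-9)
            assert res.arc_length() <= 2 * cfg.max_steps * cfg.step_size_mm \
                + 1e-9


class TestProtocolTractography:
    def test_phantom_tract_recovery(self, phantom, fast_cfg):
        p = phantom.protocols.get("ARC_L")
        pd_ = run_protocol_tractography(phantom.field, p.rois,
                                        phantom.brain_mask, fast_cfg)
        assert pd_.n_valid / pd_.n_seeded >= 0.5
        gt = phantom.tract_masks["arc_l"].values
        coverage = (np.asarray(pd_.counts.values)[gt] > 0).mean()
        assert coverage >= 0.8

    def test_exclusion_slab_across_tube_rejects_everything(self, phantom,
                                                           fast_cfg):
        p = phantom.protocols.get("RAD_L")
        pts, _ = phantom.curves["rad_l"]
        mid = pts[len(pts) // 2]
        world = phantom.brain_mask.voxel_centers_world()
        slab = np.abs(world[..., 2] - mid[2]) <= 1.5
        rois = dataclasses.replace(
            p.rois, exclusion=BinaryMask(slab, phantom.brain_mask.affine))
        pd_ = run_protocol_tractography(phantom.field, rois,
                                        phantom.brain_mask, fast_cfg)
        assert pd_.n_valid == 0
        assert np.all(pd_.counts.values == 0)

    def test_vacuous_criteria_accept_all_streamlines(self, phantom, fast_cfg):
        p = phantom.protocols.get("VRT_L")
        rois = ProtocolROIs(seed=p.rois.seed)
        pd_ = run_protocol_tractography(phantom.field, rois,
                                        phantom.brain_mask, fast_cfg)
        assert pd_.n_valid == pd_.n_seeded

    def test_deterministic_given_seed(self, phantom, fast_cfg):
        p = phantom.protocols.get("CMA")
        a = run_protocol_tractography(phantom.field, p.rois,
                                      phantom.brain_mask, fast_cfg)
        b = run_protocol_tractography(phantom.field, p.rois,
                                      phantom.brain_mask, fast_cfg)
        assert np.array_equal(a.counts.values, b.counts.values)
        assert a.n_valid == b.n_valid
        other = dataclasses.replace(fast_cfg, seed=fast_cfg.seed + 1)
        c = run_protocol_tractography(phantom.field, p.rois,
                                      phantom.brain_mask, other)
        assert not np.array_equal(a.counts.values, c.counts.values)

    def test_adding_exclusion_cannot_increase_n_valid(self, phantom,
                                                      fast_cfg):
        p = phantom.protocols.get("ATR_L")
        base = run_protocol_tractography(phantom.field, p.rois,
                                         phantom.brain_mask, fast_cfg)
        world = phantom.brain_mask.voxel_centers_world()
        bigger = np.asarray(p.rois.exclusion.values) | (world[..., 1] > 15.0)
        rois = dataclasses.replace(
            p.rois, exclusion=BinaryMask(bigger, phantom.brain_mask.affine))
        harder = run_protocol_tractography(phantom.field, rois,
                                           phantom.brain_mask, fast_cfg)
        assert harder.n_valid <= base.n_valid

    def test_counts_bounded_by_n_valid(self, phantom, fast_cfg):
        p = phantom.protocols.get("CMP")
        pd_ = run_protocol_tractography(phantom.field, p.rois,
                                        phantom.brain_mask, fast_cfg)
        assert pd_.counts.values.max() <= pd_.n_valid

    def test_empty_seed_rejected(self, phantom, fast_cfg):
        p = phantom.protocols.get("ARC_L")
        empty = BinaryMask(np.zeros(phantom.brain_mask.shape, dtype=bool),
                           phantom.brain_mask.affine)
        with pytest.raises(ValueError, match="empty seed"):
            run_protocol_tractography(
                phantom.field, dataclasses.replace(p.rois, seed=empty),
                phantom.brain_mask, fast_cfg)


class TestSurfaceSeeding:
    def test_zero_streamlines_gives_zero_matrix(self, phantom, coarse_mask):
        cfg = TrackingConfig(streamlines_per_surface_vertex=0, seed=1)
        conn = run_surface_seeded_tractography(
            phantom.field, phantom.surface, phantom.brain_mask, coarse_mask,
            cfg)
        assert conn.matrix.sum() == 0
        assert conn.zero_rows.all()

    def test_vertex_outside_mask_is_flagged_not_error(self, phantom,
                                                      coarse_mask):
        surf = dataclasses.replace(phantom.surface)
        surf = type(phantom.surface)(
            np.vstack([phantom.surface.vertices, [[500.0, 0.0, 0.0]]]),
            phantom.surface.faces)
        cfg = TrackingConfig(streamlines_per_surface_vertex=5, seed=1)
        conn = run_surface_seeded_tractography(
            phantom.field, surf, phantom.brain_mask, coarse_mask, cfg)
        assert conn.outside_vertices[-1]
        assert conn.matrix[-1].sum() == 0

    def test_visitation_counts_bounded_per_streamline(self, surface_conn,
                                                      fast_cfg):
        assert surface_conn.matrix.max() <= \
            fast_cfg.streamlines_per_surface_vertex

    def test_config_validation_names_offending_field(self):
        with pytest.raises(ValueError, match="curvature_limit_deg"):
            TrackingConfig(curvature_limit_deg=200).validate()
        with pytest.raises(ValueError, match="step_size_mm"):
            TrackingConfig(step_size_mm=0).validate()
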