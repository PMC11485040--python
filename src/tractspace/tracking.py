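"""Protocol-constrained probabilistic streamline tractography.

Desk-scale re-implementation of the constraint logic of protocol-driven
probabilistic tractography: streamlines are propagated through a fixed
multi-fibre orientation field (nearest-voxel lookup, no orientation
uncertainty), and a tract protocol — seed, waypoint, exclusion, stop and
target masks — decides which streamlines are *valid*. Only valid
streamlines contribute to the path distribution, and each streamline
increments a voxel at most once, so counts read as "number of valid
streamlines visiting this voxel".

Defaults follow common protocol-tractography practice: 80 degree
curvature threshold, 0.2 mm steps, at most 2000 steps per direction,
subsidiary fibres considered above 1 % volume fraction, and 1000
streamlines per surface vertex for cortex-seeded connectivity.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import _tracker
from .imaging import BinaryMask, SurfaceMesh, VolumeGrid
from .phantom import FiberOrientationField

__all__ = [
    "TrackingConfig",
    "ProtocolROIs",
    "PathDistribution",
    "StreamlineResult",
    "VertexVisitationMatrix",
    "propagate_streamline",
    "run_protocol_tractography",
    "run_surface_seeded_tractography",
]

_SEED_CAP = 2**31 - 1


@dataclasses.dataclass
class TrackingConfig:
    step_size_mm: float = 0.2
    curvature_limit_deg: float = 80.0
    max_steps: int = 2000
    min_volume_fraction: float = 0.01
    streamlines_per_seed_voxel: int = 50
    streamlines_per_surface_vertex: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if not self.step_size_mm > 0:
            raise ValueError("step_size_mm must be > 0")
        if not 0 < self.curvature_limit_deg <= 180:
            raise ValueError("curvature_limit_deg must be in (0, 180]")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if not 0 <= self.min_volume_fraction < 1:
            raise ValueError("min_volume_fraction must be in [0, 1)")
        if self.streamlines_per_seed_voxel < 0:
            raise ValueError("streamlines_per_seed_voxel must be >= 0")
        if self.streamlines_per_surface_vertex < 0:
            raise ValueError("streamlines_per_surface_vertex must be >= 0")

    @property
    def cos_limit(self) -> float:
        return float(np.cos(np.deg2rad(self.curvature_limit_deg)))


@dataclasses.dataclass
class ProtocolROIs:
    """Masks constraining one tract: all on a single grid, seed nonempty."""

    seed: BinaryMask
    waypoints: tuple[BinaryMask, ...] = ()
    exclusion: BinaryMask | None = None
    stop: BinaryMask | None = None
    target: BinaryMask | None = None

    def all_masks(self) -> dict[str, BinaryMask]:
        out: dict[str, BinaryMask] = {"seed": self.seed}
        for i, w in enumerate(self.waypoints):
            out[f"waypoint{i}" if len(self.waypoints) > 1 else "waypoint"] = w
        if self.target is not None:
            out["target"] = self.target
        if self.exclusion is not None:
            out["exclude"] = self.exclusion
        if self.stop is not None:
            out["stop"] = self.stop
        return out


@dataclasses.dataclass
class PathDistribution:
    """Voxelwise valid-streamline visitation counts for one tract."""

    counts: VolumeGrid  # integer counts
    n_valid: int
    n_seeded: int
    seed: int
    config: TrackingConfig

    def __post_init__(self) -> None:
        c = np.asarray(self.counts.values)
        if c.min() < 0:
            raise ValueError("negative visitation count")
        if self.n_valid > self.n_seeded:
            raise ValueError("n_valid cannot exceed n_seeded")


@dataclasses.dataclass
class StreamlineResult:
    points: np.ndarray  # (N, 3) world mm, back-end ... seed ... front-end
    reason_forward: str
    reason_backward: str

    @property
    def reason(self) -> str:
        return self.reason_forward

    @property
    def reasons(self) -> tuple[str, str]:
        return (self.reason_backward, self.reason_forward)

    def arc_length(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclasses.dataclass
class VertexVisitationMatrix:
    """(vertices x coarse voxels) streamline-unique visitation counts."""

    matrix: np.ndarray  # (V, n_coarse_flat) int64
    coarse_grid: BinaryMask  # the downsampled brain mask defining the grid
    n_per_vertex: int
    zero_rows: np.ndarray  # (V,) bool — no visitation recorded
    outside_vertices: np.ndarray  # (V,) bool — vertex not in the brain mask


def _prep_field(field: FiberOrientationField, brain_mask: BinaryMask,
                stop: BinaryMask | None):
    mask8 = np.ascontiguousarray(brain_mask.values.astype(np.uint8))
    if stop is None:
        stop8 = np.zeros_like(mask8)
    else:
        stop8 = np.ascontiguousarray(stop.values.astype(np.uint8))
    inv = np.linalg.inv(field.affine)
    return (field.directions, field.fractions, mask8, stop8,
            np.ascontiguousarray(inv[:3, :3]), np.ascontiguousarray(inv[:3, 3]))


def propagate_streamline(
    field: FiberOrientationField,
    brain_mask: BinaryMask,
    start_point: np.ndarray,
    config: TrackingConfig,
    streamline_seed: int | None = None,
    stop_mask: BinaryMask | None = None,
) -> StreamlineResult:
    """Track one streamline (both directions) from a world-mm point."""
    config.validate()
    dirs, fracs, mask8, stop8, inv_lin, inv_off = _prep_field(
        field, brain_mask, stop_mask)
    pts = np.empty((2 * config.max_steps + 1, 3))
    seed = int(config.seed if streamline_seed is None else streamline_seed)
    nb, nf, rb, rf = _tracker._track_one(
        np.asarray(start_point, dtype=np.float64), seed % _SEED_CAP,
        dirs, fracs, mask8, stop8, inv_lin, inv_off,
        config.step_size_mm, config.cos_limit, config.max_steps,
        config.min_volume_fraction, pts)
    out = pts[config.max_steps - nb: config.max_steps + nf + 1].copy()
    return StreamlineResult(out, _tracker.REASON_NAMES[rf],
                            _tracker.REASON_NAMES[rb])


def run_protocol_tractography(
    field: FiberOrientationField,
    protocol: ProtocolROIs,
    brain_mask: BinaryMask,
    config: TrackingConfig,
) -> PathDistribution:
    """Seed uniformly in the seed mask; keep only protocol-valid streamlines.

    A streamline is valid iff it intersects every waypoint (and the
    target, if present) and never touches the exclusion mask. Counts are
    binary per streamline per voxel. Deterministic given ``config.seed``.
    """
    config.validate()
    for name, m in protocol.all_masks().items():
        if not m.same_grid(brain_mask):
            raise ValueError(f"protocol ROI {name!r} is not on the brain grid")
    seed_vox = np.argwhere(protocol.seed.values)
    if len(seed_vox) == 0:
        raise ValueError("empty seed mask")

    rng = np.random.default_rng(config.seed)
    n_per = config.streamlines_per_seed_voxel
    n_total = len(seed_vox) * n_per
    offsets = rng.uniform(-0.5, 0.5, size=(n_total, 3))
    vox = np.repeat(seed_vox, n_per, axis=0).astype(float) + offsets
    starts = np.ascontiguousarray(
        vox @ brain_mask.affine[:3, :3].T + brain_mask.affine[:3, 3])
    seeds = rng.integers(0, _SEED_CAP, size=n_total, dtype=np.int64)

    dirs, fracs, mask8, stop8, inv_lin, inv_off = _prep_field(
        field, brain_mask, protocol.stop)
    excl8 = (np.ascontiguousarray(protocol.exclusion.values.astype(np.uint8))
             if protocol.exclusion is not None else np.zeros_like(mask8))
    if protocol.waypoints:
        ways = np.ascontiguousarray(np.stack(
            [w.values.astype(np.uint8) for w in protocol.waypoints]))
    else:
        ways = np.zeros((0,) + brain_mask.shape, dtype=np.uint8)
    has_target = protocol.target is not None
    target8 = (np.ascontiguousarray(protocol.target.values.astype(np.uint8))
               if has_target else np.zeros_like(mask8))

    counts = np.zeros(brain_mask.shape, dtype=np.int64)
    stamp = np.full(brain_mask.shape, -1, dtype=np.int64)
    pts = np.empty((2 * config.max_steps + 1, 3))
    vox_buf = np.empty((2 * config.max_steps + 1, 3), dtype=np.int64)
    n_valid = _tracker._protocol_drive(
        starts, seeds, dirs, fracs, mask8, stop8, excl8, ways, target8,
        has_target, inv_lin, inv_off, config.step_size_mm, config.cos_limit,
        config.max_steps, config.min_volume_fraction,
        counts, stamp, pts, vox_buf)
    return PathDistribution(
        counts=VolumeGrid(counts, brain_mask.affine.copy()),
        n_valid=int(n_valid), n_seeded=n_total, seed=config.seed,
        config=config)


def _surface_seeds(config: TrackingConfig, n_vertices: int) -> np.ndarray:
    rng = np.random.default_rng(config.seed)
    n = n_vertices * config.streamlines_per_surface_vertex
    return rng.integers(0, _SEED_CAP, size=max(n, 1), dtype=np.int64)


def run_surface_seeded_tractography(
    field: FiberOrientationField,
    surface: SurfaceMesh,
    brain_mask: BinaryMask,
    coarse_grid: BinaryMask,
    config: TrackingConfig,
) -> VertexVisitationMatrix:
    """Whole-brain connectivity of every surface vertex.

    Seeds ``config.streamlines_per_surface_vertex`` streamlines at each
    vertex and counts, per (vertex, coarse voxel), how many of them visit
    that voxel (once per streamline). ``coarse_grid`` is typically the
    brain mask down-sampled to 2 mm; visitations are recorded over the
    whole coarse grid and masked later when tract matrices are applied.
    Vertices outside the brain mask are flagged, not errors.
    """
    config.validate()
    verts = np.ascontiguousarray(surface.vertices, dtype=np.float64)
    n_per = config.streamlines_per_surface_vertex
    n_coarse = int(np.prod(coarse_grid.shape))
    conn = np.zeros((len(verts), n_coarse), dtype=np.int64)
    vox = brain_mask.world_to_voxel(verts)
    ivox = np.floor(vox + 0.5).astype(int)
    inside = np.all((ivox >= 0) & (ivox < np.asarray(brain_mask.shape)), axis=1)
    outside = ~inside.copy()
    ok = np.flatnonzero(inside)
    outside[ok] = ~brain_mask.values[ivox[ok, 0], ivox[ok, 1], ivox[ok, 2]]

    if n_per > 0:
        seeds = _surface_seeds(config, len(verts))
        dirs, fracs, mask8, stop8, inv_lin, inv_off = _prep_field(
            field, brain_mask, None)
        cinv = np.linalg.inv(coarse_grid.affine)
        cstamp = np.full(n_coarse, -1, dtype=np.int64)
        pts = np.empty((2 * config.max_steps + 1, 3))
        _tracker._surface_drive(
            verts, seeds, n_per, dirs, fracs, mask8, stop8,
            inv_lin, inv_off, np.ascontiguousarray(cinv[:3, :3]),
            np.ascontiguousarray(cinv[:3, 3]),
            np.asarray(coarse_grid.shape, dtype=np.int64),
            config.step_size_mm, config.cos_limit, config.max_steps,
            config.min_volume_fraction, conn, cstamp, pts)
    zero_rows = conn.sum(axis=1) == 0
    return VertexVisitationMatrix(
        matrix=conn, coarse_grid=coarse_grid, n_per_vertex=n_per,
        zero_rows=zero_rows, outside_vertices=outside)
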