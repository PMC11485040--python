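"""Connectivity blueprints: (cortex vertices x tracts) projection patterns.

A blueprint is built in two steps. First, every tract's normalised path
distribution is block-averaged to a coarse whole-brain grid, masked to
the brain and unwrapped in 1-D, giving a (coarse voxels x tracts) *tract
matrix*. Second, the (vertices x coarse voxels) whole-brain connectivity
matrix from surface-seeded tracking is multiplied with the tract matrix;
each row is then divided by its sum, so a non-excluded row is the
probability profile of that cortical location's connections to the tract
repertoire. Rows with zero sum (locations not represented by the tract
set) are excluded rather than renormalised.

Exactness: path-distribution fractions are rationals (counts divided by
the valid-streamline total), so the tract matrix carries integer
numerators alongside its float values and the blueprint product is
evaluated in integer arithmetic before the final division. This makes
the identity "matrix product == per-streamline accumulation" hold bit
for bit, which :func:`streamline_oracle_blueprint` exploits as an
independent correctness oracle.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import _tracker
from .imaging import BinaryMask, SurfaceMesh, downsample_mask
from .phantom import FiberOrientationField
from .tracking import (
    TrackingConfig,
    VertexVisitationMatrix,
    _prep_field,
    _surface_seeds,
)
from .tract_metrics import NormalisedPathDistribution

__all__ = [
    "TractMatrix",
    "ConnectivityBlueprint",
    "build_tract_matrix",
    "build_blueprint",
    "streamline_oracle_blueprint",
    "group_average_blueprints",
    "exclude_region",
    "average_region_profile",
]


@dataclasses.dataclass
class TractMatrix:
    """(brain coarse voxels x tracts) vectorised tract maps."""

    values: np.ndarray  # (M, T) float
    numerators: np.ndarray | None  # (M, T) int64, exact counts (block sums)
    denominators: np.ndarray  # (T,) float, n_valid * block size
    voxel_indices: np.ndarray  # (M,) flat indices into the coarse grid
    coarse_grid: BinaryMask
    tract_names: list[str]

    @property
    def n_tracts(self) -> int:
        return len(self.tract_names)

    def permuted(self, order: np.ndarray) -> "TractMatrix":
        return TractMatrix(
            values=self.values[:, order],
            numerators=None if self.numerators is None
            else np.ascontiguousarray(self.numerators[:, order]),
            denominators=self.denominators[order],
            voxel_indices=self.voxel_indices,
            coarse_grid=self.coarse_grid,
            tract_names=[self.tract_names[i] for i in order],
        )


@dataclasses.dataclass
class ConnectivityBlueprint:
    """(vertices x tracts) matrix of tract projection probabilities."""

    values: np.ndarray  # (V, T)
    tract_names: list[str]
    excluded: np.ndarray  # (V,) bool
    normalised: bool = True
    raw: np.ndarray | None = None  # pre-normalisation values

    @property
    def n_vertices(self) -> int:
        return self.values.shape[0]

    def active_rows(self) -> np.ndarray:
        return np.flatnonzero(~self.excluded)


def _block_sum(arr: np.ndarray, f: np.ndarray) -> np.ndarray:
    x, y, z = arr.shape
    return arr.reshape(x // f[0], f[0], y // f[1], f[1],
                       z // f[2], f[2]).sum(axis=(1, 3, 5))


def build_tract_matrix(
    npds: list[NormalisedPathDistribution],
    coarse_grid: BinaryMask,
    brain_mask: BinaryMask | None = None,
) -> TractMatrix:
    """Downsample, mask and vectorise a set of path distributions.

    ``coarse_grid`` is the coarse brain mask (typically the fine brain
    mask down-sampled to 2 mm with the any-voxel rule); its active voxels
    define the rows, in fixed lexicographic order. ``brain_mask`` defaults
    to the coarse grid itself.
    """
    names = [n.tract for n in npds]
    if len(set(names)) != len(names):
        raise ValueError("tract name collision in tract matrix")
    first = npds[0].values
    for n in npds[1:]:
        if not n.values.same_grid(first):
            raise ValueError("path distributions must share one grid")
    factors = (coarse_grid.voxel_size / first.voxel_size)
    f = np.rint(factors).astype(int)
    if not np.allclose(factors, f, atol=1e-6):
        raise ValueError("non-integer downsampling factor")
    block = int(np.prod(f))
    sel = coarse_grid.values
    if brain_mask is not None:
        sel = sel & brain_mask.values
    flat_idx = np.flatnonzero(sel.ravel())

    nums = np.empty((len(flat_idx), len(npds)), dtype=np.int64)
    vals = np.empty((len(flat_idx), len(npds)), dtype=np.float64)
    denoms = np.empty(len(npds), dtype=np.float64)
    for t, npd in enumerate(npds):
        counts = np.asarray(npd.counts.values, dtype=np.int64)
        coarse_counts = _block_sum(counts, f).ravel()[flat_idx]
        nums[:, t] = coarse_counts
        denom = float(npd.n_valid * block) if npd.n_valid > 0 else 1.0
        denoms[t] = denom
        vals[:, t] = coarse_counts / denom
    return TractMatrix(values=vals, numerators=nums, denominators=denoms,
                       voxel_indices=flat_idx, coarse_grid=coarse_grid,
                       tract_names=names)


def _normalise_rows(raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sums = raw.sum(axis=1)
    excluded = sums <= 0
    out = np.zeros_like(raw)
    keep = ~excluded
    out[keep] = raw[keep] / sums[keep, None]
    return out, excluded


def build_blueprint(
    conn: VertexVisitationMatrix | np.ndarray,
    tm: TractMatrix,
    normalise: bool = True,
) -> ConnectivityBlueprint:
    """Blueprint = (vertex x voxel connectivity) x (voxel x tract matrix).

    Integer connectivity counts are multiplied with the tract matrix's
    integer numerators and divided by the per-tract denominators, so the
    result is exact. Zero-sum rows are marked excluded; if ``normalise``
    each remaining row is divided by its sum.
    """
    matrix = conn.matrix if isinstance(conn, VertexVisitationMatrix) else conn
    if matrix.shape[1] < tm.voxel_indices.max() + 1:
        raise ValueError("connectivity matrix does not cover the coarse grid")
    sub = matrix[:, tm.voxel_indices]
    if np.issubdtype(sub.dtype, np.integer) and tm.numerators is not None:
        raw = (sub.astype(np.int64) @ tm.numerators) / tm.denominators
    else:
        raw = sub.astype(float) @ tm.values
    if normalise:
        values, excluded = _normalise_rows(raw)
    else:
        values = raw
        excluded = raw.sum(axis=1) <= 0
    return ConnectivityBlueprint(values=values, tract_names=list(tm.tract_names),
                                 excluded=excluded, normalised=normalise,
                                 raw=raw)


def streamline_oracle_blueprint(
    field: FiberOrientationField,
    surface: SurfaceMesh,
    brain_mask: BinaryMask,
    tm: TractMatrix,
    config: TrackingConfig,
    normalise: bool = True,
) -> ConnectivityBlueprint:
    """Independent oracle: per-streamline accumulation of tract values.

    Re-runs the surface-seeded streamlines (same seeds, same order as
    :func:`tractspace.tracking.run_surface_seeded_tractography`) and, for
    each streamline, adds the tract-matrix numerators of the coarse
    voxels it visits (once per streamline). Equals the matrix-product
    blueprint bit for bit.
    """
    config.validate()
    if tm.numerators is None:
        raise ValueError("oracle requires an exact (integer) tract matrix")
    verts = np.ascontiguousarray(surface.vertices, dtype=np.float64)
    n_per = config.streamlines_per_surface_vertex
    n_coarse = int(np.prod(tm.coarse_grid.shape))
    num_full = np.zeros((n_coarse, tm.n_tracts), dtype=np.int64)
    num_full[tm.voxel_indices] = tm.numerators
    rows = np.zeros((len(verts), tm.n_tracts), dtype=np.int64)
    if n_per > 0:
        seeds = _surface_seeds(config, len(verts))
        dirs, fracs, mask8, stop8, inv_lin, inv_off = _prep_field(
            field, brain_mask, None)
        cinv = np.linalg.inv(tm.coarse_grid.affine)
        cstamp = np.full(n_coarse, -1, dtype=np.int64)
        pts = np.empty((2 * config.max_steps + 1, 3))
        _tracker._surface_oracle_drive(
            verts, seeds, n_per, dirs, fracs, mask8, stop8,
            inv_lin, inv_off, np.ascontiguousarray(cinv[:3, :3]),
            np.ascontiguousarray(cinv[:3, 3]),
            np.asarray(tm.coarse_grid.shape, dtype=np.int64),
            config.step_size_mm, config.cos_limit, config.max_steps,
            config.min_volume_fraction, num_full, rows, cstamp, pts)
    raw = rows / tm.denominators
    if normalise:
        values, excluded = _normalise_rows(raw)
    else:
        values = raw
        excluded = raw.sum(axis=1) <= 0
    return ConnectivityBlueprint(values=values, tract_names=list(tm.tract_names),
                                 excluded=excluded, normalised=normalise,
                                 raw=raw)


def group_average_blueprints(
    blueprints: list[ConnectivityBlueprint],
    renormalise: bool = True,
) -> ConnectivityBlueprint:
    """Element-wise mean over subjects, then row renormalisation.

    A vertex is averaged over the subjects in which it is not excluded
    and excluded only if excluded in all subjects.
    """
    if not blueprints:
        raise ValueError("need at least one blueprint")
    first = blueprints[0]
    for bp in blueprints[1:]:
        if bp.tract_names != first.tract_names or \
                bp.n_vertices != first.n_vertices:
            raise ValueError("blueprint frames do not match")
    vals = np.stack([bp.values for bp in blueprints])
    incl = np.stack([~bp.excluded for bp in blueprints]).astype(float)
    n_incl = incl.sum(axis=0)
    excluded = n_incl == 0
    mean = np.zeros_like(first.values)
    keep = ~excluded
    mean[keep] = (vals[:, keep] * incl[:, keep, None]).sum(axis=0) \
        / n_incl[keep, None]
    if renormalise:
        sums = mean.sum(axis=1)
        pos = keep & (sums > 0)
        mean[pos] = mean[pos] / sums[pos, None]
        excluded = excluded | (sums <= 0)
    return ConnectivityBlueprint(values=mean, tract_names=list(first.tract_names),
                                 excluded=excluded, normalised=renormalise)


def exclude_region(bp: ConnectivityBlueprint,
                   region_vertex_mask: np.ndarray) -> ConnectivityBlueprint:
    """Mark the region's vertices excluded (dropped from divergences)."""
    region_vertex_mask = np.asarray(region_vertex_mask, dtype=bool)
    if region_vertex_mask.shape[0] != bp.n_vertices:
        raise ValueError("region mask is not on the blueprint's vertex frame")
    return ConnectivityBlueprint(
        values=bp.values.copy(), tract_names=list(bp.tract_names),
        excluded=bp.excluded | region_vertex_mask, normalised=bp.normalised,
        raw=None if bp.raw is None else bp.raw.copy())


def average_region_profile(bp: ConnectivityBlueprint,
                           region_vertex_mask: np.ndarray) -> np.ndarray:
    """Mean of the region's (non-excluded) rows, renormalised to sum 1."""
    region_vertex_mask = np.asarray(region_vertex_mask, dtype=bool)
    if region_vertex_mask.shape[0] != bp.n_vertices:
        raise ValueError("region mask is not on the blueprint's vertex frame")
    sel = region_vertex_mask & ~bp.excluded
    if not sel.any():
        raise ValueError("region is empty after exclusions")
    profile = bp.values[sel].mean(axis=0)
    total = profile.sum()
    if total <= 0:
        raise ValueError("region profile has zero mass")
    return profile / total
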