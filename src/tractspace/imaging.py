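"""Volumetric and surface primitives shared by every pipeline stage.

The data model is deliberately small: a :class:`VolumeGrid` couples a 3-D
scalar array with a NIfTI-style voxel-to-world affine (all geometry in mm,
voxel indices 0-based), a :class:`BinaryMask` restricts the values to
{0, 1}, a :class:`WarpField` stores a per-voxel displacement (in mm) that
maps points of its own (target) grid into a source space, and a
:class:`SurfaceMesh` holds a triangulated surface with optional per-vertex
scalar maps.

Resampling conventions used throughout the package:

* warps follow the pull-back convention — the displacement lives on the
  *target* grid and maps target world-points to source world-points, so
  resampling never leaves holes;
* masks are interpolated trilinearly and re-binarised at a threshold
  (default 0.5);
* samples falling outside the source grid read 0 (background), never error.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


@dataclasses.dataclass
class VolumeGrid:
    """A single 3-D scalar volume on a regular grid.

    Parameters
    ----------
    values : ndarray, shape (X, Y, Z)
        Scalar value per voxel.
    affine : ndarray, shape (4, 4)
        Voxel-index -> world-mm transform. Must be invertible.
    """

    values: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got ndim={self.values.ndim}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular / degenerate")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        """mm per axis (column norms of the linear part)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def inverse_affine(self) -> np.ndarray:
        return np.linalg.inv(self.affine)

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        inv = self.inverse_affine
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def voxel_centers_world(self) -> np.ndarray:
        """World coordinates of every voxel center, shape (X, Y, Z, 3)."""
        idx = np.indices(self.shape, dtype=float)
        coords = np.stack([idx[0], idx[1], idx[2]], axis=-1)
        return coords @ self.affine[:3, :3].T + self.affine[:3, 3]

    def same_grid(self, other: "VolumeGrid", tol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=tol
        )

    def with_values(self, values: np.ndarray) -> "VolumeGrid":
        return VolumeGrid(values, self.affine.copy())


class BinaryMask(VolumeGrid):
    """A VolumeGrid whose values are in {0, 1} (stored as bool)."""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.dtype != bool:
            uniq = np.unique(vals)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask values must be in {0, 1}")
            vals = vals.astype(bool)
        self.values = vals
        super().__post_init__()

    @property
    def n_active(self) -> int:
        return int(self.values.sum())

    def with_values(self, values: np.ndarray) -> "BinaryMask":
        return BinaryMask(values, self.affine.copy())


@dataclasses.dataclass
class WarpField:
    """Displacement field on a target grid (pull-back convention).

    ``displacement[i, j, k]`` is the mm offset added to the world
    coordinates of target voxel (i, j, k) to obtain the corresponding
    point in the source space.
    """

    displacement: np.ndarray  # (X, Y, Z, 3), mm
    affine: np.ndarray  # target grid voxel -> world

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.displacement.ndim != 4 or self.displacement.shape[3] != 3:
            raise ValueError("displacement must have shape (X, Y, Z, 3)")
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("displacement contains non-finite values")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("target affine is singular / degenerate")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.displacement.shape[:3]  # type: ignore[return-value]

    def target_grid(self) -> VolumeGrid:
        return VolumeGrid(np.zeros(self.shape, dtype=np.uint8), self.affine)

    @classmethod
    def identity(cls, grid: VolumeGrid) -> "WarpField":
        return cls(np.zeros(grid.shape + (3,)), grid.affine.copy())


@dataclasses.dataclass
class SurfaceMesh:
    """Triangulated surface with world-mm vertices and per-vertex scalars."""

    vertices: np.ndarray  # (V, 3) world mm
    faces: np.ndarray  # (F, 3) vertex indices
    scalars: dict[str, np.ndarray] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must have shape (V, 3)")
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ValueError("triangle index out of range")
            a, b, c = self.faces.T
            if np.any((a == b) | (b == c) | (a == c)):
                raise ValueError("degenerate triangle (repeated vertex)")
        for key, val in self.scalars.items():
            val = np.asarray(val)
            if val.shape[0] != len(self.vertices):
                raise ValueError(f"scalar map {key!r} length mismatch")
            self.scalars[key] = val

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


# ---------------------------------------------------------------------------
# NIfTI / GIFTI I/O
# ---------------------------------------------------------------------------

def read_volume(path: str | Path, mask: bool = False) -> VolumeGrid:
    """Read a single 3-D NIfTI volume (gzipped accepted).

    Raises on missing files, 4-D inputs and non-finite voxels (the first
    offending voxel index is reported).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"{path.name}: expected a 3-D volume, got shape {data.shape}"
        )
    if np.issubdtype(data.dtype, np.floating) and not np.all(np.isfinite(data)):
        idx = tuple(int(i) for i in np.argwhere(~np.isfinite(data))[0])
        raise ValueError(f"{path.name}: non-finite value at voxel {idx}")
    cls = BinaryMask if mask else VolumeGrid
    return cls(data, np.asarray(img.affine))


def write_volume(vol: VolumeGrid, path: str | Path) -> None:
    data = np.asarray(vol.values)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    elif data.dtype in (np.int64, np.uint64):
        data = data.astype(np.int32)  # NIfTI-1 friendly; counts fit easily
    img = nib.Nifti1Image(data, vol.affine)
    img.set_data_dtype(data.dtype)
    nib.save(img, str(path))


def read_warp(path: str | Path) -> WarpField:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4 or data.shape[3] != 3:
        raise ValueError("warp file must be a 3-vector 4-D image")
    return WarpField(data, np.asarray(img.affine))


def write_warp(warp: WarpField, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(warp.displacement.astype(np.float32), warp.affine),
             str(path))


def read_surface(path: str | Path) -> SurfaceMesh:
    img = nib.load(str(path))
    verts = faces = None
    for arr in img.darrays:
        code = nib.gifti.gifti.intent_codes.label.get(arr.intent, arr.intent)
        if arr.intent == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
            verts = np.asarray(arr.data, dtype=float)
        elif arr.intent == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
            faces = np.asarray(arr.data, dtype=np.int64)
        del code
    if verts is None or faces is None:
        raise ValueError("GIFTI file lacks pointset/triangle arrays")
    return SurfaceMesh(verts, faces)


def write_surface(mesh: SurfaceMesh, path: str | Path) -> None:
    img = nib.gifti.GiftiImage()
    img.add_gifti_data_array(nib.gifti.GiftiDataArray(
        mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"))
    img.add_gifti_data_array(nib.gifti.GiftiDataArray(
        mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"))
    nib.save(img, str(path))


def read_vertex_map(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    if not img.darrays:
        raise ValueError("empty GIFTI scalar file")
    return np.asarray(img.darrays[0].data)


def write_vertex_map(values: np.ndarray, path: str | Path) -> None:
    img = nib.gifti.GiftiImage()
    img.add_gifti_data_array(nib.gifti.GiftiDataArray(
        np.asarray(values, dtype=np.float32), intent="NIFTI_INTENT_SHAPE"))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Resampling operations
# ---------------------------------------------------------------------------

def sample_trilinear(vol: VolumeGrid, world_pts: np.ndarray) -> np.ndarray:
    """Trilinear sample of ``vol`` at world points; outside reads 0."""
    vox = vol.world_to_voxel(world_pts)
    return ndimage.map_coordinates(
        np.asarray(vol.values, dtype=float), vox.T, order=1,
        mode="constant", cval=0.0)


def apply_warp_to_mask(
    mask: BinaryMask,
    warp: WarpField,
    interpolation_threshold: float = 0.5,
) -> BinaryMask:
    """Resample a binary mask through a warp onto the warp's target grid.

    For every target voxel the source mask is sampled trilinearly at the
    displaced point and the output voxel is set iff the sampled value is
    >= ``interpolation_threshold``. Points outside the source grid read 0.
    """
    target = warp.target_grid()
    centers = target.voxel_centers_world().reshape(-1, 3)
    src_pts = centers + warp.displacement.reshape(-1, 3)
    sampled = sample_trilinear(mask, src_pts)
    out = (sampled >= interpolation_threshold).reshape(warp.shape)
    return BinaryMask(out, warp.affine.copy())


def mirror_mask(
    mask: BinaryMask,
    axis: int | str,
    plane_coord_mm: float,
    interpolation_threshold: float = 0.5,
) -> BinaryMask:
    """Reflect a mask across a grid-axis-aligned plane (world coordinate).

    The reflection is resampled to the mask's own grid with the trilinear
    + threshold rule, so a plane through a voxel-center column makes the
    operation an exact involution.
    """
    ax = {"x": 0, "y": 1, "z": 2}.get(axis, axis)
    if not isinstance(ax, int) or ax not in (0, 1, 2):
        raise ValueError(f"invalid axis {axis!r}")
    centers = mask.voxel_centers_world()
    lo = centers[..., ax].min()
    hi = centers[..., ax].max()
    if not (lo - 1e-9 <= plane_coord_mm <= hi + 1e-9):
        raise ValueError(
            f"mirror plane {plane_coord_mm} mm lies outside grid "
            f"extent [{lo}, {hi}] on axis {ax}")
    pts = centers.reshape(-1, 3).copy()
    pts[:, ax] = 2.0 * plane_coord_mm - pts[:, ax]
    sampled = sample_trilinear(mask, pts)
    out = (sampled >= interpolation_threshold).reshape(mask.shape)
    return BinaryMask(out, mask.affine.copy())


def _decimation_factors(vol: VolumeGrid, target_voxel_mm: float) -> np.ndarray:
    factors = np.asarray(target_voxel_mm, dtype=float) / vol.voxel_size
    rounded = np.rint(factors)
    if np.any(rounded < 1 - 1e-9):
        raise ValueError("target voxel size must be >= source voxel size")
    if not np.allclose(factors, rounded, atol=1e-6):
        raise ValueError(
            f"non-integer decimation factor {factors} for target "
            f"{target_voxel_mm} mm")
    f = rounded.astype(int)
    if np.any(np.mod(vol.shape, f) != 0):
        raise ValueError(
            f"grid shape {vol.shape} not divisible by decimation factor {f}")
    return f


def downsample_volume(
    vol: VolumeGrid,
    target_voxel_mm: float,
    reduce: str = "mean",
) -> VolumeGrid:
    """Integer-factor block downsampling.

    ``reduce='mean'`` block-averages scalars; ``reduce='any'`` marks a
    coarse voxel active if any voxel of its block is active (the
    conservative rule for masks used in visitation counting). The affine
    is updated so the world extent is preserved.
    """
    f = _decimation_factors(vol, target_voxel_mm)
    x, y, z = vol.shape
    blocks = np.asarray(vol.values, dtype=float).reshape(
        x // f[0], f[0], y // f[1], f[1], z // f[2], f[2])
    if reduce == "mean":
        out = blocks.mean(axis=(1, 3, 5))
    elif reduce == "any":
        out = blocks.max(axis=(1, 3, 5)) > 0
    else:
        raise ValueError(f"unknown reduce rule {reduce!r}")
    new_affine = vol.affine.copy()
    new_affine[:3, :3] = vol.affine[:3, :3] * f[np.newaxis, :]
    # coarse voxel (0,0,0) center sits at fine index (f-1)/2
    first_center = (np.asarray(f, float) - 1.0) / 2.0
    new_affine[:3, 3] = vol.voxel_to_world(first_center)[0]
    if reduce == "any":
        return BinaryMask(out, new_affine)
    return VolumeGrid(out, new_affine)


def downsample_mask(mask: BinaryMask, target_voxel_mm: float) -> BinaryMask:
    out = downsample_volume(mask, target_voxel_mm, reduce="any")
    assert isinstance(out, BinaryMask)
    return out
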