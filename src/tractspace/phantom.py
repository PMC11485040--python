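"""Synthetic phantom brains with known ground truth.

A phantom is an ellipsoidal "brain" carrying a small repertoire of
tube-shaped white-matter tracts. Each tract is a quadratic Bezier curve
between two cortical *hubs* on a shell just inside the brain surface,
thickened to a tube; inside the tube the dominant fibre orientation is the
curve tangent, and where tubes overlap the voxel carries several
orientations with volume fractions proportional to tube membership.
Outside the tubes a smooth "funnel" orientation field points from the
cortex towards the nearest hub, so that streamlines seeded on the
cortical surface are guided into the tubes — a crude but fully controlled
stand-in for superficial white matter.

The default repertoire has four bilateral tract types (left/right
pairs, each attached to its own hub with a subcortical far end) plus two
commissural tracts crossing the midline — ten tracts — and eight
cortical parcels (one per hub). Every parcel thereby touches a
distinctive combination of tracts, which makes cortical locations
identifiable from their tract-connectivity profile alone — the property
the blueprint/divergence machinery is designed to exploit.

Twin pairs emulate a cross-species setting: two brains share the tract
repertoire and the vertex parametrisation (hence a known vertex-level
correspondence), but differ in geometry — by default tube calibre,
superficial funnel depth and commissural curve shape; global scale and
rotation are also available — which changes tract masses and the mixing
proportions of streamlines where bundles meet, the synthetic analogue of
two species whose homologous tracts attach to cortex with different
emphasis.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import ConvexHull, cKDTree

from .imaging import (
    BinaryMask,
    SurfaceMesh,
    VolumeGrid,
    WarpField,
    read_surface,
    read_vertex_map,
    read_volume,
    write_surface,
    write_vertex_map,
    write_volume,
)

__all__ = [
    "FiberOrientationField",
    "PhantomSpec",
    "PhantomBrain",
    "TwinPair",
    "TubeSpec",
    "DEFAULT_HUBS",
    "DEFAULT_TRACTS",
    "make_phantom_brain",
    "make_twin_pair",
    "make_smooth_warp",
    "save_phantom",
    "load_phantom",
]


@dataclasses.dataclass
class FiberOrientationField:
    """Per-voxel set of up to 3 unit orientations with volume fractions."""

    directions: np.ndarray  # (X, Y, Z, 3, 3); [..., m, :] is orientation m
    fractions: np.ndarray  # (X, Y, Z, 3)
    affine: np.ndarray  # voxel -> world

    def __post_init__(self) -> None:
        self.directions = np.ascontiguousarray(self.directions, dtype=np.float64)
        self.fractions = np.ascontiguousarray(self.fractions, dtype=np.float64)
        if self.fractions.min() < 0:
            raise ValueError("volume fractions must be non-negative")
        if self.fractions.sum(axis=-1).max() > 1 + 1e-9:
            raise ValueError("per-voxel volume fractions must sum to <= 1")
        norms = np.linalg.norm(self.directions, axis=-1)
        active = self.fractions > 0
        if active.any() and not np.allclose(norms[active], 1.0, atol=1e-6):
            raise ValueError("active orientations must be unit-norm")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.fractions.shape[:3]  # type: ignore[return-value]


@dataclasses.dataclass(frozen=True)
class TubeSpec:
    """One tube-shaped tract: a Bezier curve between two named hubs.

    If ``deep_b`` is set, the far end is not cortical: it sits at that
    (fractional) depth along hub_b's direction, emulating a projection
    tract with one cortical and one subcortical termination.
    ``radius_scale`` multiplies the phantom-wide tube radius; giving the
    two hemispheres slightly different calibres breaks the left/right
    mirror degeneracy of connectivity profiles (real hemispheres are not
    mirror images either), while protocol ROIs — spheres at mirrored
    curve points — remain exactly mirror-symmetric.
    """

    name: str
    abbreviation: str
    category: str  # association | commissural | limbic | projection
    hemisphere: str  # left | right | none
    hub_a: str
    hub_b: str
    deep_b: float | None = None
    radius_scale: float = 1.0


def _unit(v) -> tuple[float, float, float]:
    a = np.asarray(v, dtype=float)
    a = a / np.linalg.norm(a)
    return (float(a[0]), float(a[1]), float(a[2]))


# Eight hubs on the cortical shell; the left four mirror to the right four.
DEFAULT_HUBS: dict[str, tuple[float, float, float]] = {
    "L1": _unit((-0.60, 0.62, 0.50)),
    "L2": _unit((-0.60, -0.62, 0.50)),
    "L3": _unit((-0.60, -0.52, -0.60)),
    "L4": _unit((-0.60, 0.52, -0.60)),
    "R1": _unit((0.60, 0.62, 0.50)),
    "R2": _unit((0.60, -0.62, 0.50)),
    "R3": _unit((0.60, -0.52, -0.60)),
    "R4": _unit((0.60, 0.52, -0.60)),
}

# Four bilateral tract types (each hub hosts its own radiation-like tube
# with a subcortical far end, so every parcel carries a distinctive
# dominant tract) plus two commissural tubes crossing the midline, whose
# cortical attachments overlap the L1/R1 and L3/R3 private tubes — those
# four parcels therefore show characteristic tract *mixtures*.
DEFAULT_TRACTS: tuple[TubeSpec, ...] = (
    TubeSpec("arc_l", "ARC_L", "association", "left", "L1", "L1",
             deep_b=0.45),
    TubeSpec("arc_r", "ARC_R", "association", "right", "R1", "R1",
             deep_b=0.45, radius_scale=1.15),
    TubeSpec("vert_l", "VRT_L", "limbic", "left", "L2", "L2", deep_b=0.45),
    TubeSpec("vert_r", "VRT_R", "limbic", "right", "R2", "R2",
             deep_b=0.45, radius_scale=1.15),
    TubeSpec("atr_l", "ATR_L", "projection", "left", "L3", "L3",
             deep_b=0.45),
    TubeSpec("atr_r", "ATR_R", "projection", "right", "R3", "R3",
             deep_b=0.45, radius_scale=1.15),
    TubeSpec("rad_l", "RAD_L", "projection", "left", "L4", "L4",
             deep_b=0.45),
    TubeSpec("rad_r", "RAD_R", "projection", "right", "R4", "R4",
             deep_b=0.45, radius_scale=1.15),
    TubeSpec("comm_a", "CMA", "commissural", "none", "L1", "R1",
             radius_scale=0.75),
    TubeSpec("comm_p", "CMP", "commissural", "none", "L3", "R3",
             radius_scale=0.75),
)


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom brain (a pure function input).

    ``scale``/``rotation_deg`` apply a similarity transform to the whole
    geometry (used to make twin-"species" partners); ``membership_sharpness``
    is the exponent applied to tube-membership weights when several tubes
    share a voxel, controlling how quickly streamlines commit to one
    bundle at junctions; ``funnel_depth`` sets how deep below the shell
    the superficial funnel field aims.
    """

    shape: tuple[int, int, int] = (40, 48, 40)
    voxel_mm: float = 1.0
    tube_radius_mm: float = 2.5
    shell_frac: float = 0.92
    brain_frac: float = 0.44
    n_vertices: int = 600
    noise: float = 0.05
    seed: int = 0
    scale: float = 1.0
    rotation_deg: float = 0.0
    funnel_depth: float = 0.90
    funnel_jitter_deg: float = 0.0
    membership_sharpness: float = 1.0
    control_pull: float = 0.35
    tracts: tuple[TubeSpec, ...] = DEFAULT_TRACTS
    hubs: tuple[tuple[str, tuple[float, float, float]], ...] = tuple(
        DEFAULT_HUBS.items()
    )

    def __post_init__(self) -> None:
        if self.tube_radius_mm < self.voxel_mm:
            raise ValueError("tube radius must be >= voxel size")
        if len(self.hubs) < 2:
            raise ValueError("need at least 2 parcels (hubs)")
        names = [t.name for t in self.tracts]
        if len(set(names)) != len(names):
            raise ValueError("duplicate tract names")

    @property
    def hub_dict(self) -> dict[str, tuple[float, float, float]]:
        return dict(self.hubs)

    @property
    def n_parcels(self) -> int:
        return len(self.hubs)


@dataclasses.dataclass
class PhantomBrain:
    spec: PhantomSpec
    brain_mask: BinaryMask
    field: FiberOrientationField
    fa: VolumeGrid
    md: VolumeGrid
    surface: SurfaceMesh
    parcel_labels: np.ndarray  # (V,) int, hub index
    parcel_names: list[str]
    myelin: np.ndarray  # (V,) ground-truth scalar map
    tract_masks: dict[str, BinaryMask]
    curves: dict[str, tuple[np.ndarray, np.ndarray]]  # samples, tangents
    hubs_world: dict[str, np.ndarray]
    protocols: "object"  # ProtocolSet; typed loosely to avoid import cycle


@dataclasses.dataclass
class TwinPair:
    brain_a: PhantomBrain
    brain_b: PhantomBrain
    correspondence: np.ndarray  # (V,) index into B vertices for each A vertex
    warp: WarpField


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _similarity(spec: PhantomSpec) -> np.ndarray:
    th = np.deg2rad(spec.rotation_deg)
    rot = np.array([
        [np.cos(th), -np.sin(th), 0.0],
        [np.sin(th), np.cos(th), 0.0],
        [0.0, 0.0, 1.0],
    ])
    return spec.scale * rot


def _bezier(p0, c, p1, n: int) -> tuple[np.ndarray, np.ndarray]:
    t = np.linspace(0.0, 1.0, n)[:, None]
    pts = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * c + t**2 * p1
    dv = 2 * (1 - t) * (c - p0) + 2 * t * (p1 - c)
    tan = dv / np.linalg.norm(dv, axis=1, keepdims=True)
    return pts, tan


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float)
    phi = (1 + 5**0.5) / 2
    z = 1 - 2 * (i + 0.5) / n
    r = np.sqrt(1 - z**2)
    theta = 2 * np.pi * i / phi
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def _ball_mask(grid_world: np.ndarray, center: np.ndarray, radius: float,
               brain: np.ndarray) -> np.ndarray:
    d2 = ((grid_world - center) ** 2).sum(axis=-1)
    return (d2 <= radius**2) & brain


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def make_phantom_brain(spec: PhantomSpec) -> PhantomBrain:
    """Generate one phantom brain; deterministic given ``spec`` (incl. seed)."""
    from .protocols import ProtocolSet, TractProtocol  # local: avoid cycle
    from .tracking import ProtocolROIs

    rng = np.random.default_rng(spec.seed)
    shape = np.asarray(spec.shape, dtype=int)
    v = spec.voxel_mm
    affine = np.eye(4)
    affine[:3, :3] *= v
    affine[:3, 3] = -(shape - 1) / 2.0 * v

    grid = VolumeGrid(np.zeros(tuple(shape), dtype=np.uint8), affine)
    world = grid.voxel_centers_world()  # (X, Y, Z, 3)
    semi = spec.brain_frac * shape * v  # ellipsoid semi-axes, mm
    frac2 = ((world / semi) ** 2).sum(axis=-1)
    brain = frac2 <= 1.0
    brain_mask = BinaryMask(brain, affine)

    T = _similarity(spec)
    hub_dict = spec.hub_dict
    hubs_world = {
        name: T @ (spec.shell_frac * semi * np.asarray(u))
        for name, u in hub_dict.items()
    }

    # --- tract curves -----------------------------------------------------
    curves: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for tract in spec.tracts:
        p0u = spec.shell_frac * semi * np.asarray(hub_dict[tract.hub_a])
        depth_b = spec.shell_frac if tract.deep_b is None else tract.deep_b
        p1u = depth_b * semi * np.asarray(hub_dict[tract.hub_b])
        c = spec.control_pull * (p0u + p1u) / 2.0
        length_est = np.linalg.norm(p1u - p0u) * 1.3
        n = max(64, int(np.ceil(length_est / 0.25)))
        pts, tan = _bezier(p0u, c, p1u, n)
        pts = pts @ T.T
        tan = tan @ T.T
        tan /= np.linalg.norm(tan, axis=1, keepdims=True)
        inside = ((pts / semi) ** 2).sum(axis=1)
        if inside.max() > 0.98:
            raise ValueError(f"tube {tract.name} exits the brain mask")
        curves[tract.name] = (pts, tan)

    # --- fibre field ------------------------------------------------------
    radii = np.array([spec.tube_radius_mm * t.radius_scale
                      for t in spec.tracts])
    flat_world = world.reshape(-1, 3)
    n_vox = flat_world.shape[0]
    n_tracts = len(spec.tracts)
    dist = np.empty((n_tracts, n_vox))
    tangent_at = np.empty((n_tracts, n_vox, 3))
    for ti, tract in enumerate(spec.tracts):
        pts, tan = curves[tract.name]
        tree = cKDTree(pts)
        d, idx = tree.query(flat_world)
        dist[ti] = d
        tangent_at[ti] = tan[idx]

    # gentle falloff: near-equal fractions where tubes overlap, so tube
    # choice at junctions stays genuinely stochastic per streamline
    rcol = radii[:, None]
    member = np.where(dist <= rcol, np.exp(-0.5 * (dist / rcol) ** 2), 0.0)
    member = member**spec.membership_sharpness
    in_tube = (dist <= rcol).any(axis=0)

    directions = np.zeros((n_vox, 3, 3))
    fractions = np.zeros((n_vox, 3))

    tube_idx = np.flatnonzero(in_tube & brain.reshape(-1))
    # keep the top-3 memberships per voxel
    order = np.argsort(-member[:, tube_idx], axis=0)[:3]
    for slot in range(min(3, n_tracts)):
        ti = order[slot]
        w = member[ti, tube_idx]
        directions[tube_idx, slot] = tangent_at[ti, tube_idx]
        fractions[tube_idx, slot] = w
    tot = fractions[tube_idx].sum(axis=1, keepdims=True)
    fractions[tube_idx] = 0.85 * fractions[tube_idx] / np.maximum(tot, 1e-12)

    funnel_idx = np.flatnonzero(brain.reshape(-1) & ~in_tube)
    hub_arr = np.stack(list(hubs_world.values()))
    d_hub = np.linalg.norm(
        flat_world[funnel_idx, None, :] - hub_arr[None, :, :], axis=2)
    nearest = np.argmin(d_hub, axis=1)
    target = spec.funnel_depth * hub_arr[nearest]
    vec = target - flat_world[funnel_idx]
    nrm = np.linalg.norm(vec, axis=1, keepdims=True)
    vec = np.where(nrm > 1e-9, vec / np.maximum(nrm, 1e-12),
                   np.array([0.0, 0.0, 1.0]))
    # two orientations splayed around the hub direction: per-step sampling
    # then diffuses superficial paths laterally, so where a streamline
    # meets the tube caps is stochastic rather than fixed by its vertex
    axis1 = np.cross(vec, np.array([0.0, 0.0, 1.0]))
    bad = np.linalg.norm(axis1, axis=1) < 1e-6
    axis1[bad] = np.cross(vec[bad], np.array([1.0, 0.0, 0.0]))
    axis1 /= np.linalg.norm(axis1, axis=1, keepdims=True)
    ang = np.deg2rad(spec.funnel_jitter_deg)
    for slot, sign in ((0, 1.0), (1, -1.0)):
        jit = np.cos(ang) * vec + sign * np.sin(ang) * axis1
        jit /= np.linalg.norm(jit, axis=1, keepdims=True)
        directions[funnel_idx, slot] = jit
        fractions[funnel_idx, slot] = 0.25

    field = FiberOrientationField(
        directions.reshape(tuple(shape) + (3, 3)),
        fractions.reshape(tuple(shape) + (3,)),
        affine,
    )

    # --- scalar maps ------------------------------------------------------
    fa = np.where(in_tube.reshape(tuple(shape)), 0.7, 0.2)
    fa = fa + spec.noise * rng.standard_normal(tuple(shape))
    fa = np.clip(fa, 0.0, 1.0) * brain
    md = np.where(in_tube.reshape(tuple(shape)), 0.6e-3, 0.9e-3)
    md = md + spec.noise * 1e-4 * rng.standard_normal(tuple(shape))
    md = np.clip(md, 1e-5, None) * brain

    # --- surface, parcels, myelin ----------------------------------------
    units = _fibonacci_sphere(spec.n_vertices)
    verts = (spec.shell_frac * semi * units) @ T.T
    faces = ConvexHull(units).simplices
    surface = SurfaceMesh(verts, faces)

    d_vh = np.linalg.norm(verts[:, None, :] - hub_arr[None, :, :], axis=2)
    parcel_labels = np.argmin(d_vh, axis=1)
    parcel_names = list(hubs_world.keys())

    # bilaterally symmetric parcel baseline (as real T1w/T2w myelin maps
    # roughly are), varying smoothly around the ring of hubs so that
    # spatially adjacent parcels have similar values, plus a gentle
    # geometric gradient
    n_base = max(2, (len(parcel_names) + 1) // 2)
    ring = np.arange(n_base)
    base = 0.6 + 0.4 * np.cos(2 * np.pi * ring / n_base)
    myelin = (1.0 + 0.4 * base[parcel_labels % n_base]
              + 0.25 * units[:, 2])
    surface.scalars["myelin"] = myelin
    surface.scalars["parcel"] = parcel_labels.astype(np.int32)

    # --- ground-truth tract masks and protocols ---------------------------
    tract_masks: dict[str, BinaryMask] = {}
    protocols = []
    for ti, tract in enumerate(spec.tracts):
        r_t = radii[ti]
        tm = (dist[ti] <= r_t).reshape(tuple(shape)) & brain
        tract_masks[tract.name] = BinaryMask(tm, affine)

        pts, _ = curves[tract.name]
        n = len(pts)
        # seed/target sit just inside the tube ends, clear of the hub
        # junction where sibling tubes overlap; the ROI ball radius
        # follows the tube calibre (tight ROIs for thin tubes) but uses
        # the left partner's calibre on both sides so bilateral protocol
        # pairs stay exactly mirror-symmetric
        seed_c = pts[int(0.15 * (n - 1))]
        targ_c = pts[int(0.85 * (n - 1))]
        way_c = pts[(n - 1) // 2]
        roi_scale = tract.radius_scale
        if tract.hemisphere == "right":
            partner = tract.name[:-2] + "_l"
            for t2 in spec.tracts:
                if t2.name == partner:
                    roi_scale = t2.radius_scale
        roi_r = float(np.clip(0.85 * spec.tube_radius_mm * roi_scale,
                              1.2, 2.2))
        seed = _ball_mask(world, seed_c, roi_r, brain)
        targ = _ball_mask(world, targ_c, roi_r, brain)
        way = _ball_mask(world, way_c, 4.0, brain)
        # off-tract exclusion ball, pushed away from the curve midpoint;
        # right-hemisphere tracts reuse the mirrored left exclusion so a
        # symmetric phantom has exactly mirror-symmetric protocols
        excl = None
        if tract.hemisphere == "right":
            partner = tract.name[:-2] + "_l"
            left = next((p for p in protocols if p.name == partner), None)
            if left is not None:
                cand = left.rois.exclusion.values[::-1, :, :]
                clear = dist[ti].reshape(tuple(shape)) > r_t + 2.0
                if (cand & brain & clear).sum() >= 3:
                    excl = cand & brain & clear
        if excl is None:
            chord = pts[-1] - pts[0]
            normal = np.cross(chord, np.array([0.0, 0.0, 1.0]))
            if np.linalg.norm(normal) < 1e-6:
                normal = np.cross(chord, np.array([0.0, 1.0, 0.0]))
            normal /= np.linalg.norm(normal)
            excl = np.zeros(tuple(shape), dtype=bool)
            for off in (r_t + 5.0, r_t + 4.0, -(r_t + 5.0), -(r_t + 4.0)):
                cand_c = way_c + off * normal
                cand = _ball_mask(world, cand_c, 2.0, brain)
                cand &= (dist[ti].reshape(tuple(shape)) > r_t + 2.0)
                if cand.sum() >= 3:
                    excl = cand
                    break
        if not seed.any() or not targ.any():
            raise ValueError(f"empty seed/target ROI for tract {tract.name}")
        rois = ProtocolROIs(
            seed=BinaryMask(seed, affine),
            waypoints=(BinaryMask(way, affine),),
            exclusion=BinaryMask(excl, affine),
            stop=None,
            target=BinaryMask(targ, affine),
        )
        protocols.append(TractProtocol(
            name=tract.name, abbreviation=tract.abbreviation,
            category=tract.category, hemisphere=tract.hemisphere, rois=rois))

    pset = ProtocolSet(
        template=f"phantom-{spec.seed}", protocols=protocols,
        brain_mask=brain_mask)

    return PhantomBrain(
        spec=spec, brain_mask=brain_mask, field=field,
        fa=VolumeGrid(fa, affine), md=VolumeGrid(md, affine),
        surface=surface, parcel_labels=parcel_labels,
        parcel_names=parcel_names, myelin=myelin,
        tract_masks=tract_masks, curves=curves, hubs_world=hubs_world,
        protocols=pset)


def make_twin_pair(
    spec_a: PhantomSpec,
    spec_b: PhantomSpec | None = None,
    seed: int = 0,
) -> TwinPair:
    """Two phantom "species" with known vertex correspondence.

    By default the partner keeps the tract repertoire, hubs and vertex
    parametrisation of ``spec_a`` but carries thicker tubes (calibre
    x1.28), a shallower superficial funnel and straighter commissural
    curves — so homologous cortical locations keep the same *pattern* of
    tract attachment while tract masses and mixing proportions genuinely
    differ. The scalar ("myelin") map of B is the pull-back of A's map
    through the correspondence plus Gaussian noise of s.d.
    ``spec_b.noise``.
    """
    if spec_b is None:
        spec_b = dataclasses.replace(
            spec_a,
            tube_radius_mm=1.28 * spec_a.tube_radius_mm,
            funnel_depth=0.85,
            control_pull=0.28,
            seed=seed + 1,
        )
    if [t.name for t in spec_a.tracts] != [t.name for t in spec_b.tracts]:
        raise ValueError("twin specs must share the tract repertoire")
    if spec_a.n_vertices != spec_b.n_vertices:
        raise ValueError("twin specs must share the vertex parametrisation")
    if spec_a.hubs != spec_b.hubs:
        raise ValueError("twin specs must share hub placement")

    brain_a = make_phantom_brain(spec_a)
    brain_b = make_phantom_brain(spec_b)
    correspondence = np.arange(spec_a.n_vertices)

    rng = np.random.default_rng(seed + 2)
    myelin_b = brain_a.myelin[correspondence].copy()
    if spec_b.noise > 0:
        myelin_b = myelin_b + spec_b.noise * rng.standard_normal(len(myelin_b))
    brain_b.myelin = myelin_b
    brain_b.surface.scalars["myelin"] = myelin_b

    grid_a = brain_a.brain_mask
    grid_b = brain_b.brain_mask
    warp = make_smooth_warp(grid_a, grid_b, amplitude_mm=1.5,
                            smoothness_mm=6.0, seed=seed + 3)
    return TwinPair(brain_a, brain_b, correspondence, warp)


def make_smooth_warp(
    grid_a: VolumeGrid,
    grid_b: VolumeGrid,
    amplitude_mm: float,
    smoothness_mm: float,
    seed: int = 0,
) -> WarpField:
    """Smooth random displacement on grid B pointing into grid A's space.

    Band-limited Gaussian noise, rescaled so the maximum displacement norm
    equals ``amplitude_mm``; the world-frame identity provides the affine
    bridge between the grids (amplitude 0 gives a pure affine bridge).
    Requires amplitude < smoothness/2, which keeps the warp invertible in
    practice.
    """
    if amplitude_mm < 0:
        raise ValueError("amplitude must be >= 0")
    if amplitude_mm > 0 and not amplitude_mm < smoothness_mm / 2.0:
        raise ValueError("require amplitude < smoothness/2")
    disp = np.zeros(grid_b.shape + (3,))
    if amplitude_mm > 0:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(grid_b.shape + (3,))
        sigma = smoothness_mm / grid_b.voxel_size
        for c in range(3):
            disp[..., c] = gaussian_filter(noise[..., c], sigma=sigma)
        maxnorm = np.linalg.norm(disp, axis=-1).max()
        if maxnorm > 0:
            disp *= amplitude_mm / maxnorm
    return WarpField(disp, grid_b.affine.copy())


# ---------------------------------------------------------------------------
# file export / import (NIfTI + GIFTI + JSON manifest)
# ---------------------------------------------------------------------------

def save_phantom(brain: PhantomBrain, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(brain.brain_mask, out / "brain_mask.nii.gz")
    write_volume(brain.fa, out / "fa.nii.gz")
    write_volume(brain.md, out / "md.nii.gz")
    sh = brain.field.shape
    import nibabel as nib

    nib.save(nib.Nifti1Image(
        brain.field.directions.reshape(sh + (9,)).astype(np.float32),
        brain.field.affine), str(out / "fibre_dirs.nii.gz"))
    nib.save(nib.Nifti1Image(
        brain.field.fractions.astype(np.float32), brain.field.affine),
        str(out / "fibre_fracs.nii.gz"))
    write_surface(brain.surface, out / "wgb.surf.gii")
    write_vertex_map(brain.myelin, out / "myelin.shape.gii")
    write_vertex_map(brain.parcel_labels.astype(np.float32),
                     out / "parcels.shape.gii")
    for name, m in brain.tract_masks.items():
        write_volume(m, out / f"tract_{name}.nii.gz")
    from .protocols import save_protocol_set

    save_protocol_set(brain.protocols, out / "protocols")
    manifest = {
        "seed": brain.spec.seed,
        "shape": list(brain.spec.shape),
        "voxel_mm": brain.spec.voxel_mm,
        "n_vertices": brain.spec.n_vertices,
        "tracts": [t.name for t in brain.spec.tracts],
        "parcel_names": brain.parcel_names,
        "scale": brain.spec.scale,
        "rotation_deg": brain.spec.rotation_deg,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_phantom(path: str | Path):
    """Load the file-level view of a phantom directory.

    Returns a dict with the fields needed by the CLI stages (brain mask,
    fibre field, surface, scalars, protocols, manifest). Only the pieces
    that round-trip through standard formats are restored; curves and the
    spec itself are not.
    """
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    brain_mask = read_volume(path / "brain_mask.nii.gz", mask=True)
    import nibabel as nib

    dimg = nib.load(str(path / "fibre_dirs.nii.gz"))
    dirs = np.asanyarray(dimg.dataobj).astype(np.float64)
    dirs = dirs.reshape(dirs.shape[:3] + (3, 3))
    fimg = nib.load(str(path / "fibre_fracs.nii.gz"))
    fracs = np.asanyarray(fimg.dataobj).astype(np.float64)
    field = FiberOrientationField(dirs, fracs, np.asarray(dimg.affine))
    surface = read_surface(path / "wgb.surf.gii")
    surface.scalars["myelin"] = read_vertex_map(path / "myelin.shape.gii")
    surface.scalars["parcel"] = read_vertex_map(
        path / "parcels.shape.gii").astype(np.int64)
    from .protocols import load_protocol_set

    protocols = load_protocol_set(path / "protocols", brain_mask)
    return {
        "manifest": manifest,
        "brain_mask": brain_mask,
        "field": field,
        "surface": surface,
        "fa": read_volume(path / "fa.nii.gz"),
        "md": read_volume(path / "md.nii.gz"),
        "protocols": protocols,
    }
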