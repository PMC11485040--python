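"""Tract protocol sets: inventory expansion, warp transfer, QC, revision.

A *protocol* is the set of ROI masks (seed, waypoints, exclusion, stop,
target) that constrains tracking for one named tract. Protocol sets are
defined on a template grid and moved between template grids by warp
resampling; because warped ROIs routinely develop defects — overlap with
exclusion masks, spill outside the brain, left-right asymmetry — a QC
battery flags protocols needing revision, and a small algebra of mask
edits (add / subtract / mirror-from-contralateral / erode-along-interface)
implements the revisions.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import (
    BinaryMask,
    WarpField,
    apply_warp_to_mask,
    mirror_mask,
    read_volume,
    write_volume,
)
from .tracking import ProtocolROIs

__all__ = [
    "CATEGORIES",
    "STANDARD_TRACT_INVENTORY",
    "TractProtocol",
    "ProtocolSet",
    "QCReport",
    "expand_tract_inventory",
    "warp_protocol_set",
    "qc_protocol_set",
    "apply_revision",
    "save_protocol_set",
    "load_protocol_set",
]

CATEGORIES = ("association", "commissural", "limbic", "projection")

#: The standard 23-type cross-species tract repertoire (10 association,
#: 4 commissural, 4 limbic, 5 projection). All non-commissural types are
#: bilateral, so expansion yields 19 x 2 + 4 = 42 protocols.
STANDARD_TRACT_INVENTORY: tuple[tuple[str, str, str], ...] = (
    ("Arcuate fasciculus", "AF", "association"),
    ("Frontal aslant tract", "FA", "association"),
    ("Inferior fronto-occipital fasciculus", "IFO", "association"),
    ("Inferior longitudinal fasciculus", "ILF", "association"),
    ("Middle longitudinal fasciculus", "MDLF", "association"),
    ("Superior longitudinal fasciculus I", "SLF1", "association"),
    ("Superior longitudinal fasciculus II", "SLF2", "association"),
    ("Superior longitudinal fasciculus III", "SLF3", "association"),
    ("Uncinate fasciculus", "UF", "association"),
    ("Vertical occipital fasciculus", "VOF", "association"),
    ("Anterior commissure", "AC", "commissural"),
    ("Forceps major", "FMA", "commissural"),
    ("Forceps minor", "FMI", "commissural"),
    ("Middle cerebellar peduncle", "MCP", "commissural"),
    ("Cingulum bundle: dorsal section", "CBD", "limbic"),
    ("Cingulum bundle: perigenual section", "CBP", "limbic"),
    ("Cingulum bundle: temporal section", "CBT", "limbic"),
    ("Fornix", "FX", "limbic"),
    ("Acoustic radiation", "AR", "projection"),
    ("Anterior thalamic radiation", "ATR", "projection"),
    ("Corticospinal tract", "CST", "projection"),
    ("Optic radiation", "OR", "projection"),
    ("Superior thalamic radiation", "STR", "projection"),
)


@dataclasses.dataclass
class TractProtocol:
    name: str
    abbreviation: str
    category: str
    hemisphere: str  # left | right | none
    rois: ProtocolROIs | None = None
    provenance: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"invalid category {self.category!r}")
        if self.hemisphere not in ("left", "right", "none"):
            raise ValueError(f"invalid hemisphere {self.hemisphere!r}")
        if (self.category == "commissural") != (self.hemisphere == "none"):
            raise ValueError(
                "commissural tracts (and only those) have hemisphere 'none'")

    @property
    def pair_key(self) -> str:
        """Base abbreviation shared by a left/right pair."""
        for suffix in ("_L", "_R"):
            if self.abbreviation.endswith(suffix):
                return self.abbreviation[: -len(suffix)]
        return self.abbreviation


@dataclasses.dataclass
class ProtocolSet:
    template: str
    protocols: list[TractProtocol]
    brain_mask: BinaryMask

    def __post_init__(self) -> None:
        abbrevs = [p.abbreviation for p in self.protocols]
        if len(set(abbrevs)) != len(abbrevs):
            raise ValueError("duplicate abbreviation in protocol set")

    def get(self, abbreviation: str) -> TractProtocol:
        for p in self.protocols:
            if p.abbreviation == abbreviation:
                return p
        raise KeyError(abbreviation)

    def __len__(self) -> int:
        return len(self.protocols)


@dataclasses.dataclass
class QCReport:
    """Per-tract QC metrics with pass/fail flags.

    ``table`` has one row per (tract, roi-or-roi-pair, metric); metrics
    are ``overlap`` (voxel counts for ROI pairs), ``out_of_brain`` (voxel
    counts per ROI) and ``asymmetry`` (1 - Dice between an ROI and the
    mirrored contralateral ROI, in [0, 1]).
    """

    table: pd.DataFrame
    thresholds: dict[str, float]
    failing: list[str]

    def passed(self) -> bool:
        return not self.failing


DEFAULT_QC_THRESHOLDS = {
    "seed_exclude_overlap": 0,
    "target_exclude_overlap": 0,
    "out_of_brain": 0,
    "asymmetry": 0.5,
}


def expand_tract_inventory(
    table=STANDARD_TRACT_INVENTORY,
) -> list[TractProtocol]:
    """Expand (name, abbreviation, category) rows into protocol stubs.

    Non-commissural entries yield a left and a right stub; commissural
    entries yield a single one.
    """
    stubs: list[TractProtocol] = []
    seen: set[str] = set()
    for name, abbrev, category in table:
        if category not in CATEGORIES:
            raise ValueError(f"invalid category {category!r} for {abbrev}")
        if abbrev in seen:
            raise ValueError(f"duplicate abbreviation {abbrev!r}")
        seen.add(abbrev)
        if category == "commissural":
            stubs.append(TractProtocol(name, abbrev, category, "none"))
        else:
            stubs.append(TractProtocol(
                f"{name} (left)", f"{abbrev}_L", category, "left"))
            stubs.append(TractProtocol(
                f"{name} (right)", f"{abbrev}_R", category, "right"))
    return stubs


def _warp_rois(rois: ProtocolROIs, warp: WarpField) -> ProtocolROIs:
    def w(m: BinaryMask | None) -> BinaryMask | None:
        return None if m is None else apply_warp_to_mask(m, warp)

    return ProtocolROIs(
        seed=w(rois.seed),
        waypoints=tuple(w(m) for m in rois.waypoints),
        exclusion=w(rois.exclusion),
        stop=w(rois.stop),
        target=w(rois.target),
    )


def warp_protocol_set(
    pset: ProtocolSet,
    warp: WarpField,
    target_brain_mask: BinaryMask,
    target_template: str = "warped",
) -> tuple[ProtocolSet, list[str]]:
    """Warp every ROI of every protocol onto the warp's target grid.

    Returns the new set and a list of "<abbrev>:<roi>" labels for ROIs
    that came out empty (flagged, not errors).
    """
    if tuple(warp.shape) != tuple(target_brain_mask.shape) or not np.allclose(
            warp.affine, target_brain_mask.affine):
        raise ValueError("warp target grid does not match target brain mask")
    flagged: list[str] = []
    new_protocols = []
    for p in pset.protocols:
        if p.rois is None:
            raise ValueError(f"protocol {p.abbreviation} has no ROIs")
        rois = _warp_rois(p.rois, warp)
        for roi_name, m in rois.all_masks().items():
            if m.n_active == 0:
                flagged.append(f"{p.abbreviation}:{roi_name}")
        new_protocols.append(dataclasses.replace(
            p, rois=rois,
            provenance=p.provenance + [f"warped to {target_template}"]))
    return (ProtocolSet(target_template, new_protocols, target_brain_mask),
            flagged)


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def qc_protocol_set(
    pset: ProtocolSet,
    midline_plane: tuple[str | int, float] = ("x", 0.0),
    thresholds: dict[str, float] | None = None,
) -> QCReport:
    """QC battery: ROI-pair overlap, out-of-brain spill, L-R asymmetry.

    Overlap is computed for all ROI pairs but only seed-exclude and
    target-exclude overlaps are hard failures by default (waypoints may
    legitimately touch other ROIs). Asymmetry of an ROI is 1 - Dice
    between the mirrored contralateral ROI and the ROI itself; every
    bilateral tract must have a contralateral partner.
    """
    thr = dict(DEFAULT_QC_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    axis, coord = midline_plane
    brain = pset.brain_mask.values
    rows: list[dict] = []
    failing: set[str] = set()

    by_key: dict[tuple[str, str], TractProtocol] = {}
    for p in pset.protocols:
        by_key[(p.pair_key, p.hemisphere)] = p

    for p in pset.protocols:
        if p.rois is None:
            raise ValueError(f"protocol {p.abbreviation} has no ROIs")
        masks = p.rois.all_masks()
        names = list(masks)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                overlap = int((masks[a].values & masks[b].values).sum())
                pair = {a, b}
                if pair == {"seed", "exclude"}:
                    key, hard = "seed_exclude_overlap", True
                elif pair == {"target", "exclude"}:
                    key, hard = "target_exclude_overlap", True
                else:
                    key, hard = "overlap", False
                ok = (overlap <= thr[key]) if hard else True
                rows.append(dict(tract=p.abbreviation, roi=f"{a}&{b}",
                                 metric="overlap", value=overlap, passed=ok))
                if not ok:
                    failing.add(p.abbreviation)
        for name, m in masks.items():
            oob = int((m.values & ~brain).sum())
            ok = oob <= thr["out_of_brain"]
            rows.append(dict(tract=p.abbreviation, roi=name,
                             metric="out_of_brain", value=oob, passed=ok))
            if not ok:
                failing.add(p.abbreviation)
        if p.hemisphere in ("left", "right"):
            other_hemi = "right" if p.hemisphere == "left" else "left"
            partner = by_key.get((p.pair_key, other_hemi))
            if partner is None or partner.rois is None:
                raise ValueError(
                    f"bilateral tract {p.abbreviation} lacks a "
                    f"contralateral partner")
            partner_masks = partner.rois.all_masks()
            for name, m in masks.items():
                if name not in partner_masks:
                    continue
                mirrored = mirror_mask(partner_masks[name], axis, coord)
                asym = 1.0 - _dice(mirrored.values, m.values)
                ok = asym <= thr["asymmetry"]
                rows.append(dict(tract=p.abbreviation, roi=name,
                                 metric="asymmetry", value=asym, passed=ok))
                if not ok:
                    failing.add(p.abbreviation)

    table = pd.DataFrame(rows, columns=["tract", "roi", "metric", "value",
                                        "passed"])
    return QCReport(table=table, thresholds=thr, failing=sorted(failing))


# --- revision operators ----------------------------------------------------

def _get_roi(rois: ProtocolROIs, name: str) -> BinaryMask:
    masks = rois.all_masks()
    if name not in masks:
        raise ValueError(f"protocol has no ROI named {name!r}")
    return masks[name]


def _set_roi(rois: ProtocolROIs, name: str, mask: BinaryMask) -> ProtocolROIs:
    if name == "seed":
        return dataclasses.replace(rois, seed=mask)
    if name == "target":
        return dataclasses.replace(rois, target=mask)
    if name == "exclude":
        return dataclasses.replace(rois, exclusion=mask)
    if name == "stop":
        return dataclasses.replace(rois, stop=mask)
    if name.startswith("waypoint"):
        idx = 0 if name == "waypoint" else int(name[len("waypoint"):])
        ways = list(rois.waypoints)
        ways[idx] = mask
        return dataclasses.replace(rois, waypoints=tuple(ways))
    raise ValueError(f"unknown ROI name {name!r}")


def apply_revision(protocol: TractProtocol, edits: list[tuple]) -> TractProtocol:
    """Apply deterministic mask-algebra edits to a protocol's ROIs.

    Supported edits (first element of each tuple):

    * ``("add", roi_name, mask)`` — union the mask in;
    * ``("subtract", roi_name, mask)`` — remove the mask's voxels;
    * ``("mirror_from_contralateral", roi_name, partner_protocol, axis, coord)``
      — replace the ROI with the mirrored contralateral ROI;
    * ``("erode_interface", roi_name, interface_mask)`` — remove the ROI
      voxels 6-adjacent to (or overlapping) the interface mask, i.e. a
      one-voxel erosion along the shared border.

    Every edit is recorded in the protocol's provenance. An edit that
    empties the seed is an error.
    """
    if protocol.rois is None:
        raise ValueError("protocol has no ROIs to revise")
    rois = protocol.rois
    provenance = list(protocol.provenance)
    for edit in edits:
        op, roi_name = edit[0], edit[1]
        current = _get_roi(rois, roi_name)
        if op == "add":
            new_vals = current.values | edit[2].values
        elif op == "subtract":
            new_vals = current.values & ~edit[2].values
        elif op == "mirror_from_contralateral":
            partner, axis, coord = edit[2], edit[3], edit[4]
            if partner.rois is None:
                raise ValueError("contralateral protocol has no ROIs")
            new_vals = mirror_mask(_get_roi(partner.rois, roi_name),
                                   axis, coord).values
        elif op == "erode_interface":
            interface = edit[2].values
            struct = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
            near = ndimage.binary_dilation(interface, structure=struct)
            new_vals = current.values & ~near
        else:
            raise ValueError(f"unknown edit {op!r}")
        if roi_name == "seed" and not new_vals.any():
            raise ValueError(f"edit {op!r} would empty the seed")
        rois = _set_roi(rois, roi_name, current.with_values(new_vals))
        provenance.append(f"{op}:{roi_name}")
    return dataclasses.replace(protocol, rois=rois, provenance=provenance)


# --- protocol directory layout ---------------------------------------------

def save_protocol_set(pset: ProtocolSet, out_dir: str | Path) -> None:
    """One directory per tract with seed/target/exclude/stop NIfTI masks."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(pset.brain_mask, out / "brain_mask.nii.gz")
    manifest = {"template": pset.template, "tracts": []}
    for p in pset.protocols:
        tract_dir = out / p.abbreviation
        tract_dir.mkdir(exist_ok=True)
        roi_files = {}
        if p.rois is not None:
            for roi_name, m in p.rois.all_masks().items():
                fname = f"{roi_name}.nii.gz"
                write_volume(m, tract_dir / fname)
                roi_files[roi_name] = fname
        manifest["tracts"].append({
            "name": p.name, "abbreviation": p.abbreviation,
            "category": p.category, "hemisphere": p.hemisphere,
            "rois": roi_files, "provenance": p.provenance,
        })
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_protocol_set(path: str | Path,
                      brain_mask: BinaryMask | None = None) -> ProtocolSet:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    if brain_mask is None:
        brain_mask = read_volume(path / "brain_mask.nii.gz", mask=True)
    protocols = []
    for entry in manifest["tracts"]:
        tract_dir = path / entry["abbreviation"]
        masks = {name: read_volume(tract_dir / fname, mask=True)
                 for name, fname in entry["rois"].items()}
        waypoints = tuple(masks[k] for k in sorted(masks)
                          if k.startswith("waypoint"))
        rois = None
        if masks:
            rois = ProtocolROIs(
                seed=masks["seed"], waypoints=waypoints,
                exclusion=masks.get("exclude"), stop=masks.get("stop"),
                target=masks.get("target"))
        protocols.append(TractProtocol(
            name=entry["name"], abbreviation=entry["abbreviation"],
            category=entry["category"], hemisphere=entry["hemisphere"],
            rois=rois, provenance=list(entry.get("provenance", []))))
    return ProtocolSet(manifest["template"], protocols, brain_mask)
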