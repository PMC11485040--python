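"""Tract similarity metrics, microstructure summaries, population atlases.

Path distributions are normalised by the number of valid streamlines,
thresholded at 0.1 % (>= rule, so a value of exactly 0.001 survives) and
compared across runs/templates by Pearson correlation of the vectorised
values inside a reference mask. Within-tract microstructure is summarised
as the median FA and MD inside the thresholded tract mask, and population
atlases give the percentage of subjects in which a tract is present at a
voxel.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .imaging import BinaryMask, VolumeGrid
from .tracking import PathDistribution

__all__ = [
    "NormalisedPathDistribution",
    "normalise",
    "threshold_binarise",
    "path_correlation",
    "tract_microstructure",
    "percent_difference",
    "population_atlas",
    "similarity_table",
    "microstructure_table",
]

DEFAULT_THRESHOLD = 0.001  # "0.1 %" of the valid-streamline count


@dataclasses.dataclass
class NormalisedPathDistribution:
    """Visitation fractions (counts / n_valid) with provenance.

    The raw integer counts are retained so downstream consumers that need
    exact arithmetic (the blueprint builder) can work on numerators.
    """

    values: VolumeGrid  # fractions in [0, 1]
    counts: VolumeGrid
    n_valid: int
    zero_valid: bool = False
    tract: str = ""
    subject: str = ""
    template: str = ""


def normalise(pd_: PathDistribution, tract: str = "", subject: str = "",
              template: str = "") -> NormalisedPathDistribution:
    """counts / n_valid; an all-zero (flagged) map when n_valid == 0."""
    counts = np.asarray(pd_.counts.values)
    if counts.min() < 0:
        raise ValueError("negative counts")
    if pd_.n_valid == 0:
        vals = np.zeros_like(counts, dtype=float)
        return NormalisedPathDistribution(
            pd_.counts.with_values(vals), pd_.counts, 0, zero_valid=True,
            tract=tract, subject=subject, template=template)
    vals = counts.astype(float) / pd_.n_valid
    return NormalisedPathDistribution(
        pd_.counts.with_values(vals), pd_.counts, pd_.n_valid,
        tract=tract, subject=subject, template=template)


def threshold_binarise(npd: NormalisedPathDistribution,
                       level: float = DEFAULT_THRESHOLD) -> BinaryMask:
    """Voxel active iff its visitation fraction is >= level."""
    vals = np.asarray(npd.values.values)
    return BinaryMask(vals >= level, npd.values.affine.copy())


def path_correlation(
    npd_a: NormalisedPathDistribution,
    npd_b: NormalisedPathDistribution,
    reference_mask: BinaryMask,
    threshold_level: float | None = DEFAULT_THRESHOLD,
) -> float:
    """Pearson r between two path distributions inside a reference mask.

    Both volumes are vectorised over the reference-mask voxels in a fixed
    lexicographic voxel order. By default values below the 0.1 % threshold
    are zeroed first (pass ``threshold_level=None`` to correlate raw
    fractions). Returns nan if either vector is constant (flagged case).
    """
    if not npd_a.values.same_grid(npd_b.values) or not npd_a.values.same_grid(
            reference_mask):
        raise ValueError("path distributions and mask must share one grid")
    if reference_mask.n_active == 0:
        raise ValueError("empty reference mask")
    sel = reference_mask.values
    a = np.asarray(npd_a.values.values)[sel].astype(float)
    b = np.asarray(npd_b.values.values)[sel].astype(float)
    if threshold_level is not None:
        a = np.where(a >= threshold_level, a, 0.0)
        b = np.where(b >= threshold_level, b, 0.0)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)


def tract_microstructure(
    mask: BinaryMask, fa: VolumeGrid, md: VolumeGrid
) -> tuple[float, float]:
    """(median FA, median MD) over in-mask voxels; (nan, nan) if empty."""
    if not mask.same_grid(fa) or not mask.same_grid(md):
        raise ValueError("mask and maps must share one grid")
    if mask.n_active == 0:
        return (float("nan"), float("nan"))
    sel = mask.values
    return (float(np.median(np.asarray(fa.values)[sel])),
            float(np.median(np.asarray(md.values)[sel])))


def percent_difference(value: float, reference: float) -> float:
    """Signed percent difference, 100 * (value - reference) / reference."""
    if reference == 0:
        raise ValueError("zero reference")
    return 100.0 * (value - reference) / reference


def population_atlas(masks: list[BinaryMask]) -> VolumeGrid:
    """Percentage of subjects with the tract present at each voxel."""
    if not masks:
        raise ValueError("need at least one mask")
    first = masks[0]
    for m in masks[1:]:
        if not m.same_grid(first):
            raise ValueError("masks must share one grid")
    stack = np.stack([np.asarray(m.values, dtype=float) for m in masks])
    return VolumeGrid(100.0 * stack.mean(axis=0), first.affine.copy())


def similarity_table(rows: list[dict]) -> pd.DataFrame:
    """Long-form (tract, subject, template, r) table with a summary.

    ``rows`` are dicts with keys tract/subject/template/r; the returned
    frame carries a ``summary()``-style mean +/- sd via groupby.
    """
    df = pd.DataFrame(rows, columns=["tract", "subject", "template", "r"])
    return df


def microstructure_table(rows: list[dict],
                         reference_template: str | None = None) -> pd.DataFrame:
    """(tract, subject, template, median_fa, median_md) with optional
    percent differences against a reference template."""
    df = pd.DataFrame(rows, columns=["tract", "subject", "template",
                                     "median_fa", "median_md"])
    if reference_template is not None:
        ref = df[df.template == reference_template].set_index(
            ["tract", "subject"])
        for col in ("median_fa", "median_md"):
            ref_vals = df.set_index(["tract", "subject"]).index.map(
                ref[col].to_dict())
            df[f"{col}_pct_diff"] = 100.0 * (
                df[col].to_numpy() - ref_vals.to_numpy()
            ) / ref_vals.to_numpy()
    return df
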