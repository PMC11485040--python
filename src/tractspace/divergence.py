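"""Symmetric-KL comparison of connectivity blueprints.

Blueprint rows are probability profiles over a shared tract repertoire,
so two brains' cortical locations can be compared — regardless of their
geometries — by the symmetric Kullback-Leibler divergence between rows.
Profiles are floored at a small epsilon and renormalised before taking
logs (blueprints legitimately contain zeros), divergences are in nats,
and the symmetric form is the arithmetic mean of the two directed
divergences (mean vs sum only rescales; it never reorders matches).

On top of the pairwise divergence matrix the module provides the two
downstream operations of the cross-brain framework: homologue
identification (the target-brain vertices with lowest divergence to a
source region's average profile) and scalar-map projection (transferring
a per-vertex scalar between brains using minimum-divergence or
softmax-weighted correspondences).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .blueprints import ConnectivityBlueprint

__all__ = [
    "DEFAULT_EPSILON",
    "KLMatrix",
    "HomologueResult",
    "MinKLSummary",
    "MapComparison",
    "symmetric_kl",
    "kl_matrix",
    "min_kl_summary",
    "find_homologue",
    "project_scalar_map",
    "compare_maps",
]

DEFAULT_EPSILON = 1e-8


def _floor_normalise(p: np.ndarray, epsilon: float) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.min() < 0:
        raise ValueError("profiles must be non-negative")
    sums = p.sum(axis=-1)
    if np.any(sums <= 0):
        raise ValueError("all-zero profile")
    q = np.maximum(p, epsilon)
    return q / q.sum(axis=-1, keepdims=True)


def symmetric_kl(p: np.ndarray, q: np.ndarray,
                 epsilon: float = DEFAULT_EPSILON) -> float:
    """Mean of the two directed KL divergences, in nats.

    Profiles are floored at ``epsilon`` and renormalised first; zero iff
    the floored profiles coincide.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("profiles must have the same length")
    pn = _floor_normalise(p, epsilon)
    qn = _floor_normalise(q, epsilon)
    log_ratio = np.log(pn) - np.log(qn)
    return float(0.5 * (np.sum(pn * log_ratio) - np.sum(qn * log_ratio)))


@dataclasses.dataclass
class KLMatrix:
    """(non-excluded vertices of A x non-excluded vertices of B)."""

    values: np.ndarray
    row_vertices: np.ndarray  # original vertex indices in A
    col_vertices: np.ndarray  # original vertex indices in B
    n_vertices_a: int
    n_vertices_b: int
    epsilon: float
    tract_names: list[str]


def kl_matrix(bp_a: ConnectivityBlueprint, bp_b: ConnectivityBlueprint,
              epsilon: float = DEFAULT_EPSILON) -> KLMatrix:
    """All-pairs symmetric KL between two blueprints' non-excluded rows."""
    if bp_a.tract_names != bp_b.tract_names:
        raise ValueError("tract frames differ (names/order must match)")
    rows_a = bp_a.active_rows()
    rows_b = bp_b.active_rows()
    P = _floor_normalise(bp_a.values[rows_a], epsilon)
    Q = _floor_normalise(bp_b.values[rows_b], epsilon)
    logP = np.log(P)
    logQ = np.log(Q)
    ent_p = np.sum(P * logP, axis=1)  # (nA,)
    ent_q = np.sum(Q * logQ, axis=1)  # (nB,)
    d_pq = ent_p[:, None] - P @ logQ.T
    d_qp = ent_q[None, :] - logP @ Q.T
    vals = 0.5 * (d_pq + d_qp)
    np.maximum(vals, 0.0, out=vals)  # clip numeric negatives near zero
    return KLMatrix(values=vals, row_vertices=rows_a, col_vertices=rows_b,
                    n_vertices_a=bp_a.n_vertices, n_vertices_b=bp_b.n_vertices,
                    epsilon=epsilon, tract_names=list(bp_a.tract_names))


@dataclasses.dataclass
class MinKLSummary:
    minima: np.ndarray  # per kept vertex
    argmin_vertices: np.ndarray  # original vertex indices on the other side
    vertices: np.ndarray  # original vertex indices on this side
    ties: np.ndarray  # bool, lowest-index tie-break applied
    median: float
    quartiles: tuple[float, float]


def min_kl_summary(klm: KLMatrix, direction: str = "rows") -> MinKLSummary:
    """Row-wise (or column-wise) minima with argmin and tie flags.

    ``direction='rows'``: best match in B for each kept A vertex;
    ``'cols'``: best match in A for each kept B vertex. The distribution
    of minima is summarised as median and quartiles.
    """
    if klm.values.size == 0:
        raise ValueError("empty KL matrix")
    if direction == "rows":
        mat, this, other = klm.values, klm.row_vertices, klm.col_vertices
    elif direction == "cols":
        mat, this, other = klm.values.T, klm.col_vertices, klm.row_vertices
    else:
        raise ValueError("direction must be 'rows' or 'cols'")
    arg = np.argmin(mat, axis=1)  # lowest index on ties
    minima = mat[np.arange(mat.shape[0]), arg]
    ties = (mat == minima[:, None]).sum(axis=1) > 1
    q1, med, q3 = np.percentile(minima, [25, 50, 75])
    return MinKLSummary(minima=minima, argmin_vertices=other[arg],
                        vertices=this, ties=ties, median=float(med),
                        quartiles=(float(q1), float(q3)))


@dataclasses.dataclass
class HomologueResult:
    divergence: np.ndarray  # (V_target,), nan for excluded vertices
    mask: np.ndarray  # (V_target,) bool, lowest-divergence set
    argmin_vertex: int
    percentile_cut: float


def find_homologue(bp_target: ConnectivityBlueprint,
                   source_profile: np.ndarray,
                   percentile_cut: float = 5.0,
                   epsilon: float = DEFAULT_EPSILON) -> HomologueResult:
    """Target vertices most similar to a source region's average profile.

    Computes the symmetric KL of every non-excluded target row to the
    profile and returns the set below the stated divergence percentile.
    """
    source_profile = np.asarray(source_profile, dtype=float)
    rows = bp_target.active_rows()
    if rows.size == 0:
        raise ValueError("all target vertices are excluded")
    P = _floor_normalise(bp_target.values[rows], epsilon)
    q = _floor_normalise(source_profile, epsilon)
    logP = np.log(P)
    logq = np.log(q)
    d = 0.5 * (np.sum(P * (logP - logq[None, :]), axis=1)
               + np.sum(q[None, :] * (logq[None, :] - logP), axis=1))
    d = np.maximum(d, 0.0)
    cut = np.percentile(d, percentile_cut)
    div = np.full(bp_target.n_vertices, np.nan)
    div[rows] = d
    mask = np.zeros(bp_target.n_vertices, dtype=bool)
    mask[rows] = d <= cut
    return HomologueResult(divergence=div, mask=mask,
                           argmin_vertex=int(rows[np.argmin(d)]),
                           percentile_cut=percentile_cut)


def project_scalar_map(klm: KLMatrix, source_map: np.ndarray,
                       mode: str = "softmax",
                       temperature: float | None = None) -> np.ndarray:
    """Project a per-vertex scalar from the column (source) brain onto
    the row (target) brain through the divergence matrix.

    ``mode='argmin'``: each target vertex takes the source value at its
    minimum-divergence source vertex. ``mode='softmax'``: weighted mean
    with weights ~ exp(-KL / temperature); the default temperature is the
    median of the KL matrix (scale-adaptive smoothing). Excluded target
    vertices receive nan.
    """
    source_map = np.asarray(source_map, dtype=float)
    if source_map.shape[0] != klm.n_vertices_b:
        raise ValueError("source map is not on the KL matrix's source frame")
    src = source_map[klm.col_vertices]
    out = np.full(klm.n_vertices_a, np.nan)
    if mode == "argmin":
        arg = np.argmin(klm.values, axis=1)
        out[klm.row_vertices] = src[arg]
    elif mode == "softmax":
        if temperature is None:
            temperature = float(np.median(klm.values))
            if temperature <= 0:
                temperature = 1.0
        if temperature <= 0:
            raise ValueError("temperature must be > 0 in softmax mode")
        w = np.exp(-(klm.values - klm.values.min(axis=1, keepdims=True))
                   / temperature)
        w /= w.sum(axis=1, keepdims=True)
        out[klm.row_vertices] = w @ src
    else:
        raise ValueError("mode must be 'argmin' or 'softmax'")
    return out


@dataclasses.dataclass
class MapComparison:
    r: float
    abs_difference: np.ndarray
    n_used: int
    constant_input: bool = False


def compare_maps(predicted: np.ndarray, measured: np.ndarray) -> MapComparison:
    """Pearson r plus per-vertex absolute difference (nan-aware).

    Vertices where either map is nan (e.g. excluded) are dropped from the
    correlation; a constant input flags r as undefined (nan).
    """
    predicted = np.asarray(predicted, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if predicted.shape != measured.shape:
        raise ValueError("maps must share one vertex frame")
    diff = np.abs(predicted - measured)
    keep = np.isfinite(predicted) & np.isfinite(measured)
    a, b = predicted[keep], measured[keep]
    if len(a) < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return MapComparison(float("nan"), diff, int(keep.sum()),
                             constant_input=True)
    r = float(stats.pearsonr(a, b).statistic)
    return MapComparison(r, diff, int(keep.sum()))
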