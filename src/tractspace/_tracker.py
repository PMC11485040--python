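"""Numba kernels for streamline propagation and visitation counting.

The propagation rule (shared by every driver):

* orientations are looked up at the nearest voxel (no interpolation);
* candidate orientations are those with volume fraction above the
  subsidiary-fibre threshold; one is sampled with probability
  proportional to its fraction;
* the sampled orientation's sign is flipped if needed so its angle with
  the previous direction is <= 90 degrees; if the remaining turn exceeds
  the curvature limit the streamline terminates without taking the step;
* termination also occurs on leaving the brain mask, entering a stop
  mask, exhausting the step budget, or reaching a voxel with no
  orientation above threshold;
* both directions from the seed point are tracked and concatenated.

Randomness: each streamline seeds numpy's global (numba-local) RNG with
its own 31-bit seed, so results are bit-reproducible and independent of
how streamlines are batched.
"""

import numpy as np
from numba import njit

# termination reasons
LEFT_MASK = 0
STOP = 1
MAX_STEPS = 2
CURVATURE = 3
NO_FIBRE = 4

REASON_NAMES = ("left_mask", "stop", "max_steps", "curvature", "no_fibre")


@njit(cache=True)
def _voxel_of(px, py, pz, inv_lin, inv_off, sx, sy, sz):
    x = inv_lin[0, 0] * px + inv_lin[0, 1] * py + inv_lin[0, 2] * pz + inv_off[0]
    y = inv_lin[1, 0] * px + inv_lin[1, 1] * py + inv_lin[1, 2] * pz + inv_off[1]
    z = inv_lin[2, 0] * px + inv_lin[2, 1] * py + inv_lin[2, 2] * pz + inv_off[2]
    i = int(np.floor(x + 0.5))
    j = int(np.floor(y + 0.5))
    k = int(np.floor(z + 0.5))
    inside = 0 <= i < sx and 0 <= j < sy and 0 <= k < sz
    return i, j, k, inside


@njit(cache=True)
def _sample_orientation(dirs, fracs, i, j, k, min_vf):
    """Pick an orientation at voxel (i,j,k) with prob ~ fraction.

    Returns (ok, dx, dy, dz).
    """
    tot = 0.0
    for m in range(3):
        f = fracs[i, j, k, m]
        if f > min_vf:
            tot += f
    if tot <= 0.0:
        return False, 0.0, 0.0, 0.0
    u = np.random.random() * tot
    acc = 0.0
    for m in range(3):
        f = fracs[i, j, k, m]
        if f > min_vf:
            acc += f
            if u <= acc:
                return True, dirs[i, j, k, m, 0], dirs[i, j, k, m, 1], dirs[i, j, k, m, 2]
    m = 2  # numeric fall-through: take the last candidate
    for mm in range(2, -1, -1):
        if fracs[i, j, k, mm] > min_vf:
            m = mm
            break
    return True, dirs[i, j, k, m, 0], dirs[i, j, k, m, 1], dirs[i, j, k, m, 2]


@njit(cache=True)
def _half(px, py, pz, dx, dy, dz, dirs, fracs, mask, stop,
          inv_lin, inv_off, step, cos_lim, max_steps, min_vf,
          pts, base, direction):
    """Track one half-streamline.

    Writes points at pts[base + direction*n] for n = 1..n_written and
    returns (n_written, reason). The seed point itself lives at pts[base].
    """
    sx, sy, sz = mask.shape
    n = 0
    for _ in range(max_steps):
        i, j, k, inside = _voxel_of(px, py, pz, inv_lin, inv_off, sx, sy, sz)
        if not inside or mask[i, j, k] == 0:
            return n, LEFT_MASK
        ok, ndx, ndy, ndz = _sample_orientation(dirs, fracs, i, j, k, min_vf)
        if not ok:
            return n, NO_FIBRE
        dot = ndx * dx + ndy * dy + ndz * dz
        if dot < 0.0:
            ndx, ndy, ndz, dot = -ndx, -ndy, -ndz, -dot
        if dot < cos_lim - 1e-12:
            return n, CURVATURE
        qx = px + step * ndx
        qy = py + step * ndy
        qz = pz + step * ndz
        i2, j2, k2, inside2 = _voxel_of(qx, qy, qz, inv_lin, inv_off, sx, sy, sz)
        if not inside2 or mask[i2, j2, k2] == 0:
            return n, LEFT_MASK
        n += 1
        idx = base + direction * n
        pts[idx, 0] = qx
        pts[idx, 1] = qy
        pts[idx, 2] = qz
        px, py, pz = qx, qy, qz
        dx, dy, dz = ndx, ndy, ndz
        if stop[i2, j2, k2] != 0:
            return n, STOP
    return n, MAX_STEPS


@njit(cache=True)
def _track_one(start, seed, dirs, fracs, mask, stop,
               inv_lin, inv_off, step, cos_lim, max_steps, min_vf, pts):
    """Full two-sided streamline into the shared pts buffer.

    pts has shape (2*max_steps + 1, 3); the seed sits at index max_steps,
    the forward half grows upward, the backward half downward. Returns
    (n_back, n_fwd, reason_back, reason_fwd); the occupied slice is
    pts[max_steps - n_back : max_steps + n_fwd + 1].
    """
    np.random.seed(seed)
    sx, sy, sz = mask.shape
    base = max_steps
    pts[base, 0] = start[0]
    pts[base, 1] = start[1]
    pts[base, 2] = start[2]
    i, j, k, inside = _voxel_of(start[0], start[1], start[2],
                                inv_lin, inv_off, sx, sy, sz)
    if not inside or mask[i, j, k] == 0:
        return 0, 0, LEFT_MASK, LEFT_MASK
    if stop[i, j, k] != 0:
        return 0, 0, STOP, STOP
    ok, d0x, d0y, d0z = _sample_orientation(dirs, fracs, i, j, k, min_vf)
    if not ok:
        return 0, 0, NO_FIBRE, NO_FIBRE
    nf, rf = _half(start[0], start[1], start[2], d0x, d0y, d0z,
                   dirs, fracs, mask, stop, inv_lin, inv_off,
                   step, cos_lim, max_steps, min_vf, pts, base, 1)
    nb, rb = _half(start[0], start[1], start[2], -d0x, -d0y, -d0z,
                   dirs, fracs, mask, stop, inv_lin, inv_off,
                   step, cos_lim, max_steps, min_vf, pts, base, -1)
    return nb, nf, rb, rf


@njit(cache=True)
def _protocol_drive(starts, seeds, dirs, fracs, mask, stop, excl,
                    ways, target, has_target,
                    inv_lin, inv_off, step, cos_lim, max_steps, min_vf,
                    counts, stamp, pts, vox_buf):
    """Run all streamlines of one protocol; accumulate valid visitations.

    counts: (X, Y, Z) int64 visitation counts (one per streamline per
    voxel); stamp: int64 workspace initialised to -1; vox_buf: int64
    (2*max_steps+1, 3) workspace. Returns n_valid.
    """
    sx, sy, sz = mask.shape
    n_valid = 0
    n_ways = ways.shape[0]
    way_hit = np.zeros(8, dtype=np.uint8)
    for s in range(starts.shape[0]):
        nb, nf, rb, rf = _track_one(
            starts[s], seeds[s], dirs, fracs, mask, stop,
            inv_lin, inv_off, step, cos_lim, max_steps, min_vf, pts)
        lo = max_steps - nb
        hi = max_steps + nf
        for w in range(n_ways):
            way_hit[w] = 0
        tgt_hit = False
        exc_hit = False
        n_vox = 0
        for idx in range(lo, hi + 1):
            i, j, k, inside = _voxel_of(pts[idx, 0], pts[idx, 1], pts[idx, 2],
                                        inv_lin, inv_off, sx, sy, sz)
            if not inside:
                continue
            if excl[i, j, k] != 0:
                exc_hit = True
                break
            if stamp[i, j, k] != s:
                stamp[i, j, k] = s
                vox_buf[n_vox, 0] = i
                vox_buf[n_vox, 1] = j
                vox_buf[n_vox, 2] = k
                n_vox += 1
            for w in range(n_ways):
                if ways[w, i, j, k] != 0:
                    way_hit[w] = 1
            if has_target and target[i, j, k] != 0:
                tgt_hit = True
        valid = not exc_hit
        if has_target and not tgt_hit:
            valid = False
        for w in range(n_ways):
            if way_hit[w] == 0:
                valid = False
        if valid:
            n_valid += 1
            for q in range(n_vox):
                counts[vox_buf[q, 0], vox_buf[q, 1], vox_buf[q, 2]] += 1
    return n_valid


@njit(cache=True)
def _coarse_flat(px, py, pz, cinv_lin, cinv_off, cx, cy, cz):
    i = int(np.floor(cinv_lin[0, 0] * px + cinv_lin[0, 1] * py
                     + cinv_lin[0, 2] * pz + cinv_off[0] + 0.5))
    j = int(np.floor(cinv_lin[1, 0] * px + cinv_lin[1, 1] * py
                     + cinv_lin[1, 2] * pz + cinv_off[1] + 0.5))
    k = int(np.floor(cinv_lin[2, 0] * px + cinv_lin[2, 1] * py
                     + cinv_lin[2, 2] * pz + cinv_off[2] + 0.5))
    if 0 <= i < cx and 0 <= j < cy and 0 <= k < cz:
        return (i * cy + j) * cz + k
    return -1


@njit(cache=True)
def _surface_drive(verts, seeds, n_per, dirs, fracs, mask, stop,
                   inv_lin, inv_off, cinv_lin, cinv_off, cshape,
                   step, cos_lim, max_steps, min_vf, conn, cstamp, pts):
    """Seed n_per streamlines per vertex; count coarse-voxel visitations.

    conn: (V, n_coarse) int64; cstamp: (n_coarse,) int64 initialised -1.
    """
    cx, cy, cz = cshape[0], cshape[1], cshape[2]
    sid = 0
    for v in range(verts.shape[0]):
        for s in range(n_per):
            nb, nf, rb, rf = _track_one(
                verts[v], seeds[sid], dirs, fracs, mask, stop,
                inv_lin, inv_off, step, cos_lim, max_steps, min_vf, pts)
            lo = max_steps - nb
            hi = max_steps + nf
            for idx in range(lo, hi + 1):
                flat = _coarse_flat(pts[idx, 0], pts[idx, 1], pts[idx, 2],
                                    cinv_lin, cinv_off, cx, cy, cz)
                if flat >= 0 and cstamp[flat] != sid:
                    cstamp[flat] = sid
                    conn[v, flat] += 1
            sid += 1


@njit(cache=True)
def _surface_oracle_drive(verts, seeds, n_per, dirs, fracs, mask, stop,
                          inv_lin, inv_off, cinv_lin, cinv_off, cshape,
                          step, cos_lim, max_steps, min_vf,
                          num_full, rows, cstamp, pts):
    """Per-streamline accumulation of integer tract numerators.

    num_full: (n_coarse, T) int64 tract-matrix numerators scattered onto
    the full coarse grid (zero off-mask); rows: (V, T) int64 output.
    Re-runs exactly the same streamlines as _surface_drive (same seeds,
    same order) and must reproduce conn @ num_full exactly.
    """
    cx, cy, cz = cshape[0], cshape[1], cshape[2]
    n_tracts = num_full.shape[1]
    sid = 0
    for v in range(verts.shape[0]):
        for s in range(n_per):
            nb, nf, rb, rf = _track_one(
                verts[v], seeds[sid], dirs, fracs, mask, stop,
                inv_lin, inv_off, step, cos_lim, max_steps, min_vf, pts)
            lo = max_steps - nb
            hi = max_steps + nf
            for idx in range(lo, hi + 1):
                flat = _coarse_flat(pts[idx, 0], pts[idx, 1], pts[idx, 2],
                                    cinv_lin, cinv_off, cx, cy, cz)
                if flat >= 0 and cstamp[flat] != sid:
                    cstamp[flat] = sid
                    for t in range(n_tracts):
                        rows[v, t] += num_full[flat, t]
            sid += 1
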