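"""Quality-guided residual-voxel growing kernel.

This module implements the inner loop of residual unwrapping: a stable
priority queue of candidate voxels ordered by (quality ascending, insertion
order), where each popped voxel is unwrapped by fitting the local
polynomial model to the already-unwrapped voxels inside a centered cubic
window and rounding the prediction to the nearest 2*pi branch.

The loop visits hundreds of thousands of voxels one at a time, so it is
compiled with numba; the source is plain Python and runs (slowly) without a
JIT as well.  Fits use ridge-stabilized normal equations on affinely
normalized coordinates (the library-level :mod:`polyunwrap.polyfit` is the
reference implementation; on well-conditioned systems the two agree to
high precision).  Three safeguards keep the growing stable in heavy noise:

* **order fallback** — sparse point sets get lower polynomial orders;
* **extrapolation guard** — a prediction further than one full turn from
  the nearest done voxel's value (at most one diagonal step away) is
  implausible for a smooth phase and triggers a lower-order refit;
* **outlier trimming** — fitting points whose residual exceeds pi are
  discarded once and the model refitted: a previously mis-unwrapped voxel
  sits a whole turn off the local surface and would otherwise poison
  every window it appears in.

A fourth mechanism, **boundary refinement**, controls the misclassification
floor in heavy noise: when the rounded offset fraction falls close to the
rounding boundary, the prediction is recomputed from *every* done voxel in
the window (not just the capped nearest subset) to shrink its variance
before the integer is committed.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    NUMBA_AVAILABLE = True
except ImportError:  # pragma: no cover
    NUMBA_AVAILABLE = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


TWO_PI = 2.0 * np.pi
MIN_POINTS_LINEAR = 8  # keep in sync with polyfit
OVERSAMPLING = 1
#: residual magnitude above which a fitting point is discarded as a
#: wrong-branch outlier (a mis-unwrapped done voxel is off by >= 2*pi)
TRIM_RESID = np.pi
#: a prediction farther than this from the nearest done voxel's value is
#: treated as implausible extrapolation and the model order is reduced;
#: candidates are 26-adjacent to a done voxel, so a smooth phase cannot
#: legitimately jump a full turn over that distance
GUARD = TWO_PI


@njit(cache=True)
def _heap_push(hkey, hord, hidx, size, key, ordv, idxv):
    i = size
    hkey[i] = key
    hord[i] = ordv
    hidx[i] = idxv
    while i > 0:
        p = (i - 1) // 2
        if hkey[p] > hkey[i] or (hkey[p] == hkey[i] and hord[p] > hord[i]):
            hkey[p], hkey[i] = hkey[i], hkey[p]
            hord[p], hord[i] = hord[i], hord[p]
            hidx[p], hidx[i] = hidx[i], hidx[p]
            i = p
        else:
            break
    return size + 1


@njit(cache=True)
def _heap_pop(hkey, hord, hidx, size):
    top = hidx[0]
    size -= 1
    hkey[0] = hkey[size]
    hord[0] = hord[size]
    hidx[0] = hidx[size]
    i = 0
    while True:
        l = 2 * i + 1
        r = l + 1
        best = i
        if l < size and (hkey[l] < hkey[best]
                         or (hkey[l] == hkey[best] and hord[l] < hord[best])):
            best = l
        if r < size and (hkey[r] < hkey[best]
                         or (hkey[r] == hkey[best] and hord[r] < hord[best])):
            best = r
        if best == i:
            break
        hkey[best], hkey[i] = hkey[i], hkey[best]
        hord[best], hord[i] = hord[i], hord[best]
        hidx[best], hidx[i] = hidx[i], hidx[best]
        i = best
    return top, size


@njit(cache=True)
def _solve_ne(cx, cy, cz, cval, keep, cnt, x0, y0, z0, Le, Me, Ne, resid_out):
    """One ridge-stabilized normal-equations fit over the kept points.

    Coordinates are normalized by centroid and half-extent of the kept
    points (mirroring polyfit).  Fills ``resid_out`` with per-point
    residuals (kept points only; others get 0) and returns the prediction
    at ``(x0, y0, z0)``.
    """
    t = (Le + 1) * (Me + 1) * (Ne + 1)
    nk = 0
    mx = 0.0
    my = 0.0
    mz = 0.0
    for i in range(cnt):
        if keep[i]:
            mx += cx[i]
            my += cy[i]
            mz += cz[i]
            nk += 1
    if nk == 0:
        return np.nan
    mx /= nk
    my /= nk
    mz /= nk
    if t == 1:
        s = 0.0
        for i in range(cnt):
            if keep[i]:
                s += cval[i]
        mean = s / nk
        for i in range(cnt):
            resid_out[i] = cval[i] - mean if keep[i] else 0.0
        return mean

    first = True
    minx = 0.0
    maxx = 0.0
    miny = 0.0
    maxy = 0.0
    minz = 0.0
    maxz = 0.0
    for i in range(cnt):
        if not keep[i]:
            continue
        if first:
            minx = cx[i]
            maxx = cx[i]
            miny = cy[i]
            maxy = cy[i]
            minz = cz[i]
            maxz = cz[i]
            first = False
        else:
            if cx[i] < minx:
                minx = cx[i]
            if cx[i] > maxx:
                maxx = cx[i]
            if cy[i] < miny:
                miny = cy[i]
            if cy[i] > maxy:
                maxy = cy[i]
            if cz[i] < minz:
                minz = cz[i]
            if cz[i] > maxz:
                maxz = cz[i]
    sx = max(1.0, (maxx - minx) / 2.0)
    sy = max(1.0, (maxy - miny) / 2.0)
    sz = max(1.0, (maxz - minz) / 2.0)

    ata = np.zeros((t, t), dtype=np.float64)
    atb = np.zeros(t, dtype=np.float64)
    row = np.empty(t, dtype=np.float64)
    px = np.empty(Le + 1, dtype=np.float64)
    py = np.empty(Me + 1, dtype=np.float64)
    pz = np.empty(Ne + 1, dtype=np.float64)
    for i in range(cnt):
        if not keep[i]:
            continue
        tx = (cx[i] - mx) / sx
        ty = (cy[i] - my) / sy
        tz = (cz[i] - mz) / sz
        px[0] = 1.0
        for l in range(1, Le + 1):
            px[l] = px[l - 1] * tx
        py[0] = 1.0
        for m in range(1, Me + 1):
            py[m] = py[m - 1] * ty
        pz[0] = 1.0
        for n in range(1, Ne + 1):
            pz[n] = pz[n - 1] * tz
        c = 0
        for l in range(Le + 1):
            for m in range(Me + 1):
                for n in range(Ne + 1):
                    row[c] = px[l] * py[m] * pz[n]
                    c += 1
        v = cval[i]
        for a in range(t):
            ra = row[a]
            atb[a] += ra * v
            for b in range(a, t):
                ata[a, b] += ra * row[b]
    for a in range(t):
        for b in range(a):
            ata[a, b] = ata[b, a]
    ridge = 1e-9 * nk
    for a in range(t):
        ata[a, a] += ridge
    coeffs = np.linalg.solve(ata, atb)

    for i in range(cnt):
        if not keep[i]:
            resid_out[i] = 0.0
            continue
        tx = (cx[i] - mx) / sx
        ty = (cy[i] - my) / sy
        tz = (cz[i] - mz) / sz
        px[0] = 1.0
        for l in range(1, Le + 1):
            px[l] = px[l - 1] * tx
        py[0] = 1.0
        for m in range(1, Me + 1):
            py[m] = py[m - 1] * ty
        pz[0] = 1.0
        for n in range(1, Ne + 1):
            pz[n] = pz[n - 1] * tz
        p = 0.0
        c = 0
        for l in range(Le + 1):
            for m in range(Me + 1):
                for n in range(Ne + 1):
                    p += coeffs[c] * px[l] * py[m] * pz[n]
                    c += 1
        resid_out[i] = cval[i] - p

    tx = (x0 - mx) / sx
    ty = (y0 - my) / sy
    tz = (z0 - mz) / sz
    px[0] = 1.0
    for l in range(1, Le + 1):
        px[l] = px[l - 1] * tx
    py[0] = 1.0
    for m in range(1, Me + 1):
        py[m] = py[m - 1] * ty
    pz[0] = 1.0
    for n in range(1, Ne + 1):
        pz[n] = pz[n - 1] * tz
    pred = 0.0
    c = 0
    for l in range(Le + 1):
        for m in range(Me + 1):
            for n in range(Ne + 1):
                pred += coeffs[c] * px[l] * py[m] * pz[n]
                c += 1
    return pred


@njit(cache=True)
def _fit_level(cx, cy, cz, cval, cnt, x0, y0, z0, Le, Me, Ne,
               keep, resid):
    """Fit one model order with a single outlier-trim round.

    Returns ``(pred, rss, nk)`` — the prediction, the residual sum of
    squares and the number of points kept after trimming (points with
    residual above pi are wrong-branch values from mis-unwrapped voxels).
    """
    for i in range(cnt):
        keep[i] = True
    pred = _solve_ne(cx, cy, cz, cval, keep, cnt,
                     x0, y0, z0, Le, Me, Ne, resid)
    if not np.isfinite(pred):
        return np.nan, np.inf, 0
    n_out = 0
    for i in range(cnt):
        if abs(resid[i]) > TRIM_RESID:
            n_out += 1
    min_keep = (Le + 1) * (Me + 1) * (Ne + 1)
    if min_keep < MIN_POINTS_LINEAR:
        min_keep = MIN_POINTS_LINEAR
    if 0 < n_out and cnt - n_out >= min_keep:
        for i in range(cnt):
            if abs(resid[i]) > TRIM_RESID:
                keep[i] = False
        pred2 = _solve_ne(cx, cy, cz, cval, keep, cnt,
                          x0, y0, z0, Le, Me, Ne, resid)
        if np.isfinite(pred2):
            pred = pred2
    rss = 0.0
    nk = 0
    for i in range(cnt):
        if keep[i]:
            rss += resid[i] * resid[i]
            nk += 1
    return pred, rss, nk


@njit(cache=True)
def _fit_predict(cx, cy, cz, cval, cnt, x0, y0, z0, L, M, N, near_val):
    """Robust adaptive-order fit; predict at ``(x0, y0, z0)``.

    Every model order the point count supports — requested orders,
    trilinear, constant — is fitted (each with one outlier-trim round)
    and the winner is chosen by an AIC-style score,
    ``n*log(rss/n) + 2*terms``: where curvature dominates noise the
    quadratic residual is decisively smaller and the full model wins;
    where the window is noise-dominated all residuals tie and the
    low-variance constant/linear model wins, which keeps the prediction
    variance (and hence the offset flip rate) small.  Candidates whose
    prediction is non-finite or violates the extrapolation guard against
    ``near_val`` are discarded; the constant model is the last resort.
    """
    terms_full = (L + 1) * (M + 1) * (N + 1)
    keep = np.empty(cnt, dtype=np.bool_)
    resid = np.empty(cnt, dtype=np.float64)

    best_pred = np.nan
    best_score = np.inf
    # level 0: constant (always available; exempt from the guard so a
    # result exists even in pathological windows)
    pred0, rss0, nk0 = _fit_level(cx, cy, cz, cval, cnt, x0, y0, z0,
                                  0, 0, 0, keep, resid)
    if np.isfinite(pred0) and nk0 > 0:
        s2 = rss0 / nk0
        if s2 < 1e-12:
            s2 = 1e-12
        best_score = nk0 * np.log(s2) + 2.0
        best_pred = pred0

    if cnt >= MIN_POINTS_LINEAR:
        pred1, rss1, nk1 = _fit_level(cx, cy, cz, cval, cnt, x0, y0, z0,
                                      1, 1, 1, keep, resid)
        if np.isfinite(pred1) and nk1 > 0 and abs(pred1 - near_val) <= GUARD:
            s2 = rss1 / nk1
            if s2 < 1e-12:
                s2 = 1e-12
            score = nk1 * np.log(s2) + 2.0 * 8.0
            if score < best_score:
                best_score = score
                best_pred = pred1

    if cnt >= OVERSAMPLING * terms_full and terms_full > 8:
        pred2, rss2, nk2 = _fit_level(cx, cy, cz, cval, cnt, x0, y0, z0,
                                      L, M, N, keep, resid)
        if np.isfinite(pred2) and nk2 > 0 and abs(pred2 - near_val) <= GUARD:
            s2 = rss2 / nk2
            if s2 < 1e-12:
                s2 = 1e-12
            score = nk2 * np.log(s2) + 2.0 * terms_full
            if score < best_score:
                best_score = score
                best_pred = pred2

    return best_pred


@njit(cache=True)
def grow_pass(wrapped, unwrapped, kvol, done, candid, quality, band,
              window, L, M, N, cap_points, refine_band,
              order_out, order_start):
    """Unwrap one pass of residual voxels by quality-guided growing.

    Candidates are voxels of ``candid`` (not yet done) that are 26-adjacent
    to a done voxel; they are processed from a stable min-heap keyed by
    (band, quality, insertion order).  ``band`` is a coarse distance-to-
    anchor layer (precomputed by the caller): ordering by it first makes
    the fronts from all anchors advance concentrically, so that regions
    grown from different anchors meet early — a mis-branched excursion
    cannot silently capture territory far from its origin.  Within a band
    the order is purely quality-guided.  Each processed voxel is fitted against the
    done voxels in its centered ``window``³ neighborhood (at most
    ``cap_points`` nearest ones; all of them when the offset fraction falls
    within ``refine_band`` of the rounding boundary), unwrapped via the
    rounded 2*pi offset, and its not-yet-queued residual neighbors are
    enqueued.  Modifies ``unwrapped``, ``kvol``, ``done`` and ``order_out``
    in place (the latter records each voxel's growing sequence number,
    starting at ``order_start``); returns the number of voxels unwrapped.
    """
    nx, ny, nz = wrapped.shape
    hw = window // 2
    nvox = nx * ny * nz

    n_candid = 0
    for xx in range(nx):
        for yy in range(ny):
            for zz in range(nz):
                if candid[xx, yy, zz] and not done[xx, yy, zz]:
                    n_candid += 1
    if n_candid == 0:
        return 0

    hkey = np.empty(n_candid + 1, dtype=np.float64)
    hord = np.empty(n_candid + 1, dtype=np.int64)
    hidx = np.empty(n_candid + 1, dtype=np.int64)
    hsize = 0
    in_heap = np.zeros(nvox, dtype=np.bool_)
    counter = 0

    # seed: candidates touching the done set, in index order
    for xx in range(nx):
        for yy in range(ny):
            for zz in range(nz):
                if not candid[xx, yy, zz] or done[xx, yy, zz]:
                    continue
                touch = False
                for dx in range(-1, 2):
                    x2 = xx + dx
                    if x2 < 0 or x2 >= nx:
                        continue
                    for dy in range(-1, 2):
                        y2 = yy + dy
                        if y2 < 0 or y2 >= ny:
                            continue
                        for dz in range(-1, 2):
                            z2 = zz + dz
                            if z2 < 0 or z2 >= nz:
                                continue
                            if done[x2, y2, z2]:
                                touch = True
                if touch:
                    flat = (xx * ny + yy) * nz + zz
                    hsize = _heap_push(hkey, hord, hidx, hsize,
                                       band[xx, yy, zz] + quality[xx, yy, zz],
                                       counter, flat)
                    in_heap[flat] = True
                    counter += 1

    wn = window * window * window
    gx = np.empty(wn, dtype=np.float64)
    gy = np.empty(wn, dtype=np.float64)
    gz = np.empty(wn, dtype=np.float64)
    gval = np.empty(wn, dtype=np.float64)
    gd2 = np.empty(wn, dtype=np.int64)
    sx = np.empty(wn, dtype=np.float64)
    sy = np.empty(wn, dtype=np.float64)
    sz = np.empty(wn, dtype=np.float64)
    sval = np.empty(wn, dtype=np.float64)

    n_new = 0
    while hsize > 0:
        flat, hsize = _heap_pop(hkey, hord, hidx, hsize)
        in_heap[flat] = False
        z0 = flat % nz
        y0 = (flat // nz) % ny
        x0 = flat // (ny * nz)
        if done[x0, y0, z0]:
            continue

        cnt = 0
        for x2 in range(max(0, x0 - hw), min(nx, x0 + hw + 1)):
            for y2 in range(max(0, y0 - hw), min(ny, y0 + hw + 1)):
                for z2 in range(max(0, z0 - hw), min(nz, z0 + hw + 1)):
                    if done[x2, y2, z2]:
                        gx[cnt] = x2
                        gy[cnt] = y2
                        gz[cnt] = z2
                        gval[cnt] = unwrapped[x2, y2, z2]
                        gd2[cnt] = ((x2 - x0) * (x2 - x0)
                                    + (y2 - y0) * (y2 - y0)
                                    + (z2 - z0) * (z2 - z0))
                        cnt += 1
        if cnt == 0:
            # unreachable for now; a later done neighbor re-enqueues it
            continue

        nearest = 0
        for i in range(1, cnt):
            if gd2[i] < gd2[nearest]:
                nearest = i
        near_val = gval[nearest]

        if cnt > cap_points:
            order = np.argsort(gd2[:cnt], kind='mergesort')
            for j in range(cap_points):
                o = order[j]
                sx[j] = gx[o]
                sy[j] = gy[o]
                sz[j] = gz[o]
                sval[j] = gval[o]
            fx, fy, fz, fv, fcnt = sx, sy, sz, sval, cap_points
        else:
            fx, fy, fz, fv, fcnt = gx, gy, gz, gval, cnt

        pred = _fit_predict(fx, fy, fz, fv, fcnt,
                            float(x0), float(y0), float(z0), L, M, N,
                            near_val)
        w = wrapped[x0, y0, z0]
        frac = (pred - w) / TWO_PI
        # boundary refinement: near the rounding boundary the capped fit's
        # noise can flip the integer; refit on every done voxel in the
        # window to shrink the prediction variance before committing
        if refine_band > 0.0 and cnt > fcnt:
            dist_half = abs(frac - np.floor(frac) - 0.5)
            if dist_half < refine_band:
                pred2 = _fit_predict(gx, gy, gz, gval, cnt,
                                     float(x0), float(y0), float(z0),
                                     L, M, N, near_val)
                if np.isfinite(pred2) and abs(pred2 - near_val) <= GUARD:
                    pred = pred2
        kk = int(np.round((pred - w) / TWO_PI))
        unwrapped[x0, y0, z0] = w + TWO_PI * kk
        kvol[x0, y0, z0] = kk
        done[x0, y0, z0] = True
        order_out[x0, y0, z0] = order_start + n_new
        n_new += 1

        for dx in range(-1, 2):
            x2 = x0 + dx
            if x2 < 0 or x2 >= nx:
                continue
            for dy in range(-1, 2):
                y2 = y0 + dy
                if y2 < 0 or y2 >= ny:
                    continue
                for dz in range(-1, 2):
                    z2 = z0 + dz
                    if z2 < 0 or z2 >= nz:
                        continue
                    if candid[x2, y2, z2] and not done[x2, y2, z2]:
                        flat2 = (x2 * ny + y2) * nz + z2
                        if not in_heap[flat2]:
                            hsize = _heap_push(hkey, hord, hidx, hsize,
                                               band[x2, y2, z2]
                                               + quality[x2, y2, z2],
                                               counter, flat2)
                            in_heap[flat2] = True
                            counter += 1
    return n_new
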