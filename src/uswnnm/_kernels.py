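"""Compiled (numba) kernels for the inner loops of the iterative denoiser.

These mirror the reference implementations in :mod:`uswnnm.patch_match` and
:mod:`uswnnm.wnnm` exactly — same candidate enumeration, same raster-order
tie-break, same shrinkage arithmetic — but are organised for speed:

* block matching evaluates each window displacement once for *all*
  reference anchors via separable box sums of the squared-difference image,
  then keeps the K smallest distances per reference with a bounded max-heap;
* singular-value shrinkage works on the eigendecomposition of the K x K
  Gram matrix of the stack (algebraically identical to shrinking the
  singular values of the stack itself, since the nonzero eigenvalues of
  ``X^T X`` are the squared singular values of ``X``).

Equivalence with the reference implementations is asserted by the tests.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _box_distances(img, p, radius):
    """Squared-difference box sums for every (displacement, anchor) pair.

    Returns D of shape (side^2, nr, nc) with side = 2*radius + 1 and
    nr/nc the number of valid patch anchors; D[di, r, c] is the SSD between
    the patch at (r, c) and the patch at (r + dr, c + dc), or +inf when the
    displaced anchor is invalid.  Displacements are enumerated in raster
    order (dr, then dc), which for a fixed reference is exactly the raster
    order of the candidate anchors.
    """
    h, w = img.shape
    nr = h - p + 1
    nc = w - p + 1
    side = 2 * radius + 1
    nd = side * side
    D = np.full((nd, nr, nc), np.inf)
    e = np.empty((h, w))
    s1 = np.empty((h, w))
    for di in range(nd):
        dr = di // side - radius
        dc = di % side - radius
        r0 = max(0, -dr)
        r1 = min(h, h - dr)  # rows where both r and r+dr are inside the image
        c0 = max(0, -dc)
        c1 = min(w, w - dc)
        for r in range(r0, r1):
            for c in range(c0, c1):
                t = img[r, c] - img[r + dr, c + dc]
                e[r, c] = t * t
        # horizontal box sums of width p
        ar0 = max(0, -dr)
        ar1 = min(nr - 1, nr - 1 - dr)
        ac0 = max(0, -dc)
        ac1 = min(nc - 1, nc - 1 - dc)
        for r in range(r0, r1):
            acc = 0.0
            for v in range(p):
                acc += e[r, ac0 + v]
            s1[r, ac0] = acc
            for c in range(ac0 + 1, ac1 + 1):
                acc += e[r, c + p - 1] - e[r, c - 1]
                s1[r, c] = acc
        # vertical box sums of height p
        for c in range(ac0, ac1 + 1):
            acc = 0.0
            for u in range(p):
                acc += s1[ar0 + u, c]
            D[di, ar0, c] = acc
            for r in range(ar0 + 1, ar1 + 1):
                acc += s1[r + p - 1, c] - s1[r - 1, c]
                D[di, r, c] = acc
    return D


@njit(cache=True)
def match_all(img, refs_r, refs_c, p, radius, K):
    """Block-match every reference anchor.

    Returns (members_r, members_c, counts): for reference i the stack anchors
    are members_*[i, :counts[i]], reference first, then the K-1 candidates
    with the smallest mean-squared difference, ties broken by raster order
    of the candidate anchors.
    """
    n = refs_r.size
    side = 2 * radius + 1
    nd = side * side
    D = _box_distances(img, p, radius)
    members_r = np.zeros((n, K), np.int64)
    members_c = np.zeros((n, K), np.int64)
    counts = np.zeros(n, np.int64)
    kn = K - 1
    heap_d = np.empty(max(kn, 1))
    heap_i = np.empty(max(kn, 1), np.int64)
    self_di = (nd - 1) // 2  # displacement (0, 0)
    for i in range(n):
        rr = refs_r[i]
        rc = refs_c[i]
        cnt = 0
        for di in range(nd):
            if di == self_di:
                continue
            d = D[di, rr, rc]
            if d == np.inf:
                continue
            if cnt < kn:
                # push and sift up (max-heap on (distance, raster index))
                j = cnt
                heap_d[j] = d
                heap_i[j] = di
                cnt += 1
                while j > 0:
                    parent = (j - 1) // 2
                    if heap_d[parent] < heap_d[j] or (
                        heap_d[parent] == heap_d[j] and heap_i[parent] < heap_i[j]
                    ):
                        heap_d[parent], heap_d[j] = heap_d[j], heap_d[parent]
                        heap_i[parent], heap_i[j] = heap_i[j], heap_i[parent]
                        j = parent
                    else:
                        break
            elif kn > 0 and (
                d < heap_d[0] or (d == heap_d[0] and di < heap_i[0])
            ):
                # replace root and sift down
                heap_d[0] = d
                heap_i[0] = di
                j = 0
                while True:
                    left = 2 * j + 1
                    right = left + 1
                    largest = j
                    if left < kn and (
                        heap_d[left] > heap_d[largest]
                        or (heap_d[left] == heap_d[largest] and heap_i[left] > heap_i[largest])
                    ):
                        largest = left
                    if right < kn and (
                        heap_d[right] > heap_d[largest]
                        or (heap_d[right] == heap_d[largest] and heap_i[right] > heap_i[largest])
                    ):
                        largest = right
                    if largest == j:
                        break
                    heap_d[j], heap_d[largest] = heap_d[largest], heap_d[j]
                    heap_i[j], heap_i[largest] = heap_i[largest], heap_i[j]
                    j = largest
        # insertion sort of the kept candidates by (distance, raster index)
        for a in range(1, cnt):
            dv = heap_d[a]
            iv = heap_i[a]
            b = a - 1
            while b >= 0 and (
                heap_d[b] > dv or (heap_d[b] == dv and heap_i[b] > iv)
            ):
                heap_d[b + 1] = heap_d[b]
                heap_i[b + 1] = heap_i[b]
                b -= 1
            heap_d[b + 1] = dv
            heap_i[b + 1] = iv
        members_r[i, 0] = rr
        members_c[i, 0] = rc
        for j in range(cnt):
            di = heap_i[j]
            members_r[i, j + 1] = rr + di // side - radius
            members_c[i, j + 1] = rc + di % side - radius
        counts[i] = cnt + 1
    return members_r, members_c, counts


@njit(cache=True)
def shrink_and_aggregate(
    x_in, y, members_r, members_c, counts, p, sigma, weight_const, weight_eps,
    intensity_scale, noise_rescale,
):
    """One pass of per-stack noise re-estimation, weighted singular-value
    shrinkage and uniform-weight collaborative aggregation.

    Returns the aggregated image (numerator / coverage count).
    """
    h, w = x_in.shape
    num = np.zeros((h, w))
    den = np.zeros((h, w))
    n = members_r.shape[0]
    npx = p * p
    for i in range(n):
        k = counts[i]
        stack = np.empty((npx, k))
        msr = 0.0
        for j in range(k):
            ar = members_r[i, j]
            ac = members_c[i, j]
            for u in range(p):
                for v in range(p):
                    xv = x_in[ar + u, ac + v]
                    stack[u * p + v, j] = xv
                    t = y[ar + u, ac + v] - xv
                    msr += t * t
        msr /= npx * k
        sig2 = noise_rescale * (sigma * sigma - msr)
        if sig2 < 0.0:
            sig2 = 0.0
        if sig2 > 0.0:
            # eigendecomposition of the Gram matrix: eigenvalues are the
            # squared singular values of the stack, eigenvectors are the
            # right singular vectors
            gram = stack.T @ stack
            evals, evecs = np.linalg.eigh(gram)
            w_num = intensity_scale * weight_const * np.sqrt(k) * sig2
            coef = np.empty(k)
            for j in range(k):
                lam = evals[j] if evals[j] > 0.0 else 0.0
                s = np.sqrt(lam)
                sig_hat2 = lam - k * sig2
                sig_hat = np.sqrt(sig_hat2) if sig_hat2 > 0.0 else 0.0
                s_shrunk = s - w_num / (sig_hat + weight_eps)
                if s_shrunk < 0.0:
                    s_shrunk = 0.0
                coef[j] = s_shrunk / s if s > 1e-12 else 0.0
            denoised = stack @ ((evecs * coef) @ evecs.T)
        else:
            # clean stack: all weights are zero, shrinkage is the identity
            denoised = stack
        for j in range(k):
            ar = members_r[i, j]
            ac = members_c[i, j]
            for u in range(p):
                for v in range(p):
                    num[ar + u, ac + v] += denoised[u * p + v, j]
                    den[ar + u, ac + v] += 1.0
    return num / den
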