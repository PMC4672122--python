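"""Numba-compiled inner loops for the morphological shared-weight network.

The network trains by per-sample (sequential) gradient descent, which in
pure numpy is dominated by Python call overhead; these kernels implement
the exact same arithmetic as the numpy reference in :mod:`spinewave.rmsnn`
(a unit test keeps the two in lockstep).

Layout: a 2-feature-layer network with ``M`` maps per layer, one-to-one
connectivity between layers, shared Hit/Miss structuring elements stored
flat over the ``nd`` domain offsets ``(dy, dx)``.  Feature maps keep the
input size (replicate padding, stride 1).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@njit(cache=True)
def _pad_replicate(inp, r, out):
    """Replicate-pad `inp` by r pixels into preallocated `out`."""
    h, w = inp.shape
    for i in range(h + 2 * r):
        si = min(max(i - r, 0), h - 1)
        for j in range(w + 2 * r):
            sj = min(max(j - r, 0), w - 1)
            out[i, j] = inp[si, sj]


@njit(cache=True, fastmath=True)
def _hm_core(padded, hitv, missv, dy, dx, r, out, amin, amax):
    h = out.shape[0]
    w = out.shape[1]
    nd = hitv.shape[0]
    for i in range(h):
        for j in range(w):
            best_min = 1e300
            best_max = -1e300
            imin = 0
            imax = 0
            for d in range(nd):
                v = padded[i + r + dy[d], j + r + dx[d]]
                vh = v - hitv[d]
                if vh < best_min:
                    best_min = vh
                    imin = d
                vm = v - missv[d]
                if vm > best_max:
                    best_max = vm
                    imax = d
            out[i, j] = best_min - best_max
            amin[i, j] = imin
            amax[i, j] = imax


@njit(cache=True)
def hm_map(inp, hitv, missv, dy, dx, out, amin, amax):
    """One Hit-Miss feature map with replicate padding; records the
    arg-extremal domain index per position (first index wins ties)."""
    h, w = inp.shape
    r = 0
    nd = dy.shape[0]
    for d in range(nd):
        if abs(dy[d]) > r:
            r = abs(dy[d])
        if abs(dx[d]) > r:
            r = abs(dx[d])
    padded = np.empty((h + 2 * r, w + 2 * r))
    _pad_replicate(inp, r, padded)
    _hm_core(padded, hitv, missv, dy, dx, r, out, amin, amax)


@njit(cache=True)
def forward_sample(img, hit1, miss1, hit2, miss2, dy, dx, W1, b1, W2, b2, a1, a2, amin1, amax1, amin2, amax2):
    """Full forward pass for one subimage; fills the provided work arrays
    and returns (hidden activations, output activations)."""
    M = hit1.shape[0]
    h, w = img.shape
    for m in range(M):
        hm_map(img, hit1[m], miss1[m], dy, dx, a1[m], amin1[m], amax1[m])
    for m in range(M):
        hm_map(a1[m], hit2[m], miss2[m], dy, dx, a2[m], amin2[m], amax2[m])
    nf = M * h * w
    feat = a2.reshape(nf)
    nh = W1.shape[0]
    no = W2.shape[0]
    hid = np.empty(nh)
    for q in range(nh):
        s = b1[q]
        for i in range(nf):
            s += W1[q, i] * feat[i]
        hid[q] = _sigmoid(s)
    out = np.empty(no)
    for o in range(no):
        s = b2[o]
        for q in range(nh):
            s += W2[o, q] * hid[q]
        out[o] = _sigmoid(s)
    return hid, out


@njit(cache=True)
def forward_batch(images, hit1, miss1, hit2, miss2, dy, dx, W1, b1, W2, b2):
    n = images.shape[0]
    M = hit1.shape[0]
    h, w = images.shape[1], images.shape[2]
    no = W2.shape[0]
    scores = np.empty((n, no))
    a1 = np.empty((M, h, w))
    a2 = np.empty((M, h, w))
    amin1 = np.empty((M, h, w), dtype=np.int32)
    amax1 = np.empty((M, h, w), dtype=np.int32)
    amin2 = np.empty((M, h, w), dtype=np.int32)
    amax2 = np.empty((M, h, w), dtype=np.int32)
    for s in range(n):
        _, out = forward_sample(
            images[s], hit1, miss1, hit2, miss2, dy, dx, W1, b1, W2, b2, a1, a2, amin1, amax1, amin2, amax2
        )
        scores[s] = out
    return scores


@njit(cache=True)
def _penalty_grad(w, lam, w0):
    # d/dw of lam * (w/w0)^2 / (1 + (w/w0)^2) = lam * 2 w w0^2 / (w0^2 + w^2)^2
    return lam * 2.0 * w * w0 * w0 / (w0 * w0 + w * w) ** 2


@njit(cache=True)
def train_epoch(
    images,
    targets,
    order,
    hit1,
    miss1,
    hit2,
    miss2,
    dy,
    dx,
    W1,
    b1,
    W2,
    b2,
    eta,
    lam,
    w0,
    regularize_ses,
):
    """One sequential epoch of gradient descent with weight elimination.

    Updates all parameters in place, one sample at a time in the given
    order; structuring-element subgradients are routed through the
    recorded arg-extrema (first raster-order index on ties) and
    accumulated over all window positions before being applied.
    Returns the per-sample squared errors in presentation order.
    """
    n = images.shape[0]
    M = hit1.shape[0]
    h, w = images.shape[1], images.shape[2]
    nd = dy.shape[0]
    nf = M * h * w
    nh = W1.shape[0]
    no = W2.shape[0]

    a1 = np.empty((M, h, w))
    a2 = np.empty((M, h, w))
    amin1 = np.empty((M, h, w), dtype=np.int32)
    amax1 = np.empty((M, h, w), dtype=np.int32)
    amin2 = np.empty((M, h, w), dtype=np.int32)
    amax2 = np.empty((M, h, w), dtype=np.int32)
    ghit1 = np.empty((M, nd))
    gmiss1 = np.empty((M, nd))
    ghit2 = np.empty((M, nd))
    gmiss2 = np.empty((M, nd))
    delta_a1 = np.empty((h, w))
    errors = np.empty(n)

    for si in range(n):
        s = order[si]
        img = images[s]
        t = targets[s]
        hid, out = forward_sample(
            img, hit1, miss1, hit2, miss2, dy, dx, W1, b1, W2, b2, a1, a2, amin1, amax1, amin2, amax2
        )
        e = 0.0
        for o in range(no):
            diff = t[o] - out[o]
            e += 0.5 * diff * diff
        errors[si] = e

        # output and hidden deltas (delta = -dE/dnet)
        delta_o = np.empty(no)
        for o in range(no):
            delta_o[o] = (t[o] - out[o]) * out[o] * (1.0 - out[o])
        delta_h = np.empty(nh)
        for q in range(nh):
            sacc = 0.0
            for o in range(no):
                sacc += W2[o, q] * delta_o[o]
            delta_h[q] = hid[q] * (1.0 - hid[q]) * sacc
        # deltas at the flattened feature nodes (linear pass-through)
        delta_feat = np.empty(nf)
        for i in range(nf):
            sacc = 0.0
            for q in range(nh):
                sacc += W1[q, i] * delta_h[q]
            delta_feat[i] = sacc

        ghit1[:] = 0.0
        gmiss1[:] = 0.0
        ghit2[:] = 0.0
        gmiss2[:] = 0.0

        feat = a2.reshape(nf)
        for m in range(M):
            # layer-2 SE subgradients and routing to layer-1 activations
            delta_a1[:] = 0.0
            for i in range(h):
                for j in range(w):
                    g = delta_feat[m * h * w + i * w + j]
                    if g == 0.0:
                        continue
                    dmin = amin2[m, i, j]
                    dmax = amax2[m, i, j]
                    ghit2[m, dmin] -= eta * g
                    gmiss2[m, dmax] += eta * g
                    ii = i + dy[dmin]
                    jj = j + dx[dmin]
                    if ii < 0:
                        ii = 0
                    elif ii >= h:
                        ii = h - 1
                    if jj < 0:
                        jj = 0
                    elif jj >= w:
                        jj = w - 1
                    delta_a1[ii, jj] += g
                    ii = i + dy[dmax]
                    jj = j + dx[dmax]
                    if ii < 0:
                        ii = 0
                    elif ii >= h:
                        ii = h - 1
                    if jj < 0:
                        jj = 0
                    elif jj >= w:
                        jj = w - 1
                    delta_a1[ii, jj] -= g
            # layer-1 SE subgradients
            for i in range(h):
                for j in range(w):
                    g1 = delta_a1[i, j]
                    if g1 == 0.0:
                        continue
                    ghit1[m, amin1[m, i, j]] -= eta * g1
                    gmiss1[m, amax1[m, i, j]] += eta * g1

        # classifier updates (with weight elimination on connection weights)
        for o in range(no):
            for q in range(nh):
                W2[o, q] += eta * delta_o[o] * hid[q] - eta * _penalty_grad(W2[o, q], lam, w0)
            b2[o] += eta * delta_o[o]
        for q in range(nh):
            dq = delta_h[q]
            for i in range(nf):
                W1[q, i] += eta * dq * feat[i] - eta * _penalty_grad(W1[q, i], lam, w0)
            b1[q] += eta * dq

        # apply accumulated shared-SE updates
        for m in range(M):
            for d in range(nd):
                if regularize_ses:
                    ghit1[m, d] -= eta * _penalty_grad(hit1[m, d], lam, w0)
                    gmiss1[m, d] -= eta * _penalty_grad(miss1[m, d], lam, w0)
                    ghit2[m, d] -= eta * _penalty_grad(hit2[m, d], lam, w0)
                    gmiss2[m, d] -= eta * _penalty_grad(miss2[m, d], lam, w0)
                hit1[m, d] += ghit1[m, d]
                miss1[m, d] += gmiss1[m, d]
                hit2[m, d] += ghit2[m, d]
                miss2[m, d] += gmiss2[m, d]
    return errors
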