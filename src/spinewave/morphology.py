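"""Binary and gray-scale mathematical morphology and the Hit-Miss node.

These are the primitives underneath the morphological shared-weight
network: set-theoretic binary dilation/erosion and the Hit-Miss
transform, their gray-scale counterparts

    (f (+) b)(s, t) = max { f(s-x, t-y) + b(x, y) }   (dilation)
    (f (-) b)(s, t) = min { f(s+x, t+y) - b(x, y) }   (erosion)

and the scalar Hit-Miss node feature

    a_y = min_{x in D} (a(x) - t_h(x)) - max_{x in D} (a(x) - t_m(x)),

which measures how well the Hit template fits under the patch and the
Miss template above it.  Adding a constant to the patch cancels in
``a_y``: the gray-scale Hit-Miss transform is invariant to intensity
shifts.

Structuring elements are given as small 2D arrays with the origin at
the center; binary SEs are boolean, gray SEs real-valued over a domain
mask.  The implementations evaluate the set/min-max definitions
directly (vectorized over shifted copies), so they serve as the
package's single source of truth for the morphology conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _se_offsets(se: np.ndarray) -> np.ndarray:
    """Offsets (dy, dx) of the true elements of a boolean SE, relative to
    its center."""
    se = np.asarray(se).astype(bool)
    cy, cx = (np.asarray(se.shape) - 1) // 2
    return np.argwhere(se) - np.array([cy, cx])


def _shift(mask: np.ndarray, dy: int, dx: int, fill: bool = False) -> np.ndarray:
    """Translate a 2D array by (dy, dx) with constant fill."""
    out = np.full_like(mask, fill)
    h, w = mask.shape
    ys = slice(max(dy, 0), min(h + dy, h))
    xs = slice(max(dx, 0), min(w + dx, w))
    ys_src = slice(max(-dy, 0), min(h - dy, h))
    xs_src = slice(max(-dx, 0), min(w - dx, w))
    out[ys, xs] = mask[ys_src, xs_src]
    return out


def binary_dilation(mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    """A (+) B = { x : reflected-B translated to x intersects A }
    = union of A translated by each element of B."""
    offsets = _se_offsets(se)
    if offsets.size == 0:
        raise ValueError("structuring element must be nonempty")
    mask = np.asarray(mask).astype(bool)
    out = np.zeros_like(mask)
    for dy, dx in offsets:
        out |= _shift(mask, dy, dx)
    return out


def binary_erosion(mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    """A (-) B = { x : B translated to x fits inside A }.  Pixels outside
    the grid count as background, so the erosion shrinks at the frame.
    An empty SE fits vacuously everywhere."""
    offsets = _se_offsets(se)
    mask = np.asarray(mask).astype(bool)
    if offsets.size == 0:
        return np.ones_like(mask)
    out = np.ones_like(mask)
    for dy, dx in offsets:
        out &= _shift(mask, -dy, -dx, fill=False)
    return out


def hit_miss_binary(mask: np.ndarray, hit: np.ndarray, miss: np.ndarray) -> np.ndarray:
    """Positions where `hit` fits the foreground and `miss` fits the
    background: (A (-) H) intersect (A^c (-) M).  Hit and Miss must be
    disjoint."""
    hit = np.asarray(hit).astype(bool)
    miss = np.asarray(miss).astype(bool)
    if hit.shape == miss.shape and np.any(hit & miss):
        raise ValueError("hit and miss structuring elements must be disjoint")
    mask = np.asarray(mask).astype(bool)
    return binary_erosion(mask, hit) & binary_erosion(~mask, miss)


def _windows(f: np.ndarray, k: int) -> np.ndarray:
    """Replicate-padded sliding windows of size k x k centered per pixel:
    shape (H, W, k, k)."""
    r = (k - 1) // 2
    padded = np.pad(np.asarray(f, float), r, mode="edge")
    return np.lib.stride_tricks.sliding_window_view(padded, (k, k))


def gray_erosion(f: np.ndarray, se: np.ndarray, domain: np.ndarray | None = None) -> np.ndarray:
    """(f (-) b)(s,t) = min over (x,y) in D_b of f(s+x, t+y) - b(x,y),
    with replicate padding at the borders."""
    se = np.asarray(se, float)
    domain = np.ones_like(se, bool) if domain is None else np.asarray(domain, bool)
    k = se.shape[0]
    win = _windows(f, k)
    vals = win - se  # broadcast over the window axes
    return np.where(domain, vals, np.inf).min(axis=(2, 3))


def gray_dilation(f: np.ndarray, se: np.ndarray, domain: np.ndarray | None = None) -> np.ndarray:
    """(f (+) b)(s,t) = max over (x,y) in D_b of f(s-x, t-y) + b(x,y).

    Dual of the erosion: -((-f) (-) b_reflected) = f (+) b.
    """
    se = np.asarray(se, float)
    domain = np.ones_like(se, bool) if domain is None else np.asarray(domain, bool)
    k = se.shape[0]
    win = _windows(f, k)
    # f(s-x, t-y) for (x,y) in D  <=>  window entry at offset (-x,-y):
    # flip both the SE and its domain.
    se_f = se[::-1, ::-1]
    dom_f = domain[::-1, ::-1]
    vals = win + se_f
    return np.where(dom_f, vals, -np.inf).max(axis=(2, 3))


def disk_domain(radius: int) -> np.ndarray:
    """Boolean disk domain of the given radius (Euclidean), side 2r+1."""
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (yy**2 + xx**2) <= radius**2


def square_domain(width: int) -> np.ndarray:
    return np.ones((width, width), dtype=bool)


@dataclass
class StructElementPair:
    """A learned Hit/Miss structuring-element pair over a shared domain."""

    hit: np.ndarray
    miss: np.ndarray
    domain: np.ndarray

    def __post_init__(self) -> None:
        self.hit = np.asarray(self.hit, float)
        self.miss = np.asarray(self.miss, float)
        self.domain = np.asarray(self.domain, bool)
        if not (self.hit.shape == self.miss.shape == self.domain.shape):
            raise ValueError("hit, miss and domain must share one shape")
        if not (np.isfinite(self.hit).all() and np.isfinite(self.miss).all()):
            raise ValueError("structuring element values must be finite")


def hit_miss_node(patch: np.ndarray, pair: StructElementPair) -> float:
    """Scalar Hit-Miss feature of a patch covering the SE domain:
    min(patch - hit) - max(patch - miss) over the domain."""
    patch = np.asarray(patch, float)
    if patch.shape != pair.domain.shape:
        raise ValueError("patch must cover the structuring-element domain")
    d = pair.domain
    net_h = (patch[d] - pair.hit[d]).min()
    net_m = (patch[d] - pair.miss[d]).max()
    return float(net_h - net_m)
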