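"""Dendrite backbone extraction by wavelet conditional-symmetry analysis.

The dendrite trunk is a bright tube on a dark background.  At a wavelet
scale ``s`` the gradient of the smoothed image,

    W_{x,s} f = s * d/dx (f * theta_s),   W_{y,s} f = s * d/dy (f * theta_s),

with ``theta_s(x, y) = (1/s^2) theta(x/s, y/s)`` a unit-mass low-pass
kernel, has modulus maxima along the gradient direction that trace the
two contour curves of the tube.  Two contour points on opposite walls
form a *symmetric pair* when their gradient directions oppose and their
separation matches the scale; the pair midpoint lies on the centerline.
Pairs lacking a counterpart ("unstable symmetry") and pairs whose
midpoint falls outside the foreground mask are discarded.  The backbone
is the one-pixel-wide curve of all connected pair midpoints, carrying
the pair separation as local width.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from scipy.ndimage import binary_dilation
from skimage.morphology import skeletonize

DEFAULT_SCALES = (3, 5, 7, 9, 11, 13)

# theta at scale 1 is a unit-mass Gaussian with this standard deviation;
# theta_s then has sigma = s * THETA_SIGMA0 so that the two wall maxima of a
# tube of width ~ s stay well separated at the matching scale.
THETA_SIGMA0 = 1.0 / 3.0


@dataclass
class WaveletConfig:
    scales: tuple[int, ...] = DEFAULT_SCALES
    kernel: str = "gaussian_derivative"
    pair_distance_tolerance: float = 0.2  # fraction of s, floored at 1 px
    opposite_angle_tolerance: float = math.pi / 4
    modulus_threshold: float = 0.05  # fraction of the max modulus
    min_spur_length: int = 5

    def __post_init__(self) -> None:
        scales = tuple(self.scales)
        if any(s <= 0 for s in scales) or list(scales) != sorted(scales):
            raise ValueError("scales must be positive and ascending")
        if self.pair_distance_tolerance <= 0:
            raise ValueError("pair_distance_tolerance must be > 0")
        self.scales = scales

    def tolerance(self, s: float) -> float:
        return max(1.0, self.pair_distance_tolerance * s)


@dataclass
class GradientField:
    """Per-pixel wavelet gradient: components, modulus and angle."""

    wx: np.ndarray  # d/dcol component (x = column)
    wy: np.ndarray  # d/drow component (y = row)
    modulus: np.ndarray
    angle: np.ndarray
    scale: float


@dataclass
class SymmetricPair:
    p: tuple[int, int]
    q: tuple[int, int]
    scale: float
    midpoint: tuple[float, float]
    separation: float


@dataclass
class BackbonePath:
    """Ordered one-pixel-wide centerline curve with per-point attributes."""

    points: np.ndarray  # (N, 2) int row/col
    widths: np.ndarray  # (N,) local width (pair separation)
    tangents: np.ndarray  # (N,) tangent angle in radians
    junction: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    def __len__(self) -> int:
        return self.points.shape[0]


# ---------------------------------------------------------------------------
# kernels


def smoothing_kernel(scale: float, sigma0: float = THETA_SIGMA0) -> np.ndarray:
    """Discrete sampling of theta_s(x, y) = (1/s^2) theta(x/s, y/s).

    theta is the unit-mass isotropic Gaussian with standard deviation
    ``sigma0``; the returned grid covers +-5 sigma and follows the 1/s^2
    scaling law exactly (doubling ``s`` doubles the support and quarters
    the values).
    """
    if scale < 1:
        raise ValueError("scale must be >= 1")
    sigma = sigma0 * scale
    r = max(int(math.ceil(5 * sigma)), 1)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1].astype(float)
    theta = lambda x, y: np.exp(-(x**2 + y**2) / (2 * sigma0**2)) / (2 * math.pi * sigma0**2)
    return theta(xx / scale, yy / scale) / scale**2


_SQRT2_OVER_PI = math.sqrt(2.0) / math.pi


def phi_plus(x) -> np.ndarray:
    """Piecewise symmetric wavelet basis function phi+ on [0, 1].

    Best-effort reconstruction of a typographically ambiguous printed
    formula: each branch has the form (sqrt(2)/pi) * 4x * log(N/D) built
    from the radicals sqrt(1-16x^2), sqrt(9-16x^2) and sqrt(1-x^2), and
    the function vanishes for x >= 1 (and for x < 0; the full odd
    wavelet is assembled as phi(x) = phi+(x) - phi+(-x)).  Radicands are
    clipped at zero and denominators floored at machine epsilon, so the
    branches are defined on their whole intervals even where the printed
    source is ambiguous.
    """
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)

    def _sqrt(v):
        return np.sqrt(np.clip(v, 0.0, None))

    b1 = (x >= 0) & (x < 0.25)
    if np.any(b1):
        z = x[b1]
        num = (1 - 8 * z**2 + 2 * _sqrt(1 - 16 * z**2)) * (1 + _sqrt(1 - z**2))
        den = 9 * z - 8 * z**2 - 12 * z * _sqrt(1 - 16 * z**2) + 8 * _sqrt(1 - z**2)
        out[b1] = _SQRT2_OVER_PI * 4 * z * np.log(np.maximum(num, 1e-300) / np.maximum(den, 1e-300))
    b2 = (x >= 0.25) & (x < 0.75)
    if np.any(b2):
        z = x[b2]
        num = 8 * z * (1 + _sqrt(1 - z**2))
        den = 9 + 3 * _sqrt(9 - 16 * z**2) - 12 * z
        out[b2] = _SQRT2_OVER_PI * 4 * z * np.log(np.maximum(num, 1e-300) / np.maximum(den, 1e-300))
    b3 = (x >= 0.75) & (x < 1.0)
    if np.any(b3):
        z = x[b3]
        out[b3] = _SQRT2_OVER_PI * 4 * z * (np.log((1 + _sqrt(1 - z**2)) / z) - _sqrt(1 - z**2))
    return out if out.ndim else float(out)


def phi_minus(x) -> np.ndarray:
    """phi-(x) = -phi+(-x)."""
    return -phi_plus(-np.asarray(x, dtype=float))


def _piecewise_lowpass(scale: float) -> np.ndarray:
    """Low-pass kernel derived from the piecewise basis: separable product
    of the even bump |phi+(|t|/?)|-style profile, normalized to unit mass."""
    r = max(int(math.ceil(scale)), 2)
    t = np.arange(-r, r + 1, dtype=float) / (r + 1)
    prof = phi_plus(np.abs(t))
    prof = np.abs(prof)
    if prof.sum() <= 0:
        prof = np.exp(-(t**2) * 4.0)
    prof = prof / prof.sum()
    return np.outer(prof, prof)


# ---------------------------------------------------------------------------
# gradient field and modulus maxima


def wavelet_gradient(image: np.ndarray, scale: float, config: WaveletConfig | None = None) -> GradientField:
    """Wavelet gradient at scale ``s``: s times the spatial derivative of
    the theta_s-smoothed image (central differences)."""
    config = config or WaveletConfig()
    img = np.asarray(image, float)
    if config.kernel == "gaussian_derivative":
        smoothed = gaussian_filter(img, sigma=THETA_SIGMA0 * scale, mode="nearest")
    elif config.kernel == "piecewise_phi":
        from scipy.ndimage import convolve

        smoothed = convolve(img, _piecewise_lowpass(scale), mode="nearest")
    else:
        raise ValueError(f"unknown kernel {config.kernel!r}")
    wy = scale * np.gradient(smoothed, axis=0)
    wx = scale * np.gradient(smoothed, axis=1)
    modulus = np.hypot(wx, wy)
    angle = np.arctan2(wy, wx)
    return GradientField(wx=wx, wy=wy, modulus=modulus, angle=angle, scale=scale)


def modulus_maxima(field: GradientField, threshold: float | None = None) -> np.ndarray:
    """Pixels whose modulus is a local maximum along the gradient direction.

    Neighbors one pixel away along +-(gradient direction) are evaluated
    by bilinear interpolation; a pixel is kept when its modulus is >=
    both (and strictly greater than one, to break plateau double lines)
    and exceeds ``threshold`` (absolute; defaults to the configured
    fraction of the maximum modulus).

    Returns an (N, 2) int array of (row, col) contour points.
    """
    mod = field.modulus
    if threshold is None:
        threshold = 0.05 * mod.max()
    h, w = mod.shape
    with np.errstate(invalid="ignore", divide="ignore"):
        ur = np.where(mod > 0, field.wy / np.maximum(mod, 1e-12), 0.0)
        uc = np.where(mod > 0, field.wx / np.maximum(mod, 1e-12), 0.0)
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    m_plus = map_coordinates(mod, [rr + ur, cc + uc], order=1, mode="nearest")
    m_minus = map_coordinates(mod, [rr - ur, cc - uc], order=1, mode="nearest")
    keep = (mod > threshold) & (mod >= m_plus) & (mod >= m_minus) & ((mod > m_plus) | (mod > m_minus))
    return np.argwhere(keep)


# ---------------------------------------------------------------------------
# conditional symmetric pairing


def pair_symmetric_points(
    contours: np.ndarray,
    field: GradientField,
    mask: np.ndarray,
    scale: float,
    config: WaveletConfig | None = None,
) -> list[SymmetricPair]:
    """Pair opposite-wall contour points whose separation matches the scale.

    From each contour point the search marches along its gradient
    direction (into the bright tube); the first contour point met whose
    gradient direction approximately opposes (within the configured
    angle tolerance) and whose separation is within ``tolerance(s)`` of
    ``s`` forms a pair.  Pairs whose midpoint lies outside the
    foreground mask are rejected as unstable symmetry.
    """
    config = config or WaveletConfig()
    contours = np.asarray(contours)
    if contours.size == 0:
        return []
    h, w = field.modulus.shape
    tol = config.tolerance(scale)

    is_contour = np.zeros((h, w), dtype=bool)
    is_contour[contours[:, 0], contours[:, 1]] = True

    pr = contours[:, 0].astype(float)
    pc = contours[:, 1].astype(float)
    mod = field.modulus[contours[:, 0], contours[:, 1]]
    ur = field.wy[contours[:, 0], contours[:, 1]] / np.maximum(mod, 1e-12)
    uc = field.wx[contours[:, 0], contours[:, 1]] / np.maximum(mod, 1e-12)

    gr = field.wy / np.maximum(field.modulus, 1e-12)
    gc = field.wx / np.maximum(field.modulus, 1e-12)
    cos_tol = -math.cos(config.opposite_angle_tolerance)

    n = contours.shape[0]
    found = np.zeros(n, dtype=bool)
    q_rows = np.zeros(n, dtype=int)
    q_cols = np.zeros(n, dtype=int)
    steps = np.arange(1.0, scale + tol + 0.5, 0.5)
    mask = np.asarray(mask).astype(bool)
    for t in steps:
        todo = ~found
        if not np.any(todo):
            break
        rr = np.clip(np.rint(pr[todo] + t * ur[todo]).astype(int), 0, h - 1)
        cc = np.clip(np.rint(pc[todo] + t * uc[todo]).astype(int), 0, w - 1)
        hit = is_contour[rr, cc]
        # not the point itself
        hit &= ~((rr == contours[todo, 0]) & (cc == contours[todo, 1]))
        # opposite gradient direction
        dot = ur[todo] * gr[rr, cc] + uc[todo] * gc[rr, cc]
        hit &= dot <= cos_tol
        # separation matches the scale
        sep = np.hypot(rr - pr[todo], cc - pc[todo])
        hit &= np.abs(sep - scale) <= tol
        idx = np.flatnonzero(todo)[hit]
        found[idx] = True
        q_rows[idx] = rr[hit]
        q_cols[idx] = cc[hit]

    pairs: list[SymmetricPair] = []
    for i in np.flatnonzero(found):
        p = (int(contours[i, 0]), int(contours[i, 1]))
        q = (int(q_rows[i]), int(q_cols[i]))
        mid = ((p[0] + q[0]) / 2.0, (p[1] + q[1]) / 2.0)
        mr, mc = int(round(mid[0])), int(round(mid[1]))
        if not mask[mr, mc]:
            continue
        sep = math.hypot(p[0] - q[0], p[1] - q[1])
        pairs.append(SymmetricPair(p=p, q=q, scale=scale, midpoint=mid, separation=sep))
    return pairs


# ---------------------------------------------------------------------------
# backbone assembly


def _trace_paths(skel: np.ndarray) -> list[np.ndarray]:
    """Split a skeleton into ordered 8-connected paths, breaking at
    junction pixels (more than two skeleton neighbors)."""
    h, w = skel.shape
    offs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    pts = set(map(tuple, np.argwhere(skel)))

    def neighbors(p):
        return [(p[0] + dr, p[1] + dc) for dr, dc in offs if (p[0] + dr, p[1] + dc) in pts]

    degree = {p: len(neighbors(p)) for p in pts}
    junctions = {p for p, d in degree.items() if d > 2}
    visited_edges: set[tuple] = set()
    paths: list[np.ndarray] = []

    def walk(start, first):
        path = [start, first]
        visited_edges.add((start, first))
        visited_edges.add((first, start))
        cur, prev = first, start
        while cur not in junctions and degree[cur] == 2:
            nxt = [q for q in neighbors(cur) if q != prev]
            if not nxt:
                break
            nxt = nxt[0]
            if (cur, nxt) in visited_edges:
                break
            visited_edges.add((cur, nxt))
            visited_edges.add((nxt, cur))
            path.append(nxt)
            prev, cur = cur, nxt
        return path

    endpoints = sorted([p for p, d in degree.items() if d == 1] + sorted(junctions))
    for start in endpoints:
        for nb in neighbors(start):
            if (start, nb) not in visited_edges:
                paths.append(np.array(walk(start, nb)))
    # isolated loops
    remaining = pts - {tuple(p) for path in paths for p in path}
    while remaining:
        start = sorted(remaining)[0]
        nbs = [q for q in neighbors(start) if (start, q) not in visited_edges]
        if not nbs:
            remaining.discard(start)
            continue
        path = walk(start, nbs[0])
        paths.append(np.array(path))
        remaining -= {tuple(p) for p in path}
    return [p for p in paths if len(p) >= 2]


def extract_backbone(
    pairs: list[SymmetricPair],
    shape: tuple[int, int],
    mask: np.ndarray | None = None,
    config: WaveletConfig | None = None,
) -> list[BackbonePath]:
    """Rasterize pair midpoints, link, thin to one pixel and prune spurs.

    Midpoints from all scales are accumulated on a canvas (per pixel the
    width whose separation best matches its scale is kept), closed by a
    one-pixel dilation to bridge sampling gaps, skeletonized, and split
    into ordered paths at junctions; dangling branches shorter than
    ``min_spur_length`` are removed.
    """
    config = config or WaveletConfig()
    if not pairs:
        return []
    h, w = shape
    canvas = np.zeros((h, w), dtype=bool)
    width_map = np.full((h, w), np.nan)
    score_map = np.full((h, w), np.inf)
    for pair in pairs:
        r, c = int(round(pair.midpoint[0])), int(round(pair.midpoint[1]))
        if not (0 <= r < h and 0 <= c < w):
            continue
        canvas[r, c] = True
        score = abs(pair.separation - pair.scale)
        if score < score_map[r, c]:
            score_map[r, c] = score
            width_map[r, c] = pair.separation

    closed = binary_dilation(canvas, np.ones((3, 3), bool))
    if mask is not None:
        closed &= np.asarray(mask).astype(bool)
    skel = skeletonize(closed)

    # prune short dangling spurs, iteratively
    for _ in range(3):
        paths = _trace_paths(skel)
        if not paths:
            break
        pts = set(map(tuple, np.argwhere(skel)))
        changed = False
        for path in paths:
            if len(path) >= config.min_spur_length:
                continue
            ends = [tuple(path[0]), tuple(path[-1])]
            dangling = []
            for e in ends:
                nb = sum(
                    1
                    for dr in (-1, 0, 1)
                    for dc in (-1, 0, 1)
                    if (dr, dc) != (0, 0) and (e[0] + dr, e[1] + dc) in pts
                )
                dangling.append(nb <= 1)
            if any(dangling):
                interior = path if all(dangling) else path[1:] if dangling[0] else path[:-1]
                for p in interior:
                    skel[p[0], p[1]] = False
                changed = True
        if not changed:
            break

    # per-point widths: nearest recorded midpoint width
    from scipy.ndimage import distance_transform_edt

    have = ~np.isnan(width_map)
    if np.any(have):
        _, (ir, ic) = distance_transform_edt(~have, return_indices=True)
        filled_width = width_map[ir, ic]
    else:
        filled_width = np.zeros((h, w))

    out: list[BackbonePath] = []
    for path in _trace_paths(skel):
        n = len(path)
        widths = filled_width[path[:, 0], path[:, 1]]
        tangents = np.zeros(n)
        for i in range(n):
            a = path[max(i - 1, 0)]
            b = path[min(i + 1, n - 1)]
            tangents[i] = math.atan2(b[0] - a[0], b[1] - a[1])
        out.append(BackbonePath(points=path, widths=widths, tangents=tangents))
    return out


def extract_backbone_from_image(
    image: np.ndarray,
    mask: np.ndarray,
    config: WaveletConfig | None = None,
) -> list[BackbonePath]:
    """Full multi-scale sweep: gradient, modulus maxima and symmetric
    pairing at every configured scale, then backbone assembly."""
    config = config or WaveletConfig()
    all_pairs: list[SymmetricPair] = []
    for s in config.scales:
        fld = wavelet_gradient(image, s, config)
        contours = modulus_maxima(fld, threshold=config.modulus_threshold * fld.modulus.max())
        all_pairs.extend(pair_symmetric_points(contours, fld, mask, s, config))
    return extract_backbone(all_pairs, np.asarray(image).shape, mask=mask, config=config)
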