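"""Seeded generator of confocal-like dendrite images and spine libraries.

Real confocal images of dendritic spines are acquired at ~0.24 um/pixel,
where a dendrite trunk is a bright curvilinear tube a few to a dozen
pixels wide on a dark, photomultiplier-noisy background, and spines are
small protrusions that fit inside a 20x20-pixel box (thin spines in
roughly 5x20).  This module emulates those images with full ground
truth: smooth spline dendrites of prescribed width, attached or detached
protrusions of the three canonical morphologies, a Gaussian-blur optics
surrogate, and Poisson+Gaussian shot/read noise.

Morphology conventions (all sizes in pixels):

* ``mushroom`` — thin neck (width < head diameter) ending in a bulbous
  head;
* ``stubby``  — bulbous head attached directly to the trunk, no neck;
* ``thin``    — long thin neck with at most a vestigial head
  (head radius <= neck width).

Every generator is a pure function of its spec and seed: the same seed
reproduces bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import interpolate
from scipy.ndimage import gaussian_filter

CLASS_NAMES = ("mushroom", "stubby", "thin")

# Canonical geometry (midpoints of the sampling ranges below).
_CANONICAL = {
    "mushroom": dict(neck_length=6.5, neck_width=1.8, head_radius=3.2),
    "stubby": dict(neck_length=0.0, neck_width=0.0, head_radius=3.5),
    "thin": dict(neck_length=13.5, neck_width=1.5, head_radius=0.65),
}

# Sampling ranges used by the library generator and random scenes.
_RANGES = {
    "mushroom": dict(neck_length=(5.0, 8.0), neck_width=(1.4, 2.2), head_radius=(2.6, 3.8)),
    "stubby": dict(neck_length=(0.0, 0.0), neck_width=(0.0, 0.0), head_radius=(2.8, 4.2)),
    "thin": dict(neck_length=(11.0, 16.0), neck_width=(1.2, 1.8), head_radius=(0.5, 0.8)),
}


@dataclass
class SpineSpec:
    """Geometry of a single spine to be rendered on a dendrite scene.

    ``base_t`` is the arc-length fraction (in [0, 1]) along the dendrite
    backbone where the spine attaches; ``orientation`` is an absolute
    angle in radians (``None`` means perpendicular to the local tangent,
    on the side given by ``side``).
    """

    class_label: str
    base_t: float = 0.5
    orientation: float | None = None
    side: int = 1
    attachment: str = "attached"
    neck_length: float | None = None
    neck_width: float | None = None
    head_radius: float | None = None
    gap: float = 3.0

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_NAMES:
            raise ValueError(f"unknown spine class {self.class_label!r}")
        if self.attachment not in ("attached", "detached"):
            raise ValueError(f"unknown attachment {self.attachment!r}")
        canon = _CANONICAL[self.class_label]
        if self.neck_length is None:
            self.neck_length = canon["neck_length"]
        if self.neck_width is None:
            self.neck_width = canon["neck_width"]
        if self.head_radius is None:
            self.head_radius = canon["head_radius"]
        self.validate()

    @property
    def total_length(self) -> float:
        if self.class_label == "stubby":
            return 1.7 * self.head_radius
        return self.neck_length + 2.0 * self.head_radius

    def validate(self) -> None:
        L, nw, hr = self.neck_length, self.neck_width, self.head_radius
        if self.class_label == "mushroom":
            if not (L > 0 and nw < 2.0 * hr):
                raise ValueError("mushroom spine needs neck_length > 0 and neck thinner than head")
        elif self.class_label == "stubby":
            if L != 0:
                raise ValueError("stubby spine has no neck (neck_length must be 0)")
        else:  # thin
            if not (hr <= nw and self.total_length > 4.0 * hr):
                raise ValueError("thin spine needs head_radius <= neck_width and length > 2 head diameters")
        if self.total_length > 20.0:
            raise ValueError("spine does not fit the 20x20 pixel envelope")
        width = max(2.0 * hr, nw)
        limit = 6.0 if self.class_label == "thin" else 20.0
        if width > limit:
            raise ValueError("spine wider than its class envelope")


@dataclass
class SceneSpec:
    """Full description of one synthetic dendrite scene."""

    height: int = 256
    width: int = 256
    control_points: np.ndarray = field(
        default_factory=lambda: np.array([[40.0, 20.0], [100.0, 90.0], [150.0, 170.0], [220.0, 236.0]])
    )
    width_profile: float | Sequence[float] = 7.0
    spines: list[SpineSpec] = field(default_factory=list)
    foreground_level: float = 0.85
    background_level: float = 0.05
    gaussian_sigma: float = 0.02
    poisson_scale: float = 200.0
    blur_sigma: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        self.control_points = np.asarray(self.control_points, dtype=float)
        widths = np.atleast_1d(np.asarray(self.width_profile, dtype=float))
        if np.any(widths < 2):
            raise ValueError("width_profile values must be >= 2 pixels")
        if not self.foreground_level > self.background_level:
            raise ValueError("foreground_level must exceed background_level")
        if self.control_points.ndim != 2 or self.control_points.shape[0] < 2:
            raise ValueError("need at least two dendrite control points")


@dataclass
class GroundTruthSpine:
    class_label: str
    mask: np.ndarray
    center: tuple[float, float]
    area: int
    max_width: float
    length: float
    attachment: str


@dataclass
class GroundTruth:
    """Golden-standard annotation accompanying a rendered scene."""

    backbone_points: np.ndarray  # (M, 2) float, ordered along the dendrite
    backbone_widths: np.ndarray  # (M,) local tube width in pixels
    dendrite_mask: np.ndarray  # bool (H, W) trunk region; its edge is the boundary
    spine_records: list[GroundTruthSpine]


# ---------------------------------------------------------------------------
# low-level rasterization helpers


def _paint_disk(canvas: np.ndarray, center: tuple[float, float], radius: float) -> None:
    """Set to True all pixels within `radius` of `center` (in-place)."""
    h, w = canvas.shape
    r0 = max(int(math.floor(center[0] - radius)), 0)
    r1 = min(int(math.ceil(center[0] + radius)), h - 1)
    c0 = max(int(math.floor(center[1] - radius)), 0)
    c1 = min(int(math.ceil(center[1] + radius)), w - 1)
    if r0 > r1 or c0 > c1:
        return
    rr, cc = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    inside = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    canvas[r0 : r1 + 1, c0 : c1 + 1] |= inside


def _paint_capsule(canvas: np.ndarray, p0: np.ndarray, p1: np.ndarray, radius: float) -> None:
    """Paint a stadium shape (line segment dilated by `radius`)."""
    length = float(np.hypot(*(p1 - p0)))
    n = max(int(math.ceil(length / 0.3)), 1)
    for t in np.linspace(0.0, 1.0, n + 1):
        pt = p0 + t * (p1 - p0)
        _paint_disk(canvas, (pt[0], pt[1]), radius)


def _resample_curve(control_points: np.ndarray, step: float = 0.5) -> np.ndarray:
    """Smooth spline through control points, resampled at ~`step` px arc length."""
    pts = np.asarray(control_points, float)
    if pts.shape[0] == 2:
        length = np.hypot(*(pts[1] - pts[0]))
        n = max(int(length / step), 2)
        t = np.linspace(0, 1, n + 1)[:, None]
        return pts[0] + t * (pts[1] - pts[0])
    k = min(3, pts.shape[0] - 1)
    tck, _ = interpolate.splprep([pts[:, 0], pts[:, 1]], s=0, k=k)
    # dense evaluation, then arc-length reparametrization
    u = np.linspace(0, 1, 40 * pts.shape[0])
    dense = np.column_stack(interpolate.splev(u, tck))
    seg = np.hypot(*np.diff(dense, axis=0).T)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    targets = np.arange(0.0, total + step / 2, step)
    rows = np.interp(targets, arclen, dense[:, 0])
    cols = np.interp(targets, arclen, dense[:, 1])
    return np.column_stack([rows, cols])


def add_noise(image: np.ndarray, gaussian_sigma: float, poisson_scale: float, rng: np.random.Generator) -> np.ndarray:
    """PMT surrogate: Poisson shot noise at `poisson_scale` photons per unit
    intensity, then additive Gaussian read noise; clipped to [0, 1]."""
    out = image.astype(float)
    if poisson_scale and poisson_scale > 0:
        out = rng.poisson(np.clip(out, 0, None) * poisson_scale).astype(float) / poisson_scale
    if gaussian_sigma and gaussian_sigma > 0:
        out = out + rng.normal(0.0, gaussian_sigma, size=out.shape)
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# scene generation


def _spine_geometry(scene: SceneSpec, spine: SpineSpec, centerline: np.ndarray, widths: np.ndarray):
    """Resolve a spine's base point and unit direction on a given centerline."""
    m = centerline.shape[0]
    i = int(round(spine.base_t * (m - 1)))
    i = min(max(i, 1), m - 2)
    tangent = centerline[i + 1] - centerline[i - 1]
    tangent = tangent / (np.hypot(*tangent) + 1e-12)
    normal = np.array([-tangent[1], tangent[0]]) * (1 if spine.side >= 0 else -1)
    if spine.orientation is None:
        u = normal
    else:
        u = np.array([math.sin(spine.orientation), math.cos(spine.orientation)])
    half = widths[i] / 2.0
    offset = half - 0.5 if spine.attachment == "attached" else half + spine.gap
    base = centerline[i] + normal * offset
    return base, u


def _render_spine(canvas: np.ndarray, base: np.ndarray, u: np.ndarray, spine: SpineSpec) -> None:
    if spine.class_label == "stubby":
        center = base + u * (0.7 * spine.head_radius)
        _paint_disk(canvas, (center[0], center[1]), spine.head_radius)
        return
    tip = base + u * spine.neck_length
    _paint_capsule(canvas, base, tip, spine.neck_width / 2.0)
    head_center = tip + u * spine.head_radius
    _paint_disk(canvas, (head_center[0], head_center[1]), spine.head_radius)


def make_dendrite_image(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a dendrite scene and its ground truth.

    Returns a float image in [0, 1] and a :class:`GroundTruth` whose
    backbone points trace the tube centerline at ~0.5 px arc spacing.

    Raises ``ValueError`` when a spine would fall outside the canvas.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    centerline = _resample_curve(spec.control_points, step=0.5)
    m = centerline.shape[0]
    widths_cp = np.atleast_1d(np.asarray(spec.width_profile, float))
    if widths_cp.size == 1:
        widths = np.full(m, widths_cp[0])
    else:
        widths = np.interp(np.linspace(0, 1, m), np.linspace(0, 1, widths_cp.size), widths_cp)

    tube = np.zeros((h, w), dtype=bool)
    for (r, c), wd in zip(centerline, widths):
        _paint_disk(tube, (r, c), wd / 2.0)

    spine_canvas = np.zeros_like(tube)
    spine_masks: list[np.ndarray] = []
    for spine in spec.spines:
        base, u = _spine_geometry(spec, spine, centerline, widths)
        tip = base + u * (spine.total_length + spine.head_radius)
        for pt in (base, tip):
            if not (0 <= pt[0] < h and 0 <= pt[1] < w):
                raise ValueError(
                    f"spine {spine.class_label!r} at base_t={spine.base_t:.2f} "
                    f"falls outside the {h}x{w} canvas"
                )
        single = np.zeros_like(tube)
        _render_spine(single, base, u, spine)
        spine_canvas |= single
        spine_masks.append(single)

    fg_mask = tube | spine_canvas
    image = spec.background_level + (spec.foreground_level - spec.background_level) * fg_mask.astype(float)
    if spec.blur_sigma and spec.blur_sigma > 0:
        image = gaussian_filter(image, spec.blur_sigma, mode="nearest")
    image = add_noise(image, spec.gaussian_sigma, spec.poisson_scale, rng)

    records = []
    for spine, single in zip(spec.spines, spine_masks):
        only = single & ~tube
        area = int(only.sum())
        if area == 0:
            center = (float("nan"), float("nan"))
        else:
            rr, cc = np.nonzero(only)
            center = (float(rr.mean()), float(cc.mean()))
        if spine.class_label == "thin":
            max_width = max(spine.neck_width, 2 * spine.head_radius)
        else:
            max_width = 2 * spine.head_radius
        records.append(
            GroundTruthSpine(
                class_label=spine.class_label,
                mask=only,
                center=center,
                area=area,
                max_width=float(max_width),
                length=float(spine.total_length),
                attachment=spine.attachment,
            )
        )

    # keep only backbone samples that fall inside the canvas
    inside = (
        (centerline[:, 0] >= 0)
        & (centerline[:, 0] <= h - 1)
        & (centerline[:, 1] >= 0)
        & (centerline[:, 1] <= w - 1)
    )
    truth = GroundTruth(
        backbone_points=centerline[inside],
        backbone_widths=widths[inside],
        dendrite_mask=tube,
        spine_records=records,
    )
    return image, truth


def max_intensity_projection(stack: np.ndarray) -> np.ndarray:
    """Project a 3D stack (z, y, x) to 2D by the per-pixel maximum over z."""
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValueError("stack must be a non-empty 3D array (z, y, x)")
    return stack.max(axis=0)


def make_dendrite_stack(spec: SceneSpec, n_slices: int = 5, depth_sigma: float = 0.9) -> tuple[np.ndarray, GroundTruth]:
    """Mini 3D stack whose maximum intensity projection recovers the scene.

    The scene's intensity is spread across slices with a Gaussian axial
    profile around a smoothly varying focal depth, emulating a thin
    structure meandering through a confocal z-stack.
    """
    image, truth = make_dendrite_image(spec)
    rng = np.random.default_rng(spec.seed + 1)
    depth = gaussian_filter(rng.uniform(0.5, n_slices - 1.5, size=image.shape), 8.0, mode="nearest")
    z = np.arange(n_slices)[:, None, None]
    weights = np.exp(-((z - depth[None]) ** 2) / (2 * depth_sigma**2))
    stack = image[None] * weights
    return stack, truth


# ---------------------------------------------------------------------------
# labeled 20x20 subimage library


def _sample_geometry(label: str, rng: np.random.Generator, jitter: bool) -> dict:
    if not jitter:
        return dict(_CANONICAL[label])
    out = {}
    for key, (lo, hi) in _RANGES[label].items():
        out[key] = float(rng.uniform(lo, hi)) if hi > lo else lo
    return out


def _paint_arc(canvas: np.ndarray, anchor: np.ndarray, v: np.ndarray, radius: float, half_len: float, tube_radius: float) -> None:
    """Paint a tube along a circular arc through `anchor` with tangent `v`
    and signed curvature radius `radius` (0 or inf => straight)."""
    if not np.isfinite(radius) or radius == 0:
        _paint_capsule(canvas, anchor - v * half_len, anchor + v * half_len, tube_radius)
        return
    n = np.array([-v[1], v[0]])
    center = anchor + n * radius
    phi0 = math.atan2(anchor[0] - center[0], anchor[1] - center[1])
    dphi = half_len / abs(radius)
    for phi in np.arange(-dphi, dphi, 0.3 / abs(radius)):
        pt = center + abs(radius) * np.array([math.sin(phi0 + phi), math.cos(phi0 + phi)])
        _paint_disk(canvas, (pt[0], pt[1]), tube_radius)


def render_spine_subimage(
    label: str,
    size: int = 20,
    orientation: float = 0.0,
    geometry: dict | None = None,
    tube_width: float = 7.0,
    tube_curvature_radius: float = float("inf"),
    foreground_level: float = 0.85,
    background_level: float = 0.05,
    blur_sigma: float = 0.7,
    return_truth: bool = False,
):
    """Render one spine subimage: a dendrite band crossing one side of the
    window (optionally curved) with the spine protruding along
    `orientation`; the window is centered on the centroid of the
    spine's visible (non-trunk) pixels, matching how detection windows
    land on spines when scanning whole images."""
    geometry = geometry or _CANONICAL[label]
    spine = SpineSpec(class_label=label, **geometry)
    u = np.array([math.sin(orientation), math.cos(orientation)])
    v = np.array([-u[1], u[0]])
    pad = 8
    big = size + 2 * pad
    c = np.array([(big - 1) / 2.0, (big - 1) / 2.0])
    total = spine.total_length
    base = c - u * (total / 2.0)
    tube_anchor = base - u * (tube_width / 2.0 - 0.5)

    tube = np.zeros((big, big), dtype=bool)
    _paint_arc(tube, tube_anchor, v, tube_curvature_radius, 2.0 * big, tube_width / 2.0)
    spines = np.zeros_like(tube)
    _render_spine(spines, base, u, spine)

    only = spines & ~tube
    if only.any():
        rr, cc = np.nonzero(only)
        cy, cx = rr.mean(), cc.mean()
    else:
        cy, cx = c
    r0 = int(round(cy - (size - 1) / 2.0))
    c0 = int(round(cx - (size - 1) / 2.0))
    r0 = min(max(r0, 0), big - size)
    c0 = min(max(c0, 0), big - size)

    fg = tube | spines
    image = background_level + (foreground_level - background_level) * fg.astype(float)
    if blur_sigma and blur_sigma > 0:
        image = gaussian_filter(image, blur_sigma, mode="nearest")
    image = image[r0 : r0 + size, c0 : c0 + size]
    if return_truth:
        return image, only[r0 : r0 + size, c0 : c0 + size]
    return image


def make_spine_library(
    n_per_class: int,
    subimage_size: int = 20,
    seed: int = 0,
    jitter: bool = True,
    noise: bool = True,
    gaussian_sigma: float = 0.02,
    poisson_scale: float = 200.0,
    return_truth: bool = False,
):
    """Labeled library of spine subimages, `n_per_class` per morphology.

    With ``jitter`` (default), orientation is uniform in [0, 2pi), the
    class geometry is drawn from its realistic range, and foreground /
    background levels vary sample to sample; ``noise`` adds the PMT
    surrogate.  With both disabled and ``n_per_class=1`` each class
    yields its canonical template.

    Returns ``(images, labels)`` where ``images`` is ``(3*n, s, s)``
    float64 and ``labels`` holds class indices into
    :data:`CLASS_NAMES` (0=mushroom, 1=stubby, 2=thin).  With
    ``return_truth`` a list of per-sample spine masks is appended.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    images, labels, masks = [], [], []
    for ci, label in enumerate(CLASS_NAMES):
        for _ in range(n_per_class):
            orientation = float(rng.uniform(0, 2 * math.pi)) if jitter else 0.0
            geometry = _sample_geometry(label, rng, jitter)
            if jitter:
                fg = float(rng.uniform(0.6, 0.95))
                bg = float(rng.uniform(0.03, 0.10))
                tw = float(rng.uniform(5.0, 9.0))
                # half the band segments are straight, half curved like a
                # meandering dendrite seen through a 20x20 window
                if rng.uniform() < 0.5:
                    curv = float("inf")
                else:
                    curv = float(rng.uniform(25.0, 80.0)) * (1 if rng.uniform() < 0.5 else -1)
            else:
                fg, bg, tw, curv = 0.85, 0.05, 7.0, float("inf")
            img, mask = render_spine_subimage(
                label,
                size=subimage_size,
                orientation=orientation,
                geometry=geometry,
                tube_width=tw,
                tube_curvature_radius=curv,
                foreground_level=fg,
                background_level=bg,
                return_truth=True,
            )
            if noise:
                img = add_noise(img, gaussian_sigma, poisson_scale, rng)
            images.append(img)
            labels.append(ci)
            masks.append(mask)
    images = np.stack(images)
    labels = np.asarray(labels, dtype=np.int64)
    if return_truth:
        return images, labels, masks
    return images, labels


def demo_scene(
    seed: int = 0,
    n_mushroom: int = 8,
    n_stubby: int = 8,
    n_thin: int = 4,
    height: int = 400,
    width: int = 400,
    dendrite_width: float = 8.0,
    noiseless: bool = False,
) -> SceneSpec:
    """A long S-shaped dendrite carrying the requested spine composition,
    spaced along the arc with alternating sides."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, 7)
    rows = 40 + (height - 80) * t
    cols = width / 2 + (width / 2 - 60) * np.sin(2.2 * math.pi * t + rng.uniform(0, math.pi))
    control = np.column_stack([rows, cols])
    labels = ["mushroom"] * n_mushroom + ["stubby"] * n_stubby + ["thin"] * n_thin
    order = rng.permutation(len(labels))
    spines = []
    n = len(labels)
    for k, idx in enumerate(order):
        geometry = _sample_geometry(labels[idx], rng, jitter=True)
        spines.append(
            SpineSpec(
                class_label=labels[idx],
                base_t=(k + 0.5) / n * 0.9 + 0.05,
                side=1 if k % 2 == 0 else -1,
                **geometry,
            )
        )
    return SceneSpec(
        height=height,
        width=width,
        control_points=control,
        width_profile=dendrite_width,
        spines=spines,
        gaussian_sigma=0.0 if noiseless else 0.02,
        poisson_scale=0.0 if noiseless else 200.0,
        seed=seed,
    )
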