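"""End-to-end spine detection: scan, segment, characterize.

The trained network is slid over the whole (preprocessed) image to
build per-class *detection planes*; their local maxima above a score
threshold become spine candidates.  Independently, the backbone and
boundary stages delimit the dendrite trunk, and foreground components
outside the trunk are segmented as spine pixel sets (attached when they
touch the trunk, detached when within a small distance of it).  Each
candidate is matched to its nearest spine component, which is then
characterized (area, perimeter, maximum width, geodesic length,
centroid) into a :class:`SpineRecord`.
"""

from __future__ import annotations

import json
import math
from collections import deque
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import line as _draw_line
from skimage.measure import find_contours

from . import preprocess
from .backbone import WaveletConfig, extract_backbone_from_image, BackbonePath
from .boundary import BoundaryConfig, BoundaryPointSet, search_boundary, fill_boundary
from .rmsnn import RMSNNModel, predict_scores
from .synthetic import CLASS_NAMES


@dataclass
class DetectionPlane:
    """Per-class score grids over the scanned window centers."""

    planes: np.ndarray  # (3, nh, nw)
    stride: int
    window: int

    def center_of(self, i: int, j: int) -> tuple[int, int]:
        half = self.window // 2
        return (i * self.stride + half, j * self.stride + half)


@dataclass
class Candidate:
    class_index: int
    score: float
    center: tuple[int, int]


@dataclass
class SpineRecord:
    class_label: str
    center: tuple[float, float]
    area: int
    perimeter: float
    max_width: float
    length: float
    attachment: str
    score: float
    pixels: np.ndarray = field(repr=False, default=None)


@dataclass
class PipelineConfig:
    median_window: int = 3
    pde_iterations: int = 10
    otsu_window: int = 32
    isolated_n: int = 2
    hysteresis_fraction: float = 0.85
    wavelet: WaveletConfig = field(default_factory=WaveletConfig)
    boundary: BoundaryConfig = field(default_factory=BoundaryConfig)
    stride: int = 2
    score_threshold: float = 0.5
    nms_radius: int = 10  # suppression *radius*: one window diameter between kept peaks
    detach_threshold: float = 5.0
    min_spine_area: int = 4
    min_protrusion: float = 2.5
    match_radius: float = 15.0
    min_backbone_length: int = 20  # spine-sized centerline fragments are not trunk


def scan_detect(
    image: np.ndarray,
    model: RMSNNModel,
    stride: int = 2,
    score_threshold: float = 0.5,
    nms_radius: int | None = None,
    min_contrast: float = 0.15,
) -> tuple[DetectionPlane, list[Candidate]]:  # nms_radius defaults to window/2
    """Score every stride-spaced window and extract candidate maxima.

    The detection plane holds the three class-node outputs per window
    position; candidates are local maxima of the per-position best
    score above ``score_threshold``, greedily non-maximum-suppressed
    within one window size.  The network has no background class (its
    Hit-Miss features are intensity-shift invariant, so a flat window
    produces an arbitrary constant score); windows whose intensity range
    is below ``min_contrast`` therefore cannot hold a spine and are
    excluded from candidacy.
    """
    img = np.asarray(image, float)
    wsz = model.input_size
    h, w = img.shape
    if h < wsz or w < wsz:
        raise ValueError(f"image {h}x{w} smaller than the {wsz}x{wsz} scan window")
    nms_radius = wsz // 2 if nms_radius is None else nms_radius
    rows = range(0, h - wsz + 1, stride)
    cols = range(0, w - wsz + 1, stride)
    windows = np.stack([img[r : r + wsz, c : c + wsz] for r in rows for c in cols])
    scores = predict_scores(model, windows)
    nh, nw = len(rows), len(cols)
    planes = scores.T.reshape(3, nh, nw)
    plane = DetectionPlane(planes=planes, stride=stride, window=wsz)

    contrast = (windows.max(axis=(1, 2)) - windows.min(axis=(1, 2))).reshape(nh, nw)
    best = planes.max(axis=0)
    best_class = planes.argmax(axis=0)
    # local maxima of the best-score surface above threshold
    footprint = np.ones((3, 3), bool)
    local_max = best == ndimage.maximum_filter(best, footprint=footprint, mode="nearest")
    cand_idx = np.argwhere(local_max & (best > score_threshold) & (contrast >= min_contrast))
    order = np.argsort(-best[cand_idx[:, 0], cand_idx[:, 1]])
    kept: list[Candidate] = []
    centers: list[tuple[int, int]] = []
    for k in order:
        i, j = cand_idx[k]
        cy, cx = plane.center_of(i, j)
        if any((cy - py) ** 2 + (cx - px) ** 2 < nms_radius**2 for py, px in centers):
            continue
        centers.append((cy, cx))
        kept.append(Candidate(class_index=int(best_class[i, j]), score=float(best[i, j]), center=(cy, cx)))
    return plane, kept


def trunk_mask_from_boundary(
    shape: tuple[int, int],
    backbone_paths: list[BackbonePath],
    boundaries: list[BoundaryPointSet],
    mask: np.ndarray | None = None,
    smooth_window: int = 15,
) -> np.ndarray:
    """Dendrite trunk region: pixels between the two boundary chains.

    Where the perpendicular search crossed an attached spine, the
    boundary point overshoots the wall; since the trunk half-width
    varies slowly along the dendrite while spines are local, a running
    median over each side's offset profile (window ``smooth_window``)
    restores the wall position there before the cross-sections are
    painted.
    """
    trunk = np.zeros(shape, dtype=bool)
    for path, bnd in zip(backbone_paths, boundaries):
        n = len(path)
        off_a = np.full(n, np.nan)
        off_b = np.full(n, np.nan)
        for i in range(n):
            p = path.points[i]
            if bnd.side_a[i] is not None:
                off_a[i] = math.hypot(bnd.side_a[i][0] - p[0], bnd.side_a[i][1] - p[1])
            if bnd.side_b[i] is not None:
                off_b[i] = math.hypot(bnd.side_b[i][0] - p[0], bnd.side_b[i][1] - p[1])
        for off in (off_a, off_b):
            valid = ~np.isnan(off)
            if not valid.any():
                continue
            fallback = float(np.median(off[valid]))
            off[~valid] = fallback
            med = ndimage.median_filter(off, size=smooth_window, mode="nearest")
            outlier = np.abs(off - med) > 2.0
            off[outlier] = med[outlier]
        def paint_section(r0, c0, tang, oa, ob):
            nr, nc = math.cos(tang), -math.sin(tang)
            pa = (int(round(r0 + oa * nr)), int(round(c0 + oa * nc)))
            pb = (int(round(r0 - ob * nr)), int(round(c0 - ob * nc)))
            rr, cc = _draw_line(pa[0], pa[1], pb[0], pb[1])
            ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
            trunk[rr[ok], cc[ok]] = True

        for i in range(n):
            if np.isnan(off_a[i]) or np.isnan(off_b[i]):
                continue
            paint_section(path.points[i][0], path.points[i][1], path.tangents[i], off_a[i], off_b[i])
        # extrapolate past both ends: the extracted backbone stops short
        # of a terminating (or frame-leaving) tube, whose end cap is
        # dendrite, not spine; follow the foreground as long as it
        # continues straight ahead
        for end, step in ((0, -1.0), (n - 1, 1.0)):
            if np.isnan(off_a[end]) or np.isnan(off_b[end]):
                continue
            tang = path.tangents[end]
            tr_, tc_ = math.sin(tang), math.cos(tang)
            width = off_a[end] + off_b[end]
            min_reach = int(math.ceil(width)) + 2
            max_reach = int(math.ceil(4 * width)) if mask is not None else min_reach
            for t in range(1, max(min_reach, max_reach) + 1):
                r0 = path.points[end][0] + step * t * tr_
                c0 = path.points[end][1] + step * t * tc_
                ri, ci = int(round(r0)), int(round(c0))
                inside = 0 <= ri < shape[0] and 0 <= ci < shape[1]
                if t > min_reach:
                    if mask is None or not inside or not mask[ri, ci]:
                        break
                paint_section(r0, c0, tang, off_a[end], off_b[end])
    return ndimage.binary_closing(trunk, np.ones((3, 3)))


def segment_spines(
    mask: np.ndarray,
    trunk: np.ndarray,
    candidates: list[Candidate],
    detach_threshold: float = 5.0,
    min_area: int = 4,
    match_radius: float = 15.0,
    min_protrusion: float = 2.5,
):
    """Foreground components outside the trunk, flagged attached (touching
    the trunk) or detached (within ``detach_threshold`` px of it); each
    surviving candidate is matched to the nearest component.

    Components that never protrude more than ``min_protrusion`` px past
    the trunk are boundary slivers, not spines, and are discarded.

    Returns ``(components, assignments, dropped)`` where ``components``
    is a list of ``(pixel_mask, attachment)``, ``assignments`` maps each
    candidate index to a component index (or -1), and ``dropped`` lists
    (candidate index, reason) pairs.
    """
    mask = np.asarray(mask, bool)
    trunk = np.asarray(trunk, bool)
    outside = mask & ~trunk
    # close single-pixel cuts so a neck+head severed by the trunk fill
    # stays one component
    closed = ndimage.binary_closing(outside, np.ones((3, 3)))
    labeled, nlab = ndimage.label(closed, structure=np.ones((3, 3)))
    dist_to_trunk = ndimage.distance_transform_edt(~trunk)
    components: list[tuple[np.ndarray, str]] = []
    comp_centers = []
    for lb in range(1, nlab + 1):
        comp = (labeled == lb) & outside
        if comp.sum() < min_area:
            continue
        if dist_to_trunk[comp].max() < min_protrusion:
            continue  # wall sliver
        dmin = dist_to_trunk[comp].min()
        if dmin <= 1.5:
            attachment = "attached"
        elif dmin <= detach_threshold:
            attachment = "detached"
        else:
            continue  # too far from the dendrite to be a spine
        components.append((comp, attachment))
        rr, cc = np.nonzero(comp)
        comp_centers.append((rr.mean(), cc.mean()))
    assignments = []
    dropped = []
    for ci, cand in enumerate(candidates):
        if not comp_centers:
            assignments.append(-1)
            dropped.append((ci, "no spine component near candidate"))
            continue
        d = [math.hypot(cand.center[0] - r, cand.center[1] - c) for r, c in comp_centers]
        best = int(np.argmin(d))
        if d[best] > match_radius:
            assignments.append(-1)
            dropped.append((ci, "no spine component near candidate"))
        else:
            assignments.append(best)
    return components, assignments, dropped


def characterize_spine(pixels: np.ndarray, trunk: np.ndarray | None = None) -> dict:
    """Geometric attributes of one spine pixel set.

    area = pixel count; perimeter = length of the outer iso-contour;
    max_width = maximal extent perpendicular to the principal axis;
    length = geodesic 8-connected step distance from the attachment
    point (pixel nearest the trunk) to the farthest spine pixel;
    center = centroid.
    """
    pixels = np.asarray(pixels, bool)
    if not pixels.any():
        raise ValueError("empty spine pixel set")
    rr, cc = np.nonzero(pixels)
    center = (float(rr.mean()), float(cc.mean()))
    area = int(pixels.sum())

    contours = find_contours(np.pad(pixels.astype(float), 1), 0.5)
    perimeter = max((np.hypot(*np.diff(c, axis=0).T).sum() for c in contours), default=0.0)

    pts = np.column_stack([rr, cc]).astype(float)
    pts -= pts.mean(axis=0)
    if len(pts) > 1:
        _, vecs = np.linalg.eigh(np.cov(pts.T))
        minor = vecs[:, 0]  # eigenvector of the smaller eigenvalue
        proj = pts @ minor
        max_width = float(proj.max() - proj.min() + 1)
    else:
        max_width = 1.0

    # geodesic length by BFS from the attachment point (or the pixel
    # nearest the centroid-side extreme when no trunk is given)
    if trunk is not None and trunk.any():
        dist_to_trunk = ndimage.distance_transform_edt(~np.asarray(trunk, bool))
        start_idx = np.argmin(dist_to_trunk[rr, cc])
    else:
        start_idx = 0
    start = (rr[start_idx], cc[start_idx])
    inside = set(zip(rr.tolist(), cc.tolist()))
    depth = {start: 0}
    queue = deque([start])
    while queue:
        p = queue.popleft()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                q = (p[0] + dr, p[1] + dc)
                if q in inside and q not in depth:
                    depth[q] = depth[p] + 1
                    queue.append(q)
    length = float(max(depth.values()))
    return dict(center=center, area=area, perimeter=float(perimeter), max_width=max_width, length=length)


def run_pipeline(
    image: np.ndarray,
    model: RMSNNModel,
    config: PipelineConfig | None = None,
    output_dir: str | Path | None = None,
) -> tuple[list[SpineRecord], dict]:
    """preprocess -> backbone -> boundary -> scan -> segment -> characterize.

    Returns the spine records and a log dict (per-stage counts and the
    intermediate artifacts).  With ``output_dir`` the overlay PNG and
    CSV/JSON record files are written there.
    """
    config = config or PipelineConfig()
    log: dict = {}
    img = np.asarray(image, float)

    stage = "preprocess"
    try:
        filtered = preprocess.median_filter(img, config.median_window)
        enhanced = preprocess.pde_enhance(filtered, iterations=config.pde_iterations)
        mask, thresholds = preprocess.local_otsu_binarize(
            enhanced, window=config.otsu_window, return_thresholds=True
        )
        mask = preprocess.remove_isolated_points(mask, n=config.isolated_n)
        mask = preprocess.hysteresis_grow(enhanced, mask, thresholds, config.hysteresis_fraction)
        log["foreground_pixels"] = int(mask.sum())

        stage = "backbone"
        paths = extract_backbone_from_image(enhanced, mask, config.wavelet)
        paths = [p for p in paths if len(p) >= config.min_backbone_length]
        log["backbone_paths"] = len(paths)
        log["backbone_points"] = int(sum(len(p) for p in paths))

        stage = "boundary"
        raw_boundaries = [search_boundary(enhanced, p, config.boundary) for p in paths]
        boundaries = [fill_boundary(b) for b in raw_boundaries]
        # the trunk needs the raw (per-backbone-point) chains: filling
        # inserts points and breaks the 1:1 index alignment
        trunk = trunk_mask_from_boundary(img.shape, paths, raw_boundaries, mask=mask)
        log["trunk_pixels"] = int(trunk.sum())

        stage = "scan_detect"
        plane, candidates = scan_detect(
            enhanced, model, stride=config.stride, score_threshold=config.score_threshold,
            nms_radius=config.nms_radius,
        )
        log["candidates"] = len(candidates)

        stage = "segment"
        components, assignments, dropped = segment_spines(
            mask, trunk, candidates,
            detach_threshold=config.detach_threshold,
            min_area=config.min_spine_area,
            match_radius=config.match_radius,
            min_protrusion=config.min_protrusion,
        )
        log["spine_components"] = len(components)
        log["dropped_candidates"] = dropped

        stage = "characterize"
        # one record per matched component; the class comes from the
        # detection-plane evaluation recentered on the component (the
        # stride-1 plane position nearest its centroid), which matches
        # how the training subimages frame a spine
        matched_components = sorted({a for a in assignments if a >= 0})
        records: list[SpineRecord] = []
        wsz = model.input_size
        for comp_idx in matched_components:
            comp, attachment = components[comp_idx]
            attrs = characterize_spine(comp, trunk)
            r0 = int(round(attrs["center"][0] - (wsz - 1) / 2))
            c0 = int(round(attrs["center"][1] - (wsz - 1) / 2))
            r0 = min(max(r0, 0), img.shape[0] - wsz)
            c0 = min(max(c0, 0), img.shape[1] - wsz)
            sc = predict_scores(model, enhanced[r0 : r0 + wsz, c0 : c0 + wsz][None])[0]
            records.append(
                SpineRecord(
                    class_label=CLASS_NAMES[int(sc.argmax())], attachment=attachment,
                    score=float(sc.max()), pixels=comp, **attrs,
                )
            )
        records.sort(key=lambda r: (r.center[0], r.center[1]))
        log["records"] = len(records)
        log["detection_plane"] = plane
        log["paths"] = paths
        log["trunk"] = trunk
        log["mask"] = mask
    except Exception as exc:  # annotate the failing stage
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_records(out / "records.csv", out / "records.json", records)
        overlay = render_overlay(img, paths, boundaries, records)
        from .io import write_image

        write_image(out / "overlay.png", overlay)
    return records, log


def write_records(csv_path: Path, json_path: Path, records: list[SpineRecord]) -> None:
    rows = []
    for r in records:
        d = asdict(r)
        d.pop("pixels")
        d["center_row"], d["center_col"] = (round(v, 2) for v in d.pop("center"))
        for k in ("perimeter", "max_width", "length", "score"):
            d[k] = round(d[k], 3)
        rows.append(d)
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    Path(json_path).write_text(json.dumps(rows, indent=1))


def render_overlay(image: np.ndarray, paths, boundaries, records) -> np.ndarray:
    """RGB overlay: backbone purple, boundary red, spine peripheries blue."""
    img = np.clip(np.asarray(image, float), 0, 1)
    rgb = np.stack([img, img, img], axis=-1)
    for p in paths:
        rgb[p.points[:, 0], p.points[:, 1]] = (0.7, 0.2, 0.9)
    for b in boundaries:
        for pt in b.side_a + b.side_b:
            if pt is not None:
                rgb[pt[0], pt[1]] = (1.0, 0.1, 0.1)
    for r in records:
        if r.pixels is None:
            continue
        edge = r.pixels & ~ndimage.binary_erosion(r.pixels)
        rgb[edge] = (0.15, 0.4, 1.0)
    return rgb
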