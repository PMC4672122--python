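"""Dendrite boundary localization by perpendicular intensity search.

From each backbone point the image is searched along the two directions
perpendicular to the local line direction until the intensity drops
below a threshold alpha; the last pixel with ``I(p) >= alpha`` before
the drop is a boundary point.  Boundary points missed by the search are
filled in afterwards by linking consecutive non-adjacent points with an
8-connected discrete straight line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import line as _draw_line

from .backbone import BackbonePath, GradientField


@dataclass
class BoundaryConfig:
    """alpha is either a global intensity level (``alpha_mode='global'``)
    or a fraction of the local backbone intensity
    (``alpha_mode='fraction_of_backbone'``, the default: robust to the
    intensity variation seen along real dendrites)."""

    alpha_mode: str = "fraction_of_backbone"
    alpha: float = 0.5
    max_search: int = 20

    def __post_init__(self) -> None:
        if self.alpha_mode not in ("global", "fraction_of_backbone"):
            raise ValueError(f"unknown alpha_mode {self.alpha_mode!r}")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.max_search < 1:
            raise ValueError("max_search must be >= 1")


@dataclass
class BoundaryPointSet:
    """Two ordered point chains, one per side of the backbone.

    ``side_a``/``side_b`` hold one entry per backbone point: an (r, c)
    tuple or ``None`` where the search failed (flagged point)."""

    side_a: list[tuple[int, int] | None]
    side_b: list[tuple[int, int] | None]
    flagged: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    closed: bool = False

    def points(self) -> np.ndarray:
        pts = [p for p in self.side_a + self.side_b if p is not None]
        return np.array(pts, dtype=int).reshape(-1, 2)


def local_line_direction(
    field: GradientField,
    point: tuple[int, int],
    fallback: float | None = None,
) -> float:
    """Tangent direction at a backbone point: the wavelet-gradient angle
    rotated by pi/2.  With zero gradient the ``fallback`` chord
    direction is returned (error if none is available)."""
    r, c = int(point[0]), int(point[1])
    if field.modulus[r, c] < 1e-9:
        if fallback is None:
            raise ValueError(f"zero gradient at {point} and no fallback direction")
        return fallback
    return float(field.angle[r, c] + math.pi / 2.0)


def search_boundary(
    image: np.ndarray,
    backbone: BackbonePath,
    config: BoundaryConfig | None = None,
) -> BoundaryPointSet:
    """March perpendicular to the backbone on both sides until I < alpha.

    For each backbone point the search steps outward along the rounded
    perpendicular direction (re-evaluated from the local tangent); the
    last pixel with intensity >= alpha before the first below-alpha
    pixel is recorded.  Backbone points whose own intensity is below
    alpha are flagged and skipped; searches exceeding ``max_search``
    record no point.
    """
    config = config or BoundaryConfig()
    img = np.asarray(image, float)
    h, w = img.shape
    n = len(backbone)
    side_a: list[tuple[int, int] | None] = [None] * n
    side_b: list[tuple[int, int] | None] = [None] * n
    flagged = np.zeros(n, dtype=bool)

    for i in range(n):
        r0, c0 = backbone.points[i]
        if config.alpha_mode == "global":
            alpha = config.alpha
        else:
            alpha = config.alpha * img[r0, c0]
        if img[r0, c0] < alpha or alpha <= 0:
            flagged[i] = True
            continue
        tang = backbone.tangents[i]
        nr, nc = math.cos(tang), -math.sin(tang)  # unit normal (rotate tangent by +90 deg)
        for sign, store in ((1.0, side_a), (-1.0, side_b)):
            last_in = (int(r0), int(c0))
            found = False
            for t in range(1, config.max_search + 1):
                r = int(round(r0 + sign * t * nr))
                c = int(round(c0 + sign * t * nc))
                if not (0 <= r < h and 0 <= c < w):
                    break
                if img[r, c] >= alpha:
                    last_in = (r, c)
                else:
                    store[i] = last_in
                    found = True
                    break
            if not found:
                store[i] = None  # aborted: no edge within max_search
    return BoundaryPointSet(side_a=side_a, side_b=side_b, flagged=flagged)


def _adjacent(p1, p2) -> bool:
    return max(abs(p1[0] - p2[0]), abs(p1[1] - p2[1])) <= 1


def link_missing_points(p1: tuple[int, int], p2: tuple[int, int]) -> list[tuple[int, int]]:
    """Interior pixels of the 8-connected discrete line from p1 to p2.

    Endpoints are excluded; 8-adjacent points need no fill and return an
    empty list.  ``p1 == p2`` is an error.
    """
    if tuple(p1) == tuple(p2):
        raise ValueError("p1 and p2 must differ")
    if _adjacent(p1, p2):
        return []
    rr, cc = _draw_line(int(p1[0]), int(p1[1]), int(p2[0]), int(p2[1]))
    return [(int(r), int(c)) for r, c in zip(rr[1:-1], cc[1:-1])]


def fill_boundary(boundary: BoundaryPointSet) -> BoundaryPointSet:
    """Insert discrete-line fills between consecutive non-adjacent points
    on each side, making each chain 8-connected.  Idempotent on already
    connected chains."""

    def fill_side(side):
        out: list[tuple[int, int] | None] = []
        prev = None
        for p in side:
            if p is None:
                out.append(None)
                continue
            if prev is not None and not _adjacent(prev, p) and prev != p:
                out.extend(link_missing_points(prev, p))
            out.append(p)
            prev = p
        return out

    return BoundaryPointSet(
        side_a=fill_side(boundary.side_a),
        side_b=fill_side(boundary.side_b),
        flagged=boundary.flagged,
        closed=boundary.closed,
    )
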