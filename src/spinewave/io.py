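"""Reading and writing of images, ground truth and spine records.

Images are handled as float arrays in [0, 1]; 8- and 16-bit TIFF/PNG
files are rescaled by their dtype range on read and quantized on write.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile


def read_image(path: str | Path) -> np.ndarray:
    """Read a 2D grayscale image (TIFF/PNG, 8- or 16-bit) as float [0,1].

    Multi-page TIFFs come back as a (z, y, x) stack; RGB images are
    averaged to gray.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        arr = arr[..., :3].mean(axis=-1)
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(float) / info.max
    return np.clip(arr.astype(float), 0.0, 1.0)


def write_image(path: str | Path, image: np.ndarray, bitdepth: int = 8) -> None:
    path = Path(path)
    img = np.clip(np.asarray(image, float), 0.0, 1.0)
    if bitdepth == 16:
        data = (img * 65535).round().astype(np.uint16)
    else:
        data = (img * 255).round().astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)


def write_stack(path: str | Path, stack: np.ndarray, bitdepth: int = 16) -> None:
    """Multi-page TIFF from a (z, y, x) float stack."""
    stack = np.clip(np.asarray(stack, float), 0.0, 1.0)
    if bitdepth == 16:
        data = (stack * 65535).round().astype(np.uint16)
    else:
        data = (stack * 255).round().astype(np.uint8)
    tifffile.imwrite(Path(path), data)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, bool) * 255).astype(np.uint8))


def write_ground_truth(path: str | Path, truth) -> None:
    """Ground truth as JSON (spine records and backbone polyline)."""
    payload = {
        "backbone_points": np.asarray(truth.backbone_points).tolist(),
        "backbone_widths": np.asarray(truth.backbone_widths).tolist(),
        "spines": [
            {
                "class_label": s.class_label,
                "center": list(s.center),
                "area": s.area,
                "max_width": s.max_width,
                "length": s.length,
                "attachment": s.attachment,
            }
            for s in truth.spine_records
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_backbone(path: str | Path, paths) -> None:
    payload = [
        {
            "points": p.points.tolist(),
            "widths": np.round(p.widths, 3).tolist(),
            "tangents": np.round(p.tangents, 4).tolist(),
        }
        for p in paths
    ]
    Path(path).write_text(json.dumps(payload))


def write_boundary(path: str | Path, boundary) -> None:
    payload = {
        "side_a": [list(p) if p is not None else None for p in boundary.side_a],
        "side_b": [list(p) if p is not None else None for p in boundary.side_b],
    }
    Path(path).write_text(json.dumps(payload))
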