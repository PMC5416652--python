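"""Reading and writing images, manifests and cluster exports.

Images are 8-bit/channel PNG, TIFF or BMP.  The mask convention is
positional: exact RGB black (0, 0, 0) marks non-tongue pixels, anything
else is tongue.  Manifests are CSV with at least ``path`` and ``label``
columns; paths are resolved relative to the manifest's directory.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .clustering import ClusterSet
from .labels import TongueColor

__all__ = ["read_image", "write_image", "read_manifest", "write_cluster_export"]


def read_image(path: str | Path) -> np.ndarray:
    """Load an image as an (H, W, 3) uint8 RGB array.

    Greyscale or alpha-carrying images are rejected: the classifier's
    input contract is 24-bit RGB with black background.
    """
    img = Image.open(path)
    if img.mode != "RGB":
        raise ValueError(
            f"{path}: expected a 24-bit RGB image, got mode {img.mode!r}"
        )
    return np.asarray(img)


def write_image(rgb: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(rgb, dtype=np.uint8)).save(path)


def read_manifest(path: str | Path):
    """Load a (path, label) manifest CSV; returns (images, labels, ids)."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("path", "label"):
        if col not in df.columns:
            raise ValueError(f"manifest {path} lacks a {col!r} column")
    images = [read_image(path.parent / p) for p in df["path"]]
    labels = [TongueColor(l) for l in df["label"]]
    ids = list(df.get("image_id", df["path"]))
    return images, labels, ids


# A fixed palette for indexed cluster images (background first).
_PALETTE = np.array(
    [[0, 0, 0], [220, 70, 70], [240, 170, 140], [120, 30, 40],
     [90, 90, 200], [80, 180, 90], [230, 220, 90], [160, 160, 160]],
    dtype=np.uint8,
)


def write_cluster_export(cs: ClusterSet, out_prefix: str | Path) -> tuple[Path, Path]:
    """Write an indexed PNG (one colour per cluster) + summary CSV."""
    out_prefix = Path(out_prefix)
    shape = cs.clusters[0].mask.shape
    index = np.zeros(shape, dtype=np.uint8)
    for c in cs.clusters:
        index[c.mask] = c.id
    rgb = _PALETTE[index % len(_PALETTE)]
    rgb[cs[cs.background_id].mask] = 0
    png_path = out_prefix.with_suffix(".png")
    write_image(rgb, png_path)

    rows = [
        {
            "cluster_id": c.id,
            "is_background": c.id == cs.background_id,
            "centroid_L": c.centroid[0], "centroid_a": c.centroid[1],
            "centroid_b": c.centroid[2],
            "mean_L": c.mean_color[0], "mean_a": c.mean_color[1],
            "mean_b": c.mean_color[2],
            "n_pixels": c.n_pixels,
        }
        for c in cs.clusters
    ]
    csv_path = out_prefix.with_suffix(".csv")
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    return png_path, csv_path


def write_feature_csv(feature_rows: list[dict], path: str | Path) -> None:
    pd.DataFrame(feature_rows).to_csv(path, index=False)
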