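"""Encode a normalized 1-D feature vector as a 2-D image.

Three encodings are provided:

* **bar graph** — each feature becomes a vertical bar of width psi
  pixels separated by gaps of gamma pixels, drawn bottom-up with height
  proportional to the feature value; the canvas is square with side
  ``psi*d + gamma*(d+1)``.
* **distance matrix** — the d x d matrix of absolute pairwise feature
  differences, scaled so its largest entry is 1, then upscaled by pixel
  replication (default 3x, giving 3d x 3d).
* **combined** — a 3-channel 3d x 3d image stacking the distance matrix,
  the bar graph, and a row-wise copy of the feature vector.

All encoders operate on values in [0, 1] and emit intensities in [0, 1].
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .tabular_io import TabularDataset

__all__ = [
    "EncodingConfig",
    "EncodedImage",
    "encode_bar_graph",
    "encode_distance_matrix",
    "encode_combined",
    "encode_row",
    "encode_dataset",
]

#: bar widths for the px1/px2/px4 encoder variants
PX_VARIANTS = {"px1": 1, "px2": 2, "px4": 4}


@dataclass(frozen=True)
class EncodingConfig:
    """Encoder selection and geometry.

    ``psi`` is the bar width in pixels, ``gamma`` the gap between bars;
    ``upscale`` replicates each distance-matrix pixel into an
    ``upscale x upscale`` block. ``field_order`` optionally permutes the
    features (1-based indices) before encoding.
    """

    method: str = "bar_graph"
    psi: int = 1
    gamma: int = 2
    upscale: int = 3
    field_order: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.method not in ("bar_graph", "distance_matrix", "combined"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.psi < 1:
            raise ValueError("psi must be >= 1")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.upscale < 1:
            raise ValueError("upscale must be >= 1")

    @classmethod
    def from_px_variant(cls, method: str, px: str = "px1", **kw) -> "EncodingConfig":
        return cls(method=method, psi=PX_VARIANTS[px], **kw)


@dataclass(frozen=True)
class EncodedImage:
    """A square raster in [0, 1] with provenance."""

    pixels: np.ndarray  # H x W (single channel) or H x W x 3
    source_row: int
    method: str

    def __post_init__(self) -> None:
        p = self.pixels
        if p.ndim not in (2, 3):
            raise ValueError("pixels must be H x W or H x W x C")
        if p.ndim == 3 and p.shape[2] != 3:
            raise ValueError("multi-channel images must have 3 channels")
        if p.shape[0] != p.shape[1]:
            raise ValueError("encoded images are square")
        if p.size and (p.min() < 0 or p.max() > 1):
            raise ValueError("intensities must lie in [0, 1]")

    @property
    def channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else 3


def _check_vector(x: Sequence[float], min_d: int) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < min_d:
        raise ValueError(f"need at least {min_d} feature(s), got {x.size}")
    if np.isnan(x).any() or x.min() < 0 or x.max() > 1:
        raise ValueError("feature vector must be normalized to [0, 1]")
    return x


def bar_graph_width(d: int, psi: int = 1, gamma: int = 2) -> int:
    """Canvas side length for d bars: psi*d + gamma*(d+1)."""
    return psi * d + gamma * (d + 1)


def _bar_heights(x: np.ndarray, side: int) -> np.ndarray:
    # round half away from zero, so a bar at value v covers round(v*side) rows
    return np.floor(x * side + 0.5).astype(int)


def encode_bar_graph(x: Sequence[float], cfg: EncodingConfig | None = None,
                     source_row: int = -1) -> EncodedImage:
    """Rasterize x as equidistant vertical bars on a square canvas.

    Bar k occupies ``psi`` columns starting at ``gamma + k*(psi+gamma)``
    and grows bottom-up over ``round(x_k * side)`` rows at intensity 1.
    """
    cfg = cfg or EncodingConfig(method="bar_graph")
    x = _check_vector(x, 1)
    d = x.size
    side = bar_graph_width(d, cfg.psi, cfg.gamma)
    img = np.zeros((side, side), dtype=float)
    heights = _bar_heights(x, side)
    for k in range(d):
        h = heights[k]
        if h == 0:
            continue
        c0 = cfg.gamma + k * (cfg.psi + cfg.gamma)
        img[side - h:, c0:c0 + cfg.psi] = 1.0
    return EncodedImage(img, source_row, "bar_graph")


def _distance_matrix(x: np.ndarray) -> np.ndarray:
    m = np.abs(np.subtract.outer(x, x))
    peak = m.max()
    if peak > 0:
        m = m / peak
    return m


def upscale(img: np.ndarray, r: int) -> np.ndarray:
    """Replicate each pixel into an r x r constant block."""
    if r == 1:
        return img
    return np.kron(img, np.ones((r, r), dtype=img.dtype))


def encode_distance_matrix(x: Sequence[float], cfg: EncodingConfig | None = None,
                           source_row: int = -1) -> EncodedImage:
    """Absolute pairwise differences |x_i - x_j|, max-normalized, upscaled."""
    cfg = cfg or EncodingConfig(method="distance_matrix")
    x = _check_vector(x, 2)
    m = upscale(_distance_matrix(x), cfg.upscale)
    return EncodedImage(m, source_row, "distance_matrix")


def encode_combined(x: Sequence[float], cfg: EncodingConfig | None = None,
                    source_row: int = -1) -> EncodedImage:
    """Three aligned 3d x 3d channels: distances, bars, row-wise copy.

    The bar graph's native canvas (side ``psi*d + gamma*(d+1)``) differs
    from 3d; at the default psi=1, gamma=2 it is 3d+2 and is center-cropped
    by one pixel per side. Other geometries are resampled to 3d with
    nearest-neighbour interpolation.
    """
    cfg = cfg or EncodingConfig(method="combined")
    x = _check_vector(x, 2)
    d = x.size
    s = 3 * d
    ch1 = upscale(_distance_matrix(x), 3)
    bars = encode_bar_graph(x, replace(cfg, method="bar_graph")).pixels
    if bars.shape[0] == s + 2:
        ch2 = bars[1:-1, 1:-1]
    elif bars.shape[0] == s:
        ch2 = bars
    else:
        im = Image.fromarray((bars * 255).astype(np.uint8), mode="L")
        ch2 = np.asarray(im.resize((s, s), Image.NEAREST), dtype=float) / 255.0
    # rows 3i..3i+2 constant at x_i, across all columns
    ch3 = np.repeat(x, 3)[:, np.newaxis] * np.ones((1, s))
    return EncodedImage(np.stack([ch1, ch2, ch3], axis=-1), source_row, "combined")


_ENCODERS = {
    "bar_graph": encode_bar_graph,
    "distance_matrix": encode_distance_matrix,
    "combined": encode_combined,
}


def apply_field_order(x: np.ndarray, order: Sequence[int] | None) -> np.ndarray:
    """Permute features by 1-based field indices."""
    if order is None:
        return x
    idx = np.asarray(order, dtype=int) - 1
    if sorted(idx.tolist()) != list(range(x.size)):
        raise ValueError("field_order is not a permutation of 1..d")
    return x[idx]


def encode_row(x: Sequence[float], cfg: EncodingConfig,
               source_row: int = -1) -> EncodedImage:
    """Encode one feature vector with the configured method and order."""
    x = apply_field_order(np.asarray(x, dtype=float).ravel(), cfg.field_order)
    return _ENCODERS[cfg.method](x, cfg, source_row)


def encode_dataset(ds: TabularDataset, cfg: EncodingConfig,
                   out_dir: str | Path | None = None) -> list[EncodedImage]:
    """Encode every row; optionally write PNGs plus a CSV manifest.

    PNG intensities are 8-bit quantized (``round(v*255)``); the returned
    in-memory images keep full precision.
    """
    if not ds.normalized:
        raise ValueError("normalize the dataset before encoding")
    images = [encode_row(ds.features[i], cfg, source_row=i)
              for i in range(ds.n_rows)]
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "manifest.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["filename", "row", "label"])
            for img in images:
                name = f"{cfg.method}_{img.source_row:05d}.png"
                arr = np.floor(img.pixels * 255 + 0.5).astype(np.uint8)
                mode = "L" if img.channels == 1 else "RGB"
                Image.fromarray(arr, mode=mode).save(out_dir / name)
                writer.writerow([name, img.source_row,
                                 int(ds.labels[img.source_row])])
    return images
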