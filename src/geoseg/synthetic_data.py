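"""Synthetic microscopy-like test sets.

Two seeded generators make every pipeline stage testable without any
external download:

* ``generate_beans`` — 256x256 images of kidney-bean silhouettes (each
  bean is a pair of half-ellipses sharing their major axis with offset
  minor semi-axes) on a flat background, with binary ground-truth masks
  and optional additive Gaussian noise.  Used for the segmentation
  workflow.
* ``generate_shapes`` — one filled shape per 256x256 instance, either a
  circle of random size or an affinely transformed (rotated, scaled,
  sheared) triangle, placed at random; used for the whole-image
  classification workflow, where circles and triangles stress the
  complementary sensitivities of Zernike and Legendre moments.

All randomness flows through one ``numpy.random.Generator`` per call, so
a given seed reproduces the data set bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .regional_features import RegionMask

__all__ = ["BeanSetSpec", "ShapeSetSpec", "generate_beans", "generate_shapes"]


@dataclass(frozen=True)
class BeanSetSpec:
    n_images: int = 5
    size: int = 256
    beans_min: int = 3
    beans_max: int = 8
    foreground: float = 200.0
    background: float = 50.0
    noise_sigma: float = 0.0
    axis_ratio: Tuple[float, float] = (1.5, 2.5)   # major/minor semi-axis
    minor_range: Tuple[float, float] = (8.0, 16.0)  # minor semi-axis, px
    offset_frac: Tuple[float, float] = (0.15, 0.30)  # half-ellipse offset / minor
    max_overlap: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 64:
            raise ValueError("size must be >= 64")
        if self.foreground == self.background:
            raise ValueError("foreground and background levels must differ")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class ShapeSetSpec:
    n_per_class: int = 100
    size: int = 256
    radius_range: Tuple[float, float] = (15.0, 45.0)
    triangle_side: Tuple[float, float] = (40.0, 100.0)
    vertex_jitter: float = 0.15     # fraction of side length
    scale_range: Tuple[float, float] = (0.6, 1.4)
    shear_range: Tuple[float, float] = (-0.3, 0.3)
    foreground: float = 200.0
    background: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 64:
            raise ValueError("size must be >= 64")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _bean_mask(size: int, cx: float, cy: float, a: float, b1: float, b2: float,
               offset: float, theta: float) -> np.ndarray:
    """Kidney silhouette: two half-ellipses sharing the major (u) axis.

    The upper half (v >= 0) has minor semi-axis b1 centered at v = +offset,
    the lower half b2 at v = -offset; the offset bends the outline into a
    bean shape.
    """
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    u = (xx - cx) * math.cos(theta) + (yy - cy) * math.sin(theta)
    v = -(xx - cx) * math.sin(theta) + (yy - cy) * math.cos(theta)
    upper = (v >= 0) & ((u / a) ** 2 + ((v - offset) / b1) ** 2 <= 1.0)
    lower = (v < 0) & ((u / a) ** 2 + ((v + offset) / b2) ** 2 <= 1.0)
    return upper | lower


def generate_beans(spec: BeanSetSpec | None = None) -> List[Tuple[np.ndarray, np.ndarray]]:
    """List of (image, binary ground-truth mask) pairs.

    Beans are placed by rejection sampling so any new bean overlaps the
    existing foreground by at most ``max_overlap`` of its own area.
    Noise, when enabled, is additive i.i.d. Gaussian clipped to the
    [min(levels), max(levels)] intensity range.
    """
    spec = spec or BeanSetSpec()
    rng = np.random.default_rng(spec.seed)
    out: List[Tuple[np.ndarray, np.ndarray]] = []
    for _ in range(spec.n_images):
        mask = np.zeros((spec.size, spec.size), dtype=bool)
        n_beans = int(rng.integers(spec.beans_min, spec.beans_max + 1))
        placed = 0
        attempts = 0
        while placed < n_beans and attempts < 200:
            attempts += 1
            b = rng.uniform(*spec.minor_range)
            a = b * rng.uniform(*spec.axis_ratio)
            offset = b * rng.uniform(*spec.offset_frac)
            theta = rng.uniform(0, math.pi)
            margin = a + b + offset + 2
            cx = rng.uniform(margin, spec.size - margin)
            cy = rng.uniform(margin, spec.size - margin)
            b2 = b * rng.uniform(0.6, 0.9)  # thinner lower half
            bean = _bean_mask(spec.size, cx, cy, a, b, b2, offset, theta)
            if bean.sum() == 0:
                continue
            if (bean & mask).sum() / bean.sum() > spec.max_overlap:
                continue
            mask |= bean
            placed += 1
        img = np.where(mask, spec.foreground, spec.background).astype(np.float64)
        if spec.noise_sigma > 0:
            lo = min(spec.foreground, spec.background)
            hi = max(spec.foreground, spec.background)
            img = np.clip(img + rng.normal(0, spec.noise_sigma, img.shape), lo, hi)
        out.append((img, mask.astype(np.int64)))
    return out


def _triangle_vertices(spec: ShapeSetSpec, rng: np.random.Generator) -> np.ndarray:
    """Jittered equilateral triangle, then a random affine map."""
    side = rng.uniform(*spec.triangle_side)
    base = side * np.array(
        [[0.0, -1.0 / math.sqrt(3)],
         [0.5, 0.5 / math.sqrt(3)],
         [-0.5, 0.5 / math.sqrt(3)]]
    )
    base += rng.uniform(-spec.vertex_jitter, spec.vertex_jitter, (3, 2)) * side
    theta = rng.uniform(0, 2 * math.pi)
    rot = np.array([[math.cos(theta), -math.sin(theta)],
                    [math.sin(theta), math.cos(theta)]])
    sx, sy = rng.uniform(*spec.scale_range, size=2)
    shear = rng.uniform(*spec.shear_range)
    aff = np.array([[sx, shear * sx], [0.0, sy]]) @ rot
    return base @ aff.T


def _fill_polygon(size: int, verts: np.ndarray) -> np.ndarray:
    """Pixel-center even-odd rasterization of a polygon."""
    from matplotlib.path import Path

    yy, xx = np.mgrid[0:size, 0:size]
    pts = np.stack([xx.ravel() + 0.0, yy.ravel() + 0.0], axis=1)
    inside = Path(verts).contains_points(pts)
    return inside.reshape(size, size)


def generate_shapes(
    spec: ShapeSetSpec | None = None,
) -> List[Tuple[np.ndarray, str, RegionMask]]:
    """List of (image, class label, region mask) triples.

    Classes alternate "circle", "triangle" so any prefix of the list is
    roughly balanced; ``n_per_class`` instances of each are produced.
    """
    spec = spec or ShapeSetSpec()
    rng = np.random.default_rng(spec.seed)
    out: List[Tuple[np.ndarray, str, RegionMask]] = []
    yy, xx = np.mgrid[0:spec.size, 0:spec.size].astype(np.float64)
    for i in range(2 * spec.n_per_class):
        label = "circle" if i % 2 == 0 else "triangle"
        if label == "circle":
            r = rng.uniform(*spec.radius_range)
            cx = rng.uniform(r + 2, spec.size - r - 2)
            cy = rng.uniform(r + 2, spec.size - r - 2)
            mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
        else:
            while True:
                verts = _triangle_vertices(spec, rng)
                half = np.abs(verts).max() + 2
                cx = rng.uniform(half, spec.size - half)
                cy = rng.uniform(half, spec.size - half)
                mask = _fill_polygon(spec.size, verts + [cx, cy])
                if mask.sum() >= 25:  # degenerate shears can collapse the area
                    break
        img = np.where(mask, spec.foreground, spec.background).astype(np.float64)
        if spec.noise_sigma > 0:
            img = img + rng.normal(0, spec.noise_sigma, img.shape)
        out.append((img, label, RegionMask.from_full_mask(mask)))
    return out
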