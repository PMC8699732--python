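"""Trainable pixel-classification workflow: annotations -> per-pixel
feature vectors -> trained model -> class probability maps -> masks.

Annotations are class-labeled regions (polygons or masks) over one or
more images.  A pixel belongs to a polygon ROI when its center lies
inside it (even-odd rule, 0-based coordinates, origin top-left).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath

from .feature_selection import FeatureTable
from .learning import TrainedModel, predict_proba
from .scale_space import FeatureStack

__all__ = [
    "ClassDef",
    "Roi",
    "AnnotationSet",
    "ProbabilityMap",
    "sample_training_pixels",
    "classify_stack",
    "probability_to_mask",
    "overlay",
]


@dataclass(frozen=True)
class ClassDef:
    id: int
    name: str
    color: Tuple[int, int, int] = (255, 0, 0)


@dataclass
class Roi:
    """Labeled region: either polygon vertices [(x, y), ...] or a boolean mask."""

    class_id: int
    image_id: int = 0
    polygon: Optional[List[Tuple[float, float]]] = None
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if (self.polygon is None) == (self.mask is None):
            raise ValueError("ROI needs exactly one of polygon or mask")
        if self.polygon is not None and len(self.polygon) < 3:
            raise ValueError("polygon needs at least 3 vertices")

    def rasterize(self, shape: Tuple[int, int]) -> np.ndarray:
        if self.mask is not None:
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != shape:
                raise ValueError(f"mask ROI shape {m.shape} != image {shape}")
            return m
        verts = np.asarray(self.polygon, dtype=np.float64)
        if verts[:, 0].min() < -0.5 or verts[:, 1].min() < -0.5 \
                or verts[:, 0].max() > shape[1] - 0.5 or verts[:, 1].max() > shape[0] - 0.5:
            raise ValueError("polygon extends outside image bounds")
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        pts = np.stack([xx.ravel(), yy.ravel()], axis=1).astype(np.float64)
        return MplPath(verts).contains_points(pts).reshape(shape)


@dataclass
class AnnotationSet:
    classes: List[ClassDef]
    rois: List[Roi] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.classes]
        if len(set(ids)) != len(ids):
            raise ValueError("class ids must be unique")
        known = set(ids)
        for roi in self.rois:
            if roi.class_id not in known:
                raise ValueError(f"ROI references undefined class id {roi.class_id}")

    def class_by_id(self, cid: int) -> ClassDef:
        for c in self.classes:
            if c.id == cid:
                return c
        raise KeyError(cid)

    def label_mask(self, shape: Tuple[int, int], image_id: int = 0) -> np.ndarray:
        """-1 for unlabeled pixels, class id elsewhere; overlap is rejected."""
        out = np.full(shape, -1, dtype=np.int64)
        for roi in self.rois:
            if roi.image_id != image_id:
                continue
            m = roi.rasterize(shape)
            clash = (out >= 0) & m & (out != roi.class_id)
            if clash.any():
                raise ValueError(
                    "overlapping ROIs of different classes: ambiguous ground truth"
                )
            out[m] = roi.class_id
        return out


@dataclass
class ProbabilityMap:
    """Per-class H x W probability planes (pixelwise sum 1)."""

    class_ids: List[int]
    planes: np.ndarray  # (n_classes, H, W)

    def __post_init__(self) -> None:
        p = np.asarray(self.planes, dtype=np.float64)
        if p.min() < -1e-9 or p.max() > 1 + 1e-9:
            raise ValueError("probabilities outside [0, 1]")
        if np.abs(p.sum(axis=0) - 1.0).max() > 1e-6:
            raise ValueError("probability planes must sum to 1 pixelwise")
        self.planes = p


def sample_training_pixels(
    stack: FeatureStack,
    annotations: AnnotationSet,
    max_per_class: Optional[int] = None,
    seed: int = 0,
    image_id: int = 0,
) -> FeatureTable:
    """Feature table of annotated pixels, optionally capped per class.

    Pixels are taken in row-major order, then seed-shuffled; with a cap
    the first ``max_per_class`` of the shuffled pixels per class are
    kept.  A class with zero annotated pixels is rejected by name.
    """
    labels_img = annotations.label_mask(stack.shape, image_id=image_id)
    mat = stack.as_matrix()
    rng = np.random.default_rng(seed)
    rows: List[np.ndarray] = []
    labels: List[np.ndarray] = []
    for cdef in annotations.classes:
        flat_idx = np.flatnonzero(labels_img.ravel() == cdef.id)
        if flat_idx.size == 0:
            raise ValueError(f"class {cdef.name!r} (id {cdef.id}) has no annotated pixels")
        perm = rng.permutation(flat_idx.size)
        flat_idx = flat_idx[perm]
        if max_per_class is not None:
            flat_idx = flat_idx[:max_per_class]
        rows.append(mat[flat_idx])
        labels.append(np.full(flat_idx.size, cdef.id, dtype=np.int64))
    data = pd.DataFrame(np.concatenate(rows), columns=stack.names)
    return FeatureTable(data, np.concatenate(labels))


def classify_stack(model: TrainedModel, stack: FeatureStack) -> ProbabilityMap:
    """Score every pixel's feature vector; preserves H x W."""
    mat = stack.as_matrix()
    proba = predict_proba(model, mat, feature_names=stack.names)
    h, w = stack.shape
    planes = proba.T.reshape(len(model.classes), h, w)
    return ProbabilityMap(class_ids=[int(c) for c in model.classes], planes=planes)


def probability_to_mask(
    pmap: ProbabilityMap,
    mode: str = "argmax",
    threshold: float = 0.5,
    target_class: Optional[int] = None,
) -> np.ndarray:
    """Label image from a probability map.

    argmax mode assigns every pixel the most probable class (ties toward
    the lower class id); threshold mode yields the binary mask of
    ``target_class`` with probability >= threshold.
    """
    if mode == "argmax":
        order = np.argsort(pmap.class_ids)  # ties resolve to lower id
        planes = pmap.planes[order]
        ids = np.asarray(pmap.class_ids)[order]
        return ids[np.argmax(planes, axis=0)]
    if mode == "threshold":
        if not (0 < threshold < 1):
            raise ValueError("threshold must be in (0, 1)")
        if target_class is None:
            raise ValueError("threshold mode needs target_class")
        i = pmap.class_ids.index(target_class)
        return (pmap.planes[i] >= threshold).astype(np.int64)
    raise ValueError(f"unknown mode {mode!r}")


def overlay(
    img: np.ndarray,
    label_image: np.ndarray,
    colors: Dict[int, Tuple[int, int, int]],
    alpha: float = 0.5,
    path=None,
) -> np.ndarray:
    """Alpha-blend class colors onto the image; optionally write a PNG.

    Label 0 is treated as background (left unpainted) when it has no
    color entry; any other label without a color entry is an error.
    """
    img = np.asarray(img, dtype=np.float64)
    lo, hi = img.min(), img.max()
    base = (img - lo) / (hi - lo) * 255.0 if hi > lo else np.zeros_like(img)
    rgb = np.stack([base] * 3, axis=-1)
    for lab in np.unique(label_image):
        lab = int(lab)
        if lab not in colors:
            if lab == 0:
                continue
            raise ValueError(f"no color defined for class id {lab}")
        m = label_image == lab
        rgb[m] = (1 - alpha) * rgb[m] + alpha * np.asarray(colors[lab], dtype=np.float64)
    out = np.clip(rgb, 0, 255).astype(np.uint8)
    if path is not None:
        iio.imwrite(path, out)
    return out
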