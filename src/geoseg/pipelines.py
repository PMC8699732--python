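"""End-to-end workflows composed from the library modules.

Two reference pipelines mirror the platform's operation modes:

* whole-image classification — regional features (Legendre + Zernike
  moments of order 0-6 and ROI statistics) per shape instance, a
  maximum-margin classifier, train/test scoring;
* pixel segmentation — a scale-space feature stack per image, a random
  forest trained on annotated pixels, probability-map thresholding, and
  Vrand / pixel-F1 scoring against ground truth.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .evaluation import classification_metrics, contingency, v_info, v_rand
from .feature_selection import FeatureTable
from .learning import ClassifierSpec, TrainedModel, predict, predict_proba, train
from .regional_features import (
    GLCMSpec,
    MomentSpec,
    RegionMask,
    compute_regional_vector,
)
from .scale_space import FeatureStack, ScaleSpec, build_feature_stack
from .segmentation import (
    AnnotationSet,
    ClassDef,
    Roi,
    classify_stack,
    probability_to_mask,
    sample_training_pixels,
)
from .synthetic_data import BeanSetSpec, ShapeSetSpec, generate_beans, generate_shapes

__all__ = [
    "shape_feature_table",
    "run_shape_classification",
    "run_bean_segmentation",
    "SEGMENTATION_FILTERS",
]

#: default filter set of the pixel-segmentation pipeline
SEGMENTATION_FILTERS = ("Gauss2D", "Gradient", "LoG", "Hessian")


def shape_feature_table(
    instances: Sequence[Tuple[np.ndarray, str, RegionMask]],
    moment_max_order: int = 6,
    include_haralick: bool = False,
) -> FeatureTable:
    """Regional feature table of shape instances (one row per instance)."""
    specs = (MomentSpec("legendre", moment_max_order), MomentSpec("zernike", moment_max_order))
    glcm = GLCMSpec() if include_haralick else None
    rows: List[Dict[str, float]] = []
    labels: List[str] = []
    for img, label, region in instances:
        rows.append(compute_regional_vector(img, region, specs, glcm))
        labels.append(label)
    return FeatureTable(pd.DataFrame(rows), np.asarray(labels))


def run_shape_classification(
    n_train: int = 100,
    n_test: int = 50,
    seed: int = 0,
    size: int = 256,
    noise_sigma: float = 0.0,
    classifier: Optional[ClassifierSpec] = None,
) -> Dict[str, object]:
    """Circle-vs-triangle classification with the SVM pipeline.

    Generates ``n_train`` + ``n_test`` instances per class, computes the
    regional features, trains the maximum-margin classifier, and scores
    both splits.  Returns the trained model and per-split metric reports.
    """
    train_set = generate_shapes(
        ShapeSetSpec(n_per_class=n_train, size=size, noise_sigma=noise_sigma, seed=seed)
    )
    test_set = generate_shapes(
        ShapeSetSpec(n_per_class=n_test, size=size, noise_sigma=noise_sigma,
                     seed=seed + 100_003)
    )
    table_train = shape_feature_table(train_set)
    table_test = shape_feature_table(test_set)
    spec = classifier or ClassifierSpec(kind="svm", seed=seed)
    model = train(table_train, spec)
    out: Dict[str, object] = {"model": model}
    for split, table in (("train", table_train), ("test", table_test)):
        pred = predict(model, table)
        proba = predict_proba(model, table)
        report = classification_metrics(table.labels, pred, proba, classes=model.classes)
        out[split] = {
            "accuracy": float(np.mean(pred == table.labels)),
            "report": report,
        }
    return out


def _full_annotations(mask: np.ndarray) -> AnnotationSet:
    """Two-class annotation covering every pixel of a bean ground truth."""
    classes = [ClassDef(0, "background", (0, 0, 255)), ClassDef(1, "bean", (255, 0, 0))]
    rois = [
        Roi(class_id=0, mask=mask == 0),
        Roi(class_id=1, mask=mask == 1),
    ]
    return AnnotationSet(classes=classes, rois=rois)


def run_bean_segmentation(
    seed: int = 0,
    n_train_images: int = 4,
    noise_sigma: float = 15.0,
    max_per_class: int = 2000,
    sigmas: Tuple[float, ...] = (2.0, 4.0, 8.0),
    filters: Sequence[str] = SEGMENTATION_FILTERS,
    rf_trees: int = 100,
) -> Dict[str, float]:
    """Train a random forest on bean images, segment a held-out one.

    The generator produces ``n_train_images + 1`` images; the model is
    trained on fully annotated pixels (seeded cap per class) of the
    first ``n_train_images`` and evaluated on the last.  Returns Vrand,
    Vinfo and pixel F1 of the foreground-vs-background segmentation.
    """
    spec = BeanSetSpec(n_images=n_train_images + 1, noise_sigma=noise_sigma, seed=seed)
    data = generate_beans(spec)
    scale_spec = ScaleSpec(sigmas=sigmas)
    tables: List[FeatureTable] = []
    for img, mask in data[:n_train_images]:
        stack = build_feature_stack(img, scale_spec, filters)
        tables.append(
            sample_training_pixels(stack, _full_annotations(mask),
                                   max_per_class=max_per_class, seed=seed)
        )
    table = FeatureTable(
        pd.concat([t.data for t in tables], ignore_index=True),
        np.concatenate([t.labels for t in tables]),
    )
    model = train(table, ClassifierSpec(kind="random_forest", rf_trees=rf_trees, seed=seed))
    test_img, test_mask = data[-1]
    stack = build_feature_stack(test_img, scale_spec, filters)
    pmap = classify_stack(model, stack)
    labels = probability_to_mask(pmap, mode="threshold", threshold=0.5, target_class=1)
    ct = contingency(labels, test_mask)
    tp = float(np.sum((labels == 1) & (test_mask == 1)))
    fp = float(np.sum((labels == 1) & (test_mask == 0)))
    fn = float(np.sum((labels == 0) & (test_mask == 1)))
    f1 = 2 * tp / (2 * tp + fp + fn) if tp > 0 else 0.0
    return {"v_rand": v_rand(ct), "v_info": v_info(ct), "pixel_f1": f1}
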