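"""Project metadata, folder layout, ARFF/CSV export, and image I/O.

A project is a directory with a canonical layout::

    <root>/
      project.json      # all settings: filters, scales, classes, ROIs, seeds
      images/           # training raw data
      features/         # filter responses for the training data
      learning/         # ARFF feature tables
      testfilters/      # filter responses for the test data
      testimages/       # test raw data

``project.json`` is written with sorted keys and a format version, so
save -> load -> save is byte-identical and a reloaded project re-runs a
workflow bit-identically.  Unknown future fields are preserved on
rewrite.
"""

from __future__ import annotations

import datetime
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .feature_selection import FeatureTable
from .scale_space import FeatureStack

__all__ = [
    "Project",
    "FOLDERS",
    "save_project",
    "load_project",
    "export_arff",
    "read_arff",
    "export_csv",
    "run_log",
    "read_image",
    "write_image",
    "write_feature_stack",
    "read_feature_stack",
]

FORMAT_VERSION = 1
FOLDERS = ("images", "features", "learning", "testfilters", "testimages")
# some existing project trees spell this folder "tesfilters"; accept on load
_FOLDER_ALIASES = {"tesfilters": "testfilters"}

#: ITU-R 601 luma weights used when converting color images to grayscale
GRAY_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class Project:
    name: str = "untitled"
    mode: str = "segmentation"  # or "classification"
    filters: List[str] = field(default_factory=lambda: ["Gradient", "LoG", "Hessian"])
    sigmas: List[float] = field(default_factory=lambda: [2.0, 4.0, 8.0])
    moment_max_order: int = 6
    glcm_distances: List[int] = field(default_factory=lambda: [1, 2, 3])
    glcm_angles: List[int] = field(default_factory=lambda: [0, 45, 90, 135])
    classifier: Dict = field(default_factory=lambda: {"kind": "random_forest"})
    selection: Dict = field(default_factory=dict)   # method + selected features
    classes: List[Dict] = field(default_factory=list)
    rois: List[Dict] = field(default_factory=list)
    seed: int = 0
    extra: Dict = field(default_factory=dict)       # unknown fields, preserved

    def to_json_dict(self) -> Dict:
        d = {
            "format_version": FORMAT_VERSION,
            "name": self.name,
            "mode": self.mode,
            "filters": self.filters,
            "sigmas": self.sigmas,
            "moment_max_order": self.moment_max_order,
            "glcm_distances": self.glcm_distances,
            "glcm_angles": self.glcm_angles,
            "classifier": self.classifier,
            "selection": self.selection,
            "classes": self.classes,
            "rois": self.rois,
            "seed": self.seed,
        }
        d.update(self.extra)
        return d

    def validate(self) -> None:
        if self.mode not in ("segmentation", "classification"):
            raise ValueError(f"unknown project mode {self.mode!r}")
        ids = [c["id"] for c in self.classes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate class ids in project")
        for i, roi in enumerate(self.rois):
            if roi["class_id"] not in ids:
                raise ValueError(
                    f"ROI record {i} references undefined class id {roi['class_id']}"
                )


def save_project(project: Project, root_dir) -> Path:
    """Create the folder layout and write canonical project.json."""
    project.validate()
    root = Path(root_dir)
    root.mkdir(parents=True, exist_ok=True)
    for folder in FOLDERS:
        (root / folder).mkdir(exist_ok=True)
    payload = json.dumps(project.to_json_dict(), sort_keys=True, indent=2) + "\n"
    (root / "project.json").write_text(payload, encoding="utf-8")
    return root / "project.json"


def load_project(root_dir) -> Project:
    """Read and validate project.json from a project directory."""
    root = Path(root_dir)
    pfile = root / "project.json"
    if not pfile.exists():
        raise FileNotFoundError(f"no project.json under {root}")
    d = json.loads(pfile.read_text(encoding="utf-8"))
    version = d.pop("format_version", None)
    if version != FORMAT_VERSION:
        raise ValueError(
            f"{pfile}: unsupported project format version {version!r} "
            f"(expected {FORMAT_VERSION})"
        )
    known = {
        "name", "mode", "filters", "sigmas", "moment_max_order",
        "glcm_distances", "glcm_angles", "classifier", "selection",
        "classes", "rois", "seed",
    }
    kwargs = {k: d[k] for k in known if k in d}
    extra = {k: v for k, v in d.items() if k not in known}
    project = Project(**kwargs, extra=extra)
    project.validate()
    return project


# ---------------------------------------------------------------------------
# ARFF / CSV

def _quote(name: str) -> str:
    if re.search(r"[\s,'\"%{}]", name):
        return "'" + name.replace("'", r"\'") + "'"
    return name


def export_arff(table: FeatureTable, path, relation: str = "geoseg") -> None:
    """Write a feature table as ARFF: numeric attributes in table order,
    nominal class attribute last."""
    lines = [f"@relation {_quote(relation)}", ""]
    for name in table.feature_names:
        lines.append(f"@attribute {_quote(name)} numeric")
    classes = ",".join(_quote(str(c)) for c in sorted(set(map(str, table.labels))))
    lines.append(f"@attribute class {{{classes}}}")
    lines.append("")
    lines.append("@data")
    X = table.matrix
    for row, label in zip(X, table.labels):
        lines.append(",".join(repr(float(v)) for v in row) + f",{_quote(str(label))}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _unquote(tok: str) -> str:
    tok = tok.strip()
    if len(tok) >= 2 and tok[0] == tok[-1] and tok[0] in "'\"":
        return tok[1:-1].replace(r"\'", "'")
    return tok


def read_arff(path) -> FeatureTable:
    """Parse back the ARFF subset written by :func:`export_arff`."""
    names: List[str] = []
    rows: List[List[float]] = []
    labels: List[str] = []
    in_data = False
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line or line.startswith("%"):
            continue
        low = line.lower()
        if low.startswith("@attribute"):
            rest = line[len("@attribute"):].strip()
            if rest.startswith("'"):
                end = rest.index("'", 1)
                name = rest[1:end].replace(r"\'", "'")
            else:
                name = rest.split()[0]
            if "{" not in rest:
                names.append(name)
        elif low.startswith("@data"):
            in_data = True
        elif in_data:
            toks = line.split(",")
            rows.append([float(t) for t in toks[:-1]])
            labels.append(_unquote(toks[-1]))
    data = pd.DataFrame(np.asarray(rows, dtype=np.float64), columns=names)
    return FeatureTable(data, np.asarray(labels))


def export_csv(table: FeatureTable, path) -> None:
    df = table.data.copy()
    df["class"] = table.labels
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Run log

def run_log(root_dir, event: str, params: Optional[Dict] = None) -> Path:
    """Append a human-readable line to <root>/run.log."""
    from . import __version__

    root = Path(root_dir)
    root.mkdir(parents=True, exist_ok=True)
    log = root / "run.log"
    stamp = datetime.datetime.now().isoformat(timespec="seconds")
    detail = json.dumps(params or {}, sort_keys=True)
    with open(log, "a", encoding="utf-8") as fh:
        fh.write(f"{stamp} geoseg-{__version__} {event} {detail}\n")
    return log


# ---------------------------------------------------------------------------
# Images and feature stacks

def read_image(path) -> np.ndarray:
    """Read TIFF/PNG as float64 grayscale (ITU-R 601 weights for color)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        arr = arr[..., :3] @ np.asarray(GRAY_WEIGHTS)
    return arr


def write_image(path, img: np.ndarray) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, np.asarray(img, dtype=np.float32))
    else:
        arr = np.asarray(img)
        if arr.dtype.kind == "f":
            arr = np.clip(arr, 0, 255).astype(np.uint8)
        iio.imwrite(path, arr)


def write_feature_stack(path, stack: FeatureStack) -> None:
    """Multi-page float TIFF, one page per plane, names in descriptions."""
    planes = [p.astype(np.float32) for p in stack.planes.values()]
    with tifffile.TiffWriter(path) as tw:
        for name, plane in zip(stack.names, planes):
            tw.write(plane, description=name, contiguous=False)


def read_feature_stack(path, source: Optional[np.ndarray] = None) -> FeatureStack:
    stack = None
    with tifffile.TiffFile(path) as tf:
        for page in tf.pages:
            plane = page.asarray().astype(np.float64)
            if stack is None:
                stack = FeatureStack(source=source if source is not None else plane)
            stack.add(page.description, plane)
    if stack is None:
        raise ValueError(f"{path}: empty feature stack")
    return stack
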