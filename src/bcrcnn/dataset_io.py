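"""Dataset types, PASCAL-VOC2007 annotation I/O, and run configuration.

Coordinate convention used throughout the package: continuous, 0-based,
half-open boxes [x_min, x_max) x [y_min, y_max), origin at the top-left,
x rightward, y downward.  VOC XML stores 1-based inclusive integer corners;
conversion is min-1 on read and min+1 on write, which keeps widths, heights
and IoU arithmetic exact.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from pathlib import Path

import numpy as np
import yaml
from lxml import etree
from PIL import Image

log = logging.getLogger("bcrcnn")

BACKGROUND, BENIGN, MALIGNANT = 0, 1, 2
CLASS_NAMES = {BACKGROUND: "background", BENIGN: "benign", MALIGNANT: "malignant"}
LESION_CLASSES = ("benign", "malignant")


class Plane(str, Enum):
    AXIAL = "axial"
    SAGITTAL = "sagittal"


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle in continuous half-open pixel coordinates."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self):
        vals = (self.x_min, self.y_min, self.x_max, self.y_max)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"box coordinates must be finite, got {vals}")
        if self.x_max < self.x_min or self.y_max < self.y_min:
            raise ValueError(f"degenerate box: {vals}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def as_array(self) -> np.ndarray:
        return np.array([self.x_min, self.y_min, self.x_max, self.y_max], dtype=np.float64)

    def clip(self, width: float, height: float) -> "Box":
        return Box(
            min(max(self.x_min, 0.0), width),
            min(max(self.y_min, 0.0), height),
            min(max(self.x_max, 0.0), width),
            min(max(self.y_max, 0.0), height),
        )


def boxes_to_array(boxes) -> np.ndarray:
    """Stack boxes (Box instances or 4-sequences) into an (N, 4) float array."""
    if len(boxes) == 0:
        return np.zeros((0, 4), dtype=np.float64)
    rows = [b.as_array() if isinstance(b, Box) else np.asarray(b, dtype=np.float64)
            for b in boxes]
    return np.stack(rows)


def array_to_boxes(arr: np.ndarray) -> list[Box]:
    return [Box(*row) for row in np.asarray(arr, dtype=np.float64)]


@dataclass(frozen=True)
class LesionAnnotation:
    box: Box
    label: int  # BENIGN or MALIGNANT
    lesion_id: str
    plane: Plane = Plane.AXIAL

    def __post_init__(self):
        if self.label not in (BENIGN, MALIGNANT):
            raise ValueError(f"label must be benign(1) or malignant(2), got {self.label}")
        if not self.lesion_id:
            raise ValueError("lesion_id must be non-empty")


@dataclass
class VOCRecord:
    image_path: Path
    image_size: tuple[int, int]  # (width, height)
    annotations: list[LesionAnnotation] = field(default_factory=list)

    @property
    def image_id(self) -> str:
        return Path(self.image_path).stem


@dataclass
class RunConfig:
    """All knobs of the pipeline with their canonical defaults.

    The detection defaults follow the standard two-stage recipe: IoU match
    threshold 0.5, 300 ROI candidates, a 7x7 aligned pool, a 160-pixel
    canonical ROI size for pyramid level assignment, and batch-1 SGD
    (momentum 0.9, weight decay 5e-4, lr 1e-5) for 30 epochs.
    """

    num_classes: int = 3  # background, benign, malignant
    num_candidates: int = 300
    iou_threshold: float = 0.5
    batch_size: int = 1
    weight_decay: float = 0.0005
    learning_rate: float = 0.00001
    epochs: int = 30
    momentum: float = 0.9
    use_fpn: bool = True
    canonical_roi_size: int = 160
    pooled_size: int = 7
    malignant_threshold: float = 0.5
    backbone_preset: str = "vgg16"  # or "tiny"
    seed: int = 0
    # unstated knobs of the standard recipe, logged for provenance
    rpn_nms_threshold: float = 0.7
    detection_nms_threshold: float = 0.3
    pre_nms_top_n: int = 1000
    rpn_batch_size: int = 128
    roi_batch_size: int = 128
    positive_fraction: float = 0.5
    negative_iou: float = 0.3
    short_side: int = 512
    fpn_channels: int = 64
    # anchor areas: single-level mode uses anchor_scales (3 scales x 3
    # ratios = 9 shapes); FPN mode uses one base scale per level P2..P6,
    # expanded to the two geometric neighbours s/sqrt2 and s*sqrt2.
    anchor_scales: tuple = (128, 256, 512)
    fpn_base_scales: tuple = (32, 64, 128, 256, 512)

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2 (background + >=1 lesion class)")
        if not (0.0 < self.malignant_threshold < 1.0):
            raise ValueError("malignant_threshold must lie strictly in (0, 1)")
        if self.num_candidates < 1:
            raise ValueError("num_candidates must be >= 1")
        if self.backbone_preset not in ("vgg16", "tiny"):
            raise ValueError(f"unknown backbone preset: {self.backbone_preset!r}")


_CONFIG_KEYS = {f.name for f in fields(RunConfig)}


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional flat YAML file plus overrides.

    Overrides win over file values; unknown keys raise.  The effective
    configuration is echoed to the log as ``key=value`` lines.
    """
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a flat mapping")
        values.update(loaded)
    values.update(overrides)
    unknown = set(values) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}; "
                         f"allowed: {sorted(_CONFIG_KEYS)}")
    for key in ("anchor_scales", "fpn_base_scales"):
        if key in values:
            values[key] = tuple(values[key])
    cfg = RunConfig(**values)
    for f in fields(cfg):
        log.info("config %s=%s", f.name, getattr(cfg, f.name))
    return cfg


def config_overrides(cfg: RunConfig, **kw) -> RunConfig:
    return replace(cfg, **kw)


# ---------------------------------------------------------------------------
# VOC2007 annotation XML

_NAME_TO_LABEL = {"benign": BENIGN, "malignant": MALIGNANT}


def read_voc_annotation(path: str | Path) -> VOCRecord:
    """Parse one VOC2007 annotation file into a VOCRecord.

    Class names are matched case-insensitively against {benign, malignant};
    ``difficult``/``truncated`` flags are tolerated and ignored.  The
    1-based inclusive integer corners of ``bndbox`` are converted to the
    package's 0-based half-open convention (min corners minus one).
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed VOC XML in {path}: {exc}") from exc
    root = tree.getroot()
    size = root.find("size")
    width = int(size.findtext("width"))
    height = int(size.findtext("height"))
    folder = root.findtext("folder") or "JPEGImages"
    filename = root.findtext("filename") or (path.stem + ".png")
    image_path = path.parent.parent / folder / filename
    plane_text = root.findtext("plane") or Plane.AXIAL.value
    annotations: list[LesionAnnotation] = []
    for i, obj in enumerate(root.findall("object")):
        name = (obj.findtext("name") or "").strip().lower()
        if name not in _NAME_TO_LABEL:
            raise ValueError(
                f"unknown class {name!r} in {path}; allowed: {sorted(_NAME_TO_LABEL)}")
        bb = obj.find("bndbox")
        xmin = float(bb.findtext("xmin")) - 1.0
        ymin = float(bb.findtext("ymin")) - 1.0
        xmax = float(bb.findtext("xmax"))
        ymax = float(bb.findtext("ymax"))
        box = Box(xmin, ymin, xmax, ymax).clip(width, height)
        lesion_id = obj.findtext("lesion_id") or f"{path.stem}_obj{i}"
        obj_plane = obj.findtext("plane") or plane_text
        annotations.append(LesionAnnotation(box, _NAME_TO_LABEL[name],
                                            lesion_id, Plane(obj_plane)))
    return VOCRecord(image_path=image_path, image_size=(width, height),
                     annotations=annotations)


def write_voc_annotation(record: VOCRecord, path: str | Path) -> None:
    """Serialize a VOCRecord as deterministic VOC2007-dialect XML."""
    path = Path(path)
    root = etree.Element("annotation")
    etree.SubElement(root, "folder").text = "JPEGImages"
    etree.SubElement(root, "filename").text = Path(record.image_path).name
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(int(record.image_size[0]))
    etree.SubElement(size, "height").text = str(int(record.image_size[1]))
    etree.SubElement(size, "depth").text = "1"
    planes = {a.plane for a in record.annotations}
    if len(planes) == 1:
        etree.SubElement(root, "plane").text = next(iter(planes)).value
    for ann in record.annotations:
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = CLASS_NAMES[ann.label]
        etree.SubElement(obj, "lesion_id").text = ann.lesion_id
        etree.SubElement(obj, "plane").text = ann.plane.value
        etree.SubElement(obj, "difficult").text = "0"
        bb = etree.SubElement(obj, "bndbox")
        etree.SubElement(bb, "xmin").text = str(int(round(ann.box.x_min)) + 1)
        etree.SubElement(bb, "ymin").text = str(int(round(ann.box.y_min)) + 1)
        etree.SubElement(bb, "xmax").text = str(int(round(ann.box.x_max)))
        etree.SubElement(bb, "ymax").text = str(int(round(ann.box.y_max)))
    path.parent.mkdir(parents=True, exist_ok=True)
    etree.ElementTree(root).write(str(path), pretty_print=True,
                                  xml_declaration=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# image I/O and dataset layout


def read_image(path: str | Path) -> np.ndarray:
    """Load a grayscale PNG/TIFF raster as a float64 intensity array."""
    with Image.open(path) as img:
        arr = np.asarray(img)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr.astype(np.float64)


def write_image(pixels: np.ndarray, path: str | Path) -> None:
    """Write intensities as a 16-bit grayscale PNG (values clipped to range)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.clip(np.round(pixels), 0, 65535).astype(np.uint16)
    Image.fromarray(arr).save(str(path))


def load_split(data_dir: str | Path, split: str) -> list[VOCRecord]:
    """Load the VOCRecords of one ImageSets/Main split (train/val/test)."""
    data_dir = Path(data_dir)
    ids = [ln.strip() for ln in
           (data_dir / "ImageSets" / "Main" / f"{split}.txt").read_text().splitlines()
           if ln.strip()]
    return [read_voc_annotation(data_dir / "Annotations" / f"{i}.xml") for i in ids]
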