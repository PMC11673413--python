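"""Synthetic dual-plane breast-slice phantom with full ground truth.

Each case renders the same lesion in an axial view (two bright half-ellipse
breasts over a dark noisy background with a constant additive offset) and a
sagittal view (a single half-ellipse breast), sharing one lesion identity,
pathology label and 3D quadrant.  Benign lesions are smooth rotated
ellipses; malignant lesions are radially spiculated stars whose boundary
radius is modulated by amplitude*sin(lobes*theta).  Annotations are the
tight bounding boxes of the rendered lesion masks, and the per-case
geometry (breast midlines, chest-wall baseline, row orientation) is exact
by construction, so quadrant/laterality localization can be validated
end-to-end.

Generation is deterministic: each case draws from an RNG keyed on
(seed XOR case_index), so datasets are stable under any generation order.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .dataset_io import (BENIGN, CLASS_NAMES, MALIGNANT, Box, LesionAnnotation,
                         Plane, VOCRecord, write_image, write_voc_annotation)
from .eval3d import BreastGeometry, Laterality, QuadrantLabel, laterality
from .preprocess import RawImage


@dataclass
class PhantomSpec:
    """Generator conditions; defaults define the package's study setting."""

    seed: int = 0
    image_size: tuple[int, int] = (128, 128)   # (width, height)
    n_cases: int = 145
    lesions_per_case: tuple[int, int] = (1, 1)
    malignant_fraction: float = 0.5
    background_offset: float = 20.0
    noise_sd: float = 4.0
    benign_radius_range: tuple[float, float] = (5.0, 9.0)
    malignant_radius_range: tuple[float, float] = (6.0, 9.0)
    spiculation_amplitude: float = 0.5
    spiculation_lobes: int = 9
    breast_intensity: float = 90.0
    lesion_intensity: float = 200.0

    def __post_init__(self):
        if not 0.0 <= self.malignant_fraction <= 1.0:
            raise ValueError("malignant_fraction must lie in [0, 1]")
        if min(self.benign_radius_range + self.malignant_radius_range) <= 0:
            raise ValueError("lesion radii must be positive")
        if not 0.0 <= self.spiculation_amplitude < 1.0:
            raise ValueError("spiculation_amplitude must lie in [0, 1)")


@dataclass
class PhantomCase:
    case_id: str
    axial_image: RawImage
    sagittal_image: RawImage
    axial_annotations: list[LesionAnnotation]
    sagittal_annotations: list[LesionAnnotation]
    geometry: BreastGeometry
    true_quadrant: dict[str, QuadrantLabel]
    true_laterality: dict[str, Laterality]
    lesion_masks: dict[str, np.ndarray] = field(default_factory=dict)
    axial_breast_mask: np.ndarray | None = None
    sagittal_breast_mask: np.ndarray | None = None


class GenerationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# scene layout


def _axial_layout(w: int, h: int):
    baseline = 0.78 * h
    cxr, cxl = 0.27 * w, 0.73 * w
    ax, ay = 0.21 * w, 0.58 * h
    return baseline, cxr, cxl, ax, ay


def _sagittal_layout(w: int, h: int):
    chest_col = 0.72 * w
    cy = 0.5 * h
    sax, say = 0.55 * chest_col, 0.38 * h
    return chest_col, cy, sax, say


def case_geometry(spec: PhantomSpec) -> BreastGeometry:
    w, h = spec.image_size
    baseline, cxr, cxl, _, _ = _axial_layout(w, h)
    _, cy, _, _ = _sagittal_layout(w, h)
    # anatomical y = -row (superior at smaller row indices)
    return BreastGeometry(Y_mid=-cy, x_Rmid=cxr, x_Lmid=cxl, x_mid=w / 2.0,
                          axial_baseline=baseline, y_orientation=-1)


def _axial_breast_mask(w: int, h: int) -> np.ndarray:
    baseline, cxr, cxl, ax, ay = _axial_layout(w, h)
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), dtype=bool)
    for cx in (cxr, cxl):
        mask |= (((xx - cx) / ax) ** 2 + ((yy - baseline) / ay) ** 2 <= 1.0)
    return mask & (yy <= baseline)


def _sagittal_breast_mask(w: int, h: int) -> np.ndarray:
    chest_col, cy, sax, say = _sagittal_layout(w, h)
    yy, xx = np.mgrid[0:h, 0:w]
    return (((xx - chest_col) / sax) ** 2 + ((yy - cy) / say) ** 2 <= 1.0) \
        & (xx <= chest_col)


# ---------------------------------------------------------------------------
# lesion rendering


def _lesion_mask(shape: tuple[int, int], cx: float, cy: float, r: float,
                 label: int, spec: PhantomSpec, rng: np.random.Generator
                 ) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dx, dy = xx - cx, yy - cy
    if label == BENIGN:
        e1 = rng.uniform(0.85, 1.15)
        e2 = rng.uniform(0.85, 1.15)
        phi = rng.uniform(0, math.pi)
        u = dx * math.cos(phi) + dy * math.sin(phi)
        v = -dx * math.sin(phi) + dy * math.cos(phi)
        return (u / (r * e1)) ** 2 + (v / (r * e2)) ** 2 <= 1.0
    amp = spec.spiculation_amplitude
    lobes = spec.spiculation_lobes
    phase = rng.uniform(0, 2 * math.pi)
    theta = np.arctan2(dy, dx)
    boundary = r * (1.0 + amp * np.sin(lobes * theta + phase))
    return np.hypot(dx, dy) <= boundary


def boundary_roughness(mask: np.ndarray) -> float:
    """Isoperimetric roughness perimeter^2 / (4*pi*area); 1 for a disk.

    The perimeter is measured on the marching-squares contour of the mask
    after a 5-point circular moving average, which suppresses the
    pixelation staircase (a raw digital contour overstates smooth
    boundaries by ~15%) while leaving genuine spiculation intact.
    """
    mask = np.asarray(mask).astype(bool)
    area = float(mask.sum())
    if area == 0:
        raise ValueError("boundary_roughness requires a non-empty mask")
    padded = np.pad(mask.astype(np.float64), 1)
    win = 5
    kernel = np.ones(win) / win
    perim = 0.0
    for contour in measure.find_contours(padded, 0.5):
        if len(contour) > win:
            half = win // 2
            sm = np.stack([np.convolve(np.r_[contour[-half:, i], contour[:, i],
                                             contour[:half, i]], kernel, "valid")
                           for i in (0, 1)], axis=1)
        else:
            sm = contour
        perim += float(np.hypot(*np.diff(sm, axis=0).T).sum())
    return perim ** 2 / (4.0 * math.pi * area)


def _tight_box(mask: np.ndarray) -> Box:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return Box(float(cols[0]), float(rows[0]), float(cols[-1] + 1), float(rows[-1] + 1))


# ---------------------------------------------------------------------------
# placement


_MIDLINE_MARGIN = 4.0  # keeps box centers robustly on the intended side


def _lesion_extent(r: float, label: int, spec: PhantomSpec) -> float:
    """Worst-case boundary radius of a rendered lesion."""
    return r * (1.0 + spec.spiculation_amplitude) if label == MALIGNANT else r * 1.15


def _sample_axial_center(rng, spec: PhantomSpec, side: str, inside: bool,
                         ext: float, tries: int = 40
                         ) -> tuple[float, float] | None:
    w, h = spec.image_size
    baseline, cxr, cxl, ax, ay = _axial_layout(w, h)
    mb = ext + 4.0  # containment margin: lesion stays inside the breast
    cx_breast = cxr if side == "R" else cxl
    if side == "R":
        lo, hi = ((cxr + _MIDLINE_MARGIN, w / 2 - _MIDLINE_MARGIN) if inside
                  else (cxr - ax + mb, cxr - _MIDLINE_MARGIN))
    else:
        lo, hi = ((w / 2 + _MIDLINE_MARGIN, cxl - _MIDLINE_MARGIN) if inside
                  else (cxl + _MIDLINE_MARGIN, cxl + ax - mb))
    if hi <= lo:
        return None
    for _ in range(tries):
        x = rng.uniform(lo, hi)
        y = rng.uniform(baseline - ay + mb, baseline - mb)
        if (((x - cx_breast) / (ax - mb)) ** 2
                + ((y - baseline) / (ay - mb)) ** 2) <= 1.0:
            return x, y
    return None


def _sample_sagittal_center(rng, spec: PhantomSpec, up: bool, ext: float,
                            tries: int = 40) -> tuple[float, float] | None:
    w, h = spec.image_size
    chest_col, cy, sax, say = _sagittal_layout(w, h)
    mb = ext + 4.0
    for _ in range(tries):
        # superior (up) lies at smaller row indices
        row = (rng.uniform(cy - say + mb, cy - _MIDLINE_MARGIN) if up
               else rng.uniform(cy + _MIDLINE_MARGIN, cy + say - mb))
        col = rng.uniform(chest_col - sax + mb, chest_col - mb)
        if (((col - chest_col) / (sax - mb)) ** 2
                + ((row - cy) / (say - mb)) ** 2) <= 1.0:
            return col, row
    return None


# ---------------------------------------------------------------------------
# case generation


def generate_case(spec: PhantomSpec, case_index: int) -> PhantomCase:
    """Render one deterministic dual-plane case with ground truth."""
    rng = np.random.default_rng(int(spec.seed) ^ int(case_index))
    w, h = spec.image_size
    case_id = f"case{case_index:04d}"
    geometry = case_geometry(spec)
    ax_mask = _axial_breast_mask(w, h)
    sag_mask = _sagittal_breast_mask(w, h)
    ax_img = np.where(ax_mask, spec.breast_intensity, 0.0)
    sag_img = np.where(sag_mask, spec.breast_intensity, 0.0)

    n_lesions = int(rng.integers(spec.lesions_per_case[0],
                                 spec.lesions_per_case[1] + 1))
    side = "R" if rng.random() < 0.5 else "L"
    ax_annotations: list[LesionAnnotation] = []
    sag_annotations: list[LesionAnnotation] = []
    true_quadrant: dict[str, QuadrantLabel] = {}
    true_laterality: dict[str, Laterality] = {}
    lesion_masks: dict[str, np.ndarray] = {}
    placed_ax: list[tuple[float, float, float]] = []
    placed_sag: list[tuple[float, float, float]] = []
    for li in range(n_lesions):
        lesion_id = f"{case_id}_L{li}"
        label = MALIGNANT if rng.random() < spec.malignant_fraction else BENIGN
        lo, hi = (spec.malignant_radius_range if label == MALIGNANT
                  else spec.benign_radius_range)
        r_ax = rng.uniform(lo, hi)
        r_sag = r_ax * rng.uniform(0.8, 1.2)
        ext_ax = _lesion_extent(r_ax, label, spec)
        ext_sag = _lesion_extent(r_sag, label, spec)

        def clear_of(placed, x, y, ext):
            return all(math.hypot(x - px, y - py) >= ext + pe + 2.0
                       for px, py, pe in placed)

        for attempt in range(100):
            # quadrant is resampled per attempt so crowded cases can still
            # place later lesions somewhere
            inside = rng.random() < 0.5
            up = rng.random() < 0.5
            ax_c = _sample_axial_center(rng, spec, side, inside, ext_ax)
            sag_c = _sample_sagittal_center(rng, spec, up, ext_sag)
            if ax_c is None or sag_c is None:
                continue
            if clear_of(placed_ax, *ax_c, ext_ax) and clear_of(placed_sag, *sag_c, ext_sag):
                break
        else:
            raise GenerationError(f"lesion collision unresolved in {case_id}")
        placed_ax.append((*ax_c, ext_ax))
        placed_sag.append((*sag_c, ext_sag))

        m_ax = _lesion_mask((h, w), ax_c[0], ax_c[1], r_ax, label, spec, rng)
        m_sag = _lesion_mask((h, w), sag_c[0], sag_c[1], r_sag, label, spec, rng)
        contrast = spec.lesion_intensity - spec.breast_intensity
        for img, m in ((ax_img, m_ax), (sag_img, m_sag)):
            img += ndimage.gaussian_filter(m.astype(np.float64), 0.6) * contrast
        ax_annotations.append(LesionAnnotation(_tight_box(m_ax), label,
                                               lesion_id, Plane.AXIAL))
        sag_annotations.append(LesionAnnotation(_tight_box(m_sag), label,
                                                lesion_id, Plane.SAGITTAL))
        lesion_masks[lesion_id] = m_ax
        up_true = geometry.anatomical_y(sag_c[1]) > geometry.Y_mid
        out_true = ax_c[0] < geometry.x_Rmid or ax_c[0] > geometry.x_Lmid
        true_quadrant[lesion_id] = (
            (QuadrantLabel.OUTSIDE_UP if up_true else QuadrantLabel.OUTSIDE_DOWN)
            if out_true else
            (QuadrantLabel.INSIDE_UP if up_true else QuadrantLabel.INSIDE_DOWN))
        true_laterality[lesion_id] = laterality(ax_c[0], geometry)

    for img in (ax_img, sag_img):
        img += spec.background_offset
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
        np.maximum(img, 0.0, out=img)

    return PhantomCase(
        case_id=case_id,
        axial_image=RawImage(ax_img, Plane.AXIAL),
        sagittal_image=RawImage(sag_img, Plane.SAGITTAL),
        axial_annotations=ax_annotations,
        sagittal_annotations=sag_annotations,
        geometry=geometry,
        true_quadrant=true_quadrant,
        true_laterality=true_laterality,
        lesion_masks=lesion_masks,
        axial_breast_mask=ax_mask,
        sagittal_breast_mask=sag_mask,
    )


# ---------------------------------------------------------------------------
# dataset export


def _split_counts(n_cases: int, fractions=(0.65, 0.10, 0.25)) -> tuple[int, int, int]:
    n_train = int(round(n_cases * fractions[0]))
    n_val = int(round(n_cases * fractions[1]))
    return n_train, n_val, n_cases - n_train - n_val


def generate_dataset(spec: PhantomSpec, out_dir: str | Path,
                     split_counts: tuple[int, int, int] | None = None
                     ) -> pd.DataFrame:
    """Write a VOC2007-layout dataset plus manifest and geometry tables.

    Cases [0, train) go to train, [train, train+val) to val, the rest to
    test; both planes of a case share its split.  Returns the manifest.
    """
    out_dir = Path(out_dir)
    counts = split_counts if split_counts is not None else _split_counts(spec.n_cases)
    if sum(counts) != spec.n_cases:
        raise ValueError("split counts must sum to n_cases")
    splits = (["train"] * counts[0] + ["val"] * counts[1] + ["test"] * counts[2])
    ids_by_split: dict[str, list[str]] = {"train": [], "val": [], "test": []}
    manifest_rows = []
    geometry_rows = []
    for case_index in range(spec.n_cases):
        case = generate_case(spec, case_index)
        split = splits[case_index]
        for plane, image, annotations in (
                (Plane.AXIAL, case.axial_image, case.axial_annotations),
                (Plane.SAGITTAL, case.sagittal_image, case.sagittal_annotations)):
            image_id = f"{case.case_id}_{plane.value}"
            write_image(image.pixels, out_dir / "JPEGImages" / f"{image_id}.png")
            record = VOCRecord(
                image_path=out_dir / "JPEGImages" / f"{image_id}.png",
                image_size=(image.shape[1], image.shape[0]),
                annotations=annotations)
            write_voc_annotation(record, out_dir / "Annotations" / f"{image_id}.xml")
            ids_by_split[split].append(image_id)
            for ann in annotations:
                manifest_rows.append({
                    "case": case.case_id, "split": split, "plane": plane.value,
                    "image_id": image_id, "lesion_id": ann.lesion_id,
                    "label": CLASS_NAMES[ann.label],
                    "quadrant": case.true_quadrant[ann.lesion_id].value,
                    "laterality": case.true_laterality[ann.lesion_id].value,
                })
        g = case.geometry
        geometry_rows.append({
            "case": case.case_id, "Y_mid": g.Y_mid, "x_Rmid": g.x_Rmid,
            "x_Lmid": g.x_Lmid, "x_mid": g.x_mid,
            "axial_baseline": g.axial_baseline, "y_orientation": g.y_orientation,
        })
    sets_dir = out_dir / "ImageSets" / "Main"
    sets_dir.mkdir(parents=True, exist_ok=True)
    for split, ids in ids_by_split.items():
        (sets_dir / f"{split}.txt").write_text("\n".join(ids) + "\n")
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    pd.DataFrame(geometry_rows).to_csv(out_dir / "geometry.csv", index=False)
    return manifest


def load_geometry_table(data_dir: str | Path) -> dict[str, BreastGeometry]:
    df = pd.read_csv(Path(data_dir) / "geometry.csv")
    return {row["case"]: BreastGeometry(
        Y_mid=row["Y_mid"], x_Rmid=row["x_Rmid"], x_Lmid=row["x_Lmid"],
        x_mid=row["x_mid"], axial_baseline=row["axial_baseline"],
        y_orientation=int(row["y_orientation"])) for _, row in df.iterrows()}
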