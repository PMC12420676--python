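"""Deterministic rule-based per-cell grading by nucleolar prominence.

Visibility-at-magnification criteria are encoded as physical size/contrast
thresholds: a cell is G3 when its dominant nucleolus is at least D100 in
diameter with high contrast, G2 when at least D400 with moderate contrast,
G1 when no visible nucleolus and the nucleus is small, and Other otherwise.
The primary downstream task is the binary split G3 vs Other.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

GRADES = ("G1", "G2", "G3", "Other")


@dataclass(frozen=True)
class ClassifierRules:
    """Physical thresholds encoding nucleolar visibility at x100 / x400."""

    d100_um: float = 1.5  # min nucleolus diameter visible at x100 (G3)
    d400_um: float = 0.7  # min nucleolus diameter visible at x400 (G2)
    c_hi: float = 0.25  # min contrast for G3
    c_lo: float = 0.10  # min contrast for G2
    small_nucleus_um: float = 7.5  # max equivalent diameter for G1
    detect_min_contrast: float = 0.05  # blob-detection floor

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "ClassifierRules":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass(frozen=True)
class CellFeatures:
    nucleus_area: float  # um^2
    nucleus_equiv_diam: float  # um
    nucleus_mean_darkness: float  # [0, 1]
    nucleolus_diam: float  # um, 0 if none
    nucleolus_contrast: float  # [0, 1], 0 if none
    n_nucleoli: int

    def __post_init__(self):
        if self.nucleus_area <= 0:
            raise ValueError("nucleus_area must be > 0")
        if self.n_nucleoli == 0 and self.nucleolus_contrast != 0:
            raise ValueError("contrast must be 0 when no nucleolus detected")


def _darkness(image: np.ndarray) -> np.ndarray:
    return 1.0 - np.asarray(image, dtype=np.float64).mean(axis=2) / 255.0


def detect_nucleoli(
    image: np.ndarray,
    nucleus_mask: np.ndarray,
    pixel_size: float,
    min_contrast: float = 0.05,
    min_blob_px: int = 2,
) -> list[tuple[float, float]]:
    """Intra-nuclear dark blobs as (diameter um, contrast), diameter-sorted.

    A blob is a connected set of pixels darker than the nucleoplasm median
    by at least ``min_contrast``; contrast is the blob's mean darkness minus
    the median darkness of the remaining nucleoplasm.
    """
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    n_px = int(nucleus_mask.sum())
    if n_px < 4:
        raise ValueError("nucleus mask must cover at least 4 pixels")
    dark = _darkness(image)
    ref = float(np.median(dark[nucleus_mask]))
    blob_mask = nucleus_mask & (dark >= ref + min_contrast)
    labeled, n_blobs = ndimage.label(blob_mask, structure=np.ones((3, 3)))
    if n_blobs == 0:
        return []
    plasma = nucleus_mask & ~blob_mask
    plasma_ref = float(np.median(dark[plasma])) if plasma.any() else ref
    out = []
    for b in range(1, n_blobs + 1):
        sel = labeled == b
        area_px = int(sel.sum())
        if area_px < min_blob_px:
            continue
        area_um2 = area_px * pixel_size**2
        diam = 2.0 * np.sqrt(area_um2 / np.pi)
        contrast = float(dark[sel].mean() - plasma_ref)
        out.append((float(diam), contrast))
    out.sort(key=lambda t: -t[0])
    return out


def extract_features(
    image: np.ndarray,
    nucleus_mask: np.ndarray,
    pixel_size: float,
    rules: ClassifierRules | None = None,
) -> CellFeatures:
    """Morphometric features of one nucleus from its boolean mask."""
    rules = rules or ClassifierRules()
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    area_px = int(nucleus_mask.sum())
    if area_px == 0:
        raise ValueError("zero-area instance")
    area = area_px * pixel_size**2
    equiv_diam = 2.0 * np.sqrt(area / np.pi)
    dark = _darkness(image)
    mean_dark = float(dark[nucleus_mask].mean())
    blobs = (
        detect_nucleoli(image, nucleus_mask, pixel_size, rules.detect_min_contrast)
        if area_px >= 4
        else []
    )
    if blobs:
        diam, contrast = blobs[0]  # largest nucleolus governs grading
        # cap at nucleus equivalent diameter (rasterization can overshoot)
        diam = min(diam, equiv_diam)
    else:
        diam, contrast = 0.0, 0.0
    return CellFeatures(
        nucleus_area=area,
        nucleus_equiv_diam=float(equiv_diam),
        nucleus_mean_darkness=mean_dark,
        nucleolus_diam=diam,
        nucleolus_contrast=contrast if blobs else 0.0,
        n_nucleoli=len(blobs),
    )


def assign_grade(f: CellFeatures, rules: ClassifierRules | None = None) -> str:
    """Total deterministic grading rule (boundary-inclusive thresholds)."""
    r = rules or ClassifierRules()
    if f.nucleolus_diam >= r.d100_um and f.nucleolus_contrast >= r.c_hi:
        return "G3"
    if f.nucleolus_diam >= r.d400_um and f.nucleolus_contrast >= r.c_lo:
        return "G2"
    if f.nucleus_equiv_diam <= r.small_nucleus_um:
        return "G1"
    return "Other"


def binarize(label: str) -> str:
    """Collapse to the evaluated binary task: G3 vs everything else."""
    if label == "G3":
        return "G3"
    if label in ("G1", "G2", "Other"):
        return "Other"
    raise ValueError(f"unknown label {label!r}")


def classify_cells(
    image: np.ndarray,
    label_mask: np.ndarray,
    pixel_size: float,
    rules: ClassifierRules | None = None,
) -> pd.DataFrame:
    """Grade every instance of a label mask.

    Returns the cell table with columns cell_id, x_um, y_um, area_um2,
    nucleolus_diam_um, nucleolus_contrast, label, binary_label.
    """
    rules = rules or ClassifierRules()
    label_mask = np.asarray(label_mask)
    n = int(label_mask.max())
    slices = ndimage.find_objects(label_mask)
    rows = []
    for cid in range(1, n + 1):
        sl = slices[cid - 1]
        if sl is None:
            continue
        sub_mask = label_mask[sl] == cid
        sub_img = image[sl]
        try:
            f = extract_features(sub_img, sub_mask, pixel_size, rules)
        except ValueError:
            continue
        ii, jj = np.nonzero(sub_mask)
        cy = (ii.mean() + sl[0].start) * pixel_size
        cx = (jj.mean() + sl[1].start) * pixel_size
        lab = assign_grade(f, rules)
        rows.append(
            (cid, cx, cy, f.nucleus_area, f.nucleolus_diam, f.nucleolus_contrast,
             lab, binarize(lab))
        )
    return pd.DataFrame(
        rows,
        columns=["cell_id", "x_um", "y_um", "area_um2", "nucleolus_diam_um",
                 "nucleolus_contrast", "label", "binary_label"],
    )


def _round2_half_up(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def class_percentages(counts, total: int | None = None) -> list[float]:
    """Percentages 100*count/total, half-up rounded to two decimals.

    ``total`` defaults to the sum of counts; pass it explicitly when the
    published denominator differs from the tabulated counts.
    """
    counts = [int(c) for c in counts]
    if any(c < 0 for c in counts):
        raise ValueError("counts must be >= 0")
    denom = int(total) if total is not None else sum(counts)
    if denom <= 0:
        raise ValueError("total must be > 0")
    return [_round2_half_up(100.0 * c / denom) for c in counts]


def summarize_class_distribution(cells_or_counts, total: int | None = None) -> pd.DataFrame:
    """Count/percentage table per class.

    Accepts a cell table (with a ``label`` column), a mapping class->count,
    or a sequence of counts ordered G1, G2, G3, Other.
    """
    if isinstance(cells_or_counts, pd.DataFrame):
        vc = cells_or_counts["label"].value_counts()
        counts = [int(vc.get(c, 0)) for c in GRADES]
        names = list(GRADES)
    elif isinstance(cells_or_counts, dict):
        names = list(cells_or_counts)
        counts = [int(cells_or_counts[k]) for k in names]
    else:
        counts = [int(c) for c in cells_or_counts]
        names = list(GRADES[: len(counts)]) if len(counts) <= 4 else [
            f"class{i}" for i in range(len(counts))
        ]
    pct = class_percentages(counts, total)
    return pd.DataFrame({"class": names, "count": counts, "percent": pct})
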