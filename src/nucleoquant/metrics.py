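"""ROI handling and tissue-profile statistics.

Profiles count G3 and Other cells inside a square region of interest and
express them as densities per mm^2 and as the percentage of G3 cells.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: cell-count range a verification ROI is expected to contain
ROI_CELL_RANGE = (400, 1200)


@dataclass(frozen=True)
class ROI:
    """Axis-aligned square ROI in um; half-open on its max-x/max-y edges."""

    x0: float
    y0: float
    side: float
    id: int = 0

    def __post_init__(self):
        if self.side <= 0:
            raise ValueError("ROI side must be > 0")

    @property
    def area_mm2(self) -> float:
        return self.side**2 / 1e6

    @property
    def boundary(self) -> np.ndarray:
        x0, y0, s = self.x0, self.y0, self.side
        return np.array([(x0, y0), (x0 + s, y0), (x0 + s, y0 + s), (x0, y0 + s)])

    def contains(self, x, y) -> np.ndarray:
        """Vectorized membership, inclusive on min-x/min-y edges only."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            (x >= self.x0)
            & (x < self.x0 + self.side)
            & (y >= self.y0)
            & (y < self.y0 + self.side)
        )


@dataclass(frozen=True)
class ROIProfile:
    roi_id: int
    area_mm2: float
    n_total: int
    n_g3: int
    n_other: int
    dens_g3: float  # cells / mm^2
    dens_other: float  # cells / mm^2
    pct_g3: float  # percent; nan when the ROI is empty
    empty: bool = False

    def as_dict(self) -> dict:
        return {
            "roi_id": self.roi_id,
            "area_mm2": self.area_mm2,
            "n_total": self.n_total,
            "n_g3": self.n_g3,
            "n_other": self.n_other,
            "dens_g3": self.dens_g3,
            "dens_other": self.dens_other,
            "pct_g3": self.pct_g3,
        }


def roi_from_perimeter(perimeter_um: float, center=(0.0, 0.0), roi_id: int = 0) -> ROI:
    """Square ROI of the given perimeter centered on ``center``."""
    if perimeter_um <= 0:
        raise ValueError("perimeter must be > 0")
    side = perimeter_um / 4.0
    cx, cy = center
    return ROI(x0=cx - side / 2.0, y0=cy - side / 2.0, side=side, id=roi_id)


def profile_roi(cells: pd.DataFrame, roi: ROI) -> ROIProfile:
    """Count classified cells inside the ROI by centroid membership.

    ``cells`` needs columns x_um, y_um and binary_label (or label, which is
    binarized on the fly).  An empty ROI yields a flagged profile with
    pct_g3 = nan rather than an error.
    """
    if "binary_label" in cells.columns:
        binary = cells["binary_label"].astype(str)
    elif "label" in cells.columns:
        binary = cells["label"].map(lambda s: "G3" if s == "G3" else "Other")
    else:
        raise ValueError("cell table needs a binary_label or label column")
    inside = roi.contains(cells["x_um"].to_numpy(), cells["y_um"].to_numpy())
    n_total = int(inside.sum())
    n_g3 = int((binary.to_numpy()[inside] == "G3").sum())
    n_other = n_total - n_g3
    area = roi.area_mm2
    if n_total == 0:
        return ROIProfile(roi.id, area, 0, 0, 0, 0.0, 0.0, math.nan, empty=True)
    if not (ROI_CELL_RANGE[0] <= n_total <= ROI_CELL_RANGE[1]):
        log.warning(
            "ROI %s contains %d cells, outside the verification range %s",
            roi.id, n_total, ROI_CELL_RANGE,
        )
    return ROIProfile(
        roi_id=roi.id,
        area_mm2=area,
        n_total=n_total,
        n_g3=n_g3,
        n_other=n_other,
        dens_g3=n_g3 / area,
        dens_other=n_other / area,
        pct_g3=100.0 * n_g3 / n_total,
    )


def profile_range(profiles) -> tuple[float, float]:
    """(min, max) of pct_g3 over profiles with at least one cell."""
    vals = [p.pct_g3 for p in profiles if not p.empty]
    if not vals:
        raise ValueError("all profiles are empty")
    return (min(vals), max(vals))


def profiles_to_frame(profiles) -> pd.DataFrame:
    return pd.DataFrame([p.as_dict() for p in profiles])
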