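"""Seeded generators for synthetic H&E-like tiles and survival cohorts.

Tiles contain non-overlapping, star-convex nuclei rendered dark on a pale
background, with intra-nuclear nucleolus discs planted so that each cell
class sits strictly inside the grading rule boundaries of
:mod:`nucleoquant.classify` by a stated margin.  Every generator is a pure
function of its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CLASSES = ("G1", "G2", "G3", "Other")

#: Quadrant labels: positivity for G3-cell density / Other-cell density.
QUADRANTS = ("G3+/O-", "G3+/O+", "G3-/O-", "G3-/O+")

# Rendering constants (darkness = 1 - mean(RGB)/255).
BG_RGB = (242, 231, 238)
_BG_DARKNESS = 1.0 - (sum(BG_RGB) / 3.0) / 255.0

# Planted feature ranges, chosen to clear the default classifier rule
# boundaries (D100=1.5 um, D400=0.7 um, C_hi=0.25, C_lo=0.10, small
# nucleus bound 7.5 um) by a comfortable margin.
_NUCLEUS_DARKNESS = (0.55, 0.65)
_NUCLEOLUS_SPECS = {
    # class -> (diam_lo_um, diam_hi_um, contrast_lo, contrast_hi)
    "G2": (1.1, 1.4, 0.14, 0.20),
    "G3": (1.9, 2.6, 0.32, 0.42),
}
_DIAM_SPECS = {
    # class -> (mean_um, sd_um, clip_lo, clip_hi)
    "G1": (6.0, 0.4, 4.8, 6.8),
    "G2": (7.5, 0.5, 6.4, 8.6),
    "G3": (9.0, 0.5, 7.8, 10.4),
    "Other": (9.0, 0.6, 8.3, 10.8),
}
_SHAPE_AMP_MAX = 0.07  # Fourier perturbation amplitude (star-convex by construction)
_RADIUS_SAFETY = 1.0 + 2.0 * _SHAPE_AMP_MAX  # max boundary excursion of the Fourier shape


class PackingError(RuntimeError):
    """Raised when dart-throwing cannot place the requested cell count."""

    def __init__(self, placed: int, requested: int):
        self.achievable_max = placed
        super().__init__(
            f"could only place {placed} of {requested} non-overlapping nuclei; "
            f"achievable maximum for this tile is ~{placed}"
        )


@dataclass(frozen=True)
class TileSpec:
    """Parameters of one synthetic tile."""

    width_px: int = 2000
    height_px: int = 2000
    pixel_size: float = 0.5  # um / px
    n_cells: int = 800
    class_mix: dict = field(
        default_factory=lambda: {"G1": 0.30, "G2": 0.25, "G3": 0.10, "Other": 0.35}
    )
    nucleus_diam_mean_low: float = 6.0  # um, low-grade nuclei
    nucleus_diam_mean_high: float = 9.0  # um, high-grade nuclei
    nucleolus_diam_range: dict = field(
        default_factory=lambda: {k: v[:2] for k, v in _NUCLEOLUS_SPECS.items()}
    )
    stain_noise: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if not (1 <= self.n_cells <= 10000):
            raise ValueError("n_cells must be in [1, 10000]")
        if self.width_px < 8 or self.height_px < 8:
            raise ValueError("tile must be at least 8x8 px")
        mix = [self.class_mix.get(c, 0.0) for c in CLASSES]
        if any(p < 0 for p in mix):
            raise ValueError("class_mix proportions must be >= 0")
        if abs(sum(mix) - 1.0) > 1e-9:
            raise ValueError("class_mix proportions must sum to 1")
        if self.stain_noise < 0:
            raise ValueError("stain_noise must be >= 0")


@dataclass
class GroundTruth:
    """Planted truth for one tile: label image plus per-instance metadata."""

    instance_mask: np.ndarray  # (H, W) uint16, 0 = background, ids 1..K
    labels: list  # per-instance class, index i -> instance id i+1
    centers: np.ndarray  # (K, 2) um, columns (x, y)

    @property
    def n_instances(self) -> int:
        return len(self.labels)

    def planted_pct_g3(self) -> float:
        labs = np.asarray(self.labels)
        return 100.0 * float(np.sum(labs == "G3")) / len(labs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": np.arange(1, self.n_instances + 1),
                "x_um": self.centers[:, 0],
                "y_um": self.centers[:, 1],
                "label": self.labels,
            }
        )


def apportion_counts(class_mix: dict, n: int) -> dict:
    """Largest-remainder apportionment of ``n`` over CLASSES.

    Ties in the fractional remainders are broken by class order
    G1 < G2 < G3 < Other, so the allocation is deterministic.
    """
    props = np.array([float(class_mix.get(c, 0.0)) for c in CLASSES])
    if np.any(props < 0) or abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("class_mix must be non-negative and sum to 1")
    exact = props * n
    base = np.floor(exact).astype(int)
    remainder = exact - base
    short = n - int(base.sum())
    # argsort is stable: equal remainders keep class order.
    order = np.argsort(-remainder, kind="stable")
    for i in order[:short]:
        base[i] += 1
    return {c: int(k) for c, k in zip(CLASSES, base)}


def _sample_positions(rng, n, width_um, height_um, radii_um, max_attempts):
    """Dart-throwing with per-pair minimum center distance; grid-hashed."""
    rmax = float(np.max(radii_um)) * _RADIUS_SAFETY
    lo_x, hi_x = rmax + 0.5, width_um - rmax - 0.5
    lo_y, hi_y = rmax + 0.5, height_um - rmax - 0.5
    if hi_x <= lo_x or hi_y <= lo_y:
        raise PackingError(0, n)
    cell = 2.0 * rmax + 1.0
    grid: dict = {}
    xs = np.empty(n)
    ys = np.empty(n)
    placed = 0
    attempts = 0
    while placed < n and attempts < max_attempts:
        attempts += 1
        x = rng.uniform(lo_x, hi_x)
        y = rng.uniform(lo_y, hi_y)
        gx, gy = int(x // cell), int(y // cell)
        ok = True
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for j in grid.get((gx + dx, gy + dy), ()):
                    dmin = _RADIUS_SAFETY * (radii_um[placed] + radii_um[j]) + 0.25
                    if (x - xs[j]) ** 2 + (y - ys[j]) ** 2 < dmin * dmin:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            xs[placed] = x
            ys[placed] = y
            grid.setdefault((gx, gy), []).append(placed)
            placed += 1
    if placed < n:
        raise PackingError(placed, n)
    return xs, ys


def make_tile(spec: TileSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a tile and its ground truth.

    Returns an (H, W, 3) uint8 RGB image and a :class:`GroundTruth` whose
    instance ids are 1..n_cells.  Bit-identical for identical specs.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    counts = apportion_counts(spec.class_mix, spec.n_cells)
    labels = np.array(
        [c for c in CLASSES for _ in range(counts[c])], dtype=object
    )
    rng.shuffle(labels)
    n = spec.n_cells

    # Per-cell geometry in um.
    diam_shift = {
        "G1": spec.nucleus_diam_mean_low - 6.0,
        "G2": 0.5 * (spec.nucleus_diam_mean_low + spec.nucleus_diam_mean_high) - 7.5,
        "G3": spec.nucleus_diam_mean_high - 9.0,
        "Other": spec.nucleus_diam_mean_high - 9.0,
    }
    r0 = np.empty(n)
    for i, lab in enumerate(labels):
        mean, sd, lo, hi = _DIAM_SPECS[lab]
        d = float(np.clip(rng.normal(mean + diam_shift[lab], sd), lo, hi))
        r0[i] = 0.5 * d
    amp2 = rng.uniform(0.0, _SHAPE_AMP_MAX, n)
    amp3 = rng.uniform(0.0, _SHAPE_AMP_MAX, n)
    ph2 = rng.uniform(0.0, 2 * np.pi, n)
    ph3 = rng.uniform(0.0, 2 * np.pi, n)
    darkness = rng.uniform(*_NUCLEUS_DARKNESS, n)

    # Nucleolus parameters per cell (0 diameter where absent).
    nucl_d = np.zeros(n)
    nucl_c = np.zeros(n)
    nucl_off = rng.uniform(-0.25, 0.25, (n, 2))  # fraction of r0
    for i, lab in enumerate(labels):
        if lab in _NUCLEOLUS_SPECS:
            d_lo, d_hi = spec.nucleolus_diam_range.get(lab, _NUCLEOLUS_SPECS[lab][:2])
            c_lo, c_hi = _NUCLEOLUS_SPECS[lab][2:]
            nucl_d[i] = rng.uniform(d_lo, d_hi)
            nucl_c[i] = rng.uniform(c_lo, c_hi)

    width_um = spec.width_px * spec.pixel_size
    height_um = spec.height_px * spec.pixel_size
    xs, ys = _sample_positions(rng, n, width_um, height_um, r0, 10 * n)

    gray = np.empty((spec.height_px, spec.width_px), dtype=np.float32)
    gray[:] = 255.0 * (1.0 - _BG_DARKNESS)
    mask = np.zeros((spec.height_px, spec.width_px), dtype=np.uint16)
    p = spec.pixel_size
    for i in range(n):
        rmax = r0[i] * _RADIUS_SAFETY
        j0 = max(0, int((xs[i] - rmax) / p) - 1)
        j1 = min(spec.width_px, int((xs[i] + rmax) / p) + 2)
        i0 = max(0, int((ys[i] - rmax) / p) - 1)
        i1 = min(spec.height_px, int((ys[i] + rmax) / p) + 2)
        jj, ii = np.meshgrid(np.arange(j0, j1), np.arange(i0, i1))
        dx = jj * p - xs[i]
        dy = ii * p - ys[i]
        rr = np.hypot(dx, dy)
        th = np.arctan2(dy, dx)
        bound = r0[i] * (
            1.0 + amp2[i] * np.cos(2 * th + ph2[i]) + amp3[i] * np.cos(3 * th + ph3[i])
        )
        inside = rr <= bound
        g_nuc = 255.0 * (1.0 - darkness[i])
        sub_g = gray[i0:i1, j0:j1]
        sub_m = mask[i0:i1, j0:j1]
        sub_g[inside] = g_nuc
        sub_m[inside] = i + 1
        if nucl_d[i] > 0:
            cx = xs[i] + nucl_off[i, 0] * r0[i]
            cy = ys[i] + nucl_off[i, 1] * r0[i]
            disc = inside & (np.hypot(jj * p - cx, ii * p - cy) <= 0.5 * nucl_d[i])
            sub_g[disc] = 255.0 * (1.0 - darkness[i] - nucl_c[i])

    rgb = np.empty((spec.height_px, spec.width_px, 3), dtype=np.float32)
    for ch, bg in enumerate(BG_RGB):
        chan = gray.copy()
        chan[mask == 0] = bg
        rgb[:, :, ch] = chan
    if spec.stain_noise > 0:
        rgb += rng.normal(0.0, spec.stain_noise * 255.0, rgb.shape).astype(np.float32)
    rgb = np.clip(rgb, 0, 255).astype(np.uint8)

    truth = GroundTruth(
        instance_mask=mask,
        labels=list(labels),
        centers=np.column_stack([xs, ys]),
    )
    return rgb, truth


# ---------------------------------------------------------------------------
# Tissue-pattern presets
# ---------------------------------------------------------------------------

#: pattern -> (pct_g3_mean, pct_g3_sd, total_density_mean, total_density_sd,
#:             total_density_clip_lo, total_density_clip_hi) with densities
#: in cells per mm^2.
PATTERN_PRESETS = {
    "monomorphic": (5.24, 3.55, 4800.0, 250.0, 4300.0, 5300.0),
    "pluralistic": (18.45, 5.57, 4900.0, 250.0, 4400.0, 5400.0),
    "nucleolar": (28.29, 10.04, 4500.0, 250.0, 4000.0, 5000.0),
    "dystrophic": (8.56, 7.06, 2800.0, 700.0, 900.0, 4500.0),
}


def draw_pattern_params(pattern: str, rng, *, sd_scale: float = 1.0):
    """Draw (pct_g3, total cells/mm^2) for a named tissue pattern.

    pct_g3 is normal, truncated to [0, 100] by redrawing; total density is
    normal clipped to the preset range (dystrophic stays below 5000/mm^2).
    """
    if pattern not in PATTERN_PRESETS:
        raise ValueError(f"unknown pattern {pattern!r}; known: {sorted(PATTERN_PRESETS)}")
    mu, sd, dmu, dsd, dlo, dhi = PATTERN_PRESETS[pattern]
    sd = sd * sd_scale
    pct = mu if sd == 0 else float(rng.normal(mu, sd))
    for _ in range(100):
        if 0.0 <= pct <= 100.0:
            break
        pct = float(rng.normal(mu, sd))
    pct = float(np.clip(pct, 0.0, 100.0))
    total = float(np.clip(rng.normal(dmu, dsd * sd_scale if sd_scale else dsd), dlo, dhi))
    return pct, total


def make_pattern_tile(
    pattern: str,
    seed: int,
    *,
    width_px: int = 2000,
    height_px: int = 2000,
    pixel_size: float = 0.5,
    sd_scale: float = 1.0,
) -> tuple[np.ndarray, GroundTruth]:
    """Tile whose planted %G3 and total density follow a pattern preset."""
    rng = np.random.default_rng(seed)
    pct, total = draw_pattern_params(pattern, rng, sd_scale=sd_scale)
    area_mm2 = width_px * height_px * pixel_size**2 / 1e6
    n_cells = max(1, int(round(total * area_mm2)))
    g3 = pct / 100.0
    rest = 1.0 - g3
    mix = {"G1": 0.35 * rest, "G2": 0.15 * rest, "G3": g3, "Other": 0.50 * rest}
    spec = TileSpec(
        width_px=width_px,
        height_px=height_px,
        pixel_size=pixel_size,
        n_cells=n_cells,
        class_mix=mix,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return make_tile(spec)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

_DEFAULT_MEDIANS = {
    "G3+/O-": 804.0,
    "G3+/O+": 2400.0,
    "G3-/O-": 1062.5,
    "G3-/O+": 2600.0,
}

_DEFAULT_DENSITY_PARAMS = {
    "G3+/O-": {"g3": (1400.0, 400.0), "other": (3300.0, 450.0)},
    "G3+/O+": {"g3": (1300.0, 400.0), "other": (5700.0, 700.0)},
    "G3-/O-": {"g3": (250.0, 140.0), "other": (3400.0, 450.0)},
    "G3-/O+": {"g3": (300.0, 150.0), "other": (6200.0, 700.0)},
}

#: grade distribution over (2, 3, 4) per quadrant; high-%G3 / dystrophic
#: quadrants skew toward higher expert grade.
_DEFAULT_GRADE_PROBS = {
    "G3+/O-": (0.20, 0.50, 0.30),
    "G3+/O+": (0.55, 0.30, 0.15),
    "G3-/O-": (0.50, 0.20, 0.30),
    "G3-/O+": (0.80, 0.10, 0.10),
}


def default_hazards() -> dict:
    """Exponential hazards calibrated so medians ln2/lambda match presets."""
    return {q: math.log(2.0) / m for q, m in _DEFAULT_MEDIANS.items()}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic patient cohort."""

    n_samples: int = 70
    quadrant_mix: dict = field(
        default_factory=lambda: {q: 0.25 for q in QUADRANTS}
    )
    density_params: dict = field(default_factory=lambda: dict(_DEFAULT_DENSITY_PARAMS))
    hazard_per_quadrant: dict = field(default_factory=default_hazards)
    censor_time: float = 1825.0  # 5 years
    cuts: tuple = (533.0, 4133.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        mix = [self.quadrant_mix.get(q, 0.0) for q in QUADRANTS]
        if any(m < 0 for m in mix) or abs(sum(mix) - 1.0) > 1e-9:
            raise ValueError("quadrant_mix must be non-negative and sum to 1")
        for q in QUADRANTS:
            if self.quadrant_mix.get(q, 0.0) > 0 and self.hazard_per_quadrant[q] <= 0:
                raise ValueError("hazards must be > 0")
        if self.censor_time <= 0:
            raise ValueError("censor_time must be > 0")


def _quadrant_counts(mix: dict, n: int) -> dict:
    props = np.array([mix.get(q, 0.0) for q in QUADRANTS])
    exact = props * n
    base = np.floor(exact).astype(int)
    order = np.argsort(-(exact - base), kind="stable")
    for i in order[: n - int(base.sum())]:
        base[i] += 1
    return {q: int(k) for q, k in zip(QUADRANTS, base)}


def _draw_density_in_region(rng, mean, sd, lo, hi):
    for _ in range(200):
        x = rng.normal(mean, sd)
        if lo < x <= hi:
            return float(x)
    return float(np.clip(rng.normal(mean, sd), lo + 1e-6, hi))


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a cohort as a DataFrame.

    Columns: sample_id, grade, dens_g3, dens_other, quadrant, time_days,
    event.  Densities are drawn inside each sample's quadrant region so
    downstream threshold assignment round-trips; survival is exponential
    with the quadrant hazard, right-censored at ``censor_time``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    counts = _quadrant_counts(spec.quadrant_mix, spec.n_samples)
    cut_g3, cut_other = spec.cuts
    rows = []
    sid = 0
    for q in QUADRANTS:
        g3_pos = q.startswith("G3+")
        o_pos = q.endswith("O+")
        pg3 = spec.density_params[q]["g3"]
        pot = spec.density_params[q]["other"]
        lam = spec.hazard_per_quadrant[q]
        gp = _DEFAULT_GRADE_PROBS[q]
        for _ in range(counts[q]):
            sid += 1
            dens_g3 = _draw_density_in_region(
                rng, pg3[0], pg3[1],
                cut_g3 if g3_pos else -1e-9,
                np.inf if g3_pos else cut_g3,
            )
            dens_other = _draw_density_in_region(
                rng, pot[0], pot[1],
                cut_other if o_pos else -1e-9,
                np.inf if o_pos else cut_other,
            )
            grade = int(rng.choice((2, 3, 4), p=gp))
            t_event = rng.exponential(1.0 / lam)
            event = int(t_event <= spec.censor_time)
            t = min(t_event, spec.censor_time)
            rows.append(
                (f"S{sid:04d}", grade, max(dens_g3, 0.0), max(dens_other, 0.0),
                 q, max(t, 1e-6), event)
            )
    df = pd.DataFrame(
        rows,
        columns=["sample_id", "grade", "dens_g3", "dens_other", "quadrant",
                 "time_days", "event"],
    )
    return df


def make_grade_profiles(n_per_grade: int, seed: int, *, grades=(1, 2, 3, 4)) -> pd.DataFrame:
    """Per-sample ROI profiles with expert grades, from pattern presets.

    Grades 1-2 draw %G3 from the monomorphic preset, grades 3-4 from the
    nucleolar preset (the presets whose %G3 separates low from high grade).
    Returns columns sample_id, grade, pct_g3, dens_g3, dens_other.
    """
    rng = np.random.default_rng(seed)
    grade_pattern = {1: "monomorphic", 2: "monomorphic", 3: "nucleolar", 4: "nucleolar"}
    rows = []
    sid = 0
    for g in grades:
        for _ in range(n_per_grade):
            sid += 1
            pct, total = draw_pattern_params(grade_pattern[g], rng)
            dens_g3 = total * pct / 100.0
            rows.append((f"P{sid:04d}", g, pct, dens_g3, total - dens_g3))
    return pd.DataFrame(
        rows, columns=["sample_id", "grade", "pct_g3", "dens_g3", "dens_other"]
    )
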