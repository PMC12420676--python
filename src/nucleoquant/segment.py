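"""Star-convex polygon instance segmentation of nuclei.

The stage that a trained network would provide is replaced by a
deterministic classical computation: per-pixel object probability is the
smoothed nuclear-stain darkness, and per-pixel radial distances are ray-cast
on the thresholded foreground.  Candidates (one polygon per foreground
pixel, optionally grid-subsampled) are reduced by greedy IoU non-maximum
suppression and rasterized to a label mask.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.ndimage import gaussian_filter
from shapely.geometry import Polygon as ShapelyPolygon

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentationParams:
    n_rays: int = 32
    prob_threshold: float = 0.5
    iou_threshold: float = 0.5
    stride: int = 2  # candidate grid stride in px
    smooth_sigma: float = 1.0
    max_radius_px: int = 40

    def validate(self) -> None:
        if self.n_rays < 3:
            raise ValueError("n_rays must be >= 3")
        if not (0.0 < self.prob_threshold < 1.0):
            raise ValueError("prob_threshold must be in (0, 1)")
        if not (0.0 < self.iou_threshold < 1.0):
            raise ValueError("iou_threshold must be in (0, 1)")


@dataclass
class ProbDistMaps:
    """Per-pixel object probability and radial distances along fixed rays.

    Ray k points at angle 2*pi*k/n_rays, angle 0 = +x, measured toward +y
    (image convention, y = row).
    """

    prob: np.ndarray  # (H, W) float32 in [0, 1]
    dist: np.ndarray  # (H, W, n_rays) float32, px; 0 where not computed
    n_rays: int


@dataclass(eq=False)
class NucleusInstance:
    """One candidate or accepted nucleus in pixel coordinates."""

    center: tuple  # (x, y) px
    radii: np.ndarray  # (n_rays,) px, all > 0
    score: float
    id: int = 0
    _polygon: object = field(default=None, repr=False, compare=False)

    @property
    def polygon(self) -> np.ndarray:
        """Vertex array (n_rays, 2): center + r_k * (cos, sin)(2*pi*k/n)."""
        return polygon_from_rays(self.center, self.radii)

    @property
    def shapely(self):
        if self._polygon is None:
            poly = ShapelyPolygon(self.polygon)
            if not poly.is_valid:
                poly = poly.buffer(0)
            self._polygon = poly
        return self._polygon


def ray_angles(n_rays: int) -> np.ndarray:
    return 2.0 * np.pi * np.arange(n_rays) / n_rays


def polygon_from_rays(center, radii, n_rays: int | None = None) -> np.ndarray:
    """Vertices of the star-convex polygon defined by radial distances."""
    radii = np.asarray(radii, dtype=float)
    if n_rays is not None and len(radii) != n_rays:
        raise ValueError("radii length must equal n_rays")
    if np.any(radii <= 0):
        raise ValueError("all radii must be > 0")
    ang = ray_angles(len(radii))
    cx, cy = center
    return np.column_stack([cx + radii * np.cos(ang), cy + radii * np.sin(ang)])


def polygon_iou(a, b) -> float:
    """Exact intersection-over-union of two simple polygons (0 on degenerate)."""
    pa = a if hasattr(a, "intersection") else ShapelyPolygon(np.asarray(a))
    pb = b if hasattr(b, "intersection") else ShapelyPolygon(np.asarray(b))
    if not pa.is_valid:
        pa = pa.buffer(0)
    if not pb.is_valid:
        pb = pb.buffer(0)
    if pa.area == 0.0 or pb.area == 0.0:
        return 0.0
    inter = pa.intersection(pb).area
    union = pa.area + pb.area - inter
    if union <= 0.0:
        return 0.0
    return float(inter / union)


def compute_maps(image: np.ndarray, params: SegmentationParams) -> ProbDistMaps:
    """Probability and radial-distance maps for an RGB tile.

    prob = Gaussian-smoothed darkness (1 - mean RGB / 255); dist is computed
    by ray casting on the foreground prob >= prob_threshold, only at
    foreground pixels (0 elsewhere).
    """
    params.validate()
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    darkness = 1.0 - image.astype(np.float32).mean(axis=2) / 255.0
    prob = gaussian_filter(darkness, params.smooth_sigma)
    np.clip(prob, 0.0, 1.0, out=prob)

    H, W = prob.shape
    fg = prob >= params.prob_threshold
    dist = np.zeros((H, W, params.n_rays), dtype=np.float32)
    ys, xs = np.nonzero(fg)
    if len(ys) == 0:
        return ProbDistMaps(prob=prob.astype(np.float32), dist=dist, n_rays=params.n_rays)

    steps = np.arange(1, params.max_radius_px + 1)
    for k, ang in enumerate(ray_angles(params.n_rays)):
        dy = np.rint(steps * np.sin(ang)).astype(np.intp)
        dx = np.rint(steps * np.cos(ang)).astype(np.intp)
        alive = np.ones(len(ys), dtype=bool)  # still inside foreground
        radius = np.full(len(ys), params.max_radius_px, dtype=np.float32)
        for si, s in enumerate(steps):
            yy = ys + dy[si]
            xx = xs + dx[si]
            inside = (yy >= 0) & (yy < H) & (xx >= 0) & (xx < W)
            ok = np.zeros(len(ys), dtype=bool)
            ok[inside] = fg[yy[inside], xx[inside]]
            newly_out = alive & ~ok
            radius[newly_out] = s - 0.5
            alive &= ok
            if not alive.any():
                break
        dist[ys, xs, k] = radius
    return ProbDistMaps(prob=prob.astype(np.float32), dist=dist, n_rays=params.n_rays)


def candidates(
    maps: ProbDistMaps, prob_threshold: float, stride: int = 1
) -> list[NucleusInstance]:
    """One polygon candidate per (grid-subsampled) pixel above threshold.

    Sorted by score descending, ties broken by (row, column) scan order.
    Pixels whose distance vector was not computed (any ray 0) are skipped.
    """
    if not (0.0 < prob_threshold < 1.0):
        raise ValueError("prob_threshold must be in (0, 1)")
    sel = maps.prob >= prob_threshold
    if stride > 1:
        grid = np.zeros_like(sel)
        grid[::stride, ::stride] = True
        sel &= grid
    sel &= (maps.dist > 0).all(axis=2)
    ys, xs = np.nonzero(sel)
    scores = maps.prob[ys, xs]
    order = np.lexsort((xs, ys, -scores))
    return [
        NucleusInstance(
            center=(int(xs[i]), int(ys[i])),
            radii=maps.dist[ys[i], xs[i]].astype(float),
            score=float(scores[i]),
        )
        for i in order
    ]


def nms(cands: list[NucleusInstance], iou_threshold: float) -> list[NucleusInstance]:
    """Greedy non-maximum suppression on score-sorted candidates.

    Accepts the highest-score candidate, suppresses every candidate whose
    IoU with an already accepted instance exceeds ``iou_threshold``.  Uses a
    spatial hash on centers so only plausible overlaps are clipped exactly.
    """
    if not (0.0 < iou_threshold < 1.0):
        raise ValueError("iou_threshold must be in (0, 1)")
    if not cands:
        return []
    rmax = max(float(np.max(c.radii)) for c in cands)
    cell = max(2.0 * rmax, 1.0)
    grid: dict = {}
    accepted: list[NucleusInstance] = []
    for cand in cands:
        cx, cy = cand.center
        gx, gy = int(cx // cell), int(cy // cell)
        r_cand = float(np.max(cand.radii))
        keep = True
        for dgx in (-1, 0, 1):
            for dgy in (-1, 0, 1):
                for j in grid.get((gx + dgx, gy + dgy), ()):
                    acc = accepted[j]
                    ax, ay = acc.center
                    reach = r_cand + float(np.max(acc.radii))
                    if (ax - cx) ** 2 + (ay - cy) ** 2 > reach * reach:
                        continue
                    if polygon_iou(cand.shapely, acc.shapely) > iou_threshold:
                        keep = False
                        break
                if not keep:
                    break
            if not keep:
                break
        if keep:
            grid.setdefault((gx, gy), []).append(len(accepted))
            accepted.append(cand)
    return accepted


def rasterize(instances: list[NucleusInstance], shape: tuple) -> np.ndarray:
    """Label image: each pixel gets the highest-score covering instance.

    Instance ids are 1..K in score order (1 = best).  Pixel membership is
    by pixel-center inclusion; instances fully outside the frame are dropped
    with a warning.
    """
    H, W = shape
    out = np.zeros((H, W), dtype=np.int32)
    ranked = sorted(instances, key=lambda c: -c.score)
    for rank, inst in enumerate(ranked, start=1):
        inst.id = rank
    # Paint lowest score first so higher scores overwrite.
    for inst in reversed(ranked):
        verts = inst.polygon
        j0 = max(0, int(np.floor(verts[:, 0].min())))
        j1 = min(W - 1, int(np.ceil(verts[:, 0].max())))
        i0 = max(0, int(np.floor(verts[:, 1].min())))
        i1 = min(H - 1, int(np.ceil(verts[:, 1].max())))
        if j1 < j0 or i1 < i0:
            log.warning("instance %d fully outside image; dropped", inst.id)
            continue
        jj, ii = np.meshgrid(
            np.arange(j0, j1 + 1, dtype=float), np.arange(i0, i1 + 1, dtype=float)
        )
        inside = shapely.contains_xy(inst.shapely, jj.ravel(), ii.ravel()).reshape(jj.shape)
        if not inside.any():
            log.warning("instance %d covers no pixel centers; dropped", inst.id)
            continue
        out[i0 : i1 + 1, j0 : j1 + 1][inside] = inst.id
    return out


def segment_tile(image: np.ndarray, params: SegmentationParams | None = None):
    """Full stage: maps -> candidates -> NMS -> label mask.

    Returns (instances, label_mask) with instance ids matching the mask.
    """
    params = params or SegmentationParams()
    maps = compute_maps(image, params)
    cands = candidates(maps, params.prob_threshold, stride=params.stride)
    kept = nms(cands, params.iou_threshold)
    mask = rasterize(kept, maps.prob.shape)
    return kept, mask


def match_instances(gt_mask: np.ndarray, pred_mask: np.ndarray, iou: float = 0.5):
    """Greedy one-to-one matching of label masks at an IoU threshold.

    Returns dict with n_gt, n_pred, n_matched and the list of
    (gt_id, pred_id, iou) matches.  Used for segmentation-recovery checks.
    """
    gt = np.asarray(gt_mask).ravel()
    pr = np.asarray(pred_mask).ravel()
    n_gt = int(gt.max())
    n_pred = int(pr.max())
    if n_gt == 0 or n_pred == 0:
        return {"n_gt": n_gt, "n_pred": n_pred, "n_matched": 0, "matches": []}
    joint = np.zeros((n_gt + 1, n_pred + 1), dtype=np.int64)
    np.add.at(joint, (gt, pr), 1)
    areas_gt = joint.sum(axis=1)
    areas_pr = joint.sum(axis=0)
    inter = joint[1:, 1:].astype(float)
    union = areas_gt[1:, None] + areas_pr[None, 1:] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        iou_mat = np.where(union > 0, inter / union, 0.0)
    matches = []
    used_gt = np.zeros(n_gt, dtype=bool)
    used_pr = np.zeros(n_pred, dtype=bool)
    order = np.argsort(-iou_mat, axis=None)
    for flat in order:
        g, p = divmod(flat, n_pred)
        if iou_mat[g, p] < iou:
            break
        if used_gt[g] or used_pr[p]:
            continue
        used_gt[g] = used_pr[p] = True
        matches.append((int(g + 1), int(p + 1), float(iou_mat[g, p])))
    return {
        "n_gt": n_gt,
        "n_pred": n_pred,
        "n_matched": len(matches),
        "matches": matches,
    }
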